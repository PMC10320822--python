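"""Areas of interest (AOIs) for 3x3 matrix-completion displays.

The display is partitioned into ten axis-aligned rectangles: the nine matrix
cells, numbered 1-9 in row-major order (1-3 across the top row, so 1/4/7 form
the left column), and the solution array as AOI 10.  Coordinates use the
screen convention: origin at the top-left corner, y increasing downward,
pixel units.  Rectangles are half-open, ``[x0, x1) x [y0, y1)``, so shared
edges cannot produce double containment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

MATRIX_AOIS = tuple(range(1, 10))
ARRAY_AOI = 10
#: cells of the first rows/columns vs the last row and column; used by the
#: matrix-time-distribution index
EARLY_CELLS = (1, 2, 4, 5)
LATE_CELLS = (3, 6, 7, 8, 9)

Rect = tuple[float, float, float, float]


@dataclass(frozen=True)
class AOILayout:
    """Ten named rectangles: matrix cells 1-9 plus the solution array (10).

    Parameters
    ----------
    rects
        Mapping from AOI label (1-10) to ``(x0, y0, x1, y1)`` in pixels.
    margin
        Tolerance in pixels added around every rectangle when a point falls
        outside all of them.  If the expanded rectangles of several AOIs
        contain the point, the one whose center is nearest wins
        (deterministic tie-break).
    """

    rects: dict[int, Rect]
    margin: float = 0.0

    def __post_init__(self) -> None:
        labels = sorted(self.rects)
        if labels != list(range(1, 11)):
            raise ValueError(f"layout must define AOIs 1..10, got {labels}")
        for lab, (x0, y0, x1, y1) in self.rects.items():
            if not (x1 > x0 and y1 > y0):
                raise ValueError(f"degenerate rectangle for AOI {lab}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        for a in MATRIX_AOIS:
            for b in MATRIX_AOIS:
                if a < b and _overlap(self.rects[a], self.rects[b]):
                    raise ValueError(f"matrix AOIs {a} and {b} overlap")

    @property
    def centers(self) -> np.ndarray:
        """(10, 2) array of rectangle centers, row ``i`` = AOI ``i + 1``."""
        return np.array(
            [
                ((r[0] + r[2]) / 2.0, (r[1] + r[3]) / 2.0)
                for _, r in sorted(self.rects.items())
            ]
        )

    def assign(self, x: float, y: float) -> int:
        """AOI label containing ``(x, y)``, or 0 if outside all AOIs."""
        for lab, (x0, y0, x1, y1) in self.rects.items():
            if x0 <= x < x1 and y0 <= y < y1:
                return lab
        if self.margin > 0:
            m = self.margin
            hits = [
                lab
                for lab, (x0, y0, x1, y1) in self.rects.items()
                if x0 - m <= x < x1 + m and y0 - m <= y < y1 + m
            ]
            if len(hits) == 1:
                return hits[0]
            if hits:
                c = self.centers
                d2 = [
                    (x - c[lab - 1, 0]) ** 2 + (y - c[lab - 1, 1]) ** 2
                    for lab in hits
                ]
                return hits[int(np.argmin(d2))]
        return 0

    def assign_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`assign`; returns int array, 0 = outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(x.shape, dtype=np.int64)
        for lab, (x0, y0, x1, y1) in self.rects.items():
            inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
            out[inside & (out == 0)] = lab
        if self.margin > 0:
            miss = out == 0
            if miss.any():
                xm, ym = x[miss], y[miss]
                res = np.array([self.assign(xi, yi) for xi, yi in zip(xm, ym)])
                out[miss] = res
        return out

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "margin": float(self.margin),
            "aois": {int(k): [float(v) for v in r] for k, r in self.rects.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AOILayout":
        rects = {int(k): tuple(map(float, v)) for k, v in d["aois"].items()}
        return cls(rects=rects, margin=float(d.get("margin", 0.0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "AOILayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _overlap(a: Rect, b: Rect) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def default_layout(margin: float = 0.0) -> AOILayout:
    """Layout for a 1280x1024 display: 3x3 matrix of 140 px cells with 20 px
    gaps in the upper half, solution-array strip along the bottom."""
    rects: dict[int, Rect] = {}
    for r in range(3):
        for c in range(3):
            x0 = 280.0 + 160.0 * c
            y0 = 100.0 + 160.0 * r
            rects[1 + 3 * r + c] = (x0, y0, x0 + 140.0, y0 + 140.0)
    rects[ARRAY_AOI] = (160.0, 660.0, 1120.0, 880.0)
    return AOILayout(rects=rects, margin=margin)
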