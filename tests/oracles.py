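"""Brute-force reference implementations of the sequence detectors.

Deliberately naive: explicit loops over every window / adjacent pair, used
to cross-check the vectorised detectors on random sequences.
"""

ROWS = [{1, 2, 3}, {4, 5, 6}, {7, 8, 9}]
COLS = [{1, 4, 7}, {2, 5, 8}, {3, 6, 9}]


def brute_encoding(seq, order_strict=False):
    row = col = False
    for i in range(len(seq) - 2):
        w = list(seq[i : i + 3])
        if any(v is None or v == 0 or v == 10 for v in w):
            continue
        if len(set(w)) != 3:
            continue
        if order_strict and not (w[0] < w[1] < w[2]):
            continue
        if set(w) in ROWS:
            row = True
        if set(w) in COLS:
            col = True
    return row, col


def brute_integration(seq, order_strict=False):
    r, c = brute_encoding(seq, order_strict)
    return r and c


def brute_toggles(seq):
    filtered = [v for v in seq if v not in (None, 0)]
    collapsed = []
    for v in filtered:
        if not collapsed or collapsed[-1] != v:
            collapsed.append(v)
    n = 0
    for a, b in zip(collapsed, collapsed[1:]):
        if (a == 10) != (b == 10):
            n += 1
    return n
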