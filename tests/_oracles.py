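"""Independent brute-force oracles used to validate production code paths.

These deliberately avoid the libraries the implementation uses (edlib):
the edit distance is the textbook full-matrix dynamic program, and the
RLE oracle is a character-by-character scan.
"""

from itertools import groupby

import numpy as np


def edit_distance_dp(a: str, b: str) -> int:
    """Full-matrix unit-cost Levenshtein distance (quadratic DP)."""
    n, m = len(a), len(b)
    prev = np.arange(m + 1)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    for i, ch in enumerate(a.encode(), start=1):
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (bv != ch)
        dele = prev[1:] + 1
        cand = np.minimum(sub, dele)
        # insertions need a sequential pass
        running = cur[0]
        for j in range(m):
            running = min(cand[j], running + 1)
            cur[j + 1] = running
        prev = cur
    return int(prev[m])


def rle_oracle(seq: str) -> str:
    out = []
    for ch in seq:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def max_run_oracle(seq: str) -> int:
    return max((sum(1 for _ in g) for _, g in groupby(seq)), default=0)
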