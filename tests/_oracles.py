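"""Independent reference implementations used only to check the package.

These are deliberately plain-Python, written from the definitions (not
from the package source), and kept quadratic/simple: an affine-gap
Smith–Waterman with the same stated conventions (gap of length L costs
open + (L-1)*extend; ties broken diagonal > up > left; traceback from
the first maximal cell in row-major order), and a sort-and-interpolate
percentile.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_affine(query: str, target: str, match=2, mismatch=-3, gap_open=-5,
              gap_extend=-2):
    """Optimal local alignment score and path.

    Returns (score, path) where path is a list of (qpos | None, tpos | None)
    pairs, 0-based.
    """
    n, m = len(query), len(target)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (up)
    ph = [[0] * (m + 1) for _ in range(n + 1)]
    pe = [[0] * (m + 1) for _ in range(n + 1)]
    pf = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        for j in range(1, m + 1):
            eo, ee = H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend
            if eo >= ee:
                E[i][j], pe[i][j] = eo, 1
            else:
                E[i][j] = ee
            fo, fe = H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend
            if fo >= fe:
                F[i][j], pf[i][j] = fo, 1
            else:
                F[i][j] = fe
            tc = target[j - 1]
            s = match if (qc == tc and qc != "N") else mismatch
            d = H[i - 1][j - 1] + s
            h, p = 0.0, 0
            if d > h:
                h, p = d, 1
            if F[i][j] > h:
                h, p = F[i][j], 2
            if E[i][j] > h:
                h, p = E[i][j], 3
            H[i][j], ph[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    path = []
    i, j, state = bi, bj, 0
    while True:
        if state == 0:
            p = ph[i][j]
            if p == 0:
                break
            if p == 1:
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            else:
                state = p
        elif state == 2:
            path.append((i - 1, None))
            opened = pf[i][j]
            i -= 1
            if opened:
                state = 0
        else:
            path.append((None, j - 1))
            opened = pe[i][j]
            j -= 1
            if opened:
                state = 0
    path.reverse()
    return best, path


def percentile_interpolated(values, q):
    """q-th percentile with linear interpolation between order statistics."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    if len(xs) == 1:
        return xs[0]
    h = (len(xs) - 1) * q / 100.0
    lo = int(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
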