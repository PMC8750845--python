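"""Pairwise local alignment and per-read genotyping at informative sites.

Two alignment engines share one result type:

* ``exact`` — an affine-gap Smith–Waterman with a fixed, documented
  tie-breaking order (diagonal > up > left > stop), so that optimal
  alignments are bit-reproducible.  Used for the paralog-pair alignment
  and as the reference engine in validation.
* ``fast`` — an edit-distance infix alignment (edlib) whose path is
  re-scored under the Smith–Waterman scoring scheme and trimmed to its
  best-scoring contiguous segment.  Used for per-read work, where
  thousands of multi-kilobase alignments are needed.

Scoring convention: a gap of length L costs ``gap_open + (L-1) * gap_extend``
(both penalties are negative numbers; the first gapped base pays the open
penalty).  This matches the convention of Biopython's ``PairwiseAligner``
``open_gap_score`` / ``extend_gap_score`` pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from numba import njit

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte codes used in per-target-position base maps
GAP = ord("-")
UNCOVERED = 0


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Smith–Waterman scoring parameters.

    match is positive; mismatch, gap_open and gap_extend are the (negative)
    scores applied per event, with gap_open charged for the first base of a
    gap and gap_extend for each subsequent base.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch/gap penalties must be <= 0")


@dataclass
class Alignment:
    """A local alignment of ``query`` against ``target``.

    ``path`` is a pair of int32 arrays (query index, target index) with -1
    marking a gap on that side; indices are 0-based and strictly increasing
    on each side.
    """

    score: float
    query_start: int
    query_end: int  # half-open
    target_start: int
    target_end: int  # half-open
    path_q: np.ndarray
    path_t: np.ndarray

    def target_base_map(self, query: str, target_len: int) -> np.ndarray:
        """Byte array over target positions: read base aligned to each
        position, ``GAP`` for a deletion, ``UNCOVERED`` outside the span."""
        out = np.zeros(target_len, dtype=np.uint8)
        qb = np.frombuffer(query.encode(), dtype=np.uint8)
        t_idx = self.path_t
        q_idx = self.path_q
        sel = t_idx >= 0
        tpos = t_idx[sel]
        qpos = q_idx[sel]
        vals = np.where(qpos >= 0, qb[np.clip(qpos, 0, None)], GAP).astype(np.uint8)
        out[tpos] = vals
        return out


# ---------------------------------------------------------------------------
# exact engine
# ---------------------------------------------------------------------------

_ENC = np.full(256, 15, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
_ENC[ord("N")] = 14  # N mismatches everything, including N


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    neg = -(10**8)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in query (left)
    F = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in target (up)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop 1 diag 2 up 3 left
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = opened from H
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptr_e[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptr_f[i, j] = 1
            else:
                F[i, j] = fe
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            d = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return ptr_h, ptr_e, ptr_f, best, bi, bj


def local_align(query: str, target: str, params: AlignParams | None = None) -> Alignment:
    """Optimal affine-gap Smith–Waterman local alignment (exact engine).

    Ties are broken diagonal > up > left, gap-open preferred over
    gap-extend, and the traceback starts from the first maximal cell in
    row-major order, so the result is deterministic.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    params = params or AlignParams()
    a = encode(query)
    b = encode(target)
    ptr_h, ptr_e, ptr_f, best, bi, bj = _sw_fill(
        a, b, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    # traceback
    pq: list[int] = []
    pt: list[int] = []
    i, j = bi, bj
    state = 0  # 0 = H, 2 = F chain, 3 = E chain
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                pq.append(i - 1)
                pt.append(j - 1)
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:  # up: consume query base against gap
            pq.append(i - 1)
            pt.append(-1)
            opened = ptr_f[i, j]
            i -= 1
            if opened:
                state = 0
        else:  # left: consume target base against gap
            pq.append(-1)
            pt.append(j - 1)
            opened = ptr_e[i, j]
            j -= 1
            if opened:
                state = 0
    pq.reverse()
    pt.reverse()
    path_q = np.array(pq, dtype=np.int32)
    path_t = np.array(pt, dtype=np.int32)
    return Alignment(
        score=float(best),
        query_start=i,
        query_end=bi,
        target_start=j,
        target_end=bj,
        path_q=path_q,
        path_t=path_t,
    )


# ---------------------------------------------------------------------------
# fast engine
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@njit(cache=True)
def _best_segment(scores):
    """Kadane: (best_sum, start, end) of the max-sum contiguous segment."""
    best = 0.0
    bs = 0
    be = 0
    cur = 0.0
    cs = 0
    for i in range(scores.shape[0]):
        if cur <= 0.0:
            cur = scores[i]
            cs = i
        else:
            cur += scores[i]
        if cur > best:
            best = cur
            bs = cs
            be = i + 1
    return best, bs, be


def fast_infix_align(query: str, target: str, params: AlignParams | None = None) -> Alignment:
    """Approximate local alignment via edit-distance infix alignment.

    The whole query is aligned inside the target (edlib ``HW`` mode); the
    resulting path is re-scored under ``params`` and trimmed to its
    best-scoring contiguous segment, which emulates local-alignment end
    clipping.  The score is a lower bound on the exact Smith–Waterman
    score; for reads within ~15% divergence of the target the two agree
    closely (validated against the exact engine in the test suite).
    """
    params = params or AlignParams()
    res = edlib.align(query, target, mode="HW", task="path")
    loc = res["locations"][0]
    t0 = loc[0]
    qb = np.frombuffer(query.encode(), dtype=np.uint8)
    tb = np.frombuffer(target.encode(), dtype=np.uint8)

    # expand cigar into per-step arrays (vectorised: 0 = aligned pair,
    # 1 = query-only step, 2 = target-only step)
    parsed = _CIGAR_RE.findall(res["cigar"])
    if not parsed:
        return Alignment(0.0, 0, 0, 0, 0, np.empty(0, np.int32), np.empty(0, np.int32))
    lens = np.array([int(n) for n, _ in parsed])
    codes = np.array([0 if op in "=XM" else (1 if op == "I" else 2)
                      for _, op in parsed], dtype=np.int8)
    op_codes = np.repeat(codes, lens)
    n_steps = op_codes.size
    q_cons = op_codes != 2
    t_cons = op_codes != 1
    path_q = np.where(q_cons, np.cumsum(q_cons) - 1, -1).astype(np.int32)
    path_t = np.where(t_cons, t0 + np.cumsum(t_cons) - 1, -1).astype(np.int32)

    scores = np.full(n_steps, float(params.gap_extend))
    first_of_run = np.ones(n_steps, dtype=bool)
    first_of_run[1:] = op_codes[1:] != op_codes[:-1]
    scores[first_of_run & (op_codes != 0)] = params.gap_open
    aligned = op_codes == 0
    qa = qb[path_q[aligned]]
    eq = (qa == tb[path_t[aligned]]) & (qa != ord("N"))
    scores[aligned] = np.where(eq, params.match, params.mismatch)

    best, s, e = _best_segment(scores)
    path_q = path_q[s:e]
    path_t = path_t[s:e]
    qcov = path_q[path_q >= 0]
    tcov = path_t[path_t >= 0]
    if qcov.size == 0 or tcov.size == 0:
        return Alignment(0.0, 0, 0, 0, 0, np.empty(0, np.int32), np.empty(0, np.int32))
    return Alignment(
        score=float(best),
        query_start=int(qcov[0]),
        query_end=int(qcov[-1]) + 1,
        target_start=int(tcov[0]),
        target_end=int(tcov[-1]) + 1,
        path_q=path_q,
        path_t=path_t,
    )


_ENGINES = {"exact": local_align, "fast": fast_infix_align}


def align_read(query: str, target: str, params: AlignParams | None = None,
               engine: str = "fast") -> Alignment:
    try:
        fn = _ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown alignment engine: {engine!r}") from None
    return fn(query, target, params)


def edit_distance(query: str, target: str) -> int:
    """Infix edit distance of query inside target (orientation scoring)."""
    return edlib.align(query, target, mode="HW", task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# per-read genotyping at catalog sites
# ---------------------------------------------------------------------------

# observation codes for discriminating units
OBS_A = 0
OBS_B = 1
OBS_NEITHER = 2
OBS_UNCOVERED = 3

# observation codes for ambiguous sites
AMB_MATCH = 0
AMB_MISMATCH = 1
AMB_UNCOVERED = 2


@dataclass
class ReadSiteCalls:
    """Per-read observations at every catalog site.

    ``disc_obs[i]`` is the observation code for the i-th discriminating
    unit of the catalog (OBS_A / OBS_B / OBS_NEITHER / OBS_UNCOVERED);
    ``amb_obs[i]`` likewise for the i-th unmasked ambiguous site.
    """

    read_id: str
    orientation: str  # "+" or "-"
    score_a: float
    score_b: float
    disc_obs: np.ndarray = field(repr=False)
    amb_obs: np.ndarray = field(repr=False)

    @property
    def best_score(self) -> float:
        return max(self.score_a, self.score_b)


def _orient(seq: str, pair) -> tuple[str, str]:
    """Pick read orientation by the lower combined infix edit distance
    against the two paralogs (ties prefer forward)."""
    rc = revcomp(seq)
    fwd = edit_distance(seq, pair.seq_a) + edit_distance(seq, pair.seq_b)
    rev = edit_distance(rc, pair.seq_a) + edit_distance(rc, pair.seq_b)
    if rev < fwd:
        return rc, "-"
    return seq, "+"


def genotype_read(read, pair, catalog, params: AlignParams | None = None,
                  engine: str = "fast") -> ReadSiteCalls:
    """Align one read to both paralogs and record its base at every
    catalog site.

    Orientation is chosen by the best combined score against the two
    paralogs.  Each discriminating unit is read off the alignment to its
    host paralog (units with bases in gene A from the A-alignment;
    insertion-type units whose bases exist only in gene B from the
    B-alignment) and classified as matching A, matching B, or neither —
    the latter are treated downstream as sequencing/PCR errors.  Ambiguous
    sites are read off the A-alignment.
    """
    params = params or AlignParams()
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    rid = getattr(read, "id", "read")
    oriented, orientation = _orient(seq, pair)

    aln_a = align_read(oriented, pair.seq_a, params, engine)
    aln_b = align_read(oriented, pair.seq_b, params, engine)
    map_a = aln_a.target_base_map(oriented, len(pair.seq_a))
    map_b = aln_b.target_base_map(oriented, len(pair.seq_b))

    units = catalog.disc_units
    disc = np.full(len(units), OBS_UNCOVERED, dtype=np.int8)

    # vectorised path for substitution-type units (the common case): read
    # the site from both alignments and reconcile — a definite call from
    # either alignment wins, but contradictory definite calls are treated
    # as errors (matches_neither)
    sub_ix = catalog._sub_unit_index
    if sub_ix.size:
        def classify(obs, base_a, base_b):
            code = np.full(obs.size, OBS_NEITHER, dtype=np.int8)
            code[obs == base_a] = OBS_A
            code[obs == base_b] = OBS_B
            code[(obs == UNCOVERED) | (obs == GAP)] = OBS_UNCOVERED
            return code

        ca = classify(map_a[catalog._sub_pos_a],
                      catalog._sub_base_a, catalog._sub_base_b)
        cb = classify(map_b[catalog._sub_pos_b],
                      catalog._sub_base_a, catalog._sub_base_b)
        code = np.where(ca != OBS_UNCOVERED, ca, cb)
        def_a = np.isin(ca, (OBS_A, OBS_B))
        def_b = np.isin(cb, (OBS_A, OBS_B))
        code[def_b & ~def_a] = cb[def_b & ~def_a]
        code[def_a & def_b & (ca != cb)] = OBS_NEITHER
        disc[sub_ix] = code

    for k in catalog._indel_unit_index:
        u = units[k]
        if u.bases_a:  # bases present in A, absent in B (deletion in B)
            seg = map_a[u.pos_a: u.pos_a + len(u.bases_a)]
            ref = np.frombuffer(u.bases_a.encode(), dtype=np.uint8)
        else:  # bases present only in B (insertion in B)
            seg = map_b[u.pos_b: u.pos_b + len(u.bases_b)]
            ref = np.frombuffer(u.bases_b.encode(), dtype=np.uint8)
        if np.any(seg == UNCOVERED):
            disc[k] = OBS_UNCOVERED
        elif np.array_equal(seg, ref):
            disc[k] = OBS_A if u.bases_a else OBS_B
        elif np.all(seg == GAP):
            disc[k] = OBS_B if u.bases_a else OBS_A
        else:
            disc[k] = OBS_NEITHER

    amb_pos = catalog._amb_pos_a
    amb_base = catalog._amb_base
    obs = map_a[amb_pos] if amb_pos.size else np.empty(0, dtype=np.uint8)
    amb = np.full(amb_pos.size, AMB_MISMATCH, dtype=np.int8)
    amb[obs == amb_base] = AMB_MATCH
    amb[(obs == UNCOVERED) | (obs == GAP)] = AMB_UNCOVERED

    return ReadSiteCalls(
        read_id=rid,
        orientation=orientation,
        score_a=aln_a.score,
        score_b=aln_b.score,
        disc_obs=disc,
        amb_obs=amb,
    )
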