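"""Synthetic paralog pairs, chimeric templates and nanopore-like reads.

The generator emulates the study design end to end: a ~4 kb pair of
paralogs at ~94% identity (matching the similarity of the CYP11B1/CYP11B2
crossover region), a chimeric amplicon template joining the 5' part of
gene A to the 3' part of gene B at a known crossover position, and
full-length amplicon reads carrying i.i.d. per-base substitution,
insertion and deletion errors at nanopore-like rates (5% / 2% / 3% by
default).  Everything is deterministic under a fixed seed, and the ground
truth (true crossover position, bracketing catalog sites, expected region
label) is returned alongside so parameter-recovery tests need no external
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .alignment import AlignParams, revcomp
from .reference import (GenePair, GeneModel, PairAlignment, align_gene_pair,
                        annotate_interval)
from .qc import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. error probabilities for simulated reads."""

    sub_rate: float = 0.05
    ins_rate: float = 0.02
    del_rate: float = 0.03

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 0.3:
                raise ValueError("error rates must be in [0, 0.3)")


@dataclass
class SimTruth:
    """Ground truth of one simulated sample."""

    crossover_template: int | None  # template coordinate; None for pure gene
    crossover_a: int | None         # gene-A coordinate of the junction
    crossover_b: int | None
    n_reads: int = 0
    error_model: ErrorModel = field(default_factory=ErrorModel)
    rc_fraction: float = 0.5
    off_target_fraction: float = 0.0
    seed: int = 0
    snapped: bool = False
    true_interval_a: tuple[int, int] | None = None  # bracketing disc sites
    true_label: str | None = None

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def make_toy_gene_pair(length: int = 4000, divergence: float = 0.06,
                       indel_rate: float = 0.002, seed: int = 0,
                       ) -> tuple[GenePair, list[tuple[int, str]]]:
    """Generate a synthetic paralog pair with known divergence.

    Gene A is uniform random DNA; gene B is a copy with Bernoulli
    ``divergence`` substitutions (always to a different base) and
    Bernoulli ``indel_rate`` indels of 1–3 bp.  The default 6% divergence
    mirrors the ~94% identity of the flagship paralog pair.  Returns the
    pair and the list of true divergence events as (gene-A position,
    kind) with kind in {"sub", "ins", "del"}.
    """
    if length < 500:
        raise ValueError("length must be >= 500")
    if not 0 <= divergence < 0.2:
        raise ValueError("divergence must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, length)
    b_parts: list[np.ndarray] = []
    events: list[tuple[int, str]] = []
    i = 0
    while i < length:
        r = rng.random()
        if r < indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion in B after this base
                b_parts.append(a[i:i + 1])
                b_parts.append(_random_seq(rng, size))
                events.append((i, "ins"))
                i += 1
            else:  # deletion in B
                events.append((i, "del"))
                i += size
            continue
        if rng.random() < divergence:
            base = a[i]
            alt = _BASES[_BASES != base][rng.integers(0, 3)]
            b_parts.append(np.array([alt], dtype=np.uint8))
            events.append((i, "sub"))
        else:
            b_parts.append(a[i:i + 1])
        i += 1
    seq_a = a.tobytes().decode()
    seq_b = np.concatenate(b_parts).tobytes().decode()
    pair = GenePair("toyA", "toyB", seq_a, seq_b)
    return pair, events


def make_toy_gene_model(length: int = 4000, n_exons: int = 5,
                        exon_len: int | None = None) -> GeneModel:
    """Evenly spaced synthetic exon/intron features covering [0, length).

    ``n_exons`` exons (E1..En) alternate with equal introns (I1..In-1);
    the last exon absorbs the remainder.  The default exon length scales
    with the gene (3/8 of the span shared across exons: 300 bp at 4 kb).
    """
    n_introns = n_exons - 1
    if exon_len is None:
        exon_len = max(1, round(0.375 * length / n_exons))
    intron_len = (length - n_exons * exon_len) // n_introns
    feats = []
    pos = 0
    for k in range(1, n_exons + 1):
        end = pos + exon_len if k < n_exons else length
        feats.append((f"E{k}", pos, end))
        pos = end
        if k <= n_introns:
            feats.append((f"I{k}", pos, pos + intron_len))
            pos += intron_len
    return GeneModel(feats)


def write_gene_model_bed(model: GeneModel, path, chrom: str = "toyA") -> None:
    with open(path, "w") as fh:
        for label, s, e in model.features:
            fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def feature_midpoint(model: GeneModel, label: str) -> int:
    for lab, s, e in model.features:
        if lab == label:
            return (s + e) // 2
    raise ValueError(f"feature {label!r} not in gene model")


def make_chimera(pair: GenePair, c: int,
                 aln: PairAlignment | None = None,
                 params: AlignParams | None = None,
                 ) -> tuple[str, int, bool]:
    """Join gene A[0..c) to gene B[c'..] at the aligned position.

    ``c`` is a gene-A coordinate; ``c'`` is the gene-B position aligned
    to it.  If position c falls in a gap column of the pair alignment it
    is snapped to the nearest column aligned in both genes.  Returns
    (template, c_b, snapped).  c == 0 yields pure gene B; c == len(A)
    yields pure gene A.
    """
    if aln is None:
        aln = align_gene_pair(pair, params)
    if c <= 0:
        return pair.seq_b, 0, False
    if c >= len(pair.seq_a):
        return pair.seq_a, len(pair.seq_b), False
    both = (aln.col_pos_a >= 0) & (aln.col_pos_b >= 0)
    pos_a = aln.col_pos_a[both]
    pos_b = aln.col_pos_b[both]
    k = int(np.argmin(np.abs(pos_a - c)))
    snapped = int(pos_a[k]) != c
    ca, cb = int(pos_a[k]), int(pos_b[k])
    return pair.seq_a[:ca] + pair.seq_b[cb:], cb, snapped


def mutate_read(template: np.ndarray, rng: np.random.Generator,
                em: ErrorModel) -> str:
    """Apply i.i.d. per-base deletion / substitution / insertion errors."""
    n = len(template)
    keep = rng.random(n) >= em.del_rate
    seq = template[keep].copy()
    m = len(seq)
    sub = rng.random(m) < em.sub_rate
    if sub.any():
        shift = rng.integers(1, 4, int(sub.sum())).astype(np.uint8)
        idx = np.searchsorted(_BASES, seq[sub])
        seq[sub] = _BASES[(idx + shift) % 4]
    ins = np.flatnonzero(rng.random(m) < em.ins_rate)
    if ins.size:
        ins_bases = _BASES[rng.integers(0, 4, ins.size)]
        seq = np.insert(seq, ins + 1, ins_bases)
    return seq.tobytes().decode()


def simulate_reads(template: str, n_reads: int = 200,
                   error_model: ErrorModel | None = None,
                   rc_fraction: float = 0.5,
                   off_target_fraction: float = 0.0,
                   seed: int = 0, read_prefix: str = "sim",
                   ) -> list[ReadRecord]:
    """Simulate full-length amplicon reads from a template.

    Each read spans the whole template (single-amplicon long-range PCR
    model) with per-base errors; ``rc_fraction`` of reads are
    reverse-complemented and ``off_target_fraction`` are replaced by
    uniform-random sequences of the same expected length.  Deterministic
    under a fixed seed; qualities are uniform placeholders.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    tpl = np.frombuffer(template.encode(), dtype=np.uint8)
    reads = []
    for k in range(n_reads):
        if rng.random() < off_target_fraction:
            seq = _random_seq(rng, len(tpl)).tobytes().decode()
            rid = f"{read_prefix}_{k:05d}_offtarget"
        else:
            seq = mutate_read(tpl, rng, em)
            rid = f"{read_prefix}_{k:05d}"
        if rng.random() < rc_fraction:
            seq = revcomp(seq)
        reads.append(ReadRecord(rid, seq, quality="I" * len(seq)))
    return reads


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * r.length
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def simulate_sample(out_dir=None, length: int = 4000, divergence: float = 0.06,
                    indel_rate: float = 0.002, crossover: int | None = None,
                    crossover_feature: str = "I2", n_reads: int = 200,
                    error_model: ErrorModel | None = None,
                    rc_fraction: float = 0.5, off_target_fraction: float = 0.0,
                    seed: int = 0, pure_gene: str | None = None,
                    params: AlignParams | None = None):
    """One-stop sample generator: pair + model + template + reads + truth.

    ``crossover`` defaults to the midpoint of ``crossover_feature`` in
    the toy gene model.  ``pure_gene`` = "A" or "B" generates a
    non-chimeric sample (negative control) instead.  When ``out_dir`` is
    given, writes reads.fastq, reference.fa, gene_model.bed, truth.json.
    Returns (pair, model, reads, truth).
    """
    em = error_model or ErrorModel()
    pair, _ = make_toy_gene_pair(length, divergence, indel_rate, seed=seed)
    model = make_toy_gene_model(length)
    aln = align_gene_pair(pair, params)

    if pure_gene is not None:
        template = pair.seq_a if pure_gene == "A" else pair.seq_b
        truth = SimTruth(None, None, None, n_reads=n_reads, error_model=em,
                         rc_fraction=rc_fraction,
                         off_target_fraction=off_target_fraction, seed=seed,
                         true_label="No fusion observed")
    else:
        c = crossover if crossover is not None else feature_midpoint(model, crossover_feature)
        template, cb, snapped = make_chimera(pair, c, aln=aln)
        from .reference import extract_informative_sites
        catalog = extract_informative_sites(aln)
        anchors = sorted(u.anchor_a for u in catalog.disc_units)
        left = max((p for p in anchors if p < c), default=c)
        right = min((p for p in anchors if p >= c), default=c)
        truth = SimTruth(len(pair.seq_a[:c]), c, cb, n_reads=n_reads,
                         error_model=em, rc_fraction=rc_fraction,
                         off_target_fraction=off_target_fraction, seed=seed,
                         snapped=snapped, true_interval_a=(left, right),
                         true_label=annotate_interval(model, (left, right + 1)))

    reads = simulate_reads(template, n_reads, em, rc_fraction,
                           off_target_fraction, seed=seed + 1)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, out / "reads.fastq")
        with open(out / "reference.fa", "w") as fh:
            fh.write(f">{pair.name_a}\n{pair.seq_a}\n>{pair.name_b}\n{pair.seq_b}\n")
        write_gene_model_bed(model, out / "gene_model.bed", chrom=pair.name_a)
        truth.to_json(out / "truth.json")
    return pair, model, reads, truth
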