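"""Informative-site catalog for a pair of highly similar paralogs.

The two paralog genomic sequences (e.g. CYP11B1 and CYP11B2, ~94%
identical) are aligned once; every alignment column is classified as

* **discriminating** — the paralogs differ (substitution column, or a
  run of single-sided gap columns forming one indel), so a read base
  there reveals which paralog the read segment came from;
* **ambiguous** — the paralogs agree, so mismatches there estimate the
  sequencing/PCR error floor;
* **masked** — an originally-ambiguous column discarded because a known
  polymorphism (dbSNP) is reported at that position, or a column
  overlapping an N base in either reference.

Consecutive gap columns of one indel are collapsed into a single
discriminating *unit*: an indel is one divergence event however long it
is, and the per-gene unit counts (units carrying a base in gene A vs in
gene B) differ exactly by the indel asymmetry between the paralogs.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alignment import AlignParams, local_align

logger = logging.getLogger(__name__)

DISCRIMINATING = "discriminating"
AMBIGUOUS = "ambiguous"
MASKED = "masked"

_VALID = set("ACGTN")


@dataclass
class GenePair:
    """The two paralog sequences and their (optional) genomic origins."""

    name_a: str
    name_b: str
    seq_a: str
    seq_b: str
    origin_a: str | None = None
    origin_b: str | None = None

    def __post_init__(self):
        for name, seq in ((self.name_a, self.seq_a), (self.name_b, self.seq_b)):
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"non-nucleotide characters {sorted(bad)} in record {name!r}"
                )
        n = self.seq_a.count("N") + self.seq_b.count("N")
        if n:
            warnings.warn(f"{n} N bases in paralog pair; sites overlapping N are masked")

    def swapped(self) -> "GenePair":
        return GenePair(self.name_b, self.name_a, self.seq_b, self.seq_a,
                        self.origin_b, self.origin_a)


def load_reference_pair(fasta_source, name_a: str | None = None,
                        name_b: str | None = None) -> GenePair:
    """Read the paralog pair from a FASTA file.

    By default the first two records are gene A and gene B; records can
    instead be selected by name.  Sequences are uppercased; anything
    outside A/C/G/T/N is rejected.
    """
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if name_a or name_b:
        by_name = {r.id: r for r in records}
        try:
            records = [by_name[name_a], by_name[name_b]]
        except KeyError as e:
            raise ValueError(f"record {e.args[0]!r} not found in {fasta_source}") from None
    if len(records) < 2:
        raise ValueError("need two sequences (paralog A and paralog B) in the FASTA")
    ra, rb = records[0], records[1]
    origin = lambda r: r.description.split(maxsplit=1)[1] if " " in r.description.strip() else None
    return GenePair(
        name_a=ra.id, name_b=rb.id,
        seq_a=str(ra.seq).upper(), seq_b=str(rb.seq).upper(),
        origin_a=origin(ra), origin_b=origin(rb),
    )


@dataclass
class PairAlignment:
    """Column frame of the paralog-pair local alignment.

    ``col_pos_a[k]`` is the 0-based position in gene A aligned to column
    k, or -1 for a gap-in-A column (likewise ``col_pos_b``).
    """

    pair: GenePair
    col_pos_a: np.ndarray
    col_pos_b: np.ndarray
    score: float
    params: AlignParams

    @property
    def n_columns(self) -> int:
        return len(self.col_pos_a)

    @property
    def identity(self) -> float:
        """Fraction of both-aligned columns where the two bases agree."""
        both = (self.col_pos_a >= 0) & (self.col_pos_b >= 0)
        a = np.frombuffer(self.pair.seq_a.encode(), dtype=np.uint8)
        b = np.frombuffer(self.pair.seq_b.encode(), dtype=np.uint8)
        eq = a[self.col_pos_a[both]] == b[self.col_pos_b[both]]
        return float(eq.mean()) if both.any() else 0.0

    def coverage(self) -> tuple[float, float]:
        cov_a = float((self.col_pos_a >= 0).sum()) / len(self.pair.seq_a)
        cov_b = float((self.col_pos_b >= 0).sum()) / len(self.pair.seq_b)
        return cov_a, cov_b


def align_gene_pair(pair: GenePair, params: AlignParams | None = None) -> PairAlignment:
    """Smith–Waterman local alignment of the two full paralog sequences.

    For genuinely homologous paralogs the aligned region covers nearly
    the whole of both sequences; coverage below 50% of either sequence is
    rejected as non-homologous.
    """
    params = params or AlignParams()
    aln = local_align(pair.seq_a, pair.seq_b, params)
    pa = PairAlignment(pair=pair, col_pos_a=aln.path_q, col_pos_b=aln.path_t,
                       score=aln.score, params=params)
    cov_a, cov_b = pa.coverage()
    if cov_a < 0.5 or cov_b < 0.5:
        raise ValueError(
            f"sequences do not appear homologous (aligned coverage "
            f"{cov_a:.0%} / {cov_b:.0%})"
        )
    return pa


@dataclass
class InformativeSite:
    """One alignment column of the site catalog."""

    column: int
    kind: str
    base_a: str | None
    base_b: str | None
    pos_a: int | None
    pos_b: int | None
    unit: int = -1  # discriminating-unit id; -1 for non-discriminating


@dataclass
class DiscUnit:
    """One discriminating unit: a substitution column or one whole indel.

    ``anchor_a``/``anchor_b`` are the positions used to place the unit on
    either gene's coordinate axis; for an insertion-type unit (no base in
    that gene) the anchor is the last aligned position to the left.
    """

    uid: int
    col_start: int
    col_end: int  # half-open
    bases_a: str  # "" when the unit is a gap in A
    bases_b: str
    pos_a: int | None
    pos_b: int | None
    anchor_a: int
    anchor_b: int

    @property
    def is_indel(self) -> bool:
        return not (self.bases_a and self.bases_b)


@dataclass
class SiteCatalog:
    """Classified alignment columns plus collapsed discriminating units."""

    sites: list[InformativeSite]
    pair: GenePair
    disc_units: list[DiscUnit] = field(default_factory=list)

    # vectorised lookup caches (built by _reindex)
    _sub_unit_index: np.ndarray = field(default=None, repr=False)
    _sub_pos_a: np.ndarray = field(default=None, repr=False)
    _sub_pos_b: np.ndarray = field(default=None, repr=False)
    _sub_base_a: np.ndarray = field(default=None, repr=False)
    _sub_base_b: np.ndarray = field(default=None, repr=False)
    _indel_unit_index: np.ndarray = field(default=None, repr=False)
    _amb_pos_a: np.ndarray = field(default=None, repr=False)
    _amb_base: np.ndarray = field(default=None, repr=False)
    _amb_pos_b: np.ndarray = field(default=None, repr=False)

    @property
    def n_discriminating_a(self) -> int:
        """Discriminating units carrying a base in gene A."""
        return sum(1 for u in self.disc_units if u.bases_a)

    @property
    def n_discriminating_b(self) -> int:
        return sum(1 for u in self.disc_units if u.bases_b)

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for s in self.sites if s.kind == AMBIGUOUS)

    @property
    def ambiguous_sites(self) -> list[InformativeSite]:
        return [s for s in self.sites if s.kind == AMBIGUOUS]

    def _reindex(self) -> None:
        subs = [(k, u) for k, u in enumerate(self.disc_units) if not u.is_indel]
        self._sub_unit_index = np.array([k for k, _ in subs], dtype=np.intp)
        self._sub_pos_a = np.array([u.pos_a for _, u in subs], dtype=np.intp)
        self._sub_pos_b = np.array([u.pos_b for _, u in subs], dtype=np.intp)
        self._sub_base_a = np.array([ord(u.bases_a) for _, u in subs], dtype=np.uint8)
        self._sub_base_b = np.array([ord(u.bases_b) for _, u in subs], dtype=np.uint8)
        self._indel_unit_index = np.array(
            [k for k, u in enumerate(self.disc_units) if u.is_indel], dtype=np.intp
        )
        amb = self.ambiguous_sites
        self._amb_pos_a = np.array([s.pos_a for s in amb], dtype=np.intp)
        self._amb_base = np.array([ord(s.base_a) for s in amb], dtype=np.uint8)
        self._amb_pos_b = np.array([s.pos_b for s in amb], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a table (1-based positions; '-' for gaps)."""
        rows = [
            {
                "column": s.column,
                "kind": s.kind,
                "base_a": s.base_a or "-",
                "base_b": s.base_b or "-",
                "pos_a": s.pos_a + 1 if s.pos_a is not None else "",
                "pos_b": s.pos_b + 1 if s.pos_b is not None else "",
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows, columns=["column", "kind", "base_a", "base_b",
                                           "pos_a", "pos_b"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def extract_informative_sites(aln: PairAlignment) -> SiteCatalog:
    """Classify every alignment column and collapse indels into units.

    Substitution columns and single-sided-gap columns are discriminating;
    equal-base columns are ambiguous; columns overlapping an N in either
    sequence are masked outright (an N carries no paralog information).
    """
    seq_a, seq_b = aln.pair.seq_a, aln.pair.seq_b
    sites: list[InformativeSite] = []
    units: list[DiscUnit] = []
    last_a = int(aln.col_pos_a[aln.col_pos_a >= 0][0]) if len(aln.col_pos_a) else 0
    last_b = int(aln.col_pos_b[aln.col_pos_b >= 0][0]) if len(aln.col_pos_b) else 0
    open_gap: str | None = None  # "A" / "B" while inside a gap run

    for col in range(aln.n_columns):
        ia = int(aln.col_pos_a[col])
        ib = int(aln.col_pos_b[col])
        ba = seq_a[ia] if ia >= 0 else None
        bb = seq_b[ib] if ib >= 0 else None
        if ia >= 0:
            last_a = ia
        if ib >= 0:
            last_b = ib

        if ba == "N" or bb == "N":
            sites.append(InformativeSite(col, MASKED, ba, bb,
                                         ia if ia >= 0 else None,
                                         ib if ib >= 0 else None))
            open_gap = None
            continue

        if ba is not None and bb is not None:
            open_gap = None
            if ba == bb:
                sites.append(InformativeSite(col, AMBIGUOUS, ba, bb, ia, ib))
            else:
                uid = len(units)
                units.append(DiscUnit(uid, col, col + 1, ba, bb, ia, ib, ia, ib))
                sites.append(InformativeSite(col, DISCRIMINATING, ba, bb, ia, ib, uid))
        elif ba is None:  # gap in A: bases only in B (insertion in B)
            if open_gap == "A":
                u = units[-1]
                u.col_end = col + 1
                u.bases_b += bb
            else:
                uid = len(units)
                units.append(DiscUnit(uid, col, col + 1, "", bb, None, ib,
                                      anchor_a=last_a, anchor_b=ib))
                open_gap = "A"
            sites.append(InformativeSite(col, DISCRIMINATING, None, bb, None, ib,
                                         units[-1].uid))
        else:  # gap in B: bases only in A (deletion in B)
            if open_gap == "B":
                u = units[-1]
                u.col_end = col + 1
                u.bases_a += ba
            else:
                uid = len(units)
                units.append(DiscUnit(uid, col, col + 1, ba, "", ia, None,
                                      anchor_a=ia, anchor_b=last_b))
                open_gap = "B"
            sites.append(InformativeSite(col, DISCRIMINATING, ba, None, ia, None,
                                         units[-1].uid))

    catalog = SiteCatalog(sites=sites, pair=aln.pair, disc_units=units)
    catalog._reindex()
    return catalog


def mask_polymorphic_sites(catalog: SiteCatalog,
                           positions_a: set[int] | None = None,
                           positions_b: set[int] | None = None,
                           ) -> tuple[SiteCatalog, int]:
    """Mask ambiguous sites at known polymorphic positions (0-based).

    Only ambiguous sites are ever masked — discriminating sites define
    the paralogs and stay; a polymorphic position hitting one triggers a
    warning only.  Returns (new catalog, number masked).
    """
    positions_a = positions_a or set()
    positions_b = positions_b or set()
    span_a, span_b = len(catalog.pair.seq_a), len(catalog.pair.seq_b)
    for p in positions_a:
        if not 0 <= p < span_a:
            warnings.warn(f"polymorphic position {p + 1} outside gene A span; ignored")
    for p in positions_b:
        if not 0 <= p < span_b:
            warnings.warn(f"polymorphic position {p + 1} outside gene B span; ignored")

    new = copy.deepcopy(catalog)
    n_masked = 0
    for s in new.sites:
        hit = (s.pos_a in positions_a) or (s.pos_b in positions_b)
        if not hit:
            continue
        if s.kind == DISCRIMINATING:
            warnings.warn(
                f"polymorphic position at discriminating site (column {s.column}) "
                "not masked: only ambiguous sites are maskable"
            )
        elif s.kind == AMBIGUOUS:
            s.kind = MASKED
            n_masked += 1
    new._reindex()
    return new, n_masked


def load_polymorphic_positions(path, name_a: str, name_b: str
                               ) -> tuple[set[int], set[int]]:
    """Read known polymorphic positions from TSV or VCF.

    TSV: two columns (gene name, 1-based position); '#' lines are
    comments.  VCF: the CHROM field must equal one of the two gene names
    and POS is the 1-based position on that gene's own coordinates (a
    dbSNP subset lifted onto the paralog intervals).
    """
    path = Path(path)
    pos_a: set[int] = set()
    pos_b: set[int] = set()
    if path.name.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF
        for v in VCF(str(path)):
            if v.CHROM == name_a or v.CHROM == "A":
                pos_a.add(v.POS - 1)
            elif v.CHROM == name_b or v.CHROM == "B":
                pos_b.add(v.POS - 1)
            else:
                warnings.warn(f"unknown contig {v.CHROM!r} in {path}; ignored")
        return pos_a, pos_b
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, pos = line.split("\t")[:2]
            if gene == name_a or gene == "A":
                pos_a.add(int(pos) - 1)
            elif gene == name_b or gene == "B":
                pos_b.add(int(pos) - 1)
            else:
                warnings.warn(f"unknown gene {gene!r} in {path}; line ignored")
    return pos_a, pos_b


def spacing_stats(catalog: SiteCatalog, gene: str = "A") -> dict:
    """Spacing between consecutive discriminating positions on one gene.

    Returns the median / min / max gap in bp (that gene's own
    coordinates) and the number of gaps.
    """
    if gene not in ("A", "B"):
        raise ValueError("gene must be 'A' or 'B'")
    pos = sorted(
        u.pos_a if gene == "A" else u.pos_b
        for u in catalog.disc_units
        if (u.bases_a if gene == "A" else u.bases_b)
    )
    if len(pos) < 2:
        raise ValueError("need at least two discriminating sites for spacing stats")
    gaps = np.diff(np.asarray(pos))
    return {
        "median_bp": float(np.median(gaps)),
        "min_bp": int(gaps.min()),
        "max_bp": int(gaps.max()),
        "n": int(len(gaps)),
    }


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon/intron features on the reference paralog's own coordinates.

    Features are (label, start, end) with 0-based half-open intervals,
    sorted and non-overlapping.
    """

    features: list[tuple[str, int, int]]

    def __post_init__(self):
        feats = sorted(self.features, key=lambda f: f[1])
        for (l1, s1, e1), (l2, s2, e2) in zip(feats, feats[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping features {l1} and {l2}")
            if s2 > e1:
                warnings.warn(f"gap between features {l1} and {l2} in gene model")
        self.features = feats

    @property
    def span(self) -> tuple[int, int]:
        return self.features[0][1], self.features[-1][2]


def load_gene_model(path) -> GeneModel:
    """Read a gene model from BED (start, end, label) or GFF3.

    BED intervals are 0-based half-open; GFF3 1-based closed (converted).
    For GFF3 the feature label is the ``Name`` attribute, falling back to
    the feature type.
    """
    path = Path(path)
    feats: list[tuple[str, int, int]] = []
    if path.suffix.lower() in (".gff", ".gff3"):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                ) if len(f) > 8 else {}
                label = attrs.get("Name", f[2])
                feats.append((label, int(f[3]) - 1, int(f[4])))
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 4:
            raise ValueError("BED gene model needs 4 columns: chrom start end label")
        for _, row in df.iterrows():
            feats.append((str(row[3]), int(row[1]), int(row[2])))
    if not feats:
        raise ValueError(f"no features found in gene model {path}")
    return GeneModel(feats)


def annotate_interval(model: GeneModel, interval: tuple[int, int],
                      join_single: bool = False) -> str:
    """Label an interval by the features it overlaps, e.g. "E2-I2".

    ``interval`` is 0-based half-open on the reference paralog.  An
    interval within one feature returns the single label (or the label
    joined to itself when ``join_single``); an interval outside the model
    returns "outside-model" with a warning.
    """
    start, end = interval
    if end <= start:
        end = start + 1
    hit = [lab for lab, s, e in model.features if s < end and e > start]
    if not hit:
        warnings.warn(f"interval {start + 1}-{end} outside gene model span")
        return "outside-model"
    if len(hit) == 1:
        return f"{hit[0]}-{hit[0]}" if join_single else hit[0]
    return f"{hit[0]}-{hit[-1]}"
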