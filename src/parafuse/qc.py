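"""Read-level quality control: length window and on-target selection.

Amplicon reads are expected to span (most of) the ~3.9 kb long-range PCR
product, so reads outside a 3000–5000 bp window are dropped.  Remaining
reads must align convincingly to at least one of the two paralogs (either
orientation): a read passes when its best local-alignment score reaches
``min_score_frac`` of the maximum achievable score (match score x read
length).  Random off-target sequence scores far below the default 0.4
fraction, while genuine amplicon reads — even at nanopore error rates —
score well above it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alignment import AlignParams, align_read, edit_distance, revcomp

logger = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str | None = None
    corrected: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class QCReport:
    n_input: int
    n_length_pass: int
    n_on_target: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_length_pass": self.n_length_pass,
            "n_on_target": self.n_on_target,
        }


def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastx(path, corrected: bool = False) -> list[ReadRecord]:
    """Read FASTQ or FASTA (gzip-transparent), by extension sniffing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    out = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual,
                                  corrected=corrected))
    return out


def external_corrected_input(path) -> list[ReadRecord]:
    """Accept externally error-corrected reads (FASTA or FASTQ).

    The pipeline itself performs no correction; this hook just loads the
    records and flags them ``corrected=True`` so reports record which
    input was analysed.
    """
    return read_fastx(path, corrected=True)


def length_filter(reads: list[ReadRecord], min_len: int = 3000,
                  max_len: int = 5000) -> list[ReadRecord]:
    """Keep reads with min_len <= length <= max_len (inclusive bounds)."""
    if min_len <= 0 or max_len < min_len:
        raise ValueError("need 0 < min_len <= max_len")
    return [r for r in reads if min_len <= r.length <= max_len]


def on_target_filter(reads: list[ReadRecord], pair,
                     min_score_frac: float = 0.4,
                     params: AlignParams | None = None,
                     engine: str = "fast",
                     ) -> tuple[list[ReadRecord], QCReport]:
    """Keep reads whose best paralog alignment clears the score threshold.

    Each read is aligned (both orientations) against both paralogs; the
    best score is expressed as a fraction of ``match * read length`` and
    compared to ``min_score_frac``.
    """
    if not 0 < min_score_frac <= 1:
        raise ValueError("min_score_frac must be in (0, 1]")
    params = params or AlignParams()
    rows = []
    kept = []
    for r in reads:
        if engine == "fast":
            # screen the four (gene, orientation) combinations by infix
            # edit distance, then score only the best one
            combos = []
            for orient, seq in (("+", r.sequence), ("-", revcomp(r.sequence))):
                for gene, target in (("A", pair.seq_a), ("B", pair.seq_b)):
                    combos.append((edit_distance(seq, target), orient, seq,
                                   gene, target))
            _, orient, seq, gene, target = min(combos, key=lambda c: c[0])
            score = align_read(seq, target, params, engine).score
            best = (score, gene, orient)
        else:
            best = (-1.0, "", "")
            for orient, seq in (("+", r.sequence), ("-", revcomp(r.sequence))):
                for gene, target in (("A", pair.seq_a), ("B", pair.seq_b)):
                    score = align_read(seq, target, params, engine).score
                    if score > best[0]:
                        best = (score, gene, orient)
        frac = best[0] / (params.match * r.length) if r.length else 0.0
        ok = frac >= min_score_frac
        rows.append({"read_id": r.id, "length": r.length, "best_gene": best[1],
                     "orientation": best[2], "score": best[0],
                     "score_frac": round(frac, 4), "on_target": ok})
        if ok:
            kept.append(r)
    table = pd.DataFrame(rows)
    report = QCReport(n_input=len(reads), n_length_pass=len(reads),
                      n_on_target=len(kept), table=table)
    return kept, report


def run_qc(reads: list[ReadRecord], pair, min_len: int = 3000,
           max_len: int = 5000, min_score_frac: float = 0.4,
           params: AlignParams | None = None, engine: str = "fast",
           ) -> tuple[list[ReadRecord], QCReport]:
    """Length window then on-target selection, with a combined report."""
    n_input = len(reads)
    passed = length_filter(reads, min_len, max_len)
    kept, rep = on_target_filter(passed, pair, min_score_frac, params, engine)
    rep.n_input = n_input
    rep.n_length_pass = len(passed)
    logger.info("QC: %d input, %d length-pass, %d on-target",
                n_input, len(passed), len(kept))
    return kept, rep
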