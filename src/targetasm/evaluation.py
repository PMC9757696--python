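"""Scoring recovered genes against a gold standard.

Two families of statistics:

* **T50** — the number of genes whose recovered sequence length is at least
  50% of the gene's target length (the mean length of that gene's reference
  instances).
* **Error rates** — each recovered contig is aligned to its true sequence by
  semi-global pairwise alignment (contig end gaps free, since contigs are by
  nature partial; match=1, mismatch=-1, gap open=-2, gap extend=-1), in the
  orientation scoring best.  The base-calling error rate is the fraction of
  aligned both-base columns that mismatch; the indel error rate is the
  fraction of gap columns within the aligned span.  Rates are reported
  per gene and aggregated over total aligned length across genes.

A recovered sequence is flagged invalid when its alignment covers fewer than
20 bases or its base-calling error rate exceeds a configurable threshold
(default 5%): such sequences should not enter phylogenetic analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Optional

from Bio import Align

from .io_formats import SequenceRecord, reverse_complement

__all__ = [
    "GeneReport",
    "RecoveryReport",
    "t50",
    "error_rates",
    "evaluate_recovery",
    "write_report",
]

MIN_ALIGNED_BASES = 20
DEFAULT_ERROR_THRESHOLD = 0.05


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps on the contig (query) side: truth overhang beyond a
    # partial contig is not an assembly error
    aligner.end_deletion_score = 0
    return aligner


def t50(
    recovered_lengths: Mapping[str, int], target_lengths: Mapping[str, float]
) -> int:
    """Count genes recovered to at least half their target length.

    Genes absent from ``recovered_lengths`` count as length 0; the result is
    bounded by the number of target genes.
    """
    return sum(
        1
        for gene, target in target_lengths.items()
        if recovered_lengths.get(gene, 0) >= 0.5 * target
    )


def _alignment_columns(alignment) -> tuple[int, int, int]:
    """(both-base columns, mismatch columns, internal gap columns)."""
    t_blocks, q_blocks = alignment.aligned
    target = str(alignment.target)
    query = str(alignment.query)
    both = 0
    mismatch = 0
    gaps = 0
    prev_t_end: Optional[int] = None
    prev_q_end: Optional[int] = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        both += te - ts
        mismatch += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a != b
        )
        if prev_t_end is not None:
            gaps += (ts - prev_t_end) + (qs - prev_q_end)
        prev_t_end, prev_q_end = te, qe
    return both, mismatch, gaps


def _best_orientation_counts(
    truth_seq: str, contig_seq: str, aligner: Align.PairwiseAligner
) -> tuple[int, int, int]:
    """Column counts for the higher-scoring of forward / revcomp alignment."""
    rev = reverse_complement(contig_seq)
    oriented = (
        contig_seq
        if aligner.score(truth_seq, contig_seq) >= aligner.score(truth_seq, rev)
        else rev
    )
    return _alignment_columns(aligner.align(truth_seq, oriented)[0])


def error_rates(
    contig: SequenceRecord,
    truth: SequenceRecord,
    min_aligned: int = MIN_ALIGNED_BASES,
) -> tuple[Optional[float], Optional[float]]:
    """(base_error_rate, indel_error_rate) of a contig vs its true sequence.

    The contig is compared in whichever orientation (forward or reverse
    complement) yields the higher-scoring semi-global alignment; rates are
    therefore strand symmetric.  Returns (None, None) when the alignment
    covers fewer than ``min_aligned`` bases.
    """
    if not contig.seq or not truth.seq:
        raise ValueError("error_rates requires non-empty sequences")
    both, mismatch, gaps = _best_orientation_counts(
        truth.seq, contig.seq, _make_aligner()
    )
    if both < min_aligned:
        return None, None
    span = both + gaps
    return mismatch / both, gaps / span


@dataclass(slots=True)
class GeneReport:
    """Per-gene recovery metrics."""

    gene_id: str
    recovered_length: int
    target_length: float
    recovered_fraction: float
    base_error_rate: Optional[float] = None
    indel_error_rate: Optional[float] = None
    valid: bool = False


@dataclass
class RecoveryReport:
    """Whole-run recovery metrics: per-gene rows plus aggregates."""

    per_gene: dict[str, GeneReport] = field(default_factory=dict)
    t50: int = 0
    n_valid: int = 0
    aggregate_base_error_rate: Optional[float] = None
    aggregate_indel_error_rate: Optional[float] = None


def evaluate_recovery(
    contigs: Mapping[str, SequenceRecord],
    truths: Mapping[str, SequenceRecord],
    target_lengths: Mapping[str, float],
    error_threshold: float = DEFAULT_ERROR_THRESHOLD,
    min_aligned: int = MIN_ALIGNED_BASES,
) -> RecoveryReport:
    """Score recovered contigs against gold-standard truths.

    Aggregate rates pool error and aligned-length counts over all genes
    (total errors / total aligned length), alongside the per-gene rates.
    """
    report = RecoveryReport()
    total_both = total_mismatch = total_gaps = total_span = 0
    recovered_lengths: dict[str, int] = {}
    aligner = _make_aligner()
    for gene in sorted(target_lengths):
        target = target_lengths[gene]
        contig = contigs.get(gene)
        length = len(contig.seq) if contig else 0
        recovered_lengths[gene] = length
        row = GeneReport(
            gene_id=gene,
            recovered_length=length,
            target_length=target,
            recovered_fraction=length / target if target else 0.0,
        )
        truth = truths.get(gene)
        if contig and truth:
            both, mismatch, gaps = _best_orientation_counts(
                truth.seq, contig.seq, aligner
            )
            if both >= min_aligned:
                row.base_error_rate = mismatch / both
                row.indel_error_rate = gaps / (both + gaps)
                row.valid = row.base_error_rate <= error_threshold
                total_both += both
                total_mismatch += mismatch
                total_gaps += gaps
                total_span += both + gaps
        report.per_gene[gene] = row
    report.t50 = t50(recovered_lengths, target_lengths)
    report.n_valid = sum(1 for r in report.per_gene.values() if r.valid)
    if total_both:
        report.aggregate_base_error_rate = total_mismatch / total_both
        report.aggregate_indel_error_rate = total_gaps / total_span
    return report


def write_report(report: RecoveryReport, path: str | PathLike) -> None:
    """Write the per-gene table as TSV with a one-line aggregate footer."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "gene_id",
                "recovered_length",
                "target_length",
                "recovered_fraction",
                "base_error_rate",
                "indel_error_rate",
                "valid",
            ]
        )
        for gene in sorted(report.per_gene):
            r = report.per_gene[gene]
            w.writerow(
                [
                    r.gene_id,
                    r.recovered_length,
                    f"{r.target_length:.1f}",
                    f"{r.recovered_fraction:.4f}",
                    "" if r.base_error_rate is None else f"{r.base_error_rate:.6f}",
                    "" if r.indel_error_rate is None else f"{r.indel_error_rate:.6f}",
                    int(r.valid),
                ]
            )
        agg_b = report.aggregate_base_error_rate
        agg_i = report.aggregate_indel_error_rate
        w.writerow(
            [
                "#summary",
                f"t50={report.t50}",
                f"n_valid={report.n_valid}",
                "",
                "" if agg_b is None else f"{agg_b:.6f}",
                "" if agg_i is None else f"{agg_i:.6f}",
                "",
            ]
        )
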