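"""k-mer read filtering: classify raw reads into per-gene bins.

Each read (and its reverse complement — input reads are unstranded while the
index is forward-strand only) is split into k-mers at a configurable stride
(``step``) and looked up in the reference hash table.  Exact matching only: a
single mismatching base disqualifies a k-mer.  A read is recruited to every
gene with which it shares at least ``min_hits`` k-mers; for paired input,
either mate matching a gene recruits both mates into that gene's bin (pair
rescue), so mates covering gene flanks are retained for assembly.
"""

from __future__ import annotations

import csv
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from itertools import islice
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .io_formats import ReadPair, SequenceRecord, reverse_complement, write_fasta
from .reference_db import KmerIndex, ParameterError

__all__ = [
    "FilterParams",
    "ReadBin",
    "FilterSummary",
    "kmerize",
    "classify_read",
    "filter_reads",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

_CHUNK = 10_000  # read pairs per work unit when filtering with threads


@dataclass(slots=True)
class FilterParams:
    """Filtering parameters.

    k:        filter k-mer length (long k-mers, no mismatches allowed).
    step:     interval between successive k-mer start offsets when splitting
              a read; step > 1 trades sensitivity for speed.
    min_hits: shared k-mers required to call a read/gene match.
    """

    k: int = 31
    step: int = 1
    min_hits: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError(f"filter k must be >= 2, got {self.k}")
        if self.step < 1:
            raise ParameterError(f"step must be >= 1, got {self.step}")
        if self.min_hits < 1:
            raise ParameterError(f"min_hits must be >= 1, got {self.min_hits}")


@dataclass
class ReadBin:
    """The reads assigned to one target gene by filtering."""

    gene_id: str
    reads: list[SequenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class FilterSummary:
    """Counts produced by one filtering run."""

    reads_scanned: int = 0
    reads_matched: int = 0
    bin_sizes: dict[str, int] = field(default_factory=dict)


def kmerize(seq: str, k: int, step: int = 1) -> list[str]:
    """Split a sequence into k-mers at offsets 0, step, 2*step, ...

    k-mers containing a base outside {A,C,G,T} are omitted; a sequence
    shorter than k yields an empty list.
    """
    n = len(seq) - k + 1
    if n <= 0:
        return []
    if set(seq) <= _ACGT:
        return [seq[i : i + k] for i in range(0, n, step)]
    out = []
    for i in range(0, n, step):
        km = seq[i : i + k]
        if set(km) <= _ACGT:
            out.append(km)
    return out


def classify_read(
    read: SequenceRecord, index: KmerIndex, params: FilterParams
) -> set[str]:
    """Genes sharing >= min_hits exact k-mers with the read or its revcomp."""
    entries = index.entries
    hits: dict[str, int] = {}
    for strand_seq in (read.seq, reverse_complement(read.seq)):
        for km in kmerize(strand_seq, params.k, params.step):
            per_gene = entries.get(km)
            if per_gene:
                for gene in per_gene:
                    hits[gene] = hits.get(gene, 0) + 1
    if params.min_hits == 1:
        return set(hits)
    return {g for g, c in hits.items() if c >= params.min_hits}


def _classify_chunk(
    chunk: list[ReadPair],
    index: KmerIndex,
    params: FilterParams,
    pair_rescue: bool,
) -> list[tuple[frozenset[str], ReadPair]]:
    """Per-pair gene assignments; pure function of its inputs."""
    out = []
    for pair in chunk:
        g1 = classify_read(pair.r1, index, params)
        if pair.r2 is None:
            out.append((frozenset(g1), pair))
        elif pair_rescue:
            g2 = classify_read(pair.r2, index, params)
            out.append((frozenset(g1 | g2), pair))
        else:
            g2 = classify_read(pair.r2, index, params)
            # no rescue: each mate goes only to its own genes
            out.append((frozenset(g1), ReadPair(r1=pair.r1)))
            out.append((frozenset(g2), ReadPair(r1=pair.r2)))
    return out


def _chunks(pairs: Iterable[ReadPair], size: int) -> Iterator[list[ReadPair]]:
    it = iter(pairs)
    while chunk := list(islice(it, size)):
        yield chunk


def filter_reads(
    pairs: Iterable[ReadPair],
    index: KmerIndex,
    params: FilterParams,
    out_dir: Optional[str | PathLike] = None,
    pair_rescue: bool = True,
    threads: int = 1,
) -> tuple[dict[str, ReadBin], FilterSummary]:
    """Classify a read stream into per-gene bins.

    For paired input with pair rescue (default), if either mate classifies to
    gene g both mates enter bin g; a read may enter multiple bins.  When
    ``out_dir`` is given, each nonempty bin is written as
    ``<out_dir>/<gene_id>.fasta`` along with a tab-separated ``filter_summary.tsv``
    listing every gene of the index.  Results are independent of read order
    (as sets) and of ``threads``.
    """
    bins: dict[str, ReadBin] = {}
    summary = FilterSummary()

    def _consume(results: list[tuple[frozenset[str], ReadPair]]) -> None:
        for genes, pair in results:
            mates = [pair.r1] if pair.r2 is None else [pair.r1, pair.r2]
            summary.reads_scanned += len(mates)
            if not genes:
                continue
            summary.reads_matched += len(mates)
            for gene in genes:
                bin_ = bins.setdefault(gene, ReadBin(gene_id=gene))
                bin_.reads.extend(mates)

    if threads <= 1:
        for chunk in _chunks(pairs, _CHUNK):
            _consume(_classify_chunk(chunk, index, params, pair_rescue))
    else:
        # classification is pure; merge chunk results in submission order so
        # the outcome is identical to the single-threaded run
        with ThreadPoolExecutor(max_workers=threads) as pool:
            futures = [
                pool.submit(_classify_chunk, chunk, index, params, pair_rescue)
                for chunk in _chunks(pairs, _CHUNK)
            ]
            for fut in futures:
                _consume(fut.result())

    summary.bin_sizes = {g: len(b) for g, b in sorted(bins.items())}
    logger.info(
        "filtered %d reads: %d matched across %d gene bins",
        summary.reads_scanned, summary.reads_matched, len(bins),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gene in sorted(bins):
            if bins[gene].reads:
                write_fasta(bins[gene].reads, out_dir / f"{gene}.fasta")
        with open(out_dir / "filter_summary.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "n_reads"])
            for gene in index.gene_ids:
                w.writerow([gene, len(bins[gene]) if gene in bins else 0])
    return bins, summary
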