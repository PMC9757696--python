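"""Per-gene reference database and positional k-mer hash index.

The reference database is a directory of FASTA files, one per target gene,
each holding one or more homologous nucleotide sequences from related taxa.
Every reference is decomposed (forward strand only) into its k-mers, which are
kept in an in-memory hash table mapping k-mer -> gene(s).  For each (k-mer,
gene) pair the table also records the occurrence count and the mean fractional
position of the k-mer along that gene's references — the positional prior the
assembler uses to weight extension candidates.

Fractional position of a k-mer starting at 0-based offset ``start`` in a
reference of length ``L`` is ``start / (L - k)`` (defined as 0 when ``L == k``)
so positions span [0, 1] regardless of reference length.  Statistics pool all
homologs of a gene with equal weight per occurrence.  k-mers containing any
base outside {A,C,G,T} are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .io_formats import SequenceRecord, read_fasta

__all__ = [
    "ReferenceSet",
    "KmerIndex",
    "ConfigurationError",
    "ParameterError",
    "build_reference_set",
    "build_reference_set_from_combined",
    "build_kmer_index",
    "positional_kmer_map",
]

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = (".fasta", ".fa", ".fna", ".ffn")
_ACGT = frozenset("ACGT")


class ConfigurationError(ValueError):
    """The reference database layout is unusable (e.g. empty directory)."""


class ParameterError(ValueError):
    """An index/filter parameter is out of its valid range."""


@dataclass
class ReferenceSet:
    """Homologous reference sequences grouped by target gene.

    ``target_length[g]`` is the arithmetic mean reference length of gene *g*
    — the target length against which recovery is later measured.
    """

    genes: dict[str, list[SequenceRecord]]
    target_length: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.target_length:
            self.target_length = {
                g: sum(len(r.seq) for r in recs) / len(recs)
                for g, recs in self.genes.items()
                if recs
            }

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class KmerIndex:
    """Hash table: k-mer -> {gene-id -> (occurrence_count, mean_frac_pos)}."""

    k: int
    entries: dict[str, dict[str, tuple[int, float]]]
    gene_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.entries)


def _gene_id_from_filename(path: Path) -> str:
    name = path.name
    if name.endswith(".gz"):
        name = name[:-3]
    for suf in _FASTA_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return Path(name).stem


def _is_fasta_file(path: Path) -> bool:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return path.is_file() and name.endswith(_FASTA_SUFFIXES)


def build_reference_set(ref_dir: str | PathLike) -> ReferenceSet:
    """Load a directory of per-gene FASTA files into a :class:`ReferenceSet`.

    The gene id is the file basename with FASTA/.gz extensions stripped.
    A file with zero records produces a warning and the gene is skipped;
    a directory with no FASTA files raises :class:`ConfigurationError`.
    """
    ref_dir = Path(ref_dir)
    if not ref_dir.is_dir():
        raise ConfigurationError(f"reference directory not found: {ref_dir}")
    files = sorted(p for p in ref_dir.iterdir() if _is_fasta_file(p))
    if not files:
        raise ConfigurationError(f"no FASTA files in reference directory {ref_dir}")
    genes: dict[str, list[SequenceRecord]] = {}
    for path in files:
        records = list(read_fasta(path))
        gene = _gene_id_from_filename(path)
        if not records:
            logger.warning("reference file %s has no records; gene skipped", path)
            continue
        genes[gene] = records
    if not genes:
        raise ConfigurationError(f"all reference files in {ref_dir} were empty")
    return ReferenceSet(genes=genes)


def build_reference_set_from_combined(path: str | PathLike) -> ReferenceSet:
    """Load a single combined FASTA whose headers encode the gene id.

    The gene id is the token after the last '-' in the record id, a common
    convention for combined Angiosperms353 reference files
    (e.g. ``TaxonName-5162``).
    """
    genes: dict[str, list[SequenceRecord]] = {}
    for rec in read_fasta(path):
        gene = rec.id.rsplit("-", 1)[-1]
        genes.setdefault(gene, []).append(rec)
    if not genes:
        raise ConfigurationError(f"combined reference FASTA {path} has no records")
    return ReferenceSet(genes=genes)


def _valid_kmer_starts(seq: str, k: int) -> Iterator[int]:
    """Yield 0-based start offsets of k-mers containing only A/C/G/T."""
    n_windows = len(seq) - k + 1
    if n_windows <= 0:
        return
    if set(seq) <= _ACGT:  # common clean case: every window is valid
        yield from range(n_windows)
        return
    # next_bad[i] = smallest index >= i holding a non-ACGT base
    next_bad = len(seq)
    bad_after = [len(seq)] * (len(seq) + 1)
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] not in _ACGT:
            next_bad = i
        bad_after[i] = next_bad
    for i in range(n_windows):
        if bad_after[i] >= i + k:
            yield i


def _accumulate(
    acc: dict[str, dict[str, list[float]]],
    gene: str,
    records: Sequence[SequenceRecord],
    k: int,
) -> None:
    for rec in records:
        seq = rec.seq
        L = len(seq)
        if L < k:
            logger.warning(
                "reference %s (gene %s) shorter than k=%d; contributes no k-mers",
                rec.id, gene, k,
            )
            continue
        denom = L - k
        for start in _valid_kmer_starts(seq, k):
            frac = start / denom if denom else 0.0
            stats = acc.setdefault(seq[start : start + k], {}).setdefault(
                gene, [0, 0.0]
            )
            stats[0] += 1
            stats[1] += frac


def build_kmer_index(refs: ReferenceSet, k: int) -> KmerIndex:
    """Index every forward-strand k-mer of every reference with positional stats.

    Deterministic: rebuilding from the same inputs is bit-identical.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    acc: dict[str, dict[str, list[float]]] = {}
    for gene in refs.genes:
        _accumulate(acc, gene, refs.genes[gene], k)
    entries = {
        kmer: {g: (int(c), s / c) for g, (c, s) in per_gene.items()}
        for kmer, per_gene in acc.items()
    }
    return KmerIndex(k=k, entries=entries, gene_ids=tuple(sorted(refs.genes)))


def positional_kmer_map(
    records: Iterable[SequenceRecord], k: int
) -> dict[str, tuple[int, float]]:
    """Positional k-mer statistics for a single gene's references.

    Returns k-mer -> (occurrence_count, mean_frac_pos), pooled over the given
    homologs.  Used by the assembler to annotate graph nodes at its own k.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    acc: dict[str, dict[str, list[float]]] = {}
    _accumulate(acc, "_", list(records), k)
    return {kmer: (int(st["_"][0]), st["_"][1] / st["_"][0]) for kmer, st in acc.items()}
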