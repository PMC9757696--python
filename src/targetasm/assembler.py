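"""Greedy assembly of a gene's read bin on a weighted de Bruijn graph.

Nodes are the assembly k-mers of the bin's reads (counted in both
orientations, at a k independent of the filtering k); a directed edge u -> v
exists whenever the (k-1)-suffix of u equals the (k-1)-prefix of v.  Assembly
walks the graph greedily from the most abundant k-mer under a visit-once
constraint, extending right then left, seeking the path that traverses the
most nodes.

At a branch, each candidate node is scored

    W_node = count ** (1 - pos)

where ``count`` is the candidate k-mer's abundance in the bin and ``pos`` is
the positional jump: the absolute difference between the mean fractional
positions of the candidate and the current k-mer on the gene's reference
sequences.  A candidate positionally consistent with the current node (small
jump) keeps near-full abundance weight; positional outliers, and candidates
absent from the references (pos = 1), decay to weight 1 — the floor for any
k-mer, so an unreferenced k-mer never outranks a positionally consistent
referenced one, yet still extends unbranched regions.  Ties on weight are
resolved by abundance, then lexicographically, so assembly is fully
deterministic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import SequenceRecord, reverse_complement
from .read_filter import ReadBin
from .reference_db import ParameterError, positional_kmer_map

__all__ = [
    "DbgNode",
    "AssemblyGraph",
    "ContigResult",
    "build_graph",
    "node_weight",
    "extend_path",
    "assemble_gene",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")
_BASES = "ACGT"


@dataclass(slots=True)
class DbgNode:
    """One k-mer node: abundance plus optional reference positional prior."""

    kmer: str
    count: int
    ref_pos: Optional[float] = None


@dataclass
class AssemblyGraph:
    """de Bruijn graph over assembly k-mers; edges implicit in node keys."""

    k_asm: int
    nodes: dict[str, DbgNode]

    def __len__(self) -> int:
        return len(self.nodes)

    def successors(self, kmer: str) -> list[str]:
        suffix = kmer[1:]
        return [suffix + b for b in _BASES if suffix + b in self.nodes]

    def predecessors(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in _BASES if b + prefix in self.nodes]


@dataclass(slots=True)
class ContigResult:
    """A single assembled contig for one gene."""

    gene_id: str
    seq: str
    n_nodes_visited: int
    seed_kmer: str
    recovered_fraction: float


def _segments(seq: str) -> list[str]:
    """Maximal A/C/G/T-only stretches of a sequence (N splits, never spans)."""
    if set(seq) <= _ACGT:
        return [seq]
    out, cur = [], []
    for c in seq:
        if c in _ACGT:
            cur.append(c)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def build_graph(
    reads: ReadBin | Iterable[SequenceRecord],
    k_asm: int,
    min_count: int = 1,
    ref_pos: Optional[Mapping[str, tuple[int, float]]] = None,
) -> AssemblyGraph:
    """Count every N-free k-mer of every read and of its reverse complement.

    Nodes with abundance below ``min_count`` are dropped.  ``ref_pos`` (a
    positional k-mer map for this gene's references, built at the assembly k)
    annotates surviving nodes with their mean fractional reference position.
    """
    if k_asm < 2:
        raise ParameterError(f"assembly k must be >= 2, got {k_asm}")
    records = reads.reads if isinstance(reads, ReadBin) else reads
    counts: Counter[str] = Counter()
    for rec in records:
        for oriented in (rec.seq, reverse_complement(rec.seq)):
            for seg in _segments(oriented):
                n = len(seg) - k_asm + 1
                if n > 0:
                    counts.update(seg[i : i + k_asm] for i in range(n))
    nodes: dict[str, DbgNode] = {}
    for kmer, count in counts.items():
        if count < min_count:
            continue
        stat = ref_pos.get(kmer) if ref_pos else None
        nodes[kmer] = DbgNode(kmer=kmer, count=count,
                              ref_pos=stat[1] if stat else None)
    return AssemblyGraph(k_asm=k_asm, nodes=nodes)


def node_weight(count: int, pos: float) -> float:
    """Extension-candidate weight W = count ** (1 - pos).

    ``pos`` outside [0, 1] is clipped defensively (upstream guarantees range).
    """
    if pos < 0.0 or pos > 1.0:
        logger.debug("pos %.4f outside [0,1]; clipped", pos)
        pos = min(max(pos, 0.0), 1.0)
    return count ** (1.0 - pos)


_MAX_BACKTRACKS = 10_000  # safety valve; bounded anyway by edge consumption


def _ranked_neighbors(
    nodes: dict[str, DbgNode],
    cur: DbgNode,
    going_right: bool,
    visited: set[str],
) -> list[DbgNode]:
    """Unvisited neighbours of ``cur`` best first.

    Ranking key: weight W = count^(1 - pos_delta) where pos_delta is the
    positional jump (1 when either node lacks a reference position), then
    abundance, then lexicographically smallest k-mer.
    """
    core = cur.kmer[1:] if going_right else cur.kmer[:-1]
    ranked: list[tuple[float, int, DbgNode]] = []
    for b in _BASES:  # ACGT order => stable sort keeps lexicographic min first
        cand_key = core + b if going_right else b + core
        cand = nodes.get(cand_key)
        if cand is None or cand_key in visited:
            continue
        if cur.ref_pos is not None and cand.ref_pos is not None:
            pos_delta = abs(cand.ref_pos - cur.ref_pos)
        else:
            pos_delta = 1.0
        ranked.append((node_weight(cand.count, pos_delta), cand.count, cand))
    ranked.sort(key=lambda t: (-t[0], -t[1]))
    return [cand for _, _, cand in ranked]


def extend_path(
    graph: AssemblyGraph,
    seed: str,
    direction: str = "right",
    visited: Optional[set[str]] = None,
    tip_window: Optional[int] = None,
) -> list[str]:
    """Greedy visit-once walk from ``seed``; returns k-mers in walk order.

    At each step every unvisited successor (or predecessor, going left) is
    scored with :func:`node_weight` using the positional jump from the current
    node; the highest weight wins, ties broken by abundance then by
    lexicographically smallest k-mer.  The visit-once constraint guarantees
    termination on any finite graph, cycles included.

    Dead ends reached within ``tip_window`` nodes of the last open branch
    (default: the graph k, the span of k-mers a single read error corrupts)
    are treated as tip artifacts: the walk backtracks to that branch and tries
    the next-ranked candidate, finally keeping the longest completion found.
    Branches left more than ``tip_window`` nodes behind are committed and
    never reopened, so the walk stays effectively linear.  ``tip_window=0``
    disables backtracking (pure greedy).  Fully deterministic.
    """
    if seed not in graph.nodes:
        raise KeyError(f"seed k-mer not in graph: {seed}")
    if direction not in ("right", "left"):
        raise ValueError(f"direction must be 'right' or 'left', got {direction!r}")
    nodes = graph.nodes
    going_right = direction == "right"
    if tip_window is None:
        tip_window = graph.k_asm
    if visited is None:
        visited = set()
    visited.add(seed)
    added = {seed}
    path = [nodes[seed]]
    # open branches: (path length at branch, remaining candidates best first)
    alts: list[tuple[int, list[DbgNode]]] = []
    best_path: Optional[list[DbgNode]] = None
    backtracks = 0
    while True:
        cands = _ranked_neighbors(nodes, path[-1], going_right, visited)
        if cands:
            if len(cands) > 1:
                alts.append((len(path), cands[1:]))
            nxt = cands[0]
            visited.add(nxt.kmer)
            added.add(nxt.kmer)
            path.append(nxt)
            # commit branches that fell more than tip_window behind
            while alts and len(path) - alts[0][0] > tip_window:
                alts.pop(0)
            continue
        # dead end
        if best_path is None or len(path) > len(best_path):
            best_path = list(path)
        if not alts or backtracks >= _MAX_BACKTRACKS:
            break
        branch_len, branch_cands = alts.pop()
        if len(path) - branch_len > tip_window:
            break  # ran long past the last open branch: not a tip, accept
        backtracks += 1
        for node in path[branch_len:]:
            visited.discard(node.kmer)
        del path[branch_len:]
        nxt = branch_cands.pop(0)
        if branch_cands:
            alts.append((branch_len, branch_cands))
        visited.add(nxt.kmer)
        added.add(nxt.kmer)
        path.append(nxt)
    final = best_path if best_path is not None else path
    final_keys = {nd.kmer for nd in final}
    visited.difference_update(added - final_keys)
    visited.update(final_keys)
    return [nd.kmer for nd in final]


def _contig_from_walks(left: Sequence[str], right: Sequence[str]) -> tuple[str, int]:
    """Merge left and right walks (both starting at the seed) into a contig."""
    ordered = list(reversed(left))[:-1] + list(right)
    seq = ordered[0] + "".join(km[-1] for km in ordered[1:])
    return seq, len(ordered)


def assemble_gene(
    read_bin: ReadBin | Iterable[SequenceRecord],
    gene_refs: Sequence[SequenceRecord],
    k_asm: int = 41,
    min_count: int = 1,
    min_length: Optional[int] = None,
    max_seed_retries: int = 4,
    gene_id: Optional[str] = None,
) -> Optional[ContigResult]:
    """Assemble one gene's bin into a single best contig.

    Builds the weighted graph, seeds at the most abundant k-mer (ties
    lexicographic) and extends right then left under a shared visit-once set.
    If the contig is shorter than ``min_length`` (default k_asm + 20), up to
    ``max_seed_retries`` further seeds are tried in decreasing abundance
    order; the first contig reaching ``min_length`` is returned, otherwise
    the one visiting the most nodes.  Returns None for an empty graph or when
    no attempt reaches ``min_length``.
    """
    if isinstance(read_bin, ReadBin) and gene_id is None:
        gene_id = read_bin.gene_id
    gene_id = gene_id or "unknown"
    if min_length is None:
        min_length = k_asm + 20
    ref_pos = positional_kmer_map(gene_refs, k_asm) if gene_refs else None
    graph = build_graph(read_bin, k_asm, min_count=min_count, ref_pos=ref_pos)
    if not graph.nodes:
        return None
    target_length = (
        sum(len(r.seq) for r in gene_refs) / len(gene_refs) if gene_refs else 0.0
    )
    seeds = sorted(graph.nodes.values(), key=lambda nd: (-nd.count, nd.kmer))
    seeds = seeds[: 1 + max(0, max_seed_retries)]
    best: Optional[tuple[str, int, str]] = None  # (seq, n_nodes, seed)
    for seed_node in seeds:
        visited: set[str] = set()
        right = extend_path(graph, seed_node.kmer, "right", visited)
        left = extend_path(graph, seed_node.kmer, "left", visited)
        seq, n_nodes = _contig_from_walks(left, right)
        if best is None or n_nodes > best[1]:
            best = (seq, n_nodes, seed_node.kmer)
        if len(seq) >= min_length:
            break
    assert best is not None
    seq, n_nodes, seed_kmer = best
    if len(seq) < min_length:
        return None
    frac = len(seq) / target_length if target_length else 0.0
    return ContigResult(
        gene_id=gene_id,
        seq=seq,
        n_nodes_visited=n_nodes,
        seed_kmer=seed_kmer,
        recovered_fraction=frac,
    )
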