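"""Independent reference implementations used only to check aquamob.

These deliberately avoid the package's own code paths: alignment goes
through Bio.Align.PairwiseAligner, spacer search through a literal
sliding-window scan, clustering through all-pairs alignment, and the
rank-sum p-value through exhaustive enumeration of label arrangements.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def best_local_stats(small: str, large: str) -> tuple[float, float]:
    """(identity, coverage of the smaller sequence), best over strands."""
    aligner = _aligner()
    best = (0.0, 0.0)
    for query in (small, revcomp(small)):
        alns = aligner.align(large, query)
        if alns.score <= 0:
            continue
        aln = alns[0]
        counts = aln.counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        identity = counts.identities / columns if columns else 0.0
        qblocks = aln.aligned[1]
        span = qblocks[-1][1] - qblocks[0][0]
        cov = span / len(small)
        if (identity, cov) > best:
            best = (identity, cov)
    return best


def containment_edge(seq_a: str, seq_b: str, min_identity: float = 0.90,
                     min_cov: float = 0.90) -> bool:
    small, large = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    identity, cov = best_local_stats(small, large)
    return identity >= min_identity and cov >= min_cov


def brute_force_clusters(sequences: dict[str, str], min_identity: float = 0.90,
                         min_cov: float = 0.90) -> set[frozenset]:
    graph = nx.Graph()
    graph.add_nodes_from(sequences)
    for a, b in combinations(sorted(sequences), 2):
        if containment_edge(sequences[a], sequences[b], min_identity, min_cov):
            graph.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(graph)}


def brute_force_spacer_hits(spacer: str, mge_seq: str,
                            max_mm: int = 2,
                            min_identity: float = 0.90) -> int | None:
    """Best mismatch count over every window on both strands, or None."""
    L = len(spacer)
    best = None
    for probe in (spacer, revcomp(spacer)):
        for i in range(len(mge_seq) - L + 1):
            mm = sum(1 for x, y in zip(probe, mge_seq[i:i + L]) if x != y)
            if best is None or mm < best:
                best = mm
    if best is None or best > max_mm or (L - best) / L < min_identity:
        return None
    return best


def exact_ranksum_p(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum p by enumerating all label arrangements."""
    pooled = np.asarray(list(x) + list(y), dtype=float)
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties expected
    obs = ranks[:n].sum()
    mean = n * (n + m + 1) / 2
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        s = ranks[list(idx)].sum()
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
        total += 1
    return count / total


def canonical_kmer_set(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        out.add(min(kmer, revcomp(kmer)))
    return out
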