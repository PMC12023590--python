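"""Candidate-MGE catalog: containment dereplication, similarity modules,
composition summaries and reference-database matching.

Candidate contigs from upstream plasmid predictors are merged into one
catalog, dereplicated by pairwise containment (an edge when a local
alignment reaches >=90% identity over >=90% of the shorter sequence, both
thresholds configurable), and the same containment graph over the
non-redundant set yields similarity modules whose type composition
(plasmid-only / phage-only / uMGE-only / hybrid) is reported for modules
with at least three members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .alignment import align_containment, check_dna, revcomp, _SEED_K
from .util import pct

logger = logging.getLogger(__name__)

#: minimum candidate length carried through the pipeline (bp)
MIN_MGE_LENGTH = 1000


@dataclass(frozen=True)
class MgeRecord:
    """One candidate MGE contig."""

    mge_id: str
    sequence: str
    source_sample: str = ""
    predictors: frozenset = frozenset()
    circular_flag: bool | None = None  # metadata only, not used in clustering

    def __post_init__(self):
        check_dna(self.sequence, self.mge_id)
        if len(self.sequence) < MIN_MGE_LENGTH:
            raise ValueError(
                f"{self.mge_id}: length {len(self.sequence)} below the "
                f"{MIN_MGE_LENGTH} bp minimum")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DereplicationParams:
    min_identity: float = 0.90
    min_cov_smaller: float = 0.90

    def __post_init__(self):
        for name in ("min_identity", "min_cov_smaller"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class RefMatchParams:
    min_cov: float = 0.90
    min_identity: float = 0.60

    def __post_init__(self):
        for name in ("min_cov", "min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ContainmentEdge:
    id_a: str
    id_b: str
    identity: float
    cov_smaller: float
    strand: str = "+"  # orientation of the better alignment


@dataclass
class SimilarityModule:
    module_id: str
    member_ids: frozenset
    composition: str  # plasmid-only | phage-only | uMGE-only | hybrid | unlabeled
    eligible: bool    # at least three members -> counted in composition stats
    host_taxa: frozenset = field(default_factory=frozenset)


def _best_containment(seq_small: str, seq_large: str):
    """Best (identity, cov_smaller, strand) over both orientations."""
    best = None
    for strand, query in (("+", seq_small), ("-", revcomp(seq_small))):
        aln = align_containment(query, seq_large)
        if aln is None:
            continue
        ident = aln.identity
        cov = aln.coverage_of(len(seq_small), "a")
        if best is None or (ident, cov) > (best[0], best[1]):
            best = (ident, cov, strand)
    return best


def pairwise_containment(a: MgeRecord, b: MgeRecord,
                         params: DereplicationParams = DereplicationParams(),
                         ) -> ContainmentEdge | None:
    """Containment edge between two records, or None below thresholds.

    Symmetric in its arguments: the shorter sequence is always the aligned
    query, both strands are tried and the better orientation reported.
    """
    if a.mge_id == b.mge_id:
        raise ValueError("pairwise_containment requires distinct records")
    small, large = (a, b) if a.length <= b.length else (b, a)
    best = _best_containment(small.sequence, large.sequence)
    if best is None:
        return None
    ident, cov, strand = best
    if ident >= params.min_identity and cov >= params.min_cov_smaller:
        return ContainmentEdge(a.mge_id, b.mge_id, ident, cov, strand)
    return None


_CANDIDATE_K = 16
_CANDIDATE_MIN_SHARED = 2


def _candidate_pairs(records: list[MgeRecord], k: int = _CANDIDATE_K,
                     min_shared: int = _CANDIDATE_MIN_SHARED):
    """Pairs sharing >= ``min_shared`` seed k-mers (either strand).

    A containment at >=90% identity over >=1 kb shares hundreds of exact
    16-mers, so the prescreen cannot lose qualifying pairs in practice
    while skipping the quadratic alignment over unrelated ones.
    """
    index: dict[str, set[int]] = {}
    for idx, rec in enumerate(records):
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(idx)
    shared: dict[tuple[int, int], int] = {}
    for idx, rec in enumerate(records):
        for seq in (rec.sequence, revcomp(rec.sequence)):
            seen = {seq[i:i + k] for i in range(len(seq) - k + 1)}
            for kmer in seen:
                for jdx in index.get(kmer, ()):
                    if jdx > idx:
                        key = (idx, jdx)
                        shared[key] = shared.get(key, 0) + 1
    return sorted(p for p, c in shared.items() if c >= min_shared)


def containment_edges(records: list[MgeRecord],
                      params: DereplicationParams = DereplicationParams(),
                      ) -> list[ContainmentEdge]:
    edges = []
    for i, j in _candidate_pairs(records):
        edge = pairwise_containment(records[i], records[j], params)
        if edge is not None:
            edges.append(edge)
    return edges


def _identity_between(a: MgeRecord, b: MgeRecord) -> float:
    small, large = (a, b) if a.length <= b.length else (b, a)
    best = _best_containment(small.sequence, large.sequence)
    return best[0] if best else 0.0


def dereplicate(records: list[MgeRecord],
                params: DereplicationParams = DereplicationParams(),
                ) -> tuple[list[frozenset], dict[frozenset, str]]:
    """Cluster by containment and pick one representative per cluster.

    Clusters are connected components of the containment graph.  The
    representative maximizes mean pairwise identity to the other members;
    ties break by greater length, then lexicographic id.
    """
    ids = [r.mge_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mge_ids in input")
    by_id = {r.mge_id: r for r in records}
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from((e.id_a, e.id_b) for e in containment_edges(records, params))

    clusters: list[frozenset] = []
    representatives: dict[frozenset, str] = {}
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        cluster = frozenset(members)
        clusters.append(cluster)
        if len(members) == 1:
            representatives[cluster] = members[0]
            continue
        mean_ident = {}
        for mid in members:
            others = [m for m in members if m != mid]
            mean_ident[mid] = sum(
                _identity_between(by_id[mid], by_id[o]) for o in others
            ) / len(others)
        representatives[cluster] = sorted(
            members,
            key=lambda m: (-mean_ident[m], -by_id[m].length, m),
        )[0]
    clusters.sort(key=lambda c: sorted(c)[0])
    return clusters, representatives


def cluster_table(clusters, representatives) -> pd.DataFrame:
    rows = []
    for i, cluster in enumerate(clusters):
        rep = representatives[cluster]
        for mid in sorted(cluster):
            rows.append({"mge_id": mid, "cluster_id": f"C{i + 1:05d}",
                         "is_representative": mid == rep})
    return pd.DataFrame(rows)


def build_similarity_network(records: list[MgeRecord],
                             type_calls: dict[str, str],
                             params: DereplicationParams = DereplicationParams(),
                             host_taxa: dict[str, set] | None = None,
                             ) -> list[SimilarityModule]:
    """Similarity modules over the non-redundant catalog.

    ``type_calls`` maps mge_id to its triage label.  Modules with fewer
    than three members are retained but flagged ineligible for the
    composition statistics.
    """
    graph = nx.Graph()
    graph.add_nodes_from(r.mge_id for r in records)
    graph.add_edges_from((e.id_a, e.id_b) for e in containment_edges(records, params))
    modules = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps):
        members = frozenset(comp)
        labels = set()
        missing = False
        for mid in members:
            if mid in type_calls:
                labels.add(type_calls[mid])
            else:
                missing = True
        if missing:
            warnings.warn(f"module M{i + 1:05d} has members without triage "
                          "labels; composition set to 'unlabeled'")
            composition = "unlabeled"
        elif len(labels) > 1:
            composition = "hybrid"
        else:
            composition = f"{labels.pop()}-only"
        taxa = frozenset().union(
            *[frozenset((host_taxa or {}).get(m, ())) for m in members])
        modules.append(SimilarityModule(
            module_id=f"M{i + 1:05d}", member_ids=members,
            composition=composition, eligible=len(members) >= 3,
            host_taxa=taxa))
    return modules


def module_composition_summary(modules: list[SimilarityModule]) -> pd.DataFrame:
    """Composition shares among modules with at least three members."""
    eligible = [m for m in modules if m.eligible]
    denom = len(eligible)
    rows = []
    for comp in ("plasmid-only", "phage-only", "uMGE-only", "hybrid", "unlabeled"):
        count = sum(1 for m in eligible if m.composition == comp)
        if count == 0 and comp == "unlabeled":
            continue
        rows.append({"composition": comp, "count": count, "denominator": denom,
                     "percent": pct(count, denom) if denom else float("nan")})
    return pd.DataFrame(rows)


def summarize_catalog(type_counts: dict[str, int],
                      mobilizable_plasmids: int | None = None) -> pd.DataFrame:
    """Catalog composition table with explicit denominators.

    Percentages are count/denominator rounded half-up to two decimals.
    """
    for label, count in type_counts.items():
        if count < 0:
            raise ValueError(f"negative count for {label!r}")
    total = sum(type_counts.values())
    if total == 0:
        raise ZeroDivisionError("summarize_catalog: total count is zero")
    rows = [{"row": label, "count": count, "denominator": total,
             "percent": pct(count, total)}
            for label, count in type_counts.items()]
    if mobilizable_plasmids is not None:
        denom = type_counts.get("plasmid", 0)
        if denom == 0:
            raise ZeroDivisionError(
                "summarize_catalog: zero denominator for row "
                "'mobilizable_plasmids' (no plasmids)")
        rows.append({"row": "mobilizable_plasmids",
                     "count": mobilizable_plasmids, "denominator": denom,
                     "percent": pct(mobilizable_plasmids, denom)})
    return pd.DataFrame(rows)


def match_reference_db(mges: list[MgeRecord], refs: dict[str, str],
                       params: RefMatchParams = RefMatchParams(),
                       ) -> pd.DataFrame:
    """Best reference hit per MGE (>=90% MGE coverage, >=60% identity).

    Best match = highest identity, ties broken by coverage.  MGEs without a
    qualifying hit are absent from the table.
    """
    if not refs:
        raise ValueError("reference database is empty")
    rows = []
    for rec in mges:
        best = None
        for ref_id in sorted(refs):
            ref_seq = refs[ref_id]
            for query in (rec.sequence, revcomp(rec.sequence)):
                aln = align_containment(query, ref_seq)
                if aln is None:
                    continue
                ident = aln.identity
                cov = aln.coverage_of(rec.length, "a")
                if ident >= params.min_identity and cov >= params.min_cov:
                    cand = (ident, cov, ref_id)
                    if best is None or cand[:2] > best[:2]:
                        best = cand
        if best is not None:
            rows.append({"mge_id": rec.mge_id, "ref_id": best[2],
                         "identity": best[0], "query_coverage": best[1]})
    return pd.DataFrame(rows, columns=["mge_id", "ref_id", "identity",
                                       "query_coverage"])
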