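"""Microbe-MGE association networks from co-abundance.

Coverage prefilters are applied first, in a fixed order: (1) depths below
2X are treated as 0, (2) entities with post-zeroing total coverage below
50X are dropped, (3) entities detected in fewer than 25% of samples are
dropped.

Association inference is a compositional partial-correlation method:
depths are centered-log-ratio transformed per sample (zeros replaced by a
pseudocount of half the smallest nonzero value of the matrix), the joint
covariance across all nodes is estimated with Ledoit-Wolf shrinkage, and
partial correlations are read off the precision matrix.  Significance
comes from a permutation null (sample order permuted independently per
node), with Benjamini-Hochberg control at q <= 0.05 across node pairs.
This estimates the same conditional-dependence structure that sparse
inverse-covariance network methods target, at desk scale and fully
seeded; it is not a numerical replica of any particular tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from sklearn.covariance import LedoitWolf

MIN_SAMPLES = 8


@dataclass(frozen=True)
class NetworkFilterParams:
    min_total_coverage: float = 50.0
    min_depth: float = 2.0
    min_prevalence: float = 0.25

    def __post_init__(self):
        for name in ("min_total_coverage", "min_depth", "min_prevalence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def prefilter(coverage: pd.DataFrame,
              params: NetworkFilterParams = NetworkFilterParams()) -> pd.DataFrame:
    """Zero sub-threshold depths, then drop low-total and rare entities."""
    m = coverage.copy().astype(float)
    m[m < params.min_depth] = 0.0
    m = m[m.sum(axis=1) >= params.min_total_coverage]
    prevalence = (m > 0).mean(axis=1)
    return m[prevalence >= params.min_prevalence]


def clr_transform(coverage: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio per sample; pseudocount = half min nonzero value."""
    X = coverage.to_numpy(dtype=float)
    nonzero = X[X > 0]
    if nonzero.size == 0:
        raise ValueError("matrix has no nonzero entries")
    X = X + nonzero.min() / 2 * (X == 0)
    logX = np.log(X)
    clr = logX - logX.mean(axis=0, keepdims=True)  # center within sample
    return pd.DataFrame(clr, index=coverage.index, columns=coverage.columns)


def _partial_correlations(X: np.ndarray) -> np.ndarray:
    """Partial correlation matrix from samples-x-nodes data.

    Columns are standardized so the Ledoit-Wolf shrinkage acts on the
    correlation scale; partial correlations come off the precision matrix.
    """
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    prec = LedoitWolf(assume_centered=False).fit(Z).precision_
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def infer_network(mge_coverage: pd.DataFrame,
                  mag_coverages: list[pd.DataFrame] | None = None,
                  seed: int = 0, n_perm: int = 100,
                  q_threshold: float = 0.05) -> pd.DataFrame:
    """Association edges between prefiltered nodes.

    Each input matrix (MGE plus any number of MAG-group matrices) is CLR
    transformed separately, then all nodes are pooled.  Returns an edge
    table (node_a, node_b, weight, sign, p_value, q_value) with edges
    significant at BH q <= ``q_threshold``.
    """
    matrices = [mge_coverage] + list(mag_coverages or [])
    n_samples = matrices[0].shape[1]
    if n_samples < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, "
                         f"got {n_samples}")
    for m in matrices[1:]:
        if list(m.columns) != list(matrices[0].columns):
            raise ValueError("all matrices must share the same sample columns")
    clr = pd.concat([clr_transform(m) for m in matrices], axis=0)
    nodes = list(clr.index)
    if len(nodes) < 2:
        return pd.DataFrame(columns=["node_a", "node_b", "weight", "sign",
                                     "p_value", "q_value"])
    X = clr.to_numpy(dtype=float).T  # samples x nodes
    pc = _partial_correlations(X)

    # the null permutes the RAW depths per node and re-applies CLR, so the
    # closure-induced baseline dependence of the transform is present in
    # the null pool and only genuine co-abundance stands out
    rng = np.random.default_rng(seed)
    null_pool = []
    for _ in range(n_perm):
        permuted = []
        for m in matrices:
            raw = m.to_numpy(dtype=float)
            raw = np.stack([row[rng.permutation(n_samples)] for row in raw])
            permuted.append(pd.DataFrame(raw, index=m.index,
                                         columns=m.columns))
        clr_p = pd.concat([clr_transform(p) for p in permuted], axis=0)
        pcp = _partial_correlations(clr_p.to_numpy(dtype=float).T)
        null_pool.append(np.abs(pcp[np.triu_indices_from(pcp, 1)]))
    null_pool = np.sort(np.concatenate(null_pool))

    pairs = list(combinations(range(len(nodes)), 2))
    obs = np.array([abs(pc[i, j]) for i, j in pairs])
    # fraction of pooled null values >= observed, with the +1 correction
    exceed = null_pool.size - np.searchsorted(null_pool, obs, side="left")
    pvals = (1 + exceed) / (1 + null_pool.size)
    qvals = false_discovery_control(pvals, method="bh")

    rows = []
    for (i, j), p, qv in zip(pairs, pvals, qvals):
        if qv <= q_threshold:
            w = float(pc[i, j])
            rows.append({"node_a": nodes[i], "node_b": nodes[j], "weight": w,
                         "sign": "positive" if w > 0 else "negative",
                         "p_value": float(p), "q_value": float(qv)})
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "sign",
                                       "p_value", "q_value"])


def congruence_with_hosts(edges: pd.DataFrame, assignments: pd.DataFrame,
                          taxonomy: pd.DataFrame,
                          type_calls: pd.DataFrame) -> pd.DataFrame:
    """Positive MGE-MAG edges whose MAG matches the MGE's linked host order.

    Per MGE type: number of positive MGE-MAG edges, how many of them point
    at a MAG of the same order as an already-linked host, and the
    fraction.  MGEs without any host link count in the denominator.
    """
    tax = taxonomy.set_index("mag_id")["order"]
    labels = type_calls.set_index("mge_id")["label"]
    linked_orders: dict[str, set] = {}
    for _, row in assignments.iterrows():
        order = tax.get(row["mag_id"])
        if order is not None:
            linked_orders.setdefault(row["mge_id"], set()).add(order)

    stats: dict[str, list[int]] = {}
    for _, e in edges.iterrows():
        if e["sign"] != "positive":
            continue
        a, b = e["node_a"], e["node_b"]
        if a in labels.index and b in tax.index:
            mge, mag = a, b
        elif b in labels.index and a in tax.index:
            mge, mag = b, a
        else:
            continue
        label = labels[mge]
        rec = stats.setdefault(label, [0, 0])
        rec[0] += 1
        if tax[mag] in linked_orders.get(mge, set()):
            rec[1] += 1
    rows = [{"mge_type": label, "n_positive_edges": n, "n_congruent_at_order": c,
             "fraction": c / n if n else 0.0}
            for label, (n, c) in sorted(stats.items())]
    return pd.DataFrame(rows, columns=["mge_type", "n_positive_edges",
                                       "n_congruent_at_order", "fraction"])


def to_graphml(edges: pd.DataFrame, path) -> None:
    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["node_a"], e["node_b"], weight=float(e["weight"]),
                   sign=e["sign"], q_value=float(e["q_value"]))
    nx.write_graphml(g, path)
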