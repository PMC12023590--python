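"""Coverage normalization, presence/core logic and community statistics.

Depth matrices (entities x samples, MetaBAT-style adjusted coverage
computed upstream) are normalized by a per-sample scaling factor
mean(rpoB)/rpoB(s) derived from single-copy RNA polymerase B counts, so
that multiplying every rpoB count by a constant leaves the output
unchanged.  An entity is "present" in a (well, fraction) group when its
normalized depth exceeds 1 (strict) in any replicate (configurable to
all).  Core sets are derived per well (both fractions), per fraction
(all wells having that fraction) and globally.

The permutation statistics (PERMANOVA pseudo-F, Mantel on Spearman
correlation of distance triangles, Procrustes/protest over principal
coordinates) all use the (1 + #{permuted >= observed}) / (1 + n_perm)
p-value estimator and an explicit integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class PresenceParams:
    depth_threshold: float = 1.0  # strict >
    replicate_rule: str = "any"   # any | all

    def __post_init__(self):
        if self.depth_threshold < 0:
            raise ValueError("depth_threshold must be >= 0")
        if self.replicate_rule not in ("any", "all"):
            raise ValueError("replicate_rule must be 'any' or 'all'")


@dataclass
class CoreSummary:
    per_well_core: dict[str, frozenset]      # both fractions within a well
    per_fraction_core: dict[str, frozenset]  # one fraction across all wells
    global_core: frozenset                   # every (well, fraction) group
    catalog_size: int

    def counts(self) -> pd.DataFrame:
        rows = [{"scope": f"well:{w}", "count": len(s),
                 "denominator": self.catalog_size}
                for w, s in sorted(self.per_well_core.items())]
        rows += [{"scope": f"fraction:{f}", "count": len(s),
                  "denominator": self.catalog_size}
                 for f, s in sorted(self.per_fraction_core.items())]
        rows.append({"scope": "global", "count": len(self.global_core),
                     "denominator": self.catalog_size})
        return pd.DataFrame(rows)


def _check_metadata(coverage: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    missing = [s for s in coverage.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return meta.loc[list(coverage.columns)]


def normalize_coverage(coverage: pd.DataFrame, rpob: pd.Series) -> pd.DataFrame:
    """Scale each sample column by mean(rpoB) / rpoB(sample)."""
    factors = {}
    for sample in coverage.columns:
        if sample not in rpob.index:
            raise ValueError(f"no rpoB count for sample {sample!r}")
        if rpob[sample] <= 0:
            raise ValueError(f"rpoB count for sample {sample!r} must be > 0")
    mean_rpob = float(rpob[list(coverage.columns)].mean())
    factors = {s: mean_rpob / float(rpob[s]) for s in coverage.columns}
    return coverage * pd.Series(factors)


def presence(normalized: pd.DataFrame, metadata: pd.DataFrame,
             params: PresenceParams = PresenceParams()) -> pd.DataFrame:
    """Entity x group boolean matrix; groups are (well, fraction) pairs."""
    meta = _check_metadata(normalized, metadata)
    groups = meta.groupby(["well", "fraction"]).groups
    out = {}
    for (well, fraction), samples in sorted(groups.items()):
        if len(samples) == 0:
            raise ValueError(f"group ({well}, {fraction}) has no replicates")
        over = normalized[list(samples)] > params.depth_threshold
        col = over.any(axis=1) if params.replicate_rule == "any" else over.all(axis=1)
        out[f"{well}|{fraction}"] = col
    return pd.DataFrame(out)


def core_mges(presence_matrix: pd.DataFrame, metadata: pd.DataFrame,
              catalog_size: int | None = None) -> CoreSummary:
    """Core sets at well, fraction and global scope.

    Wells lacking a fraction are excluded from that fraction's all-well
    core, mirroring designs where one well misses a filter fraction.
    """
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    group_cols = list(presence_matrix.columns)
    wells_by_group = {g: g.split("|")[0] for g in group_cols}
    fracs_by_group = {g: g.split("|")[1] for g in group_cols}
    wells = sorted(set(wells_by_group.values()))
    fractions = sorted(set(fracs_by_group.values()))
    if len(wells) < 2:
        raise ValueError("core analysis requires at least two wells")

    per_well = {}
    for well in wells:
        cols = [g for g in group_cols if wells_by_group[g] == well]
        per_well[well] = frozenset(
            presence_matrix.index[presence_matrix[cols].all(axis=1)])

    per_fraction = {}
    for fraction in fractions:
        cols = [g for g in group_cols if fracs_by_group[g] == fraction]
        per_fraction[fraction] = frozenset(
            presence_matrix.index[presence_matrix[cols].all(axis=1)])

    global_core = frozenset(
        presence_matrix.index[presence_matrix[group_cols].all(axis=1)])
    return CoreSummary(per_well_core=per_well, per_fraction_core=per_fraction,
                       global_core=global_core,
                       catalog_size=catalog_size or len(presence_matrix))


def distance_matrix(data: pd.DataFrame, metric: str = "bray_curtis",
                    presence_threshold: float = 1.0) -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix.

    Bray-Curtis on depths, Jaccard on presence (depth > threshold).  Two
    all-empty samples are at distance 0, an empty vs a non-empty sample at
    distance 1 (documented convention).
    """
    if data.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = data.to_numpy(dtype=float).T  # samples x entities
    n = X.shape[0]
    D = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                denom = (X[i] + X[j]).sum()
                D[i, j] = D[j, i] = (np.abs(X[i] - X[j]).sum() / denom
                                     if denom > 0 else 0.0)
    elif metric == "jaccard":
        P = X > presence_threshold
        for i in range(n):
            for j in range(i + 1, n):
                union = (P[i] | P[j]).sum()
                inter = (P[i] & P[j]).sum()
                D[i, j] = D[j, i] = 1 - inter / union if union else 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(D, index=data.columns, columns=data.columns)


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances for one labelling.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum_g sum_{i<j in g} d2_ij
    / n_g, computed as a one-hot quadratic form.
    """
    n = d2.shape[0]
    a = int(labels.max()) + 1
    M = np.zeros((n, a))
    M[np.arange(n), labels] = 1.0
    ng = M.sum(axis=0)
    quad = (M * (d2 @ M)).sum(axis=0)  # sum_{i,j in g} d2_ij per group
    ss_within = float((quad / (2 * ng)).sum())
    ss_total = float(d2.sum() / (2 * n))
    ss_among = ss_total - ss_within
    if ss_within == 0.0:
        # perfect within-group homogeneity: pseudo-F diverges
        f = np.inf if ss_among > 0 else 0.0
    else:
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(d: pd.DataFrame | np.ndarray, grouping, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float, float]:
    """One-factor PERMANOVA: (pseudo-F, R^2, permutation p).

    Distance-based partition of the sum of squares; p is estimated as
    (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    D = np.asarray(d, dtype=float)
    labels, _ = pd.factorize(np.asarray(grouping))
    labels = labels.astype(np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = D ** 2
    f_obs, r2 = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_f(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(r2), float(p)


def pcoa_coordinates(d: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Principal coordinates of a distance matrix (positive axes only)."""
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(vals.max(), 0) * 1e-10
    if not keep.any():
        raise ValueError("distance matrix has no positive principal axes")
    return vecs[:, keep] * np.sqrt(vals[keep])


def _protest_r(Xc: np.ndarray, Yc: np.ndarray) -> float:
    """Procrustes correlation r = sqrt(1 - m12^2) for centered, unit-norm
    configurations (rotation/reflection optimal by SVD)."""
    s = np.linalg.svd(Xc.T @ Yc, compute_uv=False).sum()
    m12_sq = max(0.0, 1.0 - s ** 2)
    return float(np.sqrt(1.0 - m12_sq))


def procrustes_test(dA: pd.DataFrame | np.ndarray, dB: pd.DataFrame | np.ndarray,
                    n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """Procrustean superimposition of two ordinations with permutation p.

    Principal-coordinate configurations are computed from each distance
    matrix, centered and scaled to unit sum of squares; the statistic is
    r = sqrt(1 - m12^2) and p permutes the row order of one configuration.
    """
    A, B = np.asarray(dA, float), np.asarray(dB, float)
    if A.shape != B.shape:
        raise ValueError("distance matrices must have identical shape")
    if A.shape[0] < 3:
        raise ValueError("procrustes_test needs at least three samples")
    X, Y = pcoa_coordinates(A), pcoa_coordinates(B)
    k = min(X.shape[1], Y.shape[1])
    X, Y = X[:, :k], Y[:, :k]
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    X /= np.linalg.norm(X)
    Y /= np.linalg.norm(Y)
    r_obs = _protest_r(X, Y)
    rng = np.random.default_rng(seed)
    count = 0
    n = X.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _protest_r(X, Y[perm]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else np.nan


def mantel(dA: pd.DataFrame | np.ndarray, dB: pd.DataFrame | np.ndarray,
           n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """Mantel test: Spearman correlation of lower-triangle distances.

    p permutes rows and columns of the second matrix jointly.  A constant
    distance matrix has no defined correlation: returns (nan, nan) with a
    warning.
    """
    A, B = np.asarray(dA, float), np.asarray(dB, float)
    if A.shape != B.shape:
        raise ValueError("distance matrices must have identical shape")
    n = A.shape[0]
    tri = np.tril_indices(n, -1)
    a, b = A[tri], B[tri]
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        warnings.warn("constant distance matrix: Mantel r undefined")
        return float("nan"), float("nan")
    r_obs = _spearman(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _spearman(a, B[np.ix_(perm, perm)][tri]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)
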