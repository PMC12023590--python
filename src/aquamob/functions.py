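"""Functional profiling of MGE types and environmental screening.

COG single-letter categories are profiled per (sample, MGE type) as
relative abundances over categorized genes, with the uncategorized
fraction reported separately.  Between-type enrichment uses the two-sided
rank-sum (Wilcoxon/Mann-Whitney) test per category with BH adjustment.
Environmental screening computes Spearman correlations of normalized MGE
depths against measured variables with a seeded permutation test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata

ENV_VARIABLES = ("pH", "dissolved_oxygen", "ammonium", "nitrate", "sulfate")


def cog_profile(annotations: pd.DataFrame, type_calls: pd.DataFrame,
                sample_map: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(profile, uncategorized) tables per (sample, MGE type).

    ``annotations`` needs mge_id, gene_id, cog_category (empty/NaN means
    uncategorized); ``sample_map`` maps mge_id -> sample.  Relative
    abundance = category count / categorized genes of that (sample, type).
    """
    labels = type_calls.set_index("mge_id")["label"]
    ann = annotations.copy()
    ann["label"] = ann["mge_id"].map(labels)
    ann["sample"] = ann["mge_id"].map(sample_map)
    ann = ann.dropna(subset=["label", "sample"])
    cat = ann["cog_category"].fillna("").astype(str).str.strip()
    ann["categorized"] = cat != ""
    ann["cog_category"] = cat

    profile_rows, uncat_rows = [], []
    for (sample, label), sub in ann.groupby(["sample", "label"], sort=True):
        total = len(sub)
        n_cat = int(sub["categorized"].sum())
        uncat_rows.append({"sample": sample, "mge_type": label,
                           "n_genes": total, "n_categorized": n_cat,
                           "uncategorized_fraction":
                               (total - n_cat) / total if total else 0.0})
        if n_cat == 0:
            continue
        counts = sub.loc[sub["categorized"], "cog_category"].value_counts()
        for category, count in sorted(counts.items()):
            profile_rows.append({"sample": sample, "mge_type": label,
                                 "category": category,
                                 "relative_abundance": count / n_cat})
    profile = pd.DataFrame(profile_rows, columns=["sample", "mge_type",
                                                  "category",
                                                  "relative_abundance"])
    uncategorized = pd.DataFrame(uncat_rows)
    return profile, uncategorized


def compare_types(profile: pd.DataFrame, type_a: str, type_b: str,
                  exact_max_n: int = 20) -> pd.DataFrame:
    """Per-category two-sided rank-sum test between two MGE types.

    Exact null distribution for combined sample count <= ``exact_max_n``
    (and no ties), normal approximation with tie and continuity correction
    otherwise; BH adjustment across categories.
    """
    sub_a = profile[profile["mge_type"] == type_a]
    sub_b = profile[profile["mge_type"] == type_b]
    samples_a = sorted(set(sub_a["sample"]))
    samples_b = sorted(set(sub_b["sample"]))
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("compare_types needs >= 3 samples per type")
    lut_a = sub_a.set_index(["sample", "category"])["relative_abundance"]
    lut_b = sub_b.set_index(["sample", "category"])["relative_abundance"]
    rows = []
    categories = sorted(set(sub_a["category"]) | set(sub_b["category"]))
    for category in categories:
        # a type lacking the category in some sample contributes 0 there
        va = np.array([lut_a.get((s, category), 0.0) for s in samples_a])
        vb = np.array([lut_b.get((s, category), 0.0) for s in samples_b])
        if np.array_equal(va, vb):
            rows.append({"category": category, "statistic": len(va) * len(vb) / 2,
                         "p_value": 1.0})
            continue
        has_ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
        method = "exact" if (len(va) + len(vb) <= exact_max_n
                             and not has_ties) else "asymptotic"
        res = mannwhitneyu(va, vb, alternative="two-sided", method=method,
                           use_continuity=True)
        rows.append({"category": category, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = false_discovery_control(out["p_value"], method="bh")
    else:
        out = pd.DataFrame(columns=["category", "statistic", "p_value", "q_value"])
    return out


def env_correlation(normalized_coverage: pd.DataFrame, env: pd.DataFrame,
                    n_perm: int = 999, alpha: float = 0.05,
                    seed: int = 0) -> tuple[pd.DataFrame, frozenset]:
    """Spearman rho and permutation p per (MGE, environmental variable).

    p = (1 + #{|rho_perm| >= |rho|}) / (1 + n_perm) with the environmental
    vector permuted.  An MGE is flagged "strongly associated" when any
    variable reaches p < alpha.  Constant variables give missing rho.
    """
    env = env.set_index("sample") if "sample" in env.columns else env
    samples = [s for s in normalized_coverage.columns if s in env.index]
    if len(samples) < 5:
        raise ValueError("env_correlation needs >= 5 samples with "
                         "environmental values")
    X = normalized_coverage[samples].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    flagged = set()
    n = len(samples)
    rX = np.apply_along_axis(rankdata, 1, X)
    rX = rX - rX.mean(axis=1, keepdims=True)
    norm_X = np.sqrt((rX ** 2).sum(axis=1))
    variables = [v for v in env.columns if v in ENV_VARIABLES] or list(env.columns)
    for var in variables:
        y = env.loc[samples, var].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            warnings.warn(f"environmental variable {var!r} is constant; "
                          "rho undefined")
            for mge_id in normalized_coverage.index:
                rows.append({"mge_id": mge_id, "variable": var,
                             "rho": np.nan, "p_value": np.nan})
            continue
        ry = rankdata(y)
        ry = ry - ry.mean()
        norm_y = np.sqrt((ry ** 2).sum())
        with np.errstate(invalid="ignore"):
            rho = (rX @ ry) / (norm_X * norm_y)
        rho = np.where(norm_X > 0, rho, np.nan)
        perms = np.stack([ry[rng.permutation(n)] for _ in range(n_perm)])
        with np.errstate(invalid="ignore"):
            rho_perm = (rX @ perms.T) / (norm_X[:, None] * norm_y)
        exceed = (np.abs(rho_perm) >= np.abs(rho)[:, None]).sum(axis=1)
        pvals = (1 + exceed) / (1 + n_perm)
        for mge_id, r, p in zip(normalized_coverage.index, rho, pvals):
            rows.append({"mge_id": mge_id, "variable": var,
                         "rho": float(r) if np.isfinite(r) else np.nan,
                         "p_value": float(p) if np.isfinite(r) else np.nan})
            if np.isfinite(r) and p < alpha:
                flagged.add(mge_id)
    return pd.DataFrame(rows), frozenset(flagged)


def unique_functions_of_correlated(flagged: frozenset,
                                   annotations: pd.DataFrame) -> pd.DataFrame:
    """Function terms present only among flagged MGEs, with counts."""
    texts = annotations[["mge_id", "function_text"]].dropna()
    in_flagged = texts[texts["mge_id"].isin(flagged)]
    in_rest = set(texts.loc[~texts["mge_id"].isin(flagged), "function_text"])
    counts = in_flagged["function_text"].value_counts()
    rows = [{"function_text": fn, "count": int(c)}
            for fn, c in sorted(counts.items()) if fn not in in_rest]
    return pd.DataFrame(rows, columns=["function_text", "count"])


def tpm_summarize(tpm: pd.DataFrame, well_map: pd.Series,
                  rpob_factors: pd.Series) -> pd.DataFrame:
    """Per-gene per-well mean of rpoB-scaled TPM on log2 scale.

    value = log2(mean_over_well_samples(tpm * factor) + 1); single-sample
    wells pass their value through unaveraged.
    """
    unknown = [s for s in tpm.columns if s not in well_map.index]
    if unknown:
        raise ValueError(f"samples missing from well map: {unknown}")
    scaled = tpm * rpob_factors[list(tpm.columns)]
    out = {}
    for well in sorted(set(well_map[list(tpm.columns)])):
        samples = [s for s in tpm.columns if well_map[s] == well]
        out[well] = np.log2(scaled[samples].mean(axis=1) + 1)
    return pd.DataFrame(out, index=tpm.index)


def ordered_presence_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence matrix reordered by average-linkage hierarchical
    clustering on Euclidean distance (rows and columns), ready for
    heatmap rendering."""
    M = presence.astype(float)

    def _order(frame):
        if len(frame) < 3:
            return list(frame.index)
        link = hierarchy.linkage(pdist(frame.to_numpy()), method="average")
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    return M.loc[_order(M), _order(M.T)]
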