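"""Normalization, presence/core logic and permutation statistics, with
scikit-bio as the independent cross-check for PERMANOVA and Mantel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aquamob import abundance
from aquamob.abundance import (PresenceParams, core_mges, distance_matrix,
                               mantel, normalize_coverage, permanova,
                               presence, procrustes_test)


def _meta(wells=("W1", "W2"), fractions=("f1", "f2"), reps=2):
    rows = []
    for w in wells:
        for f in fractions:
            for r in range(1, reps + 1):
                rows.append({"sample": f"{w}_{f}_r{r}", "well": w,
                             "fraction": f, "replicate": r})
    return pd.DataFrame(rows)


class TestNormalize:
    def test_equal_rpob_is_identity(self):
        cov = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 0.0]})
        rpob = pd.Series({"s1": 7.0, "s2": 7.0})
        pd.testing.assert_frame_equal(normalize_coverage(cov, rpob), cov)

    def test_doubled_rpob_scales_by_mean_ratio(self):
        # rpob {1, 2}: mean 1.5 -> column 2 multiplied by 0.75
        cov = pd.DataFrame({"s1": [4.0], "s2": [4.0]})
        rpob = pd.Series({"s1": 1.0, "s2": 2.0})
        out = normalize_coverage(cov, rpob)
        assert out.loc[0, "s1"] == pytest.approx(6.0)
        assert out.loc[0, "s2"] == pytest.approx(3.0)

    def test_scaling_all_rpob_is_invariant(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(rng.lognormal(1, 1, (5, 4)),
                           columns=list("abcd"))
        rpob = pd.Series(rng.integers(50, 200, 4).astype(float),
                         index=list("abcd"))
        out1 = normalize_coverage(cov, rpob)
        out2 = normalize_coverage(cov, rpob * 13.7)
        pd.testing.assert_frame_equal(out1, out2)

    def test_zeros_stay_zero_and_bad_rpob_rejected(self):
        cov = pd.DataFrame({"s1": [0.0], "s2": [1.0]})
        rpob = pd.Series({"s1": 5.0, "s2": 3.0})
        assert normalize_coverage(cov, rpob).loc[0, "s1"] == 0.0
        with pytest.raises(ValueError, match="s2"):
            normalize_coverage(cov, pd.Series({"s1": 5.0, "s2": 0.0}))


class TestPresence:
    def test_strict_threshold_and_replicate_rules(self):
        meta = _meta(wells=("W1",), fractions=("f1",), reps=3)
        cov = pd.DataFrame(
            {"W1_f1_r1": [1.0, 1.01], "W1_f1_r2": [0.5, 0.0],
             "W1_f1_r3": [0.9, 0.2]}, index=["at_one", "just_over"])
        any_rule = presence(cov, meta, PresenceParams(replicate_rule="any"))
        assert not any_rule.loc["at_one", "W1|f1"]      # 1.0 is not > 1
        assert any_rule.loc["just_over", "W1|f1"]
        all_rule = presence(cov, meta, PresenceParams(replicate_rule="all"))
        assert not all_rule.loc["just_over", "W1|f1"]

    def test_unknown_sample_metadata_rejected(self):
        cov = pd.DataFrame({"mystery": [2.0]})
        with pytest.raises(ValueError, match="mystery"):
            presence(cov, _meta())


class TestCore:
    def _presence_frame(self):
        meta = _meta()
        cols = ["W1|f1", "W1|f2", "W2|f1", "W2|f2"]
        data = {
            "everywhere": [True, True, True, True],
            "f1_only": [True, False, True, False],
            "w1_only": [True, True, False, False],
            "nowhere": [False, False, False, False],
        }
        return pd.DataFrame(data, index=cols).T, meta

    def test_scope_membership(self):
        pres, meta = self._presence_frame()
        core = core_mges(pres, meta)
        assert core.global_core == frozenset({"everywhere"})
        assert core.per_fraction_core["f1"] == {"everywhere", "f1_only"}
        assert core.per_fraction_core["f2"] == {"everywhere"}
        assert core.per_well_core["W1"] == {"everywhere", "w1_only"}

    def test_missing_fraction_well_excluded_from_fraction_core(self):
        # one well lacks fraction f1 entirely (the missing-filter case):
        # its absence must not empty the f1 all-well core
        meta = _meta()
        pres = pd.DataFrame({
            "W1|f1": [True], "W1|f2": [True],
            "W2|f2": [True],  # W2 has no f1 group
        }, index=["m"])
        core = core_mges(pres, meta)
        assert core.per_fraction_core["f1"] == {"m"}
        assert core.global_core == {"m"}

    def test_planted_core_recovered_exactly(self, small_bundle, small_truth):
        cov = small_bundle.mge_coverage
        norm = normalize_coverage(cov.raw(), cov.rpob)
        pres = presence(norm, small_bundle.metadata)
        core = core_mges(pres, small_bundle.metadata)
        assert core.global_core == small_truth.planted_core_ids

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nesting_invariants_on_random_presence(self, seed):
        rng = np.random.default_rng(seed)
        meta = _meta(wells=("W1", "W2", "W3"))
        cols = [f"{w}|{f}" for w in ("W1", "W2", "W3") for f in ("f1", "f2")]
        pres = pd.DataFrame(rng.random((12, 6)) < 0.6,
                            index=[f"m{i}" for i in range(12)], columns=cols)
        core = core_mges(pres, meta)
        for frac_core in core.per_fraction_core.values():
            assert core.global_core <= frac_core
        for well, well_core in core.per_well_core.items():
            present_somewhere = {
                m for m in pres.index
                if pres.loc[m, [c for c in cols if c.startswith(well)]].any()}
            assert well_core <= present_somewhere


class TestDistances:
    def test_identical_columns_at_distance_zero(self):
        cov = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        d = distance_matrix(cov, "bray_curtis")
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_presence_is_jaccard_one(self):
        cov = pd.DataFrame({"a": [5.0, 0.0], "b": [0.0, 5.0]})
        assert distance_matrix(cov, "jaccard").loc["a", "b"] == 1.0

    def test_bray_curtis_closed_form(self):
        cov = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert distance_matrix(cov, "bray_curtis").loc["a", "b"] == 1.0

    def test_empty_sample_convention(self):
        cov = pd.DataFrame({"a": [0.0, 0.0], "b": [0.0, 0.0], "c": [1.0, 2.0]})
        d = distance_matrix(cov, "bray_curtis")
        assert d.loc["a", "b"] == 0.0 and d.loc["a", "c"] == 1.0

    def test_matches_scipy_on_random_data(self):
        from scipy.spatial.distance import braycurtis
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(rng.lognormal(1, 1, (8, 5)),
                           columns=list("abcde"))
        d = distance_matrix(cov, "bray_curtis")
        for i, x in enumerate("abcde"):
            for y in "abcde"[i + 1:]:
                assert d.loc[x, y] == pytest.approx(
                    braycurtis(cov[x], cov[y]))


class TestPermanova:
    def _data(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(1, 0.5, (10, 12))
        X[:, 6:] *= np.exp(shift)
        cov = pd.DataFrame(X, columns=[f"s{i}" for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        return distance_matrix(cov, "bray_curtis"), groups

    def test_agrees_with_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        d, groups = self._data(seed=3, shift=0.8)
        f_obs, r2, _ = permanova(d, groups, n_perm=99, seed=1)
        res = skbio_permanova(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                              grouping=groups, permutations=99)
        assert f_obs == pytest.approx(res["test statistic"], rel=1e-9)

    def test_separated_clusters_reach_minimum_p(self):
        # disjoint entity blocks: every between-group distance is 1, and
        # with C(24,12) ~ 2.7M partitions the permutation stream will not
        # re-draw the observed grouping
        rng = np.random.default_rng(4)
        X = np.zeros((10, 24))
        X[:5, :12] = rng.lognormal(2, 0.3, (5, 12))
        X[5:, 12:] = rng.lognormal(2, 0.3, (5, 12))
        cov = pd.DataFrame(X, columns=[f"s{i}" for i in range(24)])
        groups = ["a"] * 12 + ["b"] * 12
        d = distance_matrix(cov, "bray_curtis")
        _, r2, p = permanova(d, groups, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert 0 <= r2 <= 1

    def test_single_group_rejected(self):
        d, _ = self._data()
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["a"] * 12)

    def test_seed_reproducibility(self):
        d, groups = self._data(seed=5, shift=0.3)
        assert permanova(d, groups, seed=7) == permanova(d, groups, seed=7)


class TestProcrustesAndMantel:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        covA = pd.DataFrame(rng.lognormal(1, 1, (10, 9)))
        covB = pd.DataFrame(rng.lognormal(1, 1, (10, 9)))
        return (distance_matrix(covA, "bray_curtis"),
                distance_matrix(covB, "bray_curtis"))

    def test_identical_matrices_give_r_one_min_p(self):
        dA, _ = self._pair(1)
        r, p = procrustes_test(dA, dA, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)
        r, p = mantel(dA, dA, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_mantel_agrees_with_scikit_bio_statistic(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel
        dA, dB = self._pair(2)
        r, _ = mantel(dA, dB, n_perm=9, seed=0)
        r_ref = skbio_mantel(DistanceMatrix(dA.to_numpy()),
                             DistanceMatrix(dB.to_numpy()),
                             method="spearman", permutations=9)[0]
        assert r == pytest.approx(r_ref, rel=1e-9)

    def test_independent_configurations_rarely_significant(self):
        hits = 0
        for s in range(30):
            dA, dB = self._pair(100 + s)
            _, p = procrustes_test(dA, dB, n_perm=99, seed=s)
            hits += p <= 0.05
        assert hits <= 5  # ~alpha of 30 trials

    def test_constant_matrix_mantel_is_missing(self):
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
        with pytest.warns(UserWarning, match="constant"):
            r, p = mantel(d, d * 0.5 + 0.5 - np.eye(4) * 0.5)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_samples_rejected(self):
        d = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="three samples"):
            procrustes_test(d, d)
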