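"""MinHash screen, spacer matching and link summaries."""

import numpy as np
import pandas as pd
import pytest

from aquamob import hostlink
from aquamob.hostlink import (SpacerParams, match_spacers, merge_host_links,
                              normalize_counts_by_taxon, screen,
                              summarize_links)
from aquamob.minhash import (SketchParams, canonical_kmer_hashes, containment,
                             sketch)

from conftest import mutate_seq, random_seq
from _oracles import brute_force_spacer_hits, canonical_kmer_set, revcomp


class TestSketch:
    def test_reverse_complement_gives_identical_sketch(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 3000)
        assert np.array_equal(sketch(seq).hashes, sketch(revcomp(seq)).hashes)

    def test_sketch_size_bounded_by_distinct_kmers(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 600)
        sk = sketch(seq)
        n_distinct = len(canonical_kmer_set(seq, 21))
        assert len(sk) == min(1000, n_distinct)

    def test_sketch_is_deterministic(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 2000)
        assert np.array_equal(sketch(seq).hashes, sketch(seq).hashes)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            sketch("ACGTACGT")

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="min_shared"):
            SketchParams(min_shared=2000)
        with pytest.raises(ValueError, match="k must"):
            SketchParams(k=40)


class TestScreen:
    def test_embedded_sequence_has_containment_exactly_one(self):
        rng = np.random.default_rng(3)
        mge = random_seq(rng, 4000)
        mag = random_seq(rng, 20000)
        mag = mag[:7000] + mge + mag[7000:]
        sk = sketch(mge, source_id="m")
        pool = canonical_kmer_hashes(mag, 21)
        shared, c, est = containment(sk, pool, 21)
        assert shared == len(sk) and c == 1.0 and est == 1.0
        assert screen(sk, pool, "mag") is not None

    def test_unrelated_pair_yields_no_link(self):
        rng = np.random.default_rng(4)
        sk = sketch(random_seq(rng, 5000), source_id="m")
        pool = canonical_kmer_hashes(random_seq(rng, 100000), 21)
        shared, c, est = containment(sk, pool, 21)
        assert shared <= 2
        assert screen(sk, pool, "mag") is None

    def test_identity_boundary_conversion(self):
        # c = 0.8097 at k = 21 sits exactly on the 0.99 identity threshold
        est = 0.8097 ** (1 / 21)
        assert est == pytest.approx(0.990, abs=5e-4)
        assert est == pytest.approx(np.exp(np.log(0.8097) / 21), rel=1e-12)

    def test_k_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        sk = sketch(random_seq(rng, 2000), SketchParams(k=15))
        pool = canonical_kmer_hashes(random_seq(rng, 2000), 21)
        with pytest.raises(ValueError, match="k mismatch"):
            containment(sk, pool, 21)

    def test_minhash_containment_tracks_truth_within_binomial_bounds(self):
        # bottom-k estimate vs exact containment over random pairs
        rng = np.random.default_rng(6)
        failures = 0
        trials = 100
        for _ in range(trials):
            s = random_seq(rng, 3000)
            frac = rng.uniform(0.2, 0.9)
            m = int(frac * len(s))
            t = s[:m + 20] + random_seq(rng, 2000)
            true_c = len(canonical_kmer_set(s, 21) & canonical_kmer_set(t, 21)) \
                / len(canonical_kmer_set(s, 21))
            sk = sketch(s)
            shared, c, _ = containment(sk, canonical_kmer_hashes(t, 21), 21)
            bound = 3 * np.sqrt(true_c * (1 - true_c) / len(sk))
            if abs(c - true_c) > bound:
                failures += 1
        assert failures <= 1  # >= 99% of trials inside 3 sigma


class TestSpacers:
    def _mges(self, rng):
        return {"m1": random_seq(rng, 2000), "m2": random_seq(rng, 1500)}

    def test_exact_spacer_hit(self):
        rng = np.random.default_rng(7)
        mges = self._mges(rng)
        spacer = mges["m1"][300:330]
        table = pd.DataFrame([{"spacer_id": "s1", "mag_id": "g1",
                               "sequence": spacer}])
        hits = match_spacers(table, mges)
        row = hits.iloc[0]
        assert (row["mge_id"], row["mismatches"]) == ("m1", 0)
        assert row["est_identity"] == 1.0

    def test_two_mismatches_accepted_three_rejected(self):
        rng = np.random.default_rng(8)
        mges = self._mges(rng)
        proto = mges["m2"][200:226]  # 26 bp
        two = mutate_seq_positions(proto, [3, 17])
        three = mutate_seq_positions(proto, [3, 11, 17])
        table = pd.DataFrame([
            {"spacer_id": "two", "mag_id": "g", "sequence": two},
            {"spacer_id": "three", "mag_id": "g", "sequence": three}])
        hits = match_spacers(table, mges)
        assert list(hits["spacer_id"]) == ["two"]
        assert hits.iloc[0]["mismatches"] == 2
        assert hits.iloc[0]["est_identity"] == pytest.approx(24 / 26)

    def test_length_threshold_25_vs_26(self):
        rng = np.random.default_rng(9)
        mges = self._mges(rng)
        table = pd.DataFrame([
            {"spacer_id": "short", "mag_id": "g",
             "sequence": mges["m1"][100:125]},   # 25 bp: dropped
            {"spacer_id": "keep", "mag_id": "g",
             "sequence": mges["m1"][100:126]}])  # 26 bp: searched
        hits = match_spacers(table, mges)
        assert list(hits["spacer_id"]) == ["keep"]

    def test_reverse_strand_occurrence_found(self):
        rng = np.random.default_rng(10)
        mges = self._mges(rng)
        spacer = revcomp(mges["m1"][500:532])
        table = pd.DataFrame([{"spacer_id": "s", "mag_id": "g",
                               "sequence": spacer}])
        hits = match_spacers(table, mges)
        assert hits.iloc[0]["mge_id"] == "m1"
        assert hits.iloc[0]["mismatches"] == 0

    def test_identity_filter_redundant_at_two_mismatches(self):
        # (L-2)/L >= 0.923 > 0.90 for every L >= 26: the identity rule can
        # never reject a hit that already passed the mismatch rule
        for L in range(26, 61):
            assert (L - 2) / L >= 0.90

    def test_matches_equal_brute_force_scan(self, small_bundle):
        mges = {k: small_bundle.mges[k] for k in sorted(small_bundle.mges)[:6]}
        spacers = small_bundle.spacers.head(8)
        got = match_spacers(spacers, mges)
        got_map = {(r.spacer_id, r.mge_id): r.mismatches
                   for r in got.itertuples()}
        expected = {}
        for sp in spacers.itertuples():
            if len(sp.sequence) < 26:
                continue
            for mge_id, seq in mges.items():
                mm = brute_force_spacer_hits(sp.sequence, seq)
                if mm is not None:
                    expected[(sp.spacer_id, mge_id)] = mm
        assert got_map == expected

    def test_empty_spacer_table(self):
        hits = match_spacers(pd.DataFrame(columns=["spacer_id", "mag_id",
                                                   "sequence"]), {"m": "ACGT" * 300})
        assert len(hits) == 0


def mutate_seq_positions(seq: str, positions) -> str:
    out = list(seq)
    for i in positions:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestMergeAndSummaries:
    def test_top_hit_per_method_kept(self):
        kl = pd.DataFrame([
            {"mge_id": "m", "mag_id": "g1", "method": "kmer_screen",
             "shared_hashes": 950, "est_identity": 0.995,
             "spacer_id": None, "mismatches": None},
            {"mge_id": "m", "mag_id": "g2", "method": "kmer_screen",
             "shared_hashes": 900, "est_identity": 0.992,
             "spacer_id": None, "mismatches": None}])
        merged = merge_host_links(kl, pd.DataFrame(columns=hostlink.LINK_COLUMNS))
        assert len(merged) == 1 and merged.iloc[0]["mag_id"] == "g1"

    def test_ties_across_methods_all_retained(self):
        kl = pd.DataFrame([{"mge_id": "m", "mag_id": "g1",
                            "method": "kmer_screen", "shared_hashes": 950,
                            "est_identity": 0.995, "spacer_id": None,
                            "mismatches": None}])
        sl = pd.DataFrame([{"mge_id": "m", "mag_id": "g2", "method": "spacer",
                            "shared_hashes": None, "est_identity": 1.0,
                            "spacer_id": "s", "mismatches": 0}])
        merged = merge_host_links(kl, sl)
        assert sorted(merged["method"]) == ["kmer_screen", "spacer"]

    def test_malformed_external_table_rejected(self):
        empty = pd.DataFrame(columns=hostlink.LINK_COLUMNS)
        with pytest.raises(ValueError, match="malformed external"):
            merge_host_links(empty, empty,
                             pd.DataFrame([{"mge_id": "m"}]))

    def test_association_summary_reproduces_printed_shares(self):
        # 396 of 664 plasmids associated -> 59.64%; 17 CPR-linked -> 2.56%
        type_calls = pd.DataFrame(
            [{"mge_id": f"p{i}", "label": "plasmid"} for i in range(664)])
        taxonomy = pd.DataFrame(
            [{"mag_id": "cpr", "phylum": "Patescibacteria", "order": "o1"},
             {"mag_id": "pse", "phylum": "Pseudomonadota", "order": "o2"}])
        rows = [{"mge_id": f"p{i}", "mag_id": "cpr" if i < 17 else "pse",
                 "method": "kmer_screen"} for i in range(396)]
        summary = summarize_links(pd.DataFrame(rows), taxonomy, type_calls)
        per_type = summary["per_type"].set_index("mge_type")
        assert per_type.loc["plasmid", "percent"] == 59.64
        per_phylum = summary["per_phylum"].set_index("phylum")
        assert per_phylum.loc["Patescibacteria", "percent"] == 2.56
        assert per_phylum.loc["Pseudomonadota", "count"] == 379

    def test_zero_associations_give_zero_table(self):
        type_calls = pd.DataFrame([{"mge_id": "m", "label": "plasmid"}])
        taxonomy = pd.DataFrame([{"mag_id": "g", "phylum": "p", "order": "o"}])
        empty = pd.DataFrame(columns=hostlink.LINK_COLUMNS)
        summary = summarize_links(empty, taxonomy, type_calls)
        assert (summary["per_type"]["associated"] == 0).all()
        assert len(summary["per_phylum"]) == 0

    def test_synthetic_link_rate_within_binomial_interval(self):
        from aquamob.synthetic_data import SimulationConfig, generate_community
        cfg = SimulationConfig(seed=21, n_wells=2, n_plasmid=30, n_phage=30,
                               n_umge=30, n_mags=12, mag_length=12000,
                               host_link_rate=0.5, spacer_rate=0,
                               n_contained_copies=0, n_core_mges=0,
                               n_env_correlated=0)
        _, truth = generate_community(cfg)
        n = 90
        frac = len(truth.true_host) / n
        half_width = 1.96 * np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= half_width + 1e-9


class TestNormalizeCountsByTaxon:
    def _inputs(self):
        taxonomy = pd.DataFrame([
            {"mag_id": "g1", "phylum": "A", "order": "o1"},
            {"mag_id": "g2", "phylum": "B", "order": "o2"}])
        coverage = pd.DataFrame({"s1": [2.0, 6.0], "s2": [4.0, 12.0]},
                                index=["g1", "g2"])
        counts = pd.Series({"A": 5, "B": 5})
        return counts, coverage, taxonomy

    def test_equal_counts_coverage_ratio_inverts(self):
        counts, coverage, taxonomy = self._inputs()
        out = normalize_counts_by_taxon(counts, coverage, taxonomy)
        s1 = out[out["sample"] == "s1"].set_index("phylum")
        ratio = s1.loc["A", "normalized_count"] / s1.loc["B", "normalized_count"]
        assert ratio == pytest.approx(3.0)  # coverage ratio 1:3 inverts

    def test_doubling_coverage_halves_value(self):
        counts, coverage, taxonomy = self._inputs()
        out1 = normalize_counts_by_taxon(counts, coverage, taxonomy)
        out2 = normalize_counts_by_taxon(counts, coverage * 2, taxonomy)
        merged = out1.merge(out2, on=["phylum", "sample"])
        assert np.allclose(merged["normalized_count_y"],
                           merged["normalized_count_x"] / 2)

    def test_zero_coverage_phylum_is_missing(self):
        counts, coverage, taxonomy = self._inputs()
        coverage.loc["g1"] = 0.0
        out = normalize_counts_by_taxon(counts, coverage, taxonomy)
        a = out[out["phylum"] == "A"]
        assert a["normalized_count"].isna().all()

    def test_zero_plasmid_phylum_is_zero(self):
        counts, coverage, taxonomy = self._inputs()
        counts["A"] = 0
        out = normalize_counts_by_taxon(counts, coverage, taxonomy)
        a = out[out["phylum"] == "A"]
        assert (a["normalized_count"] == 0).all()
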