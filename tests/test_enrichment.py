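"""Peak-overlap counting, binomial enrichment and composition shifts."""

import math

import numpy as np
import pytest
from scipy.special import comb

from allquads.enrichment import (
    PeakSet,
    background_probability,
    background_probability_mc,
    binomial_enrichment,
    enrich,
    fraction_of_features_with_pqs,
    peaks_with_hit,
    records_to_intervals,
    topology_composition,
)
from allquads.scanner import PQSRecord
from allquads.synthetic_data import PlantSpec, plant_pqs, pqs_free_background
from allquads.topology import CLASS_NAMES, INTERSTRAND_CLASS_NAMES


def rec(seq_id, start, end, topology="AABB"):
    return PQSRecord(seq_id, start, end, topology, "", "", None)


def binom_sum(k, n, p):
    """Direct summation of the binomial upper tail (independent oracle)."""
    return sum(comb(n, i, exact=True) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestPeaksWithHit:
    def test_one_shared_base_counts(self):
        peaks = PeakSet("p", [("c", 0, 100)])
        assert peaks_with_hit(peaks, [("c", 99, 120)]) == 1

    def test_abutting_does_not_count(self):
        peaks = PeakSet("p", [("c", 0, 100)])
        assert peaks_with_hit(peaks, [("c", 100, 120)]) == 0

    def test_peak_counted_once_despite_many_sites(self):
        peaks = PeakSet("p", [("c", 0, 100)])
        sites = [("c", 10, 20), ("c", 30, 40), ("c", 50, 60)]
        assert peaks_with_hit(peaks, sites) == 1

    def test_directional_definition(self):
        peaks = PeakSet("p", [("c", 0, 100)])
        sites = [("c", 10, 20), ("c", 30, 40)]
        assert peaks_with_hit(peaks, sites) == 1
        swapped = PeakSet("s", sites)
        assert peaks_with_hit(swapped, [("c", 0, 100)]) == 2

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(3):
            peaks = PeakSet(
                "p",
                [
                    ("c", int(s), int(s) + int(w))
                    for s, w in zip(
                        rng.integers(0, 100_000, 500), rng.integers(10, 300, 500)
                    )
                ],
            )
            sites = [
                ("c", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 100_000, 500), rng.integers(5, 50, 500))
            ]
            oracle = sum(
                1
                for _, ps, pe in peaks.intervals
                if any(ps < se and ss < pe for _, ss, se in sites)
            )
            assert peaks_with_hit(peaks, sites) == oracle


class TestBackgroundProbability:
    def test_full_coverage_caps_at_one(self):
        assert background_probability([("c", 0, 1000)], {"c": 1000}, 50) == 1.0

    def test_no_sites(self):
        assert background_probability([], {"c": 1000}, 50) == 0.0

    def test_closed_form_example(self):
        p = background_probability([("c", 100, 110)], {"c": 1000}, 11)
        assert p == pytest.approx(0.02)

    def test_overlapping_sites_are_merged_first(self):
        p1 = background_probability([("c", 100, 110), ("c", 105, 115)], {"c": 1000}, 11)
        p2 = background_probability([("c", 100, 115)], {"c": 1000}, 11)
        assert p1 == p2

    def test_empty_genome_raises(self):
        with pytest.raises(ValueError):
            background_probability([("c", 0, 10)], {}, 10)

    def test_monte_carlo_agrees_with_closed_form(self, rng):
        sites = [("c", int(s), int(s) + 20) for s in range(500, 50_000, 1000)]
        lengths = {"c": 50_000}
        p_cf = background_probability(sites, lengths, 50)
        p_mc = background_probability_mc(sites, lengths, [50], n_draws=4000, seed=5)
        assert p_mc == pytest.approx(p_cf, abs=4 * math.sqrt(p_cf * (1 - p_cf) / 4000))


class TestBinomialEnrichment:
    def test_zero_hits_p_is_one(self):
        p_upper, ratio = binomial_enrichment(0, 50, 0.2)
        assert p_upper == 1.0
        assert ratio == 0.0

    def test_all_hits_fair_coin(self):
        p_upper, _ = binomial_enrichment(12, 12, 0.5)
        assert p_upper == pytest.approx(0.5**12, rel=1e-12)

    @pytest.mark.parametrize("k,n,p", [(7, 10, 0.3), (0, 10, 0.3), (10, 10, 0.9)])
    def test_matches_direct_summation(self, k, n, p):
        p_upper, ratio = binomial_enrichment(k, n, p)
        assert p_upper == pytest.approx(binom_sum(k, n, p), abs=1e-12)
        assert ratio == pytest.approx((k / n) / p)

    def test_summation_agreement_large_n(self, rng):
        for _ in range(10):
            n = int(rng.integers(100, 1000))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            p_upper, _ = binomial_enrichment(k, n, p)
            assert p_upper == pytest.approx(float(binom_sum(k, n, p)), abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        vals = [binomial_enrichment(k, 40, 0.3)[0] for k in range(41)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_impossible_null(self):
        p_upper, ratio = binomial_enrichment(3, 10, 0.0)
        assert p_upper == 0.0 and math.isinf(ratio)
        p_upper, ratio = binomial_enrichment(0, 10, 0.0)
        assert p_upper == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_enrichment(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 10, 1.5)


class TestCategories:
    def test_records_to_intervals_filters(self):
        records = [rec("c", 0, 10, "AAAA"), rec("c", 20, 30, "AABB")]
        assert len(records_to_intervals(records, "any")) == 2
        assert records_to_intervals(records, "intra") == [("c", 0, 10)]
        assert records_to_intervals(records, "inter") == [("c", 20, 30)]
        assert records_to_intervals(records, "class:AABB") == [("c", 20, 30)]
        with pytest.raises(ValueError):
            records_to_intervals(records, "class:XXXX")
        with pytest.raises(ValueError):
            records_to_intervals(records, "weird")


class TestFractionOfFeatures:
    def test_planted_fraction(self, worked_example):
        clean = pqs_free_background(1000, 0.4, seed=9)
        features = []
        for i in range(6):
            spec = PlantSpec("ABAB", (3, 3, 3, 3), (0, 1, 0), 200)
            seq, _ = plant_pqs(clean, spec)
            features.append((f"with{i}", seq))
        for i in range(4):
            features.append((f"clean{i}", clean))
        assert fraction_of_features_with_pqs(features, category="inter") == 0.6

    def test_all_n_records(self):
        features = [("n1", "N" * 500), ("n2", "N" * 500)]
        assert fraction_of_features_with_pqs(features) == 0.0

    def test_worked_example_category_split(self, worked_example):
        features = [(f"f{i}", "ATAT" + worked_example + "TTTT") for i in range(3)]
        assert fraction_of_features_with_pqs(features, category="inter") == 1.0
        assert fraction_of_features_with_pqs(features, category="intra") == 0.0


class TestTopologyComposition:
    def test_identical_composition_zero_z(self):
        genome = [rec("c", i * 50, i * 50 + 15, name) for i, name in enumerate(CLASS_NAMES * 4)]
        df = topology_composition(genome, genome)
        assert np.allclose(df["z_all"], 0.0)
        assert np.allclose(df.loc[list(INTERSTRAND_CLASS_NAMES), "z_ds"], 0.0)

    def test_fractions_sum_to_one(self):
        genome = [rec("c", i * 50, i * 50 + 15, name) for i, name in enumerate(CLASS_NAMES * 3)]
        peaks = genome[: len(CLASS_NAMES)]
        df = topology_composition(peaks, genome)
        assert df["frac_all_in_peaks"].sum() == pytest.approx(1.0)
        assert df.loc[list(INTERSTRAND_CLASS_NAMES), "frac_ds_in_peaks"].sum() == pytest.approx(1.0)

    def test_planted_single_class_enrichment(self):
        genome = [rec("c", i * 50, i * 50 + 15, name) for i, name in enumerate(CLASS_NAMES * 10)]
        in_peaks = [r for r in genome if r.topology == "BABB"]
        df = topology_composition(in_peaks, genome)
        assert df.loc["BABB", "z_all"] > 0
        others = [n for n in CLASS_NAMES if n != "BABB"]
        assert (df.loc[others, "z_all"] < 0).all()

    def test_absent_class_degenerate(self):
        genome = [rec("c", i * 50, i * 50 + 15, "AABB") for i in range(10)]
        df = topology_composition(genome, genome)
        assert df.loc["BBAA", "z_all"] == 0.0
        assert bool(df.loc["BBAA", "degenerate"])


class TestEnrichEndToEnd:
    def test_planted_association_is_detected(self):
        """Peaks placed exactly on planted motifs give ratio >> 1 and a tiny
        upper-tail p; the Monte-Carlo null agrees with the closed form."""
        seq = pqs_free_background(60_000, 0.4, seed=21)
        records = []
        for i in range(30):
            spec = PlantSpec("AABB", (3, 3, 3, 3), (1, 1, 1), 1000 + i * 1500)
            seq, truth = plant_pqs(seq, spec, seq_id="chrS")
            records.append(truth)
        lengths = {"chrS": len(seq)}
        peaks = PeakSet("on", [("chrS", r.start - 20, r.end + 20) for r in records])
        res = enrich(peaks, records, lengths, category="inter")
        assert res.n_peaks_with_hit == 30
        assert res.enrichment_ratio > 10
        assert res.binomial_p_upper < 1e-20
        res_mc = enrich(
            peaks, records, lengths, category="inter", null="shuffle", seed=3
        )
        assert res_mc.background_p == pytest.approx(res.background_p, abs=0.02)
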