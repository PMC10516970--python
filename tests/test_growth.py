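"""Growth rates and community summaries."""

import numpy as np
import pandas as pd
import pytest

from vaporqsip import (
    absolute_abundances,
    flag_putative_predators,
    growing_fraction,
    proportional_assimilation,
    region_sum,
    relative_growth_rate,
    shared_count,
    top_assimilators,
    treatment_overlap,
    unique_count,
)
from vaporqsip.errors import InvalidLabelError, UndefinedAssimilationError
from vaporqsip.growth import assimilation_table, phylum_change, sample_mean_rgr


class TestRelativeGrowthRate:
    def test_study_arithmetic(self):
        assert relative_growth_rate(29.65, 59.3, 5) == pytest.approx(0.1)

    def test_zero_enrichment(self):
        assert relative_growth_rate(0.0, 59.3, 5) == 0.0

    def test_fully_labeled_taxon(self):
        # taxon DNA as enriched as the water pool: 1/days
        assert relative_growth_rate(59.3, 59.3, 5) == pytest.approx(0.2)

    def test_invalid_label(self):
        with pytest.raises(InvalidLabelError):
            relative_growth_rate(10, 0.0, 5)


class TestAbsoluteAbundances:
    def test_single_taxon_gets_all_copies(self, toy_tube):
        features, fractions = toy_tube
        solo = features.iloc[[0]]
        out = absolute_abundances(solo, fractions)
        assert out.loc["t1", "T1"] == pytest.approx(fractions["total_copies"].sum())

    def test_proportionality(self):
        frac_ids = ["T:1"]
        features = pd.DataFrame({"T:1": [30.0, 70.0]}, index=["a", "b"])
        fractions = pd.DataFrame(
            {"tube_id": "T", "fraction_index": [1], "density": 1.7,
             "total_copies": [1e9], "total_read_pairs": [100]},
            index=pd.Index(frac_ids, name="fraction_id"),
        )
        out = absolute_abundances(features, fractions)
        assert out.loc["a", "T"] == pytest.approx(3e8)
        assert out.loc["b", "T"] == pytest.approx(7e8)

    def test_matches_two_step_oracle(self, small_filtered):
        sim, kept = small_filtered
        out = absolute_abundances(sim.features, kept, sim.samples)
        tube = out.columns[0]
        cols = kept.index[kept["tube_id"] == tube]
        reads = sim.features.loc[:, cols].sum(axis=1)
        expected = reads / reads.sum() * kept.loc[cols, "total_copies"].sum()
        assert np.allclose(out[tube], expected, atol=1e-9)


class TestGrowingFraction:
    def test_thirty_five_percent(self):
        ab = pd.Series({"a": 35.0, "b": 65.0})
        flags = pd.Series({"a": True, "b": False})
        assert growing_fraction(ab, flags) == pytest.approx(35.0)

    def test_no_growing_taxa(self):
        ab = pd.Series({"a": 1.0, "b": 2.0})
        assert growing_fraction(ab, pd.Series({"a": False, "b": False})) == 0.0

    def test_all_growing_is_100(self):
        ab = pd.Series({"a": 1.0, "b": 2.0})
        assert growing_fraction(ab, pd.Series({"a": True, "b": True})) == 100.0

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(0)
        ab = pd.Series(rng.uniform(1, 10, 20), index=[f"t{i}" for i in range(20)])
        flags = pd.Series(rng.random(20) < 0.4, index=ab.index)
        perm = rng.permutation(ab.index)
        assert growing_fraction(ab[perm], flags[perm]) == pytest.approx(
            growing_fraction(ab, flags)
        )


class TestProportionalAssimilation:
    def test_arithmetic(self):
        p = proportional_assimilation(
            pd.Series({"a": 0.5, "b": 0.5}), pd.Series({"a": 0.1, "b": 0.3})
        )
        assert p["a"] == pytest.approx(0.25)
        assert p["b"] == pytest.approx(0.75)

    def test_single_taxon(self):
        p = proportional_assimilation(pd.Series({"a": 2.0}), pd.Series({"a": 0.1}))
        assert p["a"] == 1.0

    def test_equal_rates_reduce_to_relative_abundance(self):
        ab = pd.Series({"a": 1.0, "b": 3.0, "c": 6.0})
        p = proportional_assimilation(ab, pd.Series(0.07, index=ab.index))
        assert np.allclose(p, ab / ab.sum())

    def test_sums_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        ab = pd.Series(rng.uniform(1, 5, 10), index=[f"t{i}" for i in range(10)])
        rgr = pd.Series(rng.uniform(0.01, 0.2, 10), index=ab.index)
        p1 = proportional_assimilation(ab, rgr)
        p2 = proportional_assimilation(ab * 123.4, rgr)
        assert p1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(p1, p2)

    def test_all_zero_rates_undefined(self):
        with pytest.raises(UndefinedAssimilationError):
            proportional_assimilation(
                pd.Series({"a": 1.0}), pd.Series({"a": 0.0})
            )


def _toy_records():
    """4 samples (2 per treatment), hand-designed assimilation records."""
    rows = []
    taxa = [f"t{i}" for i in range(8)]
    rng = np.random.default_rng(8)
    for treatment, sample_ids in {"x": ["s1", "s2"], "y": ["s3", "s4"]}.items():
        for s in sample_ids:
            present = taxa if treatment == "x" else taxa[2:]
            pa = rng.uniform(0.1, 1.0, len(present))
            pa /= pa.sum()
            for t, v in zip(present, pa):
                rows.append({"taxon_id": t, "sample_id": s, "treatment": treatment,
                             "rel_abund_growing": 1 / len(present), "rgr": 0.1,
                             "proportional_assimilation": v, "rank": 0})
    return pd.DataFrame(rows)


class TestTopAssimilators:
    def _taxonomy(self):
        return pd.DataFrame(
            {
                "phylum": ["P"] * 8,
                "family": [f"F{i}" for i in range(8)],
                "genus": ["G0", "", "G2", "G3", "", "G5", "G6", "G7"],
            },
            index=pd.Index([f"t{i}" for i in range(8)], name="taxon_id"),
        )

    def test_fewer_growers_than_n_returns_all(self):
        rec = _toy_records()
        rec = rec[rec["sample_id"] == "s3"]
        out = top_assimilators(rec, self._taxonomy(), n=10, min_samples=1)
        assert set(out["taxon_id"]) == set(rec["taxon_id"])

    def test_union_bounded_and_matches_manual_ranking(self):
        rec = _toy_records()
        out = top_assimilators(rec, self._taxonomy(), n=3, min_samples=2)
        manual = set()
        for s, sub in rec.groupby("sample_id"):
            manual |= set(sub.nlargest(3, "proportional_assimilation")["taxon_id"])
        assert set(out["taxon_id"]) == manual
        assert len(set(out["taxon_id"])) <= 3 * rec["sample_id"].nunique()

    def test_genus_fallback_labels(self):
        rec = _toy_records()
        out = top_assimilators(rec, self._taxonomy(), n=8, min_samples=1)
        labels = dict(zip(out["taxon_id"], out["label"]))
        assert labels["t0"] == "G0"
        assert labels["t1"] == "F1"  # unassigned genus falls back to family

    def test_min_samples_excludes_single_sample_growers(self):
        rec = _toy_records()
        # t0/t1 only grow in treatment x (both samples) -> kept at min 2;
        # drop t0 from s2 so it grows in one sample only
        rec = rec[~((rec["taxon_id"] == "t0") & (rec["sample_id"] == "s2"))]
        out = top_assimilators(rec, self._taxonomy(), n=8, min_samples=2)
        assert "t0" not in set(out["taxon_id"])


class TestTreatmentOverlap:
    def test_disjoint_sets(self):
        sets = {"a": {1, 2}, "b": {3}, "c": {4}, "d": set()}
        regions = treatment_overlap(sets)
        assert shared_count(regions, "a", "b") == 0
        assert unique_count(regions, "a") == 2

    def test_identical_sets(self):
        sets = {"a": {1, 2, 3}, "b": {1, 2, 3}}
        regions = treatment_overlap(sets)
        assert shared_count(regions, "a", "b") == 3
        assert unique_count(regions, "a") == 0

    def test_regions_sum_to_union(self):
        rng = np.random.default_rng(1)
        universe = list(range(200))
        sets = {k: set(rng.choice(universe, 60, replace=False)) for k in "abcd"}
        regions = treatment_overlap(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_region_sum_any_of(self):
        sets = {"a": {1, 2}, "b": {2, 3}, "c": {3, 4}}
        regions = treatment_overlap(sets)
        # elements in c that also occur in a or b: {3}
        assert region_sum(regions, {"c"}, any_of={"a", "b"}) == 1


class TestPhylumChange:
    def _counts(self):
        return pd.DataFrame(
            {"s1": [10, 4, 0], "s2": [10, 2, 0], "s3": [10.7, 6, 3], "s4": [10.7, 0, 1]},
            index=["Actinobacteriota", "Proteobacteria", "Rare"],
        )

    def test_seven_percent_increase(self):
        treatments = pd.Series({"s1": "ref", "s2": "ref", "s3": "trt", "s4": "trt"})
        out = phylum_change(self._counts(), treatments, "ref", "trt")
        assert out.loc["Actinobacteriota", "relative_change"] == pytest.approx(0.07)

    def test_halving_and_zero_reference(self):
        treatments = pd.Series({"s1": "ref", "s2": "ref", "s3": "trt", "s4": "trt"})
        out = phylum_change(self._counts(), treatments, "ref", "trt")
        assert out.loc["Proteobacteria", "relative_change"] == pytest.approx(0.0)
        assert bool(out.loc["Rare", "undefined"])
        assert np.isnan(out.loc["Rare", "relative_change"])

    def test_identical_means_no_change(self):
        counts = pd.DataFrame({"s1": [5], "s2": [5]}, index=["P"])
        treatments = pd.Series({"s1": "ref", "s2": "trt"})
        out = phylum_change(counts, treatments, "ref", "trt")
        assert out.loc["P", "relative_change"] == 0.0


class TestPredators:
    @pytest.mark.parametrize(
        "order,expected",
        [
            ("Myxococcales", True),
            ("myxococcales", True),
            ("Bdellovibrionales", True),
            ("Vampirovibrionales", True),
            ("Haliangiales", True),
            ("Polyangiales", True),
            ("Rhizobiales", False),
            ("", False),
        ],
    )
    def test_order_membership(self, order, expected):
        assert flag_putative_predators({"order": order}) is expected


class TestSampleMeanRgr:
    def _enr(self):
        return pd.DataFrame(
            {
                "tube_id": ["T"] * 3,
                "taxon_id": ["a", "b", "c"],
                "ape": [29.65, 88.95, -2.0],
                "growing": [True, True, False],
                "soil_water_ape": [59.3] * 3,
                "incubation_days": [5.0] * 3,
            }
        )

    def test_growing_only_mean(self):
        out = sample_mean_rgr(self._enr(), include_nongrowing=False)
        assert out["T"] == pytest.approx((0.1 + 0.3) / 2)

    def test_all_taxa_mean_clamps_negative(self):
        out = sample_mean_rgr(self._enr(), include_nongrowing=True)
        assert out["T"] == pytest.approx((0.1 + 0.3 + 0.0) / 3)

    def test_all_taxa_mean_never_exceeds_growing_only(self, small_filtered):
        from vaporqsip import enrich_all

        sim, kept = small_filtered
        enr = enrich_all(sim.features, kept, sim.samples).merge(
            sim.samples[["soil_water_ape", "incubation_days"]],
            left_on="tube_id", right_index=True,
        )
        g = sample_mean_rgr(enr, include_nongrowing=False)
        a = sample_mean_rgr(enr, include_nongrowing=True)
        mask = g.notna() & a.notna()
        assert (a[mask] <= g[mask] + 1e-12).all()
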