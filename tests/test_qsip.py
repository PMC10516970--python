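"""Core qSIP estimator: filters, WADs, offset correction, EAF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaporqsip import (
    DEFAULT_CONSTANTS,
    ExperimentDesign,
    correct_wad_offset,
    enrich_all,
    excess_atom_fraction,
    filter_fractions,
    gc_from_wad,
    molecular_weights,
    prevalence_filter,
    simulate_experiment,
    taxon_wad,
    tube_wads,
)
from vaporqsip.errors import UncorrectableTubeError
from vaporqsip.qsip import tube_community_wad

from conftest import brute_force_wad


def _toy_filter_table():
    """5 fractions straddling the density window and the read-pair cut."""
    ids = [f"T:{i}" for i in range(1, 6)]
    return pd.DataFrame(
        {
            "tube_id": "T",
            "fraction_index": range(1, 6),
            "density": [1.60, 1.614, 1.70, 1.753, 1.76],
            "total_copies": [1e5] * 5,
            "total_read_pairs": [5000, 5000, 2000, 5000, 5000],
        },
        index=pd.Index(ids, name="fraction_id"),
    )


class TestFilterFractions:
    def test_density_window_inclusive_and_read_cut_strict(self):
        out = filter_fractions(_toy_filter_table())
        # 1.60 out (light), 1.76 out (heavy), exactly 2000 read pairs out
        assert list(out.index) == ["T:2", "T:4"]

    def test_all_good_fractions_is_identity(self):
        tab = _toy_filter_table()
        tab["density"] = [1.62, 1.65, 1.68, 1.71, 1.74]
        tab["total_read_pairs"] = 2001
        assert filter_fractions(tab).shape[0] == 5

    def test_nonfinite_density_rejected(self):
        tab = _toy_filter_table()
        tab.loc["T:1", "density"] = np.nan
        with pytest.raises(ValueError):
            filter_fractions(tab)


class TestTaxonWad:
    def test_symmetric_weights(self):
        wad, n = taxon_wad([1.70, 1.71, 1.72], [10, 80, 10])
        assert wad == pytest.approx(1.71)
        assert n == 3

    def test_single_fraction(self):
        wad, n = taxon_wad([1.68, 1.70, 1.72], [0, 7, 0])
        assert wad == 1.70 and n == 1

    def test_absent_taxon_is_marked_not_zero(self):
        wad, n = taxon_wad([1.7, 1.71], [0, 0])
        assert np.isnan(wad) and n == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = np.sort(rng.uniform(1.6, 1.78, 8))
        y = rng.uniform(0, 100, 8)
        wad, _ = taxon_wad(d, y)
        assert wad == pytest.approx(brute_force_wad(d, y), abs=1e-12)

    def test_vectorised_tube_wads_match_scalar(self, toy_tube):
        features, fractions = toy_tube
        wads, presence = tube_wads(features, fractions)
        from vaporqsip.qsip import taxon_copies

        copies = taxon_copies(features, fractions)
        for t in features.index:
            wad, n = taxon_wad(fractions["density"], copies.loc[t])
            assert wads.loc[t, "T1"] == pytest.approx(wad, abs=1e-12)
            assert presence.loc[t, "T1"] == n


class TestCompositionalInvariance:
    def test_eaf_invariant_to_read_and_ddpcr_scaling(self, small_filtered):
        sim, kept = small_filtered
        enr1 = enrich_all(sim.features, kept, sim.samples)
        scaled = sim.features * 3.0
        kept2 = kept.copy()
        kept2["total_copies"] = kept2["total_copies"] * 10.0
        enr2 = enrich_all(scaled, kept2, sim.samples)
        pd.testing.assert_series_equal(enr1["eaf"], enr2["eaf"], atol=1e-12)

    def test_eaf_monotone_in_w_lab(self):
        w_light = 1.687810
        eafs = [excess_atom_fraction(w_light, w) for w in np.linspace(1.688, 1.74, 20)]
        assert all(a < b for a, b in zip(eafs, eafs[1:]))


class TestGcAndWeights:
    def test_gc_intercept_and_slope_endpoints(self):
        assert gc_from_wad(1.646057) == 0.0
        assert gc_from_wad(1.729563) == pytest.approx(1.0)
        assert gc_from_wad(1.687810) == pytest.approx(0.5)

    def test_gc_clamped(self):
        assert gc_from_wad(1.60) == 0.0
        assert gc_from_wad(1.80) == 1.0

    def test_molecular_weights(self):
        assert molecular_weights(0.0) == pytest.approx((307.691, 319.76847))
        assert molecular_weights(0.5) == pytest.approx((307.939, 320.01647))

    @given(st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_heavy_shift_constant(self, gc):
        m_light, m_heavy = molecular_weights(gc)
        assert m_heavy - m_light == pytest.approx(12.07747)


class TestExcessAtomFraction:
    def test_no_shift_no_enrichment(self):
        assert excess_atom_fraction(1.687810, 1.687810) == 0.0

    def test_known_value(self):
        assert excess_atom_fraction(1.687810, 1.720977) == pytest.approx(0.500, abs=5e-4)

    def test_saturation_bound(self):
        c = DEFAULT_CONSTANTS
        m_light, m_heavy = molecular_weights(0.5, c)
        w_light = 1.687810
        w_lab = w_light * m_heavy / m_light
        assert excess_atom_fraction(w_light, w_lab, c) == pytest.approx(
            0.997999571, abs=1e-9
        )

    def test_negative_eaf_passes_through(self):
        assert excess_atom_fraction(1.70, 1.699) < 0


class TestPrevalenceFilter:
    def test_toy_enumeration(self):
        # 5 taxa, 2 labeled tubes with 5 fractions each; presence designed so
        # exactly t1 (4+4 fractions), t2 (5+4) and t5 (4+4) qualify
        frac_ids = [f"{tube}:{i}" for tube in ("A", "B") for i in range(1, 6)]
        rows = {
            "t1": [1, 1, 1, 1, 0, 1, 1, 1, 1, 0],
            "t2": [1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
            "t3": [1, 1, 1, 0, 0, 1, 1, 1, 1, 1],  # only 3 fractions in A
            "t4": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],  # one replicate only
            "t5": [0, 1, 1, 1, 1, 1, 1, 1, 1, 0],
        }
        features = pd.DataFrame(rows, index=frac_ids).T.astype(float)
        fractions = pd.DataFrame(
            {
                "tube_id": [f.split(":")[0] for f in frac_ids],
                "fraction_index": [int(f.split(":")[1]) for f in frac_ids],
                "density": 1.7,
                "total_copies": 1e5,
                "total_read_pairs": 9999,
            },
            index=pd.Index(frac_ids, name="fraction_id"),
        )
        samples = pd.DataFrame(
            {
                "treatment": ["x", "x"],
                "isotope": ["18O", "18O"],
                "replicate": [1, 2],
            },
            index=pd.Index(["A", "B"], name="tube_id"),
        )
        retained, coverage = prevalence_filter(features, fractions, samples)
        assert retained["x"] == {"t1", "t2", "t5"}
        assert 0 < coverage["x"] < 1

    def test_boundary_exactly_4_fractions_2_replicates(self, small_filtered):
        sim, kept = small_filtered
        retained, _ = prevalence_filter(sim.features, kept, sim.samples,
                                        min_fractions=4, min_replicates=2)
        # no treatment loses everything and none keeps everything at 30k reads
        for t, s in retained.items():
            assert 0 < len(s) <= sim.features.shape[0]


class TestOffsetCorrection:
    def test_identical_tubes_zero_offset(self, small_filtered):
        sim, kept = small_filtered
        out = correct_wad_offset(kept, sim.samples, ["ambient_r1_16O"], sim.features,
                                 group_cols=("treatment", "isotope"))
        # offset is small but nonzero under noise; correcting twice with no
        # flagged tubes is the identity
        same = correct_wad_offset(kept, sim.samples, [], sim.features)
        pd.testing.assert_frame_equal(same, kept)
        assert (out["density"] - kept["density"]).abs().max() < 0.005

    def test_deleted_light_fractions_are_compensated(self):
        design = ExperimentDesign(
            n_taxa=40, n_replicates=3, seed=21,
            drop_low_fractions={"ambient_r1_16O": 3},
        )
        sim = simulate_experiment(design)
        kept = filter_fractions(sim.fractions)
        corrected = correct_wad_offset(
            kept, sim.samples, ["ambient_r1_16O"], sim.features
        )
        comm = tube_community_wad(sim.features, corrected)
        refs = [f"ambient_r{r}_16O" for r in (2, 3)]
        assert abs(comm["ambient_r1_16O"] - np.mean([comm[r] for r in refs])) < 0.002

    def test_no_reference_tubes_raises(self, small_filtered):
        sim, kept = small_filtered
        ambient_unlabeled = [f"ambient_r{r}_16O" for r in (1, 2, 3)]
        with pytest.raises(UncorrectableTubeError):
            correct_wad_offset(kept, sim.samples, ambient_unlabeled, sim.features)


class TestEnrichAll:
    def test_noiseless_flags_match_truth(self, noiseless_experiment):
        sim = noiseless_experiment
        kept = filter_fractions(sim.fractions, density_min=0, density_max=10,
                                min_read_pairs=-1)
        enr = enrich_all(sim.features, kept, sim.samples)
        truth = sim.truth.taxa.set_index(["taxon_id", "treatment"])
        j = enr.set_index(["taxon_id", "treatment"]).join(truth, rsuffix="_true")
        assert (j["growing"] == j["growing_true"]).all()

    def test_all_natural_abundance_like_tube_has_near_zero_ape(self, noiseless_experiment):
        # labeled tubes of taxa with true EAF 0 behave like unlabeled tubes
        sim = noiseless_experiment
        kept = filter_fractions(sim.fractions, density_min=0, density_max=10,
                                min_read_pairs=-1)
        enr = enrich_all(sim.features, kept, sim.samples)
        truth = sim.truth.taxa.set_index(["taxon_id", "treatment"])
        j = enr.set_index(["taxon_id", "treatment"]).join(truth, rsuffix="_t")
        zeros = j[j["true_eaf"] == 0]
        assert np.allclose(zeros["ape"], 0.0, atol=1e-9)

    def test_thresholds_partition_inactive_active_growing(self, small_filtered):
        sim, kept = small_filtered
        enr = enrich_all(sim.features, kept, sim.samples)
        assert (enr.loc[enr["growing"], "active"]).all()
        assert (enr.loc[enr["growing"], "ape"] > 5).all()
        assert (enr.loc[enr["active"] & ~enr["growing"], "ape"] <= 5).all()
        assert (enr.loc[~enr["active"], "ape"] <= 0).all()
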