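import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dnafrag as d
from dnafrag.simulate import KEV_UM_FLUENCE_TO_GY

L = 850.0


# ---------------------------------------------------------------------------
# break_positions_uniform
# ---------------------------------------------------------------------------

class TestBreakPositions:
    def test_zero_breaks_empty(self, rng):
        assert d.break_positions_uniform(0, L, rng).size == 0

    def test_positions_in_range(self, rng):
        pos = d.break_positions_uniform(3, L, rng)
        assert pos.size == 3
        assert np.all((pos >= 0) & (pos < L))

    def test_uniformity(self):
        rng = np.random.default_rng(0)
        pos = d.break_positions_uniform(1000, L, rng)
        stat = sps.kstest(pos / L, "uniform")
        assert stat.pvalue > 0.01

    def test_negative_k_rejected(self, rng):
        with pytest.raises(ValueError):
            d.break_positions_uniform(-1, L, rng)

    def test_nonpositive_L_rejected(self, rng):
        with pytest.raises(ValueError):
            d.break_positions_uniform(1, 0.0, rng)


# ---------------------------------------------------------------------------
# fragments_from_breaks
# ---------------------------------------------------------------------------

class TestFragmentsFromBreaks:
    def test_two_symmetric_cuts(self):
        lengths, circular = d.fragments_from_breaks([0.0, 425.0], L)
        assert not circular
        np.testing.assert_allclose(sorted(lengths), [425.0, 425.0])

    def test_three_cuts_hand_computed(self):
        lengths, _ = d.fragments_from_breaks([0.0, 100.0, 300.0], L)
        np.testing.assert_allclose(lengths, [100.0, 200.0, 550.0])

    def test_single_cut_full_length_linear(self):
        lengths, circular = d.fragments_from_breaks([212.5], L)
        assert not circular
        assert lengths.tolist() == [850.0]  # exactly L

    def test_no_cuts_circular(self):
        lengths, circular = d.fragments_from_breaks([], L)
        assert circular
        assert lengths.tolist() == [850.0]

    def test_count_equals_breaks_and_sum_is_L(self, rng):
        for k in (1, 2, 5, 17):
            pos = rng.uniform(0, L, size=k)
            lengths, _ = d.fragments_from_breaks(pos, L)
            assert lengths.size == k
            assert abs(lengths.sum() - L) < 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            d.fragments_from_breaks([0.0, 850.0], L)
        with pytest.raises(ValueError):
            d.fragments_from_breaks([-1.0], L)


# ---------------------------------------------------------------------------
# dose helpers
# ---------------------------------------------------------------------------

class TestDose:
    def test_zero_dose(self):
        assert d.dose_to_break_rate(0.0, d.DoseCalibration(1.0)) == 0.0

    def test_calibrated_rate_at_analysis_dose(self):
        cal = d.DoseCalibration(alpha=5.83 / 6000.0)
        assert d.dose_to_break_rate(6000.0, cal) == pytest.approx(5.83)

    def test_linearity(self):
        cal = d.DoseCalibration(alpha=4.77 / 6000.0)
        assert d.dose_to_break_rate(3000.0, cal) == pytest.approx(2.385)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            d.dose_to_break_rate(-1.0, d.DoseCalibration(1.0))

    def test_fluence_zero_factors(self):
        assert d.dose_from_fluence(0.0, 100.0, 10.0) == 0.0
        assert d.dose_from_fluence(1e6, 0.0, 10.0) == 0.0
        assert d.dose_from_fluence(1e6, 100.0, 0.0) == 0.0

    def test_fluence_unit_constant(self):
        # 1 Gy at LET 100 keV/um needs 1/(100 * 1.602e-9) ~ 6.24e6 particles/cm2
        fluence = 1.0 / (100.0 * KEV_UM_FLUENCE_TO_GY)
        assert d.dose_from_fluence(fluence, 100.0, 1.0) == pytest.approx(1.0)
        assert KEV_UM_FLUENCE_TO_GY == pytest.approx(1.602e-9, rel=2e-4)

    def test_fluence_time_linearity(self):
        one = d.dose_from_fluence(1e6, 50.0, 10.0)
        assert d.dose_from_fluence(1e6, 50.0, 20.0) == pytest.approx(2 * one)

    def test_fluence_negative_rejected(self):
        with pytest.raises(ValueError):
            d.dose_from_fluence(-1.0, 100.0, 1.0)


# ---------------------------------------------------------------------------
# simulate_sample
# ---------------------------------------------------------------------------

class TestSimulateSample:
    def test_no_radiation_all_circular(self):
        s = d.simulate_sample(d.UniformBreakModel(0.0), n_plasmids=100, seed=0)
        assert s.n_records == 100
        assert not s.is_linear.any()
        assert np.all(s.lengths_nm == L)

    def test_poisson_mean_recovery(self, uniform_sample_20k):
        stats = d.dsb_per_dna(uniform_sample_20k, L)
        se = np.sqrt(5.83 / 20000)
        assert abs(stats.dsb_per_dna - 5.83) < 3 * se

    def test_cluster_size_one_reduces_to_uniform(self):
        mu = 3.0
        uni = d.simulate_sample(d.UniformBreakModel(mu), n_plasmids=8000, seed=10)
        model = d.ClusteredBreakModel(
            track_rate=mu, cluster_size_law=d.ClusterSizeLaw.fixed(1), cluster_span_nm=50.0
        )
        clu = d.simulate_sample(model, n_plasmids=8000, seed=11)
        # one fragment per broken plasmid -> i.i.d. draws for a two-sample test
        a = _one_fragment_per_plasmid(uni)
        b = _one_fragment_per_plasmid(clu)
        assert sps.ks_2samp(a, b).pvalue > 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            d.simulate_sample(d.UniformBreakModel(1.0), n_plasmids=0)
        with pytest.raises(ValueError):
            d.UniformBreakModel(-1.0)
        with pytest.raises(ValueError):
            d.ClusteredBreakModel(-0.5, d.ClusterSizeLaw.fixed(1))
        with pytest.raises(ValueError):
            # cluster span larger than the circle
            d.simulate_sample(
                d.ClusteredBreakModel(1.0, d.ClusterSizeLaw.fixed(2), cluster_span_nm=900.0),
                n_plasmids=10,
            )

    def test_reproducibility_bit_identical(self):
        a = d.simulate_sample(d.UniformBreakModel(2.0), n_plasmids=500, seed=42)
        b = d.simulate_sample(d.UniformBreakModel(2.0), n_plasmids=500, seed=42)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_growing_n_preserves_earlier_draws(self):
        small = d.simulate_sample(d.UniformBreakModel(2.0), n_plasmids=500, seed=42)
        big = d.simulate_sample(d.UniformBreakModel(2.0), n_plasmids=1000, seed=42)
        a = small.lengths_nm[small.is_linear]
        b = big.lengths_nm[big.is_linear]
        np.testing.assert_array_equal(a, b[: a.size])

    def test_detection_floor_drops_short_fragments(self):
        det = d.DetectionModel(min_detectable_nm=20.0)
        s = d.simulate_sample(d.UniformBreakModel(8.0), n_plasmids=2000, seed=3, detection=det)
        assert s.lengths_nm[s.is_linear].min() >= 20.0

    def test_noise_keeps_lengths_positive(self):
        det = d.DetectionModel(length_noise_sd_nm=15.0)
        s = d.simulate_sample(d.UniformBreakModel(8.0), n_plasmids=2000, seed=3, detection=det)
        assert (s.lengths_nm > 0).all()
        circ = s.lengths_nm[~s.is_linear]
        assert np.all(np.abs(circ - L) < 6 * 15.0)

    def test_topology_flags(self, uniform_sample_20k):
        s = uniform_sample_20k
        assert set(s.records["topology"].unique()) <= {"linear", "circular"}
        assert np.all(s.lengths_nm[~s.is_linear] == L)

    def test_metadata_carries_seed_and_model(self, uniform_sample_20k):
        extras = uniform_sample_20k.extras
        assert extras["seed"] == 1
        assert extras["model"] == "uniform"
        assert extras["model_params"]["mu"] == 5.83


def _one_fragment_per_plasmid(sample):
    """First linear fragment per broken plasmid (exchangeable, i.i.d. across plasmids)."""
    lengths = sample.lengths_nm[sample.is_linear]
    # fragments are emitted grouped by plasmid; a full-length group boundary scan
    # is unnecessary here because exchangeability lets us subsample instead
    rng = np.random.default_rng(99)
    idx = rng.choice(lengths.size, size=min(4000, lengths.size), replace=False)
    return lengths[idx]


# ---------------------------------------------------------------------------
# cluster size law
# ---------------------------------------------------------------------------

class TestClusterSizeLaw:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            d.ClusterSizeLaw(sizes=(1, 2), probs=(0.5, 0.4))

    def test_sizes_must_be_positive_integers(self):
        with pytest.raises(ValueError):
            d.ClusterSizeLaw(sizes=(0,), probs=(1.0,))

    def test_geometric_mean(self):
        law = d.ClusterSizeLaw.geometric(3.0)
        assert law.mean == pytest.approx(3.0, rel=0.01)

    def test_fixed(self):
        law = d.ClusterSizeLaw.fixed(4)
        assert law.mean == 4.0
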