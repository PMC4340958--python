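"""Tests for the cytometry noise statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirffl import (
    PopulationSpec,
    compare_cv,
    cv,
    generate_mixture,
    generate_paired_channels,
    generate_population,
    mixture_cv_analytic,
    peak_channel_skew,
    technical_noise_bound,
    unmix_cv_curve,
)


class TestCV:
    def test_hand_computed_example(self):
        summary = cv([90, 100, 110])
        assert summary.mean == pytest.approx(100.0)
        assert summary.sd == pytest.approx(10.0)
        assert summary.cv == pytest.approx(10.0)
        assert summary.n == 3

    def test_constant_vector_has_zero_cv(self):
        assert cv([5.0, 5.0, 5.0]).cv == 0.0

    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        values = np.array([80.0, 95.0, 110.0, 130.0])
        assert cv(scale * values).cv == pytest.approx(cv(values).cv, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cv([1.0])
        with pytest.raises(ValueError):
            cv([-2.0, 0.0, 2.0])


class TestTechnicalNoiseBound:
    def test_proportional_channels_have_zero_ratio_cv(self):
        a = np.array([100.0, 200.0, 300.0])
        assert technical_noise_bound(2 * a, a).cv == 0.0

    def test_matches_simulation_oracle(self):
        table = generate_paired_channels(100_000, 500.0, 500.0, 30.0, 5.0, seed=1)
        bound = technical_noise_bound(table.values("channel_a"), table.values("channel_b"))
        assert bound.cv == pytest.approx(np.sqrt(2) * 5.0, abs=0.3)

    def test_invariant_to_biological_cv(self):
        """The ratio CV is a technical-noise bound: biology cancels."""
        cvs = []
        for biol in (10.0, 30.0, 50.0):
            table = generate_paired_channels(50_000, 500.0, 500.0, biol, 5.0, seed=2)
            cvs.append(technical_noise_bound(table.values("channel_a"), table.values("channel_b")).cv)
        assert max(cvs) - min(cvs) < 0.5

    def test_shuffling_breaks_the_pairing(self):
        table = generate_paired_channels(20_000, 500.0, 500.0, 30.0, 5.0, seed=3)
        a, b = table.values("channel_a"), table.values("channel_b")
        paired = technical_noise_bound(a, b).cv
        rng = np.random.default_rng(0)
        shuffled = technical_noise_bound(a, rng.permutation(b)).cv
        assert shuffled > 3 * paired

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            technical_noise_bound([1.0, 2.0], [1.0])


class TestPeakChannelSkew:
    def test_symmetric_on_log_scale(self):
        x = generate_population(PopulationSpec(200_000, 100.0, 30.0), seed=4).values("intensity")
        below, above = peak_channel_skew(x, n_bins=64)
        # log-normal is symmetric on the log axis
        assert abs(below - above) < 0.05

    def test_low_mean_minority_skews_left(self):
        mix = generate_mixture(
            [(0.2, PopulationSpec(1, 100.0, 20.0)), (0.8, PopulationSpec(1, 200.0, 20.0))],
            n=100_000,
            seed=5,
        )
        below, above = peak_channel_skew(mix.values("intensity"), n_bins=64)
        assert below > above

    def test_right_skewed_population(self):
        # a bright minority emulates the right-shifted profile of
        # microRNA-deficient cells
        mix = generate_mixture(
            [(0.8, PopulationSpec(1, 100.0, 20.0)), (0.2, PopulationSpec(1, 200.0, 20.0))],
            n=100_000,
            seed=6,
        )
        below, above = peak_channel_skew(mix.values("intensity"), n_bins=64)
        assert above > below

    def test_requires_enough_events(self):
        with pytest.raises(ValueError):
            peak_channel_skew(np.ones(10))


class TestMixtureCVAnalytic:
    def test_single_component_passthrough(self):
        assert mixture_cv_analytic([(1.0, 100.0, 17.0)]) == pytest.approx(17.0)

    def test_law_of_total_variance_hand_example(self):
        """20%/80% at a 2-fold mean difference, both 20% CV -> ~30.2%."""
        composite = mixture_cv_analytic([(0.2, 1.0, 20.0), (0.8, 2.0, 20.0)])
        assert composite == pytest.approx(100 * np.sqrt(0.296) / 1.8, rel=1e-12)
        assert composite == pytest.approx(30.2, abs=0.05)

    def test_agrees_with_empirical_mixture(self):
        comps = [(0.2, 100.0, 20.0), (0.8, 200.0, 20.0)]
        analytic = mixture_cv_analytic(comps)
        mix = generate_mixture(
            [(f, PopulationSpec(1, m, c)) for f, m, c in comps], n=100_000, seed=7
        )
        empirical = cv(mix.values("intensity")).cv
        assert empirical == pytest.approx(analytic, abs=0.4)

    def test_equal_cv_unequal_means_always_raises_cv(self):
        assert mixture_cv_analytic([(0.5, 100.0, 15.0), (0.5, 150.0, 15.0)]) > 15.0

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            mixture_cv_analytic([(0.6, 100.0, 20.0), (0.6, 200.0, 20.0)])


@pytest.fixture(scope="module")
def contaminated():
    mixture = generate_mixture(
        [(0.1, PopulationSpec(1, 100.0, 20.0)), (0.9, PopulationSpec(1, 200.0, 20.0))],
        n=100_000,
        seed=8,
    )
    reference = generate_population(PopulationSpec(100_000, 100.0, 20.0), seed=9)
    pure = generate_population(PopulationSpec(100_000, 200.0, 20.0), seed=10)
    return mixture, reference, pure


class TestUnmixCurve:

    def test_zero_removal_reproduces_sample_cv_exactly(self, contaminated):
        mixture, reference, _ = contaminated
        curve = unmix_cv_curve(mixture.values("intensity"), reference.values("intensity"),
                               fraction_grid=[0.0, 0.05, 0.1])
        assert curve.cv_remainder[0] == pytest.approx(cv(mixture.values("intensity")).cv, rel=1e-12)

    def test_monotone_decrease_and_full_removal_recovers_majority(self, contaminated):
        mixture, reference, pure = contaminated
        grid = np.linspace(0.0, 0.1, 11)
        curve = unmix_cv_curve(mixture.values("intensity"), reference.values("intensity"), grid)
        assert np.all(np.diff(curve.cv_remainder) <= 1e-9)
        assert curve.cv_remainder[-1] == pytest.approx(cv(pure.values("intensity")).cv, abs=1.0)

    def test_proportional_removal_leaves_cv_unchanged(self, contaminated):
        mixture, _, _ = contaminated
        x = mixture.values("intensity")
        curve = unmix_cv_curve(x, x, fraction_grid=[0.0, 0.2, 0.4])
        assert np.allclose(curve.cv_remainder, curve.cv_remainder[0], atol=1e-6)

    def test_fraction_for_requested_reduction(self, contaminated):
        mixture, reference, _ = contaminated
        grid = np.linspace(0.0, 0.1, 21)
        curve = unmix_cv_curve(mixture.values("intensity"), reference.values("intensity"), grid)
        drop = curve.cv_remainder[0] - curve.cv_remainder[-1]
        f = curve.fraction_for_reduction(drop / 2)
        assert 0.0 < f < 0.1
        assert np.isnan(curve.fraction_for_reduction(50.0))

    def test_truncation_warns_when_mass_exhausted(self):
        x = generate_population(PopulationSpec(5000, 100.0, 20.0), seed=11).values("intensity")
        with pytest.warns(UserWarning, match="truncated"):
            curve = unmix_cv_curve(x, x, fraction_grid=[0.0, 0.5, 0.9999])
        assert len(curve.fractions) < 3


class TestCompareCV:
    def test_identical_groups_are_null(self):
        group = [14.0, 15.0, 16.0, 15.5]
        res = compare_cv(group, group)
        assert res.difference == 0.0
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_are_significant(self, rng):
        a = rng.normal(15.0, 1.0, size=8)
        b = rng.normal(20.0, 1.0, size=8)
        res = compare_cv(a, b)
        assert res.p < 0.001
        assert res.difference < 0

    def test_swapping_groups_flips_sign_only(self, rng):
        a = rng.normal(15.0, 1.0, size=6)
        b = rng.normal(18.0, 1.0, size=6)
        fwd, rev = compare_cv(a, b), compare_cv(b, a)
        assert fwd.difference == pytest.approx(-rev.difference)
        assert fwd.p == pytest.approx(rev.p)

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            compare_cv([15.0], [16.0, 17.0])
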