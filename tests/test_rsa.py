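"""Model RDMs, ERP-RDM time courses, orthogonalization, and neurometric fits."""

import numpy as np
import pandas as pd
import pytest

from sampeeg.agents import AgentParams
from sampeeg.epochs import EpochSet, GenParams, generate_epochs, value_mean_epochs
from sampeeg.erp import baseline_correct
from sampeeg.experiments import _simulate_participant_trials
from sampeeg.rsa import (
    RDM,
    default_b_grid,
    default_k_grid,
    erp_rdm_timecourse,
    frequency_rdm,
    model_rdm,
    neurometric_fit,
    orthogonalize_model,
    rsa_timecourse,
    value_frequencies,
    window_average_rdm,
)


class TestModelRDM:
    def test_distance_worked_examples(self):
        m = model_rdm("distance", k=1.0, b=0.0).matrix
        assert m[2, 6] == pytest.approx(4.0)  # values 3 and 7
        assert m[3, 5] == pytest.approx(2.0)  # values 4 and 6

    def test_extremity_of_equally_extreme_values_is_zero(self):
        m = model_rdm("extremity", k=1.0, b=0.0).matrix
        assert m[0, 8] == pytest.approx(0.0)  # values 1 and 9
        assert m[0, 4] == pytest.approx(4.0)  # values 1 and 5

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            model_rdm("distance", k=0.0)
        with pytest.raises(ValueError):
            model_rdm("size")

    def test_rdm_validation(self):
        with pytest.raises(ValueError):
            RDM(np.arange(81).reshape(9, 9))  # not symmetric
        m = np.ones((9, 9))
        with pytest.raises(ValueError):
            RDM(m)  # nonzero diagonal


class TestErpRdm:
    def test_three_four_five_toy(self):
        """Two channels with mean patterns (0,0) and (3,4) give distance 5."""
        data = np.zeros((9, 2, 250))
        data[1, 0, :] = 3.0
        data[1, 1, :] = 4.0
        ep = EpochSet(
            data=data,
            events=pd.DataFrame({"value": np.arange(1, 10)}),
            channels=("A", "B"),
        )
        rdms = erp_rdm_timecourse(ep)
        assert np.allclose(rdms[:, 0, 1], 5.0)
        assert np.allclose(rdms[:, 1, 0], 5.0)

    def test_identical_topographies_give_zero_rdm(self):
        data = np.ones((18, 64, 250))
        ep = EpochSet(
            data=data,
            events=pd.DataFrame({"value": np.tile(np.arange(1, 10), 2)}),
        )
        assert np.allclose(erp_rdm_timecourse(ep), 0.0)

    def test_missing_value_reported(self):
        data = np.zeros((8, 64, 250))
        ep = EpochSet(data=data, events=pd.DataFrame({"value": np.arange(1, 9)}))
        with pytest.raises(ValueError, match="9"):
            erp_rdm_timecourse(ep)

    def test_symmetry_and_zero_diagonal_on_random_data(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((27, 64, 250))
        ep = EpochSet(
            data=data, events=pd.DataFrame({"value": np.tile(np.arange(1, 10), 3)})
        )
        rdms = erp_rdm_timecourse(ep)
        assert np.allclose(rdms, np.transpose(rdms, (0, 2, 1)))
        assert np.allclose(rdms[:, np.arange(9), np.arange(9)], 0.0)
        assert np.all(rdms >= 0)


class TestOrthogonalization:
    def test_residual_has_zero_correlation_with_frequency(self):
        freq = frequency_rdm(np.array([0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]))
        model = orthogonalize_model(model_rdm("distance"), freq)
        r = np.corrcoef(model.lower_triangle, freq.lower_triangle)[0, 1]
        assert abs(r) < 1e-12

    def test_orthogonal_frequency_only_removes_mean(self):
        model = model_rdm("distance")
        y = model.lower_triangle
        rng = np.random.default_rng(1)
        # construct a frequency-like regressor orthogonal to the centered model
        f = rng.standard_normal(36)
        f -= f.mean()
        yc = y - y.mean()
        f -= (f @ yc) / (yc @ yc) * yc
        i, j = np.tril_indices(9, k=-1)
        fm = np.zeros((9, 9))
        fm[i, j] = f
        fm[j, i] = f
        out = orthogonalize_model(model, RDM(fm))
        assert np.allclose(out.lower_triangle, y - y.mean(), atol=1e-10)

    def test_three_value_toy_matches_hand_solved_normal_equations(self):
        """3 labels -> 3 lower-triangle entries; residuals solved by hand."""
        labels = np.array([1, 2, 3])
        model = RDM(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float), labels=labels)
        freq = RDM(np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float), labels=labels)
        # y = (1, 2, 1) on f = (1, 3, 2): slope = cov/var = 1/2, intercept 1/3,
        # residuals y - (1/3 + f/2) = (1/6, 1/6, -1/3)
        out = orthogonalize_model(model, freq)
        expected = np.array([1 / 6, 1 / 6, -1 / 3])
        assert np.allclose(out.lower_triangle, expected)

    def test_constant_frequency_returns_model_with_warning(self):
        freq = frequency_rdm(np.full(9, 1 / 9))
        with pytest.warns(UserWarning):
            out = orthogonalize_model(model_rdm("distance"), freq)
        assert np.allclose(out.matrix, model_rdm("distance").matrix)


class TestRsaTimecourse:
    def test_model_with_itself_is_one(self):
        model = model_rdm("distance")
        rdms = np.stack([model.matrix * s for s in (0.5, 1.0, 2.0)])
        r = rsa_timecourse(rdms, model)
        assert np.allclose(r, 1.0)

    def test_scale_invariance_of_model(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((18, 64, 250))
        ep = EpochSet(
            data=data, events=pd.DataFrame({"value": np.tile(np.arange(1, 10), 2)})
        )
        rdms = erp_rdm_timecourse(ep)
        model = model_rdm("distance")
        scaled = RDM(3.7 * model.matrix)
        assert np.allclose(rsa_timecourse(rdms, model), rsa_timecourse(rdms, scaled))

    def test_constant_rdm_yields_nan(self):
        model = model_rdm("distance")
        rdms = np.zeros((5, 9, 9))
        r = rsa_timecourse(rdms, model)
        assert np.all(np.isnan(r))


class TestNeurometricFit:
    def test_default_grid_bounds_and_anchors(self):
        k = default_k_grid()
        b = default_b_grid()
        assert k.min() == pytest.approx(0.5) and k.max() == pytest.approx(10.0)
        assert b.min() == pytest.approx(-0.75) and b.max() == pytest.approx(0.75)
        assert 1.0 in k
        assert 0.0 in b

    def test_grid_outside_bounds_rejected(self):
        wrdm = model_rdm("distance")
        with pytest.raises(ValueError):
            neurometric_fit(wrdm, k_grid=[0.1, 1.0])
        with pytest.raises(ValueError):
            neurometric_fit(wrdm, b_grid=[-0.9])
        with pytest.raises(ValueError):
            neurometric_fit(wrdm, k_grid=[])

    def test_noisefree_distance_family_self_consistency(self, partial_trials):
        """Pure linear distance data: the distance-family surface peaks at
        the linear, unbiased parameterization exactly."""
        rng = np.random.default_rng(3)
        params = GenParams(
            k_true=1.0, b_true=0.0, noise_sd=0.0, gain_extremity=0.0,
            gain_cpp=0.0, gain_lat=0.0, condition_gains={},
        )
        ep = baseline_correct(generate_epochs(params, partial_trials, rng))
        rdms = erp_rdm_timecourse(ep)
        wrdm = window_average_rdm(rdms, ep.times, 0.3, 0.6)
        nmap = neurometric_fit(wrdm, kinds=("distance",))
        assert nmap.argmax_k == pytest.approx(1.0)
        assert nmap.argmax_b == pytest.approx(0.0)

    def test_surface_at_linear_point_matches_plain_correlation(self, partial_trials):
        rng = np.random.default_rng(4)
        ep = baseline_correct(
            generate_epochs(GenParams(condition_gains={}), partial_trials, rng)
        )
        rdms = erp_rdm_timecourse(ep)
        wrdm = window_average_rdm(rdms, ep.times, 0.3, 0.6)
        freq = frequency_rdm(value_frequencies(ep.events))
        nmap = neurometric_fit(wrdm, freq, k_grid=[1.0], b_grid=[0.0])
        expected = np.mean(
            [
                np.corrcoef(
                    wrdm.lower_triangle,
                    orthogonalize_model(model_rdm(kind), freq).lower_triangle,
                )[0, 1]
                for kind in ("distance", "extremity")
            ]
        )
        assert nmap.corr[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_tie_breaks_toward_linear_unbiased(self):
        # a constant-plus-noise-free degenerate surface: use data equal to a
        # frequency-orthogonalized combination is overkill; instead check the
        # tie rule with a data RDM correlating identically under b sign flip
        wrdm = model_rdm("extremity", k=1.0, b=0.0)  # symmetric in b
        nmap = neurometric_fit(wrdm, kinds=("extremity",), k_grid=[1.0], b_grid=[-0.3, 0.0, 0.3])
        assert nmap.argmax_b == 0.0

    def test_group_recovery_monotone_in_true_exponent(self):
        """Group mean recovered exponent is nondecreasing in the generating
        exponent (b fixed at 0, fixed noise level)."""
        agent = AgentParams(side_policy="random")
        group_means = []
        for k_true in (0.7, 1.0, 2.0, 4.0):
            ks = []
            for p in range(5):
                rng = np.random.default_rng(np.random.SeedSequence([900, p]))
                trials = _simulate_participant_trials(agent, "partial", 20, rng)
                params = GenParams(
                    k_true=k_true, b_true=0.0, gain_cpp=0.0, gain_lat=0.0,
                    condition_gains={},
                )
                ep = generate_epochs(params, trials, rng, dtype=np.float32)
                freq = frequency_rdm(value_frequencies(ep.events))
                means = baseline_correct(value_mean_epochs(ep))
                rdms = erp_rdm_timecourse(means)
                wrdm = window_average_rdm(rdms, means.times, 0.3, 0.6)
                nmap = neurometric_fit(wrdm, freq)
                ks.append(nmap.argmax_k)
            group_means.append(np.mean(ks))
        assert all(a <= b + 1e-12 for a, b in zip(group_means, group_means[1:]))


class TestFrequencyRdm:
    def test_entries_are_absolute_frequency_differences(self):
        f = np.array([0.2, 0.05, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.15])
        m = frequency_rdm(f).matrix
        assert m[0, 1] == pytest.approx(0.15)
        assert m[1, 8] == pytest.approx(0.10)

    def test_requires_shares_summing_to_one(self):
        with pytest.raises(ValueError):
            frequency_rdm(np.full(9, 0.2))

    def test_value_frequencies_from_events(self):
        ev = pd.DataFrame({"value": [1, 1, 2, 9]})
        f = value_frequencies(ev)
        assert f[0] == pytest.approx(0.5)
        assert f.sum() == pytest.approx(1.0)
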