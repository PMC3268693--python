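"""Shell statistics and relative scale/B estimation."""

import numpy as np
import pytest

import betaburn as bb
from betaburn.exceptions import DegenerateFitError
from betaburn.scaling import ShellTable


def make_table(s2, mean_J, n=100, mean_sigma=None, wedge_index=0, dose=0.0):
    s2 = np.asarray(s2, dtype=float)
    mean_J = np.asarray(mean_J, dtype=float)
    ms = np.zeros_like(mean_J) if mean_sigma is None else np.asarray(mean_sigma, float)
    return ShellTable(
        s2_mid=s2,
        mean_J=mean_J,
        mean_sigma=ms,
        n_obs=np.full(len(s2), n),
        edges=np.concatenate([[0.0], s2 + np.diff(np.concatenate([[0.0], s2])) / 2]),
        wedge_index=wedge_index,
        nominal_dose=dose,
    )


class TestShellStatistics:
    def test_single_shell_mean(self):
        ds = bb.WedgeDataset(0, 0.0, [0, 1], [0.01, 0.02], [2.0, 4.0], [0.5, 0.7])
        t = bb.shell_statistics(ds, n_shells=1)
        assert t.mean_J[0] == pytest.approx(3.0)
        assert t.mean_sigma[0] == pytest.approx(0.6)
        assert t.n_obs[0] == 2

    def test_last_shell_snr_is_mean_ratio(self):
        ds = bb.WedgeDataset(0, 0.0, [0, 1], [0.01, 0.06], [2.0, 4.0], [0.5, 0.8])
        t = bb.shell_statistics(ds, n_shells=2, d_min=2.0)
        assert t.last_shell_snr == pytest.approx(4.0 / 0.8)

    def test_means_match_generative_model(self, wilson_default):
        ref = bb.simulate_reference(wilson_default, 20_000, seed=9)
        t = bb.shell_statistics(ref, n_shells=10, d_min=2.0)
        expect = wilson_default.shell_mean(t.s2_mid)
        assert np.allclose(t.mean_J, expect, rtol=0.03)

    def test_empty_shell_merged_and_flagged(self):
        # reflections only at low and high resolution: middle shells empty
        s2 = np.array([0.001, 0.002, 0.060, 0.061])
        ds = bb.WedgeDataset(0, 0.0, np.arange(4), s2, np.ones(4), np.zeros(4))
        with pytest.warns(UserWarning, match="merged"):
            t = bb.shell_statistics(ds, n_shells=10, d_min=2.0)
        assert t.merged
        assert t.n_shells == 2
        assert np.all(t.n_obs >= 1)


class TestFitRelativeScaleB:
    def test_identical_wedge_gives_unity(self):
        s2 = np.linspace(0.005, 0.0625, 10)
        mean = np.exp(-2 * 15 * s2)
        t = make_table(s2, mean)
        fit = bb.fit_relative_scale_B(t, t)
        assert fit.k == pytest.approx(1.0, abs=1e-12)
        assert fit.B == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_scale_and_b_recovered_exactly(self):
        s2 = np.linspace(0.005, 0.0625, 10)
        ref = make_table(s2, np.exp(-2 * 15 * s2))
        wedge = make_table(s2, 0.8 * np.exp(-2 * 2.0 * s2) * ref.mean_J)
        fit = bb.fit_relative_scale_B(wedge, ref)
        assert fit.k == pytest.approx(0.8, abs=1e-9)
        assert fit.B == pytest.approx(2.0, abs=1e-9)

    def test_two_shell_closed_form_equivalence(self):
        """Two shells determine (k, dB) exactly; fit must match the 2x2 solve."""
        s2 = np.array([0.02, 0.06])
        ref = make_table(s2, np.array([1.0, 0.4]))
        wedge = make_table(s2, np.array([0.7, 0.1]))
        fit = bb.fit_relative_scale_B(wedge, ref)
        y = np.log(wedge.mean_J / ref.mean_J)
        b = (y[1] - y[0]) / (s2[1] - s2[0])
        a = y[0] - b * s2[0]
        assert fit.B == pytest.approx(-0.5 * b, abs=1e-9)
        assert fit.k == pytest.approx(np.exp(a), abs=1e-9)

    def test_reciprocity(self):
        s2 = np.linspace(0.005, 0.0625, 8)
        ref = make_table(s2, np.exp(-2 * 12 * s2))
        wedge = make_table(s2, 0.5 * np.exp(-2 * 3.0 * s2) * ref.mean_J)
        f = bb.fit_relative_scale_B(wedge, ref)
        g = bb.fit_relative_scale_B(ref, wedge)
        assert f.k * g.k == pytest.approx(1.0, abs=1e-8)
        assert f.B + g.B == pytest.approx(0.0, abs=1e-8)

    def test_nonpositive_shells_excluded_with_warning(self):
        s2 = np.linspace(0.005, 0.0625, 6)
        ref = make_table(s2, np.exp(-2 * 10 * s2))
        bad = ref.mean_J.copy()
        bad[-1] = -0.01
        wedge = make_table(s2, bad)
        with pytest.warns(UserWarning, match="non-positive"):
            fit = bb.fit_relative_scale_B(wedge, ref)
        assert fit.B == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_with_one_usable_shell(self):
        s2 = np.array([0.02, 0.06])
        ref = make_table(s2, np.array([1.0, 0.4]))
        wedge = make_table(s2, np.array([0.7, -0.1]))
        with pytest.warns(UserWarning), pytest.raises(DegenerateFitError):
            bb.fit_relative_scale_B(wedge, ref)

    def test_unbiased_under_noise(self):
        """Monte Carlo: estimates centred on truth within 2 se of the MC mean."""
        rng = np.random.default_rng(77)
        s2 = np.linspace(0.005, 0.0625, 10)
        ref_mean = np.exp(-2 * 15 * s2)
        true_k, true_B = 0.8, 2.0
        wedge_mean = true_k * np.exp(-2 * true_B * s2) * ref_mean
        n = 200
        ks, Bs = [], []
        for _ in range(500):
            noisy = wedge_mean * (1 + rng.normal(0, 1.0 / np.sqrt(n), size=len(s2)))
            wedge = make_table(s2, noisy, n=n)
            ref = make_table(s2, ref_mean, n=10**9)  # effectively exact reference
            fit = bb.fit_relative_scale_B(wedge, ref)
            ks.append(fit.k)
            Bs.append(fit.B)
        se_k = np.std(ks) / np.sqrt(len(ks))
        se_B = np.std(Bs) / np.sqrt(len(Bs))
        assert abs(np.mean(ks) - true_k) < 2 * se_k + 0.003
        assert abs(np.mean(Bs) - true_B) < 2 * se_B + 0.01


class TestJointScaleSeries:
    def test_identical_wedges_all_unity(self):
        s2 = np.linspace(0.005, 0.0625, 10)
        tables = [make_table(s2, np.exp(-2 * 15 * s2), wedge_index=i) for i in range(5)]
        scales = bb.joint_scale_series(tables)
        for s in scales:
            assert s.k == pytest.approx(1.0, abs=1e-10)
            assert s.B == pytest.approx(0.0, abs=1e-10)

    def test_gauge_fixing_exact(self, protocol_default, wilson_default):
        noise = bb.NoiseModel(gain=bb.calibrate_gain(wilson_default, 5.0))
        wedges = bb.simulate_experiment(protocol_default, wilson_default, bb.DamageTruth(1.0), noise, seed=3)
        tables = [bb.shell_statistics(w, 10, d_min=2.0) for w in wedges]
        scales = bb.joint_scale_series(tables)
        assert max(s.k for s in scales) == 1.0
        assert scales[0].B == 0.0

    def test_recovered_b_linear_in_dose(self, protocol_default, wilson_default):
        noise = bb.NoiseModel(gain=bb.calibrate_gain(wilson_default, 5.0))
        wedges = bb.simulate_experiment(protocol_default, wilson_default, bb.DamageTruth(1.0), noise, seed=4)
        tables = [bb.shell_statistics(w, 10, d_min=2.0) for w in wedges]
        scales = bb.joint_scale_series(tables)
        doses = np.array([s.nominal_dose for s in scales])
        B = np.array([s.B for s in scales])
        slope = np.polyfit(doses, B, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.05)

    def test_order_invariance(self, protocol_default, wilson_default):
        noise = bb.NoiseModel(gain=bb.calibrate_gain(wilson_default, 5.0))
        wedges = bb.simulate_experiment(protocol_default, wilson_default, bb.DamageTruth(1.0), noise, seed=5)
        tables = [bb.shell_statistics(w, 10, d_min=2.0) for w in wedges]
        direct = {s.wedge_index: s for s in bb.joint_scale_series(tables)}
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tables))
        shuffled = {s.wedge_index: s for s in bb.joint_scale_series([tables[i] for i in perm])}
        for i in direct:
            assert shuffled[i].k == pytest.approx(direct[i].k, rel=1e-9)
            assert shuffled[i].B == pytest.approx(direct[i].B, abs=1e-9)

    def test_monotone_damage_noiseless(self, protocol_default, wilson_default):
        wedges = bb.simulate_experiment(protocol_default, wilson_default, bb.DamageTruth(0.7), None, seed=6)
        tables = [bb.shell_statistics(w, 10, d_min=2.0) for w in wedges]
        B = np.array([s.B for s in bb.joint_scale_series(tables)])
        assert np.all(np.diff(B) > 0)

    def test_requires_two_wedges(self):
        s2 = np.linspace(0.005, 0.0625, 10)
        with pytest.raises(ValueError):
            bb.joint_scale_series([make_table(s2, np.exp(-2 * 15 * s2))])
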