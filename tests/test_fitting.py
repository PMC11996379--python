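import numpy as np
import pytest

from tdfret import (
    BufferModel,
    DecayHistogram,
    DegenerateDataError,
    DistanceDistribution,
    DonorModel,
    ModelCurve,
    SpecError,
)
from tdfret.fitting import (
    FitSpec,
    ParameterSpec,
    chi2,
    chi2_profile,
    chi2_surface,
    fit,
    fit_buffer,
    fit_donor_only,
    fit_fret_global,
    fit_fret_single,
    fit_fret_two_acceptor,
    fit_window,
    make_fret_spec,
)
from tdfret.simulate import (
    DONOR_MODEL,
    FORSTER_RADIUS_ACD_RU as R0,
    intersubunit_distribution,
    make_study_fixture,
)

from conftest import make_pair


def flat_grid(n=64, dt=0.1):
    return (np.arange(n) + 0.5) * dt


class TestChi2:
    def test_perfect_fit(self):
        t = flat_grid()
        h = DecayHistogram(t, np.full(64, 100))
        m = ModelCurve(t, np.full(64, 100.0))
        total, res = chi2(h, m)
        assert total == 0.0
        assert res.size == 64

    def test_hand_computed_poisson(self):
        t = flat_grid(16)
        counts = np.full(16, 100)
        model = np.full(16, 100.0)
        model[7] = 90.0  # one bin off by 10 -> ((10)/sqrt(100))^2 = 1
        total, _ = chi2(DecayHistogram(t, counts), ModelCurve(t, model))
        assert total == pytest.approx(1.0)

    def test_hand_computed_as_printed(self):
        t = flat_grid(16)
        counts = np.full(16, 100)
        model = np.full(16, 100.0)
        model[7] = 90.0  # sigma = counts -> ((10)/100)^2
        total, _ = chi2(
            DecayHistogram(t, counts), ModelCurve(t, model), weighting="as-printed"
        )
        assert total == pytest.approx(0.01)

    def test_reduced_chi2_near_one_for_poisson_data(self):
        rng = np.random.default_rng(0)
        t = flat_grid(4096, 0.01)
        expected = np.full(4096, 500.0)
        counts = rng.poisson(expected)
        total, res = chi2(DecayHistogram(t, counts), ModelCurve(t, expected))
        assert total / 4096 == pytest.approx(1.0, abs=3.0 / np.sqrt(4096))

    def test_all_zero_rejected(self):
        t = flat_grid()
        with pytest.raises(DegenerateDataError):
            chi2(DecayHistogram(t, np.zeros(64)), ModelCurve(t, np.ones(64)))


class TestFitBuffer:
    def test_two_component_recovery(self):
        from tdfret import FretDecayParameters, SimulationConfig, simulate_decay, simulate_irf

        truth = FretDecayParameters(
            f_D=0.05, donor=DONOR_MODEL, R0=R0,
            rho1=DistanceDistribution.single(41.7, 2.3), f_B=1.0, A0=1.0,
            bkgr_dec=2.0,
        )
        cfg = SimulationConfig(
            truth=truth, buffer=BufferModel(((3.0, 1.2), (1.0, 6.0))),
            n_bins=1024, total_counts=1e6, buffer_counts=1e6, seed=77,
        )
        irf = simulate_irf(cfg)
        pair, _, buffer_eff = simulate_decay(cfg, irf)
        bmodel, result = fit_buffer(pair.buffer, pair.irf, n_components=2)
        taus = sorted(tau for _, tau in bmodel.components)
        truth_taus = sorted(tau for _, tau in buffer_eff.components)
        for fitted, true in zip(taus, truth_taus):
            assert fitted == pytest.approx(true, rel=0.05)

    def test_flat_background_only(self):
        rng = np.random.default_rng(3)
        t = flat_grid(512, 0.1)
        counts = rng.poisson(20.0, 512)
        buffer = DecayHistogram(t, counts, role="buffer")
        irf_counts = np.zeros(512, dtype=int)
        irf_counts[20] = 100000
        irf = DecayHistogram(t, irf_counts, role="irf")
        bmodel, result = fit_buffer(buffer, irf, n_components=1)
        amp, tau = bmodel.components[0]
        # counts attributable to the exponential are a negligible share
        exp_counts = amp * 100000 * tau / 0.1
        assert exp_counts < 0.05 * counts.sum()
        assert result.estimates[0]["bkgr_dec"] == pytest.approx(20.0, rel=0.05)

    def test_component_cap(self):
        t = flat_grid()
        h = DecayHistogram(t, np.full(64, 100), role="buffer")
        irf = DecayHistogram(t, np.full(64, 10), role="irf")
        with pytest.raises(SpecError):
            fit_buffer(h, irf, n_components=5)

    def test_low_counts_rejected(self):
        t = flat_grid()
        h = DecayHistogram(t, np.ones(64), role="buffer")
        irf = DecayHistogram(t, np.full(64, 10), role="irf")
        with pytest.raises(DegenerateDataError):
            fit_buffer(h, irf)


class TestFitDonorOnly:
    def test_biexponential_recovery(self):
        fx = make_study_fixture("donor_only", seed=3)
        pair = fx.pairs[0]
        bmodel, _ = fit_buffer(pair.buffer, pair.irf, 1)
        donor, result = fit_donor_only(pair, bmodel)
        (a1, tau1), (_, tau2) = donor.components
        assert tau1 == pytest.approx(17.6, rel=0.02)
        assert a1 == pytest.approx(0.87, abs=0.03)
        assert tau2 == pytest.approx(4.73, rel=0.25)
        assert 0.8 < result.reduced_chi2 < 1.2

    def test_monoexponential_truth_degeneracy(self):
        mono = DonorModel(((1.0, 17.6),))
        pair, _, _ = make_pair(
            DistanceDistribution.single(50.0, 3.0), f_D=1.0, seed=55,
            n_bins=512, total_counts=1e6,
        )
        # regenerate with a mono donor truth
        from tdfret import FretDecayParameters, SimulationConfig, simulate_decay, simulate_irf

        truth = FretDecayParameters(
            f_D=1.0, donor=mono, R0=R0,
            rho1=DistanceDistribution.single(50.0, 3.0), f_B=0.0, A0=1.0,
            bkgr_dec=2.0,
        )
        cfg = SimulationConfig(truth=truth, n_bins=512, total_counts=1e6, seed=56)
        irf = simulate_irf(cfg)
        pair, _, _ = simulate_decay(cfg, irf)
        donor, _ = fit_donor_only(pair)
        if len(donor.components) == 2:
            (a1, tau1), (a2, tau2) = donor.components
            assert tau1 == pytest.approx(tau2, rel=0.2) or min(a1, a2) < 0.05


class TestFitFretSingle:
    def test_single_gaussian_recovery(self, resting_pair):
        pair, truth, bmodel = resting_pair
        spec = make_fret_spec(
            [pair], DONOR_MODEL, [bmodel], R0,
            overrides={"f_A2": ParameterSpec("f_A2", "fixed", 0.0)},
        )
        result = fit_fret_single(pair, spec)
        est = result.estimates[0]
        assert est["r1"] == pytest.approx(41.7, abs=0.5)
        assert est["sigma1"] == pytest.approx(2.3, abs=0.8)
        assert est["f_D"] == pytest.approx(truth.f_D, abs=0.05)
        assert 0.85 < result.reduced_chi2 < 1.15

    def test_no_fret_regime_warns_unidentifiable(self):
        pair, _, _ = make_pair(
            DistanceDistribution.single(3 * R0, 1.0), seed=60,
            n_bins=512, total_counts=1e6, with_buffer=False,
        )
        spec = make_fret_spec(
            [pair], DONOR_MODEL, [None], R0,
            overrides={"f_A2": ParameterSpec("f_A2", "fixed", 0.0)},
        )
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            fit_fret_single(pair, spec, n_starts=1)

    def test_all_fixed_is_chi2_evaluation(self, resting_pair):
        pair, truth, bmodel = resting_pair
        overrides = {
            name: ParameterSpec(name, "fixed", value)
            for name, value in [
                ("f_D", truth.f_D), ("r1", 41.7), ("sigma1", 2.3),
                ("f_A2", 0.0), ("r2", 30.0), ("sigma2", 3.0),
                ("shift_irf", 0.0), ("A0", truth.A0), ("bkgr_dec", truth.bkgr_dec),
            ]
        }
        spec = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0, overrides=overrides)
        result = fit_fret_single(pair, spec)
        assert result.n_free == 0
        assert "no free parameters" in result.message
        assert result.reduced_chi2 == pytest.approx(1.0, abs=0.15)

    def test_spec_must_reference_pair(self, resting_pair, mixed_pair):
        pair, _, bmodel = resting_pair
        other_pair, _, other_b = mixed_pair
        spec = make_fret_spec([other_pair], DONOR_MODEL, [other_b], R0)
        with pytest.raises(SpecError):
            fit_fret_single(pair, spec)

    def test_state_label_tiebreak(self, mixed_pair):
        # component 1 must come out as the longer-distance Gaussian
        pair, truth, bmodel = mixed_pair
        spec = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0)
        result = fit_fret_single(pair, spec)
        est = result.estimates[0]
        assert est["r1"] > est["r2"]


@pytest.fixture(scope="module")
def titration():
    fx = make_study_fixture(
        "cterm_hetero_titration", seed=5, n_bins=512, total_counts=2e6
    )
    buffers = [fit_buffer(p.buffer, p.irf, 1)[0] for p in fx.pairs]
    return fx, buffers


class TestFitFretGlobal:
    def test_shared_distance_recovery(self, titration):
        fx, buffers = titration
        spec = make_fret_spec(
            fx.pairs, fx.donor, buffers, fx.R0,
            shared=("r1", "sigma1", "r2", "sigma2"),
        )
        result = fit_fret_global(spec)
        est0 = result.estimates[0]
        assert est0["r1"] == pytest.approx(41.7, abs=0.5)
        assert est0["r2"] == pytest.approx(28.8, abs=0.5)
        for d, f_true in enumerate(fx.f_A2):
            assert result.estimates[d]["f_A2"] == pytest.approx(f_true, abs=0.05)
        assert 0.9 < result.reduced_chi2 < 1.1

    def test_replication_consistency(self, resting_pair):
        pair, truth, bmodel = resting_pair
        overrides = {"f_A2": ParameterSpec("f_A2", "fixed", 0.0)}
        single_spec = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0, overrides=overrides)
        single = fit_fret_single(pair, single_spec, n_starts=1)
        shared = ("f_D", "r1", "sigma1", "shift_irf", "A0", "bkgr_dec")
        double_spec = make_fret_spec(
            [pair, pair], DONOR_MODEL, [bmodel, bmodel], R0,
            shared=shared, overrides=[overrides, overrides],
        )
        double = fit_fret_global(double_spec, n_starts=1)
        assert double.estimates[0]["r1"] == pytest.approx(
            single.estimates[0]["r1"], abs=0.01
        )
        assert double.chi2 == pytest.approx(2 * single.chi2, rel=1e-3)

    def test_global_requires_two_decays(self, resting_pair):
        pair, _, bmodel = resting_pair
        spec = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0)
        with pytest.raises(SpecError):
            fit_fret_global(spec)

    def test_single_decay_global_equals_single_fit(self, resting_pair):
        pair, _, bmodel = resting_pair
        overrides = {"f_A2": ParameterSpec("f_A2", "fixed", 0.0)}
        spec_a = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0, overrides=overrides)
        spec_b = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0, overrides=overrides)
        res_a = fit(spec_a, n_starts=1)
        res_b = fit_fret_single(pair, spec_b, n_starts=1)
        for name in ("r1", "sigma1", "f_D", "A0"):
            assert res_a.estimates[0][name] == res_b.estimates[0][name]

    def test_shared_group_needs_multiple_decays(self, resting_pair):
        pair, _, bmodel = resting_pair
        with pytest.raises(SpecError, match="shared"):
            make_fret_spec([pair], DONOR_MODEL, [bmodel], R0, shared=("r1",))


@pytest.fixture(scope="module")
def homo_pair():
    rho1 = DistanceDistribution.two_state(0.25, (41.6, 3.6), (29.1, 4.1))
    rho2 = intersubunit_distribution(0.25)
    pair, truth, _ = make_pair(rho1, rho2=rho2, seed=81, n_bins=512, total_counts=5e6)
    bmodel, _ = fit_buffer(pair.buffer, pair.irf, 1)
    return pair, truth, bmodel


class TestFitFretTwoAcceptor:
    def test_intrasubunit_recovery(self, homo_pair):
        pair, truth, bmodel = homo_pair
        result = fit_fret_two_acceptor(
            pair, intersubunit_distribution(0.5), donor=DONOR_MODEL,
            buffer=bmodel, R0=R0,
        )
        est = result.estimates[0]
        assert est["r1"] == pytest.approx(41.6, abs=1.0)
        # f_A2 is weakly identified at this reduced fixture scale
        assert est["f_A2"] == pytest.approx(0.25, abs=0.35)
        assert 0.85 < result.reduced_chi2 < 1.15

    def test_inert_second_acceptor_matches_single(self, resting_pair):
        pair, truth, bmodel = resting_pair
        overrides = {"f_A2": ParameterSpec("f_A2", "fixed", 0.0)}
        single_spec = make_fret_spec([pair], DONOR_MODEL, [bmodel], R0, overrides=overrides)
        single = fit_fret_single(pair, single_spec, n_starts=1)
        far = DistanceDistribution.single(10 * R0, 1.0)
        two_spec = make_fret_spec(
            [pair], DONOR_MODEL, [bmodel], R0,
            two_acceptor=True, inter=far, overrides=overrides,
        )
        result = fit_fret_two_acceptor(pair, far, spec=two_spec, n_starts=1)
        # second acceptor at 10 R0 quenches nothing; estimates agree
        assert result.estimates[0]["r1"] == pytest.approx(
            single.estimates[0]["r1"], abs=0.05
        )

    def test_inter_params_must_be_fixed(self, homo_pair):
        pair, _, bmodel = homo_pair
        spec = make_fret_spec(
            [pair], DONOR_MODEL, [bmodel], R0,
            two_acceptor=True, inter=intersubunit_distribution(0.5),
        )
        spec.params[0]["r1_inter"] = ParameterSpec("r1_inter", "free", 54.1)
        with pytest.raises(SpecError, match="intersubunit"):
            FitSpec(
                pairs=spec.pairs, params=spec.params, buffers=spec.buffers,
                two_acceptor=True,
            )


@pytest.fixture(scope="module")
def fitted():
    pair, truth, _ = make_pair(
        DistanceDistribution.single(41.7, 2.3), seed=90,
        n_bins=512, total_counts=2e6, with_buffer=False,
    )
    spec = make_fret_spec(
        [pair], DONOR_MODEL, [None], R0,
        overrides={"f_A2": ParameterSpec("f_A2", "fixed", 0.0)},
    )
    result = fit_fret_single(pair, spec, n_starts=1)
    return pair, result


class TestIdentifiability:
    def test_profile_self_consistency(self, fitted):
        _, result = fitted
        r1_hat = result.estimates[0]["r1"]
        prof = chi2_profile(result, "r1", [r1_hat])
        assert prof[0] == pytest.approx(result.reduced_chi2, rel=1e-4)

    def test_profile_minimum_near_truth(self, fitted):
        _, result = fitted
        grid = np.linspace(40.7, 42.7, 9)
        prof = chi2_profile(result, "r1", grid)
        assert abs(grid[np.argmin(prof)] - 41.7) <= 0.5
        assert prof.min() <= prof.max()
        # profile minimum matches the joint fit within optimizer tolerance
        assert prof.min() >= result.reduced_chi2 - 1e-6

    def test_sigma_profile_flatter_than_r(self, fitted):
        # matched +/-5% relative grids around the optimum
        _, result = fitted
        r_hat = result.estimates[0]["r1"]
        s_hat = result.estimates[0]["sigma1"]
        r_grid = r_hat * np.array([0.95, 1.0, 1.05])
        s_grid = s_hat * np.array([0.95, 1.0, 1.05])
        prof_r = chi2_profile(result, "r1", r_grid)
        prof_s = chi2_profile(result, "sigma1", s_grid)
        curv_r = prof_r[0] + prof_r[2] - 2 * prof_r[1]
        curv_s = prof_s[0] + prof_s[2] - 2 * prof_s[1]
        assert curv_s < curv_r

    def test_profile_warns_when_grid_excludes_optimum(self, fitted):
        _, result = fitted
        with pytest.warns(RuntimeWarning, match="excludes"):
            chi2_profile(result, "r1", [60.0, 61.0])

    def test_profile_of_fixed_param_rejected(self, fitted):
        _, result = fitted
        with pytest.raises(SpecError):
            chi2_profile(result, "R0", [43.0, 44.0])

    def test_surface_optimum_is_minimum(self, fitted):
        _, result = fitted
        r_hat = result.estimates[0]["r1"]
        f_hat = result.estimates[0]["f_D"]
        gx = np.array([r_hat - 0.8, r_hat, r_hat + 0.8])
        gy = np.array([max(f_hat - 0.04, 0.0), f_hat, min(f_hat + 0.04, 1.0)])
        surf = chi2_surface(result, "r1", "f_D", gx, gy)
        assert surf[1, 1] == pytest.approx(surf.min(), rel=1e-4)

    def test_sigma_fd_correlation(self, fitted):
        # the quadratic approximation has a nonzero mixed term: the valley is tilted
        _, result = fitted
        s_hat = result.estimates[0]["sigma1"]
        f_hat = result.estimates[0]["f_D"]
        ds, df = 0.3, 0.03
        gx = np.array([s_hat - ds, s_hat, s_hat + ds])
        gy = np.array([max(f_hat - df, 0.0), f_hat, f_hat + df])
        surf = chi2_surface(result, "sigma1", "f_D", gx, gy)
        mixed = (surf[2, 2] - surf[2, 0] - surf[0, 2] + surf[0, 0]) / 4.0
        assert abs(mixed) > 0


class TestFitWindow:
    def test_window_starts_at_rise(self):
        t = flat_grid(512, 0.1)
        counts = np.full(512, 5)
        counts[100:] = 1000
        h = DecayHistogram(t, counts)
        win = fit_window(h)
        assert win.start == 100

    def test_window_full_when_no_rise(self):
        t = flat_grid(512, 0.1)
        h = DecayHistogram(t, np.full(512, 5))
        win = fit_window(h)
        assert win == slice(0, 512)
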