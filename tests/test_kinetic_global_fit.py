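"""Loss function, time weighting, annealed global fit, and point selection."""

import numpy as np
import pytest

from anisokin.equilibrium_analysis import fit_sigmoid
from anisokin.kinetic_global_fit import (FitConfig, KineticDataset,
                                         KineticTrace, dataset_from_plate,
                                         fit_global, kinetic_loss,
                                         predict_dataset,
                                         select_competition_points,
                                         time_weights)
from anisokin.model_core import (AdditionEvent, AssayProtocol,
                                 BindingParameters, simulate_system)
from anisokin.observable import anisotropy_from_states
from anisokin.synthetic_data import (NoiseModel, generate_experiment,
                                     saturation_kinetic_design)


class TestTimeWeights:
    def test_uniform_scheme_is_flat(self):
        assert np.all(time_weights([0, 10, 100], "uniform") == 1.0)

    def test_earliest_point_has_maximal_weight_and_mean_is_one(self):
        t = np.arange(0, 6000, 300)
        w = time_weights(t, "less_timescaling", tau=600.0)
        assert w[0] == w.max()
        assert np.all(np.diff(w) <= 0)
        assert w.mean() == pytest.approx(1.0)

    def test_default_scheme_halves_at_tau(self):
        w_raw = 1.0 / (1.0 + np.array([0.0, 600.0]) / 600.0)
        assert w_raw[1] == 0.5  # pre-normalization value of the declared form
        w = time_weights([0.0, 600.0], "less_timescaling", tau=600.0)
        assert w[1] / w[0] == pytest.approx(0.5)


def flat_trace(fa_values, times=None):
    """Trace with no binding partners: predicted FA is exactly FA_free."""
    times = np.asarray(times if times is not None else [0.0, 10.0, 20.0], float)
    proto = AssayProtocol(initial={"L": 1.0, "R": 0.0, "NBV": 0.0}, times=times)
    return KineticTrace(well="T1", fa=np.asarray(fa_values, float), protocol=proto)


class TestKineticLoss:
    def test_zero_at_the_generating_truth(self, probe_params):
        proto = AssayProtocol(initial={"L": 0.5}, dilution=1 / 30,
                              times=np.linspace(0, 5400, 19))
        fa = anisotropy_from_states(simulate_system(probe_params, proto),
                                    probe_params)
        ds = KineticDataset(traces=(KineticTrace("A1", fa, proto),))
        assert kinetic_loss(probe_params, ds) < 1e-18

    def test_constant_offset_gives_delta_squared(self, probe_params):
        p = probe_params.replace(FA_free=0.081)
        delta = 0.01
        ds = KineticDataset(traces=(flat_trace([0.081 - delta] * 3),))
        loss = kinetic_loss(p, ds, weight_scheme="uniform")
        assert loss == pytest.approx(delta ** 2, rel=1e-9)

    def test_hand_computed_three_point_trace(self, probe_params):
        # predictions are FA_free = 0.081 at every point; observations differ
        obs = np.array([0.080, 0.084, 0.078])
        ds = KineticDataset(traces=(flat_trace(obs),))
        expected = np.mean((0.081 - obs) ** 2)
        assert kinetic_loss(probe_params, ds, weight_scheme="uniform") == \
            pytest.approx(expected, rel=1e-12)
        # weighted variant: w = normalized 1/(1 + t/600)
        w = 1.0 / (1.0 + np.array([0.0, 10.0, 20.0]) / 600.0)
        w /= w.mean()
        expected_w = np.mean(w * (0.081 - obs) ** 2)
        assert kinetic_loss(probe_params, ds) == pytest.approx(expected_w, rel=1e-12)


def mini_dataset(params, n_dil=2, horizon=5400.0, chase=2700.0, interval=300.0):
    """Small association+chase dataset simulated without noise."""
    times = np.arange(0.0, horizon + 1, interval)
    events = (AdditionEvent(chase, "C", 333000.0),) if chase else ()
    traces = []
    for probe in (0.5, 3.0):
        for i in range(n_dil):
            proto = AssayProtocol(initial={"L": probe}, dilution=1 / 30 * 0.5 ** i,
                                  events=events, times=times)
            fa = anisotropy_from_states(simulate_system(params, proto), params)
            traces.append(KineticTrace(f"w{probe}-{i}", fa, proto))
    return KineticDataset(traces=tuple(traces))


MINI_CONFIG = dict(start_temp=10.0, iters_per_temp=150, reduction=0.2,
                   stop_temp=0.5, nm_maxfev=150, n_uncertainty=0)


class TestFitGlobal:
    def test_noise_free_self_consistency(self, probe_params):
        ds = mini_dataset(probe_params)
        cfg = FitConfig(free=("kon_L", "Kd_L", "R_stock"), seed=7, **MINI_CONFIG)
        start = probe_params.replace(kon_L=1e-3, Kd_L=0.3, R_stock=8.0)
        res = fit_global(ds, cfg, start)
        for name, truth in (("kon_L", probe_params.kon_L),
                            ("Kd_L", probe_params.Kd_L), ("R_stock", 20.0)):
            assert res.estimates[name] == pytest.approx(truth, rel=0.01), name

    def test_identical_seed_is_bit_reproducible(self, probe_params):
        ds = mini_dataset(probe_params, n_dil=1)
        cfg = FitConfig(free=("kon_L", "Kd_L"), seed=3, **MINI_CONFIG)
        start = probe_params.replace(kon_L=1e-3, Kd_L=0.3)
        r1 = fit_global(ds, cfg, start)
        r2 = fit_global(ds, cfg, start)
        assert r1.estimates == r2.estimates
        assert r1.loss == r2.loss and r1.n_evals == r2.n_evals

    def test_loss_at_estimates_not_worse_than_truth_on_noisy_data(self, probe_params):
        ds = mini_dataset(probe_params, n_dil=1)
        rng = np.random.default_rng(11)
        noisy = KineticDataset(traces=tuple(
            KineticTrace(t.well, t.fa + 0.004 * rng.standard_normal(len(t.fa)),
                         t.protocol) for t in ds.traces))
        cfg = FitConfig(free=("kon_L", "Kd_L", "R_stock"), seed=5, **MINI_CONFIG)
        res = fit_global(noisy, cfg, probe_params)
        assert res.loss <= kinetic_loss(probe_params, noisy) + 1e-15

    def test_final_loss_matches_recomputation(self, probe_params):
        ds = mini_dataset(probe_params, n_dil=1)
        cfg = FitConfig(free=("kon_L",), seed=1, **MINI_CONFIG)
        res = fit_global(ds, cfg, probe_params.replace(kon_L=2e-4))
        assert kinetic_loss(res.params, ds) == pytest.approx(res.loss, rel=1e-12)

    def test_stacked_predictions_match_per_trace_simulation(self, probe_params):
        ds = mini_dataset(probe_params, n_dil=2)
        preds = predict_dataset(probe_params, ds)
        for tr, pred in zip(ds.traces, preds):
            direct = anisotropy_from_states(
                simulate_system(probe_params, tr.protocol), probe_params)
            np.testing.assert_allclose(pred, direct, atol=5e-8)


def test_competitor_kinetics_mode_recovers_association_rate(probe_params):
    """With the probe parameters fixed at previously fitted values, fitting
    only (kon_C, Ki_C) to a slow-competitor concentration series recovers the
    generating kon_C within 50% (competitor kinetics are weakly identified,
    matching the wide published uncertainties)."""
    from anisokin.equilibrium_analysis import fit_sigmoid, ki_from_ic50_depletion
    from anisokin.synthetic_data import (NoiseModel, competition_kinetic_design,
                                         generate_experiment)

    truth = probe_params.replace(kon_C=2.0e-4, Ki_C=2.7e-4 / 2.0e-4)
    conc = (0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0)
    design = competition_kinetic_design("slow-competitor", conc, probe_nM=1.0,
                                        horizon_s=18000.0, interval_s=900.0)
    plate, well_map, _ = generate_experiment(
        design, truth, NoiseModel(rel_sd=0.01, seed=8))
    ds = dataset_from_plate(plate, well_map, design)

    # endpoint sigmoid seeds Ki and drives the concentration-point selection
    endpoint = np.array([tr.fa[-1] for tr in ds.traces])
    concs = np.array([tr.competitor_nM for tr in ds.traces])
    sig = fit_sigmoid(concs, endpoint, "three_param")
    keep = select_competition_points(concs, endpoint, sig)
    subset = KineticDataset(traces=tuple(
        tr for tr, k in zip(ds.traces, keep) if k or tr.competitor_nM == 0))
    ki0 = ki_from_ic50_depletion(sig.log_ic50, truth.Kd_L, 1.0,
                                 truth.R_stock / 30)

    cfg = FitConfig(free=("kon_C", "Ki_C"), seed=8, start_temp=100.0,
                    iters_per_temp=300, stop_temp=0.5, nm_maxfev=300,
                    n_uncertainty=0)
    res = fit_global(subset, cfg, probe_params.replace(kon_C=1e-3, Ki_C=ki0))
    assert res.estimates["kon_C"] == pytest.approx(2.0e-4, rel=0.5)


def test_removing_dissociation_phase_inflates_affinity_uncertainty(probe_params):
    """Without the chase phase the association data alone leave the
    kon/Kd/R_stock combination much sloppier: the bootstrap SE of Kd roughly
    doubles, which is why both kinetic phases are fitted together."""
    rng = np.random.default_rng(3)

    def make(chase):
        times = np.arange(0.0, 10801.0, 600.0)
        events = (AdditionEvent(5400.0, "C", 333000.0),) if chase else ()
        traces = []
        for probe in (0.5, 3.0):
            for dil in (1 / 30, 1 / 60):
                proto = AssayProtocol(initial={"L": probe}, dilution=dil,
                                      events=events, times=times)
                fa = anisotropy_from_states(
                    simulate_system(probe_params, proto), probe_params)
                traces.append(KineticTrace(
                    f"w{probe}-{dil:.4f}",
                    fa + 0.004 * rng.standard_normal(len(fa)), proto))
        return KineticDataset(traces=tuple(traces))

    cfg = FitConfig(free=("kon_L", "Kd_L", "R_stock", "FA_bound"), seed=2,
                    start_temp=1.0, iters_per_temp=400, stop_temp=0.5,
                    nm_maxfev=400, n_uncertainty=12, perturb_scale=0.05)
    se = {}
    for chase in (True, False):
        se[chase] = fit_global(make(chase), cfg, probe_params).se
    assert se[False]["Kd_L"] > 1.5 * se[True]["Kd_L"]


class TestSelectCompetitionPoints:
    def curve(self):
        c = np.logspace(-2, 3.5, 16)  # dense enough for >= 4 points on the slope
        y = 0.05 + 0.15 / (1 + c / 10.0)
        return c, y

    def test_slope_plus_two_plateau_points_each_side(self):
        c, y = self.curve()
        fit = fit_sigmoid(c, y, "three_param")
        mask = select_competition_points(c, y, fit)
        frac = (fit.top - fit.predict(c)) / (fit.top - fit.bottom)
        on_slope = (frac >= 0.10) & (frac <= 0.90)
        assert np.all(mask[on_slope])
        # exactly up to 2 plateau points retained per side
        n_plateau_kept = int(mask.sum() - on_slope.sum())
        assert 1 <= n_plateau_kept <= 4

    def test_mask_invariant_to_input_ordering(self, rng):
        c, y = self.curve()
        fit = fit_sigmoid(c, y, "three_param")
        perm = rng.permutation(len(c))
        mask = select_competition_points(c, y, fit)
        mask_perm = select_competition_points(c[perm], y[perm], fit)
        assert np.array_equal(mask[perm], mask_perm)

    def test_all_plateau_curve_warns_and_keeps_everything(self):
        c = np.logspace(-2, 3.5, 12)
        fit = fit_sigmoid(*self.curve(), "three_param")
        y_flat = np.full(len(c), fit.top)
        with pytest.warns(UserWarning, match="slope"):
            mask = select_competition_points(c * 1e-6, y_flat, fit)
        assert mask.all()


def test_pipeline_round_trip_noise_free(probe_params):
    """Raw plate -> blank correction -> FA -> dataset reproduces model FA."""
    design = saturation_kinetic_design(
        bbv_dilutions=(1 / 30, 1 / 60), horizon_s=5400.0, chase_time_s=2700.0)
    plate, well_map, _ = generate_experiment(
        design, probe_params, NoiseModel(rel_sd=0.0, seed=0))
    ds = dataset_from_plate(plate, well_map, design)
    assert kinetic_loss(probe_params, ds) < 1e-18
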