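"""Chi-squared assembly, grid search, constrained simplex, warm starts."""

import numpy as np
import pytest

from dispfit.data import DispersionDataset, ExperimentPoint, RateValue, SpinSystem
from dispfit.fitting import (
    Objective,
    ParamKey,
    cluster_average_start,
    grid_search,
    minimise,
    nesting_map,
    translate_params,
    warm_start,
)
from dispfit.simulate import default_cpmg_design, simulate_dataset


def make_flat(values, errors, r20_field=600.0):
    spins = [SpinSystem("A")]
    points = [
        ExperimentPoint("CPMG_SQ", r20_field, nu_cpmg=50.0 * (i + 1), relax_time_T=0.04)
        for i in range(len(values))
    ]
    vals = {
        ("A", i): RateValue(v, e) for i, (v, e) in enumerate(zip(values, errors))
    }
    return DispersionDataset(spins, points, vals)


class TestChi2:
    def test_perfect_fit_is_zero(self):
        ds = make_flat([10.0, 10.0, 10.0], [0.5, 0.5, 0.5])
        obj = Objective("NoRex", ds)
        assert obj.chi2(np.array([10.0])) == 0.0

    def test_single_residual_of_two_sigma(self):
        ds = make_flat([11.0], [0.5])
        obj = Objective("NoRex", ds)
        assert obj.chi2(np.array([10.0])) == pytest.approx(4.0)

    def test_additive_across_spins(self, cr72_dataset):
        design = default_cpmg_design(seed=5, n_spins=2)
        ds = simulate_dataset(design)
        both = Objective("CR72", ds)
        v = both.template.copy().values
        total = both.chi2(v)
        parts = 0.0
        for sid in ("R2:N", "R3:N"):
            single = Objective("CR72", ds, [sid])
            # map shared values into the single-spin layout
            sub = single.template.copy()
            for i, key in enumerate(sub.keys):
                sub.values[i] = v[both.template.index(key)]
            parts += single.chi2(sub.values)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_zero_error_rejected(self):
        spins = [SpinSystem("A")]
        points = [ExperimentPoint("CPMG_SQ", 600, nu_cpmg=50, relax_time_T=0.04)]
        ds = DispersionDataset(spins, points, {("A", 0): RateValue(10.0, 0.0)})
        with pytest.raises(ValueError, match="positive errors"):
            Objective("NoRex", ds)


class TestFastEvaluators:
    @pytest.mark.parametrize("model", ["NoRex", "LM63", "CR72", "IT99", "TSMFK01"])
    def test_hot_path_matches_reference_dispatch(self, cr72_dataset, model):
        # the compiled evaluation route must agree with the public
        # back-calculation dispatch
        from dispfit.catalog import back_calc_spin

        obj = Objective(model, cr72_dataset)
        pv = obj.template.copy()
        for i, key in enumerate(pv.keys):
            pv.values[i] = {
                "pA": 0.93, "kex": 1700.0, "dw": 2.3, "dwH": 0.4,
                "phi_ex": 0.3, "k_ab": 40.0,
            }.get(key.symbol, 11.0)
        fast = obj.back_calc(pv.values)["R2:N"]
        spin = cr72_dataset.spin("R2:N")
        pts = [cr72_dataset.points[i] for i in cr72_dataset.point_indices("R2:N")]
        ref = back_calc_spin(model, spin, pv.spin_params("R2:N"), pts)
        np.testing.assert_allclose(fast, ref, rtol=1e-10, atol=1e-10)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, flat_dataset):
        obj = Objective("CR72", flat_dataset)
        pv = grid_search(obj, grid_points=1)
        assert len(pv.values) == obj.k

    def test_returned_point_minimises_over_grid(self, cr72_dataset):
        obj = Objective("CR72", cr72_dataset)
        pv = grid_search(obj, grid_points=5)
        best = obj.chi2(pv.values)
        # exhaustive re-check is the definition of the operation
        import itertools

        from dispfit.fitting import _grid_axis

        axes = []
        probe = obj.template.copy()
        obj.seed_baselines(probe)
        for i, key in enumerate(probe.keys):
            p = obj.model.param(key.symbol)
            if p.grid == "seed":
                continue
            span = probe.upper[i] - probe.lower[i]
            axes.append(
                (i, np.clip(_grid_axis(p, 5), probe.lower[i] + 1e-8 * span,
                            probe.upper[i] - 1e-8 * span))
            )
        for combo in itertools.product(*(a for _, a in axes)):
            vals = probe.values.copy()
            for (i, _), v in zip(axes, combo):
                vals[i] = v
            assert best <= obj.chi2(vals) + 1e-12

    def test_true_params_on_noiseless_data(self):
        design = default_cpmg_design(seed=9, sigma=0.0)
        ds = simulate_dataset(design)
        obj = Objective("CR72", ds)
        pv = grid_search(obj)
        fit = minimise(obj, pv)
        assert fit.params.get(ParamKey("pA")) == pytest.approx(0.95, abs=1e-4)
        assert fit.params.get(ParamKey("kex")) == pytest.approx(2000.0, rel=1e-3)
        assert fit.params.get(ParamKey("dw", "R2:N")) == pytest.approx(2.0, rel=1e-3)

    def test_empty_grid_rejected(self, flat_dataset):
        obj = Objective("CR72", flat_dataset)
        with pytest.raises(ValueError):
            grid_search(obj, grid_points=0)


class TestMinimise:
    def test_stays_at_perfect_start(self):
        design = default_cpmg_design(seed=9, sigma=0.0)
        ds = simulate_dataset(design)
        obj = Objective("CR72", ds)
        start = obj.template.copy()
        truth = {"pA": 0.95, "kex": 2000.0}
        for i, key in enumerate(start.keys):
            if key.symbol in truth:
                start.values[i] = truth[key.symbol]
            elif key.symbol == "dw":
                start.values[i] = 2.0
            else:
                start.values[i] = 10.0
        fit = minimise(obj, start)
        assert fit.chi2 < 1e-12

    def test_final_chi2_never_exceeds_start(self, cr72_dataset):
        obj = Objective("CR72", cr72_dataset)
        start = obj.template.copy()
        obj.seed_baselines(start)
        c0 = obj.chi2(start.values)
        fit = minimise(obj, start)
        assert fit.chi2 <= c0

    def test_one_parameter_quadratic_minimum(self):
        # NoRex on flat data: chi2 is an exact parabola with the weighted
        # mean as its closed-form minimum
        vals = [9.5, 10.5, 10.2, 9.9]
        errs = [0.5, 0.5, 1.0, 0.25]
        ds = make_flat(vals, errs)
        obj = Objective("NoRex", ds)
        w = 1.0 / np.array(errs) ** 2
        expected = float(np.sum(w * np.array(vals)) / np.sum(w))
        fit = minimise(obj, np.array([12.0]))
        assert fit.params.values[0] == pytest.approx(expected, abs=1e-6)

    def test_model_never_evaluated_outside_bounds(self, cr72_dataset):
        obj = Objective("CR72", cr72_dataset)
        seen = []
        orig = obj.chi2

        def logging_chi2(values):
            seen.append(np.array(values, copy=True))
            return orig(values)

        obj.chi2 = logging_chi2
        start = grid_search(obj)
        minimise(obj, start)
        lo, hi = obj.template.lower, obj.template.upper
        for v in seen:
            assert np.all(v > lo) and np.all(v < hi)

    def test_parameter_recovery_within_mc_errors(self, cr72_dataset):
        from dispfit.selection import monte_carlo_errors

        obj = Objective("CR72", cr72_dataset)
        fit = minimise(obj, grid_search(obj))
        errors, _ = monte_carlo_errors(fit, obj, n_sims=50, seed=3)
        truth = {"pA": 0.95, "kex": 2000.0, "dw:R2:N": 2.0}
        est = fit.params.as_dict()
        for name, true_val in truth.items():
            sd = errors[name]
            assert abs(est[name] - true_val) <= 3 * sd + 1e-9, name

    def test_deterministic(self, cr72_dataset):
        results = []
        for _ in range(2):
            obj = Objective("CR72", cr72_dataset)
            fit = minimise(obj, grid_search(obj))
            results.append((fit.chi2, tuple(fit.params.values)))
        assert results[0] == results[1]


class TestWarmStarts:
    def test_nesting_table_fixed_entries(self):
        assert nesting_map("NS_CPMG_2site") == "CR72"
        assert nesting_map("MP05") == "TP02"
        assert nesting_map("NoRex") == "mean"
        assert nesting_map("LM63") == "grid"
        with pytest.raises(KeyError):
            nesting_map("B14")

    def test_equivalence_copy_is_identity(self, cr72_dataset):
        src_obj = Objective("CR72", cr72_dataset)
        fit = minimise(src_obj, grid_search(src_obj))
        tgt_obj = Objective("NS_CPMG_2site", cr72_dataset)
        start = translate_params(tgt_obj.template, fit.params)
        for key in fit.params.keys:
            assert start.get(key) == pytest.approx(fit.params.get(key), rel=1e-6)

    def test_phi_ex_to_dw_translation(self, cr72_dataset):
        # phi_ex = pA*pB*dw^2 with pA seeded at 0.95
        src = Objective("LM63", cr72_dataset).template.copy()
        src.set(ParamKey("phi_ex", "R2:N"), 0.95 * 0.05 * 4.0)
        tgt = Objective("CR72", cr72_dataset).template
        start = translate_params(tgt, src)
        assert start.get(ParamKey("dw", "R2:N")) == pytest.approx(2.0)
        assert start.get(ParamKey("pA")) == pytest.approx(0.95)

    def test_warm_started_ns_fit_matches_grid_route(self):
        design = default_cpmg_design(seed=21, n_nu=8)
        ds = simulate_dataset(design)
        results = {}
        for name in ("CR72",):
            obj = Objective(name, ds)
            results[name] = minimise(obj, grid_search(obj))
        warm_obj = Objective("NS_CPMG_2site", ds)
        start, source = warm_start(warm_obj, results)
        assert source == "CR72"
        warm_fit = minimise(warm_obj, start)
        grid_obj = Objective("NS_CPMG_2site", ds)
        grid_fit = minimise(grid_obj, grid_search(grid_obj, 7))
        assert warm_fit.chi2 <= grid_fit.chi2 + 1e-6


class TestClusterAverage:
    def test_identical_members_average_to_same(self, cr72_dataset):
        design = default_cpmg_design(seed=6, n_spins=2)
        ds = simulate_dataset(design)
        fits = {}
        for sid in ("R2:N", "R3:N"):
            obj = Objective("CR72", ds, [sid])
            fits[sid] = minimise(obj, grid_search(obj))
        cl_obj = Objective("CR72", ds, ["R2:N", "R3:N"])
        start = cluster_average_start(fits, cl_obj)
        kexes = [fits[sid].params.get(ParamKey("kex")) for sid in fits]
        assert start.get(ParamKey("kex")) == pytest.approx(np.mean(kexes))
        for sid in fits:
            assert start.get(ParamKey("dw", sid)) == pytest.approx(
                fits[sid].params.get(ParamKey("dw", sid))
            )

    def test_missing_member_rejected(self):
        design = default_cpmg_design(seed=6, n_spins=2)
        ds = simulate_dataset(design)
        obj = Objective("CR72", ds, ["R2:N", "R3:N"])
        with pytest.raises(ValueError, match="missing"):
            cluster_average_start({}, obj)

    def test_averaged_start_at_least_as_good_as_grid(self):
        design = default_cpmg_design(seed=8, n_spins=2)
        ds = simulate_dataset(design)
        fits = {}
        for sid in ("R2:N", "R3:N"):
            obj = Objective("CR72", ds, [sid])
            fits[sid] = minimise(obj, grid_search(obj))
        cl_obj = Objective("CR72", ds, ["R2:N", "R3:N"])
        avg_fit = minimise(cl_obj, cluster_average_start(fits, cl_obj))
        grid_obj = Objective("CR72", ds, ["R2:N", "R3:N"])
        grid_fit = minimise(grid_obj, grid_search(grid_obj))
        assert avg_fit.chi2 <= grid_fit.chi2 + 1e-6
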