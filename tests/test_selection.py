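"""AIC arithmetic, elimination rules, Monte Carlo error propagation."""

import numpy as np
import pytest

from dispfit.fitting import FitResult, Objective, ParamVector, ParamKey, grid_search, minimise
from dispfit.selection import (
    EliminationRules,
    ErrorEstimationFailure,
    SelectionOutcome,
    aic,
    eliminate,
    monte_carlo_errors,
    select_model,
)
from dispfit.simulate import default_cpmg_design, simulate_dataset


def make_fit(symbols, values, uppers, chi2=1.0, converged=True, model="CR72"):
    keys = [ParamKey(s) for s in symbols]
    pv = ParamVector(keys, np.zeros(len(keys)), np.array(uppers), np.array(values))
    k = len(keys)
    return FitResult(
        model=model, params=pv, chi2=chi2, k=k, n=30, aic=chi2 + 2 * k,
        converged=converged,
    )


class TestAic:
    def test_arithmetic(self):
        assert aic(10.0, 3) == 16.0
        assert aic(0.0, 0) == 0.0

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            aic(1.0, -1)

    def test_equal_chi2_prefers_fewer_parameters(self):
        a = make_fit(["kex"], [100.0], [1e6], chi2=12.0)
        b = make_fit(["kex", "pA"], [100.0, 0.9], [1e6, 1.0], chi2=12.0)
        out = select_model({"A2": a, "B4": b})
        assert out.chosen == "A2"


class TestEliminate:
    def test_kex_at_upper_bound(self):
        fit = make_fit(["kex"], [0.999e6], [1e6])
        flag, reason = eliminate(fit)
        assert flag and "kex" in reason

    def test_interior_converged_fit_survives(self):
        fit = make_fit(["kex", "pA", "dw"], [2000.0, 0.9, 3.0], [1e6, 1.0, 30.0])
        assert eliminate(fit) == (False, None)

    def test_pa_at_one_with_dw_at_bound(self):
        fit = make_fit(["pA", "dw"], [1.0 - 1e-5, 29.9], [1.0, 30.0])
        flag, reason = eliminate(fit)
        assert flag and "pA" in reason

    def test_pa_at_one_alone_survives(self):
        fit = make_fit(["pA", "dw"], [1.0 - 1e-5, 3.0], [1.0, 30.0])
        assert not eliminate(fit)[0]

    def test_non_converged_eliminated(self):
        fit = make_fit(["kex"], [2000.0], [1e6], converged=False)
        flag, reason = eliminate(fit)
        assert flag and "converge" in reason

    def test_non_finite_parameter_eliminated(self):
        fit = make_fit(["kex"], [np.nan], [1e6])
        assert eliminate(fit)[0]

    def test_tightening_rules_monotone(self):
        # a stricter threshold can only eliminate more fits
        loose = EliminationRules(kex_bound_frac=0.01)
        tight = EliminationRules(kex_bound_frac=0.10)
        for kex in np.linspace(0.85e6, 1.0e6 - 1, 20):
            fit = make_fit(["kex"], [kex], [1e6])
            if eliminate(fit, loose)[0]:
                assert eliminate(fit, tight)[0]


class TestMonteCarlo:
    def test_zero_noise_gives_zero_errors(self):
        # measurement sigma of exactly zero: every simulation reproduces the
        # data, every refit stays put, every parameter spread is exactly 0
        from dispfit.data import RateValue

        design = default_cpmg_design(seed=13, sigma=0.0)
        ds = simulate_dataset(design)
        zero = ds.with_values(
            {k: RateValue(rv.value, 1e-13) for k, rv in ds.values.items()}
        )
        obj = Objective("CR72", zero)
        start = obj.template.copy()
        for i, key in enumerate(start.keys):
            start.values[i] = {"pA": 0.95, "kex": 2000.0, "dw": 2.0}.get(
                key.symbol, 10.0
            )
        fit = minimise(obj, start)
        errors, removed = monte_carlo_errors(fit, obj, n_sims=5, seed=1)
        assert removed == 0
        assert all(v == 0.0 for v in errors.values())

    def test_same_seed_reproduces_errors(self, cr72_dataset):
        obj = Objective("NoRex", cr72_dataset)
        fit = minimise(obj, grid_search(obj))
        e1, _ = monte_carlo_errors(fit, obj, n_sims=10, seed=9)
        e2, _ = monte_carlo_errors(fit, obj, n_sims=10, seed=9)
        assert e1 == e2

    def test_errors_scale_linearly_with_noise(self):
        # doubling every sigma doubles the parameter spread (linear model)
        sds = []
        for sigma in (0.25, 0.5):
            d = default_cpmg_design(seed=17, model="NoRex", fields=(600.0,), sigma=sigma)
            d.true_params = {"R2:N": {"r20": {600.0: 10.0}}}
            ds = simulate_dataset(d)
            obj = Objective("NoRex", ds)
            fit = minimise(obj, grid_search(obj))
            errors, _ = monte_carlo_errors(fit, obj, n_sims=200, seed=23)
            sds.append(list(errors.values())[0])
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.15)

    def test_too_few_sims_rejected(self, cr72_dataset):
        obj = Objective("NoRex", cr72_dataset)
        fit = minimise(obj, grid_search(obj))
        with pytest.raises(ValueError):
            monte_carlo_errors(fit, obj, n_sims=1, seed=1)


class TestSelectModel:
    def test_exchange_model_wins_with_large_chi2_drop(self):
        norex = make_fit(["r20"], [10.0], [200.0], chi2=50.0, model="NoRex")
        cr72 = make_fit(["pA", "kex", "dw", "r20"], [0.9, 2e3, 2.0, 10.0],
                        [1.0, 1e6, 30.0, 200.0], chi2=10.0)
        out = select_model({"NoRex": norex, "CR72": cr72})
        assert out.chosen == "CR72"
        assert out.ranked[0] == ("CR72", 18.0)

    def test_norex_wins_marginal_improvement(self):
        norex = make_fit(["r20"], [10.0], [200.0], chi2=12.0, model="NoRex")
        cr72 = make_fit(["pA", "kex", "dw", "r20"], [0.9, 2e3, 2.0, 10.0],
                        [1.0, 1e6, 30.0, 200.0], chi2=11.9)
        out = select_model({"NoRex": norex, "CR72": cr72})
        assert out.chosen == "NoRex"

    def test_eliminated_model_excluded(self):
        norex = make_fit(["r20"], [10.0], [200.0], chi2=50.0, model="NoRex")
        cr72 = make_fit(["kex"], [0.995e6], [1e6], chi2=5.0)
        cr72.eliminated, cr72.elimination_reason = eliminate(cr72)
        out = select_model({"NoRex": norex, "CR72": cr72})
        assert out.chosen == "NoRex"
        assert out.elimination_log

    def test_norex_survives_own_elimination_flag(self):
        norex = make_fit(["r20"], [10.0], [200.0], chi2=50.0, model="NoRex", converged=False)
        norex.eliminated = True
        out = select_model({"NoRex": norex})
        assert out.chosen == "NoRex"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_model({})
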