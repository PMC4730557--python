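"""Path models, the OLS product/difference identity, and BC bootstrap inference."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from rsfa.exceptions import DegenerateSeriesError, InsufficientDataError
from rsfa.mediation import (
    MediationInput,
    MediationResult,
    PathEstimate,
    _bc_interval,
    bc_bootstrap_ci,
    classify_effect,
    fit_paths,
    mediate,
    proportion_mediated,
)
from rsfa.simulate import simulate_mediation_dataset


def make_input(n=200, a=-0.5, b=0.3, cp=-0.15, seed=0, covs=True):
    df = simulate_mediation_dataset(n, a, b, cp, seed=seed, with_covariates=covs)
    names = ["gender", "handedness"] if covs else []
    return MediationInput.from_table(df, "iv", "m", "dv", names)


class TestFitPaths:
    def test_product_difference_identity_on_random_datasets(self):
        """a*b = c - c' to 1e-10 whenever all three fits share covariates."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            inp = make_input(
                n=int(rng.integers(30, 200)),
                a=rng.uniform(-0.7, 0.7),
                b=rng.uniform(-0.6, 0.6),
                cp=rng.uniform(-0.4, 0.4),
                seed=int(rng.integers(1 << 30)),
            )
            p = fit_paths(inp)
            assert abs(p["ab"] - (p["c"] - p["c_prime"])) < 1e-10

    def test_independent_variables_give_null_paths(self, rng):
        df = pd.DataFrame(
            {
                "iv": rng.standard_normal(2000),
                "m": rng.standard_normal(2000),
                "dv": rng.standard_normal(2000),
            }
        )
        p = fit_paths(MediationInput.from_table(df, "iv", "m", "dv"))
        for name in ("a", "b", "c", "c_prime", "ab"):
            assert abs(p[name]) < 0.08

    def test_pure_chain_recovers_planted_paths(self):
        inp = make_input(n=1000, a=-0.5, b=0.3, cp=0.0, seed=3)
        p = fit_paths(inp)
        se = 1 / np.sqrt(1000)
        assert abs(p["c_prime"]) < 3 * se
        assert abs(p["ab"] - (-0.15)) < 3 * se

    def test_matches_independent_mediation_implementation(self):
        """Point estimates agree with pingouin's mediation analysis."""
        df = simulate_mediation_dataset(300, -0.5, 0.3, -0.15, seed=42,
                                        with_covariates=False)
        z = (df - df.mean()) / df.std()
        ours = fit_paths(MediationInput.from_table(df, "iv", "m", "dv"))
        ref = pg.mediation_analysis(data=z, x="iv", m="m", y="dv", n_boot=50, seed=0)
        ref = ref.set_index("path")["coef"]
        assert ours["a"] == pytest.approx(ref["m ~ X"], abs=1e-8)
        assert ours["c"] == pytest.approx(ref["Total"], abs=1e-8)
        assert ours["c_prime"] == pytest.approx(ref["Direct"], abs=1e-8)
        assert ours["ab"] == pytest.approx(ref["Indirect"], abs=1e-8)

    def test_standardization_invariance(self):
        """Affine rescaling of iv, m, dv leaves standardized paths unchanged."""
        df = simulate_mediation_dataset(150, -0.4, 0.5, -0.1, seed=9)
        p1 = fit_paths(MediationInput.from_table(df, "iv", "m", "dv",
                                                 ["gender", "handedness"]))
        df2 = df.copy()
        df2["iv"] = 3.5 * df2["iv"] - 12
        df2["m"] = -2.0 * df2["m"] + 4  # sign flip allowed: flips a and b
        df2["dv"] = 0.1 * df2["dv"] + 100
        p2 = fit_paths(MediationInput.from_table(df2, "iv", "m", "dv",
                                                 ["gender", "handedness"]))
        assert abs(abs(p1["a"]) - abs(p2["a"])) < 1e-10
        assert abs(abs(p1["b"]) - abs(p2["b"])) < 1e-10
        assert abs(p1["c"] - p2["c"]) < 1e-10
        assert abs(p1["ab"] - p2["ab"]) < 1e-10

    def test_collinear_mediator_rejected(self, rng):
        iv = rng.standard_normal(100)
        df = pd.DataFrame({"iv": iv, "m": iv * 2 + 1e-9, "dv": rng.standard_normal(100)})
        with pytest.raises(DegenerateSeriesError):
            fit_paths(MediationInput.from_table(df, "iv", "m", "dv"))


class TestBcBootstrap:
    def test_fixed_seed_reproducible(self):
        inp = make_input(n=120, seed=5)
        r1 = bc_bootstrap_ci(inp, B=500, seed=11)
        r2 = bc_bootstrap_ci(inp, B=500, seed=11)
        for name in r1.paths:
            assert r1.paths[name].ci_lo == r2.paths[name].ci_lo
            assert r1.paths[name].ci_hi == r2.paths[name].ci_hi

    def test_point_estimate_is_analytic_fit(self):
        inp = make_input(n=150, seed=2)
        r = bc_bootstrap_ci(inp, B=400, seed=0)
        p = fit_paths(inp)
        for name, est in r.paths.items():
            assert est.beta == pytest.approx(p[name], abs=1e-12)

    def test_bc_reduces_to_percentile_when_unbiased(self, rng):
        """With z0 = 0 (median-unbiased bootstrap) the BC endpoints are the
        plain percentile quantiles."""
        boot = np.sort(rng.standard_normal(4001))
        point = float(np.median(boot))
        lo, hi = _bc_interval(boot, point, alpha=0.05)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=2e-3)
        assert hi == pytest.approx(phi, abs=2e-3)

    def test_strong_effect_detected(self):
        inp = make_input(n=335, a=-0.5, b=0.3, cp=-0.15, seed=8)
        r = bc_bootstrap_ci(inp, B=1000, alpha=0.01, seed=1)
        assert r.paths["ab"].excludes_zero()
        assert r.classification == "mediation"
        assert r.paths["ab"].p <= 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            bc_bootstrap_ci(make_input(n=15), B=100)


class TestEffectSizeAndClassification:
    def test_printed_worked_examples(self):
        """The two effect sizes recomputable from printed path estimates."""
        assert round(proportion_mediated(-0.146, -0.305)) == 48
        assert round(proportion_mediated(0.022, -0.308)) == 7

    def test_zero_indirect_effect(self):
        assert proportion_mediated(0.0, -0.3) == 0.0

    def test_undefined_when_total_effect_zero(self):
        with pytest.raises(Exception):
            proportion_mediated(0.1, 0.0)

    @staticmethod
    def result_with(ab_ci, c, c_prime, ab):
        paths = {
            "a": PathEstimate(beta=-0.49),
            "b": PathEstimate(beta=0.30),
            "c": PathEstimate(beta=c),
            "c_prime": PathEstimate(beta=c_prime),
            "ab": PathEstimate(beta=ab, ci_lo=ab_ci[0], ci_hi=ab_ci[1]),
        }
        return MediationResult(paths=paths, n=335)

    def test_shrunken_direct_effect_is_mediation(self):
        r = self.result_with((-0.219, -0.080), c=-0.305, c_prime=-0.158, ab=-0.146)
        assert classify_effect(r) == "mediation"

    def test_grown_direct_effect_is_suppression(self):
        r = self.result_with((0.002, 0.061), c=-0.308, c_prime=-0.330, ab=0.022)
        assert classify_effect(r) == "suppression"

    def test_ci_straddling_zero_is_none(self):
        r = self.result_with((-0.05, 0.03), c=-0.3, c_prime=-0.2, ab=-0.01)
        assert classify_effect(r) == "none"


def test_mediate_wrapper_round_trip():
    df = simulate_mediation_dataset(100, -0.5, 0.4, -0.1, seed=1)
    r = mediate(df, "iv", "m", "dv", ["gender", "handedness"], B=300, seed=4)
    assert set(r.paths) == {"a", "b", "c", "c_prime", "ab"}
    assert r.n == 100 and r.B == 300
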