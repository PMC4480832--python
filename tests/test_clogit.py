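"""Exact conditional likelihood, design expansion and Newton fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hhscan.clogit import (
    ModelSpec,
    build_design,
    compare_group_effects,
    conditional_loglik,
    fit,
    null_loglik,
    parse_formula,
    wald_contrast,
)
from conftest import make_strata_data


def brute_force_loglik(beta, X, strata, y):
    """Exhaustive subset enumeration of the conditional likelihood."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.asarray(beta, float)
    ll = 0.0
    for s in pd.unique(strata):
        m = np.asarray(strata) == s
        eta = X[m] @ beta
        k = int(np.sum(y[m]))
        num = eta[np.asarray(y)[m]].sum()
        den = [eta[list(c)].sum() for c in itertools.combinations(range(m.sum()), k)]
        ll += num - np.logaddexp.reduce(den)
    return ll


class TestFormula:
    def test_parse(self):
        spec = parse_formula("eqtl ~ hh:go + ddaf + maf×go + location")
        assert spec.response == "eqtl"
        assert spec.terms == (("hh", "go"), "ddaf", ("maf", "go"), "location")

    def test_parse_errors(self):
        with pytest.raises(ValueError):
            parse_formula("no tilde here")


class TestDesign:
    def _df(self, rng, n_go=3):
        gos = [f"GO:{i}" for i in range(n_go)]
        strata = np.repeat([f"g{i}" for i in range(12)], 5)
        return pd.DataFrame(
            {
                "stratum": strata,
                "eqtl": np.tile([True] + [False] * 4, 12),
                "maf": rng.normal(size=60),
                "hh": rng.normal(size=60),
                "go": np.repeat(rng.choice(gos, size=12), 5),
                "location": rng.choice(["intronic", "exonic", "UTR"], size=60),
            }
        )

    def test_interaction_expands_per_level(self, rng):
        df = self._df(rng)
        d = build_design(df, parse_formula("eqtl ~ maf:go + location"))
        slopes = [n for n in d.names if n.startswith("maf:go=")]
        assert len(slopes) == 3  # one MAF slope per GO level
        # location dummies use intronic as reference
        assert "location=intronic" not in d.names
        assert {"location=exonic", "location=UTR"} <= set(d.names)

    def test_constant_within_strata_column_dropped(self, rng):
        df = self._df(rng)
        df["fst"] = df["stratum"].map({s: i for i, s in
                                       enumerate(df["stratum"].unique())}).astype(float)
        d = build_design(df, parse_formula("eqtl ~ hh + fst"))
        assert "fst" in d.dropped and "fst" not in d.names

    def test_absent_column_is_error(self, rng):
        with pytest.raises(KeyError, match="nope"):
            build_design(self._df(rng), parse_formula("eqtl ~ nope"))


class TestLikelihood:
    def test_null_closed_form(self, rng):
        df = make_strata_data(rng, n_strata=20, size=7, beta=(0.3, -0.2), n_cases=2)
        X = df[["x0", "x1"]].to_numpy()
        ll = conditional_loglik(np.zeros(2), X, df["stratum"], df["eqtl"])
        assert ll == pytest.approx(-20 * math.log(math.comb(7, 2)), abs=1e-10)

    def test_single_stratum_example(self):
        # 1 case of 3, x = (1,0,0), beta = 1: ll = ln(e / (e + 2))
        ll = conditional_loglik(
            [1.0], [[1.0], [0.0], [0.0]], ["s"] * 3, [True, False, False]
        )
        assert ll == pytest.approx(math.log(math.e / (math.e + 2)), abs=1e-12)

    @pytest.mark.parametrize("n,k", [(4, 1), (6, 2), (9, 3), (10, 3)])
    def test_matches_enumeration(self, rng, n, k):
        X = rng.normal(size=(n, 2))
        y = np.zeros(n, bool)
        y[rng.choice(n, size=k, replace=False)] = True
        strata = np.zeros(n, int)
        for beta in ([0.0, 0.0], [0.7, -1.2], [3.0, 2.0], [-2.5, 0.1]):
            a = conditional_loglik(beta, X, strata, y)
            b = brute_force_loglik(beta, X, strata, y)
            assert a == pytest.approx(b, abs=1e-10)

    def test_uninformative_stratum_rejected(self):
        with pytest.raises(ValueError):
            conditional_loglik([0.0], [[1.0], [2.0]], ["s", "s"], [True, True])

    def test_within_stratum_shift_invariance(self, rng):
        """Conditional likelihood depends only on within-stratum contrasts."""
        df = make_strata_data(rng, n_strata=30, size=5, beta=(0.5,))
        spec = ModelSpec("eqtl", ("x0",))
        r1 = fit(df, spec)
        shifted = df.copy()
        offsets = {s: rng.normal() * 10 for s in df["stratum"].unique()}
        shifted["x0"] = shifted["x0"] + shifted["stratum"].map(offsets)
        r2 = fit(shifted, spec)
        assert r1.params["x0"] == pytest.approx(r2.params["x0"], abs=1e-6)
        assert r1.llf == pytest.approx(r2.llf, abs=1e-8)


class TestFit:
    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = make_strata_data(rng, n_strata=80, size=6, beta=(0.5, -0.3), n_cases=2)
        res = fit(df, ModelSpec("eqtl", ("x0", "x1")))
        d = build_design(df, ModelSpec("eqtl", ("x0", "x1")))
        sm_res = ConditionalLogit(
            d.y.astype(float), d.X, groups=d.strata
        ).fit(disp=0, method="bfgs", gtol=1e-10)
        np.testing.assert_allclose(res.params, sm_res.params, atol=1e-5)
        np.testing.assert_allclose(res.bse, sm_res.bse, atol=1e-5)
        np.testing.assert_allclose(res.llf, sm_res.llf, atol=1e-8)

    def test_matched_pairs_reduce_to_logistic_on_differences(self, rng):
        import statsmodels.api as sm

        df = make_strata_data(rng, n_strata=200, size=2, beta=(0.8,))
        res = fit(df, ModelSpec("eqtl", ("x0",)))
        # pair differences, randomly oriented so plain logistic has an MLE
        diffs, ys = [], []
        for s, grp in df.groupby("stratum"):
            d = grp.loc[grp["eqtl"], "x0"].iloc[0] - grp.loc[~grp["eqtl"], "x0"].iloc[0]
            flip = rng.random() < 0.5
            diffs.append(-d if flip else d)
            ys.append(0.0 if flip else 1.0)
        logit = sm.Logit(np.array(ys), np.array(diffs)[:, None]).fit(disp=0)
        assert res.params["x0"] == pytest.approx(logit.params[0], abs=1e-6)
        assert res.bse["x0"] == pytest.approx(logit.bse[0], abs=1e-6)

    def test_separation_is_flagged(self):
        # the predictor perfectly identifies the case in every stratum
        rows = []
        for s in range(20):
            for i in range(4):
                rows.append({"stratum": s, "eqtl": i == 0, "x0": 1.0 if i == 0 else 0.0})
        res = fit(pd.DataFrame(rows), ModelSpec("eqtl", ("x0",)))
        assert not res.converged
        assert "separation" in res.message

    def test_all_terms_dropped_is_error(self, rng):
        df = make_strata_data(rng, n_strata=10, size=4, beta=(0.5,))
        df["c"] = 1.0
        with pytest.raises(ValueError):
            fit(df, ModelSpec("eqtl", ("c",)))


class TestGroupContrast:
    def test_published_shape_inputs(self):
        z, p = wald_contrast(0.005, 0.001, -0.003, 0.003)
        assert z == pytest.approx(2.5298, abs=1e-3)
        assert p == pytest.approx(0.0114, abs=1e-3)

    def test_equal_betas_give_p_one(self):
        _, p = wald_contrast(0.4, 0.1, 0.4, 0.2)
        assert p == pytest.approx(1.0)

    def test_zero_errors_rejected(self):
        with pytest.raises(ValueError):
            wald_contrast(0.1, 0.0, 0.2, 0.0)

    def test_from_fit_result(self, rng):
        df = make_strata_data(rng, n_strata=120, size=6, beta=(0.5,))
        df["group"] = np.repeat(
            rng.choice(["group1", "group2"], size=120), 6
        )
        res = fit(df, ModelSpec("eqtl", (("x0", "group"),)))
        z, p = compare_group_effects(res, "x0:group=group1", "x0:group=group2")
        assert np.isfinite(z) and 0 <= p <= 1
        with pytest.raises(KeyError):
            compare_group_effects(res, "x0:group=group1", "x0:group=group3")
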