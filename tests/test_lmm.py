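"""REML engine: closed forms, oracles, invariances, ratios and LRTs."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from flockherit.lmm import (
    RESIDUAL,
    FitResult,
    ModelSpec,
    RandomTerm,
    REMLOptions,
    lrt,
    reml_fit,
    variance_ratios,
)
from flockherit.pedigree import Pedigree, additive_relationship


def one_way(rng, q, m, v_id=2.0, v_r=1.0, mu=3.0):
    ind = np.repeat([f"i{k}" for k in range(q)], m)
    u = rng.normal(0, np.sqrt(v_id), q)
    y = mu + np.repeat(u, m) + rng.normal(0, np.sqrt(v_r), q * m)
    return pd.DataFrame({"individual": ind, "y": y})


def anova_estimates(df, q, m):
    """Textbook balanced one-way ANOVA estimators (the closed-form oracle)."""
    y = df["y"].to_numpy()
    ybar = df.groupby("individual")["y"].mean()
    msb = m * ((ybar - y.mean()) ** 2).sum() / (q - 1)
    msw = (
        (y - ybar[df["individual"]].to_numpy()) ** 2
    ).sum() / (q * (m - 1))
    return (msb - msw) / m, msw


ID_TERM = [RandomTerm("ID", "individual")]


class TestClosedForm:
    @pytest.mark.parametrize("q,m", [(20, 2), (20, 10), (100, 5)])
    def test_matches_anova(self, rng, q, m):
        df = one_way(rng, q, m)
        fit = reml_fit(df, ModelSpec("y", [], ID_TERM))
        sid, sr = anova_estimates(df, q, m)
        assert fit.converged
        assert fit.components["ID"] == pytest.approx(sid, rel=1e-6)
        assert fit.components[RESIDUAL] == pytest.approx(sr, rel=1e-6)

    def test_zero_individual_effect_pinned(self, rng):
        df = one_way(rng, 40, 5, v_id=0.0)
        fit = reml_fit(df, ModelSpec("y", [], ID_TERM))
        null = reml_fit(df, ModelSpec("y", [], []))
        stat, p = lrt(fit, null)
        assert fit.components["ID"] < 0.05
        assert p > 0.05

    def test_no_random_terms_is_ols_reml(self, rng):
        n = 50
        x = rng.uniform(0, 1, n)
        df = pd.DataFrame({"y": 1 + 2 * x + rng.normal(0, 1, n), "x": x})
        fit = reml_fit(df, ModelSpec("y", ["x"], []))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        rss = ((df["y"] - X @ beta) ** 2).sum()
        assert fit.components[RESIDUAL] == pytest.approx(rss / (n - 2), rel=1e-10)


class TestInvariances:
    def test_observation_order_and_level_labels(self, rng):
        df = one_way(rng, 25, 4)
        fit1 = reml_fit(df, ModelSpec("y", [], ID_TERM))
        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        shuffled["individual"] = "zz_" + shuffled["individual"]
        fit2 = reml_fit(shuffled, ModelSpec("y", [], ID_TERM))
        for k in fit1.components:
            assert fit2.components[k] == pytest.approx(fit1.components[k], rel=1e-8)
        assert fit2.loglik_reml == pytest.approx(fit1.loglik_reml, abs=1e-8)

    def test_identity_covariance_equals_iid_term(self, rng):
        df = one_way(rng, 20, 4)
        ids = sorted(df["individual"].unique())

        class EyeCov:
            def __init__(self, ids):
                self.ids = ids
                self.values = np.eye(len(ids))

        fit_iid = reml_fit(df, ModelSpec("y", [], ID_TERM))
        fit_eye = reml_fit(
            df, ModelSpec("y", [], [RandomTerm("ID", "individual", EyeCov(ids))])
        )
        for k in fit_iid.components:
            assert fit_eye.components[k] == pytest.approx(fit_iid.components[k], rel=1e-6)

    def test_loglik_not_below_start(self, rng):
        # accepted iterations never decrease the restricted likelihood
        from flockherit.lmm import _TermDesign, _Workspace, _build_fixed, _safe_loglik

        df = one_way(rng, 15, 3)
        fit = reml_fit(df, ModelSpec("y", [], ID_TERM))
        X, _ = _build_fixed(df, [])
        ws = _Workspace(df["y"].to_numpy(), X, [_TermDesign(ID_TERM[0], df)])
        vscale = np.var(df["y"].to_numpy())
        ll_start = _safe_loglik(ws, [0], np.array([vscale / 2]), vscale / 2)
        assert fit.loglik_reml >= ll_start - 1e-10


class TestAnimalModel:
    def test_aliasing_founder_pedigree(self, rng):
        # with A = I the genetic term is confounded with identity: the fit
        # matches Model 1 in likelihood and in the ID+A total
        df = one_way(rng, 30, 5)
        ped = Pedigree.from_records([(i, None, None) for i in sorted(df["individual"].unique())])
        A = additive_relationship(ped)
        fit1 = reml_fit(df, ModelSpec("y", [], ID_TERM))
        fit2 = reml_fit(
            df, ModelSpec("y", [], ID_TERM + [RandomTerm("A", "individual", A)])
        )
        assert fit2.loglik_reml == pytest.approx(fit1.loglik_reml, abs=1e-5)
        assert fit2.components["ID"] + fit2.components["A"] == pytest.approx(
            fit1.components["ID"], rel=1e-3, abs=1e-6
        )

    def test_lme4_oracle_identity_structure(self, rng, tmp_path):
        # independent cross-check of the REML optimum against R's lme4
        df = one_way(rng, 30, 6)
        fit = reml_fit(df, ModelSpec("y", [], ID_TERM))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ 1 + (1 | individual), data = d, REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(vc$vcov[1], vc$vcov[2], sep = "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        v_id, v_r = map(float, out.stdout.strip().split())
        assert fit.components["ID"] == pytest.approx(v_id, rel=1e-4)
        assert fit.components[RESIDUAL] == pytest.approx(v_r, rel=1e-4)

    def test_singular_covariance_term_named(self, rng):
        df = one_way(rng, 10, 3)
        ids = sorted(df["individual"].unique())

        class BadCov:
            def __init__(self, ids):
                self.ids = ids
                v = np.ones((len(ids), len(ids)))
                v[0, 1] = v[1, 0] = -5.0  # indefinite
                self.values = v

        with pytest.raises(ValueError, match="A"):
            reml_fit(
                df, ModelSpec("y", [], [RandomTerm("A", "individual", BadCov(ids))])
            )

    def test_missing_cov_levels_rejected(self, rng):
        df = one_way(rng, 10, 3)

        class TinyCov:
            ids = ["i0", "i1"]
            values = np.eye(2)

        with pytest.raises(ValueError, match="levels missing"):
            reml_fit(df, ModelSpec("y", [], [RandomTerm("A", "individual", TinyCov())]))


def _fake_fit(components, cov=None):
    names = list(components)
    return FitResult(
        components=dict(components),
        se={k: 0.1 for k in names},
        loglik_reml=-10.0,
        converged=True,
        n_iter=3,
        boundary=set(),
        n_obs=100,
        n_fixed=1,
        response="y",
        fixed=(),
        random_names=tuple(k for k in names if k != RESIDUAL),
        component_cov=cov,
    )


class TestRatios:
    def test_all_terms_ratio_is_one(self):
        fit = _fake_fit({"ID": 1.0, RESIDUAL: 4.0})
        r = variance_ratios(fit, ("ID", RESIDUAL))
        assert r.value == 1.0

    def test_simple_proportion(self):
        fit = _fake_fit({"ID": 1.0, RESIDUAL: 4.0})
        assert variance_ratios(fit, ("ID",)).value == pytest.approx(0.2)

    def test_empty_numerator_rejected(self):
        with pytest.raises(ValueError):
            variance_ratios(_fake_fit({"ID": 1.0, RESIDUAL: 1.0}), ())

    def test_delta_method_matches_monte_carlo(self, rng):
        # oracle: simulate estimates from the component covariance and
        # compare the SD of the simulated ratio with the delta-method SE
        cov = pd.DataFrame(
            [[0.04, 0.01], [0.01, 0.09]], index=["ID", RESIDUAL], columns=["ID", RESIDUAL]
        )
        fit = _fake_fit({"ID": 2.0, RESIDUAL: 3.0}, cov=cov)
        r = variance_ratios(fit, ("ID",))
        draws = rng.multivariate_normal([2.0, 3.0], cov.to_numpy(), size=200_000)
        ratios = draws[:, 0] / draws.sum(axis=1)
        assert r.se == pytest.approx(ratios.std(), rel=0.05)


class TestLRT:
    def test_identical_models(self):
        f = _fake_fit({"ID": 1.0, RESIDUAL: 1.0})
        stat, p = lrt(f, f)
        assert stat == 0.0
        assert p == 1.0

    def test_quantile_consistency(self):
        full = _fake_fit({"ID": 1.0, "A": 1.0, RESIDUAL: 1.0})
        reduced = _fake_fit({"ID": 1.0, RESIDUAL: 1.0})
        full.loglik_reml = -10.0
        reduced.loglik_reml = -10.0 - 3.841458820694124 / 2
        stat, p = lrt(full, reduced)
        assert stat == pytest.approx(3.8415, abs=1e-3)
        assert p == pytest.approx(0.050, abs=1e-3)
        _, p_mix = lrt(full, reduced, mixture=True)
        assert p_mix == pytest.approx(0.025, abs=1e-3)

    def test_non_nested_rejected(self):
        a = _fake_fit({"ID": 1.0, RESIDUAL: 1.0})
        b = _fake_fit({"LOG": 1.0, RESIDUAL: 1.0})
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_different_data_rejected(self):
        a = _fake_fit({"ID": 1.0, "A": 1.0, RESIDUAL: 1.0})
        b = _fake_fit({"ID": 1.0, RESIDUAL: 1.0})
        b.n_obs = 99
        with pytest.raises(ValueError, match="share data"):
            lrt(a, b)


class TestModelConfig:
    def test_yaml_roundtrip_with_covariance_file(self, rng, tmp_path):
        ped = Pedigree.from_records(
            [("i0", None, None), ("i1", None, None), ("i2", "i0", "i1")]
        )
        A = additive_relationship(ped)
        A.to_frame().to_csv(tmp_path / "amatrix.csv")
        (tmp_path / "model.yaml").write_text(
            "response: y\nfixed: [winter]\nrandom:\n"
            "  - {name: ID, column: individual}\n"
            "  - {name: A, column: individual, covariance: amatrix.csv}\n"
        )
        from flockherit.lmm import model_spec_from_config

        spec = model_spec_from_config(tmp_path / "model.yaml")
        assert spec.response == "y"
        assert spec.fixed == ["winter"]
        assert [t.name for t in spec.random] == ["ID", "A"]
        assert spec.random[1].covariance.values[2, 0] == pytest.approx(0.5)


class TestFixedEffects:
    def test_categorical_year_absorbs_shift(self, rng):
        df = one_way(rng, 30, 6)
        df["winter"] = np.tile(["W0", "W1", "W2"], len(df) // 3)
        df["y"] += df["winter"].map({"W0": 0.0, "W1": 5.0, "W2": -4.0})
        fit = reml_fit(df, ModelSpec("y", ["winter"], ID_TERM))
        base = reml_fit(df.assign(y=df["y"] - df["winter"].map({"W0": 0.0, "W1": 5.0, "W2": -4.0})),
                        ModelSpec("y", [], ID_TERM))
        # year shifts go into the fixed part, not the variance components
        assert fit.components[RESIDUAL] == pytest.approx(
            base.components[RESIDUAL], rel=0.05
        )

    def test_aliased_fixed_column_dropped_with_warning(self, rng):
        df = one_way(rng, 10, 2)
        df["dup"] = 1.0  # aliased with the intercept
        with pytest.warns(UserWarning, match="aliased"):
            fit = reml_fit(df, ModelSpec("y", ["dup"], ID_TERM))
        assert fit.converged
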