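import numpy as np
import pandas as pd
import patsy
import pytest

from ictalsync.stats import (
    DunnettResult,
    ModelDegenerateError,
    ModelFitError,
    ModelSpec,
    TransformError,
    call_terminal_hypersync,
    dunnett_vs_termination,
    fit_lmm,
    type2_wald,
)

# 12-row balanced worked dataset: 3 seizures x 2 phases x 2 locations,
# a random per-seizure offset plus a +0.5 termination effect.
WORKED_VALUES = [
    0.2856, 0.2586, 0.4116, 0.4541,
    -0.097, -0.2222, 0.4384, -0.0804,
    0.6073, 0.7627, 1.0993, 1.0508,
]


def worked_table() -> pd.DataFrame:
    rows = []
    k = 0
    for s in range(3):
        for phase in ("onset", "termination"):
            for loc in ("anterior", "posterior"):
                rows.append(("p1", s, phase, "region", loc, WORKED_VALUES[k]))
                k += 1
    return pd.DataFrame(
        rows, columns=["patient_id", "seizure_index", "phase", "level", "location", "value"]
    )


@pytest.fixture(scope="module")
def worked_fit():
    return fit_lmm(worked_table(), ModelSpec(response_transform="identity"), level="region")


def test_wald_matches_brute_force_gls(worked_fit):
    """Block Wald chi-squares equal an explicit GLS computation at the
    REML variance estimates."""
    fit = worked_fit
    df = worked_table()
    sigma2 = float(fit.result.scale)
    tau2 = float(np.asarray(fit.result.cov_re)[0, 0])

    X = np.asarray(patsy.dmatrix("C(phase, Sum)*C(location, Sum)", df))
    Z = pd.get_dummies(df["seizure_index"]).to_numpy(float)
    V = sigma2 * np.eye(len(df)) + tau2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    y = df["value"].to_numpy()
    covb = np.linalg.inv(X.T @ Vi @ X)
    beta = covb @ X.T @ Vi @ y

    assert np.abs(beta - np.asarray(fit.fe_params)).max() < 1e-8
    assert np.abs(covb - fit.fe_cov().to_numpy()).max() < 1e-8

    wald = type2_wald(fit).set_index("term")
    # blocks: intercept | phase (1) | location (1) | interaction (1)
    for term, sl in [
        ("C(phase, Sum)", slice(1, 2)),
        ("C(location, Sum)", slice(2, 3)),
        ("C(phase, Sum):C(location, Sum)", slice(3, 4)),
    ]:
        b = beta[sl]
        chi2 = float(b @ np.linalg.solve(covb[sl, sl], b))
        assert wald.loc[term, "chisq"] == pytest.approx(chi2, abs=1e-8)


def test_wald_invariant_to_location_relabeling(effect_table):
    fit = fit_lmm(effect_table, ModelSpec(response_transform="identity"), level="region")
    relabeled = effect_table.copy()
    mapping = {"anterior": "zzz_ant", "posterior": "aaa_post"}
    relabeled["location"] = relabeled["location"].replace(mapping)
    fit2 = fit_lmm(relabeled, ModelSpec(response_transform="identity"), level="region")
    w1 = type2_wald(fit).sort_values("df")["chisq"].to_numpy()
    w2 = type2_wald(fit2).sort_values("df")["chisq"].to_numpy()
    assert np.allclose(w1, w2, atol=1e-6)


@pytest.fixture(scope="module")
def dunnett(effect_table):
    fit = fit_lmm(effect_table, ModelSpec(), level="electrode")
    return dunnett_vs_termination(fit, seed=5)


class TestDunnett:

    def test_three_contrasts_per_location(self, dunnett):
        counts = dunnett.table.groupby("location").size()
        assert (counts == 3).all() and len(counts) == 8

    def test_adjusted_p_at_least_unadjusted(self, dunnett):
        assert (dunnett.table["p_adj"] >= dunnett.table["p_unadj"] - 1e-12).all()

    def test_adjustment_no_worse_than_bonferroni(self, dunnett):
        bonf = np.minimum(1.0, 3 * dunnett.table["p_unadj"])
        assert (dunnett.table["p_adj"] <= bonf + 1e-4).all()

    def test_seeded_reproducibility(self, effect_table):
        fit = fit_lmm(effect_table, ModelSpec(), level="region")
        a = dunnett_vs_termination(fit, seed=9).table
        b = dunnett_vs_termination(fit, seed=9).table
        pd.testing.assert_frame_equal(a, b)


class TestCalls:
    def _result(self, rows):
        return DunnettResult(
            table=pd.DataFrame(
                rows, columns=["location", "phase", "estimate", "se", "tstat", "p_unadj", "p_adj"]
            )
        )

    def test_all_nonsignificant_negative(self):
        rows = [("C3", p, 1.0, 1.0, 1.0, 1.0, 1.0) for p in ("pre_ictal", "onset", "post_ictal")]
        assert call_terminal_hypersync(self._result(rows)) == {"C3": False}

    def test_three_significant_positive_contrasts(self):
        padj = [0.01, 0.02, 0.001]
        rows = [
            ("C3", p, 0.5, 0.1, 5.0, 0.001, pa)
            for p, pa in zip(("pre_ictal", "onset", "post_ictal"), padj)
        ]
        assert call_terminal_hypersync(self._result(rows)) == {"C3": True}

    def test_significant_but_negative_contrast_blocks_call(self):
        rows = [
            ("C3", "pre_ictal", -0.5, 0.1, -5.0, 0.001, 0.002),
            ("C3", "onset", 0.5, 0.1, 5.0, 0.001, 0.002),
            ("C3", "post_ictal", 0.5, 0.1, 5.0, 0.001, 0.002),
        ]
        assert call_terminal_hypersync(self._result(rows)) == {"C3": False}

    def test_any_rule_is_more_permissive(self):
        rows = [
            ("C3", "pre_ictal", 0.5, 0.1, 5.0, 0.001, 0.002),
            ("C3", "onset", 0.1, 0.1, 1.0, 0.3, 0.6),
            ("C3", "post_ictal", 0.5, 0.1, 5.0, 0.001, 0.002),
        ]
        res = self._result(rows)
        assert call_terminal_hypersync(res, rule="all") == {"C3": False}
        assert call_terminal_hypersync(res, rule="any") == {"C3": True}


class TestTransforms:
    def test_log_rejects_values_at_or_below_minus_one(self):
        df = worked_table()
        df.loc[0, "value"] = -1.0
        with pytest.raises(TransformError):
            fit_lmm(df, ModelSpec(response_transform="log"), level="region")

    def test_calls_stable_under_log1p_for_small_values(self, effect_table):
        scaled = effect_table.copy()
        scaled["value"] = scaled["value"] * 0.02  # |v| << 0.1, log1p(v) ~ v
        calls = {}
        for tr in ("identity", "log"):
            fit = fit_lmm(scaled, ModelSpec(response_transform=tr), level="electrode")
            calls[tr] = call_terminal_hypersync(dunnett_vs_termination(fit, seed=2))
        assert calls["identity"] == calls["log"]

    def test_auto_reports_chosen_transform(self, effect_table):
        fit = fit_lmm(effect_table, ModelSpec(response_transform="auto"), level="region")
        assert fit.transform in ("identity", "log", "sqrt")


class TestDegenerateInputs:
    def test_constant_response_is_handled_error(self):
        df = worked_table()
        df["value"] = 0.5
        with pytest.raises(ModelDegenerateError):
            fit_lmm(df, ModelSpec(), level="region")

    def test_single_seizure_rejected(self):
        df = worked_table()
        df = df[df["seizure_index"] == 0]
        with pytest.raises(ModelFitError, match="2 seizures"):
            fit_lmm(df, ModelSpec(), level="region")

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError, match="electrode"):
            fit_lmm(worked_table(), ModelSpec(), level="electrode")
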