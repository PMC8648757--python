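"""Mixed-model inference: fits, LRTs, contrasts, FDR, effect sizes."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirspect.stats import (
    ALPHA,
    ModelSpec,
    _group_indices,
    _loglike,
    _refit,
    cohens_d,
    default_contrast_plan,
    effect_size_label,
    fdr_adjust,
    fit_lme,
    likelihood_ratio_test,
    planned_contrasts,
    simulate_band_table,
    term_tests,
)


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def test_closed_form_reml_matches_engine_loglik():
    tab = simulate_band_table(n_subjects=8, band_means={"VLF": 2.0}, seed=3)
    m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=False))
    ll = _loglike(m.X, m.y, _group_indices(m.groups), m.sigma2, m.tau2, reml=True)
    assert abs(ll - m.llf) < 1e-6


def test_profile_fallback_matches_engine_fit():
    """The closed-form profiled fitter (used when the engine's optimizer
    fails) agrees with the engine on a well-behaved table."""
    from fnirspect.stats import _engine_fit, _profile_fit

    tab = simulate_band_table(
        n_subjects=7,
        protocol="hypercapnic",
        band_means={"VLF": 1.5, "myogenic": 0.5},
        subject_sd=0.6,
        seed=77,
    )
    m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
    for reml in (True, False):
        res_e, s2_e, t2_e = _engine_fit(m.X, m.y, m.groups, reml=reml)
        res_p, s2_p, t2_p = _profile_fit(m.X, m.y, _group_indices(m.groups), reml=reml)
        assert np.allclose(res_p.fe_params, np.asarray(res_e.fe_params), rtol=1e-4)
        assert np.isclose(s2_p, s2_e, rtol=1e-3)
        assert np.isclose(t2_p, t2_e, rtol=1e-2, atol=1e-6)
        assert abs(res_p.llf - float(res_e.llf)) < 1e-4


def test_null_fixed_effects_near_zero():
    tab = simulate_band_table(n_subjects=13, subject_sd=1.0, resid_sd=1.0, seed=11)
    m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=False))
    se = np.sqrt(np.diag(m.cov_fe))
    assert np.all(np.abs(m.fe[1:]) < 3 * se[1:])


def test_constant_response_is_degenerate():
    tab = simulate_band_table(n_subjects=4, subject_sd=0.0, resid_sd=0.0, seed=0)
    tab["epsilon"] = 7.0
    with pytest.warns(UserWarning, match="degenerate"):
        m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=False))
    assert m.degenerate
    assert np.all(m.fe[1:] == 0) and m.fe[0] == 7.0 and m.sigma2 == 0.0


def test_skewed_positive_response_triggers_log10():
    rng = np.random.default_rng(5)
    tab = simulate_band_table(n_subjects=10, subject_sd=0.2, resid_sd=0.4, seed=5)
    tab["epsilon"] = 10.0 ** tab["epsilon"]  # lognormal-like, heteroscedastic
    m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO"))
    assert m.transform == "log10"


def test_band_effect_power():
    """A 4x VLF-vs-respiratory band effect is detected by the Band LRT in
    nearly every replicate."""
    hits = 0
    n_rep = 60
    for i in range(n_rep):
        tab = simulate_band_table(
            n_subjects=8,
            protocol="hypercapnic",
            band_means={"VLF": 2.0, "myogenic": 1.0, "respiratory": 0.5, "cardiac": 1.0},
            subject_sd=0.3,
            resid_sd=0.7,
            seed=9000 + i,
        )
        m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
        p = term_tests(m)["Band"]["p"]
        hits += p < ALPHA
    assert hits / n_rep >= 0.95


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------


def test_lrt_identical_models_gives_zero():
    tab = simulate_band_table(n_subjects=5, seed=2)
    m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
    ml = _refit(m, reml=False)
    chi2, df, p = likelihood_ratio_test(ml, ml)
    assert chi2 == 0.0 and df == 0 and p == 1.0


def test_lrt_df_is_parameter_count_difference():
    tab = simulate_band_table(n_subjects=5, seed=2)
    m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=False))
    tests = term_tests(m)
    assert tests["Band"]["df"] == 3
    assert tests["Band:SDS"]["df"] == 4
    assert tests["Band:SDS:Hemisphere"]["df"] == 8
    assert tests["Band:SDS:Condition"]["df"] == 32  # 4 bands x 2 sds x 4 conditions


def test_lrt_rejects_non_nested_and_reml():
    tab = simulate_band_table(n_subjects=5, seed=2)
    full = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=False))
    red = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
    with pytest.raises(ValueError, match="maximum-likelihood"):
        likelihood_ratio_test(full, red)  # REML fits refused


# ---------------------------------------------------------------------------
# planned contrasts
# ---------------------------------------------------------------------------


def test_contrast_plan_cardinality():
    assert len(default_contrast_plan("hypercapnic")) == 7
    assert len(default_contrast_plan("cognitive")) == 63


def test_null_sds_contrasts_near_zero():
    tab = simulate_band_table(
        n_subjects=13,
        protocol="hypercapnic",
        band_means={"VLF": 2.0, "myogenic": 1.0, "respiratory": 0.5, "cardiac": 1.0},
        seed=21,
    )
    m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
    for c in planned_contrasts(m):
        if c.term == "Band:SDS":
            assert abs(c.estimate) < 3 * c.se


def test_missing_condition_level_skipped_and_reported():
    tab = simulate_band_table(n_subjects=5, seed=4)
    tab = tab[tab["condition"] != "H2"]
    m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=False))
    res = planned_contrasts(m)
    skipped = [c for c in res if c.skipped]
    assert all("H2" in c.label for c in skipped)
    assert len(skipped) == 2 * 8  # H1vH2 and E2vH2 per band x sds


def test_log10_back_transform_preserves_order_and_scale():
    tab = simulate_band_table(
        n_subjects=10,
        band_means={"VLF": 0.8, "myogenic": 0.2, "respiratory": 0.1, "cardiac": 0.3},
        subject_sd=0.1,
        resid_sd=0.2,
        seed=8,
    )
    tab["epsilon"] = 10.0 ** tab["epsilon"]  # strictly positive response
    m = fit_lme(tab, ModelSpec("cognitive", "epsilon", "HbO", log10=True))
    assert m.transform == "log10"
    for c in planned_contrasts(m):
        if c.skipped:
            continue
        assert np.isclose(c.estimate, 10.0**c.estimate_model_scale)
        assert c.ci_low <= c.estimate <= c.ci_high


def test_cohens_d_conventions():
    assert cohens_d(0.0, 1.0, 0.5) == 0.0
    assert np.isclose(cohens_d(1.5, 1.0, 0.5), 1.5 / np.sqrt(1.5))
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(cohens_d(1.0, 0.0, 0.0))
    assert effect_size_label(0.55) == "medium"
    assert effect_size_label(0.15) == "negligible"
    assert effect_size_label(-0.9) == "large"
    assert effect_size_label(0.3) == "small"


def test_cohens_d_recovery_of_unit_effect():
    """A between-SDS shift equal to one total SD is recovered as d ~ 1."""
    shift = 1.0
    subject_sd, resid_sd = 0.6, 0.8  # total SD = 1.0
    tab = simulate_band_table(
        n_subjects=13,
        protocol="hypercapnic",
        sds_effects={b: shift for b in ("VLF", "myogenic", "respiratory", "cardiac")},
        subject_sd=subject_sd,
        resid_sd=resid_sd,
        seed=13,
    )
    m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
    ds = [c.cohens_d for c in planned_contrasts(m) if c.term == "Band:SDS"]
    assert abs(np.mean(ds) - 1.0) < 0.1


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


class TestFDR:
    def test_textbook_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == 0.37

    def test_all_ones(self):
        assert np.all(fdr_adjust([1.0, 1.0, 1.0]) == 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_stepup(self, p):
        assert np.allclose(fdr_adjust(p), bh_stepup_oracle(p), atol=1e-12)
        adj = fdr_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_family_wise_application(self):
        p = [0.01, 0.02, 0.5, 0.6]
        fams = ["a", "a", "b", "b"]
        adj = fdr_adjust(p, families=np.array(fams))
        assert np.allclose(adj[:2], bh_stepup_oracle(p[:2]))
        assert np.allclose(adj[2:], bh_stepup_oracle(p[2:]))

    def test_null_discovery_rate_controlled(self):
        """Across seeded null replicates, FDR-adjusted discoveries stay
        at or below alpha (plus binomial slack)."""
        discoveries = total = 0
        for i in range(60):
            tab = simulate_band_table(n_subjects=6, protocol="hypercapnic", seed=5000 + i)
            m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
            res = planned_contrasts(m)
            discoveries += sum(c.p_adjusted < ALPHA for c in res)
            total += len(res)
        rate = discoveries / total
        assert rate <= ALPHA + 2 * np.sqrt(ALPHA * (1 - ALPHA) / total)


# ---------------------------------------------------------------------------
# independent oracle: R lme4 / lmerTest / emmeans
# ---------------------------------------------------------------------------


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_matches_r_lmer_satterthwaite(tmp_path):
    """Estimates, SEs, Satterthwaite df, p-values and variance components
    agree with lme4 + lmerTest + emmeans on a shared fixture."""
    tab = simulate_band_table(
        n_subjects=6,
        protocol="hypercapnic",
        band_means={"VLF": 2.0, "myogenic": 1.0, "respiratory": 0.5, "cardiac": 0.2},
        sds_effects={"VLF": -0.8, "myogenic": 0.5, "respiratory": 0.4, "cardiac": 0.6},
        subject_sd=0.7,
        seed=42,
    )
    csv = tmp_path / "fixture.csv"
    tab.to_csv(csv, index=False)
    script = textwrap.dedent(
        f"""
        suppressMessages({{library(lme4); library(lmerTest); library(emmeans)}})
        d <- read.csv('{csv}')
        d$band <- factor(d$band, levels=c('VLF','myogenic','respiratory','cardiac'))
        d$sds <- factor(d$sds, levels=c('long','short'))
        m <- lmer(epsilon ~ 1 + band + band:sds + (1|subject), data=d, REML=TRUE)
        vc <- as.data.frame(VarCorr(m))
        em <- emmeans(m, ~ sds | band, lmer.df='satterthwaite')
        s <- as.data.frame(pairs(em, reverse=TRUE))
        cat(vc$vcov[1], vc$vcov[2], as.numeric(logLik(m)), '\\n')
        for (i in seq_len(nrow(s))) cat(as.character(s$band[i]), s$estimate[i], s$SE[i], s$df[i], s$p.value[i], '\\n')
        """
    )
    rfile = tmp_path / "check.R"
    rfile.write_text(script)
    out = subprocess.run(
        ["Rscript", str(rfile)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    lines = [ln.split() for ln in out.stdout.strip().splitlines() if ln.strip()]
    r_tau2, r_sigma2, r_llf = map(float, lines[0])
    r_rows = {ln[0]: list(map(float, ln[1:])) for ln in lines[1:]}

    m = fit_lme(tab, ModelSpec("hypercapnic", "epsilon", "HbO", log10=False))
    assert np.isclose(m.tau2, r_tau2, rtol=1e-3)
    assert np.isclose(m.sigma2, r_sigma2, rtol=1e-3)
    assert np.isclose(m.llf, r_llf, atol=1e-3)
    for c in planned_contrasts(m, adjust=False):
        if c.term != "Band:SDS":
            continue
        band = c.label.split("| ")[1]
        est, se, df, pval = r_rows[band]
        assert np.isclose(c.estimate, est, rtol=1e-4)
        assert np.isclose(c.se, se, rtol=1e-3)
        assert np.isclose(c.df, df, rtol=0.02)
        assert np.isclose(c.p_raw, pval, rtol=1e-2, atol=1e-6)
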