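"""Group-level linear mixed-effects analysis of band energy tables.

Models the band energy density (``epsilon``) or its relative form
(``rel_epsilon``) per biomarker with a subject random intercept:

* cognitive protocol:
  ``1 + Band + Band:SDS + Band:SDS:Hemisphere + Band:SDS:Condition + (1 | subject)``
* hypercapnic protocol:
  ``1 + Band + Band:SDS + (1 | subject)``

Fixed-term significance uses likelihood-ratio tests between maximum-
likelihood fits of nested models. Planned post hoc contrasts (7 for the
hypercapnic protocol, 63 for the cognitive one) are estimated as
differences of equally weighted marginal cell means, with Satterthwaite-
approximated degrees of freedom, Benjamini-Hochberg FDR adjustment per
model-term family, and Cohen's d computed against the total SD
``sqrt(subject variance + residual variance)``.

If residual diagnostics on the initial fit indicate non-normality
(|skew| > 1) or heteroscedasticity (variance ratio across fitted-value
quartiles > 4), the response is refit on the log10 scale and contrast
estimates / CIs are back-transformed (a log-scale difference becomes a
multiplicative ratio ``10**estimate``).

Estimation engine: :class:`statsmodels` ``MixedLM`` (REML for reported
estimates, ML refits for the likelihood-ratio tests). The Satterthwaite
computation uses an in-package closed-form restricted likelihood for the
random-intercept model, since the engine does not expose it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

BAND_LEVELS = ("VLF", "myogenic", "respiratory", "cardiac")
SDS_LEVELS = ("long", "short")
HEMI_LEVELS = ("left", "right")

COGNITIVE_TERMS = ("Band", "Band:SDS", "Band:SDS:Hemisphere", "Band:SDS:Condition")
HYPERCAPNIC_TERMS = ("Band", "Band:SDS")

#: condition pairs of the planned Band:SDS:Condition comparisons
CONDITION_PAIRS = (
    ("E1", "E2"),
    ("E1", "E3"),
    ("H1", "H2"),
    ("E1", "H1"),
    ("E2", "H2"),
    ("E3", "H1"),
)

ALPHA = 0.05


@dataclass
class ModelSpec:
    """Which model to fit: protocol fixes the fixed-effect terms."""

    protocol: str = "cognitive"  # "cognitive" | "hypercapnic"
    response: str = "rel_epsilon"  # "epsilon" | "rel_epsilon"
    biomarker: str = "HbO"
    log10: bool | None = None  # None = decide from residual diagnostics

    def __post_init__(self) -> None:
        if self.protocol not in ("cognitive", "hypercapnic"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.response not in ("epsilon", "rel_epsilon"):
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return COGNITIVE_TERMS if self.protocol == "cognitive" else HYPERCAPNIC_TERMS


# ---------------------------------------------------------------------------
# design matrices (R-style treatment coding of the nested interaction model)
# ---------------------------------------------------------------------------


def _design_columns(terms: tuple[str, ...], cond_levels: tuple[str, ...]):
    """Column names and per-term slices of the fixed-effects design."""
    names = ["Intercept"]
    term_cols: dict[str, list[int]] = {}
    for b in BAND_LEVELS[1:]:
        names.append(f"Band[{b}]")
    term_cols["Band"] = list(range(1, len(names)))
    if "Band:SDS" in terms:
        start = len(names)
        for b in BAND_LEVELS:
            names.append(f"Band[{b}]:SDS[short]")
        term_cols["Band:SDS"] = list(range(start, len(names)))
    if "Band:SDS:Hemisphere" in terms:
        start = len(names)
        for b in BAND_LEVELS:
            for s in SDS_LEVELS:
                names.append(f"Band[{b}]:SDS[{s}]:Hemi[right]")
        term_cols["Band:SDS:Hemisphere"] = list(range(start, len(names)))
    if "Band:SDS:Condition" in terms:
        start = len(names)
        for b in BAND_LEVELS:
            for s in SDS_LEVELS:
                for c in cond_levels[1:]:
                    names.append(f"Band[{b}]:SDS[{s}]:Cond[{c}]")
        term_cols["Band:SDS:Condition"] = list(range(start, len(names)))
    return names, term_cols


def _design_row(
    band: str,
    sds: str,
    hemi: str | None,
    cond: str | None,
    terms: tuple[str, ...],
    cond_levels: tuple[str, ...],
) -> np.ndarray:
    row = [1.0]
    row += [1.0 if band == b else 0.0 for b in BAND_LEVELS[1:]]
    if "Band:SDS" in terms:
        row += [1.0 if (band == b and sds == "short") else 0.0 for b in BAND_LEVELS]
    if "Band:SDS:Hemisphere" in terms:
        row += [
            1.0 if (band == b and sds == s and hemi == "right") else 0.0
            for b in BAND_LEVELS
            for s in SDS_LEVELS
        ]
    if "Band:SDS:Condition" in terms:
        row += [
            1.0 if (band == b and sds == s and cond == c) else 0.0
            for b in BAND_LEVELS
            for s in SDS_LEVELS
            for c in cond_levels[1:]
        ]
    return np.array(row)


def _build_design(
    df: pd.DataFrame, terms: tuple[str, ...], cond_levels: tuple[str, ...]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    names, term_cols = _design_columns(terms, cond_levels)
    rows = np.array(
        [
            _design_row(
                r.band,
                r.sds,
                getattr(r, "hemisphere", None),
                getattr(r, "condition", None),
                terms,
                cond_levels,
            )
            for r in df.itertuples()
        ]
    )
    return rows, names, term_cols


# ---------------------------------------------------------------------------
# closed-form random-intercept likelihood (used for Satterthwaite df)
# ---------------------------------------------------------------------------


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    _, codes = np.unique(groups, return_inverse=True)
    return [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]


def _gls_pieces(X, y, gidx, sigma2, tau2):
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx in gidx:
        xi, yi = X[idx], y[idx]
        ni = len(idx)
        w = tau2 / (sigma2 + ni * tau2)
        xs, ys = xi.sum(axis=0), yi.sum()
        xtvx += (xi.T @ xi - w * np.outer(xs, xs)) / sigma2
        xtvy += (xi.T @ yi - w * xs * ys) / sigma2
        ytvy += (yi @ yi - w * ys * ys) / sigma2
        logdet += (ni - 1) * np.log(sigma2) + np.log(sigma2 + ni * tau2)
    return xtvx, xtvy, ytvy, logdet


def _loglike(X, y, gidx, sigma2, tau2, reml: bool) -> float:
    n, p = X.shape
    xtvx, xtvy, ytvy, logdet = _gls_pieces(X, y, gidx, sigma2, tau2)
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    ll = -0.5 * (logdet + quad)
    if reml:
        ll -= 0.5 * (np.linalg.slogdet(xtvx)[1] + (n - p) * np.log(2 * np.pi))
    else:
        ll -= 0.5 * n * np.log(2 * np.pi)
    return float(ll)


def _phi(X, gidx, sigma2, tau2) -> np.ndarray:
    xtvx = _gls_pieces(X, np.zeros(X.shape[0]), gidx, sigma2, tau2)[0]
    return np.linalg.inv(xtvx)


def _satterthwaite_machinery(X, y, gidx, sigma2, tau2):
    """Pieces of the Satterthwaite approximation shared by all contrasts:
    Phi = (X'V^-1 X)^-1, its gradient wrt (sigma2, tau2), and the REML
    asymptotic covariance of the variance components."""
    tau2 = max(tau2, 1e-10 * sigma2)
    theta = np.array([sigma2, tau2])
    phi0 = _phi(X, gidx, sigma2, tau2)
    dphi = []
    steps = np.maximum(1e-4 * theta, 1e-10)
    for i in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += steps[i]
        tm[i] = max(tm[i] - steps[i], 1e-12)
        dphi.append((_phi(X, gidx, *tp) - _phi(X, gidx, *tm)) / (tp[i] - tm[i]))

    hsteps = np.maximum(1e-3 * theta, 1e-8)

    def ll(th):
        return _loglike(X, y, gidx, max(th[0], 1e-12), max(th[1], 1e-12), reml=True)

    def shifted(di, dj):
        t = theta.copy()
        t[0] += di * hsteps[0]
        t[1] += dj * hsteps[1]
        return ll(t)

    hess = np.zeros((2, 2))
    ll0 = ll(theta)
    hess[0, 0] = (shifted(1, 0) - 2 * ll0 + shifted(-1, 0)) / hsteps[0] ** 2
    hess[1, 1] = (shifted(0, 1) - 2 * ll0 + shifted(0, -1)) / hsteps[1] ** 2
    cross = (shifted(1, 1) - shifted(1, -1) - shifted(-1, 1) + shifted(-1, -1)) / (
        4 * hsteps[0] * hsteps[1]
    )
    hess[0, 1] = hess[1, 0] = cross
    try:
        acov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        acov = None
    return phi0, dphi, acov


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    """A fitted random-intercept mixed model on a band-energy table."""

    spec: ModelSpec
    names: list[str]
    term_cols: dict[str, list[int]]
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    cond_levels: tuple[str, ...]
    fe: np.ndarray
    cov_fe: np.ndarray
    sigma2: float
    tau2: float
    llf: float
    reml: bool
    transform: str | None = None
    diagnostics: dict = field(default_factory=dict)
    degenerate: bool = False
    converged: bool = True

    @property
    def n_params_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.sigma2 + self.tau2))

    def marginal_row(self, cell: dict[str, str]) -> np.ndarray:
        """Equally weighted marginal-mean design row for a (partial) cell,
        averaging over every factor the cell leaves free."""
        terms = self.spec.terms
        hemis = HEMI_LEVELS if "Band:SDS:Hemisphere" in terms else (None,)
        conds = self.cond_levels if "Band:SDS:Condition" in terms else (None,)
        rows = [
            _design_row(b, s, h, c, terms, self.cond_levels)
            for b in ((cell["band"],) if "band" in cell else BAND_LEVELS)
            for s in ((cell["sds"],) if "sds" in cell else SDS_LEVELS)
            for h in ((cell["hemisphere"],) if "hemisphere" in cell else hemis)
            for c in ((cell["condition"],) if "condition" in cell else conds)
        ]
        return np.mean(rows, axis=0)


def _residual_diagnostics(y, fitted) -> dict:
    resid = y - fitted
    skew = float(sstats.skew(resid)) if np.std(resid) > 0 else 0.0
    order = np.argsort(fitted)
    quarts = np.array_split(resid[order], 4)
    variances = [np.var(q) for q in quarts if len(q) > 1]
    vmin = min(variances) if variances else 0.0
    ratio = float(max(variances) / vmin) if vmin > 0 else np.inf
    if not variances or all(v == 0 for v in variances):
        ratio = 1.0
    return {"resid_skew": skew, "quartile_var_ratio": ratio}


def _profile_fit(X, y, gidx, reml: bool):
    """Closed-form profiled fit of the random-intercept model.

    For fixed variance ratio lam = tau2/sigma2 the GLS solution and the
    profiled sigma2 are analytic, so the whole fit reduces to a bounded
    1-D search over log(lam). Used as a fallback when the engine's
    optimizer fails; agrees with it to optimizer tolerance otherwise.
    """
    from scipy.optimize import minimize_scalar
    from types import SimpleNamespace

    n, p = X.shape

    def parts(lam):
        xtvx, xtvy, ytvy, _ = _gls_pieces(X, y, gidx, 1.0, lam)
        beta = np.linalg.solve(xtvx, xtvy)
        quad = max(float(ytvy - beta @ xtvy), 1e-300)
        return xtvx, beta, quad

    def neg_ll(loglam):
        lam = np.exp(loglam)
        xtvx, _, quad = parts(lam)
        logdet_unit = sum(np.log1p(len(idx) * lam) for idx in gidx)
        if reml:
            sigma2 = quad / (n - p)
            ld = np.linalg.slogdet(xtvx)[1]
            return 0.5 * (
                (n - p) * np.log(sigma2) + logdet_unit + ld + (n - p) * (1 + np.log(2 * np.pi))
            )
        sigma2 = quad / n
        return 0.5 * (n * np.log(sigma2) + logdet_unit + n * (1 + np.log(2 * np.pi)))

    opt = minimize_scalar(neg_ll, bounds=(-15.0, 10.0), method="bounded",
                          options={"xatol": 1e-9})
    lam = float(np.exp(opt.x))
    _, beta, quad = parts(lam)
    sigma2 = quad / (n - p if reml else n)
    tau2 = lam * sigma2
    if tau2 < 1e-8 * sigma2:  # boundary: compare against the lam -> 0 limit
        tau2 = 0.0
    llf = _loglike(X, y, gidx, sigma2, max(tau2, 1e-12 * sigma2), reml)
    res = SimpleNamespace(fe_params=beta, llf=llf, converged=True)
    return res, sigma2, tau2


def _engine_fit(X, y, groups, reml: bool):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=reml, maxiter=500)
        sigma2 = float(res.scale)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        if not (np.isfinite(res.llf) and np.isfinite(sigma2) and np.isfinite(tau2)):
            raise np.linalg.LinAlgError("non-finite engine fit")
        return res, sigma2, tau2
    except (np.linalg.LinAlgError, ValueError):
        return _profile_fit(X, y, _group_indices(groups), reml)


def fit_lme(table: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> LMMResult:
    """Fit the protocol's mixed model to one biomarker's rows.

    Applies the numeric normality / homoscedasticity rule to decide the
    log10 transform when ``spec.log10`` is None. A response with zero
    variance is returned as a degenerate result (all effects zero)
    rather than crashing the run.
    """
    df = table[table["biomarker"] == spec.biomarker].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no rows for biomarker {spec.biomarker!r}")
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 subjects")
    cond_levels = tuple(sorted(df["condition"].unique()))
    X, names, term_cols = _build_design(df, spec.terms, cond_levels)
    for term, cols in term_cols.items():
        if np.any(X[:, cols].sum(axis=0) == 0) and term != "Band:SDS:Condition":
            warnings.warn(f"term {term} has unobserved levels", stacklevel=2)
    groups = df["subject"].to_numpy()
    y_raw = df[spec.response].to_numpy(dtype=float)

    if np.ptp(y_raw) == 0:
        p = X.shape[1]
        fe = np.zeros(p)
        fe[0] = y_raw[0]
        warnings.warn("constant response; degenerate zero-variance fit", stacklevel=2)
        return LMMResult(
            spec=spec,
            names=names,
            term_cols=term_cols,
            X=X,
            y=y_raw,
            groups=groups,
            cond_levels=cond_levels,
            fe=fe,
            cov_fe=np.zeros((p, p)),
            sigma2=0.0,
            tau2=0.0,
            llf=np.inf,
            reml=reml,
            degenerate=True,
        )

    transform = None
    y = y_raw
    if spec.log10 is True:
        transform = "log10"
    elif spec.log10 is None:
        res0, s20, t20 = _engine_fit(X, y_raw, groups, reml=True)
        diag0 = _residual_diagnostics(y_raw, X @ np.asarray(res0.fe_params))
        if (abs(diag0["resid_skew"]) > 1.0 or diag0["quartile_var_ratio"] > 4.0) and np.all(
            y_raw > 0
        ):
            transform = "log10"
    if transform == "log10":
        if np.any(y_raw <= 0):
            raise ValueError("log10 transform requires a strictly positive response")
        y = np.log10(y_raw)

    res, sigma2, tau2 = _engine_fit(X, y, groups, reml=reml)
    gidx = _group_indices(groups)
    fe = np.asarray(res.fe_params, dtype=float)
    cov_fe = _phi(X, gidx, sigma2, max(tau2, 1e-12))
    diagnostics = _residual_diagnostics(y, X @ fe)
    diagnostics["singular_boundary"] = bool(tau2 < 1e-8 * sigma2)
    if diagnostics["singular_boundary"]:
        warnings.warn(
            "random-intercept variance at boundary (~0); fit may be singular",
            stacklevel=2,
        )
    return LMMResult(
        spec=replace(spec, log10=(transform == "log10")),
        names=names,
        term_cols=term_cols,
        X=X,
        y=y,
        groups=groups,
        cond_levels=cond_levels,
        fe=fe,
        cov_fe=cov_fe,
        sigma2=sigma2,
        tau2=tau2,
        llf=float(res.llf),
        reml=reml,
        transform=transform,
        diagnostics=diagnostics,
        converged=bool(getattr(res, "converged", True)),
    )


def _refit(model: LMMResult, cols: list[int] | None = None, reml: bool = False) -> LMMResult:
    """Refit on the same data, optionally keeping only ``cols`` of X."""
    keep = cols if cols is not None else list(range(model.X.shape[1]))
    X = model.X[:, keep]
    res, sigma2, tau2 = _engine_fit(X, model.y, model.groups, reml=reml)
    gidx = _group_indices(model.groups)
    return replace(
        model,
        names=[model.names[i] for i in keep],
        X=X,
        fe=np.asarray(res.fe_params, dtype=float),
        cov_fe=_phi(X, gidx, sigma2, max(tau2, 1e-12)),
        sigma2=sigma2,
        tau2=tau2,
        llf=float(res.llf),
        reml=reml,
        term_cols={},
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def likelihood_ratio_test(full: LMMResult, reduced: LMMResult) -> tuple[float, int, float]:
    """LRT of two nested maximum-likelihood fits: (chi2, df, p)."""
    if not set(reduced.names) <= set(full.names):
        raise ValueError("reduced model is not nested in the full model")
    if full.reml or reduced.reml:
        raise ValueError("likelihood-ratio tests require maximum-likelihood fits")
    df = full.n_params_fixed - reduced.n_params_fixed
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(sstats.chi2.sf(chi2, df))
    return chi2, df, p


def term_tests(model: LMMResult) -> dict[str, dict]:
    """Per-term likelihood-ratio tests (full vs full-minus-term, ML)."""
    full_ml = _refit(model, reml=False)
    out = {}
    all_cols = list(range(model.X.shape[1]))
    for term, cols in model.term_cols.items():
        keep = [c for c in all_cols if c not in cols]
        reduced = _refit(model, cols=keep, reml=False)
        chi2, df, p = likelihood_ratio_test(full_ml, reduced)
        out[term] = {"chi2": chi2, "df": df, "p": p}
    return out


@dataclass
class ContrastResult:
    """One planned comparison with Satterthwaite df and effect size."""

    label: str
    term: str
    estimate: float  # back-transformed to original units when log10 used
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    df: float
    se: float
    estimate_model_scale: float
    transform: str | None = None
    skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "term": self.term,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_raw": self.p_raw,
            "p_adj": self.p_adjusted,
            "d": self.cohens_d,
            "df": self.df,
        }


@dataclass(frozen=True)
class PlannedContrast:
    label: str
    term: str
    cell_a: tuple[tuple[str, str], ...]  # frozen dict items
    cell_b: tuple[tuple[str, str], ...]


def default_contrast_plan(
    protocol: str, cond_levels: tuple[str, ...] = ("E1", "E2", "E3", "H1", "H2")
) -> list[PlannedContrast]:
    """The planned-comparison sets: 3 Band + 4 Band:SDS for both
    protocols; the cognitive protocol adds 8 Band:SDS:Hemisphere and
    48 Band:SDS:Condition pairs (63 total)."""
    plan: list[PlannedContrast] = []
    for b in BAND_LEVELS[1:]:
        plan.append(
            PlannedContrast(
                f"VLF vs {b}", "Band", (("band", "VLF"),), (("band", b),)
            )
        )
    for b in BAND_LEVELS:
        plan.append(
            PlannedContrast(
                f"short vs long | {b}",
                "Band:SDS",
                (("band", b), ("sds", "short")),
                (("band", b), ("sds", "long")),
            )
        )
    if protocol == "cognitive":
        for b in BAND_LEVELS:
            for s in SDS_LEVELS:
                plan.append(
                    PlannedContrast(
                        f"left vs right | {b},{s}",
                        "Band:SDS:Hemisphere",
                        (("band", b), ("sds", s), ("hemisphere", "left")),
                        (("band", b), ("sds", s), ("hemisphere", "right")),
                    )
                )
        for b in BAND_LEVELS:
            for s in SDS_LEVELS:
                for c1, c2 in CONDITION_PAIRS:
                    plan.append(
                        PlannedContrast(
                            f"{c1} vs {c2} | {b},{s}",
                            "Band:SDS:Condition",
                            (("band", b), ("sds", s), ("condition", c1)),
                            (("band", b), ("sds", s), ("condition", c2)),
                        )
                    )
    return plan


def cohens_d(estimate: float, sigma2: float, tau2: float) -> float:
    """Standardised effect: contrast estimate over the total SD
    (random-intercept + residual variance components)."""
    total = sigma2 + tau2
    if total <= 0:
        warnings.warn("zero total variance; Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float(estimate / np.sqrt(total))


def effect_size_label(d: float) -> str:
    """Conventional anchors: 0.2 small, 0.5 medium, > 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def fdr_adjust(p: np.ndarray, families: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, within each family."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if families is None:
        families = np.zeros(p.size)
    families = np.asarray(families)
    for fam in np.unique(families):
        idx = families == fam
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def planned_contrasts(
    model: LMMResult,
    plan: list[PlannedContrast] | None = None,
    alpha: float = ALPHA,
    adjust: bool = True,
) -> list[ContrastResult]:
    """Estimate the planned comparisons on a fitted (REML) model.

    Each contrast is the difference of equally weighted marginal cell
    means (first-listed cell minus second). Contrasts touching a level
    absent from the data are skipped and reported, not silently dropped.
    """
    if plan is None:
        plan = default_contrast_plan(model.spec.protocol, model.cond_levels)
    gidx = _group_indices(model.groups)
    if model.degenerate:
        results = [
            ContrastResult(
                c.label, c.term, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0,
                float(len(model.y) - 1), 0.0, 0.0, model.transform,
            )
            for c in plan
        ]
        return results
    phi0, dphi, acov = _satterthwaite_machinery(
        model.X, model.y, gidx, model.sigma2, model.tau2
    )
    n, p = model.X.shape
    results: list[ContrastResult] = []
    for con in plan:
        cell_a, cell_b = dict(con.cell_a), dict(con.cell_b)
        levels_needed = [v for cell in (cell_a, cell_b) for k, v in cell.items() if k == "condition"]
        if any(lv not in model.cond_levels for lv in levels_needed):
            results.append(
                ContrastResult(
                    con.label, con.term, np.nan, np.nan, np.nan, np.nan, np.nan,
                    np.nan, np.nan, np.nan, np.nan, model.transform, skipped=True,
                )
            )
            continue
        c = model.marginal_row(cell_a) - model.marginal_row(cell_b)
        est = float(c @ model.fe)
        var = float(c @ phi0 @ c)
        se = float(np.sqrt(max(var, 0.0)))
        if acov is not None and se > 0:
            g = np.array([c @ dphi[0] @ c, c @ dphi[1] @ c])
            denom = float(g @ acov @ g)
            df = 2 * var**2 / denom if denom > 0 else float(n - p)
        else:
            df = float(n - p)
        df = float(np.clip(df, 1.0, n - p))
        if se > 0:
            tval = est / se
            p_raw = float(2 * sstats.t.sf(abs(tval), df))
            half = float(sstats.t.ppf(1 - alpha / 2, df) * se)
        else:
            p_raw, half = 1.0, 0.0
        lo, hi = est - half, est + half
        d = cohens_d(est, model.sigma2, model.tau2)
        if model.transform == "log10":
            est_rep, lo_rep, hi_rep = 10.0**est, 10.0**lo, 10.0**hi
        else:
            est_rep, lo_rep, hi_rep = est, lo, hi
        results.append(
            ContrastResult(
                label=con.label,
                term=con.term,
                estimate=est_rep,
                ci_low=lo_rep,
                ci_high=hi_rep,
                p_raw=p_raw,
                p_adjusted=p_raw,
                cohens_d=d,
                df=df,
                se=se,
                estimate_model_scale=est,
                transform=model.transform,
            )
        )
    if adjust:
        live = [r for r in results if not r.skipped]
        if live:
            padj = fdr_adjust(
                np.array([r.p_raw for r in live]),
                families=np.array([r.term for r in live]),
            )
            for r, pa in zip(live, padj):
                r.p_adjusted = float(pa)
    return results


# ---------------------------------------------------------------------------
# cohort-level driver and table simulator
# ---------------------------------------------------------------------------


def analyze_band_table(
    table: pd.DataFrame,
    protocol: str,
    responses: tuple[str, ...] = ("epsilon", "rel_epsilon"),
    biomarkers: tuple[str, ...] = ("HbO", "HbR", "HbT"),
    log10: bool | None = None,
) -> dict:
    """Fit every (response, biomarker) model with term LRTs and planned
    contrasts; returns a nested dict plus a tidy contrast DataFrame under
    the ``"contrasts"`` key."""
    report: dict = {"protocol": protocol, "models": {}}
    rows = []
    for response in responses:
        for biomarker in biomarkers:
            if biomarker not in set(table["biomarker"]):
                continue
            spec = ModelSpec(protocol=protocol, response=response, biomarker=biomarker, log10=log10)
            model = fit_lme(table, spec)
            tests = term_tests(model) if not model.degenerate else {}
            contrasts = planned_contrasts(model)
            key = f"{response}/{biomarker}"
            report["models"][key] = {
                "transform": model.transform,
                "variance_components": {"subject": model.tau2, "residual": model.sigma2},
                "diagnostics": model.diagnostics,
                "term_tests": tests,
                "degenerate": model.degenerate,
            }
            for r in contrasts:
                rows.append({"response": response, "biomarker": biomarker, **r.to_dict()})
    report["contrasts"] = pd.DataFrame(rows)
    return report


def simulate_band_table(
    n_subjects: int = 13,
    protocol: str = "cognitive",
    band_means: dict[str, float] | None = None,
    sds_effects: dict[str, float] | None = None,
    hemi_effects: dict[tuple[str, str], float] | None = None,
    cond_effects: dict[tuple[str, str, str], float] | None = None,
    subject_sd: float = 0.5,
    resid_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a band-energy table directly at the cell-mean level.

    A statistical simulator for exercising the inference layer (nulls,
    power, type-I calibration): response = band mean + band:SDS shift +
    optional hemisphere / condition shifts + subject intercept + noise.
    Both the ``epsilon`` and ``rel_epsilon`` columns carry the simulated
    response.
    """
    rng = np.random.default_rng(seed)
    band_means = band_means or {b: 0.0 for b in BAND_LEVELS}
    sds_effects = sds_effects or {}
    hemi_effects = hemi_effects or {}
    cond_effects = cond_effects or {}
    conds = ("E1", "E2", "E3", "H1", "H2") if protocol == "cognitive" else ("steady",)
    rows = []
    for subj in range(n_subjects):
        intercept = rng.normal(0.0, subject_sd)
        for band in BAND_LEVELS:
            for sds in SDS_LEVELS:
                for hemi in HEMI_LEVELS:
                    for cond in conds:
                        mu = (
                            band_means.get(band, 0.0)
                            + (sds_effects.get(band, 0.0) if sds == "short" else 0.0)
                            + (hemi_effects.get((band, sds), 0.0) if hemi == "right" else 0.0)
                            + cond_effects.get((band, sds, cond), 0.0)
                        )
                        yv = mu + intercept + rng.normal(0.0, resid_sd)
                        rows.append(
                            {
                                "subject": f"S{subj:02d}",
                                "condition": cond,
                                "sds": sds,
                                "hemisphere": hemi,
                                "band": band,
                                "biomarker": "HbO",
                                "epsilon": yv,
                                "rel_epsilon": yv,
                            }
                        )
    return pd.DataFrame(rows)
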