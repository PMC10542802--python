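"""Survival and association models for heteroplasmy burden.

Cox proportional-hazards fits (stratified baselines, Efron ties, late
entry), Poisson heteroplasmy-count models with an age-spline x smoking
interaction tested by likelihood ratio, marginal prevalence ratios with
delta-method intervals, Fine-Gray subdistribution hazards via the
censoring-weighted (IPCW) partial likelihood, Benjamini-Hochberg FDR
control, and fixed-effect inverse-variance meta-analysis.

Exposures enter per 1-unit (continuous MSS), as count categories against
a zero reference, or as carrier indicators; age enters as a restricted
cubic spline (default 4 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass(frozen=True)
class EffectEstimate:
    """One ratio-scale effect estimate with its 95% interval."""

    term: str
    estimate: float          # HR / PR / sub-HR / rate ratio
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    n: int
    n_events: int

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"CI ordering violated for {self.term}: "
                f"{self.ci_low}, {self.estimate}, {self.ci_high}"
            )

    @property
    def log_estimate(self) -> float:
        return float(np.log(self.estimate))


# -- spline basis -------------------------------------------------------------

def _harrell_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knot placement at the conventional outer/inner quantiles."""
    presets = {
        3: [0.10, 0.50, 0.90],
        4: [0.05, 0.35, 0.65, 0.95],
        5: [0.05, 0.275, 0.50, 0.725, 0.95],
        6: [0.05, 0.23, 0.41, 0.59, 0.77, 0.95],
        7: [0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975],
    }
    qs = presets.get(n_knots, list(np.linspace(0.05, 0.95, n_knots)))
    return np.quantile(x, qs)


def rcs_basis(x, df: int = 4, knots: np.ndarray | None = None,
              name: str = "x") -> pd.DataFrame:
    """Restricted (natural) cubic spline basis with ``df`` columns.

    Truncated-power construction over df+1 quantile knots: the first
    column is ``x`` itself; the basis is linear beyond the boundary
    knots.  Raises if ``x`` has too few distinct values to place knots.
    """
    if df < 3:
        raise ValueError("restricted cubic splines need df >= 3")
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = _harrell_knots(x, df + 1)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(np.unique(knots)) != len(knots):
        raise ValueError(
            f"covariate {name!r} has too few distinct values for {len(knots)} knots"
        )
    t = knots
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def tp(v, knot):
        return np.clip(v - knot, 0.0, None) ** 3

    cols = {f"{name}_rcs1": x}
    for j in range(k - 2):
        term = (
            tp(x, t[j])
            - tp(x, t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + tp(x, t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / norm
        cols[f"{name}_rcs{j + 2}"] = term
    basis = pd.DataFrame(cols)
    basis.attrs["knots"] = t
    return basis


# -- design construction ------------------------------------------------------

def build_design(table: pd.DataFrame, terms) -> pd.DataFrame:
    """Expand a covariate spec into a numeric design frame.

    Each term is a plain column name (continuous / 0-1 indicator), a
    tuple ("rcs", col, df) for a restricted cubic spline, or
    ("cat", col, reference) for dummy coding against the given reference
    level.
    """
    pieces = []
    for term in terms:
        if isinstance(term, str):
            pieces.append(table[[term]].astype(float))
        elif term[0] == "rcs":
            _, col, df = term
            pieces.append(rcs_basis(table[col].to_numpy(), df=df, name=col)
                          .set_index(table.index))
        elif term[0] == "cat":
            _, col, ref = term
            cat = pd.Categorical(table[col])
            if ref not in cat.categories:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            dummies = pd.get_dummies(cat, prefix=col, dtype=float)
            dummies = dummies.drop(columns=f"{col}_{ref}")
            dummies.index = table.index
            pieces.append(dummies)
        else:
            raise ValueError(f"unrecognized design term {term!r}")
    return pd.concat(pieces, axis=1)


def _estimate_from_fit(term, coef, se, n, n_events) -> EffectEstimate:
    z = coef / se
    p = 2 * stats.norm.sf(abs(z))
    return EffectEstimate(
        term=term,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        se_log=float(se),
        p_value=float(p),
        n=int(n),
        n_events=int(n_events),
    )


# -- Cox proportional hazards -------------------------------------------------

def fit_cox(
    table: pd.DataFrame,
    exposure,
    covariates=(),
    duration_col: str = "followup_time",
    event_col: str = "event",
    strata: str | None = None,
    entry_col: str | None = None,
) -> tuple[dict[str, EffectEstimate], CoxPHFitter]:
    """Stratified Cox fit; returns estimates for the exposure term(s).

    ``exposure`` is a term spec as in :func:`build_design` (or a list of
    them); late entry (left truncation) is honoured via ``entry_col``.
    Ties are handled by the Efron approximation.  Competing causes are
    analysed cause-specifically by passing an event column that censors
    the other causes.
    """
    exposures = exposure if isinstance(exposure, list) else [exposure]
    design = build_design(table, exposures + list(covariates))
    exposure_cols = list(build_design(table, exposures).columns)

    df = design.copy()
    df[duration_col] = table[duration_col].to_numpy()
    df[event_col] = table[event_col].astype(int).to_numpy()
    if (df[duration_col] <= 0).any() and entry_col is None:
        raise ValueError("non-positive follow-up times without late entry")
    if strata is not None:
        df["_stratum"] = table[strata].to_numpy()
    if entry_col is not None:
        df["_entry"] = table[entry_col].to_numpy()
        if (df["_entry"] >= df[duration_col]).any():
            raise ValueError("entry time must precede exit time")

    fitter = CoxPHFitter()
    fitter.fit(
        df,
        duration_col=duration_col,
        event_col=event_col,
        strata="_stratum" if strata is not None else None,
        entry_col="_entry" if entry_col is not None else None,
        fit_options={"precision": 1e-10},
    )
    n_events = int(df[event_col].sum())
    out = {
        col: _estimate_from_fit(
            col,
            fitter.params_[col],
            fitter.standard_errors_[col],
            len(df),
            n_events,
        )
        for col in exposure_cols
    }
    return out, fitter


def cause_specific_events(
    table: pd.DataFrame, cause, cause_col: str = "cause", event_col: str = "event"
) -> pd.Series:
    """Event indicator for one cause; other causes become censorings."""
    causes = [cause] if isinstance(cause, str) else list(cause)
    return ((table[event_col].astype(int) == 1)
            & table[cause_col].isin(causes)).astype(int)


# -- Poisson count model with interaction LRT ---------------------------------

def fit_poisson_interaction(
    table: pd.DataFrame,
    count_col: str = "heteroplasmy_count",
    age_col: str = "age",
    smoking_col: str = "smoking",
    age_df: int = 4,
):
    """Poisson heteroplasmy-count model; LRT for age-spline x smoking.

    The full model regresses the count on a restricted cubic spline of
    age (``age_df`` df), smoking (never as reference) and their
    interaction; the reduced model drops the interaction.  Returns
    (full fit, reduced fit, lrt_stat, lrt_df, p_value).
    """
    counts = table[count_col].to_numpy()
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("heteroplasmy counts must be non-negative integers")
    age_b = rcs_basis(table[age_col].to_numpy(), df=age_df, name="age")
    smoke = pd.get_dummies(pd.Categorical(table[smoking_col]),
                           prefix="smoking", dtype=float)
    if "smoking_never" in smoke.columns:
        smoke = smoke.drop(columns="smoking_never")
    if smoke.shape[1] == 0 or (smoke.sum(axis=0) == 0).any():
        raise ValueError("degenerate smoking category: a level has no observations")
    inter = {}
    for s_col in smoke.columns:
        for a_col in age_b.columns:
            inter[f"{s_col}:{a_col}"] = smoke[s_col].to_numpy() * age_b[a_col].to_numpy()
    inter = pd.DataFrame(inter)

    base = pd.concat(
        [age_b.reset_index(drop=True), smoke.reset_index(drop=True)], axis=1
    )
    full_X = sm.add_constant(pd.concat([base, inter.reset_index(drop=True)], axis=1))
    red_X = sm.add_constant(base)
    full = sm.GLM(counts, full_X, family=sm.families.Poisson()).fit()
    reduced = sm.GLM(counts, red_X, family=sm.families.Poisson()).fit()
    lrt = 2 * (full.llf - reduced.llf)
    df_diff = inter.shape[1]
    p = float(stats.chi2.sf(lrt, df_diff))
    return full, reduced, float(lrt), df_diff, p


# -- marginal prevalence ratio ------------------------------------------------

def marginal_prevalence_ratio(
    table: pd.DataFrame,
    outcome_col: str,
    exposure_col: str = "mss",
    covariates=(),
    increment: float = 1.0,
) -> EffectEstimate:
    """Prevalence ratio per ``increment`` of exposure by marginal standardization.

    A logistic model is fitted; PR is the mean predicted prevalence with
    every row's exposure incremented, divided by the mean prediction at
    the observed exposures.  The CI comes from the delta method on
    log PR using the logistic coefficient covariance.
    """
    y = table[outcome_col].astype(int).to_numpy()
    if y.mean() in (0.0, 1.0):
        raise ValueError(f"outcome {outcome_col!r} has prevalence 0 or 1")
    design = build_design(table, [exposure_col] + list(covariates))
    X0 = sm.add_constant(design, has_constant="add").to_numpy(dtype=float)
    shifted = design.copy()
    shifted[exposure_col] = shifted[exposure_col] + increment
    X1 = sm.add_constant(shifted, has_constant="add").to_numpy(dtype=float)

    fit = sm.Logit(y, X0).fit(disp=0)
    beta, cov = fit.params, fit.cov_params()

    def mean_p_and_grad(X):
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        grad = (p * (1 - p)) @ X / len(p)  # d mean(p) / d beta
        return p.mean(), grad

    p1, g1 = mean_p_and_grad(X1)
    p0, g0 = mean_p_and_grad(X0)
    pr = p1 / p0
    grad_log = g1 / p1 - g0 / p0
    var_log = float(grad_log @ cov @ grad_log)
    se_log = float(np.sqrt(var_log))
    return _estimate_from_fit(
        f"PR({exposure_col}+{increment:g})", np.log(pr), se_log, len(y), int(y.sum())
    )


# -- Fine-Gray subdistribution hazards ----------------------------------------

def _censoring_survival(time, censored, entry=None) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=censored, entry=entry, label="G")
    return km


def fit_subdistribution(
    table: pd.DataFrame,
    exposure,
    covariates=(),
    duration_col: str = "followup_time",
    event_col: str = "event_type",
    entry_col: str | None = None,
) -> tuple[dict[str, EffectEstimate], CoxTimeVaryingFitter]:
    """Fine-Gray subdistribution-hazard fit via the IPCW partial likelihood.

    ``event_col`` codes 0 = censored, 1 = event of interest, >= 2 =
    competing event.  Subjects with a competing event stay in the risk
    set after their event time, down-weighted by the censoring survival
    ratio G(t)/G(T_i); the weighted risk sets are expanded at the event
    times of interest and fitted as a weighted start-stop Cox model.
    With no competing events present the fit coincides with the
    cause-specific Cox model.
    """
    time = table[duration_col].to_numpy(dtype=float)
    etype = table[event_col].to_numpy(dtype=int)
    entry = (table[entry_col].to_numpy(dtype=float)
             if entry_col is not None else np.zeros(len(table)))
    design = build_design(
        table, (exposure if isinstance(exposure, list) else [exposure])
        + list(covariates)
    )
    exposure_cols = list(
        build_design(
            table, exposure if isinstance(exposure, list) else [exposure]
        ).columns
    )

    km = _censoring_survival(time, (etype == 0).astype(int), entry=entry)

    def G(t: np.ndarray) -> np.ndarray:
        # left-continuous censoring survival G(t-)
        vals = km.survival_function_at_times(np.asarray(t) - 1e-9).to_numpy()
        return np.clip(vals, 1e-12, None)

    interest_times = np.sort(np.unique(time[etype == 1]))
    rows = []
    for i in range(len(table)):
        x = design.iloc[i]
        base = {"id": i, "start": entry[i], "stop": time[i],
                "event": int(etype[i] == 1), "w": 1.0, **x}
        if time[i] <= entry[i]:
            raise ValueError("entry time must precede exit time")
        rows.append(base)
        if etype[i] >= 2:  # competing event: extend with IPCW weights
            later = interest_times[interest_times > time[i]]
            if len(later) == 0:
                continue
            g_t = G(later)
            g_T = G(np.array([time[i]]))[0]
            prev = time[i]
            for t_j, g in zip(later, g_t):
                rows.append({"id": i, "start": prev, "stop": t_j, "event": 0,
                             "w": float(g / g_T), **x})
                prev = t_j
    long_df = pd.DataFrame(rows)

    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        long_df,
        id_col="id",
        start_col="start",
        stop_col="stop",
        event_col="event",
        weights_col="w",
        show_progress=False,
        fit_options={"precision": 1e-10},
    )
    n_events = int((etype == 1).sum())
    out = {
        col: _estimate_from_fit(
            col, ctv.params_[col], ctv.standard_errors_[col], len(table), n_events
        )
        for col in exposure_cols
    }
    return out, ctv


# -- meta-analysis and FDR ----------------------------------------------------

@dataclass(frozen=True)
class MetaResult:
    pooled: EffectEstimate
    q_statistic: float
    q_p_value: float
    i_squared: float
    tau_squared: float
    method: str


def meta_inverse_variance(estimates, random_effects: bool = False) -> MetaResult:
    """Inverse-variance pooling of log-scale effect estimates.

    Fixed-effect by default; ``random_effects=True`` uses the
    DerSimonian-Laird between-study variance.  Reports Cochran's Q and
    I-squared heterogeneity.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate to pool")
    logs = np.array([e.log_estimate for e in estimates])
    ses = np.array([e.se_log for e in estimates])
    if (ses <= 0).any() or not np.isfinite(ses).all():
        raise ValueError("degenerate input: every estimate needs a finite positive SE")

    w = 1.0 / ses**2
    pooled_fixed = float(np.sum(w * logs) / np.sum(w))
    q = float(np.sum(w * (logs - pooled_fixed) ** 2))
    k = len(estimates)
    q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 and k > 1 else 0.0

    tau2 = 0.0
    method = "fixed"
    if random_effects and k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w = 1.0 / (ses**2 + tau2)
        method = "random (DerSimonian-Laird)"
    pooled_log = float(np.sum(w * logs) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))

    pooled = _estimate_from_fit(
        "pooled", pooled_log, pooled_se,
        sum(e.n for e in estimates), sum(e.n_events for e in estimates),
    )
    return MetaResult(pooled, q, q_p, float(i2), float(tau2), method)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def random_heteroplasmy_pick(calls: pd.DataFrame, seed: int,
                             sample_col: str = "sample_id") -> pd.DataFrame:
    """Select one heteroplasmic call per sample, uniformly, reproducibly.

    Samples absent from ``calls`` simply do not appear (recorded by the
    caller's bookkeeping); identical seeds give identical picks.
    """
    rng = np.random.default_rng(seed)
    picks = []
    for _, grp in calls.sort_values([sample_col, "pos"]).groupby(sample_col, sort=True):
        picks.append(grp.iloc[int(rng.integers(len(grp)))])
    return pd.DataFrame(picks).reset_index(drop=True)
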