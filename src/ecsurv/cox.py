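"""Cox proportional-hazards machinery, written against the partial likelihood.

The model is h(t, x) = h0(t) * exp(beta' x) with categorical predictors
dummy-coded against their reference level (a record at all reference levels
has linear predictor 0). Estimation is Newton-Raphson on the log partial
likelihood with step-halving, supporting both the Efron (default) and
Breslow corrections for tied event times. The baseline cumulative hazard is
the Breslow estimator, which at beta = 0 reduces to Nelson-Aalen, and the
5-year survival prediction is S(t | x) = S0(t) ** exp(beta' x).

Columns that are constant in the data carry no partial-likelihood
information and are dropped with a warning (their coefficients are reported
as 0), which keeps small simulated cohorts fittable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codebook import VariableCodebook
from .cohort import Cohort, PatientRecord

__all__ = [
    "CoxDesign",
    "CoxFit",
    "BaselineSurvival",
    "UnivariateTestResult",
    "dummy_encode",
    "encode_record",
    "negative_log_partial_likelihood",
    "partial_likelihood_parts",
    "fit_cox",
    "hazard_ratios",
    "wald_statistics",
    "univariate_lr_test",
    "breslow_baseline",
    "linear_predictors",
    "predict_survival_probability",
]

_TIES = ("efron", "breslow")


@dataclass(frozen=True)
class CoxDesign:
    """Dummy-coded design: X (n, p), follow-up time, event indicator."""

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    column_names: tuple[str, ...]
    codebook: VariableCodebook | None = None
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        n = X.shape[0]
        if t.shape != (n,) or e.shape != (n,):
            raise ValueError("time/event length mismatch with X")
        if X.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch with X")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _dummy_columns(
    codebook: VariableCodebook, variables: tuple[str, ...]
) -> list[tuple[str, int, int]]:
    """(column name, variable index, level) for every non-reference level."""
    cols = []
    for name in variables:
        var = codebook[name]
        j = codebook.index_of(name)
        for lev in range(var.n_levels):
            if lev != var.reference_level:
                cols.append((f"{name}={var.levels[lev]}", j, lev))
    return cols


def dummy_encode(cohort: Cohort, variables: list[str] | None = None) -> CoxDesign:
    """One indicator column per non-reference level, in codebook order."""
    cb = cohort.codebook
    variables = tuple(variables) if variables is not None else cb.names
    cols = _dummy_columns(cb, variables)
    X = np.zeros((len(cohort), len(cols)))
    for c, (_, j, lev) in enumerate(cols):
        X[:, c] = cohort.levels[:, j] == lev
    return CoxDesign(
        X,
        cohort.months.astype(float),
        cohort.events,
        tuple(name for name, _, _ in cols),
        codebook=cb,
        variables=variables,
    )


def encode_record(
    codebook: VariableCodebook, variables: tuple[str, ...], record: PatientRecord
) -> np.ndarray:
    cols = _dummy_columns(codebook, variables)
    return np.array(
        [1.0 if record.levels[j] == lev else 0.0 for _, j, lev in cols]
    )


# --------------------------------------------------------------------------
# partial likelihood
# --------------------------------------------------------------------------

def partial_likelihood_parts(
    beta: np.ndarray, design: CoxDesign, ties: str = "efron"
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score vector and observed information.

    Iterates event times in decreasing order, maintaining risk-set
    accumulators S0 = sum e^eta, S1 = sum e^eta x, S2 = sum e^eta x x'.
    For d tied deaths the Efron correction subtracts l/d of the tied-set
    sums from the denominator at step l; Breslow uses the full risk set d
    times. Both reduce to the same expression when event times are distinct.
    """
    if ties not in _TIES:
        raise ValueError(f"ties must be one of {_TIES}")
    beta = np.asarray(beta, dtype=float)
    X, time, event = design.X, design.time, design.event
    p = X.shape[1]
    if beta.shape != (p,):
        raise ValueError(f"beta must have length {p}")
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    Xs, ws, es, etas = X[order], w[order], event[order], eta[order]
    wx = ws[:, None] * Xs
    # group boundaries of tied times in descending order; cumulative sums up
    # to a group's end are exactly the risk-set accumulators at its time
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    ends = np.r_[starts[1:], t_sorted.size]
    S0g = np.cumsum(ws)[ends - 1]
    S1g = np.cumsum(wx, axis=0)[ends - 1]
    S2g = np.cumsum(
        (wx[:, :, None] * Xs[:, None, :]).reshape(len(ws), p * p), axis=0
    )[ends - 1].reshape(-1, p, p)

    csum = np.r_[0, np.cumsum(es)]
    d_g = csum[ends] - csum[starts]  # deaths per group
    has_event = d_g > 0

    ev = es == 1
    loglik = float(etas[ev].sum())
    score = Xs[ev].sum(axis=0) if ev.any() else np.zeros(p)
    info = np.zeros((p, p))

    # groups whose denominator never mixes in the tied-death correction:
    # Breslow always; Efron when d = 1 (frac = 0) — fully vectorized
    simple = has_event & ((ties == "breslow") | (d_g == 1))
    if simple.any():
        d_s = d_g[simple].astype(float)
        R0 = S0g[simple]
        mu = S1g[simple] / R0[:, None]
        loglik -= float((d_s * np.log(R0)).sum())
        score -= (d_s[:, None] * mu).sum(axis=0)
        info += np.einsum("g,gjk->jk", d_s / R0, S2g[simple]) - np.einsum(
            "g,gj,gk->jk", d_s, mu, mu
        )

    if ties == "efron":
        for gi in np.flatnonzero(has_event & (d_g > 1)):
            rows = np.arange(starts[gi], ends[gi])
            g = rows[es[rows] == 1]
            d = g.size
            wg = ws[g, None] * Xs[g]
            T0 = ws[g].sum()
            T1 = wg.sum(axis=0)
            T2 = Xs[g].T @ wg
            for frac in np.arange(d) / d:
                R0 = S0g[gi] - frac * T0
                R1 = S1g[gi] - frac * T1
                R2 = S2g[gi] - frac * T2
                loglik -= np.log(R0)
                mu = R1 / R0
                score -= mu
                info += R2 / R0 - np.outer(mu, mu)
    return loglik, score, info


def negative_log_partial_likelihood(
    beta: np.ndarray, design: CoxDesign, ties: str = "efron"
) -> float:
    return -partial_likelihood_parts(beta, design, ties)[0]


@dataclass(frozen=True)
class CoxFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    ties: str
    column_names: tuple[str, ...]
    dropped_columns: tuple[str, ...] = ()
    codebook: VariableCodebook | None = None
    variables: tuple[str, ...] = ()
    iteration_trace: tuple[float, ...] = field(default=(), repr=False)

    def summary_frame(self):
        import pandas as pd

        z, pvals = wald_statistics(self)
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "exp(coef)": hazard_ratios(self),
                "se(coef)": self.standard_errors,
                "z": z,
                "p": pvals,
            },
            index=list(self.column_names),
        )


def fit_cox(
    design: CoxDesign,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson with step-halving on the log partial likelihood.

    Convergence: max |score| < tol. The covariance is the inverse observed
    information at the optimum. A singular information matrix (monotone
    likelihood / separation) is reported as a warning, with a
    pseudo-inverse covariance.
    """
    if design.event.sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    keep = [
        c for c in range(design.X.shape[1])
        if np.ptp(design.X[:, c]) > 0
    ]
    dropped = tuple(
        design.column_names[c]
        for c in range(design.X.shape[1])
        if c not in keep
    )
    if dropped:
        warnings.warn(
            f"dropping constant column(s): {list(dropped)}", stacklevel=2
        )
    sub = CoxDesign(
        design.X[:, keep],
        design.time,
        design.event,
        tuple(design.column_names[c] for c in keep),
        codebook=design.codebook,
        variables=design.variables,
    )
    p = sub.X.shape[1]
    beta = np.zeros(p)
    loglik, score, info = partial_likelihood_parts(beta, sub, ties)
    loglik_null = loglik
    trace = [loglik]
    converged = bool(p == 0 or np.max(np.abs(score)) < tol)
    it = 0
    while not converged and it < max_iter:
        it += 1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        new_beta, new = beta + step, None
        for _ in range(11):  # up to 10 halvings
            new = partial_likelihood_parts(new_beta, sub, ties)
            if new[0] >= loglik - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta = new_beta
        loglik, score, info = new
        trace.append(loglik)
        if np.max(np.abs(score)) < tol:
            converged = True
    if not converged:
        warnings.warn(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(trace: {[round(v, 6) for v in trace]})",
            stacklevel=2,
        )
    if p:
        try:
            cov_sub = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular information matrix (possible monotone likelihood / "
                "separation); using pseudo-inverse covariance",
                stacklevel=2,
            )
            cov_sub = np.linalg.pinv(info)
    else:
        cov_sub = np.zeros((0, 0))

    # re-expand to the full column set; dropped columns get coef 0, se NaN
    p_full = design.X.shape[1]
    coef = np.zeros(p_full)
    se = np.full(p_full, np.nan)
    cov = np.full((p_full, p_full), np.nan)
    keep_arr = np.array(keep, dtype=int)
    if p:
        coef[keep_arr] = beta
        se[keep_arr] = np.sqrt(np.clip(np.diag(cov_sub), 0, None))
        cov[np.ix_(keep_arr, keep_arr)] = cov_sub
    return CoxFit(
        coefficients=coef,
        standard_errors=se,
        covariance=cov,
        loglik=float(loglik),
        loglik_null=float(loglik_null),
        n_iter=it,
        converged=converged,
        ties=ties,
        column_names=design.column_names,
        dropped_columns=dropped,
        codebook=design.codebook,
        variables=design.variables,
        iteration_trace=tuple(trace),
    )


def hazard_ratios(fit: CoxFit) -> np.ndarray:
    return np.exp(fit.coefficients)


def wald_statistics(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient Wald z = coef/se and two-sided normal p-value."""
    se = fit.standard_errors
    if np.any(se[~np.isnan(se)] == 0):
        raise ZeroDivisionError("zero standard error in Wald statistic")
    with np.errstate(invalid="ignore"):
        z = fit.coefficients / se
    z = np.where(np.isnan(se), 0.0, z)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return z, pvals


@dataclass(frozen=True)
class UnivariateTestResult:
    variable: str
    lr: float
    df: int
    p_value: float


def univariate_lr_test(
    cohort: Cohort, v: str, ties: str = "efron"
) -> UnivariateTestResult:
    """Likelihood-ratio screen of a single categorical predictor.

    LR = 2 * (fitted - null log partial likelihood); df is the number of
    observed non-reference levels; p from the chi-square distribution.
    """
    j = cohort.codebook.index_of(v)
    observed = np.unique(cohort.levels[:, j])
    if observed.size < 2:
        raise ValueError(f"variable {v!r} has a single observed level")
    design = dummy_encode(cohort, [v])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cox(design, ties=ties)
    df = int(observed.size - 1)
    lr = max(0.0, 2.0 * (fit.loglik - fit.loglik_null))
    return UnivariateTestResult(v, lr, df, float(stats.chi2.sf(lr, df)))


# --------------------------------------------------------------------------
# baseline hazard and prediction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineSurvival:
    """Breslow step estimates of H0 and S0 at the ordered event times."""

    times: np.ndarray
    cumulative_hazard: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S0 as a right-continuous step function; S0(t) = 1 before the
        first event, last value carried beyond the final event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def breslow_baseline(fit: CoxFit, design: CoxDesign) -> BaselineSurvival:
    """Breslow increments d_t / sum_{risk set} exp(beta' x)."""
    eta = linear_predictors_from_design(fit, design)
    w = np.exp(eta)
    order = np.argsort(design.time, kind="stable")
    t_sorted = design.time[order]
    e_sorted = design.event[order]
    w_sorted = w[order]
    # risk set at t = records with time >= t: suffix sums
    suffix = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    times, haz = [], []
    i, n = 0, design.n
    while i < n:
        t = t_sorted[i]
        at_risk = suffix[i]
        d = 0
        while i < n and t_sorted[i] == t:
            d += int(e_sorted[i])
            i += 1
        if d:
            times.append(t)
            haz.append(d / at_risk)
    H0 = np.cumsum(haz)
    return BaselineSurvival(
        np.asarray(times, dtype=float), H0, np.exp(-H0)
    )


def _kept_mask(fit: CoxFit) -> np.ndarray:
    return ~np.isnan(fit.standard_errors) | (fit.coefficients != 0)


def linear_predictors_from_design(fit: CoxFit, design: CoxDesign) -> np.ndarray:
    coef = np.where(np.isnan(fit.coefficients), 0.0, fit.coefficients)
    return design.X @ coef


def linear_predictors(fit: CoxFit, cohort: Cohort) -> np.ndarray:
    """beta' x for every cohort record (dropped columns contribute 0)."""
    design = dummy_encode(cohort, list(fit.variables))
    return linear_predictors_from_design(fit, design)


def predict_survival_probability(
    fit: CoxFit,
    baseline: BaselineSurvival,
    record: PatientRecord,
    horizon: float,
) -> float:
    """S(horizon | x) = S0(horizon) ** exp(beta' x)."""
    if baseline.times.size and horizon > baseline.times[-1]:
        warnings.warn(
            f"horizon {horizon} beyond last event time "
            f"{baseline.times[-1]}; carrying the last baseline value",
            stacklevel=2,
        )
    if fit.codebook is None:
        raise ValueError("fit carries no codebook; encode manually")
    x = encode_record(fit.codebook, fit.variables, record)
    coef = np.where(np.isnan(fit.coefficients), 0.0, fit.coefficients)
    lp = float(x @ coef)
    return baseline.survival_at(horizon) ** np.exp(lp)
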