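"""Five-year survival modelling: median dichotomization, dataset assembly
and Cox proportional-hazards fitting.

The Cox partial likelihood is maximized by Newton-Raphson with Breslow
handling of tied event times.  Wald 95% confidence intervals are
exp(β̂ ± 1.96·SE).  Monotone likelihood (complete separation) and
non-convergence are flagged explicitly and never reported as a finite
hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import apply_exclusions

__all__ = [
    "MULTIVARIABLE_COVARIATES",
    "CoxResult",
    "HazardEstimate",
    "dichotomize_at_median",
    "build_survival_dataset",
    "cox_fit",
]

#: Adjustment covariates of the multivariable model: age (continuous),
#: T-stage, N-stage, grade, adjuvant chemotherapy, vascular and lymphatic
#: invasion, perineural growth; morphology is added for entire-cohort
#: analyses only.
MULTIVARIABLE_COVARIATES = (
    "age", "t_stage", "n_stage", "grade", "adjuvant",
    "vascular_invasion", "lymphatic_invasion", "perineural_growth",
)


def dichotomize_at_median(values: pd.Series) -> pd.Series:
    """Median split into ``high``/``low``.

    high ⇔ value strictly above the median of non-missing values; values
    equal to the median go to ``low``; missing values stay missing.
    """
    v = pd.Series(values, dtype=float)
    nonmiss = v.dropna()
    if nonmiss.size < 2:
        raise ValueError("need at least 2 non-missing values to dichotomize")
    med = float(nonmiss.median())
    out = pd.Series(pd.NA, index=v.index, dtype="object")
    out[v.notna()] = np.where(v[v.notna()] > med, "high", "low")
    return out


_BINARY_CODING = {
    "t_stage": ("T1_T2", "T3_T4"),
    "n_stage": ("negative", "positive"),
    "grade": ("well_moderate", "poor"),
    "morphology": ("I-type", "PB-type"),
}


def build_survival_dataset(
    clinical: pd.DataFrame,
    exposure: pd.Series,
    stratum: str = "all",
    cap: float = 60.0,
    covariates: tuple[str, ...] = MULTIVARIABLE_COVARIATES,
) -> pd.DataFrame:
    """Assemble the per-case dataset for Cox modelling.

    Applies the survival exclusions, restricts to the requested morphology
    stratum, caps follow-up at `cap` months (deaths after the cap are
    recoded as censored at the cap), numerically codes the covariates and
    drops cases with missing covariates or missing exposure.  Morphology
    enters as a covariate only for entire-cohort analyses.
    """
    excl = apply_exclusions(clinical)
    df = excl.survival.copy()
    if stratum != "all":
        df = df[df["morphology"] == stratum]

    time = df["os_months"].astype(float).clip(upper=cap)
    event = df["event"].astype(bool) & (df["os_months"].astype(float) <= cap)
    data = pd.DataFrame({"case_id": df["case_id"], "time": time,
                         "event": event})

    cov_list = list(covariates)
    if stratum == "all" and "morphology" not in cov_list:
        cov_list.append("morphology")
    for cov in cov_list:
        if cov == "age":
            data["age"] = df["age"].astype(float)
        elif cov in _BINARY_CODING:
            ref, alt = _BINARY_CODING[cov]
            col = df[cov].astype(str)
            coded = pd.Series(np.nan, index=df.index)
            coded[col == ref] = 0.0
            coded[col == alt] = 1.0
            data[cov] = coded
        else:
            data[cov] = df[cov].astype(float)

    data = data.set_index("case_id")
    data["exposure"] = exposure.reindex(data.index)
    if data["exposure"].dtype == object:
        data["exposure"] = data["exposure"].map({"low": 0.0, "high": 1.0})
    data = data.dropna()
    if len(data) and not data["event"].any():
        raise ValueError("no events after filtering")
    data["time"] = data["time"].clip(lower=1e-6)  # 0 < time <= cap
    return data.reset_index()


@dataclass
class HazardEstimate:
    variable: str
    stratum: str
    model: str
    hr: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    p: float = np.nan
    flag: str = ""


@dataclass
class CoxResult:
    coef: pd.Series
    se: pd.Series
    loglik: float
    n: int
    n_events: int
    converged: bool
    flag: str = ""  # "", "separation", "no_convergence"
    n_iter: int = 0
    covariance: np.ndarray | None = field(default=None, repr=False)

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.coef)

    def hazard_estimate(self, variable: str = "exposure",
                        stratum: str = "all",
                        model: str = "univariable") -> HazardEstimate:
        from scipy.stats import norm
        if self.flag:
            return HazardEstimate(variable=variable, stratum=stratum,
                                  model=model, hr=np.nan, ci_low=0.0,
                                  ci_high=np.inf, n=self.n,
                                  n_events=self.n_events, flag=self.flag)
        b = float(self.coef[variable])
        s = float(self.se[variable])
        z = b / s if s > 0 else np.nan
        with np.errstate(over="ignore"):
            return HazardEstimate(
                variable=variable, stratum=stratum, model=model,
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.959963984540054 * s)),
                ci_high=float(np.exp(b + 1.959963984540054 * s)),
                n=self.n, n_events=self.n_events,
                p=float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            )


def _breslow_loglik(beta, X, time, event):
    """Breslow partial log-likelihood, gradient and Hessian.

    Rows must be sorted by ascending time; the risk set at an event time t
    is every subject with time >= t.
    """
    eta = X @ beta
    eta = eta - eta.max()  # stabilise exp; constant shift cancels
    w = np.exp(eta)
    # Suffix (reverse cumulative) sums over the sorted order.
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    xxw = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    s2 = np.cumsum(xxw[::-1], axis=0)[::-1]

    # First index of each distinct event time (ascending sort -> suffix sums
    # at that index cover the full risk set).
    ev_idx = np.flatnonzero(event)
    if ev_idx.size == 0:
        raise ValueError("no events")
    t_ev = time[ev_idx]
    uniq_t, inv = np.unique(t_ev, return_inverse=True)
    d = np.bincount(inv).astype(float)
    first_u = np.searchsorted(time, uniq_t, side="left")

    ll = float(eta[ev_idx].sum() - (d * np.log(s0[first_u])).sum())
    grad = X[ev_idx].sum(axis=0) - (d[:, None] * s1[first_u] /
                                    s0[first_u, None]).sum(axis=0)
    p = X.shape[1]
    hess = np.zeros((p, p))
    for j in range(uniq_t.size):
        i = first_u[j]
        mean = s1[i] / s0[i]
        hess -= d[j] * (s2[i] / s0[i] - np.outer(mean, mean))
    return ll, grad, hess


_SEPARATION_COEF = 15.0
_SEPARATION_SE = 50.0


def cox_fit(
    data: pd.DataFrame,
    covariate_cols: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    Newton-Raphson on the Breslow partial likelihood with step halving;
    convergence when the log-likelihood improves by less than `tol`.
    Raises on a singular (collinear) covariate matrix, naming the
    offending columns; monotone likelihood is flagged, not reported as a
    finite hazard ratio.
    """
    df = data.sort_values(duration_col, kind="mergesort").reset_index(drop=True)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=bool)
    X = df[covariate_cols].to_numpy(dtype=float)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("no events")

    center = X.mean(axis=0)
    Xc = X - center
    # Collinearity check via QR of the centered design.
    r = np.linalg.qr(Xc, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [covariate_cols[i] for i in range(p) if diag[i] < 1e-10 * scale]
    if bad:
        raise ValueError("singular covariate matrix; collinear or "
                         f"constant column(s): {bad}")

    beta = np.zeros(p)
    ll, grad, hess = _breslow_loglik(beta, Xc, time, event)
    converged = False
    flag = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            flag = "separation"
            break
        new_beta = beta + step
        new_ll, new_grad, new_hess = _breslow_loglik(new_beta, Xc, time, event)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = _breslow_loglik(new_beta, Xc, time, event)
            halvings += 1
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta).max() > _SEPARATION_COEF:
            flag = "separation"
            break
        if abs(delta) < tol:
            converged = True
            break
    if not converged and not flag:
        flag = "no_convergence"
    # Monotone likelihood plateaus, so |Δloglik| < tol can trigger the
    # convergence test at an extreme, still-diverging coefficient.  Treat a
    # huge |β̂| or a huge Wald SE as separation rather than a finite HR.
    if converged and np.abs(beta).max() > _SEPARATION_COEF:
        flag = "separation"
        converged = False

    if flag:
        se = np.full(p, np.nan)
        cov = None
    else:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)) or se.max() > _SEPARATION_SE:
            flag = "separation"
            converged = False
            se = np.full(p, np.nan)
            cov = None

    return CoxResult(
        coef=pd.Series(beta, index=covariate_cols),
        se=pd.Series(se, index=covariate_cols),
        loglik=ll, n=n, n_events=n_events,
        converged=converged, flag=flag, n_iter=it, covariance=cov,
    )
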