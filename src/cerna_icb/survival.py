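"""ceRNA-signature survival risk score and stratification.

Each signature feature gets a univariate Cox proportional-hazards
coefficient (Newton--Raphson on the Efron-tie-corrected partial
likelihood, implemented here); a patient's risk score is the
coefficient-weighted sum of normalized expression,

    RS = sum_i expression_i * coefficient_i,

with expression on the log2(size-factor-normalized + 1) scale, z-scored
per feature.  Patients are split into high and low risk at the median
score and the groups are compared with Kaplan--Meier curves and the
two-group log-rank test (delegated to lifelines).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from sklearn.base import BaseEstimator

__all__ = [
    "CoxRiskScore",
    "fit_univariate_cox",
    "compute_risk_score",
    "stratify",
    "km_curve",
    "logrank_test",
]

_COEF_CAP = 10.0


def _efron_derivatives(beta: float, x, times, events):
    """Efron log partial likelihood and its first two derivatives."""
    order = np.argsort(-times, kind="stable")  # descending time
    x = x[order]
    t = times[order]
    d = events[order]
    eb = np.exp(beta * x)
    # cumulative risk-set sums walking down in time
    cs0 = np.cumsum(eb)
    cs1 = np.cumsum(x * eb)
    cs2 = np.cumsum(x * x * eb)
    ll = grad = hess = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # block [i, j) shares one time; risk set = everything up to j-1
        ev = slice(i, j)
        dmask = d[ev] == 1
        dd = int(dmask.sum())
        if dd > 0:
            xe = x[ev][dmask]
            ee = eb[ev][dmask]
            s0r, s1r, s2r = cs0[j - 1], cs1[j - 1], cs2[j - 1]
            s0d, s1d, s2d = ee.sum(), (xe * ee).sum(), (xe * xe * ee).sum()
            ll += beta * xe.sum()
            for l in range(dd):
                c = l / dd
                phi = s0r - c * s0d
                dphi = s1r - c * s1d
                d2phi = s2r - c * s2d
                ll -= np.log(phi)
                grad_term = dphi / phi
                grad -= grad_term
                hess -= d2phi / phi - grad_term**2
            grad += xe.sum()
        i = j
    return ll, grad, hess


def fit_univariate_cox(
    x,
    times,
    events,
    tol: float = 1e-8,
    max_iter: int = 50,
    cap: float = _COEF_CAP,
) -> dict:
    """Univariate Cox PH fit with Efron tie handling.

    Parameters
    ----------
    x
        One covariate value per patient (normalized expression).
    times, events
        Right-censored survival data; at least two events required.

    Returns
    -------
    dict with ``coef``, ``se``, ``converged`` and ``flag``
    (``""``, ``"untestable"`` for zero-variance covariates — coefficient
    0 — or ``"separation"`` when the partial likelihood is monotone and
    the coefficient is capped at +/-``cap``).
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(x) == len(times) == len(events)):
        raise ValueError("x, times and events must share one length")
    if events.sum() < 2:
        raise ValueError("at least two events are required")
    if np.std(x) == 0.0:
        return {"coef": 0.0, "se": np.nan, "converged": True,
                "flag": "untestable"}

    beta = 0.0
    converged = False
    flag = ""
    ll, grad, hess = _efron_derivatives(beta, x, times, events)
    for _ in range(max_iter):
        if hess >= 0:  # degenerate curvature
            break
        step = -grad / hess
        # step-halving to guarantee likelihood ascent
        new_beta = beta + step
        for _ in range(20):
            new_ll, new_grad, new_hess = _efron_derivatives(
                new_beta, x, times, events
            )
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(beta) > cap:  # monotone likelihood / separation
            beta = float(np.clip(beta, -cap, cap))
            ll, grad, hess = _efron_derivatives(beta, x, times, events)
            flag = "separation"
            break
        if abs(step) < tol:
            converged = True
            break
    se = float(np.sqrt(-1.0 / hess)) if hess < 0 else np.nan
    return {"coef": float(beta), "se": se, "converged": converged,
            "flag": flag}


def compute_risk_score(
    expression: pd.DataFrame, coefficients: pd.Series
) -> pd.Series:
    """RS = sum_i expression_i * coefficient_i per patient.

    ``expression`` is signature-features x patients; every coefficient's
    feature must be present with finite values.
    """
    coefficients = pd.Series(coefficients)
    for fid in coefficients.index:
        if fid not in expression.index:
            raise ValueError(f"expression missing for feature {fid!r}")
    sub = expression.loc[coefficients.index]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)][0]
        raise ValueError(f"missing expression value for feature {bad!r}")
    scores = sub.T @ coefficients
    scores.name = "risk_score"
    return scores


def stratify(scores: pd.Series, cutoff="median") -> tuple[pd.Series, float]:
    """Split patients into high/low risk at a cutoff (default median).

    Scores strictly above the cutoff are ``high``; ties go to ``low``.
    Returns ``(labels, cutoff_value)``.
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("at least two patients are required")
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical: no stratification "
                         "possible")
    cut = float(scores.median()) if isinstance(cutoff, str) and \
        cutoff == "median" else float(cutoff)
    labels = pd.Series(
        np.where(scores > cut, "high", "low"), index=scores.index,
        name="risk_group",
    )
    return labels, cut


def km_curve(times, events, groups) -> dict[str, dict]:
    """Kaplan--Meier product-limit fit per group.

    Returns, per group label: the step function as a ``(time, survival)``
    DataFrame, the median survival (``inf`` when unreached) and its 95%
    confidence interval (Greenwood on the log(-log) scale; bounds may be
    unreached).  A cohort with no events yields flat curves at 1 — not an
    error.
    """
    times = pd.Series(np.asarray(times, dtype=float))
    events = pd.Series(np.asarray(events, dtype=int))
    groups = pd.Series(np.asarray(groups, dtype=object))
    out: dict[str, dict] = {}
    for g in sorted(groups.unique()):
        sel = (groups == g).to_numpy()
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        surv = kmf.survival_function_.reset_index()
        surv.columns = ["time", "survival"]
        median = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = (float(ci.iloc[0, 0]), float(ci.iloc[0, 1]))
        out[str(g)] = {
            "survival": surv,
            "median": median,
            "median_ci": (lo, hi),
            "n": int(sel.sum()),
            "events": int(events[sel].sum()),
        }
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a = groups == labels[0]
    b = groups == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both groups must be nonempty")
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    res = _ll_logrank(times[a], times[b], events[a], events[b])
    return float(res.test_statistic), float(res.p_value)


class CoxRiskScore(BaseEstimator):
    """Univariate-Cox-weighted expression signature risk model.

    :meth:`fit` takes normalized expression
    (log2(size-factor-scaled + 1)), z-scores each feature across the
    training patients, fits one univariate Cox model per feature against
    the chosen endpoint, and stores the coefficients; risk scores are
    the coefficient-weighted sums, and patients split into high/low risk
    at the (default median) cutoff.

    Parameters
    ----------
    cutoff
        ``"median"`` or an explicit score value.
    zscore
        Z-score features across patients before fitting (default True).
    cap
        Coefficient cap under monotone partial likelihood (default 10).

    Attributes
    ----------
    coef_ : pd.Series
        Per-feature Cox coefficients (log hazard per unit expression).
    se_, flags_ : pd.Series
    risk_scores_ : pd.Series
    groups_ : pd.Series of {"high", "low"}
    cutoff_ : float
    """

    def __init__(self, cutoff="median", zscore: bool = True,
                 cap: float = _COEF_CAP):
        self.cutoff = cutoff
        self.zscore = zscore
        self.cap = cap

    def _transform_X(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.zscore:
            return X
        return (X.sub(self.feature_mean_, axis=0)).div(self.feature_scale_,
                                                       axis=0)

    def fit(self, X: pd.DataFrame, times, events):
        """Fit on normalized expression (features x patients)."""
        if X.shape[0] < 1:
            raise ValueError("at least one signature feature is required")
        if X.shape[1] > 0 and X.shape[0] > X.shape[1]:
            warnings.warn(
                f"fitting {X.shape[0]} per-feature Cox models on only "
                f"{X.shape[1]} patients: coefficients will be unstable",
                UserWarning,
                stacklevel=2,
            )
        self.feature_mean_ = X.mean(axis=1)
        scale = X.std(axis=1, ddof=0)
        self.feature_scale_ = scale.where(scale > 0, 1.0)
        Z = self._transform_X(X)
        t = pd.Series(np.asarray(times, dtype=float), index=X.columns)
        e = pd.Series(np.asarray(events, dtype=int), index=X.columns)

        fits = {
            fid: fit_univariate_cox(Z.loc[fid].to_numpy(), t.to_numpy(),
                                    e.to_numpy(), cap=self.cap)
            for fid in Z.index
        }
        self.coef_ = pd.Series({f: r["coef"] for f, r in fits.items()},
                               name="coefficient")
        self.se_ = pd.Series({f: r["se"] for f, r in fits.items()}, name="se")
        self.flags_ = pd.Series({f: r["flag"] for f, r in fits.items()},
                                name="flag")
        self.risk_scores_ = compute_risk_score(Z, self.coef_)
        self.groups_, self.cutoff_ = stratify(self.risk_scores_, self.cutoff)
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Risk scores for new patients (training normalization reused)."""
        if not hasattr(self, "coef_"):
            raise ValueError("CoxRiskScore is not fitted yet")
        return compute_risk_score(self._transform_X(X), self.coef_)

    def predict_group(self, X: pd.DataFrame) -> pd.Series:
        scores = self.predict(X)
        return pd.Series(
            np.where(scores > self.cutoff_, "high", "low"),
            index=scores.index, name="risk_group",
        )

    def evaluate(self, times, events) -> dict:
        """KM fits and log-rank test of the fitted high/low split."""
        km = km_curve(times, events, self.groups_.to_numpy())
        stat, p = logrank_test(times, events, self.groups_.to_numpy())
        return {"km": km, "logrank_statistic": stat, "logrank_p": p}
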