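"""Cox immune-cell risk signature and survival comparison.

The risk score of a sample is the linear predictor ``sum_k beta_k * a_k``
over the driven cells ``S`` of a chosen mutation gene, with ``beta_k`` the
coefficients of a multivariate Cox proportional-hazards model fitted on the
cell abundances and overall survival. Patients are split at the median risk
score into high- and low-risk groups and compared with the log-rank test.

The Cox partial likelihood is maximised by Newton-Raphson with step-halving;
tied event times use the Breslow approximation by default (Efron available
via ``ties=``). Convergence requires every component of the score vector to
fall below 1e-6; the inverse observed information provides standard errors
and Wald confidence intervals.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError

MAX_ITER = 100
SCORE_TOL = 1e-6


def _prepare_design(abundance_subset: pd.DataFrame, survival: pd.DataFrame):
    """Align samples, drop zero-variance and collinear cells.

    ``abundance_subset`` is cells x samples; returns (X samples x p, kept
    cell ids, time, event).
    """
    shared = [s for s in abundance_subset.columns if s in survival.index]
    if len(shared) < 4:
        raise ValidationError("too few samples shared between abundance and survival data")
    ab = abundance_subset.loc[:, shared]
    surv = survival.loc[shared]
    if int(surv["event"].sum()) < 10:
        warnings.warn("fewer than 10 observed events; Cox estimates will be unstable",
                      stacklevel=3)

    sd = ab.to_numpy(dtype=np.float64).std(axis=1)
    dropped = list(ab.index[sd == 0])
    if dropped:
        warnings.warn(f"cells with zero variance dropped from the Cox model: {dropped}",
                      stacklevel=3)
        ab = ab.loc[sd > 0]
    if ab.shape[0] == 0:
        raise ValidationError("no cells with nonzero variance to fit")

    X = ab.to_numpy(dtype=np.float64).T
    keep: list[int] = []
    # Greedy rank check: drop later-indexed columns that are linear
    # combinations of earlier ones (within fp tolerance).
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand - cand.mean(axis=0), tol=1e-10 * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    collinear = [ab.index[j] for j in range(X.shape[1]) if j not in keep]
    if collinear:
        warnings.warn(f"collinear cells dropped from the Cox model: {collinear}", stacklevel=3)
    cells = list(ab.index[keep])
    return X[:, keep], cells, surv["time"].to_numpy(float), surv["event"].to_numpy(int), shared


def _cox_loglik(beta, X, time, event, ties="breslow"):
    """(loglik, score, information) of the Cox partial likelihood."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # descending time
    Xo, to, eo = X[order], time[order], event[order]
    eta = Xo @ beta
    eta = eta - eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * Xo
    wxx = wx[:, :, None] * Xo[:, None, :]

    # cumulative risk-set aggregates: at index i, everything with time >= to[i]
    S0 = np.cumsum(w)
    S1 = np.cumsum(wx, axis=0)
    S2 = np.cumsum(wxx, axis=0)
    # extend risk set over tied times: use the last index of each tied block
    last = np.empty(n, dtype=np.intp)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and to[j + 1] == to[i]:
            j += 1
        last[i : j + 1] = j
        i = j + 1

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    ev_idx = np.nonzero(eo == 1)[0]
    if ties == "breslow":
        for i in ev_idx:
            k = last[i]
            s0, s1, s2 = S0[k], S1[k], S2[k]
            ll += eta[i] - np.log(s0)
            score += Xo[i] - s1 / s0
            info += s2 / s0 - np.outer(s1, s1) / s0**2
    elif ties == "efron":
        i = 0
        while i < n:
            k = last[i]
            tied = [j for j in range(i, k + 1) if eo[j] == 1]
            dcount = len(tied)
            if dcount:
                s0, s1, s2 = S0[k], S1[k], S2[k]
                d0 = w[tied].sum()
                d1 = wx[tied].sum(axis=0)
                d2 = wxx[tied].sum(axis=0)
                for r, j in enumerate(tied):
                    f = r / dcount
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll += eta[j] - np.log(a0)
                    score += Xo[j] - a1 / a0
                    info += a2 / a0 - np.outer(a1, a1) / a0**2
            i = k + 1
    else:
        raise ValidationError(f"unknown ties method {ties!r}")
    return ll, score, info


def fit_cox(
    abundance_subset: pd.DataFrame,
    survival: pd.DataFrame,
    ties: str = "breslow",
) -> "CoxFit":
    """Fit the multivariate Cox model of survival on cell abundances.

    ``abundance_subset`` is cells x samples; ``survival`` is indexed by
    sample with columns time, event. Returns the fitted coefficients with
    their covariance; raises ``ConvergenceError`` after 100 iterations.
    """
    X, cells, time, event, samples = _prepare_design(abundance_subset, survival)
    if event.sum() < 1:
        raise ValidationError("no observed events")
    p = X.shape[1]
    center = X.mean(axis=0)
    Xc = X - center  # centering improves conditioning; beta unchanged
    beta = np.zeros(p)
    ll, score, info = _cox_loglik(beta, Xc, time, event, ties)
    for _ in range(MAX_ITER):
        if np.max(np.abs(score)) < SCORE_TOL:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix in Cox fit; "
                                   "try fewer cells") from exc
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik(new_beta, Xc, time, event, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-10) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik(new_beta, Xc, time, event, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
    else:
        raise ConvergenceError(
            "Cox fit did not converge in 100 iterations; consider fewer cells"
        )
    cov = np.linalg.inv(info)
    return CoxFit(
        params=pd.Series(beta, index=pd.Index(cells, name="cell"), name="beta"),
        cov=pd.DataFrame(cov, index=cells, columns=cells),
        loglik=float(ll),
        ties=ties,
        n=len(time),
        n_events=int(event.sum()),
        samples=samples,
    )


@dataclasses.dataclass
class CoxFit:
    """Fitted Cox coefficients with covariance and fit metadata."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    ties: str
    n: int
    n_events: int
    samples: list[str]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index,
                         name="se")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        zq = norm.ppf(1 - alpha / 2)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - zq * se, "upper": self.params + zq * se},
            index=self.params.index,
        )


def risk_scores(beta: pd.Series, abundance_subset: pd.DataFrame) -> pd.Series:
    """Per-sample risk score: the exact sum of beta_k times abundance a_k."""
    missing = [c for c in beta.index if c not in abundance_subset.index]
    if missing:
        raise ValidationError(f"abundance matrix lacks cells {missing}")
    ab = abundance_subset.loc[beta.index]
    scores = beta.to_numpy(dtype=np.float64) @ ab.to_numpy(dtype=np.float64)
    return pd.Series(scores, index=ab.columns, name="risk_score")


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median)."""
    if len(scores) < 4:
        raise ValidationError("median split needs >=4 samples")
    values = scores.to_numpy(dtype=np.float64)
    if np.all(values == values[0]):
        raise ValidationError("degenerate signature: all risk scores identical")
    med = float(np.median(values))
    return pd.Series(np.where(values > med, "high", "low"), index=scores.index, name="group")


def log_rank(groups: pd.Series, survival: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    from lifelines.statistics import logrank_test

    shared = [s for s in groups.index if s in survival.index]
    g = groups.loc[shared]
    surv = survival.loc[shared]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 non-empty groups, got {list(labels)}")
    if int(surv["event"].sum()) < 1:
        raise ValidationError("log-rank needs at least one observed event")
    m0 = g == labels[0]
    res = logrank_test(
        surv.loc[m0, "time"], surv.loc[~m0, "time"],
        event_observed_A=surv.loc[m0, "event"], event_observed_B=surv.loc[~m0, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier survival estimate as a step table (time, survival, at_risk).

    Right-continuous, nonincreasing, and equal to 1 before the first event.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    sf = kmf.survival_function_
    out = pd.DataFrame({"time": sf.index.to_numpy(float),
                        "survival": sf.iloc[:, 0].to_numpy(float)})
    out["at_risk"] = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
    return out
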