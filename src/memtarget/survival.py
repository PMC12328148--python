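"""Survival and mutation statistics used as cohort- and marker-level gates.

Kaplan-Meier product-limit curves, the k-group log-rank test with
hypergeometric variance, univariate Cox proportional-hazards regression
(Breslow tie handling, Newton-Raphson with step-halving on the partial
likelihood), the Cox score test, and per-gene 2x2 chi-square / Fisher
association between mutation status and lymph-node metastasis.

KM, log-rank and Cox are implemented directly so their numerical contracts
(monotone likelihood ascent, explicit non-convergence flags, tied-event
handling) are observable; tests cross-check them against independent
implementations.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ClinicalTable, ExpressionMatrix, MutationTable


def _as_survival_arrays(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1-D and equal length")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate for one group: S(t) at each distinct event time."""

    label: str
    times: np.ndarray  # distinct event times, ascending
    n_risk: np.ndarray  # at-risk count just before each event time
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S = 1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclasses.dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclasses.dataclass
class CoxFit:
    """Univariate Cox fit: log hazard ratio and Wald inference."""

    beta: float
    hazard_ratio: float
    se: float
    p_value: float
    converged: bool
    n_iter: int
    log_likelihood: float


@dataclasses.dataclass
class ScoreTestResult:
    chi_square: float
    df: int
    p_value: float


def km_estimate(times, events, group_labels=None) -> list[KMCurve]:
    """Kaplan-Meier product-limit estimator, one curve per group.

    Tied events at a time t contribute a single factor (1 - d/n).  A group
    with only censored observations yields a flat S = 1 curve.
    """
    times, events = _as_survival_arrays(times, events)
    if times.size == 0:
        raise ValueError("no observations")
    if group_labels is None:
        group_labels = np.zeros(times.size, dtype=int)
    group_labels = np.asarray(group_labels)
    curves = []
    for label in pd.unique(group_labels):
        mask = group_labels == label
        if not mask.any():
            raise ValueError(f"group {label!r} is empty")
        t, e = times[mask], events[mask]
        event_times = np.unique(t[e == 1])
        n_risk = np.array([(t >= et).sum() for et in event_times], dtype=int)
        d = np.array([((t == et) & (e == 1)).sum() for et in event_times], dtype=int)
        with np.errstate(divide="ignore", invalid="ignore"):
            surv = np.cumprod(1.0 - d / n_risk) if event_times.size else np.array([])
        curves.append(
            KMCurve(
                label=str(label),
                times=event_times,
                n_risk=n_risk,
                n_events=d,
                survival=surv,
            )
        )
    return curves


def logrank_test(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test (observed minus expected, hypergeometric variance)."""
    times, events = _as_survival_arrays(times, events)
    group_labels = np.asarray(group_labels)
    labels = pd.unique(group_labels)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    for label in labels:
        if not (group_labels == label).any():
            raise ValueError(f"group {label!r} is empty")

    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    covariance = np.zeros((k, k))
    for et in event_times:
        at_risk = times >= et
        n = at_risk.sum()
        dying = (times == et) & (events == 1)
        d = dying.sum()
        n_j = np.array([(at_risk & (group_labels == label)).sum() for label in labels])
        d_j = np.array([(dying & (group_labels == label)).sum() for label in labels])
        observed += d_j
        expected += d * n_j / n
        if n > 1:
            frac = n_j / n
            factor = d * (n - d) / (n - 1.0)
            covariance += factor * (np.diag(frac) - np.outer(frac, frac))

    u = (observed - expected)[: k - 1]
    v = covariance[: k - 1, : k - 1]
    if u.size == 0 or not np.any(v):
        chi = 0.0
    else:
        chi = float(u @ np.linalg.pinv(v) @ u)
    chi = max(chi, 0.0)
    df = k - 1
    return LogRankResult(chi_square=chi, df=df, p_value=float(stats.chi2.sf(chi, df)))


def _breslow_loglik_derivs(beta, times, events, x):
    """Gradient and information of the Breslow partial log-likelihood.

    Risk sets are suffix sums over samples sorted by time; subjects censored
    at an event time remain at risk for it.  The linear predictor is shifted
    by its maximum before exponentiation (overflow guard); the shift cancels
    in every ratio.
    """
    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    eta = beta * xv
    w = np.exp(eta - eta.max())
    # suffix sums: index i -> sum over subjects with time >= t[i]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]

    grad = info = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        d = 0
        x_sum = 0.0
        while j < n and t[j] == t[i]:
            if e[j] == 1:
                d += 1
                x_sum += xv[j]
            j += 1
        if d > 0:
            mean1 = s1[i] / s0[i]
            grad += x_sum - d * mean1
            info += d * (s2[i] / s0[i] - mean1 * mean1)
        i = j
    return grad, info


def _breslow_loglik(beta, times, events, x):
    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    w = np.exp(beta * xv)
    s0 = np.cumsum(w[::-1])[::-1]
    loglik = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        d = 0
        x_sum = 0.0
        while j < n and t[j] == t[i]:
            if e[j] == 1:
                d += 1
                x_sum += xv[j]
            j += 1
        if d > 0:
            loglik += beta * x_sum - d * math.log(s0[i])
        i = j
    return loglik


def cox_univariate(
    times, events, covariate, tol: float = 1e-8, max_iter: int = 50
) -> CoxFit:
    """Univariate Cox PH fit by Newton-Raphson on the Breslow partial likelihood.

    Step-halving enforces monotone likelihood ascent.  Monotone (perfectly
    separating) likelihoods are reported with ``converged=False`` rather
    than raising.
    """
    times, events = _as_survival_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != times.shape:
        raise ValueError("covariate length mismatch")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    beta = 0.0
    loglik = _breslow_loglik(beta, times, events, x)
    converged = False
    n_iter = 0
    info = np.nan
    for n_iter in range(1, max_iter + 1):
        grad, info = _breslow_loglik_derivs(beta, times, events, x)
        if info <= 0 or not math.isfinite(info):
            break
        step = grad / info
        new_beta = beta + step
        new_loglik = _breslow_loglik(new_beta, times, events, x)
        halvings = 0
        while (not math.isfinite(new_loglik) or new_loglik < loglik) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_loglik = _breslow_loglik(new_beta, times, events, x)
            halvings += 1
        beta, loglik = new_beta, new_loglik
        if abs(step) < tol:
            converged = True
            break
    if abs(beta) > 25:  # drifting to infinity: monotone likelihood
        converged = False
    _, info = _breslow_loglik_derivs(beta, times, events, x)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    return CoxFit(
        beta=float(beta),
        hazard_ratio=float(math.exp(beta)),
        se=float(se),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        converged=converged,
        n_iter=n_iter,
        log_likelihood=float(loglik),
    )


def cox_score_test(times, events, covariate) -> ScoreTestResult:
    """Cox score (Rao) test at beta = 0: U(0)^2 / I(0).

    For a binary covariate and untied event times this equals the two-group
    log-rank chi-square.
    """
    times, events = _as_survival_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    grad, info = _breslow_loglik_derivs(0.0, times, events, x)
    chi = grad * grad / info if info > 0 else 0.0
    return ScoreTestResult(chi_square=float(chi), df=1, p_value=float(stats.chi2.sf(chi, 1)))


def median_split(values: pd.Series) -> pd.Series:
    """High/low labels split at the median; ties at the median go to ``low``."""
    med = values.median()
    return pd.Series(
        np.where(values > med, "high", "low"), index=values.index, dtype=object
    )


def mutation_association(
    mutations: MutationTable,
    clinical: ClinicalTable,
    top_n: int = 20,
    method: str = "chisq",
) -> pd.DataFrame:
    """Association between mutation status and LN metastasis, top-``top_n`` genes.

    Genes are ranked by mutation frequency among tumor samples with known LN
    status; each gets a 2x2 table (mutated/wild-type x LN+/LN-) tested by
    Pearson chi-square without continuity correction (default) or Fisher's
    exact test (``method="fisher"``).  Tables with a zero margin are flagged
    ``degenerate`` with an undefined p.
    """
    if method not in ("chisq", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    met = clinical.tumor_samples("metastatic")
    nonmet = clinical.tumor_samples("non_metastatic")
    if not met or not nonmet:
        raise ValueError("need tumor samples in both LN groups")
    cohort = met + nonmet
    ind = mutations.indicator()
    present = [s for s in cohort if s in ind.columns]
    ind = ind.reindex(columns=cohort, fill_value=0) if present else pd.DataFrame(
        0, index=ind.index, columns=cohort
    )

    freq = ind.sum(axis=1) / len(cohort)
    ranked = freq.sort_values(ascending=False, kind="stable")
    # deterministic tie-break on gene name within equal frequencies
    ranked = ranked.iloc[
        np.lexsort((ranked.index.to_numpy(), -ranked.to_numpy()))
    ] if len(ranked) else ranked
    genes = list(ranked.index[:top_n])

    rows = []
    for gene in genes:
        mut_met = int(ind.loc[gene, met].sum())
        mut_non = int(ind.loc[gene, nonmet].sum())
        wt_met = len(met) - mut_met
        wt_non = len(nonmet) - mut_non
        table = np.array([[mut_met, mut_non], [wt_met, wt_non]])
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            chi, p = np.nan, np.nan
        elif method == "chisq":
            chi, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            chi = np.nan
            _, p = stats.fisher_exact(table)
        rows.append(
            {
                "gene": gene,
                "frequency": float(freq[gene]),
                "mut_met": mut_met,
                "mut_nonmet": mut_non,
                "wt_met": wt_met,
                "wt_nonmet": wt_non,
                "chi_square": chi,
                "p_value": p,
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "frequency",
            "mut_met",
            "mut_nonmet",
            "wt_met",
            "wt_nonmet",
            "chi_square",
            "p_value",
            "degenerate",
        ],
    )


def risk_ordered_view(
    expression_row: pd.Series, clinical: ClinicalTable
) -> pd.DataFrame:
    """Tumor samples ordered by descending expression with their PFS columns.

    Ties in expression break on ascending sample id, so the view is fully
    deterministic.  Mirrors a "risk curve" panel: expression rank on top,
    progression status alongside.
    """
    tumor = clinical.data[clinical.data["tissue"] == "tumor"]
    missing = [
        s
        for s in tumor["sample_id"]
        if s not in expression_row.index or pd.isna(expression_row[s])
    ]
    if missing:
        raise KeyError(f"expression missing for tumor samples: {missing[:5]}")
    view = pd.DataFrame(
        {
            "sample_id": tumor["sample_id"].to_numpy(),
            "expression": expression_row[tumor["sample_id"]].to_numpy(dtype=float),
            "pfs_time": tumor["pfs_time"].to_numpy(),
            "pfs_event": tumor["pfs_event"].to_numpy(),
            "ln_status": tumor["ln_status"].to_numpy(),
        }
    )
    return view.sort_values(
        ["expression", "sample_id"], ascending=[False, True]
    ).reset_index(drop=True)


def feature_survival_split(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    feature_id: str,
    endpoint: str = "os",
) -> tuple[LogRankResult, list[KMCurve]]:
    """Log-rank comparison of high vs low expressors of one feature.

    Tumor samples are stratified at the median abundance (ties to low).
    """
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    tumor = clinical.data[clinical.data["tissue"] == "tumor"].set_index("sample_id")
    expr = matrix.data.loc[feature_id, list(tumor.index)].dropna()
    tumor = tumor.loc[expr.index]
    groups = median_split(expr)
    times = tumor[f"{endpoint}_time"].to_numpy()
    events = tumor[f"{endpoint}_event"].to_numpy()
    return (
        logrank_test(times, events, groups.to_numpy()),
        km_estimate(times, events, groups.to_numpy()),
    )


def plot_km(curves: list[KMCurve], ax=None, title: str | None = None):
    """Step plot of KM curves (matplotlib imported lazily)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=curve.label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
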