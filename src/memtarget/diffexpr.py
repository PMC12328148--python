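"""Two-group differential expression with optional variance moderation.

The default statistic is the ordinary pooled-variance two-sample t on log2
values (so the effect size is a log2 fold-change: mean(group A) minus
mean(group B)), with two-sided p-values.  An opt-in empirical-Bayes step
shrinks per-feature variances toward a prior estimated by moment-matching
of the log residual variances against a scaled-F model (trigamma inversion
for the prior degrees of freedom d0, digamma correction for the prior
variance s0^2), the standard moderated-t construction: the posterior
variance is

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t carries d0 + d_g degrees of freedom.  With d0 = 0 the
moderated t reduces exactly to the ordinary t; with d0 = infinite every
feature shares the prior variance.

Calls follow fixed thresholds on the raw p-value and |log2FC|; features
with too few non-missing observations in either group are skipped, never
imputed.  Missing proteome entries are first-class throughout.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import ExpressionMatrix, Thresholds

RECORD_COLUMNS = ["feature_id", "log2_fc", "p_value", "n_a", "n_b", "call"]


@dataclasses.dataclass(frozen=True)
class ModerationState:
    """Empirical-Bayes prior for residual variances.

    ``d0`` is the prior degrees of freedom (``inf`` when the observed
    variances show no excess dispersion over pure chi-square sampling
    noise); ``s0_sq`` the prior variance.
    """

    d0: float
    s0_sq: float

    def posterior_variance(self, s_g_sq: np.ndarray, d_g: np.ndarray) -> np.ndarray:
        s_g_sq = np.asarray(s_g_sq, float)
        d_g = np.asarray(d_g, float)
        if math.isinf(self.d0):
            return np.full_like(s_g_sq, self.s0_sq)
        if self.d0 == 0:
            return s_g_sq.copy()
        return (self.d0 * self.s0_sq + d_g * s_g_sq) / (self.d0 + d_g)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def estimate_moderation(s_g_sq, d_g) -> ModerationState:
    """Moment-match (d0, s0^2) from observed residual variances.

    Under the scaled-F model, log s_g^2 has mean log s0^2 + digamma terms and
    excess variance trigamma(d0/2) beyond the sampling term trigamma(d_g/2);
    inverting the trigamma gives d0.  When the empirical variance of
    log s_g^2 does not exceed the sampling term, d0 = infinity (no excess
    dispersion) and s0^2 is the bias-corrected geometric mean.
    """
    s_g_sq = np.asarray(s_g_sq, float)
    d_g = np.asarray(d_g, float)
    if s_g_sq.ndim != 1 or s_g_sq.size < 2:
        raise ValueError("need at least two residual variances")
    if (s_g_sq <= 0).any():
        raise ValueError("residual variances must be positive")
    if (d_g < 1).any():
        raise ValueError("residual degrees of freedom must be >= 1")
    if d_g.size == 1:
        d_g = np.full_like(s_g_sq, d_g[()])
    z = np.log(s_g_sq)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1) - special.polygamma(1, d_g / 2.0).mean())
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModerationState(d0=d0, s0_sq=s0_sq)


def _classify(log2_fc, p_value, fc_cut, p_cut):
    if np.isnan(p_value):
        return "ns"
    if p_value < p_cut and log2_fc > fc_cut:
        return "up"
    if p_value < p_cut and log2_fc < -fc_cut:
        return "down"
    return "ns"


def two_group_t(
    matrix: ExpressionMatrix,
    group_a,
    group_b,
    thresholds: Thresholds | None = None,
    moderation: bool = False,
    fc_cut: float | None = None,
) -> pd.DataFrame:
    """Per-feature two-group comparison, group A minus group B on log2 scale.

    Returns one row per feature (input order preserved) with columns
    ``feature_id, log2_fc, p_value, n_a, n_b, call`` where ``call`` is one of
    ``up / down / ns / skipped``.  The fold-change cut defaults to the
    layer-appropriate threshold (0.585 for proteome, 1.0 for transcriptome).

    Conventions: a feature observed in fewer than ``min_obs_per_group``
    samples of either group is ``skipped`` with an undefined p-value; a
    feature with zero pooled variance has p = 1 when the group means agree
    (no evidence) and p = 0 when they differ.
    """
    thresholds = thresholds or Thresholds()
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if fc_cut is None:
        fc_cut = thresholds.fc_cut(matrix.layer_label)

    xa = matrix.data.loc[:, group_a].to_numpy(float)
    xb = matrix.data.loc[:, group_b].to_numpy(float)
    n_a = (~np.isnan(xa)).sum(axis=1)
    n_b = (~np.isnan(xb)).sum(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        mean_a = np.nanmean(xa, axis=1)
        mean_b = np.nanmean(xb, axis=1)
        var_a = np.nanvar(xa, axis=1, ddof=1)
        var_b = np.nanvar(xb, axis=1, ddof=1)

    log2_fc = mean_a - mean_b
    tested = (n_a >= thresholds.min_obs_per_group) & (n_b >= thresholds.min_obs_per_group)
    if not tested.any():
        warnings.warn("no feature passes min_obs_per_group in both groups; all skipped")

    d_g = (n_a + n_b - 2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_g_sq = ((n_a - 1) * var_a + (n_b - 1) * var_b) / d_g

    if moderation:
        idx = tested & (s_g_sq > 0)
        if idx.sum() >= 2:
            state = estimate_moderation(s_g_sq[idx], d_g[idx])
        else:
            state = ModerationState(d0=0.0, s0_sq=1.0)
        var_used = np.where(
            s_g_sq > 0, state.posterior_variance(np.where(s_g_sq > 0, s_g_sq, 1.0), d_g), 0.0
        )
        df_used = d_g + (0.0 if math.isinf(state.d0) else state.d0)
        if math.isinf(state.d0):
            df_used = np.full_like(d_g, np.inf)
    else:
        var_used = s_g_sq
        df_used = d_g

    p_value = np.full(matrix.shape[0], np.nan)
    for i in range(matrix.shape[0]):
        if not tested[i]:
            continue
        if var_used[i] == 0:
            p_value[i] = 1.0 if log2_fc[i] == 0 else 0.0
            continue
        se = math.sqrt(var_used[i] * (1.0 / n_a[i] + 1.0 / n_b[i]))
        t_stat = log2_fc[i] / se
        df = df_used[i]
        if math.isinf(df):
            p_value[i] = 2.0 * stats.norm.sf(abs(t_stat))
        else:
            p_value[i] = 2.0 * stats.t.sf(abs(t_stat), df)

    calls = []
    for i in range(matrix.shape[0]):
        if not tested[i]:
            calls.append("skipped")
        else:
            calls.append(_classify(log2_fc[i], p_value[i], fc_cut, thresholds.p_cut))

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2_fc": np.where(tested | ((n_a >= 1) & (n_b >= 1)), log2_fc, np.nan),
            "p_value": p_value,
            "n_a": n_a,
            "n_b": n_b,
            "call": calls,
        },
        columns=RECORD_COLUMNS,
    )


def count_calls(records: pd.DataFrame) -> tuple[int, int]:
    """Number of up- and down-called features in a differential table."""
    calls = records["call"]
    return int((calls == "up").sum()), int((calls == "down").sum())
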