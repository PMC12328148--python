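"""Three-component immunotherapy-target score for membrane candidates.

Each candidate protein is summarised by three raw quantities:

* its log2 fold-change in tumor versus adjacent-normal tissue,
* the p-value of its LN+ vs LN- differential test (metastasis significance),
* its maximum abundance across healthy tissues (off-tumor expression, AU).

The first two are mapped to [0, 1] by clamping negatives to zero and
dividing by the cohort maximum (the p-value after a -log10 transform); the
off-tumor component is 1 for a protein silent in every healthy tissue and
otherwise clamp(-log10(max_AU / 10), 0, 1), so abundance at or below 1 AU
scores 1 and abundance at or above 10 AU scores 0.  The final score is the
Euclidean magnitude of the component vector (c_expr, c_sig, c_off), capped
at sqrt(3) ~ 1.732 — attained only by a perfect candidate: maximal tumor
enrichment, maximal metastasis significance, no off-tumor expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import OffTumorProfile

SCORE_CAP = float(np.sqrt(3.0))
_P_FLOOR = 1e-300

SCORE_COLUMNS = [
    "feature_id",
    "raw_tumor_fc",
    "raw_met_p",
    "raw_offtumor_au",
    "c_expr",
    "c_sig",
    "c_off",
    "score",
    "rank",
]


def off_tumor_component(abundances, rule: str = "ratio") -> float:
    """Map a vector of healthy-tissue abundances (AU) to [0, 1].

    ``rule="ratio"`` (default): 1 when the maximum abundance is zero, else
    clamp(-log10(max_AU / 10), 0, 1).  ``rule="scaled_log"`` is the
    alternative reading -log10(max_AU) / 10, also clamped; it is provided
    for sensitivity analysis only.
    """
    arr = np.asarray(abundances, dtype=float)
    if arr.size == 0:
        raise ValueError("off-tumor vector is empty")
    if not np.isfinite(arr).all():
        raise ValueError("off-tumor abundances must be finite")
    if (arr < 0).any():
        raise ValueError("off-tumor abundances must be non-negative")
    max_au = float(arr.max())
    if max_au == 0.0:
        return 1.0
    if rule == "ratio":
        value = -np.log10(max_au / 10.0)
    elif rule == "scaled_log":
        value = -np.log10(max_au) / 10.0
    else:
        raise ValueError(f"unknown off-tumor rule {rule!r}")
    return float(np.clip(value, 0.0, 1.0))


def scale_to_unit(raw) -> np.ndarray:
    """Clamp negatives to zero and divide by the maximum; all-zero stays zero."""
    arr = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    m = arr.max() if arr.size else 0.0
    return arr / m if m > 0 else arr


def prioritize(
    candidates,
    tumor_vs_normal: pd.DataFrame,
    met_vs_nonmet: pd.DataFrame,
    offtumor: OffTumorProfile,
    off_rule: str = "ratio",
) -> pd.DataFrame:
    """Score and rank candidate membrane proteins.

    ``tumor_vs_normal`` and ``met_vs_nonmet`` are differential tables from
    :func:`memtarget.diffexpr.two_group_t`; every candidate must have a
    fold-change in the first, a defined p-value in the second, and a row in
    the off-tumor profile.  Returns a DataFrame sorted by descending score
    (ties: ascending metastasis p, then feature id) with 1-based ranks.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to score")
    fc_map = dict(zip(tumor_vs_normal["feature_id"], tumor_vs_normal["log2_fc"]))
    p_map = dict(zip(met_vs_nonmet["feature_id"], met_vs_nonmet["p_value"]))

    raw_fc, raw_p, raw_au, c_off = [], [], [], []
    for feature in candidates:
        if feature not in fc_map or np.isnan(fc_map[feature]):
            raise KeyError(f"candidate {feature!r} lacks a tumor-vs-normal fold-change")
        if feature not in p_map or np.isnan(p_map[feature]):
            raise KeyError(f"candidate {feature!r} lacks a metastasis p-value")
        row = offtumor.row(feature)  # KeyError names the candidate
        raw_fc.append(float(fc_map[feature]))
        raw_p.append(float(p_map[feature]))
        raw_au.append(float(row.max()))
        c_off.append(off_tumor_component(row, rule=off_rule))

    c_expr = scale_to_unit(raw_fc)
    neglog_p = -np.log10(np.maximum(raw_p, _P_FLOOR))
    c_sig = scale_to_unit(neglog_p)
    c_off = np.asarray(c_off)
    score = np.minimum(np.sqrt(c_expr**2 + c_sig**2 + c_off**2), SCORE_CAP)

    table = pd.DataFrame(
        {
            "feature_id": candidates,
            "raw_tumor_fc": raw_fc,
            "raw_met_p": raw_p,
            "raw_offtumor_au": raw_au,
            "c_expr": c_expr,
            "c_sig": c_sig,
            "c_off": c_off,
            "score": score,
        }
    )
    table = table.sort_values(
        ["score", "raw_met_p", "feature_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[SCORE_COLUMNS]
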