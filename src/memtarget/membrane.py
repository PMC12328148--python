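"""Subcellular-compartment breakdown and membrane filtering of DE results.

A feature may carry several compartment labels (GO cellular-component terms
collapsed into an eight-label vocabulary); it then contributes to every
matching compartment row of the breakdown.  Unannotated features count
under ``other``.  The membrane filter keeps called features whose labels
include ``membrane`` — these are the candidate pool for target scoring.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .cohort import CompartmentAnnotation


def compartment_breakdown(
    records: pd.DataFrame, annotation: CompartmentAnnotation
) -> pd.DataFrame:
    """Count called features per (compartment, direction).

    Fractions are normalized within each direction by the number of called
    features contributing to it, so multi-label features make the fractions
    sum above one.
    """
    rows = []
    for direction in ("up", "down"):
        called = records.loc[records["call"] == direction, "feature_id"]
        n_dir = len(called)
        counts: dict[str, int] = {}
        for feature in called:
            labels = annotation.labels(feature) or frozenset({"other"})
            for label in labels:
                counts[label] = counts.get(label, 0) + 1
        for label in sorted(counts):
            rows.append(
                {
                    "compartment": label,
                    "direction": direction,
                    "count": counts[label],
                    "fraction": counts[label] / n_dir,
                }
            )
    return pd.DataFrame(rows, columns=["compartment", "direction", "count", "fraction"])


def membrane_filter(
    records: pd.DataFrame,
    annotation: CompartmentAnnotation,
    direction: str = "up",
) -> list[str]:
    """Called features annotated to the membrane, in stable input order.

    ``direction`` is ``up``, ``down`` or ``both``.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    wanted = ("up", "down") if direction == "both" else (direction,)
    kept = [
        f
        for f, call in zip(records["feature_id"], records["call"])
        if call in wanted and annotation.is_membrane(f)
    ]
    if not kept:
        warnings.warn(f"membrane filter ({direction}) returned no features")
    return kept
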