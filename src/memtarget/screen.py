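"""End-to-end screen: differential analysis -> membrane filter -> target score,
with survival and mutation gates.

The surface follows the model/results convention of statistical modelling
packages: :class:`TargetScreen` is built from the cohort data, ``fit()``
runs every stage and returns a :class:`ScreenResults` holding the stage
tables, the ranked target list and the gate statistics, with ``summary()``
for a human-readable report and ``save()`` for a reproducible run
directory (stage TSVs plus a machine-readable manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ClinicalTable,
    CompartmentAnnotation,
    ExpressionMatrix,
    MutationTable,
    OffTumorProfile,
    Thresholds,
    read_annotation,
    read_clinical,
    read_expression_matrix,
    read_maf_lite,
    read_offtumor,
)
from .diffexpr import count_calls, two_group_t
from .membrane import compartment_breakdown, membrane_filter
from .prioritize import prioritize
from .survival import (
    CoxFit,
    LogRankResult,
    cox_univariate,
    km_estimate,
    logrank_test,
    mutation_association,
)

logger = logging.getLogger("memtarget")


class TargetScreen:
    """In-silico membrane-target screen over one cohort.

    Parameters
    ----------
    proteome
        Log2 proteome matrix; the layer the candidate pool is drawn from.
    clinical
        Sample table providing tumor/normal and LN+/LN- groupings plus
        survival endpoints.
    annotation, offtumor
        Subcellular compartments and healthy-tissue abundances.
    transcriptome
        Optional second layer, analysed with its own fold-change cut.
    mutations
        Optional MAF-lite table for the mutation-association gate.
    thresholds
        Differential-call thresholds (defaults: log2FC 0.585 proteome /
        1.0 transcriptome, raw p < 0.05, >= 3 observations per group).
    moderation
        Use the empirical-Bayes moderated t instead of the ordinary t.
    direction
        Which differential calls feed the candidate pool (default ``up``:
        proteins overexpressed with metastasis).
    """

    def __init__(
        self,
        proteome: ExpressionMatrix,
        clinical: ClinicalTable,
        annotation: CompartmentAnnotation,
        offtumor: OffTumorProfile,
        transcriptome: ExpressionMatrix | None = None,
        mutations: MutationTable | None = None,
        thresholds: Thresholds | None = None,
        moderation: bool = False,
        direction: str = "up",
        top_n_mutated: int = 20,
        off_rule: str = "ratio",
    ):
        self.proteome = proteome
        self.clinical = clinical
        self.annotation = annotation
        self.offtumor = offtumor
        self.transcriptome = transcriptome
        self.mutations = mutations
        self.thresholds = thresholds or Thresholds()
        self.moderation = moderation
        self.direction = direction
        self.top_n_mutated = top_n_mutated
        self.off_rule = off_rule

        in_matrix = set(proteome.sample_ids)
        self._met = [s for s in clinical.tumor_samples("metastatic") if s in in_matrix]
        self._nonmet = [
            s for s in clinical.tumor_samples("non_metastatic") if s in in_matrix
        ]
        self._normal = [s for s in clinical.normal_samples() if s in in_matrix]
        if not self._met or not self._nonmet:
            raise ValueError("cohort must contain tumor samples in both LN groups")
        if not self._normal:
            raise ValueError("cohort must contain adjacent-normal samples")

    def fit(self) -> "ScreenResults":
        """Run every stage and return the assembled results."""
        thr = self.thresholds
        logger.info(
            "screen: %d LN+ / %d LN- / %d normal samples, %d features",
            len(self._met), len(self._nonmet), len(self._normal),
            self.proteome.shape[0],
        )
        de_met = two_group_t(
            self.proteome, self._met, self._nonmet, thr, moderation=self.moderation
        )
        de_tumor = two_group_t(
            self.proteome,
            self._met + self._nonmet,
            self._normal,
            thr,
            moderation=self.moderation,
        )
        de_met_rna = None
        if self.transcriptome is not None:
            rna_samples = set(self.transcriptome.sample_ids)
            de_met_rna = two_group_t(
                self.transcriptome,
                [s for s in self._met if s in rna_samples],
                [s for s in self._nonmet if s in rna_samples],
                thr,
                moderation=self.moderation,
            )
        breakdown = compartment_breakdown(de_met, self.annotation)
        candidates = membrane_filter(de_met, self.annotation, self.direction)
        logger.info(
            "differential: %d up / %d down; %d membrane candidates (%s)",
            *count_calls(de_met), len(candidates), self.direction,
        )
        ranked = (
            prioritize(candidates, de_tumor, de_met, self.offtumor, off_rule=self.off_rule)
            if candidates
            else pd.DataFrame()
        )

        tumor = self.clinical.data[
            self.clinical.data["sample_id"].isin(self._met + self._nonmet)
        ]
        groups = tumor["ln_status"].to_numpy()
        is_met = (groups == "metastatic").astype(float)
        surv: dict[str, object] = {}
        km: dict[str, object] = {}
        for endpoint in ("pfs", "os"):
            times = tumor[f"{endpoint}_time"].to_numpy()
            events = tumor[f"{endpoint}_event"].to_numpy()
            surv[f"logrank_{endpoint}"] = logrank_test(times, events, groups)
            surv[f"cox_{endpoint}"] = cox_univariate(times, events, is_met)
            km[endpoint] = km_estimate(times, events, groups)

        mut_assoc = None
        if self.mutations is not None:
            mut_assoc = mutation_association(
                self.mutations, self.clinical, top_n=self.top_n_mutated
            )

        return ScreenResults(
            model=self,
            de_met_proteome=de_met,
            de_tumor_proteome=de_tumor,
            de_met_transcriptome=de_met_rna,
            breakdown=breakdown,
            candidates=candidates,
            ranked_targets=ranked,
            survival=surv,
            km_curves=km,
            mutation_assoc=mut_assoc,
        )


@dataclasses.dataclass
class ScreenResults:
    """Stage outputs of one fitted screen."""

    model: TargetScreen
    de_met_proteome: pd.DataFrame
    de_tumor_proteome: pd.DataFrame
    de_met_transcriptome: pd.DataFrame | None
    breakdown: pd.DataFrame
    candidates: list[str]
    ranked_targets: pd.DataFrame
    survival: dict
    km_curves: dict
    mutation_assoc: pd.DataFrame | None

    def top_targets(self, n: int = 10) -> pd.DataFrame:
        return self.ranked_targets.head(n)

    def stage_counts(self) -> dict[str, int]:
        counts = {
            "n_ln_pos": len(self.model._met),
            "n_ln_neg": len(self.model._nonmet),
            "n_normal": len(self.model._normal),
            "n_features": self.model.proteome.shape[0],
            "n_dep_up": count_calls(self.de_met_proteome)[0],
            "n_dep_down": count_calls(self.de_met_proteome)[1],
            "n_candidates": len(self.candidates),
            "n_ranked": len(self.ranked_targets),
        }
        if self.de_met_transcriptome is not None:
            up, down = count_calls(self.de_met_transcriptome)
            counts["n_deg_up"], counts["n_deg_down"] = up, down
        if self.mutation_assoc is not None:
            counts["n_mutation_genes"] = len(self.mutation_assoc)
        return counts

    def summary(self) -> str:
        """Plain-text report of sample sizes, calls, gates and top targets."""
        c = self.stage_counts()
        lines = [
            "Membrane-target screen",
            "=" * 58,
            f"samples: {c['n_ln_pos']} LN+ tumors, {c['n_ln_neg']} LN- tumors, "
            f"{c['n_normal']} adjacent normals",
            f"features tested: {c['n_features']}",
            "",
            f"differential (LN+ vs LN-, proteome): {c['n_dep_up']} up, "
            f"{c['n_dep_down']} down",
        ]
        if "n_deg_up" in c:
            lines.append(
                f"differential (LN+ vs LN-, transcriptome): {c['n_deg_up']} up, "
                f"{c['n_deg_down']} down"
            )
        lines += [
            f"membrane candidates ({self.model.direction}): {c['n_candidates']}",
            "",
            "survival gates (LN+ vs LN-):",
        ]
        for endpoint in ("pfs", "os"):
            lr: LogRankResult = self.survival[f"logrank_{endpoint}"]
            cox: CoxFit = self.survival[f"cox_{endpoint}"]
            lines.append(
                f"  {endpoint.upper():3s} log-rank chi2 = {lr.chi_square:6.3f}, "
                f"p = {lr.p_value:.5f}; Cox HR = {cox.hazard_ratio:5.2f} "
                f"(p = {cox.p_value:.5f})"
            )
        if self.mutation_assoc is not None and len(self.mutation_assoc):
            top = self.mutation_assoc.nsmallest(3, "p_value")
            genes = ", ".join(
                f"{r.gene} (p = {r.p_value:.4g})" for r in top.itertuples()
            )
            lines += ["", f"mutation association, most significant: {genes}"]
        lines += ["", "top-ranked targets:"]
        if len(self.ranked_targets):
            head = self.top_targets(10)[
                ["rank", "feature_id", "c_expr", "c_sig", "c_off", "score"]
            ]
            lines.append(head.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        else:
            lines.append("  (no candidates survived the filters)")
        return "\n".join(lines)

    def save(self, outdir, config: dict | None = None) -> Path:
        """Write stage TSVs, the ranked table and a run manifest to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.de_met_proteome.to_csv(outdir / "de_met_proteome.tsv", sep="\t", index=False)
        self.de_tumor_proteome.to_csv(outdir / "de_tumor_proteome.tsv", sep="\t", index=False)
        if self.de_met_transcriptome is not None:
            self.de_met_transcriptome.to_csv(
                outdir / "de_met_transcriptome.tsv", sep="\t", index=False
            )
        self.breakdown.to_csv(outdir / "compartment_breakdown.tsv", sep="\t", index=False)
        pd.Series(self.candidates, name="feature_id").to_csv(
            outdir / "membrane_candidates.tsv", sep="\t", index=False
        )
        if len(self.ranked_targets):
            out = self.ranked_targets.copy()
            out["score"] = out["score"].map(lambda v: f"{v:.6f}")
            out.to_csv(outdir / "ranked_targets.tsv", sep="\t", index=False)
        if self.mutation_assoc is not None:
            self.mutation_assoc.to_csv(outdir / "mutation_association.tsv", sep="\t", index=False)
        surv_rows = []
        for endpoint in ("pfs", "os"):
            lr = self.survival[f"logrank_{endpoint}"]
            cox = self.survival[f"cox_{endpoint}"]
            surv_rows.append(
                {
                    "endpoint": endpoint,
                    "logrank_chi2": lr.chi_square,
                    "logrank_p": lr.p_value,
                    "cox_beta": cox.beta,
                    "cox_hr": cox.hazard_ratio,
                    "cox_se": cox.se,
                    "cox_p": cox.p_value,
                    "cox_converged": cox.converged,
                }
            )
        pd.DataFrame(surv_rows).to_csv(outdir / "survival_gates.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")

        resolved = config or {}
        manifest = {
            "package_version": __version__,
            "config_sha256": hashlib.sha256(
                json.dumps(resolved, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "stage_counts": self.stage_counts(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        if config is not None:
            (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved))
        return outdir


DEFAULT_CONFIG = {
    "thresholds": {
        "dep_log2fc": 0.585,
        "deg_log2fc": 1.0,
        "p_cut": 0.05,
        "min_obs_per_group": 3,
    },
    "options": {
        "moderation": False,
        "direction": "up",
        "top_n_mutated": 20,
        "off_rule": "ratio",
        "log2_transform": False,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def load_screen(config: dict) -> TargetScreen:
    """Build a :class:`TargetScreen` from a resolved config dict."""
    inputs = config.get("inputs", {})
    for required in ("proteome", "clinical", "annotation", "offtumor"):
        if required not in inputs:
            raise ValueError(f"config inputs missing {required!r}")
    opts = config["options"]
    thr = Thresholds(**config["thresholds"])
    clinical = read_clinical(inputs["clinical"])
    proteome = read_expression_matrix(
        inputs["proteome"], "proteome", log2_transform=opts["log2_transform"]
    )
    transcriptome = (
        read_expression_matrix(
            inputs["transcriptome"], "transcriptome", log2_transform=opts["log2_transform"]
        )
        if inputs.get("transcriptome")
        else None
    )
    mutations = (
        read_maf_lite(inputs["mutations"], clinical) if inputs.get("mutations") else None
    )
    return TargetScreen(
        proteome=proteome,
        clinical=clinical,
        annotation=read_annotation(inputs["annotation"]),
        offtumor=read_offtumor(inputs["offtumor"]),
        transcriptome=transcriptome,
        mutations=mutations,
        thresholds=thr,
        moderation=opts["moderation"],
        direction=opts["direction"],
        top_n_mutated=opts["top_n_mutated"],
        off_rule=opts["off_rule"],
    )


def run_screen(config_path, outdir) -> ScreenResults:
    """Run the full screen from a YAML config; abort names the failing stage.

    The run directory receives every stage TSV, the ranked target table,
    ``summary.txt``, the resolved config and a manifest with the config
    hash and stage row counts; re-running on identical inputs reproduces
    identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        with open(config_path) as fh:
            user_cfg = yaml.safe_load(fh) or {}
        resolved = _merge(DEFAULT_CONFIG, user_cfg)
        try:
            model = load_screen(resolved)
        except Exception as exc:
            raise RuntimeError(f"stage=load: {exc}") from exc
        try:
            results = model.fit()
        except Exception as exc:
            raise RuntimeError(f"stage=fit: {exc}") from exc
        results.save(outdir, config=resolved)
        logger.info("screen complete: %s", results.stage_counts())
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
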