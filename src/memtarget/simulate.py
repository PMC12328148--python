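"""Synthetic multi-omics cohort generator.

Emulates the statistical structure the screen assumes in a laryngeal-cancer
cohort: two tumor groups (lymph-node metastatic, LN+, and non-metastatic,
LN-) plus adjacent-normal samples; a proteome and a transcriptome layer on
log2 scale; a set of planted membrane targets overexpressed in LN+ tumors
and in tumor vs normal; a matched set of decoy membrane proteins that share
the metastasis effect but are broadly expressed across healthy tissues;
missing-at-random proteome entries; exponential survival whose hazard
depends on LN status; and a binary mutation matrix with a subset of genes
enriched in the LN- group.

Everything is drawn from one ``numpy.random.default_rng(seed)`` stream in a
fixed order, so identical configurations give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    ClinicalTable,
    CompartmentAnnotation,
    ExpressionMatrix,
    MutationTable,
    OffTumorProfile,
    write_annotation,
    write_clinical,
    write_expression_matrix,
    write_maf_lite,
    write_offtumor,
)

_VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice_site", "inframe_del")
_NON_MEMBRANE = ("cytosol", "nucleus", "cytoskeleton", "mitochondria", "golgi", "lysosome")


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Sample counts default to a CPTAC-like proteome cohort (47 tumors split
    24/23 by LN status, 20 adjacent normals).  Effect sizes are on the log2
    scale; survival is exponential (constant hazard, in events/day) with a
    proportional-hazards effect of LN status; mutations are Bernoulli with an
    odds-ratio enrichment of designated genes in the LN- group.
    """

    n_ln_pos: int = 24
    n_ln_neg: int = 23
    n_normal: int = 20
    n_features: int = 1000
    n_planted_membrane: int = 15
    n_decoy_membrane: int | None = None  # None -> matched to n_planted_membrane
    planted_log2fc_met: float = 1.0
    planted_log2fc_tumor: float = 1.5
    noise_sd: float = 1.0
    missing_rate: float = 0.10
    baseline_hazard: float = 1.0 / 1500.0  # events/day; median PFS ~2.8 y in LN-
    log_hr_ln: float = math.log(2.0)
    censor_time: float = 1825.0  # 5-year administrative censoring
    mutation_gene_count: int = 50
    n_mutation_enriched: int = 5
    mutation_base_rate: float = 0.15
    mutation_or_nonmet: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_decoy_membrane is None:
            self.n_decoy_membrane = self.n_planted_membrane
        counts = (self.n_ln_pos, self.n_ln_neg, self.n_normal, self.n_features)
        if any(c <= 0 for c in counts):
            raise ValueError("sample and feature counts must be positive")
        if self.n_planted_membrane + self.n_decoy_membrane > self.n_features:
            raise ValueError("planted + decoy features exceed n_features")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0 <= self.mutation_base_rate <= 1:
            raise ValueError("mutation_base_rate must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0 or self.censor_time <= 0:
            raise ValueError("hazard and censoring horizon must be positive")
        if self.n_mutation_enriched > self.mutation_gene_count:
            raise ValueError("more enriched genes than mutation genes")


@dataclasses.dataclass
class SimulatedCohort:
    """One synthetic cohort plus its ground-truth ledger."""

    proteome: ExpressionMatrix
    transcriptome: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    annotation: CompartmentAnnotation
    offtumor: OffTumorProfile
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def planted_ids(self) -> list[str]:
        t = self.truth
        return list(t.loc[t["kind"] == "planted", "id"])

    @property
    def decoy_ids(self) -> list[str]:
        t = self.truth
        return list(t.loc[t["kind"] == "decoy", "id"])


def _feature_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    planted = [f"MEMT{i + 1:04d}" for i in range(cfg.n_planted_membrane)]
    decoys = [f"DECY{i + 1:04d}" for i in range(cfg.n_decoy_membrane)]
    n_bg = cfg.n_features - len(planted) - len(decoys)
    background = [f"FEAT{i + 1:05d}" for i in range(n_bg)]
    return planted, decoys, background


def _expression_layer(
    rng: np.random.Generator,
    features: list[str],
    samples: list[str],
    baseline: np.ndarray,
    fc_met: np.ndarray,
    fc_tumor: np.ndarray,
    is_tumor: np.ndarray,
    is_ln_pos: np.ndarray,
    noise_sd: float,
) -> pd.DataFrame:
    mean = (
        baseline[:, None]
        + fc_tumor[:, None] * is_tumor[None, :]
        + fc_met[:, None] * is_ln_pos[None, :]
    )
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    return pd.DataFrame(values, index=features, columns=samples)


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort under ``cfg``; identical seeds give identical output."""
    rng = np.random.default_rng(cfg.seed)
    planted, decoys, background = _feature_ids(cfg)
    features = planted + decoys + background
    n_feat = len(features)
    n_planted, n_decoy = len(planted), len(decoys)

    ln_pos = [f"LNP{i + 1:03d}" for i in range(cfg.n_ln_pos)]
    ln_neg = [f"LNN{i + 1:03d}" for i in range(cfg.n_ln_neg)]
    normals = [f"NOR{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = ln_pos + ln_neg + normals
    is_tumor = np.array([1.0] * (cfg.n_ln_pos + cfg.n_ln_neg) + [0.0] * cfg.n_normal)
    is_ln_pos = np.array([1.0] * cfg.n_ln_pos + [0.0] * (cfg.n_ln_neg + cfg.n_normal))

    # per-feature effects: planted carry both effects, decoys only the
    # metastasis effect (broadly expressed, not tumor-enriched), background none
    fc_met = np.zeros(n_feat)
    fc_met[: n_planted + n_decoy] = cfg.planted_log2fc_met
    fc_tumor = np.zeros(n_feat)
    fc_tumor[:n_planted] = cfg.planted_log2fc_tumor

    base_prot = rng.uniform(4.0, 10.0, size=n_feat)
    proteome_values = _expression_layer(
        rng, features, samples, base_prot, fc_met, fc_tumor, is_tumor, is_ln_pos, cfg.noise_sd
    )
    if cfg.missing_rate > 0:
        mask = rng.random(proteome_values.shape) < cfg.missing_rate
        proteome_values = proteome_values.mask(mask)

    base_rna = rng.uniform(2.0, 8.0, size=n_feat)
    transcriptome_values = _expression_layer(
        rng, features, samples, base_rna, fc_met, fc_tumor, is_tumor, is_ln_pos, cfg.noise_sd
    )

    # survival: exponential PFS/OS, right-censored administratively; the OS
    # hazard is scaled down so OS stochastically dominates PFS on average
    hazard_mult = np.exp(cfg.log_hr_ln * is_ln_pos[: cfg.n_ln_pos + cfg.n_ln_neg])
    pfs_raw = rng.exponential(1.0 / (cfg.baseline_hazard * hazard_mult))
    os_raw = rng.exponential(1.0 / (0.6 * cfg.baseline_hazard * hazard_mult))
    pfs_time = np.minimum(pfs_raw, cfg.censor_time)
    pfs_event = (pfs_raw <= cfg.censor_time).astype(int)
    os_time = np.minimum(os_raw, cfg.censor_time)
    os_event = (os_raw <= cfg.censor_time).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "tissue": ["tumor"] * (cfg.n_ln_pos + cfg.n_ln_neg)
                + ["adjacent_normal"] * cfg.n_normal,
                "ln_status": ["metastatic"] * cfg.n_ln_pos
                + ["non_metastatic"] * cfg.n_ln_neg
                + ["unknown"] * cfg.n_normal,
                "os_time": np.concatenate([os_time, np.zeros(cfg.n_normal)]),
                "os_event": np.concatenate([os_event, np.zeros(cfg.n_normal, int)]),
                "pfs_time": np.concatenate([pfs_time, np.zeros(cfg.n_normal)]),
                "pfs_event": np.concatenate([pfs_event, np.zeros(cfg.n_normal, int)]),
            }
        )
    )

    # annotation: planted and decoys are membrane; background features get
    # 1-2 compartments with a realistic ~20% membrane share
    mapping: dict[str, frozenset] = {}
    for f in planted + decoys:
        mapping[f] = frozenset({"membrane"})
    for f in background:
        labels = set()
        if rng.random() < 0.2:
            labels.add("membrane")
        n_extra = 1 if rng.random() < 0.7 else 2
        labels.update(rng.choice(_NON_MEMBRANE, size=n_extra, replace=False))
        mapping[f] = frozenset(labels)
    annotation = CompartmentAnnotation(mapping)

    # off-tumor profile (arbitrary units): planted targets are silent or
    # near-silent in normal tissues; decoys are abundantly expressed; the
    # background sits in between
    tissues = [
        "heart", "liver", "lung", "kidney", "colon", "brain",
        "pancreas", "spleen", "testis", "skin",
    ]
    n_tis = len(tissues)
    off = np.empty((n_feat, n_tis))
    planted_max = np.where(
        rng.random(n_planted) < 0.5, 0.0, rng.uniform(0.0, 1.0, size=n_planted)
    )
    off[:n_planted] = rng.uniform(0.0, 1.0, size=(n_planted, n_tis)) * planted_max[:, None]
    off[n_planted : n_planted + n_decoy] = rng.uniform(10.0, 100.0, size=(n_decoy, n_tis))
    off[n_planted + n_decoy :] = rng.uniform(0.5, 50.0, size=(n_feat - n_planted - n_decoy, n_tis))
    offtumor = OffTumorProfile(pd.DataFrame(off, index=features, columns=tissues))

    # mutations: Bernoulli per (gene, tumor sample); designated genes are
    # enriched in the LN- group at odds ratio mutation_or_nonmet
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.mutation_gene_count)]
    enriched = set(genes[: cfg.n_mutation_enriched])
    p0 = cfg.mutation_base_rate
    odds0 = p0 / (1.0 - p0)
    p_enriched = (cfg.mutation_or_nonmet * odds0) / (1.0 + cfg.mutation_or_nonmet * odds0)
    tumor_samples = ln_pos + ln_neg
    tumor_is_met = np.array([1] * cfg.n_ln_pos + [0] * cfg.n_ln_neg, bool)
    rows = []
    for gene in genes:
        p_vec = np.where(
            ~tumor_is_met & (gene in enriched), p_enriched, p0
        )
        hits = rng.random(len(tumor_samples)) < p_vec
        for s, hit in zip(tumor_samples, hits):
            if hit:
                rows.append(
                    (gene, s, _VARIANT_CLASSES[rng.integers(len(_VARIANT_CLASSES))])
                )
    mutations = MutationTable(
        pd.DataFrame(rows, columns=["gene", "sample_id", "variant_class"]),
        sample_ids=clinical.sample_ids,
    )

    kinds = (
        ["planted"] * n_planted + ["decoy"] * n_decoy + ["background"] * len(background)
    )
    truth_feat = pd.DataFrame(
        {
            "id": features,
            "kind": kinds,
            "log2fc_met": fc_met,
            "log2fc_tumor": fc_tumor,
            "membrane": [annotation.is_membrane(f) for f in features],
            "offtumor_max_au": off.max(axis=1),
            "mutation_enriched": False,
        }
    )
    truth_mut = pd.DataFrame(
        {
            "id": genes,
            "kind": "mutation_gene",
            "log2fc_met": 0.0,
            "log2fc_tumor": 0.0,
            "membrane": False,
            "offtumor_max_au": np.nan,
            "mutation_enriched": [g in enriched for g in genes],
        }
    )
    truth = pd.concat([truth_feat, truth_mut], ignore_index=True)

    return SimulatedCohort(
        proteome=ExpressionMatrix(proteome_values, "proteome"),
        transcriptome=ExpressionMatrix(transcriptome_values, "transcriptome"),
        clinical=clinical,
        mutations=mutations,
        annotation=annotation,
        offtumor=offtumor,
        truth=truth,
        config=cfg,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write the seven cohort artifacts in the pipeline's flat-file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.tsv",
        "transcriptome": outdir / "transcriptome.tsv",
        "clinical": outdir / "clinical.csv",
        "mutations": outdir / "mutations.tsv",
        "annotation": outdir / "annotation.tsv",
        "offtumor": outdir / "offtumor.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_matrix(cohort.proteome, paths["proteome"])
    write_expression_matrix(cohort.transcriptome, paths["transcriptome"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_maf_lite(cohort.mutations, paths["mutations"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_offtumor(cohort.offtumor, paths["offtumor"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
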