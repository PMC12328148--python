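"""Domain containers and flat-file IO shared by every stage of the screen.

The pipeline exchanges five tabular artifacts:

* expression TSV — features in rows, samples in columns, log2 abundance,
  empty cells or ``NA`` meaning "not quantified" (proteome data is sparse);
* clinical CSV — one row per sample with tissue type, lymph-node status
  and the two survival endpoints (OS, PFS);
* MAF-lite TSV — one row per somatic mutation call (gene, sample, class);
* annotation TSV — feature to pipe-separated subcellular compartments;
* off-tumor TSV — feature by normal-tissue abundance in arbitrary units,
  emulating a Human Proteome Map style reference.

Containers validate their invariants on construction; readers raise
:class:`ParseError` with the offending row/column named.  Sample ids are
the join key across all tables — no fuzzy matching is attempted.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

#: Controlled vocabulary of subcellular compartments.
COMPARTMENTS = frozenset(
    {
        "cytosol",
        "membrane",
        "nucleus",
        "cytoskeleton",
        "mitochondria",
        "golgi",
        "lysosome",
        "other",
    }
)

#: Coarse mapping from raw GO cellular-component term names to the
#: compartment vocabulary.  This is a small synthetic stand-in intended for
#: tests and examples; real analyses should supply their own term table.
DEFAULT_GO_TERM_MAP: dict[str, str] = {
    "plasma membrane": "membrane",
    "cell surface": "membrane",
    "integral component of plasma membrane": "membrane",
    "external side of plasma membrane": "membrane",
    "cytosol": "cytosol",
    "cytoplasm": "cytosol",
    "nucleus": "nucleus",
    "nucleoplasm": "nucleus",
    "cytoskeleton": "cytoskeleton",
    "actin cytoskeleton": "cytoskeleton",
    "intermediate filament": "cytoskeleton",
    "mitochondrion": "mitochondria",
    "mitochondrial matrix": "mitochondria",
    "golgi apparatus": "golgi",
    "golgi membrane": "golgi",
    "lysosome": "lysosome",
    "lysosomal membrane": "lysosome",
}

VALID_TISSUES = ("tumor", "adjacent_normal")
VALID_LN = ("metastatic", "non_metastatic", "unknown")


class ParseError(ValueError):
    """Structured parse failure naming the file location responsible."""

    def __init__(self, message: str, path=None, row=None, column=None):
        loc = []
        if path is not None:
            loc.append(f"file={path}")
        if row is not None:
            loc.append(f"row={row}")
        if column is not None:
            loc.append(f"column={column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.path, self.row, self.column = path, row, column


def _check_unique(ids, what: str, path=None):
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what}: {dups[:5]}", path=path)


@dataclasses.dataclass
class ExpressionMatrix:
    """Log2-abundance grid, features x samples, with missing values allowed.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.  NaN
        entries mean "not quantified" and are never treated as zero.
    layer_label
        Either ``"proteome"`` or ``"transcriptome"``.
    """

    data: pd.DataFrame
    layer_label: str = "proteome"

    def __post_init__(self):
        if self.layer_label not in ("proteome", "transcriptome"):
            raise ValueError(f"unknown layer_label {self.layer_label!r}")
        _check_unique(self.data.index, "feature ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        finite_or_nan = np.isfinite(values) | np.isnan(values)
        if not finite_or_nan.all():
            bad = np.argwhere(~finite_or_nan)[0]
            raise ValueError(
                f"non-finite entry at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.layer_label)


@dataclasses.dataclass
class ClinicalTable:
    """Per-sample clinical annotations: tissue, LN status, OS/PFS endpoints."""

    data: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "tissue",
        "ln_status",
        "os_time",
        "os_event",
        "pfs_time",
        "pfs_event",
    )

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ParseError(f"clinical table missing columns {missing}")
        _check_unique(df["sample_id"], "sample ids")
        bad_tissue = ~df["tissue"].isin(VALID_TISSUES)
        if bad_tissue.any():
            raise ParseError(
                f"unknown tissue values {sorted(df.loc[bad_tissue, 'tissue'].unique())}"
            )
        unknown_ln = ~df["ln_status"].isin(VALID_LN)
        if unknown_ln.any():
            warnings.warn(
                "unrecognised ln_status tokens "
                f"{sorted(df.loc[unknown_ln, 'ln_status'].unique())} mapped to 'unknown'",
                stacklevel=2,
            )
            df.loc[unknown_ln, "ln_status"] = "unknown"
        # adjacent-normal tissue has no LN phenotype by definition
        normal_with_ln = (df["tissue"] == "adjacent_normal") & (
            df["ln_status"] != "unknown"
        )
        if normal_with_ln.any():
            warnings.warn(
                f"{int(normal_with_ln.sum())} adjacent_normal sample(s) carried an "
                "ln_status; coerced to 'unknown'",
                stacklevel=2,
            )
            df.loc[normal_with_ln, "ln_status"] = "unknown"
        for col in ("os_time", "pfs_time"):
            df[col] = pd.to_numeric(df[col])
            if (df[col] < 0).any():
                offender = df.loc[df[col] < 0, "sample_id"].iloc[0]
                raise ParseError(f"negative {col} for sample {offender!r}")
        for col in ("os_event", "pfs_event"):
            df[col] = pd.to_numeric(df[col])
            if not df[col].isin((0, 1)).all():
                raise ParseError(f"{col} must be 0/1")
            df[col] = df[col].astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def tumor_samples(self, ln_status: str | None = None) -> list[str]:
        """Tumor sample ids, optionally restricted to one LN status."""
        df = self.data[self.data["tissue"] == "tumor"]
        if ln_status is not None:
            df = df[df["ln_status"] == ln_status]
        return list(df["sample_id"])

    def normal_samples(self) -> list[str]:
        return list(self.data.loc[self.data["tissue"] == "adjacent_normal", "sample_id"])


@dataclasses.dataclass
class MutationTable:
    """MAF-lite rows plus the derived binary gene x sample indicator."""

    rows: pd.DataFrame  # columns: gene, sample_id, variant_class
    sample_ids: list[str]  # the cohort's sample universe (from ClinicalTable)

    def __post_init__(self):
        for col in ("gene", "sample_id", "variant_class"):
            if col not in self.rows.columns:
                raise ParseError(f"mutation table missing column {col!r}")
        orphans = sorted(set(self.rows["sample_id"]) - set(self.sample_ids))
        if orphans:
            raise ParseError(f"mutation rows reference unknown samples: {orphans[:10]}")

    def indicator(self) -> pd.DataFrame:
        """Binary gene x sample matrix: 1 iff the gene is mutated at least once."""
        genes = sorted(self.rows["gene"].unique())
        ind = pd.DataFrame(0, index=genes, columns=self.sample_ids, dtype=int)
        for gene, sample in zip(self.rows["gene"], self.rows["sample_id"]):
            ind.at[gene, sample] = 1
        return ind


@dataclasses.dataclass
class CompartmentAnnotation:
    """Feature -> set of compartment labels from the controlled vocabulary."""

    mapping: dict[str, frozenset]

    def __post_init__(self):
        clean = {}
        for feature, labels in self.mapping.items():
            labels = frozenset(labels)
            bad = labels - COMPARTMENTS
            if bad:
                raise ValueError(
                    f"labels {sorted(bad)} for feature {feature!r} not in vocabulary"
                )
            clean[feature] = labels
        self.mapping = clean

    def labels(self, feature_id: str) -> frozenset:
        return self.mapping.get(feature_id, frozenset())

    def is_membrane(self, feature_id: str) -> bool:
        return "membrane" in self.labels(feature_id)

    @classmethod
    def from_go_terms(cls, raw: dict[str, set], term_map: dict[str, str] | None = None):
        """Collapse raw GO CC term names into the compartment vocabulary.

        Terms absent from ``term_map`` collapse to ``other``.
        """
        term_map = DEFAULT_GO_TERM_MAP if term_map is None else term_map
        mapping = {
            feat: frozenset(term_map.get(t.strip().lower(), "other") for t in terms)
            for feat, terms in raw.items()
        }
        return cls(mapping)


@dataclasses.dataclass
class OffTumorProfile:
    """Per-feature abundance (arbitrary units) across named normal tissues."""

    data: pd.DataFrame  # features x tissues, AU

    def __post_init__(self):
        _check_unique(self.data.index, "feature ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("off-tumor abundances must be finite")
        if (values < 0).any():
            raise ValueError("off-tumor abundances must be non-negative")
        self.data = self.data.astype(float)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    def row(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} absent from off-tumor profile")
        return self.data.loc[feature_id].to_numpy(dtype=float)


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Differential-call thresholds.

    ``dep_log2fc`` (0.585, i.e. 1.5-fold) applies to the proteome layer,
    ``deg_log2fc`` (1.0, i.e. 2-fold) to the transcriptome; ``p_cut`` is the
    raw two-sided p cut-off and ``min_obs_per_group`` the smallest per-group
    non-missing count below which a feature is skipped.
    """

    dep_log2fc: float = 0.585
    deg_log2fc: float = 1.0
    p_cut: float = 0.05
    min_obs_per_group: int = 3

    def __post_init__(self):
        if min(self.dep_log2fc, self.deg_log2fc) <= 0:
            raise ValueError("fold-change cuts must be positive")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0, 1)")
        if self.min_obs_per_group < 1:
            raise ValueError("min_obs_per_group must be >= 1")

    def fc_cut(self, layer_label: str) -> float:
        return self.dep_log2fc if layer_label == "proteome" else self.deg_log2fc


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path, layer_label: str = "proteome", log2_transform: bool = False
) -> ExpressionMatrix:
    """Read an expression TSV (features x samples; ``NA``/empty = missing).

    With ``log2_transform`` the file is assumed to hold raw-scale values and
    every entry is mapped through log2(x + 1); by default values are taken as
    already log2-transformed.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.name is None and raw.shape[1] == 0:
        raise ParseError("malformed header: no sample columns found", path=path)
    _check_unique(raw.index, "feature ids", path=path)
    _check_unique(raw.columns, "sample ids", path=path)
    values = raw.where(~raw.isin(("", "NA")))
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {values.iat[i, j]!r}",
            path=path,
            row=raw.index[i],
            column=raw.columns[j],
        )
    if log2_transform:
        if (numeric < 0).any().any():
            raise ParseError("raw-scale input contains negative values", path=path)
        numeric = np.log2(numeric + 1.0)
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric, layer_label=layer_label)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def read_clinical(path) -> ClinicalTable:
    """Read the clinical CSV and validate it (see :class:`ClinicalTable`)."""
    df = pd.read_csv(path)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, index=False)


def read_maf_lite(path, clinical: ClinicalTable) -> MutationTable:
    """Read a MAF-lite TSV; rows must reference samples known to ``clinical``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and list(df.columns) != ["gene", "sample_id", "variant_class"]:
        # tolerate a header-only file as an empty table
        df = pd.DataFrame(columns=["gene", "sample_id", "variant_class"])
    return MutationTable(df, sample_ids=clinical.sample_ids)


def write_maf_lite(mut: MutationTable, path) -> None:
    mut.rows.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> CompartmentAnnotation:
    """Read feature -> pipe-separated compartment labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "compartments"} <= set(df.columns):
        raise ParseError("annotation table needs columns feature_id, compartments", path=path)
    mapping = {}
    for _, row in df.iterrows():
        labels = [t for t in str(row["compartments"]).split("|") if t]
        mapping[row["feature_id"]] = frozenset(labels)
    return CompartmentAnnotation(mapping)


def write_annotation(annotation: CompartmentAnnotation, path) -> None:
    rows = [
        {"feature_id": f, "compartments": "|".join(sorted(labels))}
        for f, labels in annotation.mapping.items()
    ]
    pd.DataFrame(rows, columns=["feature_id", "compartments"]).to_csv(
        path, sep="\t", index=False
    )


def read_offtumor(path) -> OffTumorProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OffTumorProfile(df)


def write_offtumor(profile: OffTumorProfile, path) -> None:
    profile.data.to_csv(path, sep="\t", index_label="feature_id")
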