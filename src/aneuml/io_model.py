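"""Shared data model and tab-delimited IO for the aneuploidy pipeline.

All tables are tab-separated UTF-8 text with a mandatory header, matching the
export conventions of GISTIC2.0 / GTEx / DepMap flat files.  Gene and context
identifiers are opaque strings.  Chromosome arms follow the ``<chrom><p|q>``
convention (``13q``); whole chromosomes are bare ``<chrom>`` strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GisticArmRecord",
    "ArmLabel",
    "FeatureDef",
    "RunConfig",
    "DEFAULT_ARMS",
    "ACROCENTRIC_P_ARMS",
    "FormatError",
    "ValidationError",
    "feature_registry",
    "read_gistic_table",
    "write_gistic_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_ppi_table",
    "write_ppi_table",
    "read_context_map",
    "write_context_map",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected tab-delimited schema."""


class ValidationError(ValueError):
    """A parsed value violates a domain-type invariant."""


#: The 5 acrocentric short arms carry no annotated protein-coding genes and are
#: excluded from arm-level analyses.
ACROCENTRIC_P_ARMS = ("13p", "14p", "15p", "21p", "22p")

#: 39 autosomal chromosome arms: 22 autosomes x 2 arms minus the 5 acrocentric
#: p-arms.
DEFAULT_ARMS: tuple[str, ...] = tuple(
    f"{c}{a}"
    for c in range(1, 23)
    for a in ("p", "q")
    if f"{c}{a}" not in ACROCENTRIC_P_ARMS
)


@dataclass(frozen=True)
class GisticArmRecord:
    """Arm-level significance record for one (arm, context) pair.

    ``amp_q``/``del_q`` are GISTIC2.0-style q-values for recurrent
    amplification/deletion; ``amp_freq``/``del_freq`` are the fractions of
    samples carrying the gain/loss.
    """

    arm_id: str
    context_id: str
    amp_q: float
    del_q: float
    amp_freq: float
    del_freq: float

    def __post_init__(self) -> None:
        for name in ("amp_q", "del_q", "amp_freq", "del_freq"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{name}={v!r} outside [0, 1] for arm {self.arm_id!r}, "
                    f"context {self.context_id!r}"
                )

    @property
    def chromosome(self) -> str:
        return self.arm_id.rstrip("pq")


@dataclass(frozen=True)
class ArmLabel:
    """Gain/loss/neutral call for one (arm, context) instance."""

    arm_id: str
    context_id: str
    label: str  # "gain" | "loss" | "neutral"

    def __post_init__(self) -> None:
        if self.label not in ("gain", "loss", "neutral"):
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class FeatureDef:
    """One engineered feature: its category, source table and aggregation."""

    name: str
    category: str  # "chromosome-arm" | "cancer" | "normal"
    source: str
    aggregation: str
    tissue_relative: bool
    transcriptomic: bool = False  # re-standardized within tissue at table level


_REGISTRY: tuple[FeatureDef, ...] = (
    # -- chromosome-arm category (context-independent) ------------------------
    FeatureDef("og_density", "chromosome-arm", "gene_annotations", "density", False),
    FeatureDef("tsg_density", "chromosome-arm", "gene_annotations", "density", False),
    FeatureDef("essential_gene_density", "chromosome-arm", "gene_annotations",
               "density", False),
    # -- cancer-tissue category -----------------------------------------------
    FeatureDef("tcga_expression", "cancer", "cancer_expression",
               "top_decile_median", True, transcriptomic=True),
    FeatureDef("crispr_essentiality", "cancer", "crispr_scores",
               "top_decile_median", True),
    FeatureDef("rnai_essentiality", "cancer", "rnai_scores",
               "top_decile_median", True),
    FeatureDef("cancer_essential_density", "cancer", "crispr_scores",
               "density", False),
    # -- normal-tissue category -----------------------------------------------
    FeatureDef("gtex_expression", "normal", "normal_expression",
               "top_decile_median", True, transcriptomic=True),
    FeatureDef("tissue_specific_gene_density", "normal", "normal_expression",
               "density", True),
    FeatureDef("num_ppis", "normal", "ppi", "top_decile_median", True),
    FeatureDef("num_elevated_ppis", "normal", "ppi", "top_decile_median", True),
    FeatureDef("num_tissue_specific_ppis", "normal", "ppi",
               "top_decile_median", True),
    FeatureDef("differential_ppis", "normal", "ppi", "top_decile_median", False),
    FeatureDef("process_activity", "normal", "process_activity",
               "top_decile_median", False),
    FeatureDef("eqtl_significance", "normal", "eqtl", "top_decile_median", True),
    FeatureDef("paralog_compensation", "normal", "normal_expression",
               "top_decile_median", True),
    FeatureDef("devel_expression_fetal", "normal", "development",
               "top_decile_median", True, transcriptomic=True),
    FeatureDef("devel_expression_childhood", "normal", "development",
               "top_decile_median", True, transcriptomic=True),
    FeatureDef("devel_expression_young", "normal", "development",
               "top_decile_median", True, transcriptomic=True),
    FeatureDef("devel_expression_variability", "normal", "development",
               "top_decile_median", True, transcriptomic=True),
)


def feature_registry() -> list[FeatureDef]:
    """Return the ordered list of the 20 feature definitions.

    The registry is the single source of truth for feature naming: the feature
    table emits exactly these columns, in this order.  Category sizes are
    3 (chromosome-arm), 4 (cancer tissues) and 13 (normal tissues).
    """
    return list(_REGISTRY)


# ---------------------------------------------------------------------------
# Tab-delimited readers / writers
# ---------------------------------------------------------------------------

_GISTIC_COLUMNS = ("arm", "context", "amp_q", "del_q", "amp_freq", "del_freq")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_gistic_table(path) -> list[GisticArmRecord]:
    """Read an arm x context significance table.

    Expects columns ``arm, context, amp_q, del_q, amp_freq, del_freq``.
    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` (with the offending row) for out-of-range values
    or duplicated (arm, context) keys.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"arm": str, "context": str})
    _require_columns(df, _GISTIC_COLUMNS, path)
    dup = df.duplicated(subset=["arm", "context"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: duplicated (arm, context) key at data row {i}: "
            f"({df.iloc[i]['arm']}, {df.iloc[i]['context']})"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                GisticArmRecord(
                    arm_id=row.arm, context_id=row.context,
                    amp_q=float(row.amp_q), del_q=float(row.del_q),
                    amp_freq=float(row.amp_freq), del_freq=float(row.del_freq),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: data row {i}: {exc}") from exc
    return records


def write_gistic_table(records: Iterable[GisticArmRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.arm_id, r.context_id, r.amp_q, r.del_q, r.amp_freq, r.del_freq)
            for r in records
        ],
        columns=list(_GISTIC_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path, *, on_duplicate: str = "error") -> pd.DataFrame:
    """Read a gene x column numeric matrix (first column ``gene_id``).

    ``on_duplicate`` controls duplicated gene rows: ``"error"`` (default),
    ``"first"`` or ``"mean"``.  Non-numeric cells raise :class:`FormatError`
    with the offending coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus >=1 value column")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"{path}: non-numeric cell at gene {gene!r}, column {col!r}"
            )
        df[col] = coerced
    if df.index.duplicated().any():
        if on_duplicate == "error":
            gene = df.index[df.index.duplicated()][0]
            raise ValidationError(f"{path}: duplicated gene_id {gene!r}")
        if on_duplicate == "first":
            df = df[~df.index.duplicated(keep="first")]
        elif on_duplicate == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            raise ValueError(f"unknown on_duplicate rule {on_duplicate!r}")
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


_GENE_COLUMNS = ("gene_id", "arm", "is_og", "is_tsg", "essentiality_prob", "paralog")


def read_gene_annotations(path) -> pd.DataFrame:
    """Read the per-gene annotation table.

    Columns: ``gene_id, arm, is_og, is_tsg, essentiality_prob, paralog``.
    ``paralog`` may be empty (gene has no assigned paralog).  Every gene maps
    to exactly one arm; ``essentiality_prob`` must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "arm": str, "paralog": str})
    _require_columns(df, _GENE_COLUMNS, path)
    if df["gene_id"].duplicated().any():
        gene = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated gene_id {gene!r}")
    prob = df["essentiality_prob"].to_numpy(dtype=float)
    bad = ~np.isnan(prob) & ((prob < 0) | (prob > 1))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: data row {i}: essentiality_prob={prob[i]} outside [0, 1]"
        )
    df["is_og"] = df["is_og"].astype(bool)
    df["is_tsg"] = df["is_tsg"].astype(bool)
    df["paralog"] = df["paralog"].where(df["paralog"].notna(), None)
    return df.set_index("gene_id")


def write_gene_annotations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["is_og"] = out["is_og"].astype(int)
    out["is_tsg"] = out["is_tsg"].astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_ppi_table(path) -> dict[str, list[str]]:
    """Read gene -> PPI partner lists (``gene_id`` + comma-joined ``partners``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("gene_id", "partners"), path)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        partners = [] if pd.isna(row.partners) or row.partners == "" else row.partners.split(",")
        out[row.gene_id] = partners
    return out


def write_ppi_table(ppi: dict[str, list[str]], path) -> None:
    df = pd.DataFrame(
        {"gene_id": list(ppi), "partners": [",".join(v) for v in ppi.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


_CONTEXT_COLUMNS = ("context", "tissue", "ccl_group")


def read_context_map(path) -> pd.DataFrame:
    """Read the cancer-type -> normal tissue / CCL group / organ pairing.

    Mirrors the matched-tissue table used to restrict the analysis to cancer
    types with a transcriptome-profiled tissue of origin.  ``organ`` (for the
    developmental features) may be empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _CONTEXT_COLUMNS, path)
    if "organ" not in df.columns:
        df["organ"] = None
    df["organ"] = df["organ"].where(df["organ"].notna(), None)
    if df["context"].duplicated().any():
        raise ValidationError(f"{path}: duplicated context in context map")
    return df.set_index("context")


def write_context_map(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "context"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run-level configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Run-level settings: input paths, thresholds, CV folds and seed."""

    inputs: dict = field(default_factory=dict)
    alpha: float = 0.05
    ccl_alpha: float = 0.15
    top_fraction: float = 0.10
    expressed_tpm: float = 1.0
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.ccl_alpha < 1:
            raise ValidationError("alpha thresholds must lie in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ValidationError("top_fraction must lie in (0, 1]")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
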