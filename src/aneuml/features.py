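"""Gene-to-arm feature engineering.

Gene-level attributes are turned into chromosome-arm features in three steps:

1. values measured per tissue (expression, essentiality, PPIs, ...) are made
   *tissue-relative* by z-scoring each gene across tissues with the population
   standard deviation (features that are already tissue-relative, such as
   differential PPIs and differential process activity, are kept as-is);
2. each arm is assigned the median score of the genes ranking in the top 10%
   of the arm (density features instead use the fraction of qualifying genes);
3. per-tissue transcriptomic feature vectors are re-standardized within each
   tissue, and any remaining missing arm values are imputed by the feature's
   column median (imputation events are recorded for audit).

The resulting table has one row per (arm, context) instance and exactly the
20 registry columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import DEFAULT_ARMS, FeatureDef, feature_registry

__all__ = [
    "InputBundle",
    "DEV_PERIODS",
    "PERIOD_OF_TIMEPOINT",
    "tissue_relative_zscore",
    "aggregate_arm",
    "density_feature",
    "neutral_restricted_median",
    "essentiality_orientation",
    "cancer_specific_essential_density",
    "ppi_features",
    "tissue_specific_gene_density",
    "paralog_compensation",
    "development_features",
    "collapse_subregions",
    "build_feature_table",
]

log = logging.getLogger(__name__)

#: Developmental time periods and their member time points: fetal
#: (4-20 weeks post-conception), childhood (newborn/infant/toddler) and
#: young (school/teenager/young adult).
DEV_PERIODS = ("fetal", "childhood", "young")
PERIOD_OF_TIMEPOINT = {
    "4wpc": "fetal", "8wpc": "fetal", "12wpc": "fetal",
    "16wpc": "fetal", "20wpc": "fetal",
    "newborn": "childhood", "infant": "childhood", "toddler": "childhood",
    "school": "young", "teenager": "young", "youngadult": "young",
}


@dataclass
class InputBundle:
    """All gene-level tables feeding feature construction.

    Expression matrices are genes x tissues (TPM); essentiality matrices are
    genes x cell-line groups on the original dependency scale (negative =
    essential).  ``development`` holds one genes x time-point matrix per
    organ.  Per-tissue score tables (preferential expression, differential
    PPIs, process activity, eQTL significance) are genes x tissues.
    """

    gene_annotations: pd.DataFrame
    context_map: pd.DataFrame
    normal_expression: pd.DataFrame
    cancer_expression: pd.DataFrame
    crispr_scores: pd.DataFrame
    rnai_scores: pd.DataFrame
    ppi_partners: dict[str, list[str]] = field(default_factory=dict)
    preferential_expression: pd.DataFrame | None = None
    differential_ppi: pd.DataFrame | None = None
    process_activity: pd.DataFrame | None = None
    eqtl_significance: pd.DataFrame | None = None
    development: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def tissue_relative_zscore(values: pd.DataFrame | pd.Series):
    """Standardize each gene across tissues: z_t = (v_t - mean) / sigma.

    ``sigma`` is the population standard deviation over the tissue set.
    Genes with zero spread map to all-zero z-scores.  Requires at least two
    tissues.  NaN entries propagate (they are ignored in mean/sigma).
    """
    if isinstance(values, pd.Series):
        return tissue_relative_zscore(values.to_frame().T).iloc[0]
    if values.shape[1] < 2:
        raise ValueError("tissue-relative z-score needs >=2 tissues")
    arr = values.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape) & ~np.isnan(arr)] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def aggregate_arm(
    gene_scores: pd.Series, top_fraction: float = 0.10, stat: str = "median"
) -> float:
    """Aggregate gene scores on one arm: median of the top-decile genes.

    Genes are ranked descending (ties broken by gene identifier for
    determinism); the top ``ceil(top_fraction * n)`` genes are kept and their
    median (or mean) returned.  With no scored genes the value is missing
    (NaN) and left for the imputation stage.
    """
    scores = gene_scores.dropna()
    n = len(scores)
    if n == 0:
        return float("nan")
    k = math.ceil(top_fraction * n)
    order = scores.sort_values(ascending=False, kind="mergesort")
    order = order.loc[order.index.sort_values()].sort_values(
        ascending=False, kind="mergesort"
    )
    top = order.iloc[:k].to_numpy()
    if stat == "median":
        return float(np.median(top))
    if stat == "mean":
        return float(np.mean(top))
    raise ValueError(f"unknown stat {stat!r}")


def density_feature(flags) -> float:
    """Fraction of flagged genes among all genes on the arm."""
    arr = np.asarray(flags, dtype=bool)
    if arr.size == 0:
        raise ValueError("density feature undefined on an empty arm")
    return float(arr.mean())


def neutral_restricted_median(values, arm_status) -> float:
    """Median of per-sample values restricted to samples where the gene's
    host arm is neutral (avoids expression bias from the event itself).

    Returns NaN when no sample is neutral.
    """
    vals = np.asarray(values, dtype=float)
    status = np.asarray(arm_status, dtype=object)
    if vals.shape != status.shape:
        raise ValueError("values and arm_status must align")
    neutral = status == "neutral"
    if not neutral.any():
        return float("nan")
    return float(np.median(vals[neutral]))


def essentiality_orientation(scores):
    """Reverse dependency scores (multiply by -1) so that more essential
    genes carry higher values."""
    if isinstance(scores, (pd.Series, pd.DataFrame)):
        return -scores
    return -np.asarray(scores, dtype=float)


def cancer_specific_essential_density(
    oriented_scores, threshold: float = 0.5
) -> float:
    """Fraction of arm genes whose oriented CRISPR score exceeds ``threshold``.

    The denominator is all protein-coding genes on the arm (unscored genes
    count as non-essential).
    """
    arr = np.asarray(oriented_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("density feature undefined on an empty arm")
    return float(np.sum(arr > threshold) / arr.size)


def ppi_features(
    gene: str,
    partners: list[str],
    tissue: str,
    expression: pd.DataFrame,
    preferential_expression: pd.DataFrame,
    differential_ppi: pd.DataFrame,
    *,
    expressed_tpm: float = 1.0,
    preferential_threshold: float = 2.0,
    ts_tissue_fraction: float = 0.2,
) -> tuple[float, float, float, float]:
    """The four protein-protein interaction features of one gene in one tissue.

    (i) number of partners expressed in the tissue (TPM > 1); (ii) number of
    partners preferentially expressed there (preferential expression > 2);
    (iii) number of partners expressed in the tissue and in at most 20% of
    tissues; (iv) median differential-PPI score over the partners.  A gene
    that is itself not expressed in the tissue (TPM <= 1) gets all four
    values set to 0.  Partners absent from the expression table are treated
    as not expressed.
    """
    if gene not in expression.index or expression.at[gene, tissue] <= expressed_tpm:
        return (0.0, 0.0, 0.0, 0.0)
    known = [p for p in partners if p in expression.index]
    if len(known) < len(partners):
        log.debug("gene %s: %d partner(s) absent from expression table",
                  gene, len(partners) - len(known))
    if not known:
        return (0.0, 0.0, 0.0, 0.0)
    expr = expression.loc[known]
    expressed_here = expr[tissue] > expressed_tpm
    n_ppis = float(expressed_here.sum())
    n_elev = 0.0
    for p in known:
        if p in preferential_expression.index and (
            preferential_expression.at[p, tissue] > preferential_threshold
        ):
            n_elev += 1
    n_tissues = expr.shape[1]
    breadth = (expr > expressed_tpm).sum(axis=1)
    n_ts = float((expressed_here & (breadth <= ts_tissue_fraction * n_tissues)).sum())
    diffs = [
        differential_ppi.at[p, tissue]
        for p in known
        if p in differential_ppi.index and not pd.isna(differential_ppi.at[p, tissue])
    ]
    med_diff = float(np.median(diffs)) if diffs else 0.0
    return (n_ppis, n_elev, n_ts, med_diff)


def tissue_specific_gene_density(
    expression: pd.DataFrame, arm_genes, tissue: str, z_threshold: float = 2.0
) -> float:
    """Density of arm genes that are tissue-specific (z-score > 2) in a tissue."""
    genes = [g for g in arm_genes if g in expression.index]
    if not genes:
        raise ValueError("no arm genes present in the expression matrix")
    z = tissue_relative_zscore(expression.loc[genes])
    return float((z[tissue] > z_threshold).mean())


def paralog_compensation(
    gene_expr: pd.Series, paralog_expr: pd.Series, eps: float = 0.01
) -> pd.Series:
    """Per-tissue paralog-compensation score of one gene.

    The raw per-tissue value is the expression ratio
    ``(gene TPM + eps) / (paralog TPM + eps)``; it is made tissue-relative by
    z-scoring across tissues, then negated so that *higher* scores mean
    relatively *higher* paralog expression, i.e. more compensation.
    """
    ratio = (gene_expr.astype(float) + eps) / (paralog_expr.astype(float) + eps)
    z = tissue_relative_zscore(ratio)
    return -z


def development_features(organ_expression: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-time-point organ expression into period medians plus a
    cross-period variability column.

    Columns of the input are developmental time points (keys of
    :data:`PERIOD_OF_TIMEPOINT`); output columns are the three period medians
    and ``variability`` (population SD across the period medians).
    """
    unknown = [c for c in organ_expression.columns if c not in PERIOD_OF_TIMEPOINT]
    if unknown:
        raise ValueError(f"unknown developmental time point(s): {unknown}")
    out = {}
    for period in DEV_PERIODS:
        cols = [c for c in organ_expression.columns
                if PERIOD_OF_TIMEPOINT[c] == period]
        if not cols:
            raise ValueError(f"no time points for period {period!r}")
        out[period] = organ_expression[cols].median(axis=1)
    medians = pd.DataFrame(out)
    medians["variability"] = medians[list(DEV_PERIODS)].std(axis=1, ddof=0)
    return medians


def collapse_subregions(arm_by_tissue: pd.DataFrame) -> pd.DataFrame:
    """Collapse sub-region columns (named ``tissue|subregion``) by median.

    Applied at the arm-feature level, after gene-to-arm aggregation.
    """
    base = [c.split("|")[0] for c in arm_by_tissue.columns]
    return arm_by_tissue.T.groupby(base, sort=False).median().T


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------


def _arm_groups(annotations: pd.DataFrame, by_chromosome: bool) -> dict[str, list[str]]:
    key = annotations["arm"].str.rstrip("pq") if by_chromosome else annotations["arm"]
    groups: dict[str, list[str]] = {}
    for gene, arm in key.items():
        groups.setdefault(arm, []).append(gene)
    return groups


def _aggregate_matrix(
    scores: pd.DataFrame, groups: dict[str, list[str]], top_fraction: float
) -> pd.DataFrame:
    """Top-decile median of ``scores`` per arm, for every column at once."""
    rows = {}
    for arm, genes in groups.items():
        present = scores.index.intersection(genes)
        if len(present) == 0:
            rows[arm] = np.full(scores.shape[1], np.nan)
            continue
        sub = scores.loc[present].to_numpy(dtype=float)
        vals = np.full(scores.shape[1], np.nan)
        for j in range(sub.shape[1]):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            k = math.ceil(top_fraction * col.size)
            top = np.sort(col)[::-1][:k]
            vals[j] = np.median(top)
        rows[arm] = vals
    return pd.DataFrame(rows, index=scores.columns).T


def _ppi_count_matrices(bundle: InputBundle, expressed_tpm: float):
    """Vectorized per-gene per-tissue PPI counts via a sparse adjacency."""
    from scipy import sparse

    expr = bundle.normal_expression
    genes = expr.index
    pos = {g: i for i, g in enumerate(genes)}
    rows, cols = [], []
    for g, partners in bundle.ppi_partners.items():
        gi = pos.get(g)
        if gi is None:
            continue
        for p in partners:
            pj = pos.get(p)
            if pj is not None:
                rows.append(gi)
                cols.append(pj)
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(genes), len(genes))
    )
    expressed = (expr.to_numpy(dtype=float) > expressed_tpm)
    n_ppis = A @ expressed.astype(float)

    pref = bundle.preferential_expression
    pref_ind = np.zeros_like(expressed, dtype=float)
    if pref is not None:
        aligned = pref.reindex(index=genes, columns=expr.columns)
        pref_ind = (aligned.to_numpy(dtype=float) > 2.0).astype(float)
    n_elev = A @ pref_ind

    breadth = expressed.sum(axis=1, keepdims=True)
    narrow = expressed & (breadth <= 0.2 * expr.shape[1])
    n_ts = A @ narrow.astype(float)

    # median over partners of the differential-PPI scores, per tissue
    diff = bundle.differential_ppi
    med_diff = np.zeros_like(expressed, dtype=float)
    if diff is not None:
        diff_arr = diff.reindex(index=genes, columns=expr.columns).to_numpy(dtype=float)
        indptr, indices = A.indptr, A.indices
        for i in range(len(genes)):
            part = indices[indptr[i]: indptr[i + 1]]
            if part.size:
                med_diff[i] = np.nanmedian(diff_arr[part], axis=0)

    mask = ~expressed  # unexpressed gene: all four PPI features are 0
    out = {}
    for name, mat in (
        ("num_ppis", n_ppis), ("num_elevated_ppis", n_elev),
        ("num_tissue_specific_ppis", n_ts), ("differential_ppis", med_diff),
    ):
        m = np.asarray(mat, dtype=float)
        m[mask] = 0.0
        out[name] = pd.DataFrame(m, index=genes, columns=expr.columns)
    return out


def build_feature_table(
    bundle: InputBundle,
    registry: list[FeatureDef] | None = None,
    *,
    top_fraction: float = 0.10,
    expressed_tpm: float = 1.0,
    essential_prob_threshold: float = 0.8,
    by_chromosome: bool = False,
    standardize_transcriptomic: bool = True,
    impute: bool = True,
) -> pd.DataFrame:
    """Assemble the complete (arm x context) x 20 feature table.

    Each cancer context contributes one instance per arm; its cancer-tissue
    features come from its own expression/essentiality columns and its
    normal-tissue features from the matched tissue (and organ, for the
    developmental features) of the context map.  Contexts without a mapped
    tissue are dropped with a log message.  The result is deterministic given
    the inputs: no randomness is involved.

    Returns a DataFrame with a (arm, context) MultiIndex; the list of imputed
    cells is recorded in ``df.attrs["imputed"]``.
    """
    if registry is None:
        registry = feature_registry()
    ann = bundle.gene_annotations
    groups = _arm_groups(ann, by_chromosome)
    arm_ids = sorted(groups, key=_arm_sort_key)

    cmap = bundle.context_map
    contexts = []
    for ctx, row in cmap.iterrows():
        tissue = row["tissue"]
        if tissue is None or pd.isna(tissue) or (
            tissue not in {c.split("|")[0] for c in bundle.normal_expression.columns}
        ):
            log.info("context %s dropped: no matched normal tissue", ctx)
            continue
        contexts.append(ctx)

    names = [f.name for f in registry]
    by_name = {f.name: f for f in registry}
    missing = [n for n in (f.name for f in feature_registry()) if n not in by_name]
    if missing:
        log.warning("feature registry missing %s; table will have %d columns",
                    missing, len(names))

    # ---- arm-category densities (context-independent) ----------------------
    arm_scalar: dict[str, pd.Series] = {}
    og, tsg, ess = {}, {}, {}
    for arm, genes in groups.items():
        sub = ann.loc[genes]
        og[arm] = density_feature(sub["is_og"].to_numpy())
        tsg[arm] = density_feature(sub["is_tsg"].to_numpy())
        ess[arm] = density_feature(
            (sub["essentiality_prob"].to_numpy(dtype=float) > essential_prob_threshold)
        )
    arm_scalar["og_density"] = pd.Series(og)
    arm_scalar["tsg_density"] = pd.Series(tsg)
    arm_scalar["essential_gene_density"] = pd.Series(ess)

    # ---- arm x column matrices for tissue-mapped features ------------------
    arm_matrix: dict[str, pd.DataFrame] = {}

    def _register(name: str, gene_scores: pd.DataFrame) -> None:
        if name not in by_name:
            return
        agg = collapse_subregions(
            _aggregate_matrix(gene_scores, groups, top_fraction)
        )
        arm_matrix[name] = agg

    # cancer tissues ---------------------------------------------------------
    _register("tcga_expression", tissue_relative_zscore(bundle.cancer_expression))
    oriented_crispr = essentiality_orientation(bundle.crispr_scores)
    _register("crispr_essentiality", tissue_relative_zscore(oriented_crispr))
    _register("rnai_essentiality",
              tissue_relative_zscore(essentiality_orientation(bundle.rnai_scores)))
    if "cancer_essential_density" in by_name:
        dens = {}
        for arm, genes in groups.items():
            present = oriented_crispr.index.intersection(genes)
            if len(present) == 0:
                dens[arm] = np.full(oriented_crispr.shape[1], np.nan)
            else:
                sub = oriented_crispr.loc[present].to_numpy(dtype=float)
                dens[arm] = np.nansum(sub > 0.5, axis=0) / len(genes)
        arm_matrix["cancer_essential_density"] = pd.DataFrame(
            dens, index=oriented_crispr.columns
        ).T

    # normal tissues ---------------------------------------------------------
    expr = bundle.normal_expression
    z_expr = tissue_relative_zscore(expr)
    _register("gtex_expression", z_expr)
    if "tissue_specific_gene_density" in by_name:
        ts = {}
        for arm, genes in groups.items():
            present = z_expr.index.intersection(genes)
            if len(present) == 0:
                ts[arm] = np.full(z_expr.shape[1], np.nan)
            else:
                ts[arm] = (z_expr.loc[present].to_numpy(dtype=float) > 2.0).mean(axis=0)
        arm_matrix["tissue_specific_gene_density"] = collapse_subregions(
            pd.DataFrame(ts, index=z_expr.columns).T
        )

    if bundle.ppi_partners:
        counts = _ppi_count_matrices(bundle, expressed_tpm)
        for name in ("num_ppis", "num_elevated_ppis", "num_tissue_specific_ppis"):
            _register(name, tissue_relative_zscore(counts[name]))
        # differential PPIs are already tissue-relative: maintained
        _register("differential_ppis", counts["differential_ppis"])
    if bundle.process_activity is not None:
        _register("process_activity", bundle.process_activity)  # already relative
    if bundle.eqtl_significance is not None:
        _register("eqtl_significance",
                  tissue_relative_zscore(bundle.eqtl_significance))

    if "paralog_compensation" in by_name:
        paired = ann[ann["paralog"].notna()]
        paired = paired[paired["paralog"].isin(expr.index)
                        & paired.index.isin(expr.index)]
        if len(paired):
            g = expr.loc[paired.index].to_numpy(dtype=float)
            p = expr.loc[paired["paralog"]].to_numpy(dtype=float)
            ratio = pd.DataFrame(
                (g + 0.01) / (p + 0.01), index=paired.index, columns=expr.columns
            )
            _register("paralog_compensation", -tissue_relative_zscore(ratio))

    # development ------------------------------------------------------------
    if bundle.development:
        period_tables: dict[str, dict[str, pd.Series]] = {
            p: {} for p in (*DEV_PERIODS, "variability")
        }
        for organ, table in bundle.development.items():
            med = development_features(table)
            for p in (*DEV_PERIODS, "variability"):
                period_tables[p][organ] = med[p]
        dev_name = {
            "fetal": "devel_expression_fetal",
            "childhood": "devel_expression_childhood",
            "young": "devel_expression_young",
            "variability": "devel_expression_variability",
        }
        for p, cols in period_tables.items():
            mat = pd.DataFrame(cols)
            if mat.shape[1] >= 2:
                mat = tissue_relative_zscore(mat)
            _register(dev_name[p], mat)

    # ---- assemble instances -------------------------------------------------
    index = pd.MultiIndex.from_product([arm_ids, contexts], names=["arm", "context"])
    table = pd.DataFrame(index=index, columns=names, dtype=float)
    ctx_tissue = {c: cmap.at[c, "tissue"] for c in contexts}
    ctx_ccl = {c: cmap.at[c, "ccl_group"] for c in contexts}
    ctx_organ = {c: cmap.at[c, "organ"] for c in contexts}

    for f in registry:
        name = f.name
        if name in arm_scalar:
            vals = arm_scalar[name]
            for ctx in contexts:
                table.loc[(slice(None), ctx), name] = vals.reindex(arm_ids).to_numpy()
            continue
        mat = arm_matrix.get(name)
        if mat is None:
            continue
        for ctx in contexts:
            if f.category == "cancer":
                col = ctx if ctx in mat.columns else ctx_ccl[ctx]
            elif f.source == "development":
                col = ctx_organ[ctx]
            else:
                col = ctx_tissue[ctx]
            if col is None or col not in mat.columns:
                continue
            table.loc[(slice(None), ctx), name] = (
                mat[col].reindex(arm_ids).to_numpy()
            )

    # ---- within-tissue standardization of transcriptomic features ----------
    if standardize_transcriptomic:
        for f in registry:
            if not f.transcriptomic:
                continue
            for ctx in contexts:
                sel = (slice(None), ctx)
                v = table.loc[sel, f.name].to_numpy(dtype=float)
                if np.isnan(v).all():
                    continue
                sd = np.nanstd(v)
                if sd > 0:
                    table.loc[sel, f.name] = (v - np.nanmean(v)) / sd

    # ---- imputation ---------------------------------------------------------
    imputed: list[tuple[str, str, str]] = []
    if impute:
        for name in table.columns:
            col = table[name]
            if col.isna().any():
                fill = col.median()
                if np.isnan(fill):  # feature absent from the whole bundle
                    fill = 0.0
                for arm, ctx in table.index[col.isna()]:
                    imputed.append((arm, ctx, name))
                table[name] = col.fillna(fill)
        if imputed:
            log.info("imputed %d missing cells by column medians", len(imputed))
    table.attrs["imputed"] = imputed
    return table


def _arm_sort_key(arm: str):
    chrom = arm.rstrip("pq")
    return (int(chrom) if chrom.isdigit() else 99, arm)
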