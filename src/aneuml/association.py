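"""Feature-frequency correlations and the paralog-compensation analysis.

The correlation screen relates per-arm feature medians (across contexts) to
per-arm median gain/loss frequencies via Spearman correlation, with
Benjamini-Hochberg adjustment over the whole feature x event family.  The
paralog analysis groups recurrently lost genes by their minimal CRISPR
dependency score (essential <= -0.5, non-essential >= -0.3, intermediate in
between, on the original unreversed scale) and tests whether the arm status
of their paralogs departs from independence (chi-square), plus a two-sample
Kolmogorov-Smirnov comparison of the score distributions behind gained vs
lost paralogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ArmLabel, GisticArmRecord

__all__ = [
    "CorrelationResult",
    "feature_frequency_correlation",
    "bh_adjust",
    "essentiality_grouping",
    "paralog_status_association",
    "essentiality_distribution_test",
    "paralog_arm_status",
]

log = logging.getLogger(__name__)

ESSENTIAL_MAX = -0.5      # min CRISPR score at or below => essential
NON_ESSENTIAL_MIN = -0.3  # min CRISPR score at or above => non-essential


@dataclass
class CorrelationResult:
    feature_name: str
    event: str            # "gain" | "loss"
    rho: float
    p: float
    p_adj: float = float("nan")
    n: int = 0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def feature_frequency_correlation(
    features: pd.DataFrame, records: list[GisticArmRecord]
) -> list[CorrelationResult]:
    """Spearman correlation of each feature with gain and loss frequency.

    Per arm, the feature value and the gain (loss) frequency are medians
    across contexts; all feature x event pairs form one BH family.  Features
    that are constant across arms have no defined rank correlation and are
    flagged with NaN rho (excluded from the BH family).
    """
    freq = pd.DataFrame(
        [(r.arm_id, r.amp_freq, r.del_freq) for r in records],
        columns=["arm", "gain_freq", "loss_freq"],
    ).groupby("arm").median()
    feat_med = features.groupby(level="arm").median()
    common = feat_med.index.intersection(freq.index)
    if len(common) < 4:
        raise ValueError("need >=4 arms with both feature and frequency values")
    feat_med = feat_med.loc[common]
    freq = freq.loc[common]

    results: list[CorrelationResult] = []
    for feat in feat_med.columns:
        x = feat_med[feat].to_numpy(dtype=float)
        for event, col in (("gain", "gain_freq"), ("loss", "loss_freq")):
            yv = freq[col].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                log.warning("constant vector for %s/%s; rho undefined", feat, event)
                results.append(
                    CorrelationResult(feat, event, float("nan"), float("nan"), n=len(x))
                )
                continue
            rho, p = stats.spearmanr(x, yv)
            results.append(CorrelationResult(feat, event, float(rho), float(p),
                                             n=len(x)))
    defined = [r for r in results if not np.isnan(r.p)]
    if defined:
        adj = bh_adjust([r.p for r in defined])
        for r, a in zip(defined, adj):
            r.p_adj = float(a)
    return results


def essentiality_grouping(min_crispr_scores: pd.Series) -> pd.Series:
    """Group genes by their minimal CRISPR score across matched cell lines.

    Scores are on the original dependency scale (more negative = more
    essential).  NaN scores exclude the gene (logged).
    """
    scores = min_crispr_scores.astype(float)
    n_missing = int(scores.isna().sum())
    if n_missing:
        log.info("excluding %d gene(s) without an essentiality score", n_missing)
        scores = scores.dropna()
    group = pd.Series("intermediate", index=scores.index, name="essentiality_group")
    group[scores <= ESSENTIAL_MAX] = "essential"
    group[scores >= NON_ESSENTIAL_MIN] = "non-essential"
    return group


_GROUP_ORDER = ("essential", "intermediate", "non-essential")
_STATUS_ORDER = ("gain", "loss", "neutral")


def paralog_status_association(
    groups: pd.Series, paralog_status: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """3x3 contingency table (essentiality group x paralog arm status) and
    the chi-square test of independence (asymptotic, no continuity
    correction)."""
    common = groups.index.intersection(paralog_status.index)
    table = pd.DataFrame(
        0, index=list(_GROUP_ORDER), columns=list(_STATUS_ORDER), dtype=int
    )
    crosstab = pd.crosstab(groups.loc[common], paralog_status.loc[common])
    for g in crosstab.index:
        for s in crosstab.columns:
            table.loc[g, s] = int(crosstab.loc[g, s])
    # drop all-zero rows/columns before testing (they carry no information)
    t = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    chi2, p, _dof, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        log.warning("chi-square expected cell count < 5; test still reported")
    return table, float(chi2), float(p)


def essentiality_distribution_test(
    scores_gained_paralog, scores_lost_paralog
) -> tuple[float, float]:
    """Two-sample KS test comparing essentiality scores of genes whose
    paralogs are gained vs lost."""
    a = np.asarray(scores_gained_paralog, dtype=float)
    b = np.asarray(scores_lost_paralog, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def paralog_arm_status(
    annotations: pd.DataFrame,
    labels: list[ArmLabel] | pd.Series,
    context: str,
) -> pd.Series:
    """Arm status of each gene's paralog in one context.

    Returns, for every gene with an assigned paralog, the gain/loss/neutral
    label of the arm on which the paralog resides.
    """
    if isinstance(labels, pd.Series):
        lab = labels.xs(context, level="context")
    else:
        lab = pd.Series(
            {l.arm_id: l.label for l in labels if l.context_id == context}
        )
    paired = annotations[annotations["paralog"].notna()]
    paralog_arm = paired["paralog"].map(annotations["arm"])
    status = paralog_arm.map(lab)
    return status.dropna().rename("paralog_arm_status")
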