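"""Gain/loss/neutral calls from arm-level significance records.

An arm is called gained (lost) in a context when the q-value of its recurrent
amplification (deletion) falls below the significance threshold: 0.05 for
tumor cohorts, 0.15 for cancer cell-line groups.  When both directions are
significant the lower q-value wins; on a q-value tie the more frequent event
wins.  A whole chromosome is called gained (lost) only when both of its arms
are significant in that direction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_model import ArmLabel, GisticArmRecord

__all__ = [
    "LabelPolicy",
    "TUMOR_POLICY",
    "CCL_POLICY",
    "label_arm",
    "label_ccl",
    "label_whole_chromosome",
    "label_table",
    "label_chromosome_table",
    "label_counts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelPolicy:
    """Significance threshold and NaN handling for event calling."""

    alpha: float = 0.05
    nan_is_insignificant: bool = False  # treat NaN q as 1.0 instead of erroring

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")


TUMOR_POLICY = LabelPolicy(alpha=0.05)
CCL_POLICY = LabelPolicy(alpha=0.15)


def _clean_q(q: float, policy: LabelPolicy, rec: GisticArmRecord) -> float:
    if np.isnan(q):
        if policy.nan_is_insignificant:
            return 1.0
        raise ValueError(
            f"NaN q-value for arm {rec.arm_id!r}, context {rec.context_id!r}; "
            "pre-impute or drop, or set nan_is_insignificant"
        )
    return q


def _resolve(amp_q, del_q, amp_freq, del_freq, alpha, where: str) -> str:
    amp_sig = amp_q < alpha
    del_sig = del_q < alpha
    if amp_sig and del_sig:
        if amp_q < del_q:
            return "gain"
        if del_q < amp_q:
            return "loss"
        # q-value tie: the more frequent event is selected
        if amp_freq > del_freq:
            return "gain"
        if del_freq > amp_freq:
            return "loss"
        log.warning("q-value and frequency tie at %s; resolving to gain", where)
        return "gain"
    if amp_sig:
        return "gain"
    if del_sig:
        return "loss"
    return "neutral"


def label_arm(rec: GisticArmRecord, policy: LabelPolicy = TUMOR_POLICY) -> ArmLabel:
    """Call one arm in one context: gain, loss or neutral."""
    amp_q = _clean_q(rec.amp_q, policy, rec)
    del_q = _clean_q(rec.del_q, policy, rec)
    label = _resolve(amp_q, del_q, rec.amp_freq, rec.del_freq, policy.alpha,
                     f"({rec.arm_id}, {rec.context_id})")
    return ArmLabel(rec.arm_id, rec.context_id, label)


def label_ccl(rec: GisticArmRecord, policy: LabelPolicy = CCL_POLICY) -> ArmLabel:
    """Call one arm in a cell-line group (default alpha 0.15)."""
    return label_arm(rec, policy)


def label_whole_chromosome(
    p_rec: GisticArmRecord | None,
    q_rec: GisticArmRecord,
    policy: LabelPolicy = TUMOR_POLICY,
) -> ArmLabel:
    """Call a whole chromosome from its two arm records.

    Gain requires both arms' amplification q-values below alpha; loss requires
    both deletion q-values below alpha.  If both directions qualify, the
    direction whose worse (larger) arm-level q-value is smaller wins, with the
    frequency tie-break on the mean arm frequency.  For acrocentric
    chromosomes ``p_rec`` is None and the call falls back to the q-arm alone.
    """
    if p_rec is None:
        single = label_arm(q_rec, policy)
        return ArmLabel(q_rec.chromosome, q_rec.context_id, single.label)
    if p_rec.chromosome != q_rec.chromosome:
        raise ValueError(
            f"arm records from different chromosomes: {p_rec.arm_id}, {q_rec.arm_id}"
        )
    if p_rec.context_id != q_rec.context_id:
        raise ValueError(
            f"arm records from different contexts: {p_rec.context_id}, "
            f"{q_rec.context_id}"
        )
    amp_qs = [_clean_q(p_rec.amp_q, policy, p_rec), _clean_q(q_rec.amp_q, policy, q_rec)]
    del_qs = [_clean_q(p_rec.del_q, policy, p_rec), _clean_q(q_rec.del_q, policy, q_rec)]
    # both-arm rule collapses to comparing the worse arm of each direction
    amp_q = max(amp_qs)
    del_q = max(del_qs)
    amp_freq = 0.5 * (p_rec.amp_freq + q_rec.amp_freq)
    del_freq = 0.5 * (p_rec.del_freq + q_rec.del_freq)
    label = _resolve(amp_q, del_q, amp_freq, del_freq, policy.alpha,
                     f"(chr{q_rec.chromosome}, {q_rec.context_id})")
    return ArmLabel(q_rec.chromosome, q_rec.context_id, label)


def label_table(
    records: Iterable[GisticArmRecord], policy: LabelPolicy = TUMOR_POLICY
) -> list[ArmLabel]:
    """Label every record in a table."""
    return [label_arm(r, policy) for r in records]


def label_chromosome_table(
    records: Sequence[GisticArmRecord], policy: LabelPolicy = TUMOR_POLICY
) -> list[ArmLabel]:
    """Group arm records by (chromosome, context) and call whole chromosomes."""
    by_key: dict[tuple[str, str], dict[str, GisticArmRecord]] = {}
    for rec in records:
        arm = rec.arm_id[-1]
        if arm not in ("p", "q"):
            raise ValueError(f"record {rec.arm_id!r} is not an arm identifier")
        by_key.setdefault((rec.chromosome, rec.context_id), {})[arm] = rec
    labels = []
    for (chrom, _ctx), arms in sorted(by_key.items()):
        if "q" not in arms:
            raise ValueError(f"chromosome {chrom} missing its q arm")
        labels.append(label_whole_chromosome(arms.get("p"), arms["q"], policy))
    return labels


def label_counts(labels: Iterable[ArmLabel]) -> tuple[int, int, int]:
    """Return (n_gain, n_loss, n_neutral)."""
    c = Counter(lbl.label for lbl in labels)
    return c.get("gain", 0), c.get("loss", 0), c.get("neutral", 0)
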