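"""Synthetic input cohorts with planted feature-to-label effects.

The generator emulates the seven input families of the real analysis — arm
significance tables, gene annotations, normal/cancer/cell-line expression,
CRISPR/RNAi dependency screens, PPI annotations, process-activity and eQTL
tables, and developmental expression — as one self-consistent bundle.  A
configurable set of *planted* effects couples true arm-level feature values
to gain/loss labels through a logistic model, so that the whole pipeline
(labeling, feature engineering, modeling, interpretation) can be exercised
offline and its ability to recover the planted signal can be measured.

Every table passes the IO validators, and the arm significance records are
constructed with a guaranteed q-value gap around the significance threshold,
so the labeling module reproduces the generator's intended labels exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import DEFAULT_ARMS, GisticArmRecord
from .features import DEV_PERIODS, PERIOD_OF_TIMEPOINT, InputBundle

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "TRUTH_FEATURES",
    "generate_cohort",
    "recovery_report",
]

#: Features whose truth values the generator can couple to labels.
TRUTH_FEATURES = (
    "og_density",
    "tsg_density",
    "essential_gene_density",
    "tcga_expression",
    "gtex_expression",
    "paralog_compensation",
)

#: Default planted effects: signed coefficients on the event log-odds.
#: High TSG density suppresses gains (negative selection); high OG density
#: suppresses losses; high cancer expression favors gains; high paralog
#: compensation favors losses.
DEFAULT_EFFECTS = {
    ("tsg_density", "gain"): -2.0,
    ("og_density", "loss"): -1.5,
    ("tcga_expression", "gain"): 1.0,
    ("paralog_compensation", "loss"): 1.0,
}

DEV_TIMEPOINTS = tuple(PERIOD_OF_TIMEPOINT)


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the real analysis scale: 39 autosomal arms, 24 cancer
    contexts matched to 20 normal tissues, 50-300 protein-coding genes per
    arm (log-uniform), 10 cell-line contexts, 5% label noise.
    """

    n_arms: int = 39
    n_contexts: int = 24
    genes_per_arm: tuple[int, int] = (50, 300)
    n_tissues: int = 20
    n_organs: int = 7
    n_ccl_contexts: int = 10
    paralog_fraction: float = 0.6
    mean_ppi_degree: float = 8.0
    effect_sizes: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    gain_intercept: float = -2.4
    loss_intercept: float = -0.55
    label_noise: float = 0.05
    alpha: float = 0.05
    ccl_alpha: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_arms, self.n_contexts, self.n_tissues) <= 0:
            raise ValueError("all sizes must be positive")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for (feat, event), coef in self.effect_sizes.items():
            if feat not in TRUTH_FEATURES:
                raise ValueError(f"no planted-truth channel for feature {feat!r}")
            if event not in ("gain", "loss"):
                raise ValueError(f"unknown event {event!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    features: pd.DataFrame          # (arm, context) x truth features, standardized
    coefficients: dict[tuple[str, str], float]
    p_gain: pd.Series               # per-instance true gain probability
    p_loss: pd.Series               # conditional loss probability given no gain
    labels: pd.Series               # final labels encoded into the records
    clean_labels: pd.Series         # labels before noise flips
    ccl_labels: pd.Series | None = None


@dataclass
class SyntheticCohort:
    """A full synthetic study: tumor bundle, CCL bundle and the truth."""

    bundle: InputBundle
    records: list[GisticArmRecord]
    ccl_bundle: InputBundle
    ccl_records: list[GisticArmRecord]
    truth: SyntheticTruth
    config: GeneratorConfig


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream: adding a table family never perturbs others."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_q_records(index, labels, alpha, rng) -> list[GisticArmRecord]:
    """Arm significance records with a q-value gap: events get q < alpha/2,
    non-events q > 2*alpha (capped at 1), frequencies consistent with labels."""
    hi_lo = min(2 * alpha, 0.99)
    records = []
    for (arm, ctx), lab in zip(index, labels):
        q_sig = rng.uniform(0, alpha / 2)
        q_ns_a = rng.uniform(hi_lo, 1.0)
        q_ns_b = rng.uniform(hi_lo, 1.0)
        f_event = rng.uniform(0.3, 0.7)
        f_a = rng.uniform(0.0, 0.2)
        f_b = rng.uniform(0.0, 0.2)
        if lab == "gain":
            rec = GisticArmRecord(arm, ctx, q_sig, q_ns_a, f_event, f_b)
        elif lab == "loss":
            rec = GisticArmRecord(arm, ctx, q_ns_a, q_sig, f_b, f_event)
        else:
            rec = GisticArmRecord(arm, ctx, q_ns_a, q_ns_b, f_a, f_b)
        records.append(rec)
    return records


def _lognormal_tpm(rng, shape, mean_log2=3.5, sd_log2=1.5):
    return 2.0 ** rng.normal(mean_log2, sd_log2, size=shape)


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a complete input bundle plus its ground truth.

    See the module docstring for the construction; the key contract is that
    (1) the labeling module applied to ``records`` reproduces ``truth.labels``
    exactly, and (2) the planted coefficients act on *standardized realized*
    arm features, so stronger coefficients yield stronger feature-label
    coupling in the assembled feature table.
    """
    cfg = config or GeneratorConfig()
    seed = cfg.seed

    arms = list(DEFAULT_ARMS[: cfg.n_arms])
    if cfg.n_arms > len(DEFAULT_ARMS):
        arms += [f"x{i}q" for i in range(cfg.n_arms - len(DEFAULT_ARMS))]
    contexts = [f"C{i + 1:02d}" for i in range(cfg.n_contexts)]
    tissues = [f"T{i + 1:02d}" for i in range(cfg.n_tissues)]
    organs = [f"O{i + 1}" for i in range(cfg.n_organs)]
    ccl_groups = [f"L{i + 1:02d}" for i in range(cfg.n_contexts)]

    # ---- context map -------------------------------------------------------
    rng = _stream(seed, "contexts")
    ctx_tissue = [tissues[i % cfg.n_tissues] for i in range(cfg.n_contexts)]
    ctx_organ = [organs[i % cfg.n_organs] for i in range(cfg.n_contexts)]
    context_map = pd.DataFrame(
        {"tissue": ctx_tissue, "ccl_group": ccl_groups, "organ": ctx_organ},
        index=pd.Index(contexts, name="context"),
    )

    # ---- genes on arms -----------------------------------------------------
    rng = _stream(seed, "genes")
    lo, hi = cfg.genes_per_arm
    n_per_arm = np.round(
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(arms)))
    ).astype(int)
    gene_arm = np.repeat(arms, n_per_arm)
    n_genes = len(gene_arm)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    # OG/TSG flags and essentiality probabilities with arm-varying densities
    rng = _stream(seed, "annotations")
    d_og = rng.beta(2, 38, size=len(arms))
    d_tsg = rng.beta(2, 38, size=len(arms))
    d_ess = rng.beta(2, 8, size=len(arms))
    arm_pos = {a: i for i, a in enumerate(arms)}
    gene_arm_idx = np.array([arm_pos[a] for a in gene_arm])
    is_og = rng.random(n_genes) < d_og[gene_arm_idx]
    is_tsg = ~is_og & (rng.random(n_genes) < d_tsg[gene_arm_idx])
    hub = rng.random(n_genes) < d_ess[gene_arm_idx]
    ess_prob = np.where(hub, rng.beta(8, 2, n_genes), rng.beta(2, 8, n_genes))

    rng = _stream(seed, "paralogs")
    has_par = rng.random(n_genes) < cfg.paralog_fraction
    partner_idx = rng.integers(0, n_genes, size=n_genes)
    partner_idx[partner_idx == np.arange(n_genes)] = (
        partner_idx[partner_idx == np.arange(n_genes)] + 1
    ) % n_genes
    paralog = np.where(has_par, np.array(genes, dtype=object)[partner_idx], None)

    annotations = pd.DataFrame(
        {
            "arm": gene_arm,
            "is_og": is_og,
            "is_tsg": is_tsg,
            "essentiality_prob": ess_prob,
            "paralog": paralog,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    # ---- planted arm-level truth -------------------------------------------
    index = pd.MultiIndex.from_product([arms, contexts], names=["arm", "context"])
    n_inst = len(index)
    inst_arm = index.get_level_values("arm").to_numpy()
    inst_ctx = index.get_level_values("context").to_numpy()
    inst_arm_idx = np.array([arm_pos[a] for a in inst_arm])
    ctx_pos = {c: i for i, c in enumerate(contexts)}
    inst_ctx_idx = np.array([ctx_pos[c] for c in inst_ctx])
    tissue_pos = {t: i for i, t in enumerate(tissues)}
    inst_tis_idx = np.array([tissue_pos[ctx_tissue[i]] for i in inst_ctx_idx])

    rng = _stream(seed, "truth")
    # realized densities per arm
    dens_og = np.array(
        [is_og[gene_arm_idx == i].mean() for i in range(len(arms))]
    )
    dens_tsg = np.array(
        [is_tsg[gene_arm_idx == i].mean() for i in range(len(arms))]
    )
    dens_ess = np.array(
        [(ess_prob[gene_arm_idx == i] > 0.8).mean() for i in range(len(arms))]
    )
    shift_cancer = rng.normal(0, 1, size=(len(arms), cfg.n_contexts))
    shift_normal = rng.normal(0, 1, size=(len(arms), cfg.n_tissues))
    shift_comp = rng.normal(0, 1, size=(len(arms), cfg.n_tissues))

    truth_vals = {
        "og_density": dens_og[inst_arm_idx],
        "tsg_density": dens_tsg[inst_arm_idx],
        "essential_gene_density": dens_ess[inst_arm_idx],
        "tcga_expression": shift_cancer[inst_arm_idx, inst_ctx_idx],
        "gtex_expression": shift_normal[inst_arm_idx, inst_tis_idx],
        "paralog_compensation": shift_comp[inst_arm_idx, inst_tis_idx],
    }
    truth = pd.DataFrame(
        {k: _standardize(np.asarray(v, dtype=float)) for k, v in truth_vals.items()},
        index=index,
    )

    # ---- labels ------------------------------------------------------------
    rng = _stream(seed, "labels")
    lo_gain = np.full(n_inst, cfg.gain_intercept)
    lo_loss = np.full(n_inst, cfg.loss_intercept)
    for (feat, event), coef in cfg.effect_sizes.items():
        target = lo_gain if event == "gain" else lo_loss
        target += coef * truth[feat].to_numpy()
    p_gain = _sigmoid(lo_gain)
    p_loss = _sigmoid(lo_loss)
    u = rng.random(n_inst)
    is_gain = u < p_gain
    is_loss = ~is_gain & (rng.random(n_inst) < p_loss)
    labels = np.where(is_gain, "gain", np.where(is_loss, "loss", "neutral"))
    clean = labels.copy()
    flip = rng.random(n_inst) < cfg.label_noise
    others = {"gain": ("loss", "neutral"), "loss": ("gain", "neutral"),
              "neutral": ("gain", "loss")}
    pick = rng.integers(0, 2, size=n_inst)
    labels = np.array(
        [others[l][p] if f else l for l, p, f in zip(labels, pick, flip)],
        dtype=object,
    )

    rng = _stream(seed, "gistic")
    records = _draw_q_records(index, labels, cfg.alpha, rng)

    # ---- expression matrices ------------------------------------------------
    rng = _stream(seed, "normal_expression")
    base_log2 = rng.normal(3.5, 1.5, size=n_genes)
    noise = rng.normal(0, 0.3, size=(n_genes, cfg.n_tissues))
    log2_normal = base_log2[:, None] + 0.5 * shift_normal[gene_arm_idx] + noise
    # plant paralog compensation: paralog-bearing genes are relatively
    # under-expressed where their arm's compensation shift is high
    log2_normal[has_par] -= 0.5 * shift_comp[gene_arm_idx[has_par]]
    normal_expression = pd.DataFrame(
        2.0 ** log2_normal, index=genes, columns=tissues
    )

    rng = _stream(seed, "cancer_expression")
    noise = rng.normal(0, 0.3, size=(n_genes, cfg.n_contexts))
    cancer_expression = pd.DataFrame(
        2.0 ** (base_log2[:, None] + 0.5 * shift_cancer[gene_arm_idx] + noise),
        index=genes, columns=contexts,
    )

    # ---- dependency screens --------------------------------------------------
    rng = _stream(seed, "essentiality")
    crispr = (
        -1.2 * ess_prob[:, None]
        + 0.15
        + rng.normal(0, 0.2, size=(n_genes, cfg.n_contexts))
    )
    crispr_scores = pd.DataFrame(crispr, index=genes, columns=ccl_groups)
    rnai = (
        -1.0 * ess_prob[:, None]
        + 0.1
        + rng.normal(0, 0.25, size=(n_genes, cfg.n_contexts))
    )
    rnai_scores = pd.DataFrame(rnai, index=genes, columns=ccl_groups)

    # ---- PPI / process activity / eQTL --------------------------------------
    rng = _stream(seed, "ppi")
    degree = rng.poisson(cfg.mean_ppi_degree, size=n_genes)
    ppi_partners = {
        g: list(
            np.array(genes, dtype=object)[
                rng.choice(n_genes, size=min(d, n_genes - 1), replace=False)
            ]
        )
        for g, d in zip(genes, degree)
    }
    preferential = pd.DataFrame(
        rng.normal(0, 1.5, size=(n_genes, cfg.n_tissues)),
        index=genes, columns=tissues,
    )
    differential_ppi = pd.DataFrame(
        rng.normal(0, 1.0, size=(n_genes, cfg.n_tissues)),
        index=genes, columns=tissues,
    )
    rng = _stream(seed, "activity")
    process_activity = pd.DataFrame(
        rng.normal(0, 1.0, size=(n_genes, cfg.n_tissues)),
        index=genes, columns=tissues,
    )
    eqtl = pd.DataFrame(
        rng.exponential(1.0, size=(n_genes, cfg.n_tissues)),
        index=genes, columns=tissues,
    )

    # ---- development ---------------------------------------------------------
    rng = _stream(seed, "development")
    development = {}
    for organ in organs:
        tp = rng.normal(0, 0.4, size=(n_genes, len(DEV_TIMEPOINTS)))
        development[organ] = pd.DataFrame(
            2.0 ** (base_log2[:, None] + tp), index=genes, columns=DEV_TIMEPOINTS
        )

    bundle = InputBundle(
        gene_annotations=annotations,
        context_map=context_map,
        normal_expression=normal_expression,
        cancer_expression=cancer_expression,
        crispr_scores=crispr_scores,
        rnai_scores=rnai_scores,
        ppi_partners=ppi_partners,
        preferential_expression=preferential,
        differential_ppi=differential_ppi,
        process_activity=process_activity,
        eqtl_significance=eqtl,
        development=development,
    )

    # ---- CCL bundle: same truth, fresh noise, CCL alpha ----------------------
    rng = _stream(seed, "ccl")
    ccl_contexts = contexts[: cfg.n_ccl_contexts]
    ccl_index = pd.MultiIndex.from_product(
        [arms, ccl_contexts], names=["arm", "context"]
    )
    keep = index.get_level_values("context").isin(ccl_contexts)
    lo_g = lo_gain[keep]
    lo_l = lo_loss[keep]
    u = rng.random(len(ccl_index))
    g2 = u < _sigmoid(lo_g)
    l2 = ~g2 & (rng.random(len(ccl_index)) < _sigmoid(lo_l))
    ccl_labels = np.where(g2, "gain", np.where(l2, "loss", "neutral"))
    ccl_records = _draw_q_records(ccl_index, ccl_labels, cfg.ccl_alpha, rng)

    noise = rng.normal(0, 0.35, size=(n_genes, len(ccl_contexts)))
    ccl_expression = pd.DataFrame(
        2.0
        ** (
            base_log2[:, None]
            + 0.5 * shift_cancer[gene_arm_idx][:, : len(ccl_contexts)]
            + noise
        ),
        index=genes,
        columns=[context_map.at[c, "ccl_group"] for c in ccl_contexts],
    )
    ccl_context_map = context_map.loc[ccl_contexts].copy()
    ccl_context_map["organ"] = None  # no matched developmental organ for CCLs
    ccl_bundle = InputBundle(
        gene_annotations=annotations,
        context_map=ccl_context_map,
        normal_expression=normal_expression,
        cancer_expression=ccl_expression,
        crispr_scores=crispr_scores,
        rnai_scores=rnai_scores,
        ppi_partners=ppi_partners,
        preferential_expression=preferential,
        differential_ppi=differential_ppi,
        process_activity=process_activity,
        eqtl_significance=eqtl,
        development={},
    )

    truth_obj = SyntheticTruth(
        features=truth,
        coefficients=dict(cfg.effect_sizes),
        p_gain=pd.Series(p_gain, index=index),
        p_loss=pd.Series(p_loss, index=index),
        labels=pd.Series(labels, index=index),
        clean_labels=pd.Series(clean, index=index),
        ccl_labels=pd.Series(ccl_labels, index=ccl_index),
    )
    return SyntheticCohort(bundle, records, ccl_bundle, ccl_records,
                           truth_obj, cfg)


def recovery_report(
    ranking: pd.Series, directions: pd.Series, truth: SyntheticTruth, event: str
) -> pd.DataFrame:
    """Compare planted coefficients against recovered importance and direction.

    ``ranking``: feature name -> importance rank (1 = most important);
    ``directions``: feature name -> "event" | "neutral".  A planted
    coefficient with a positive sign means high feature values push toward
    the event, i.e. the expected direction is "event".
    """
    rows = []
    for (feat, ev), coef in truth.coefficients.items():
        if ev != event or coef == 0:
            continue
        expected = "event" if coef > 0 else "neutral"
        rec_dir = directions.get(feat)
        rows.append(
            {
                "feature": feat,
                "coefficient": coef,
                "recovered_rank": int(ranking.get(feat, -1)),
                "expected_direction": expected,
                "recovered_direction": rec_dir,
                "direction_match": rec_dir == expected,
            }
        )
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["coefficient", "recovered_rank", "expected_direction",
                 "recovered_direction", "direction_match"]
    )
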