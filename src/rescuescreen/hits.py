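"""Gene-level hit classification and recovery evaluation.

A gene is a candidate cytostasis *effector* when >=2 of its guides show a
median YAP/Empty ratio >= the fold threshold (knockout rescues growth under
forced YAP, so its guides enrich); it is *prioritized* when enough of those
guides are also enriched versus the Input sample. A candidate YAP
*inhibitor* shows the mirror pattern: >=2 guides depleted >= the fold
threshold versus Empty, with the analogous Input-contrast depletion.
Nontargeting controls are grouped into seeded pseudo-genes and classified
identically, giving an empirical false-positive readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrich import CONTRAST_EMPTY, CONTRAST_INPUT, AnalysisConfig, RatioTable
from .quantify import NTC_TOKEN, LibraryDesign
from .simulate import EFFECTOR, INHIBITOR, NULL, SimTruth

CLASS_EFFECTOR = "effector"
CLASS_EFFECTOR_PRI = "effector_prioritized"
CLASS_INHIBITOR = "inhibitor"
CLASS_NONE = "none"
CLASS_INSUFFICIENT = "insufficient_data"
CLASS_ORDER = (
    CLASS_EFFECTOR_PRI,
    CLASS_EFFECTOR,
    CLASS_INHIBITOR,
    CLASS_NONE,
    CLASS_INSUFFICIENT,
)

NTC_PSEUDO_PREFIX = "NTC_PSEUDO_"


@dataclass(frozen=True)
class GeneCall:
    klass: str
    n_sgrnas_total: int
    n_valid: int
    n_enriched_empty: int
    n_depleted_empty: int
    n_enriched_input: int
    n_depleted_input: int


def classify_gene(
    medians_empty: np.ndarray,
    medians_input: np.ndarray,
    config: AnalysisConfig | None = None,
) -> GeneCall:
    """Apply the hit rules to one gene's per-guide median ratios.

    Arrays are aligned per guide; NaN marks a missing median, which never
    counts as qualifying. Threshold comparisons are inclusive: a median of
    exactly 1.5 counts as enriched, exactly 1/1.5 as depleted. When a gene
    qualifies in both directions (possible with >=4 guides), the direction
    with more qualifying guides wins; an exact tie is called 'none'.
    """
    config = config or AnalysisConfig()
    me = np.asarray(medians_empty, dtype=float)
    mi = np.asarray(medians_input, dtype=float)
    if me.shape != mi.shape:
        raise ValueError("contrast median arrays must align per guide")
    n_total = me.size
    valid = ~np.isnan(me)

    enr_e = valid & (me >= config.fold_threshold)
    dep_e = valid & (me <= 1.0 / config.fold_threshold)
    enr_i = ~np.isnan(mi) & (mi >= config.input_rule_fold)
    dep_i = ~np.isnan(mi) & (mi <= 1.0 / config.input_rule_fold)

    counts = dict(
        n_sgrnas_total=int(n_total),
        n_valid=int(valid.sum()),
        n_enriched_empty=int(enr_e.sum()),
        n_depleted_empty=int(dep_e.sum()),
        n_enriched_input=int(enr_i.sum()),
        n_depleted_input=int(dep_i.sum()),
    )

    if valid.sum() < 2:
        return GeneCall(CLASS_INSUFFICIENT, **counts)

    effector_ok = enr_e.sum() >= 2
    inhibitor_ok = (
        dep_e.sum() >= 2
        and int((dep_e & dep_i).sum()) >= config.input_rule_min_sgrnas
    )
    if effector_ok and inhibitor_ok:
        if enr_e.sum() > dep_e.sum():
            inhibitor_ok = False
        elif dep_e.sum() > enr_e.sum():
            effector_ok = False
        else:
            return GeneCall(CLASS_NONE, **counts)
    if effector_ok:
        prioritized = int((enr_e & enr_i).sum()) >= config.input_rule_min_sgrnas
        return GeneCall(CLASS_EFFECTOR_PRI if prioritized else CLASS_EFFECTOR,
                        **counts)
    if inhibitor_ok:
        return GeneCall(CLASS_INHIBITOR, **counts)
    return GeneCall(CLASS_NONE, **counts)


def _ntc_pseudogenes(
    ntc_ids: pd.Index, group_size: int, seed: int
) -> pd.Series:
    """Random seeded partition of NTC guides into pseudo-genes of group_size."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ntc_ids))
    labels = np.empty(len(ntc_ids), dtype=object)
    for k, pos in enumerate(order):
        labels[pos] = f"{NTC_PSEUDO_PREFIX}{k // group_size + 1:03d}"
    return pd.Series(labels, index=ntc_ids)


def call_hits(
    ratio_table: RatioTable,
    library: LibraryDesign | None = None,
    config: AnalysisConfig | None = None,
    ntc_group_size: int = 4,
    ntc_partition_seed: int = 0,
) -> pd.DataFrame:
    """Classify every targeted gene plus NTC pseudo-genes.

    Returns a gene-level table with columns: gene, class, is_ntc,
    n_sgrnas_total, n_valid, qualifying-guide counts per contrast and
    direction, and best_z (the guide z-score of largest magnitude, signed).
    """
    library = library or ratio_table.library
    config = config or ratio_table.config
    med_e = ratio_table.contrasts[CONTRAST_EMPTY].median
    med_i = ratio_table.contrasts[CONTRAST_INPUT].median
    if med_e.empty:
        raise ValueError("empty ratio table")

    per_guide = library.table[["sgrna_id", "gene"]].copy()
    per_guide["med_e"] = med_e.reindex(per_guide["sgrna_id"]).to_numpy()
    per_guide["med_i"] = med_i.reindex(per_guide["sgrna_id"]).to_numpy()
    per_guide["z"] = ratio_table.zscore.reindex(per_guide["sgrna_id"]).to_numpy()
    return call_hits_from_frame(per_guide, config, ntc_group_size,
                                ntc_partition_seed)


def call_hits_from_frame(
    per_guide: pd.DataFrame,
    config: AnalysisConfig | None = None,
    ntc_group_size: int = 4,
    ntc_partition_seed: int = 0,
) -> pd.DataFrame:
    """Classify from a per-guide frame (sgrna_id, gene, med_e, med_i, z)."""
    config = config or AnalysisConfig()
    if per_guide.empty:
        raise ValueError("empty ratio table")
    per_guide = per_guide.reset_index(drop=True)
    is_ntc = per_guide["gene"] == NTC_TOKEN
    group = per_guide["gene"].copy()
    if is_ntc.any():
        pseudo = _ntc_pseudogenes(
            pd.Index(per_guide.loc[is_ntc, "sgrna_id"]),
            ntc_group_size,
            ntc_partition_seed,
        )
        group[is_ntc.to_numpy()] = pseudo.reindex(
            per_guide.loc[is_ntc, "sgrna_id"]
        ).to_numpy()

    rows = []
    for gene, sub in per_guide.groupby(group.to_numpy(), sort=False):
        call = classify_gene(sub["med_e"].to_numpy(), sub["med_i"].to_numpy(), config)
        z = sub["z"].to_numpy(dtype=float)
        best_z = np.nan
        if np.any(~np.isnan(z)):
            best_z = z[np.nanargmax(np.abs(z))]
        rows.append({
            "gene": gene,
            "class": call.klass,
            "is_ntc": str(gene).startswith(NTC_PSEUDO_PREFIX),
            "n_sgrnas_total": call.n_sgrnas_total,
            "n_valid": call.n_valid,
            "n_enriched_empty": call.n_enriched_empty,
            "n_depleted_empty": call.n_depleted_empty,
            "n_enriched_input": call.n_enriched_input,
            "n_depleted_input": call.n_depleted_input,
            "best_z": best_z,
        })
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Precision/recall/F1 of hit calling against simulation ground truth."""

    per_class: pd.DataFrame   # index: effector/inhibitor; columns: tp fp fn precision recall f1
    confusion: pd.DataFrame   # truth class x predicted group counts
    n_genes: int

    def to_dict(self) -> dict:
        return {
            "per_class": {
                k: {m: (None if pd.isna(v) else float(v)) if m in
                    ("precision", "recall", "f1") else int(v)
                    for m, v in row.items()}
                for k, row in self.per_class.iterrows()
            },
            "confusion": {
                str(t): {str(p): int(c) for p, c in row.items()}
                for t, row in self.confusion.iterrows()
            },
            "n_genes": int(self.n_genes),
        }


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def evaluate_recovery(hit_table: pd.DataFrame, truth: SimTruth) -> RecoveryReport:
    """Score effector / inhibitor calls against the generator's ground truth.

    Effector calls pool the plain and prioritized classes. Precision is
    reported as missing (NaN) when no calls of a class were made.
    """
    calls = hit_table[~hit_table["is_ntc"]].set_index("gene")["class"]
    truth_cls = truth.genes["klass"]
    if set(calls.index) != set(truth_cls.index):
        raise ValueError("hit table and truth cover different gene sets")
    calls = calls.reindex(truth_cls.index)

    pred_group = pd.Series(
        np.where(calls.isin([CLASS_EFFECTOR, CLASS_EFFECTOR_PRI]), EFFECTOR,
                 np.where(calls == CLASS_INHIBITOR, INHIBITOR, "other")),
        index=calls.index,
    )
    confusion = pd.crosstab(truth_cls, pred_group).reindex(
        index=[EFFECTOR, INHIBITOR, NULL],
        columns=[EFFECTOR, INHIBITOR, "other"],
        fill_value=0,
    )
    rows = {}
    for klass in (EFFECTOR, INHIBITOR):
        tp = int(((truth_cls == klass) & (pred_group == klass)).sum())
        fp = int(((truth_cls != klass) & (pred_group == klass)).sum())
        fn = int(((truth_cls == klass) & (pred_group != klass)).sum())
        p, r, f1 = _prf(tp, fp, fn)
        rows[klass] = dict(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)
    per_class = pd.DataFrame(rows).T
    return RecoveryReport(per_class, confusion, n_genes=len(truth_cls))
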