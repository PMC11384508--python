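"""Normalization, low-count exclusion, enrichment ratios, medians, z-scores.

The scoring procedure for a rescue screen with three arms (Input day 10,
Empty day 25, YAP day 25) over biological replicates:

1. counts are normalized to reads-per-million within each sample;
2. guides with raw count < 20 in a sample are excluded from ratios that
   touch that sample (the raw count, not the normalized value, is filtered);
3. per replicate, enrichment ratios YAP/Empty and YAP/Input are formed on
   the normalized scale;
4. the median ratio over valid replicates summarizes each guide;
5. z-scores of log2(median YAP/Empty ratio) are computed against the
   nontargeting-control distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .quantify import NTC_TOKEN, CountMatrix, LibraryDesign

CONTRAST_EMPTY = "yap_vs_empty"
CONTRAST_INPUT = "yap_vs_input"
CONTRASTS = (CONTRAST_EMPTY, CONTRAST_INPUT)
_REFERENCE_OF = {CONTRAST_EMPTY: "empty", CONTRAST_INPUT: "input"}


class ZeroVarianceError(ValueError):
    """Reference log-ratios are all identical; z-scores undefined."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and conventions of the scoring procedure.

    low_count_threshold: raw counts strictly below this are excluded (a count
        of exactly 20 survives the default filter).
    fold_threshold: a guide counts as enriched at median ratio >= 1.5 and as
        depleted at <= 1/1.5 (inclusive on both sides).
    filter_scope: 'pairwise' drops a replicate ratio only when one of its two
        samples is low; 'any_sample' invalidates a guide everywhere once any
        sample is low.
    input_rule_min_sgrnas / input_rule_fold: how many of a gene's qualifying
        guides must also pass the Input contrast, and at what fold. The
        defaults (1, 1.0) require at least one guide with any enrichment
        versus Input; the stricter alternative (2, 1.5) mirrors the
        Empty-contrast rule.
    zscore_reference: 'ntc' scores against nontargeting controls, 'all'
        against every guide.
    """

    low_count_threshold: int = 20
    fold_threshold: float = 1.5
    filter_scope: str = "pairwise"
    min_valid_replicates: int = 2
    pseudocount: float = 0.0
    zscore_reference: str = "ntc"
    input_rule_min_sgrnas: int = 1
    input_rule_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.low_count_threshold < 0:
            raise ValueError("low_count_threshold must be >= 0")
        if self.fold_threshold <= 0 or self.input_rule_fold <= 0:
            raise ValueError("fold thresholds must be > 0")
        if self.filter_scope not in ("pairwise", "any_sample"):
            raise ValueError(f"unknown filter_scope {self.filter_scope!r}")
        if self.zscore_reference not in ("ntc", "all"):
            raise ValueError(f"unknown zscore_reference {self.zscore_reference!r}")
        if self.min_valid_replicates < 1:
            raise ValueError("min_valid_replicates must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.input_rule_min_sgrnas < 0:
            raise ValueError("input_rule_min_sgrnas must be >= 0")


@dataclass
class NormalizedMatrix:
    """Reads-per-million normalized abundances plus the raw matrix they came from."""

    rpm: pd.DataFrame
    totals: pd.Series
    raw: CountMatrix


@dataclass
class ContrastResult:
    """Per-replicate ratios, validity, and median summary for one contrast."""

    contrast: str
    ratios: pd.DataFrame      # columns = replicate ids
    valid: pd.DataFrame       # same shape, bool
    median: pd.Series         # NaN where < min_valid_replicates valid
    n_valid: pd.Series


@dataclass
class RatioTable:
    """Full per-sgRNA scoring result across both contrasts."""

    library: LibraryDesign
    contrasts: dict[str, ContrastResult]
    zscore: pd.Series  # z of log2 median YAP/Empty ratio
    config: AnalysisConfig

    def to_frame(self) -> pd.DataFrame:
        """Flat results table: one row per guide, the screen-results artifact."""
        out = self.library.table[["sgrna_id", "gene"]].set_index("sgrna_id")
        for name, short in ((CONTRAST_EMPTY, "empty"), (CONTRAST_INPUT, "input")):
            cr = self.contrasts[name]
            ratios = cr.ratios.where(cr.valid)
            for rep in ratios.columns:
                out[f"ratio_{short}_r{rep}"] = ratios[rep]
            out[f"n_valid_{short}"] = cr.n_valid
            out[f"median_{short}"] = cr.median
        out["zscore"] = self.zscore
        return out.reset_index()


def normalize_total(counts: CountMatrix) -> NormalizedMatrix:
    """Scale each sample to reads-per-million of its total read count.

    Totals are computed over the full library, before any exclusion.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    rpm = counts.counts / totals * 1e6
    return NormalizedMatrix(rpm=rpm, totals=totals.astype(float), raw=counts)


def low_count_mask(counts: CountMatrix, config: AnalysisConfig) -> pd.DataFrame:
    """Boolean validity per (sgRNA, sample): False where the raw count is low.

    An entry is invalid iff raw count < low_count_threshold; with
    filter_scope='any_sample' a guide low anywhere is invalid everywhere.
    """
    mask = counts.counts >= config.low_count_threshold
    if config.filter_scope == "any_sample":
        keep = mask.all(axis=1)
        mask = mask.mul(keep, axis=0)
    return mask


def replicate_ratios(
    norm: NormalizedMatrix,
    mask: pd.DataFrame,
    contrast: str,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate (YAP + pc) / (reference + pc) ratios on the RPM scale.

    Returns (ratios, valid): a ratio is valid only when both its samples pass
    the low-count filter and the denominator is positive. Invalid cells hold
    NaN, never infinity.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    ref_cond = _REFERENCE_OF[contrast]
    cm = norm.raw
    ratios = {}
    valid = {}
    for rep in cm.replicates:
        num_s = cm.sample_for("yap", rep)
        den_s = cm.sample_for(ref_cond, rep)
        num = norm.rpm[num_s] + config.pseudocount
        den = norm.rpm[den_s] + config.pseudocount
        ok = mask[num_s] & mask[den_s] & (den > 0)
        r = np.where(ok, num / den.where(den > 0), np.nan)
        ratios[rep] = pd.Series(r, index=norm.rpm.index)
        valid[rep] = ok
    return pd.DataFrame(ratios), pd.DataFrame(valid)


def median_ratio(
    ratios: pd.DataFrame, valid: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.Series, pd.Series]:
    """Median over valid replicates; NaN when fewer than min_valid_replicates.

    An even number of valid replicates uses the midpoint mean.
    """
    masked = ratios.where(valid)
    n_valid = valid.sum(axis=1)
    med = masked.median(axis=1, skipna=True)
    med[n_valid < config.min_valid_replicates] = np.nan
    return med, n_valid


def contrast_result(
    norm: NormalizedMatrix,
    mask: pd.DataFrame,
    contrast: str,
    config: AnalysisConfig,
) -> ContrastResult:
    ratios, valid = replicate_ratios(norm, mask, contrast, config)
    med, n_valid = median_ratio(ratios, valid, config)
    return ContrastResult(contrast, ratios, valid, med, n_valid)


def zscores(
    median_ratios: pd.Series, library: LibraryDesign, config: AnalysisConfig
) -> pd.Series:
    """z of log2(median ratio) against the reference-set mean and SD.

    The reference is the nontargeting controls (zscore_reference='ntc') or
    every guide with a valid median ('all'); sample SD (ddof=1).
    """
    log2m = np.log2(median_ratios)
    if config.zscore_reference == "ntc":
        ref_ids = library.ntc_ids
    else:
        ref_ids = library.sgrna_ids
    ref = log2m.reindex(ref_ids).dropna()
    if len(ref) < 2:
        raise ValueError(
            f"z-score reference {config.zscore_reference!r} has {len(ref)} valid "
            f"member(s); need >= 2"
        )
    mu = ref.mean()
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError(
            "all reference log-ratios identical; set zscore_reference='all'"
        )
    return (log2m - mu) / sd


def run_enrichment(
    counts: CountMatrix, library: LibraryDesign, config: AnalysisConfig | None = None
) -> RatioTable:
    """Full scoring: normalize, filter, both contrasts, medians, z-scores."""
    config = config or AnalysisConfig()
    counts = counts.restrict_to(library)
    norm = normalize_total(counts)
    mask = low_count_mask(counts, config)
    contrasts = {c: contrast_result(norm, mask, c, config) for c in CONTRASTS}
    z = zscores(contrasts[CONTRAST_EMPTY].median, library, config)
    return RatioTable(library, contrasts, z, config)
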