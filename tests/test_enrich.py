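"""Normalization, filtering, ratios, medians, z-scores."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_count_matrix, random_count_matrix
from rescuescreen import (
    AnalysisConfig,
    low_count_mask,
    normalize_total,
    run_enrichment,
    zscores,
)
from rescuescreen.enrich import (
    CONTRAST_EMPTY,
    CONTRAST_INPUT,
    ZeroVarianceError,
    contrast_result,
    replicate_ratios,
)
from rescuescreen.quantify import LibraryDesign


# ---------------------------------------------------------------------------
# Brute-force oracle: plain-Python rescoring from raw counts, no pandas math
# ---------------------------------------------------------------------------

def brute_force_scores(library, cm, config):
    """Recompute RPM, ratios, medians, z from first principles with loops."""
    ids = list(library.sgrna_ids)
    samples = list(cm.counts.columns)
    raw = {s: {g: int(cm.counts.at[g, s]) for g in ids} for s in samples}
    totals = {s: sum(raw[s].values()) for s in samples}
    rpm = {s: {g: raw[s][g] / totals[s] * 1e6 for g in ids} for s in samples}

    reps = sorted(set(cm.samples.loc[samples, "replicate"]))
    sample_of = {}
    for s in samples:
        cond = cm.samples.at[s, "condition"]
        sample_of[(cond, int(cm.samples.at[s, "replicate"]))] = s

    def ok(s, g):
        if config.filter_scope == "any_sample":
            return all(raw[t][g] >= config.low_count_threshold for t in samples)
        return raw[s][g] >= config.low_count_threshold

    medians = {}
    for ref in ("empty", "input"):
        for g in ids:
            vals = []
            for r in reps:
                ys, rs = sample_of[("yap", r)], sample_of[(ref, r)]
                if ok(ys, g) and ok(rs, g) and rpm[rs][g] + config.pseudocount > 0:
                    vals.append((rpm[ys][g] + config.pseudocount)
                                / (rpm[rs][g] + config.pseudocount))
            medians[(ref, g)] = (statistics.median(vals)
                                 if len(vals) >= config.min_valid_replicates
                                 else math.nan)

    ntc = set(library.ntc_ids)
    ref_logs = [math.log2(medians[("empty", g)]) for g in ids
                if g in ntc and not math.isnan(medians[("empty", g)])]
    mu = statistics.fmean(ref_logs)
    sd = statistics.stdev(ref_logs)
    z = {g: (math.log2(medians[("empty", g)]) - mu) / sd
         if not math.isnan(medians[("empty", g)]) else math.nan for g in ids}
    return medians, z


class TestNormalize:
    def test_two_guide_proportions(self):
        cm = make_count_matrix({"input_r1": [10, 90]}, ["A_sg1", "A_sg2"])
        norm = normalize_total(cm)
        assert norm.rpm["input_r1"].tolist() == [100000.0, 900000.0]

    def test_single_guide_is_full_million(self):
        cm = make_count_matrix({"input_r1": [7]}, ["A_sg1"])
        assert normalize_total(cm).rpm["input_r1"].tolist() == [1000000.0]

    def test_zero_total_sample_named_in_error(self):
        cm = make_count_matrix({"input_r1": [1, 2], "empty_r1": [0, 0]},
                               ["A_sg1", "A_sg2"])
        with pytest.raises(ValueError, match="empty_r1"):
            normalize_total(cm)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(1, 1000, size=(100, 12))
        cm = make_count_matrix(
            {f"{c}_r{r}": mat[:, i] for i, (c, r) in enumerate(
                (c, r) for r in range(1, 5) for c in ("input", "empty", "yap"))},
            [f"G{i:03d}_sg1" for i in range(100)])
        norm = normalize_total(cm)
        np.testing.assert_allclose(norm.rpm.sum(axis=0), 1e6, rtol=1e-9)


class TestLowCountFilter:
    def test_threshold_boundary(self):
        cm = make_count_matrix({"input_r1": [19, 20, 0, 1000]},
                               [f"A_sg{i}" for i in range(1, 5)])
        mask = low_count_mask(cm, AnalysisConfig())
        assert mask["input_r1"].tolist() == [False, True, False, True]

    def test_all_high_counts_all_valid(self):
        cm = make_count_matrix({"input_r1": [20, 50], "yap_r1": [21, 99]},
                               ["A_sg1", "A_sg2"])
        assert low_count_mask(cm, AnalysisConfig()).to_numpy().all()

    def test_any_sample_scope_invalidates_row(self):
        cm = make_count_matrix({"input_r1": [19, 50], "yap_r1": [100, 99]},
                               ["A_sg1", "A_sg2"])
        mask = low_count_mask(cm, AnalysisConfig(filter_scope="any_sample"))
        assert mask.loc["A_sg1"].tolist() == [False, False]
        assert mask.loc["A_sg2"].tolist() == [True, True]


def two_rep_matrix(yap, empty, inp=None, ids=None):
    ids = ids or [f"A_sg{i+1}" for i in range(len(yap))]
    data = {"yap_r1": yap, "empty_r1": empty,
            "input_r1": inp if inp is not None else empty}
    return make_count_matrix(data, ids)


class TestRatios:
    def test_doubling_and_identity(self):
        cm = make_count_matrix(
            {"yap_r1": [200, 100], "empty_r1": [100, 100], "input_r1": [100, 100]},
            ["A_sg1", "A_sg2"])
        norm = normalize_total(cm)
        cfg = AnalysisConfig()
        ratios, valid = replicate_ratios(norm, low_count_mask(cm, cfg),
                                         CONTRAST_EMPTY, cfg)
        # totals differ between samples, so ratios are of RPM, not raw counts
        rpm_ratio = (200 / 300) / (100 / 200)
        assert ratios.loc["A_sg1", 1] == pytest.approx(rpm_ratio)
        assert ratios.loc["A_sg2", 1] == pytest.approx((100 / 300) / (100 / 200))
        assert valid.to_numpy().all()

    def test_equal_samples_give_unit_ratio(self):
        cm = two_rep_matrix([40, 60], [40, 60])
        cfg = AnalysisConfig()
        norm = normalize_total(cm)
        ratios, _ = replicate_ratios(norm, low_count_mask(cm, cfg),
                                     CONTRAST_EMPTY, cfg)
        np.testing.assert_allclose(ratios[1], 1.0)

    def test_low_count_member_invalidates_replicate(self):
        """A reference raw count of 5 (<20) drops that replicate's ratio."""
        cm = make_count_matrix(
            {"yap_r1": [100, 100], "empty_r1": [5, 100], "input_r1": [50, 50]},
            ["A_sg1", "A_sg2"])
        cfg = AnalysisConfig()
        ratios, valid = replicate_ratios(normalize_total(cm),
                                         low_count_mask(cm, cfg),
                                         CONTRAST_EMPTY, cfg)
        assert not valid.loc["A_sg1", 1]
        assert np.isnan(ratios.loc["A_sg1", 1])
        assert valid.loc["A_sg2", 1]

    def test_scale_invariance(self):
        """Multiplying one sample's raw counts by a constant leaves every
        ratio value unchanged — the per-sample totals cancel. (Only the
        low-count filter sees the scale, so validity may grow; values on the
        common valid set must be identical.)"""
        rng = np.random.default_rng(3)
        lib, cm = random_count_matrix(rng, 30)
        cfg = AnalysisConfig()
        base = run_enrichment(cm, lib, cfg)
        scaled_counts = cm.counts.copy()
        scaled_counts["yap_r1"] *= 13
        from rescuescreen.quantify import CountMatrix

        cm2 = CountMatrix(scaled_counts, cm.samples)
        scaled = run_enrichment(cm2, lib, cfg)
        for c in (CONTRAST_EMPTY, CONTRAST_INPUT):
            b, s = base.contrasts[c], scaled.contrasts[c]
            both = (b.valid & s.valid).to_numpy()
            assert (b.valid.to_numpy() <= s.valid.to_numpy()).all()
            np.testing.assert_allclose(b.ratios.to_numpy()[both],
                                       s.ratios.to_numpy()[both], rtol=1e-12)

    def test_contrast_identity_yap_as_its_own_reference(self):
        rng = np.random.default_rng(5)
        lib, cm = random_count_matrix(rng, 20)
        counts = cm.counts.copy()
        for r in cm.replicates:
            counts[f"empty_r{r}"] = counts[f"yap_r{r}"]
        from rescuescreen.quantify import CountMatrix

        cm2 = CountMatrix(counts, cm.samples)
        cfg = AnalysisConfig()
        norm = normalize_total(cm2)
        ratios, valid = replicate_ratios(norm, low_count_mask(cm2, cfg),
                                         CONTRAST_EMPTY, cfg)
        assert np.allclose(ratios.to_numpy()[valid.to_numpy()], 1.0)


class TestMedian:
    @pytest.mark.parametrize("values,valid,expected", [
        ([2.0, 1.0, 4.0, 3.0], [True] * 4, 2.5),
        ([2.0, 9.9, 4.0, 3.0], [True, False, True, True], 3.0),
        ([9.9, 9.9, 9.9, 2.0], [False, False, False, True], math.nan),
    ])
    def test_median_over_valid_replicates(self, values, valid, expected):
        from rescuescreen.enrich import median_ratio

        ratios = pd.DataFrame([values], index=["A_sg1"], columns=[1, 2, 3, 4])
        mask = pd.DataFrame([valid], index=["A_sg1"], columns=[1, 2, 3, 4])
        med, n_valid = median_ratio(ratios, mask, AnalysisConfig())
        if math.isnan(expected):
            assert math.isnan(med["A_sg1"])
        else:
            assert med["A_sg1"] == expected
        assert n_valid["A_sg1"] == sum(valid)

    def test_monotonicity_of_threshold(self):
        """Raising the low-count threshold never adds valid ratios."""
        rng = np.random.default_rng(11)
        lib, cm = random_count_matrix(rng, 40)
        n_valid = []
        for thr in (0, 20, 100, 300):
            cfg = AnalysisConfig(low_count_threshold=thr)
            cr = contrast_result(normalize_total(cm),
                                 low_count_mask(cm, cfg), CONTRAST_EMPTY, cfg)
            n_valid.append(int(cr.valid.to_numpy().sum()))
        assert n_valid == sorted(n_valid, reverse=True)


class TestZscores:
    def _library(self, n_ntc=4, n_other=2):
        rows = [(f"NTC_sg{i:03d}", "NTC") for i in range(n_ntc)]
        rows += [(f"X_sg{i}", "X") for i in range(n_other)]
        rng = np.random.default_rng(2)
        from rescuescreen.simulate import _random_spacers

        spacers = _random_spacers(len(rows), rng, min_distance=1)
        return LibraryDesign(pd.DataFrame(
            [(a, b, s) for (a, b), s in zip(rows, spacers)],
            columns=["sgrna_id", "gene", "spacer"]))

    def test_reference_mean_maps_to_zero(self):
        lib = self._library()
        med = pd.Series([2.0, 2.0, 0.5, 0.5, 1.0, 4.0],
                        index=lib.sgrna_ids)
        z = zscores(med, lib, AnalysisConfig())
        assert z["X_sg0"] == pytest.approx(0.0)  # log2(1) == NTC mean

    def test_closed_form(self):
        lib = self._library(n_ntc=2, n_other=1)
        med = pd.Series([0.5, 2.0, 2.0], index=lib.sgrna_ids)  # logs -1, +1
        z = zscores(med, lib, AnalysisConfig())
        sd = statistics.stdev([-1.0, 1.0])
        assert z["X_sg0"] == pytest.approx((1.0 - 0.0) / sd)

    def test_zero_variance_reference_raises(self):
        lib = self._library(n_ntc=3, n_other=1)
        med = pd.Series([2.0, 2.0, 2.0, 8.0], index=lib.sgrna_ids)
        with pytest.raises(ZeroVarianceError, match="all"):
            zscores(med, lib, AnalysisConfig())

    def test_all_reference_uses_every_guide(self):
        lib = self._library(n_ntc=0, n_other=4)
        med = pd.Series([1.0, 2.0, 4.0, 8.0], index=lib.sgrna_ids)
        z = zscores(med, lib, AnalysisConfig(zscore_reference="all"))
        logs = np.log2(med.to_numpy())
        expect = (logs - logs.mean()) / logs.std(ddof=1)
        np.testing.assert_allclose(z.to_numpy(), expect)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        """Full scoring equals an independent loop-based recomputation."""
        rng = np.random.default_rng(seed)
        lib, cm = random_count_matrix(rng, 50, n_replicates=4, n_ntc=10)
        cfg = AnalysisConfig()
        table = run_enrichment(cm, lib, cfg)
        medians, z = brute_force_scores(lib, cm, cfg)
        med_e = table.contrasts[CONTRAST_EMPTY].median
        med_i = table.contrasts[CONTRAST_INPUT].median
        for g in lib.sgrna_ids:
            for ref, med in (("empty", med_e), ("input", med_i)):
                a, b = medians[(ref, g)], med[g]
                assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(
                    b, abs=1e-12)
            a, b = z[g], table.zscore[g]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(
                b, abs=1e-12)
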