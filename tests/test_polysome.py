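"""Fraction profiles, pooled ratios and translation-shift classification."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ribostate.annotations import CountMatrix
from ribostate.overlap import goodness_of_fit_chisq
from ribostate.polysome import (
    FractionProfile,
    FractionScheme,
    UndefinedRatioError,
    classify_shift,
    classify_shifts,
    default_scheme,
    normalize_fractions,
    pooled_ratios,
    shift_enrichment,
)
from ribostate.ripseq import BinderSet
from ribostate.simulate import simulate_polysome


FOUR = FractionScheme(
    labels=("free", "mono", "poly1", "poly2"),
    classes={"free": "free", "mono": "mono", "poly1": "poly", "poly2": "poly"},
)


def profile(abundance, tid="t1", genotype="WT"):
    total = sum(abundance.values())
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in abundance.items()}
    return FractionProfile(tid, genotype, abundance, pct)


def fraction_matrix(rows: dict, labels) -> CountMatrix:
    roles = {label: f"fraction:{label}" for label in labels}
    return CountMatrix(pd.DataFrame(rows, index=labels).T, roles)


class TestSchemes:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FractionScheme(("free", "free"), {"free": "free"})

    def test_every_class_required(self):
        with pytest.raises(ValueError, match="no 'poly' fraction"):
            FractionScheme(("free", "mono"), {"free": "free", "mono": "mono"})


class TestNormalizeFractions:
    def test_uniform_signal_gives_equal_percentages(self):
        m = fraction_matrix({"t1": [10, 10, 10, 10]}, FOUR.labels)
        prof = normalize_fractions(m, FOUR)["t1"]
        assert all(p == pytest.approx(25.0) for p in prof.percentages.values())

    def test_all_free_signal(self):
        m = fraction_matrix({"t1": [40, 0, 0, 0], "t2": [10, 10, 10, 10]},
                            FOUR.labels)
        prof = normalize_fractions(m, FOUR)["t1"]
        assert prof.percentages["free"] == pytest.approx(100.0)
        assert prof.percentages["poly1"] == pytest.approx(0.0)

    def test_unknown_fraction_rejected(self):
        m = fraction_matrix({"t1": [1, 2]}, ["free", "mystery"])
        with pytest.raises(ValueError, match="mystery"):
            normalize_fractions(m, FOUR)

    def test_percentages_sum_to_100(self, fraction_profiles):
        wt, ko = fraction_profiles
        for prof in list(wt.values())[:500] + list(ko.values())[:500]:
            if prof.total > 0:
                assert sum(prof.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_per_row_recomputation(self, poly_sim, default_config):
        """Oracle: per-transcript percentages recomputed independently
        from per-million-scaled replicate means."""
        scheme = default_config.scheme
        counts = poly_sim.wt_counts
        profiles = normalize_fractions(counts, scheme, genotype="WT")
        df = counts.counts
        scaled = df / (df.sum(axis=0) / 1e6)
        rng = np.random.default_rng(1)
        for tid in rng.choice(df.index, 25, replace=False):
            means = {
                label: scaled[
                    [s for s, r in counts.samples if r == f"fraction:{label}"]
                ].loc[tid].mean()
                for label in scheme.labels
            }
            total = sum(means.values())
            for label in scheme.labels:
                assert profiles[tid].percentages[label] == pytest.approx(
                    100.0 * means[label] / total, rel=1e-9
                )


class TestPooledRatios:
    def test_arithmetic(self):
        prof = profile({"free": 20.0, "mono": 20.0, "poly1": 30.0, "poly2": 30.0})
        ratios = pooled_ratios(prof, FOUR)
        assert ratios.te == pytest.approx(3.0, rel=1e-4)
        assert ratios.poly_mono == pytest.approx(3.0, rel=1e-4)

    def test_all_free_limit(self):
        prof = profile({"free": 100.0, "mono": 0.0, "poly1": 0.0, "poly2": 0.0})
        assert pooled_ratios(prof, FOUR).te == pytest.approx(0.0)

    def test_empty_denominator_stays_finite(self):
        prof = profile({"free": 0.0, "mono": 0.0, "poly1": 50.0, "poly2": 50.0})
        ratios = pooled_ratios(prof, FOUR)
        assert np.isfinite(ratios.te) and ratios.te > 1e4

    def test_zero_total_is_undefined(self):
        prof = profile({label: 0.0 for label in FOUR.labels})
        with pytest.raises(UndefinedRatioError):
            pooled_ratios(prof, FOUR)


class TestClassifyShift:
    def wt_ko(self, te_wt, te_ko):
        # free fixed at 20; poly = te * free; mono arbitrary
        wt = profile({"free": 20.0, "mono": 10.0, "poly1": te_wt * 20.0,
                      "poly2": 0.0}, genotype="WT")
        ko = profile({"free": 20.0, "mono": 10.0, "poly1": te_ko * 20.0,
                      "poly2": 0.0}, genotype="KO")
        return wt, ko

    def test_exact_half_is_group_2(self):
        call = classify_shift(*self.wt_ko(2.0, 1.0), FOUR)
        assert call.group == 2  # not strictly below half

    def test_below_half_is_group_1(self):
        call = classify_shift(*self.wt_ko(2.0, 0.9), FOUR)
        assert call.group == 1

    def test_scale_invariance(self):
        wt, ko = self.wt_ko(2.0, 0.9)
        scaled = profile(
            {k: 7.0 * v for k, v in ko.abundance.items()}, genotype="KO"
        )
        assert classify_shift(wt, ko, FOUR).group == classify_shift(
            wt, scaled, FOUR
        ).group

    def test_zero_total_withholds_call(self):
        wt, _ = self.wt_ko(2.0, 1.0)
        ko = profile({label: 0.0 for label in FOUR.labels}, genotype="KO")
        call = classify_shift(wt, ko, FOUR)
        assert call.group is None
        assert call.reason == "zero_total_ko"

    def test_mismatched_transcripts_rejected(self):
        wt, ko = self.wt_ko(2.0, 1.0)
        other = profile(ko.abundance, tid="t2", genotype="KO")
        with pytest.raises(ValueError, match="mismatch"):
            classify_shift(wt, other, FOUR)

    def test_raising_threshold_never_shrinks_group_1(
        self, default_config, fraction_profiles
    ):
        wt, ko = fraction_profiles
        scheme = default_config.scheme

        def group1(threshold):
            calls = classify_shifts(wt, ko, scheme, threshold)
            return {c.transcript_id for c in calls if c.group == 1}

        g_05, g_07, g_09 = group1(0.5), group1(0.7), group1(0.9)
        assert g_05 <= g_07 <= g_09


class TestGeneratorRecovery:
    def test_group1_fraction_near_planted_rate(self, shift_calls, default_config):
        """Observed group-1 share within 3 points of the planted 30%."""
        defined = [c for c in shift_calls if c.defined]
        share = 100.0 * sum(c.group == 1 for c in defined) / len(defined)
        assert share == pytest.approx(100.0 * default_config.shift_fraction, abs=3.0)

    def test_te_drop_recovered_against_planted_expectation(
        self, shift_calls, poly_sim, default_config
    ):
        """Median te_ko/te_wt of shifted transcripts within 10% of the
        value expected from the planted proportions.

        The oracle works from the truth alone: expected per-million
        abundance is mass * proportion / library depth, with depth the
        mass-weighted fraction total; pooling and ratios are then two
        lines of arithmetic, independent of the count-based pipeline.
        """
        scheme = default_config.scheme
        shifted = sorted(poly_sim.shifted)

        def expected_te(props):
            depth = props.mul(poly_sim.mass, axis=0).sum(axis=0)
            normed = props.mul(poly_sim.mass, axis=0) / depth
            poly = normed[scheme.labels_of("poly")].sum(axis=1)
            free = normed[scheme.labels_of("free")].sum(axis=1)
            return poly / free

        expected_ratio = (
            expected_te(poly_sim.ko_props) / expected_te(poly_sim.wt_props)
        )[shifted]
        observed = pd.Series(
            {
                c.transcript_id: c.te_ko / c.te_wt
                for c in shift_calls
                if c.defined and c.transcript_id in poly_sim.shifted
            }
        )
        assert np.median(observed) == pytest.approx(
            np.median(expected_ratio), rel=0.10
        )

    def test_poly_mono_preserved_for_shifted(self, shift_calls, poly_sim):
        """The initiation-block model leaves poly:mono untouched: the
        KO/WT poly-mono ratio of shifted transcripts is centred at 1
        while their TE collapses."""
        shifted = [
            c for c in shift_calls if c.defined and c.transcript_id in poly_sim.shifted
        ]
        pm = np.median([c.poly_mono_ko / c.poly_mono_wt for c in shifted])
        te = np.median([c.te_ko / c.te_wt for c in shifted])
        assert 0.8 <= pm <= 1.25
        assert te < 0.25

    def test_poly_mono_exact_at_low_noise(self, default_config):
        """Construction check with the counting noise turned down."""
        cfg = replace(default_config, n_transcripts=200, nb_dispersion=1e-3,
                      base_mean=2e4)
        sim = simulate_polysome(cfg, frozenset())
        wt = normalize_fractions(sim.wt_counts, cfg.scheme, genotype="WT")
        ko = normalize_fractions(sim.ko_counts, cfg.scheme, genotype="KO")
        calls = classify_shifts(wt, ko, cfg.scheme)
        pm = [
            c.poly_mono_ko / c.poly_mono_wt
            for c in calls
            if c.transcript_id in sim.shifted
        ]
        assert np.mean(pm) == pytest.approx(1.0, abs=0.05)


class TestShiftEnrichment:
    def make_calls(self, n, n_group1, prefix="t"):
        calls = []
        for i in range(n):
            group = 1 if i < n_group1 else 2
            calls.append(
                classify_shift(
                    profile({"free": 20.0, "mono": 10.0, "poly1": 40.0,
                             "poly2": 0.0}, tid=f"{prefix}{i}"),
                    profile({"free": 20.0, "mono": 10.0,
                             "poly1": 8.0 if group == 1 else 40.0,
                             "poly2": 0.0}, tid=f"{prefix}{i}", genotype="KO"),
                    FOUR,
                )
            )
        return calls

    def test_bound_at_global_rate_gives_p_one(self):
        calls = self.make_calls(100, 30)
        # bound subset with exactly the global 30% group-1 share
        bound = {f"t{i}" for i in range(9)} | {f"t{i}" for i in range(40, 61)}
        summary = shift_enrichment(calls, bound)
        assert summary.test.statistic == pytest.approx(0.0)
        assert summary.test.p_value == pytest.approx(1.0)

    def test_statistic_consistent_with_chisq_oracle(self, shift_calls, binders):
        defined = {c.transcript_id for c in shift_calls if c.defined}
        bound = binders.members & defined
        summary = shift_enrichment(shift_calls, bound)
        k_global = sum(c.group == 1 for c in shift_calls if c.defined)
        oracle = goodness_of_fit_chisq(
            (summary.n_group1_bound, summary.n_bound), k_global / len(defined)
        )
        assert summary.test.statistic == pytest.approx(oracle.statistic)
        assert summary.test.p_value == pytest.approx(oracle.p_value)

    def test_enriched_binders_give_tiny_p(self, shift_calls, rip_sim):
        """Binders are planted 3x more likely to shift: p < 1e-6."""
        defined = {c.transcript_id for c in shift_calls if c.defined}
        summary = shift_enrichment(shift_calls, rip_sim.bound & defined)
        assert summary.test.p_value < 1e-6
        assert summary.pct_group1_bound > summary.pct_group1_global

    def test_unenriched_bound_set_is_calibrated(self, default_config):
        """With the binder multiplier off, the bound subset matches the
        global rate and the test stays quiet (p >= 0.01)."""
        cfg = replace(default_config, binder_shift_multiplier=1.0)
        fake_bound = frozenset(f"t{i:04d}" for i in range(1, 301))
        sim = simulate_polysome(cfg, fake_bound)
        wt = normalize_fractions(sim.wt_counts, cfg.scheme, genotype="WT")
        ko = normalize_fractions(sim.ko_counts, cfg.scheme, genotype="KO")
        calls = classify_shifts(wt, ko, cfg.scheme)
        defined = {c.transcript_id for c in calls if c.defined}
        summary = shift_enrichment(calls, fake_bound & defined)
        assert summary.test.p_value >= 0.01

    def test_empty_bound_set_rejected(self):
        calls = self.make_calls(10, 3)
        with pytest.raises(ValueError, match="empty"):
            shift_enrichment(calls, frozenset())
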