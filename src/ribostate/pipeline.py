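"""End-to-end orchestration: simulate -> binder calling -> CLIP coverage
-> polysome shift classification -> DE concordance, with one summary
report mirroring the headline quantities of the full analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

from ribostate.concordance import concordant_intersect, filter_de
from ribostate.overlap import clip_coverage, transcriptome_fraction
from ribostate.polysome import classify_shifts, normalize_fractions, shift_enrichment
from ribostate.ripseq import NormalizationConfig, call_binders, rip_enrichment
from ribostate.simulate import (
    SimulationConfig,
    simulate_de,
    simulate_eclip,
    simulate_polysome,
    simulate_ripseq,
)


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of the pipeline plus the simulation conditions.

    ``effects`` toggles the planted effects: False re-runs the whole
    pipeline under the null (no bound transcripts enriched, no
    translation shift, no concordant genes) for calibration checks.
    """

    seed: int = 0
    cutoff: float = 4.0
    secondary_cutoff: float = 2.0
    shift_threshold: float = 0.5
    fdr: float = 0.05
    fold: float = 2.0
    effects: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    norm: NormalizationConfig = field(default_factory=NormalizationConfig)

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.secondary_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")
        if not 0 < self.shift_threshold:
            raise ValueError("shift_threshold must be > 0")
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must be in [0, 1]")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")

    def effective_sim(self) -> SimulationConfig:
        sim = replace(self.sim, seed=self.seed)
        if self.effects:
            return sim
        return replace(
            sim,
            bound_fold=1.0,
            shift_strength=0.0,
            binder_shift_multiplier=1.0,
            de_concordant=(0, 0),
            peak_rate_bound=sim.peak_rate_unbound,
        )


def run_pipeline(config: RunConfig = RunConfig()) -> dict:
    """Run every stage on synthetic data and return the summary report.

    The report is a plain JSON-serializable dict: per-stage counts,
    percentages and test statistics, plus truth-based recovery metrics
    (the data is synthetic, so the planted truth is known) and the
    echoed configuration for provenance. Deterministic given the config.
    """
    sim_cfg = config.effective_sim()

    # --- RIP-seq binder calling -------------------------------------------
    rip = simulate_ripseq(sim_cfg)
    results, factors = rip_enrichment(rip.counts, rip.transcripts, config.norm)
    binders = call_binders(results, config.cutoff)
    binders_loose = call_binders(results, config.secondary_cutoff)
    true_pos = len(binders.members & rip.bound)
    sensitivity = true_pos / len(rip.bound) if rip.bound else float("nan")
    fdr_obs = (
        (len(binders) - true_pos) / len(binders) if len(binders) else 0.0
    )

    # --- eCLIP coverage of called binders ---------------------------------
    peaks = simulate_eclip(sim_cfg, rip.transcripts, rip.bound)
    coverage = (
        clip_coverage(binders, peaks, rip.transcripts)
        if len(binders)
        else None
    )

    # --- polysome shift classification ------------------------------------
    poly = simulate_polysome(sim_cfg, rip.bound)
    wt = normalize_fractions(poly.wt_counts, sim_cfg.scheme, genotype="WT")
    ko = normalize_fractions(poly.ko_counts, sim_cfg.scheme, genotype="KO")
    calls = classify_shifts(wt, ko, sim_cfg.scheme, config.shift_threshold)
    defined = [c for c in calls if c.defined]
    bound_for_test = (
        binders.members & {c.transcript_id for c in defined}
        if len(binders)
        else frozenset()
    )
    shift = (
        shift_enrichment(calls, bound_for_test) if bound_for_test else None
    )

    # --- DE concordance ----------------------------------------------------
    de = simulate_de(sim_cfg, fdr=config.fdr, fold=config.fold)
    conc = concordant_intersect(
        filter_de(de.table_a, config.fdr, config.fold),
        filter_de(de.table_b, config.fdr, config.fold),
    )

    report = {
        "config": {
            "seed": config.seed,
            "cutoff": config.cutoff,
            "secondary_cutoff": config.secondary_cutoff,
            "shift_threshold": config.shift_threshold,
            "fdr": config.fdr,
            "fold": config.fold,
            "effects": config.effects,
            "sim": {
                k: v for k, v in asdict(sim_cfg).items() if k != "scheme"
            },
        },
        "ripseq": {
            "size_factors": {s: float(f) for s, f in factors.items()},
            "n_detected": binders.universe_size,
            "n_binders": len(binders),
            "n_binders_secondary": len(binders_loose),
            "pct_transcriptome": transcriptome_fraction(binders)
            if len(binders)
            else 0,
            "recovery": {"sensitivity": sensitivity, "fdr": fdr_obs},
        },
        "eclip": {
            "n_peaks": len(peaks),
            "coverage": None
            if coverage is None
            else {
                "n_queried": coverage.n_queried,
                "n_covered": coverage.n_covered,
                "pct_covered": coverage.pct_covered,
            },
        },
        "polysome": {
            "n_calls": len(calls),
            "n_defined": len(defined),
            "pct_group1_global": None,
            "pct_group1_bound": None,
            "chisq": None,
            "p_value": None,
        },
        "concordance": {
            "n_a": conc.n_a,
            "n_b": conc.n_b,
            "n_concordant": conc.n_concordant,
            "n_up": conc.n_up,
            "n_down": conc.n_down,
        },
    }
    if defined:
        n_g1 = sum(c.group == 1 for c in defined)
        report["polysome"]["pct_group1_global"] = round(
            100.0 * n_g1 / len(defined), 1
        )
    if shift is not None:
        report["polysome"].update(
            pct_group1_bound=shift.pct_group1_bound,
            chisq=shift.test.statistic,
            p_value=shift.test.p_value,
        )
    return report


def format_report(report: dict) -> str:
    """Human-readable summary block of a pipeline report."""
    rip = report["ripseq"]
    ec = report["eclip"]
    po = report["polysome"]
    co = report["concordance"]
    lines = [
        "ribostate pipeline summary",
        f"  seed {report['config']['seed']}, effects "
        + ("on" if report["config"]["effects"] else "off (null)"),
        f"  binders: {rip['n_binders']} of {rip['n_detected']} detected "
        f"transcripts at fold > {report['config']['cutoff']:g} "
        f"({rip['pct_transcriptome']}% of transcriptome); "
        f"{rip['n_binders_secondary']} at fold > "
        f"{report['config']['secondary_cutoff']:g}",
        f"  recovery: sensitivity {rip['recovery']['sensitivity']:.3f}, "
        f"FDR {rip['recovery']['fdr']:.3f}",
    ]
    if ec["coverage"]:
        cov = ec["coverage"]
        lines.append(
            f"  eCLIP: {cov['n_covered']} of {cov['n_queried']} binders with "
            f">= 1 peak ({cov['pct_covered']}%) from {ec['n_peaks']} peaks"
        )
    if po["pct_group1_global"] is not None:
        line = (
            f"  polysome: {po['pct_group1_global']}% of mRNAs group 1 "
            f"(TE dropped > half in KO)"
        )
        if po["p_value"] is not None:
            line += (
                f"; {po['pct_group1_bound']}% among binders "
                f"(chi-square {po['chisq']:.1f}, p = {po['p_value']:.3g})"
            )
        lines.append(line)
    lines.append(
        f"  concordant DE: {co['n_concordant']} genes "
        f"({co['n_up']} up, {co['n_down']} down) at FDR <= "
        f"{report['config']['fdr']:g}, fold >= {report['config']['fold']:g}"
    )
    return "\n".join(lines)
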