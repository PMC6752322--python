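"""End-to-end per-sample pipeline: reads in, sample report out.

Stages (per locus): flank anchoring -> maximum-repeat estimation -> marker
discovery -> template-pool construction -> per-read best-match calling ->
phasing (or histogram local maxima when unphaseable) -> per-allele summaries,
interruption screen and sample classification.  Every stage is deterministic,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as nio
from .errors import ConfigurationError, InputError
from .genotype import (
    MatchRejection,
    ReadCall,
    STRINGENCY_LEVELS,
    call_markers,
    match_templates,
)
from .locus import LocusSpec, MarkerHaplotype, build_template_pool
from .ontarget import AnchoredRead, estimate_max_repeat, select_ontarget
from .report import (
    AlleleSummary,
    InterruptionReport,
    PHASE_NONE,
    PhaseDecision,
    SampleReport,
    assign_alleles,
    classify_sample,
    control_locus_call,
    decide_phase,
    detect_interruptions,
    summarize_allele,
    unphased_genotype,
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; thresholds live on the LocusSpec."""

    loci: Sequence[LocusSpec]
    reads_path: Optional[str] = None  # or pass reads directly to run_pipeline
    sample_id: str = "sample"
    out_dir: Optional[str] = None
    stringency_levels: tuple[float, ...] = STRINGENCY_LEVELS
    match_window: Optional[int] = 15
    max_repeat_margin: int = 5
    min_minor_fraction: float = 0.2
    peak_smooth_window: int = 3
    peak_min_separation: int = 5
    peak_min_weight: float = 0.05
    interruption_min_support: int = 5
    interruption_min_fraction: float = 0.8
    write_plots: bool = False
    seed: int = 0  # recorded for provenance; the analysis itself is deterministic

    def __post_init__(self) -> None:
        if not self.loci:
            raise ConfigurationError("at least one locus is required")
        if list(self.stringency_levels) != sorted(self.stringency_levels):
            raise ConfigurationError("stringency levels must be sorted ascending")
        for level in self.stringency_levels:
            if not 0 < level <= 1:
                raise ConfigurationError("stringency levels must lie in (0, 1]")


@dataclass
class LocusResult:
    """Per-locus intermediate results retained for reporting and tests."""

    locus: LocusSpec
    anchored: list[AnchoredRead]
    calls: list[ReadCall]
    rejections: list[MatchRejection]
    phase: PhaseDecision
    allele_calls: tuple[list[ReadCall], list[ReadCall]] | None
    unassigned: list[ReadCall]
    allele_summaries: list[AlleleSummary]
    modes: tuple[int, ...]
    interruptions: list[InterruptionReport] = field(default_factory=list)


@dataclass
class PipelineResult:
    report: SampleReport
    per_locus: dict[str, LocusResult]
    rejection_tally: Counter


def _discover_haplotypes(
    locus: LocusSpec,
    marker_calls,
    phase: PhaseDecision,
) -> list[Optional[MarkerHaplotype]]:
    """Marker haplotypes to enumerate in the template pool.

    For phased samples, one haplotype per allele key; markers the phase does
    not use are filled with the sample's modal determined value (falling back
    to the layout default).  Unphaseable samples get the single modal
    haplotype.  Callers pass only the observed haplotypes rather than every
    possible marker combination, keeping the pool linear in max repeat length.
    """
    layout = locus.flank2_layout
    if layout is None:
        return [None]
    ctc_counts = Counter(
        m.sec_tract_len for m in marker_calls if m.sec_tract_len is not None
    )
    snp_counts = Counter(m.snp_allele for m in marker_calls if m.snp_allele is not None)
    modal_ctc = ctc_counts.most_common(1)[0][0] if ctc_counts else layout.default_tract_len
    modal_snp = snp_counts.most_common(1)[0][0] if snp_counts else layout.snp_alleles[0]

    def make(ctc: Optional[int], snp: Optional[str]) -> MarkerHaplotype:
        tract = ctc if ctc is not None else modal_ctc
        return MarkerHaplotype(
            sec_tract_len=tract,
            ctt_index=min(layout.default_ctt_index, tract),
            snp_allele=snp if snp is not None else modal_snp,
        )

    if phase.phased and phase.allele_keys is not None:
        haps = [make(ctc, snp) for ctc, snp in phase.allele_keys]
        # keys identical in the pooled markers would collapse; dedupe keeps order
        seen: list[MarkerHaplotype] = []
        for h in haps:
            if h not in seen:
                seen.append(h)
        return list(seen)
    return [make(None, None)]


def _analyze_locus(
    locus: LocusSpec, anchored: list[AnchoredRead], config: RunConfig
) -> LocusResult:
    markers = {read.read_id: call_markers(read, locus) for read in anchored}
    phase0 = decide_phase(list(markers.values()), config.min_minor_fraction)
    max_repeat = estimate_max_repeat(anchored, locus, margin=config.max_repeat_margin)
    haplotypes = _discover_haplotypes(locus, markers.values(), phase0)
    pool = build_template_pool(locus, max_repeat, haplotypes)

    calls: list[ReadCall] = []
    rejections: list[MatchRejection] = []
    base_level = config.stringency_levels[0]
    for read in anchored:
        res = match_templates(
            read,
            pool,
            locus,
            min_similarity=base_level,
            window=config.match_window,
            markers=markers[read.read_id],
            stringency_levels=config.stringency_levels,
        )
        if isinstance(res, ReadCall):
            calls.append(res)
        else:
            rejections.append(res)

    anchored_by_id = {r.read_id: r for r in anchored}
    interruption_reports: list[InterruptionReport] = []
    if not calls:
        return LocusResult(
            locus=locus, anchored=anchored, calls=[], rejections=rejections,
            phase=PhaseDecision(PHASE_NONE), allele_calls=None, unassigned=[],
            allele_summaries=[], modes=(),
        )

    phase = decide_phase(calls, config.min_minor_fraction)
    if phase.phased:
        assignment = assign_alleles(calls, phase)
        groups = assignment.groups
        summaries = []
        for key, group in zip(phase.allele_keys or ((None, None),) * 2, groups):
            if group:
                summaries.append(
                    summarize_allele(
                        [c.repeat_len for c in group],
                        expansion_threshold=locus.expansion_threshold,
                        sec_tract_len=key[0]
                        if key[0] is not None
                        else _modal_template_tract(group),
                    )
                )
        modes = tuple(s.mode_len for s in summaries if s.mode_len is not None)
        for group in groups:
            interruption_reports.append(
                detect_interruptions(
                    group, anchored_by_id, locus,
                    min_support=config.interruption_min_support,
                    min_fraction=config.interruption_min_fraction,
                )
            )
        unassigned = assignment.unassigned
        allele_calls: tuple[list[ReadCall], list[ReadCall]] | None = groups
    else:
        lengths = [c.repeat_len for c in calls]
        peaks = unphased_genotype(
            lengths,
            smooth_window=config.peak_smooth_window,
            min_separation=config.peak_min_separation,
            min_weight=config.peak_min_weight,
        )
        modes = tuple(peaks)
        summaries = [
            AlleleSummary(
                n_reads=0, mode_len=peak, mean_len=None, min_len=None,
                max_len=None, size_range=None,
                expanded=peak >= locus.expansion_threshold,
                sec_tract_len=_modal_template_tract(calls),
            )
            for peak in peaks
        ]
        unassigned = list(calls)
        allele_calls = None

    return LocusResult(
        locus=locus, anchored=anchored, calls=calls, rejections=rejections,
        phase=phase, allele_calls=allele_calls, unassigned=unassigned,
        allele_summaries=summaries, modes=modes,
        interruptions=interruption_reports,
    )


def _modal_template_tract(calls: Sequence[ReadCall]) -> Optional[int]:
    tracts = [
        c.template_haplotype.sec_tract_len
        for c in calls
        if c.template_haplotype is not None
    ]
    return Counter(tracts).most_common(1)[0][0] if tracts else None


def run_pipeline(
    config: RunConfig, reads: Optional[list[tuple[str, str]]] = None
) -> PipelineResult:
    """Execute the full analysis for one sample.

    ``reads`` may be passed directly (library use) or read from
    ``config.reads_path``.  The first configured locus is the reported
    target; any locus with a ``control_threshold`` is reported as a control.
    """
    if reads is None:
        if config.reads_path is None:
            raise InputError("no reads: provide reads or config.reads_path")
        reads = nio.read_fastx(config.reads_path)
    if not reads:
        raise InputError("read set is empty")

    selection = select_ontarget(reads, config.loci)
    per_locus: dict[str, LocusResult] = {}
    for locus in config.loci:
        anchored = selection.accepted[locus.name]
        if anchored:
            per_locus[locus.name] = _analyze_locus(locus, anchored, config)

    target = config.loci[0]
    target_res = per_locus.get(target.name)
    category = None
    if target_res and target_res.modes:
        modes = target_res.modes
        pair = (modes[0], modes[-1]) if len(modes) >= 2 else (modes[0], modes[0])
        category = classify_sample(pair, target.expansion_threshold)

    control_calls = {}
    for locus in config.loci:
        if locus.control_threshold is None or locus.name not in per_locus:
            continue
        res = per_locus[locus.name]
        if res.modes:
            pair = (
                (res.modes[0], res.modes[-1])
                if len(res.modes) >= 2
                else (res.modes[0], res.modes[0])
            )
            control_calls[locus.name] = {
                "modes": list(pair),
                "expanded": list(control_locus_call(pair, locus.control_threshold)),
            }

    report = SampleReport(
        sample_id=config.sample_id,
        phase=target_res.phase if target_res else PhaseDecision(PHASE_NONE),
        alleles=target_res.allele_summaries if target_res else [],
        category=category,
        on_target_counts={
            name: len(selection.accepted[name]) for name in selection.accepted
        },
        control_calls=control_calls,
        interruptions=target_res.interruptions if target_res else [],
    )
    result = PipelineResult(
        report=report,
        per_locus=per_locus,
        rejection_tally=selection.rejection_tally,
    )
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nio.write_report_json(result.report, out / f"{config.sample_id}.report.json")
    for name, res in result.per_locus.items():
        nio.write_read_calls_tsv(res.calls, out / f"{config.sample_id}.{name}.calls.tsv")
        groups: dict[str, list[int]] = {}
        if res.allele_calls is not None:
            for i, group in enumerate(res.allele_calls, start=1):
                groups[f"allele{i}"] = [c.repeat_len for c in group]
        else:
            groups["all"] = [c.repeat_len for c in res.calls]
        for label, lengths in groups.items():
            nio.write_histogram_tsv(
                lengths, out / f"{config.sample_id}.{name}.{label}.hist.tsv"
            )
        if config.write_plots:
            nio.plot_histogram(
                groups, out / f"{config.sample_id}.{name}.hist.png",
                title=f"{config.sample_id} {name}",
            )
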