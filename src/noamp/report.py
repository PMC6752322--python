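"""Phasing, per-allele summaries, interruption detection and cohort tables.

Reads are phased into two alleles whenever the sample is heterozygous at the
downstream SNP or at the secondary (CTC) tract length; otherwise a biallelic
genotype is recovered from local maxima of the repeat-length histogram.
Per-allele statistics (mode, mean, min, max, size range) quantify somatic
repeat instability: the size range — largest minus smallest recorded length —
is the mosaicism measure that grows with allele length in expanded alleles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import InputError
from .genotype import MarkerCall, ReadCall
from .locus import LocusSpec
from .ontarget import AnchoredRead

PHASE_SNP = "SNP"
PHASE_CTC = "CTC"
PHASE_BOTH = "CTC_and_SNP"
PHASE_NONE = "none"

#: minimum read fraction each of the two most frequent marker values must
#: reach before the sample is declared heterozygous at that marker
DEFAULT_MIN_MINOR_FRACTION = 0.2

AlleleKey = tuple[Optional[int], Optional[str]]  # (tract length, SNP base)


@dataclass(frozen=True)
class PhaseDecision:
    """Which marker(s) make the sample phaseable, and the two allele keys."""

    method: str
    allele_keys: Optional[tuple[AlleleKey, AlleleKey]] = None

    @property
    def phased(self) -> bool:
        return self.method != PHASE_NONE


def _marker_calls(calls: Iterable) -> list[MarkerCall]:
    out = []
    for c in calls:
        out.append(c.markers if isinstance(c, ReadCall) else c)
    return out


def _het_values(values: list, min_fraction: float) -> Optional[tuple]:
    """The two most frequent values if both clear the minor-fraction floor."""
    counts = Counter(values)
    if len(counts) < 2:
        return None
    total = sum(counts.values())
    (v1, n1), (v2, n2) = counts.most_common(2)
    if n1 / total >= min_fraction and n2 / total >= min_fraction:
        return (v1, v2)
    return None


def decide_phase(
    calls: Sequence[ReadCall | MarkerCall],
    min_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
) -> PhaseDecision:
    """Aggregate per-read marker calls into a phase decision.

    A marker is heterozygous when its two most frequent determined values
    each carry at least ``min_fraction`` of the determined reads (the floor
    resists sporadically miscalled markers).  The method label prefers the
    conjunction when both markers are informative.
    """
    if not calls:
        raise InputError("cannot phase an empty call set")
    markers = _marker_calls(calls)
    snp_vals = [m.snp_allele for m in markers if m.snp_allele is not None]
    ctc_vals = [m.sec_tract_len for m in markers if m.sec_tract_len is not None]
    snp_het = _het_values(snp_vals, min_fraction)
    ctc_het = _het_values(ctc_vals, min_fraction)

    if snp_het and ctc_het:
        joint = Counter(
            (m.sec_tract_len, m.snp_allele)
            for m in markers
            if m.sec_tract_len in ctc_het and m.snp_allele in snp_het
        )
        top = [key for key, _ in joint.most_common(2)]
        if len(top) == 2:
            return PhaseDecision(PHASE_BOTH, (top[0], top[1]))
        # degenerate joint support: fall through to the single-marker methods
    if snp_het:
        return PhaseDecision(PHASE_SNP, ((None, snp_het[0]), (None, snp_het[1])))
    if ctc_het:
        return PhaseDecision(PHASE_CTC, ((ctc_het[0], None), (ctc_het[1], None)))
    return PhaseDecision(PHASE_NONE)


def phase_method_from_genotypes(
    snp_genotype: tuple[str, str], tract_lengths: tuple[Optional[int], Optional[int]]
) -> str:
    """Phase method implied by known per-sample marker genotypes.

    The same heterozygosity rule as :func:`decide_phase`, applied to genotype
    pairs rather than read sets (useful for summary tables that print marker
    genotypes but not reads).
    """
    snp_het = snp_genotype[0] != snp_genotype[1]
    a, b = tract_lengths
    ctc_het = a is not None and b is not None and a != b
    if snp_het and ctc_het:
        return PHASE_BOTH
    if snp_het:
        return PHASE_SNP
    if ctc_het:
        return PHASE_CTC
    return PHASE_NONE


@dataclass
class AlleleAssignment:
    groups: tuple[list[ReadCall], list[ReadCall]]
    unassigned: list[ReadCall]


def _read_key(call: ReadCall, phase: PhaseDecision) -> AlleleKey:
    """Marker signature of a read, restricted to the phase-informative markers.

    The matched template's haplotype takes precedence over the raw per-read
    marker call (the template was selected on full-sequence evidence).
    """
    if call.template_haplotype is not None:
        ctc, snp = call.template_haplotype.signature
    else:
        ctc, snp = call.markers.sec_tract_len, call.markers.snp_allele
    assert phase.allele_keys is not None
    use_ctc = phase.allele_keys[0][0] is not None
    use_snp = phase.allele_keys[0][1] is not None
    return (ctc if use_ctc else None, snp if use_snp else None)


def assign_alleles(
    calls: Sequence[ReadCall], phase: PhaseDecision
) -> AlleleAssignment:
    """Partition read calls into the two phased allele groups.

    Reads whose (informative-marker) signature matches neither allele key —
    including reads with the relevant marker undetermined — go to the
    unassigned pool.
    """
    if not phase.phased or phase.allele_keys is None:
        raise InputError("assign_alleles requires a phased sample")
    key1, key2 = phase.allele_keys
    need_ctc = key1[0] is not None
    need_snp = key1[1] is not None
    g1: list[ReadCall] = []
    g2: list[ReadCall] = []
    unassigned: list[ReadCall] = []
    for call in calls:
        key = _read_key(call, phase)
        if (need_ctc and key[0] is None) or (need_snp and key[1] is None):
            unassigned.append(call)
        elif key == key1:
            g1.append(call)
        elif key == key2:
            g2.append(call)
        else:
            unassigned.append(call)
    return AlleleAssignment(groups=(g1, g2), unassigned=unassigned)


@dataclass
class AlleleSummary:
    """Per-allele repeat statistics (one summary table row per allele)."""

    n_reads: int
    mode_len: Optional[int]
    mean_len: Optional[int]
    min_len: Optional[int]
    max_len: Optional[int]
    size_range: Optional[int]
    expanded: Optional[bool] = None
    sec_tract_len: Optional[int] = None


def summarize_allele(
    lengths: Sequence[int],
    expansion_threshold: int = 50,
    sec_tract_len: Optional[int] = None,
) -> AlleleSummary:
    """Mode (ties to the smallest length), rounded mean, min, max and range."""
    if not lengths:
        raise InputError("cannot summarize an empty allele")
    counts = Counter(lengths)
    top = max(counts.values())
    mode = min(v for v, n in counts.items() if n == top)
    mean = int(np.floor(np.mean(lengths) + 0.5))
    lo, hi = min(lengths), max(lengths)
    return AlleleSummary(
        n_reads=len(lengths),
        mode_len=mode,
        mean_len=mean,
        min_len=lo,
        max_len=hi,
        size_range=hi - lo,
        expanded=mode >= expansion_threshold,
        sec_tract_len=sec_tract_len,
    )


def unphased_genotype(
    lengths: Sequence[int],
    smooth_window: int = 3,
    min_separation: int = 5,
    min_weight: float = 0.05,
) -> list[int]:
    """Presumptive biallelic genotype from repeat-length histogram maxima.

    The histogram is smoothed with a moving average, local maxima separated
    by at least ``min_separation`` repeat units are found, and each peak must
    carry at least ``min_weight`` of the reads within ``min_separation`` units
    of it.  The top two peaks (by carried weight, ties to the smaller length)
    are returned in ascending length order; peaks closer than the separation
    merge into the higher one.
    """
    if not lengths:
        raise InputError("cannot genotype an empty length set")
    lo, hi = min(lengths), max(lengths)
    counts = np.bincount(np.asarray(lengths) - lo, minlength=hi - lo + 1).astype(float)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts, kernel, mode="same")
    # zero-pad so peaks at the histogram edges are detectable
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, distance=max(1, min_separation))
    total = float(len(lengths))
    scored = {}
    half = max(1, smooth_window // 2)
    for p in peaks:
        ix = p - 1
        # snap to the raw-count argmax in the smoothing neighborhood
        lov = max(0, ix - half)
        local = counts[lov : ix + half + 1]
        ix = lov + int(np.argmax(local))
        lov = max(0, ix - min_separation)
        weight = counts[lov : ix + min_separation + 1].sum() / total
        if weight >= min_weight:
            length = int(lo + ix)
            scored[length] = max(scored.get(length, 0.0), weight)
    ranked = sorted(scored.items(), key=lambda t: (-t[1], t[0]))
    return sorted(length for length, _ in ranked[:2])


@dataclass
class Interruption:
    motif: str
    triplet_index: int  # 1-based within the repeat tract
    support: float


@dataclass
class InterruptionReport:
    """Consensus deviations from the repeat unit within one allele's tract."""

    assessable: bool
    tract_len: Optional[int] = None
    n_reads_used: int = 0
    interruptions: list[Interruption] = field(default_factory=list)


def detect_interruptions(
    calls: Sequence[ReadCall],
    anchored: Mapping[str, AnchoredRead],
    locus: LocusSpec,
    min_support: int = 5,
    min_fraction: float = 0.8,
) -> InterruptionReport:
    """Find non-canonical triplets at fixed positions within an allele's tract.

    Mosaic alleles make positional consensus ill-defined, so only reads at
    the allele's modal repeat length are decomposed into triplets; any
    position whose consensus motif differs from the repeat unit with support
    above ``min_fraction`` is reported.  Fewer than ``min_support`` usable
    reads makes the allele not assessable.
    """
    if not calls:
        return InterruptionReport(assessable=False)
    modal = Counter(c.repeat_len for c in calls).most_common(1)[0][0]
    unit = locus.repeat_unit
    k = len(unit)
    columns: list[Counter] = [Counter() for _ in range(modal)]
    used = 0
    for call in calls:
        if call.repeat_len != modal:
            continue
        read = anchored.get(call.read_id)
        if read is None:
            continue
        start = read.flank1_span[1]
        tract = read.oriented_sequence[start : start + k * modal]
        if len(tract) < k * modal:
            continue
        used += 1
        for i in range(modal):
            columns[i][tract[k * i : k * (i + 1)]] += 1
    if used < min_support:
        return InterruptionReport(assessable=False, tract_len=modal, n_reads_used=used)
    found = []
    for i, col in enumerate(columns):
        motif, n = col.most_common(1)[0]
        if motif != unit and n / used >= min_fraction:
            found.append(Interruption(motif=motif, triplet_index=i + 1, support=n / used))
    return InterruptionReport(
        assessable=True, tract_len=modal, n_reads_used=used, interruptions=found
    )


CATEGORY_BIALLELIC_NONEXPANDED = "A"
CATEGORY_MONOALLELIC_EXPANSION = "B"
CATEGORY_BIALLELIC_EXPANSION = "C"


def classify_sample(modes: tuple[int, int], threshold: int = 50) -> str:
    """A: both modes < threshold; B: exactly one >=; C: both >= (inclusive)."""
    if min(modes) < 1:
        raise InputError("allele modes must be >= 1")
    n_exp = sum(m >= threshold for m in modes)
    return {0: CATEGORY_BIALLELIC_NONEXPANDED,
            1: CATEGORY_MONOALLELIC_EXPANSION,
            2: CATEGORY_BIALLELIC_EXPANSION}[n_exp]


def control_locus_call(
    modes: tuple[int, int], control_threshold: int
) -> tuple[bool, bool]:
    """Expansion flags for a control locus (strictly greater than threshold)."""
    if min(modes) < 1:
        raise InputError("allele modes must be >= 1")
    return tuple(m > control_threshold for m in modes)  # type: ignore[return-value]


@dataclass
class SampleReport:
    """Per-sample pipeline output (mirrors one cohort summary table row)."""

    sample_id: str
    phase: PhaseDecision
    alleles: list[AlleleSummary]
    category: Optional[str]
    on_target_counts: dict[str, int]
    control_calls: dict[str, dict] = field(default_factory=dict)
    interruptions: list[InterruptionReport] = field(default_factory=list)


@dataclass
class CohortSummary:
    n_samples: int
    mean_on_target: dict[str, int]
    category_counts: dict[str, int]
    phased_samples: int
    phased_alleles: int
    sec_tract_min: Optional[int]
    sec_tract_max: Optional[int]
    instability_pairs: list[tuple[int, int]]  # (mean length, size range) per allele


def cohort_summary(reports: Sequence[SampleReport]) -> CohortSummary:
    """Aggregate per-sample reports into cohort-level statistics.

    Means are rounded to the nearest integer; category counts partition the
    cohort; the phased-allele count is two per phased sample; the
    (mean length, size range) pairs over phased alleles are the
    instability-versus-length relationship for plotting.  Alleles with
    unidentifiable statistics are skipped where their fields are needed.
    """
    if not reports:
        raise InputError("cohort is empty")
    loci = sorted({name for r in reports for name in r.on_target_counts})
    mean_on_target = {
        name: int(
            np.floor(
                np.mean([r.on_target_counts.get(name, 0) for r in reports]) + 0.5
            )
        )
        for name in loci
    }
    categories = Counter(r.category if r.category else "undetermined" for r in reports)
    phased = [r for r in reports if r.phase.phased]
    tract_values = [
        a.sec_tract_len
        for r in reports
        for a in r.alleles
        if a.sec_tract_len is not None
    ]
    pairs = [
        (a.mean_len, a.size_range)
        for r in phased
        for a in r.alleles
        if a.mean_len is not None and a.size_range is not None
    ]
    return CohortSummary(
        n_samples=len(reports),
        mean_on_target=mean_on_target,
        category_counts=dict(categories),
        phased_samples=len(phased),
        phased_alleles=2 * len(phased),
        sec_tract_min=min(tract_values) if tract_values else None,
        sec_tract_max=max(tract_values) if tract_values else None,
        instability_pairs=pairs,
    )
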