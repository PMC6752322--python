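"""Target locus definitions, reference template pools and the gRNA mismatch scan.

A targeted repeat locus is modelled as ``flank1 + (unit x L) + flank2`` where
``flank2`` may itself carry two phasing markers: a polymorphic secondary
trinucleotide tract (a CTC run carrying a single CTT interruption at the
CTG18.1 locus) sitting immediately 3' of the repeat of interest, and a
biallelic SNP further downstream.  Repeat-length calling works by aligning
each on-target read against an exhaustive pool of reference templates, one
per (repeat length, marker haplotype) combination, so the pool builder here
is the backbone of the genotyping step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._seq import as_dna, revcomp
from .errors import ConfigurationError, InputError

_DNA = set("ACGT")


@dataclass(frozen=True)
class MarkerHaplotype:
    """One allele's signature at the two flank-2 markers.

    Parameters
    ----------
    sec_tract_len:
        Number of triplets in the secondary tract, counting its single
        interruption triplet (CTT within a CTC run) as one tract triplet.
    ctt_index:
        1-based triplet index of the interruption within the tract.  The
        interruption's presence is a fixed feature of the locus; its position
        is part of the haplotype and defaults to a configurable index when
        unknown.
    snp_allele:
        The base carried at the downstream SNP site.
    """

    sec_tract_len: int
    ctt_index: int
    snp_allele: str

    def __post_init__(self) -> None:
        if self.sec_tract_len < 1:
            raise ConfigurationError("secondary tract length must be >= 1")
        if not 1 <= self.ctt_index <= self.sec_tract_len:
            raise ConfigurationError(
                f"interruption index {self.ctt_index} outside tract of "
                f"{self.sec_tract_len} triplets"
            )
        if len(self.snp_allele) != 1 or self.snp_allele not in _DNA:
            raise ConfigurationError(f"invalid SNP allele {self.snp_allele!r}")

    def tract_sequence(self, unit: str = "CTC", interruption: str = "CTT") -> str:
        triplets = [unit] * self.sec_tract_len
        triplets[self.ctt_index - 1] = interruption
        return "".join(triplets)

    @property
    def signature(self) -> tuple[int, str]:
        """(tract length, SNP base) — the observable used for phasing."""
        return (self.sec_tract_len, self.snp_allele)


@dataclass(frozen=True)
class Flank2Layout:
    """Ordered segments of the downstream flank.

    ``spacer`` separates the main repeat from the secondary tract (empty when
    the tract sits immediately 3' of the repeat), ``spacer_to_snp`` is the
    constant sequence between the tract and the SNP site, and ``rest`` is the
    remaining constant flank after the SNP.
    """

    spacer: str
    spacer_to_snp: str
    snp_alleles: tuple[str, str]
    rest: str
    sec_unit: str = "CTC"
    interruption_unit: str = "CTT"
    default_tract_len: int = 12
    default_ctt_index: int = 6

    def __post_init__(self) -> None:
        for allele in self.snp_alleles:
            if len(allele) != 1 or allele not in _DNA:
                raise ConfigurationError(f"invalid SNP allele {allele!r}")
        if len(set(self.snp_alleles)) != 2:
            raise ConfigurationError("SNP must be biallelic with two distinct alleles")
        for unit in (self.sec_unit, self.interruption_unit):
            if len(unit) != 3 or set(unit) - _DNA:
                raise ConfigurationError(f"invalid tract unit {unit!r}")
        if not self.spacer_to_snp:
            raise ConfigurationError("spacer_to_snp must be non-empty (SNP anchor)")

    def default_haplotype(self) -> MarkerHaplotype:
        return MarkerHaplotype(
            sec_tract_len=self.default_tract_len,
            ctt_index=min(self.default_ctt_index, self.default_tract_len),
            snp_allele=self.snp_alleles[0],
        )

    def build(self, haplotype: MarkerHaplotype) -> str:
        return (
            self.spacer
            + haplotype.tract_sequence(self.sec_unit, self.interruption_unit)
            + self.spacer_to_snp
            + haplotype.snp_allele
            + self.rest
        )


@dataclass(frozen=True)
class LocusSpec:
    """A targeted repeat locus: flanks, repeat unit, marker layout, thresholds.

    ``flank2_layout`` is present for marker-bearing loci (the CTG18.1-style
    target); control loci without phasing markers supply a constant
    ``flank2_const`` instead.
    """

    name: str
    repeat_unit: str
    flank1: str
    flank2_layout: Optional[Flank2Layout] = None
    flank2_const: Optional[str] = None
    expansion_threshold: int = 50
    control_threshold: Optional[int] = None
    min_flank_identity: float = 0.90
    min_template_similarity: float = 0.99

    def __post_init__(self) -> None:
        unit = self.repeat_unit
        if len(unit) != 3 or set(unit) - _DNA:
            raise ConfigurationError(
                f"repeat unit must be a trinucleotide over ACGT, got {unit!r}"
            )
        if (self.flank2_layout is None) == (self.flank2_const is None):
            raise ConfigurationError(
                "exactly one of flank2_layout / flank2_const must be given"
            )
        if not self.flank1:
            raise ConfigurationError("flank1 must be non-empty")
        for label, flank in (("flank1", self.flank1), ("flank2", self.canonical_flank2)):
            if not flank:
                raise ConfigurationError(f"{label} must be non-empty")
            if unit * 3 in flank:
                raise ConfigurationError(
                    f"{label} contains a run of >=3 {unit} copies; anchors must be "
                    "distinguishable from the repeat"
                )
        if not 0 < self.min_flank_identity <= self.min_template_similarity <= 1:
            raise ConfigurationError(
                "thresholds must satisfy 0 < min_flank_identity <= "
                "min_template_similarity <= 1"
            )

    def flank2(self, haplotype: Optional[MarkerHaplotype]) -> str:
        """Downstream flank sequence for ``haplotype`` (or the constant flank)."""
        if self.flank2_layout is None:
            if haplotype is not None:
                raise ConfigurationError(
                    f"locus {self.name} has no marker layout; haplotype must be None"
                )
            assert self.flank2_const is not None
            return self.flank2_const
        if haplotype is None:
            haplotype = self.flank2_layout.default_haplotype()
        return self.flank2_layout.build(haplotype)

    @property
    def canonical_flank2(self) -> str:
        """flank2 built from the default haplotype; the anchoring reference."""
        if self.flank2_layout is None:
            assert self.flank2_const is not None
            return self.flank2_const
        return self.flank2_layout.build(self.flank2_layout.default_haplotype())

    def template_sequence(
        self, repeat_len: int, haplotype: Optional[MarkerHaplotype]
    ) -> str:
        if repeat_len < 1:
            raise ConfigurationError("repeat_len must be >= 1")
        return self.flank1 + self.repeat_unit * repeat_len + self.flank2(haplotype)


@dataclass(frozen=True)
class TemplateRef:
    """One reference sequence (repeat length x marker haplotype) in the pool."""

    locus_name: str
    repeat_len: int
    haplotype: Optional[MarkerHaplotype]
    sequence: str = field(repr=False)

    @property
    def template_id(self) -> str:
        """Canonical, diff-stable identifier ``locus|replen|ctc|snp``."""
        if self.haplotype is None:
            return f"{self.locus_name}|{self.repeat_len}|-|-"
        h = self.haplotype
        return (
            f"{self.locus_name}|{self.repeat_len}|"
            f"ctc{h.sec_tract_len}.{h.ctt_index}|snp{h.snp_allele}"
        )


def build_template_pool(
    locus: LocusSpec,
    max_repeat: int,
    haplotypes: Sequence[Optional[MarkerHaplotype]],
) -> list[TemplateRef]:
    """Enumerate every (repeat length, haplotype) reference template.

    Returns exactly ``max_repeat * len(haplotypes)`` templates ordered by
    ascending repeat length, then by haplotype input order, so downstream
    tie-breaking (smallest repeat length first) falls out of pool order.
    """
    if max_repeat < 1:
        raise ConfigurationError("max_repeat must be >= 1")
    if not haplotypes:
        raise ConfigurationError("haplotype list must be non-empty")
    if len(set(haplotypes)) != len(haplotypes):
        raise ConfigurationError("haplotypes must be pairwise distinct")
    pool = []
    for repeat_len in range(1, max_repeat + 1):
        for hap in haplotypes:
            pool.append(
                TemplateRef(
                    locus_name=locus.name,
                    repeat_len=repeat_len,
                    haplotype=hap,
                    sequence=locus.template_sequence(repeat_len, hap),
                )
            )
    return pool


@dataclass(frozen=True)
class GrnaScanHit:
    """Best ungapped placement of a gRNA within a genomic window."""

    mismatches: int
    offset: int
    strand: str  # '+' scans the window as given, '-' its reverse complement


def grna_mismatch_scan(grna: str, window: str) -> GrnaScanHit:
    """Minimum Hamming distance of a gRNA over all ungapped window offsets.

    Both the window and its reverse complement are scanned (the protospacer
    may sit on either strand); U is treated as T.  Ties break to the smallest
    offset, forward strand first.  Indels are not modelled: off-target sites
    of this kind are conventionally described by mismatch count alone.
    """
    g = as_dna(grna)
    w = as_dna(window)
    if not g or not w:
        raise InputError("gRNA and window must be non-empty")
    if len(g) > len(w):
        raise InputError("gRNA longer than window")
    best: Optional[GrnaScanHit] = None
    for strand, target in (("+", w), ("-", revcomp(w))):
        for offset in range(len(target) - len(g) + 1):
            mm = sum(a != b for a, b in zip(g, target[offset : offset + len(g)]))
            if best is None or mm < best.mismatches:
                best = GrnaScanHit(mismatches=mm, offset=offset, strand=strand)
    assert best is not None
    return best
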