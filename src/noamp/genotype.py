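"""Per-read marker genotyping and repeat-length calling.

Each on-target read is assigned a marker genotype (secondary-tract triplet
count and SNP base, read directly off the oriented sequence) and a repeat
length (by best match against the reference template pool).  A read's call
only stands if its best template reaches the similarity threshold — 99% by
default, with a stricter 99.9% level available as a pure post-hoc filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._align import global_distance, global_identity, locate
from .errors import ConfigurationError, InputError
from .locus import LocusSpec, MarkerHaplotype, TemplateRef
from .ontarget import AnchoredRead

logger = logging.getLogger(__name__)

#: default half-width, in repeat units, of the candidate-narrowing window
DEFAULT_MATCH_WINDOW = 15

#: similarity levels reported on every call (base and strict stringency)
STRINGENCY_LEVELS = (0.99, 0.999)


@dataclass(frozen=True)
class MarkerCall:
    """A read's genotype at the two phasing markers.

    ``None`` means *undetermined* — an explicit state (local indel, off-model
    base), never a guessed value.
    """

    sec_tract_len: Optional[int]
    snp_allele: Optional[str]


def call_markers(read: AnchoredRead, locus: LocusSpec) -> MarkerCall:
    """Read the secondary-tract length and SNP base off an anchored read.

    The constant tract-to-SNP spacer is located by semi-global alignment
    downstream of flank 1; the SNP is the base immediately after it.  The
    tract is measured by decomposing the interval between flank 1 and the
    spacer into triplets from the right, counting consecutive tract triplets
    (the interruption unit counts as one tract triplet).  Either field is
    undetermined when the local sequence is frame-shifted by an indel or the
    SNP base is not one of the configured alleles.
    """
    layout = locus.flank2_layout
    if layout is None:
        return MarkerCall(sec_tract_len=None, snp_allele=None)
    seq = read.oriented_sequence
    f1_end = read.flank1_span[1]
    tail = seq[f1_end:]
    if not tail:
        return MarkerCall(None, None)
    hit = locate(layout.spacer_to_snp, tail)
    if hit.identity < locus.min_flank_identity:
        return MarkerCall(None, None)

    snp_pos = f1_end + hit.end
    snp: Optional[str] = None
    if snp_pos < len(seq) and seq[snp_pos] in layout.snp_alleles:
        snp = seq[snp_pos]

    # repeat tract + spacer + secondary tract; a frame shift anywhere in it
    # makes the triplet decomposition unreliable
    region = seq[f1_end : f1_end + hit.start]
    tract_len: Optional[int] = None
    if region and (len(region) - len(layout.spacer)) % 3 == 0:
        n = 0
        for i in range(len(region) - 3, -1, -3):
            if region[i : i + 3] in (layout.sec_unit, layout.interruption_unit):
                n += 1
            else:
                break
        if n > 0:
            tract_len = n
    return MarkerCall(sec_tract_len=tract_len, snp_allele=snp)


@dataclass(frozen=True)
class ReadCall:
    """One read's inferred repeat length and supporting match evidence."""

    read_id: str
    repeat_len: int
    similarity: float
    edits: int
    template_id: str
    template_haplotype: Optional[MarkerHaplotype]
    markers: MarkerCall
    passed_stringency: dict[float, bool]

    def passes(self, threshold: float) -> bool:
        return self.similarity >= threshold


@dataclass(frozen=True)
class MatchRejection:
    read_id: str
    best_similarity: float
    best_template_id: str


def match_templates(
    read: AnchoredRead,
    pool: Sequence[TemplateRef],
    locus: LocusSpec,
    min_similarity: Optional[float] = None,
    *,
    window: Optional[int] = DEFAULT_MATCH_WINDOW,
    markers: Optional[MarkerCall] = None,
    stringency_levels: Sequence[float] = STRINGENCY_LEVELS,
) -> ReadCall | MatchRejection:
    """Best-match a read's anchored insert against the template pool.

    The insert (between and including both flank anchors, so chimeric tails
    cannot dilute similarity) is globally aligned to each candidate template;
    the template with the fewest edits wins, ties breaking to the smaller
    repeat length, then canonical pool order.  Similarity of the winner is
    1 - edits/alignment-columns; the call is rejected below
    ``min_similarity`` (the locus default is >=0.99).

    ``window`` pre-narrows candidates to repeat lengths within +/- window of
    the inter-flank span estimate; pass ``None`` to search the full pool.
    """
    if not pool:
        raise ConfigurationError("template pool is empty")
    if any(t.locus_name != locus.name for t in pool):
        raise ConfigurationError(
            f"template pool was not built for locus {locus.name}"
        )
    if min_similarity is None:
        min_similarity = locus.min_template_similarity

    insert = read.oriented_sequence[read.flank1_span[0] : read.flank2_span[1]]
    if window is not None:
        est = round(read.inter_flank_length / len(locus.repeat_unit))
        candidates = [t for t in pool if abs(t.repeat_len - est) <= window]
        if not candidates:
            candidates = list(pool)
    else:
        candidates = list(pool)

    best: Optional[TemplateRef] = None
    best_d = -1
    for tpl in candidates:
        d = global_distance(insert, tpl.sequence, k=best_d if best is not None else -1)
        if d < 0:
            continue  # beyond the current best; edlib bands it out
        if best is None or d < best_d:
            best, best_d = tpl, d
    assert best is not None
    d, similarity = global_identity(insert, best.sequence)

    if markers is None:
        markers = call_markers(read, locus)
    if similarity < min_similarity:
        return MatchRejection(
            read_id=read.read_id,
            best_similarity=similarity,
            best_template_id=best.template_id,
        )
    hap = best.haplotype
    if hap is not None and markers is not None:
        if (
            markers.sec_tract_len is not None
            and markers.sec_tract_len != hap.sec_tract_len
        ) or (markers.snp_allele is not None and markers.snp_allele != hap.snp_allele):
            # template haplotype wins for phasing; the disagreement is logged
            logger.debug(
                "read %s: marker call %s disagrees with template haplotype %s",
                read.read_id,
                markers,
                hap.signature,
            )
    return ReadCall(
        read_id=read.read_id,
        repeat_len=best.repeat_len,
        similarity=similarity,
        edits=d,
        template_id=best.template_id,
        template_haplotype=hap,
        markers=markers,
        passed_stringency={lvl: similarity >= lvl for lvl in stringency_levels},
    )


def apply_stringency(calls: Iterable[ReadCall], threshold: float) -> list[ReadCall]:
    """Keep calls at or above a similarity threshold (pure filter, no re-matching)."""
    if not 0 < threshold <= 1:
        raise InputError(f"stringency threshold must be in (0, 1], got {threshold}")
    return [c for c in calls if c.similarity >= threshold]
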