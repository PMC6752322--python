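"""On-target read selection by flank anchoring.

A read spans the locus only if both repeat-flanking sequences can be found on
it, in the right order, on the same strand, each at >=90% identity (the
repeat itself is excluded from the identity requirement by construction:
anchors are the flanks, never the repeat).  Accepted reads are reported in
locus orientation with 0-based half-open spans for both anchors and for the
inter-flank interval that contains the repeat.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._align import SemiGlobalHit, locate
from ._seq import revcomp
from .errors import AmbiguousReadError, InputError
from .locus import LocusSpec

#: identity below which a flank is considered absent rather than degraded
PRESENCE_FLOOR = 0.75

REJECT_MISSING_FLANK1 = "missing_flank1"
REJECT_MISSING_FLANK2 = "missing_flank2"
REJECT_BELOW_IDENTITY = "below_identity"
REJECT_INCONSISTENT_ORDER = "inconsistent_order"


@dataclass(frozen=True)
class AnchoredRead:
    """An accepted on-target read, normalized to locus orientation."""

    read_id: str
    oriented_sequence: str
    strand: str  # '+' if the input read was already in locus orientation
    flank1_identity: float
    flank2_identity: float
    flank1_span: tuple[int, int]
    flank2_span: tuple[int, int]

    @property
    def inter_flank_span(self) -> tuple[int, int]:
        """Interval between the anchors, containing the repeat tract."""
        return (self.flank1_span[1], self.flank2_span[0])

    @property
    def inter_flank_length(self) -> int:
        return self.inter_flank_span[1] - self.inter_flank_span[0]


@dataclass(frozen=True)
class RejectedRead:
    read_id: str
    reason: str


def _try_strand(seq: str, locus: LocusSpec) -> tuple[SemiGlobalHit, SemiGlobalHit]:
    return locate(locus.flank1, seq), locate(locus.canonical_flank2, seq)


def anchor_read(
    read_id: str, sequence: str, locus: LocusSpec
) -> AnchoredRead | RejectedRead:
    """Anchor both flanks on a read, on either strand.

    Each flank is aligned semi-globally (flank fully consumed, free read
    ends).  The read is accepted iff both flanks reach the locus's
    ``min_flank_identity`` in consistent order (flank1 before flank2, non-
    overlapping) on the same strand.  Rejections carry a reason code; a flank
    whose best identity falls below ``PRESENCE_FLOOR`` is reported missing,
    one between the floor and the threshold is reported ``below_identity``.
    """
    if not sequence:
        return RejectedRead(read_id, REJECT_MISSING_FLANK1)
    thr = locus.min_flank_identity
    best = None  # (total identity, strand, seq, f1, f2)
    saw_wrong_order = False
    best_f1 = 0.0
    best_f2 = 0.0
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else revcomp(sequence)
        f1, f2 = _try_strand(seq, locus)
        best_f1 = max(best_f1, f1.identity)
        best_f2 = max(best_f2, f2.identity)
        if f1.identity >= thr and f2.identity >= thr:
            if f1.end <= f2.start:
                total = f1.identity + f2.identity
                if best is None or total > best[0]:
                    best = (total, strand, seq, f1, f2)
            else:
                saw_wrong_order = True
    if best is not None:
        _, strand, seq, f1, f2 = best
        return AnchoredRead(
            read_id=read_id,
            oriented_sequence=seq,
            strand=strand,
            flank1_identity=f1.identity,
            flank2_identity=f2.identity,
            flank1_span=(f1.start, f1.end),
            flank2_span=(f2.start, f2.end),
        )
    if saw_wrong_order:
        return RejectedRead(read_id, REJECT_INCONSISTENT_ORDER)
    if best_f1 < PRESENCE_FLOOR:
        return RejectedRead(read_id, REJECT_MISSING_FLANK1)
    if best_f2 < PRESENCE_FLOOR:
        return RejectedRead(read_id, REJECT_MISSING_FLANK2)
    return RejectedRead(read_id, REJECT_BELOW_IDENTITY)


@dataclass
class OnTargetResult:
    """Per-locus accepted read sets plus the rejection tally."""

    accepted: dict[str, list[AnchoredRead]]
    rejected: list[RejectedRead]
    rejection_tally: Counter

    @property
    def n_input(self) -> int:
        return sum(len(v) for v in self.accepted.values()) + len(self.rejected)


def select_ontarget(
    reads: Iterable[tuple[str, str]], loci: Sequence[LocusSpec]
) -> OnTargetResult:
    """Partition reads into per-locus on-target sets and a rejected pool.

    Counts are conserved: every input read lands in exactly one accepted set
    or in the rejected pool.  A read anchoring to two loci raises
    :class:`AmbiguousReadError` (the loci's flanks are not distinguishable).
    """
    accepted: dict[str, list[AnchoredRead]] = {locus.name: [] for locus in loci}
    rejected: list[RejectedRead] = []
    tally: Counter = Counter()
    for read_id, sequence in reads:
        hits = []
        reasons = []
        for locus in loci:
            res = anchor_read(read_id, sequence, locus)
            if isinstance(res, AnchoredRead):
                hits.append((locus.name, res))
            else:
                reasons.append(res.reason)
        if len(hits) > 1:
            raise AmbiguousReadError(
                f"read {read_id} anchors to loci "
                + ", ".join(name for name, _ in hits)
            )
        if hits:
            accepted[hits[0][0]].append(hits[0][1])
        else:
            # most informative reason: order > below-identity > missing
            order = {
                REJECT_INCONSISTENT_ORDER: 0,
                REJECT_BELOW_IDENTITY: 1,
                REJECT_MISSING_FLANK2: 2,
                REJECT_MISSING_FLANK1: 3,
            }
            reason = min(reasons, key=order.__getitem__)
            rejected.append(RejectedRead(read_id, reason))
            tally[reason] += 1
    return OnTargetResult(accepted=accepted, rejected=rejected, rejection_tally=tally)


def estimate_max_repeat(
    anchored: Sequence[AnchoredRead], locus: LocusSpec, margin: int = 5
) -> int:
    """Upper bound on the sample's repeat length, from the longest inter-flank span.

    ceil(longest span / unit length) plus a safety margin; used to size the
    reference template pool in the preliminary analysis step.
    """
    if not anchored:
        raise InputError("cannot estimate maximum repeat from an empty read set")
    longest = max(read.inter_flank_length for read in anchored)
    return math.ceil(longest / len(locus.repeat_unit)) + margin
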