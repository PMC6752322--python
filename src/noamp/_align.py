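"""Thin wrappers around edlib for the two alignment modes the pipeline uses.

Identity is defined as matched bases over alignment columns: for an alignment
with edit distance *d* spanning *c* columns (matches + mismatches + gaps),
identity = 1 - d/c.  Column counts come from the edlib CIGAR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


@dataclass(frozen=True)
class SemiGlobalHit:
    """Best semi-global placement of a query inside a target sequence."""

    start: int  # 0-based, half-open span on the target
    end: int
    edits: int
    identity: float


def locate(query: str, target: str) -> SemiGlobalHit:
    """Semi-global (infix) alignment: query fully consumed, free target ends."""
    res = edlib.align(query, target, mode="HW", task="path")
    start, end_incl = res["locations"][0]
    cols = _columns(res["cigar"])
    d = res["editDistance"]
    return SemiGlobalHit(
        start=start, end=end_incl + 1, edits=d, identity=1.0 - d / cols
    )


def global_distance(query: str, target: str, k: int = -1) -> int:
    """Global (end-to-end) edit distance; -1 if it exceeds the band ``k``."""
    return edlib.align(query, target, mode="NW", task="distance", k=k)["editDistance"]


def global_identity(query: str, target: str) -> tuple[int, float]:
    """Global edit distance and identity (1 - edits/columns)."""
    res = edlib.align(query, target, mode="NW", task="path")
    d = res["editDistance"]
    return d, 1.0 - d / _columns(res["cigar"])
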