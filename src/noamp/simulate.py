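"""Synthetic CCS read sets with known truth.

The generator emulates the statistical structure the analysis assumes for an
amplification-free targeted repeat experiment: a biallelic sample whose
per-read repeat lengths are stable for short alleles and increasingly
dispersed for expanded ones (somatic mosaicism), marker haplotypes linked to
each allele, iid consensus-read substitution/indel errors, random read
orientation, coverage that decays with template length (longer molecules are
underrepresented at equal input mass), and off-target decoy reads.

Per-read repeat lengths are drawn from a discretized normal centred on the
allele's modal length, truncated at 1 — the data motivating this module show
that dispersion grows with repeat length but report no generative law, so a
two-parameter family is used and documented as a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp
from .errors import ConfigurationError, InputError
from .locus import LocusSpec, MarkerHaplotype

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AlleleModel:
    """Generative model of one allele's per-read repeat-length distribution."""

    center_len: int
    spread: float
    haplotype: Optional[MarkerHaplotype]
    weight: float = 0.5

    def __post_init__(self) -> None:
        if self.center_len < 1:
            raise ConfigurationError("center_len must be >= 1")
        if self.spread < 0:
            raise ConfigurationError("spread must be non-negative")
        if not 0 < self.weight <= 1:
            raise ConfigurationError("weight must be in (0, 1]")


def scaled_spread(center_len: int, a: float = 0.0, b: float = 0.05) -> float:
    """Mosaicism dispersion scaling linearly with modal length (a + b*L).

    Expanded alleles disperse more than short ones; the default slope keeps
    short alleles essentially stable (spread < 1.5 below the 50-repeat
    disease threshold minus intercept) while hundred-repeat alleles spread
    over tens of units.
    """
    return a + b * center_len


@dataclass
class SimConfig:
    """Full specification of one simulated sample (byte-reproducible by seed)."""

    locus: LocusSpec
    alleles: tuple[AlleleModel, AlleleModel]
    n_reads: int = 300
    error_sub_rate: float = 0.01
    error_ins_rate: float = 0.002
    error_del_rate: float = 0.002
    length_bias_exponent: float = 1.0
    offtarget_fraction: float = 0.1
    seed: int = 0
    read_id_prefix: str = "read"
    decoy_insert: Optional[str] = None  # e.g. a near-miss gRNA site to plant

    def __post_init__(self) -> None:
        for rate in (self.error_sub_rate, self.error_ins_rate, self.error_del_rate):
            if not 0 <= rate < 1:
                raise ConfigurationError("error rates must lie in [0, 1)")
        if not 0 <= self.offtarget_fraction < 1:
            raise ConfigurationError("offtarget_fraction must lie in [0, 1)")
        if self.length_bias_exponent < 0:
            raise ConfigurationError("length_bias_exponent must be non-negative")
        total = sum(a.weight for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("allele weights must sum to 1")


@dataclass
class SimRead:
    read_id: str
    sequence: str


@dataclass
class SimResult:
    reads: list[SimRead]
    truth: pd.DataFrame = field(repr=False)

    def to_fastq(self) -> str:
        """Reads as FASTQ text with constant-Q placeholder qualities."""
        chunks = []
        for r in self.reads:
            chunks.append(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
        return "".join(chunks)


def _draw_length(rng: np.random.Generator, allele: AlleleModel) -> int:
    if allele.spread == 0:
        return allele.center_len
    return max(1, int(round(rng.normal(allele.center_len, allele.spread))))


def _corrupt(
    rng: np.random.Generator, seq: str, p_sub: float, p_ins: float, p_del: float
) -> str:
    """Apply iid substitution/insertion/deletion errors per base."""
    if p_sub == p_ins == p_del == 0:
        return seq
    n = len(seq)
    keep = rng.random(n) >= p_del
    sub = rng.random(n) < p_sub
    ins = rng.random(n) < p_ins
    out: list[str] = []
    for i, base in enumerate(seq):
        if keep[i]:
            if sub[i]:
                choices = [b for b in "ACGT" if b != base]
                out.append(choices[rng.integers(3)])
            else:
                out.append(base)
        if ins[i]:
            out.append(_BASES[rng.integers(4)])
    return "".join(out)


def simulate_sample(config: SimConfig) -> SimResult:
    """Generate one sample's read set plus its truth table.

    On-target reads are built as flank1 + unit x L + flank2(haplotype), with L
    drawn from the allele's length distribution, then corrupted at the
    configured error rates and reverse-complemented with probability 0.5.
    Allele sampling probabilities are weight x template_length^(-bias),
    renormalized, so longer alleles are underrepresented when the bias
    exponent is positive.  Decoys are uniform-random sequence of comparable
    length.  The truth table records (read_id, allele index, true length,
    orientation, offtarget flag) per read.
    """
    if config.n_reads <= 0:
        raise InputError("n_reads must be positive")
    rng = np.random.default_rng(config.seed)
    locus = config.locus

    center_templates = [
        locus.template_sequence(a.center_len, a.haplotype) for a in config.alleles
    ]
    tpl_lens = np.array([len(t) for t in center_templates], dtype=float)
    weights = np.array([a.weight for a in config.alleles])
    probs = weights * tpl_lens ** (-config.length_bias_exponent)
    probs = probs / probs.sum()
    decoy_len = int(tpl_lens.mean())

    reads: list[SimRead] = []
    rows = []
    planted = False
    for i in range(config.n_reads):
        read_id = f"{config.read_id_prefix}{i:05d}"
        if rng.random() < config.offtarget_fraction:
            seq = "".join(_BASES[rng.integers(0, 4, size=decoy_len)])
            if config.decoy_insert and not planted:
                mid = decoy_len // 2
                seq = seq[:mid] + config.decoy_insert + seq[mid:]
                planted = True
            allele_ix, true_len, offtarget = -1, 0, True
        else:
            allele_ix = int(rng.choice(len(config.alleles), p=probs))
            allele = config.alleles[allele_ix]
            true_len = _draw_length(rng, allele)
            seq = locus.flank1 + locus.repeat_unit * true_len + locus.flank2(
                allele.haplotype
            )
            seq = _corrupt(
                rng,
                seq,
                config.error_sub_rate,
                config.error_ins_rate,
                config.error_del_rate,
            )
            offtarget = False
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        reads.append(SimRead(read_id=read_id, sequence=seq))
        rows.append(
            {
                "read_id": read_id,
                "allele": allele_ix,
                "true_len": true_len,
                "orientation": strand,
                "offtarget": offtarget,
            }
        )
    return SimResult(reads=reads, truth=pd.DataFrame(rows))


def write_fastq(result: SimResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(result.to_fastq())


def write_truth(result: SimResult, path) -> None:
    result.truth.to_csv(path, sep="\t", index=False)
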