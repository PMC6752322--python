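"""Built-in locus definitions and guide sequences.

The CTG18.1 and FMR1 repeat regions are defined here with *synthetic* flank
sequences: fixed random-like literals that preserve the real loci's structure
(flank lengths on the order of the captured fragment ends, a polymorphic CTC
tract immediately 3' of the CTG repeat carrying one CTT interruption, an A/T
SNP downstream, and a marker-free CGG control locus) without reproducing
genomic sequence.  Analyses of real data should load locus definitions from a
config file with the true flanks instead (see :func:`noamp.io.read_locus_config`).

The crRNA spacer sequences used for Cas9 enrichment of the two loci are
public assay reagents and are included verbatim for the off-target scan.
"""

from __future__ import annotations

from .locus import Flank2Layout, LocusSpec

TCF4_CRRNA = "CAAGAGGCUAUUUACAGCUA"
FMR1_CRRNA = "AGAGGCCGAACUGGGAUAAC"

# Synthetic flank literals (fixed; no run of >=3 repeat-unit copies).
_CTG18_FLANK1 = (
    "AAGCTCAAATCAGAATGCTTATCGCTCAGCTGGCACACACTTGCATCTTTGAGTCCAGGG"
    "GACGGCAAATCTTAAGTTCGCTCACATCCGCGCGGCTGCCTTTGCTGGTCAGTATGGGAA"
)
_CTG18_SPACER_TO_SNP = (
    "TCATCCTATCGAGCAAAGCACCTCTGATAATAACCTAACCGCAAGCCCAGTTATACCGGA"
)
_CTG18_REST = (
    "CTTGGGGTCACTGAGTATGTTGTCCGCTCAGCGCATCCACGGCCAGGCAAAGCTCCGGTT"
    "CACTACGTCACAACGTGGGA"
)
_FMR1_FLANK1 = (
    "AATAGCCATCCTATCTGACGTTTTCGCTGCCCGTCACACCGCAAGGCAAGCGAGCCAGTA"
    "CAAGAGCCTAAGTTCCGTAGACTCCGAATAGTCTAACACT"
)
_FMR1_FLANK2 = (
    "GTGAGGTCAGTGGTAGTATTGCCCGACAGATAATGTTAACCTTTGGGTCTCAAAGGTTGA"
    "GGAGATGATCCCAACGGTTGCGTTCTGTGTATTCATACGGACGCACTAGTAGGAACCATA"
    "CCCTTGGCGCCTCCCTACACTATTTTTCCA"
)


def ctg18_locus() -> LocusSpec:
    """CTG18.1-style target locus: CTG repeat, CTC tract, A/T SNP; >=50 expanded."""
    return LocusSpec(
        name="TCF4",
        repeat_unit="CTG",
        flank1=_CTG18_FLANK1,
        flank2_layout=Flank2Layout(
            spacer="",  # the CTC tract sits immediately 3' of the CTG repeat
            spacer_to_snp=_CTG18_SPACER_TO_SNP,
            snp_alleles=("A", "T"),
            rest=_CTG18_REST,
            default_tract_len=12,  # reference-genome CTC copy number
            default_ctt_index=6,
        ),
        expansion_threshold=50,
    )


def fmr1_locus() -> LocusSpec:
    """FMR1-style control locus: CGG repeat, no phasing markers; >55 expanded."""
    return LocusSpec(
        name="FMR1",
        repeat_unit="CGG",
        flank1=_FMR1_FLANK1,
        flank2_const=_FMR1_FLANK2,
        expansion_threshold=56,  # unused for controls; control_threshold governs
        control_threshold=55,
    )
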