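# Methods

This note records the models, parameter choices and numerical conventions
behind `noamp`, and what the synthetic-data tests do and do not demonstrate.

## Locus model

A locus is `flank1 + (unit)^L + flank2`. For marker-bearing loci, `flank2`
is layered: an optional spacer, a secondary trinucleotide tract (CTC with a
single CTT interruption at the CTG18.1-style locus), a constant segment, a
biallelic SNP, and the remaining flank. Template pools enumerate repeat
lengths from 1 (length 0 would collapse the two flanks into one anchor and
is rejected) up to a per-sample maximum, crossed with the *observed* marker
haplotypes only — enumerating every possible CTC length × SNP combination
would multiply pool size for no benefit, since haplotype discovery precedes
pool construction. The CTT interruption's position within the tract is part
of the haplotype; observed data constrain its presence but not its position,
so an unknown position defaults to a configurable index (default 6).

The bundled *TCF4*-like and *FMR1*-like locus definitions use **synthetic
flank literals**: fixed random-like sequences with the real loci's structure
(CTC tract immediately 3′ of the repeat, A/T SNP ~60 bp further downstream,
flanks of 100–180 bp) but not genomic sequence. Real analyses should load
true flanks from a YAML locus config. Flank lengths here compress the real
geometry (the true SNP sits ~1.3 kb downstream); this changes nothing
structurally but means absolute read lengths are smaller than real captured
fragments.

## Alignment and similarity

All alignment is unit-cost edit distance (edlib). Flank anchoring is
semi-global (flank fully consumed, free read ends) on both strands; a read
is on-target iff both flanks reach ≥90% identity in consistent order on the
same strand. **Identity is matched bases over alignment columns**
(1 − edits/columns); the denominator is a convention the source data's
"≥90% similarity" phrasing does not pin down, chosen because it penalizes
indels and substitutions symmetrically. A flank below 75% best identity is
reported *missing* rather than *degraded* — the boundary only affects
rejection bookkeeping, never acceptance.

Template matching aligns the anchored insert (between and including both
flank anchors, so chimeric tails cannot dilute similarity) globally to each
candidate template and keeps the template with the fewest edits; ties break
to the smaller repeat length, then canonical pool order (ascending length,
haplotype input order). Similarity of the winner is 1 − edits/columns, and
calls below the 99% threshold are rejected. Ranking by edit count rather
than by normalized similarity makes the matcher exactly equivalent to a
brute-force minimum-edit-distance search (verified against an independent
aligner in tests) and allows a banded distance-only pass with the full
(path) alignment computed only for the winner. Candidates are pre-narrowed
to repeat lengths within ±15 units of ⌈inter-flank span / 3⌉; ±15 is ~5× the
largest span wobble the marker-length variation can induce, and tests that
require exhaustive behaviour disable narrowing.

The strict 99.9% filter is a pure post-hoc filter over existing calls
(monotone by construction). A single unmodelled interruption in a ~350 bp
insert costs ~0.3% similarity, so the strict filter removes *all*
interruption-bearing reads when the pool lacks the interrupted template —
the documented trade-off between phasing confidence and sensitivity to
unmodelled variation. At a fixed per-base error rate the *expected*
similarity is length-free (≈1 − error rate for any read length), but longer
reads carry more absolute edits and their identity concentrates below a
fixed threshold, so expanded-allele reads pass any given filter less often —
this, not a lower mean similarity, is how stringency interacts with allele
length.

## Marker calling and phasing

The tract-to-SNP constant segment is located by semi-global alignment
downstream of flank 1; the SNP is the base immediately after it
(undetermined if not one of the configured alleles). The tract length is the
number of consecutive tract triplets counted backwards, in frame, from that
segment's start; a net frame shift (region length inconsistent with the
spacer modulo 3) marks the tract undetermined rather than guessed. A
substitution inside the tract can truncate the backward scan — such reads
scatter across shorter lengths and are absorbed by the fraction-based
heterozygosity rule.

A marker is heterozygous when its two most frequent determined values each
carry ≥20% of determined reads; the floor (data pin down the rule but not a
noise tolerance) resists sporadic miscalls. Phase method is the conjunction
when both markers are informative, else the informative one, else none.
Reads join the allele whose key matches their signature; the matched
template's haplotype takes precedence over the raw per-read marker call
(selected on full-sequence evidence; disagreements are logged), and reads
matching neither key are left unassigned.

## Unphased genotyping and summaries

Unphaseable samples get a biallelic genotype from the repeat-length
histogram: moving-average smoothing (window 3), local maxima separated by ≥5
units, each peak refined to the raw-count argmax in its smoothing
neighborhood and required to carry ≥5% of reads within ±5 units; the top two
peaks (by carried weight, ties to the smaller length) are reported, so peaks
closer than the separation merge. Parameters are configuration with these
defaults; the procedure is named by the source method but unparameterized
there.

Per-allele summaries report mode (ties to the smallest length, for
deterministic output), arithmetic mean rounded half-up to an integer
(matching the precision of published tables), min, max, and size range
(max − min), the mosaicism measure. Sample categories: A (both modes <50),
B (exactly one ≥50, inclusive), C (both ≥50). Control-locus expansion is
*strictly* greater than its threshold (>55 for the CGG control).

Interruption detection decomposes the repeat tract (starting at the flank-1
anchor end) into triplets for reads at the allele's **modal** length only —
mosaic alleles make positional consensus ill-defined — and reports positions
whose consensus motif differs from the repeat unit with ≥80% support, given
≥5 usable reads. Detection inside large unstable expansions is therefore
out of reach by design, a limitation the modal-subset restriction makes
explicit.

## Simulator

Per-read repeat lengths are a discretized normal centred on the allele's
modal length, truncated at 1; the data motivating the package show
dispersion growing with length but no generative law, so a two-parameter
family is the deliberate minimal choice, with `scaled_spread(L) = a + b·L`
(defaults a=0, b=0.05) available to reproduce the instability–length
relationship. Errors are iid per base (defaults: substitution 1%, insertion
and deletion 0.2% each — consensus-read-like, identity ≈98.6%); qualities
are constant placeholders because the pipeline's filters are identity-based.
Orientation is a fair coin. Allele sampling weight is multiplied by
(template length)^(−β), β = 1 by default: at equal input mass the molar
count of molecules is inversely proportional to length, which reproduces
the lower observed depth on expanded alleles. Decoys are uniform-random
sequence of comparable length, with a hook to plant a near-miss gRNA site.
Identical config + seed reproduces byte-identical FASTQ.

What passing simulation tests shows: the pipeline recovers exactly what the
generative model planted, at realistic error rates, including the
qualitative depth, dispersion and filtering behaviours. What it does not
show: robustness to structured CCS error (pass-number-dependent quality,
homopolymer bias), chimeras, adapter remnants, or mapping artifacts of real
genomes — none of which the generator emulates.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open; reads are normalized to locus orientation
before any downstream step. Reads whose inter-flank span is not a multiple
of 3 are still accepted (indels are expected; length resolution belongs to
template matching). Empty read sets, empty alleles and empty cohorts raise
input errors rather than returning empty statistics. Mode ties break to the
smallest length everywhere. Cohort means are rounded half-up. Alleles whose
statistics are unidentifiable are carried as explicit `None`s and skipped by
cohort aggregation where their fields are needed.

## Problem sizes used in tests

The test suite runs simulations of 80–300 reads with alleles up to ~150
units, 20-seed replication for the recovery checks, and exhaustive
brute-force cross-checks on pools of ≤50 templates and ≤500 bp reads —
sizes chosen to keep the full suite fast on a single CPU while preserving
every regime the claims concern (stable vs dispersed alleles, both phasing
markers, filter boundaries). The cohort-level numbers are computed from the
bundled 11-sample table, which is full scale.
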