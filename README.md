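# noamp — amplification-free long-read repeat genotyping

`noamp` is an analysis library for genotyping expanded tandem repeats from
amplification-free, Cas9-enriched single-molecule (CCS) long reads. It was
built around the Fuchs endothelial corneal dystrophy (FECD)–associated
intronic CTG repeat in *TCF4* (CTG18.1, disease-associated at ≥50 copies),
with the *FMR1* CGG repeat as a multiplexed control locus (expanded at >55
copies), but every locus property — flanks, repeat unit, marker layout,
thresholds — is configuration.

PCR-based assays size expanded repeats poorly: amplification skews toward
short alleles and cannot expose somatic mosaicism. With amplification-free
long reads, each molecule is read individually, so a sample's two alleles can
be separated and the *distribution* of repeat lengths per allele — not just a
single size — becomes observable.

## Method

For each sample the pipeline:

1. **Selects on-target reads** by semi-global alignment of both repeat-flanking
   sequences, requiring ≥90% identity per flank (the repeat itself is never
   part of the identity requirement), on either strand; reads are normalized
   to locus orientation.
2. **Estimates the maximum repeat length** from the longest inter-flank span
   (⌈span/3⌉ plus a safety margin).
3. **Builds a reference template pool**: every sequence
   `flank1 + (unit)^L + flank2(h)` for L = 1..max and each observed marker
   haplotype *h* — a combination of the polymorphic CTC tract
   (8–15 triplets, carrying one CTT interruption) immediately 3′ of the
   repeat, and a downstream A/T SNP (rs599550).
4. **Calls each read** against the pool by global alignment of the anchored
   insert; the template with the fewest edits wins, and the call stands only
   if similarity = 1 − edits/columns is ≥99% (a stricter 99.9% filter is
   available as a pure post-hoc filter).
5. **Phases reads into alleles** whenever the sample is heterozygous at the
   SNP or at the CTC tract length (each of the two most frequent marker
   values must carry ≥20% of determined reads); unphaseable samples get a
   biallelic genotype from local maxima of the smoothed repeat-length
   histogram.
6. **Summarizes each allele** — mode (ties to the smallest), mean, min, max,
   and size range (max − min, the per-allele mosaicism measure) — screens the
   repeat tract for consensus interruptions (e.g. a GTG triplet inside a CTG
   run), classifies the sample (A: both alleles <50; B: one ≥50; C: both
   ≥50), and calls control-locus expansions.

A matched simulator (`noamp.simulate`) generates CCS-like read sets with
known truth — per-allele length dispersion that grows with repeat length,
linked marker haplotypes, substitution/indel errors, random orientation,
coverage decaying with molecule length, and off-target decoys — and is the
basis of most of the test suite. A gRNA mismatch scan
(`noamp.grna_mismatch_scan`) scores guide sequences against putative
off-target windows.

## Worked example

```bash
python examples/01_simulate_and_genotype.py
```

```
on-target reads:   {'TCF4': 273, 'FMR1': 0}
rejected reads:    {'missing_flank1': 27}  (decoys lack both flanks)
calls >=99% match: 72 (of 273 anchored)
phase method:      CTC_and_SNP  keys ((13, 'A'), (14, 'T'))
category:          B  (>=50 repeats marks an expansion)
  allele (CTC 13): mode 23, mean 23, range 0, max 23, n=47
  allele (CTC 14): mode 91, mean 92, range 22, max 99, n=25
```

A simulated sample with alleles of 23 (stable) and 91 (dispersed) repeats is
genotyped end to end: decoy reads are rejected at flank anchoring, both
markers phase the reads (CTC 13 + SNP A versus CTC 14 + SNP T), the stable
allele is recovered exactly with zero size range, and the expanded allele
shows the mosaicism (range 22) the simulation planted. Fewer reads survive
the ≥99% filter on the long allele — longer molecules expose more bases to
error — mirroring the depth imbalance seen in real data.

Other examples: `02_cohort_summary.py` (cohort-level statistics from the
bundled 11-sample table), `03_stringency_tradeoff.py` (the 99.9% filter
discards all reads bearing an unmodelled repeat interruption),
`04_grna_offtarget_scan.py` (a planted 4-mismatch off-target site).

A thin CLI mirrors the library: `noamp simulate`, `noamp run`,
`noamp summarize-cohort`, `noamp grna-scan`.

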