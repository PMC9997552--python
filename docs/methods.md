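# Methods

## RT-stop model and profile construction

A CMC adduct on pseudouridine blocks reverse transcriptase, so the cDNA
5′ end of an affected molecule lands on the base immediately 3′ of the
Ψ in transcript orientation: the Ψ is the *upstream* base of the
recorded termination site. In the paired-end library layout consumed
here, read R2 starts at the cDNA 5′ end, so a termination profile
counts, per (contig, strand, position), the inserts whose R2 5′ end
falls at the position (`n_term`) and the inserts whose outer span
covers it (`coverage`). Only concordant proper pairs contribute;
secondary, supplementary, duplicate and QC-fail alignments are skipped,
and multi-mapping policy is left to the upstream aligner. Coverage uses
the insert's outer span rather than only aligned bases; since a
truncated cDNA *is* the observed insert, the two coincide for the reads
that matter, and the choice is visible only across unaligned gaps.
Coordinates are 0-based half-open in memory; every file format uses its
own native convention (1-based TSV/GTF, 0-based BED).

## Site calling

Per library pair, every position with positive coverage in both the CMC
and the mock profile is tabulated (zero mock coverage leaves the mock
proportion undefined, so such positions are untestable and dropped).
A site is *relevant* when ≥5 CMC inserts terminate at it and ≥5 read
through; only the CMC side is constrained. Relevant sites get the
pooled one-sided two-proportion z-test

    z = (TR_CMC − TR_Mock) / sqrt(p(1−p)(1/Cvg_CMC + 1/Cvg_Mock))

with p the pooled proportion; when p ∈ {0, 1} the variance degenerates
and the site is reported untestable with p-value 1. P-values are BH-
adjusted within the family of relevant sites of that one pair: per-pair
families keep replicates independent for the downstream reproducibility
rule, and the alternative (a global family across libraries) would tie
each library's calls to the noise of the others. Calls further require
the transcript-orientation upstream base to be uridine in the reference
and the Ψ position to overlap an annotated gene on the matching strand;
spike-in contigs carry no annotation and are exempt from the gene rule.

Aggregation demands support from ≥2 libraries spanning ≥2 experiment
labels — with exactly two experiments this means at least one library
from each; three supporting libraries from a single experiment do not
qualify. Support of 6–7 / 4–5 / 2–3 of the seven control replicates
maps to high / intermediate / low reproducibility (thresholds
configurable, recorded in output headers). A mutant-dependent site is
a control site that passes the *full* per-library call in none of the
mutant libraries; mere coverage does not count as detection, so the
output annotates per-mutant-library coverage at each site to let users
distinguish absent signal from absent data. Termination-fold-change
thresholding (TR > 0.1, TFC > 3) is deliberately not a calling mode:
it is retained only inside the diagnostic columns, because threshold
calling has poor cross-replicate reproducibility.

## Spike-in QC

The 150-nt spike-in with a single Ψ at position 43 is profiled per
pair as TFC along the contig. Because deep mock coverage can still
yield zero mock terminations at a position, the raw TFC may be +inf;
peak detection therefore ranks positions by a Haldane–Anscombe
corrected fold change, log2(((n_C+0.5)/(Cvg_C+1))/((n_M+0.5)/(Cvg_M+1))),
which is finite everywhere and agrees with the raw TFC where counts are
healthy. The cross-pair summary is the per-position median of the raw
TFC over the control pairs. Under default settings the peak sits at
position 44 (upstream base = Ψ43) with corrected fold change ≈ 7–9.

## Codon statistics

One representative (longest, ties broken lexicographically) coding
transcript per gene defines frames and abundances; genes qualify when
their mean CMC insert coverage over the CDS is ≥10 (mean was chosen as
the summary statistic for stability; median/minimum are one-line
variants). For each of the 48 (codon, uridine-position) combinations,
q = (A_c/N)/u_c with N the summed abundance of the 37 distinct
uridine-containing codons — each codon counted once no matter how many
Ψ-position rows it spawns, and AUG included (it carries a uridine).
E = T·q; the expected counts sum to T exactly before rounding.
Observed counts are tested against Binomial(T, q): strict upper tail
P(X > obs) when obs > E, inclusive lower tail P(X ≤ obs) otherwise,
then Bonferroni ×48 per genome class. The strict/inclusive asymmetry
is the convention that reproduces the published census values; note the
census's own description of the enrichment tail is ambiguous between
"more than" and "at least", and only the strict reading is consistent
with its numbers. Recomputing the published fly-head census from its
printed abundance columns reproduces all 96 integer expected counts and
90/96 adjusted p-values at their printed 3-significant-figure
precision; the remaining six agree within 0.35% relative, a residual of
the printed table's own input rounding (no tail/normalizer convention
removes it — the implied corrections are mutually inconsistent across
rows). Mitochondrial codons translate UGA as tryptophan; everything
else uses the standard code. The ΨGA contingency test is a one-sided
Fisher exact test (hypergeometric upper tail) on
(ΨGA, unmodified UGA) × (mitochondrial, nuclear).

Region classification projects a site through each isoform: exonic and
5′ of the CDS → 5UTR, inside the CDS → coding, 3′ of it → 3UTR, inside
the gene span but not exonic → intron. A site may carry different
labels on different isoforms; tallies count each label once per site,
so percentages may sum past 100.

Gene summaries report Ψ count, uridine count and percent-modified on
the representative transcript, plus RPKM = assigned·1e9/(length·total)
averaged over CMC libraries. Insert assignment is estimated as exonic
coverage mass divided by the library's mean insert length, which is
exact in the generator's one-gene-per-contig layout and an approximation
for overlapping genes. Motif extraction takes 21-nt transcript-
orientation windows centred on each Ψ (genomic strand-aware windows as
fallback), pads past-end positions with N, and normalises each position
frequency matrix column over A/C/G/U excluding N; the centre column is
uridine by construction.

## Synthetic data generator

The generator is the package's test bed for the caller, emulating the
experimental design: per pair, a CMC and a mock library over a shared
transcript set, by default 3 control pairs in one experiment batch plus
4 control and 4 mutant pairs in a second, with the 150-nt spike-in
(single Ψ at position 43) in every library. Reverse transcription
walks each fragment 3′→5′; before copying each base it halts with
background probability b (default 0.002/nt), and additionally with
ρ·π at a Ψ (adduct occupancy ρ = 0.9, stop-given-adduct π = 0.85,
CMC condition only, site writable for the genotype). A molecule
reaching the fragment 5′ boundary is full-length: coverage but no
termination. The defaults put the spike-in corrected fold change in
the 7–9 range, consistent with a treatment regime whose spike-in
readout exceeds 5–6; true occupancies are not measurable from this
assay and the defaults are stated conditions, not estimates.

Transcripts (default 30, 300–600 nt, GC 0.42) each occupy a plus-strand
contig with a central CDS; 3 Ψ per transcript are planted at uridines
≥50 nt from the ends and ≥100 nt apart, so the stated mean-coverage
condition (~50–90× at planted sites under 400 inserts/transcript,
fragment length 80±20) actually holds at every site — real clustered
sites violate this via fragment-edge coverage loss and truncation
shadowing of 5′-ward neighbours, which the recovery metrics therefore
do not probe. A configurable fraction of sites (default 0.3) is
unwritable in the mutant genotype, grounding the differential-site
sensitivity checks. All randomness flows from one master seed through
per-library spawned streams; paired libraries draw fragments
independently, mirroring a protocol that splits the sample before
treatment and fragments afterwards.

What passing tests show: under these conditions the caller recovers
≥90% of planted sites per pair at ≥95% precision, null runs (ρ·π = 0)
call ≤5% of tested positions, and unwritable sites are recovered by the
differential comparison at ≥90% sensitivity. What they do not show:
robustness to structured background noise (the generator's background
is position-independent Bernoulli), to clustered or end-proximal sites,
to alignment artifacts, or to real library-size imbalance.

## Numerical choices and limitations

- TFC is log2(TR_CMC/TR_Mock): +inf when TR_Mock = 0 with signal, NaN
  (undefined) when TR_CMC = 0; tables carry the raw value, peak logic
  the corrected one.
- BH adjustment is delegated to statsmodels (`fdr_bh`); the test suite
  pins it against a brute-force step-up oracle.
- The z-test matches an independent pooled-proportion implementation to
  1e-9 over randomized draws, and is monotone in the CMC termination
  count at fixed coverages.
- Rounding of expected counts uses floor(E+0.5) (round-half-up), the
  convention matching the published census.
- Ψ stoichiometry (fraction of molecules modified at a site) is out of
  scope: an RT-stop assay without calibration cannot estimate it.
- The acceptance script scales the synthetic study to 30 transcripts ×
  11 pairs and 5 null runs; the statistics it reports stabilise well
  below that size and complete in seconds.
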