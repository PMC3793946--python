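# Methods

## The pseudoproband screen

The screen asks whether one individual (the proband) carries aberrant
methylation at unusually many CpGs. Every sample in the β matrix is assigned
in turn as a *pseudoproband*; its β value at each retained probe is compared
to the arithmetic mean of all other samples at that probe (the pseudoproband
is always excluded from its own reference mean). A probe is called aberrant
when |Δβ| meets the threshold, two-sidedly: hypomethylation (Δβ < 0) and
hypermethylation (Δβ > 0) are both real outcomes of a maintenance defect, so
a one-sided rule would miss half the signal.

Pre-filters, in order: probes on chromosomes X and Y (methylation there is
confounded by X-inactivation and sex), probes at known imprinted genes (the
screen targets loci of *unknown* imprinting status; imprinted loci are
expected to be half-methylated and are analysed separately), and probes with
any missing β across samples. Missing handling is listwise rather than
pairwise so that every pseudoproband's reference mean is computed over the
same probe set; pairwise deletion would make counts incomparable between
samples. Probes lacking an annotation row are retained with a warning, so a
partial annotation degrades the filters, not the screen. Technical
replicates are averaged per probe before screening.

Summary statistics over the per-sample aberrant counts:

* **SD distance**: (proband count − control mean) / control SD, with the
  sample (n−1) SD. A zero control SD (possible on clean synthetic data where
  every control scores 0) makes the distance undefined; the screen warns and
  reports NaN rather than failing, because the empirical p-value below does
  not depend on the SD.
* **Empirical p-value**: with r = #{permutation individuals whose count ≥
  proband count} out of n, p_emp = (r + 1)/(n + 1). Ties count toward r.
  The permutation set is an explicit argument — it need not equal the set of
  samples used for the control mean/SD — and p_emp is bounded below by
  1/(n + 1), its value at r = 0.
* **Clopper–Pearson upper bound**: the exact two-sided upper confidence
  limit for the proportion r/n, computed as the 1 − α/2 quantile of
  Beta(r + 1, n − r) (scipy's beta quantile); for r = 0 this equals
  1 − (α/2)^(1/n), and for r = n it is 1.

Defaults: Δβ threshold 0.3 (β units; large enough to clear typical
array-level technical noise of a few hundredths of β), confidence 0.95.
An optional control pre-screen flags controls that themselves show more than
one aberrant CpG at an imprinted locus (run without the imprinted exclusion);
it is off by default because it requires imprinted annotations.

## The bisulfite amplicon analyzer

Reads carry a sample barcode (MID) at their 5' end. Demultiplexing is exact
prefix matching in either orientation of the read; MIDs are designed to be
edit-distance robust, so fuzzy matching buys little and risks collisions.
A barcode table in which one MID is a prefix of another is rejected outright.

**Alignment.** After bisulfite conversion an unmethylated C reads as T, so a
read cannot be aligned against the raw reference with a symmetric scorer.
Both read and reference are collapsed to three-letter space (C → T) and
aligned semi-globally (Biopython `PairwiseAligner`; match +1, mismatch −1,
gap open −2, gap extend −1, end gaps free). In collapsed space a reference C
matches a read T or C at no cost, exactly the required asymmetry; the
collapse also tolerates a read C over a reference T, which only ever
involves error bases and is harmless in practice. Both the given orientation
and the reverse complement are aligned and the higher score wins; an exact
tie is ambiguous and the read is discarded (logged). Reads shorter than
40 nt are skipped; alignments with identity below 0.70 — assessed over
aligned columns at non-C reference positions, where conversion cannot mask a
mismatch — are flagged unalignable.

**Per-read calling.** At each CpG cytosine the aligned read base maps to
methylated (C), unmethylated (T) or missing (gap or other base). The
conversion rate is computed over *non-CpG* reference cytosines covered by
the read: the fraction read as T. The SNP position is excluded from this
denominator even when the reference base there is C, because a polymorphic
site is not a reliable conversion readout. Reads covering no non-CpG C have
an undefined conversion rate and are dropped as unassessable. The
default filter keeps reads with conversion rate strictly above 0.98; the
150-read floor per sample is a QC flag, not a hard failure, so a
poorly-amplifying sample still yields its (flagged) summary. When no read at
all survives, the sample's result carries an empty pattern (no matrix)
rather than raising.

**Allele separation.** Each allele of the declared SNP has a set of bases it
can show after bisulfite chemistry: a C allele is observable as T
(converted) or C (failure/methylation); any other base only as itself. A
read is assigned to an allele only when its observed SNP base is compatible
with exactly one allele. Consequences: for a C/T SNP an observed T is
ambiguous and stays unassigned (with a warning at spec load time — such
amplicons cannot be fully separated on the analyzed strand); for a C/G SNP
that destroys a CpG, an observed T is *uniquely* the converted C allele, so
separation works even at the disrupting variant. Per-allele read counts may
therefore sum to less than the total.

A SNP that destroys a CpG on one allele also voids that CpG's state on reads
of that allele: the dinucleotide does not exist on those molecules, so the
state is recorded missing and the CpG's mean is computed from the intact
allele's reads only.

**Summaries.** The pattern matrix (reads × CpGs; 1/0/NA) yields per-CpG
means, per-read means and an overall mean defined as methylated cells over
non-missing cells. Cell-averaging is the default because it weights every
observed CpG equally; the alternative — the mean of per-read means, which
differs when missingness is uneven — is exposed as `per_read_average`.
The allelic-imbalance-corrected level is the unweighted average of the two
per-allele overall means: PCR can amplify one allele better than the other,
and the unweighted average removes that read-depth bias (at a perfectly
imprinted locus it restores ~50 % from, say, an 80:20 read split).

## The synthetic-data generators

**Array generator.** Per-probe baselines are drawn uniformly (default range
0.1–0.9), each sample's value is baseline + independent Gaussian noise
clipped to [0, 1], and the proband additionally carries planted signed Δβ
offsets at chosen probes. Defaults mirror the screen's design conditions:
18 controls, 1,000 probes, 87 planted epimutations of |Δβ| = 0.35, noise
SD 0.01. The planted magnitude 0.35 sits one noise-margin above the 0.3
threshold — a planted probe is an unambiguous truth but not a trivial one —
and the sign of each planted delta points away from the nearer boundary so
clipping never erodes the signal. Gaussian probe noise is a transparency
choice; real array noise is heteroskedastic (larger near β = 0.5) and
correlated between probes, so passing tests show threshold/counting
correctness, not robustness to array artefacts. Replicate copies of the
proband share the expected value and draw independent noise.

**Read generator.** Per read: the allele is fixed by the configured counts;
the allele base is substituted at the SNP (which may destroy a CpG — that
CpG's truth becomes NA for the allele); each intact CpG is methylated with
the allele's per-CpG probability; unmethylated and non-CpG cytosines convert
to T, non-CpG cytosines surviving with the conversion-failure rate (0.5 %
default); substitution errors hit each base independently (0.5 % default);
half of the reads are emitted reverse-complemented; the sample's MID is
prepended error-free. Simplifications, deliberate and documented: no indel
errors, no chimeras, no quality-string realism, conversion failure only at
non-CpG cytosines, and exact barcodes — the generator probes the analyzer's
logic, not a sequencer's error profile. `random_amplicon_spec` builds
references from junction-safe tokens so the CpG count is exact by
construction and the SNP lands on a bisulfite-invariant base away from any
CpG (the disrupting-SNP case is constructed explicitly in tests).

Both generators are deterministic given their seed, and every accuracy
metric in the test suite is computable from generator outputs plus truth
tables alone.

## Numerical and interface choices

* Coordinates are 0-based offsets on the analyzed strand internally; CpG
  columns are reported 1-based ("CpG_1..n") to match how such patterns are
  figured. Only the declared strand is analysed; no automatic
  opposite-strand run.
* Thresholds (Δβ 0.3, conversion 0.98, 150 reads, confidence 0.95) are
  defaults, overridable everywhere, and recorded post-resolution in each
  run's `manifest.json`.
* Multi-SNP haplotype phasing is out of scope; two informative SNPs are two
  independent single-SNP runs.
* Test and demonstration problem sizes (1,000 probes × 20 samples × 20
  seeds for the screen; 1,000 reads × ~350 bp for the amplicon tier) run in
  seconds on one core and give binomial standard errors small enough to
  verify recovery within 3 SE per CpG.

## Known limitations

* The screen consumes exported β tables; raw-array (IDAT) processing and
  normalisation must happen upstream.
* Demultiplexing is exact-match; a 1-mismatch mode exists but is off by
  default.
* FASTQ qualities are parsed and ignored.
* The empirical p-value's resolution is 1/(n + 1); with ~19 permutation
  individuals the smallest attainable p is ~0.05 regardless of effect size.
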