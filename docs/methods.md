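# Methods

## Statistical model

Every base pair of every cohort sample inside the candidate-region catalogue
is treated as an independent Bernoulli trial for somatic mutation. The
per-sample rate r_s = c_s / B (c_s = sample s's SNV count inside the merged
catalogue, B = total catalogue bp) absorbs each sample's global mutation
burden; every cohort sample enters the table, with r_s = 0 for unmutated
samples. A region of length L is then tested against
X ~ Binomial(L·N, μ), where N is the cohort size and μ the expected per-bp
per-sample rate, with the exact upper tail P(X ≥ k) for its pooled count k
(P = 1 when k = 0). The premise is that the catalogue itself controls for
chromatin context: all regions in it are comparable targets, so a
catalogue-wide per-bp rate is a meaningful null.

Two background calibrations:

* **allsamples** — μ is the arithmetic mean of r_s over the cohort; one μ
  for every region. Appropriate when no sample subset is unusually mutated.
* **regionsamples** — μ is the mean of r_s over only the samples mutated in
  the region under test. A region dominated by hypermutated samples is then
  judged against those samples' own (high) rates rather than a diluted
  cohort average, which removes their excess nominal calls (measured in the
  verification experiments: roughly 35 vs 22 null regions per 5000 reaching
  nominal p ≤ 0.05 when 5 of 55 samples carry 20× the cohort rate).

### Binomial trial count

The trial count is L·N with N = full cohort size in **both** modes; only μ
changes between modes. The alternative of shrinking N to the number of
mutated samples in regionsamples mode was considered and rejected: it makes
the null expectation for a region mutated in m samples L·m·μ, far below the
cohort-wide expectation (a region is surveyed in all N samples whether or
not they are mutated), which is strongly anti-conservative exactly when the
mode is meant to be protective, and it would make the two modes disagree
even on a perfectly homogeneous cohort. The convention is recorded in
`run_metadata.txt` and remains selectable (`trials_convention="mutated"`).

### Multiple testing

Benjamini–Hochberg step-up q-values, implemented directly as
q_(i) = min_{j≥i} p_(j)·m/j (the canonical formula; an independent
statsmodels route cross-checks it in the tests to 1 ulp). The FDR family is
**every region of the merged catalogue**: a region with zero mutations has
exact p-value 1 and enters BH at that value. Restricting the family to
mutated regions would condition each member on k ≥ 1; in a sparse cohort
(expected counts per region ≪ 1) those conditional p-values are all ≈ the
regions' expected counts, i.e. uniformly small, and BH over them alone calls
essentially every mutated region significant under a pure-noise cohort.
With the whole-catalogue family the same cohorts yield ~0 significant calls
per run, as they should. Untested regions are reported with p = q = 1 and a
`tested = False` flag.

### Mutation-rate threshold

Significance additionally requires the region's per-bp rate (k/L) to reach a
cohort-specific cutoff found from the ranked rates of all mutated regions —
the hockey-stick rule familiar from super-enhancer calling. Both the rank
axis and the rate axis are min–max rescaled to [0, 1]; the threshold is the
rate at the first ranked point whose arriving-segment slope (backward finite
difference; the first point uses its forward segment) reaches 1. The
arriving-segment convention is deliberate: a symmetric difference window
spans the elbow and flags the *last point of the flat bulk*, placing the
cutoff at the top of the noise rather than the bottom of the signal tail.
Degenerate cases are fixed by definition: a constant rate vector returns
that constant (every region passes), a perfectly linear ramp returns the
first rank (slope is 1 everywhere, so no region is excluded). The threshold
is always one of the observed rates. The rule is a single swappable
function (`inflection_threshold`) should a different elbow criterion be
preferred.

## Input handling

* Coordinates are 0-based half-open (BED convention) everywhere internally;
  VCF POS is converted on read (pos0 = POS − 1). An SNV at a region's `end0`
  is outside it.
* BED SNVs must be 1-bp intervals; longer intervals are rejected as
  non-SNVs. The sample id comes from a designated column or the file stem.
  VCF records are kept only for single-base REF/ALT pairs; multi-allelic
  sites contribute one record per single-base ALT; indels and symbolic
  alleles are counted and skipped.
* Duplicate records — identical (chrom, pos0, sample, ref, alt) — are
  dropped on read with a logged count, so re-called variants cannot inflate
  the binomial numerator. Alleles are part of the key so the split records
  of a multi-allelic site survive.
* Known-SNP filtering matches by position only (the BED-level catalogue
  carries no alleles): mode `all` removes every match, mode `maf` removes
  only matches with catalogue MAF > 1%, keeping rarer matches as possibly
  acquired variants. Catalogue entries without a MAF are kept in `maf` mode
  (conservative: possibly rare) and removed in `all` mode.
* Overlapping or book-ended input regions are merged (gene names unioned),
  so every SNV maps to exactly one interval; the merged catalogue is what
  rates, tests and outputs refer to.
* Promoter windows from a GTF use the TSS (transcript start on +, end on −):
  [t−1−up, t−1+down+1) on the plus strand, mirrored on minus, clipped at 0,
  defaulting to up = 2000, down = 500 — a conventional promoter span; the
  window is a parameter and is recorded in run metadata. Same-gene
  overlapping windows are merged; different genes keep separate entries. A
  region is `promoter` on ≥ 1 bp overlap, else `distal`.
* Chromosome names are matched as exact strings; an opt-in normalization
  can add or strip the `chr` prefix, off by default so naming mismatches
  surface as errors rather than silent empty intersections.

## Synthetic cohorts

The generator emulates the counts-level structure of a tumour-cohort ×
accessibility-peak analysis: disjoint regions placed uniformly (with ≥ 1 bp
gaps so merging is a no-op and ground-truth identities are stable), and
per-region, per-sample counts drawn Binomial(L, β·f_r·h_s) with background
β, region fold f_r (1, or the spike fold for truly enriched regions), and
sample multiplier h_s (1, or the hypermutation factor). Positions are
uniform without replacement within a region per sample; the same position
may recur across samples. A known-SNP catalogue (density 10⁻⁵ per genome
bp, 10% of entries without MAF) and promoter windows over a quarter of the
regions are emitted alongside, in exactly the BED dialects the readers
consume, plus a ground-truth table. All randomness flows from one master
seed through named child streams; fixed seed ⇒ byte-identical files.

Default conditions are a sparse null cohort calibrated to the real-data
regime the tool targets (whole genomes intersected with peaks: ~10⁻⁶
mutations per bp per sample inside the catalogue; 20 samples, 2000 regions
of 200–1000 bp). The spike-recovery experiment uses 50 of 5000 regions at
50× background in a 50-sample cohort with β = 10⁻⁵, chosen a priori so a
spiked region's expected cohort count is ≈ 15 — a clearly detectable
regime mirroring elements recurrently mutated in a handful of samples; at
β = 10⁻⁶ the same geometry gives expected count 1.5 and no method could
recover 90% of spikes. What the generator does **not** model: sequence
context and signatures, clustered/hotspot positions within a region,
covariates like replication timing, indels/SVs, and sample-level rate
heterogeneity beyond the hypermutation multiplier. Passing tests therefore
demonstrate the statistical machinery (calibration, recovery, FDR control,
mode robustness) on counts-level data, not robustness to those real-data
features.

Matched peak sampling bins the reference lengths into quantile bins
(deciles by default; duplicate quantile edges collapsed) and draws the same
per-bin counts from the candidates without replacement; candidates outside
the reference length range are ineligible, so a constant-length reference
draws only that length. The binning scheme is a documented choice, not a
claim about any particular published procedure.

## Numerical choices and edge cases

* Binomial tails come from `scipy.stats.binom.sf`; verified against an
  exact rational-arithmetic tail sum to 10⁻¹² relative error on the full
  grid k ≤ n ≤ 50, p ∈ {0.001, 0.01, 0.1, 0.5}. P-values are floored at
  10⁻³⁰⁰ so −log10(q) stays finite.
* A background rate of 0 (or ≥ 1) is an error, never a silent p = 1: a
  mutated region always implies a positive background in both modes, so a
  zero can only mean a caller bug or an empty cohort.
* `regionsamples` on a region with no mutated samples is an error; such
  regions are excluded from testing upstream (k = 0 ⇒ p = 1).
* BH ties: equal p-values receive equal q-values (step-up minimum runs
  through them); sorting is stable.
* The slope-1 crossing test uses a 10⁻¹² tolerance so an exactly linear
  rescaled ramp (slope 1 up to rounding) triggers at the first point.
* Empty inputs degrade explicitly: empty region file → warning + empty
  results; zero retained SNVs → pipeline completes with nothing tested.
* Pipeline outputs are written only after all stages succeed (no partial
  output directories), sorted by (chrom, start0), making reruns
  byte-identical.

## Verification problem sizes

The acceptance script runs: the full binomial grid (5 300 evaluations);
1000 random BH vectors (lengths 1–500); 100 null-cohort seeds; one spiked
cohort (5000 regions × 50 samples); 5 hypermutation seeds × 2 modes; 200
random intersection instances (plus per-region boundary probes) and 1000
random merge sets; and 2 determinism reruns — about 15 s total on one CPU.

## Known limitations

* The background is a single per-bp rate per (mode, region); no
  trinucleotide-context or covariate model. The method's premise is that
  the user's catalogue already matches chromatin context.
* Position-only SNP matching can remove a true somatic variant that
  coincides with a common SNP position; allele-aware matching would need an
  allele-bearing catalogue.
* Pooled counts: a sample contributing several SNVs to one region counts
  each of them; recurrence across samples is reported (unique-sample count)
  but not separately tested.
* The inflection threshold assumes the ranked-rate curve has a single
  elbow; multimodal rate distributions may place the cutoff conservatively
  high.
* Downstream target-gene assignment for distal elements is out of scope;
  the BED of significant distal regions is written for external tools.
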