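# Methods

## The measurement model

MCTA-Seq reads out methylated CpG-island loci anchored at a CGCGCGG 7-mer.
The quantification unit is the pair (site, CpG index *j*): a sequenced
molecule is a *fully methylated molecule* (FMM) at *j* when CpGs 1..*j*
downstream of the anchor are all methylated. The methylation value of a
marker in a sample is

    MePM = FMM count × 10⁶ / total uniquely mapped reads .

MePM is non-increasing in *j* by construction (a prefix property), which
the quantification module asserts on all outputs. The read-count
denominator is interpreted as molecules/read-pairs; duplicate reads (the
`copies` column of a molecule table) inflate the denominator but never the
FMM count.

Matched plasma/WBC pairs are equalised to the same duplication rate before
comparison. The mechanism used is seeded removal of duplicate reads from
the higher-rate library until its rate matches the lower one (default),
which preserves the count nature of MePM; a multiplicative read-total
rescaling mode is available behind a switch. The choice matters little in
practice (rates differ by ≈0.1) but the downsampling mode keeps the data
integer-valued.

## Differential methylation

Per-locus two-tailed Mann-Whitney-Wilcoxon test between plasma and WBC
groups (exact null when both groups have ≤ 8 observations and no ties,
tie-corrected normal approximation otherwise — delegated to
`scipy.stats.mannwhitneyu`), Benjamini-Hochberg FDR (via
`statsmodels`), and a group-mean fold-change filter (> 5 at q < 0.05, each
direction separately). Group means receive a 0.1-MePM pseudocount before
the ratio: WBC group means of exactly 0 are routine under the marker
criteria, so some regularisation is required for finite fold changes; 0.1
is one tenth of the smallest meaningful MePM threshold used anywhere in
the pipeline and leaves strong signals (50 vs 0 → FC ≈ 500) unambiguous.
The 14 plasma/WBC pairs are treated as unpaired groups, matching the
stated test. Both thresholds and the pseudocount are parameters.

## Marker selection

Candidates are scored per tissue panel (8 tissues: liver, lung, stomach,
colon, kidney, pancreas, muscle, skin) with five criteria, evaluated in
the order (v) anchor distance < 60 bp, (iii) WBC-training 90th percentile
= 0, (ii) source-tissue MePM > 10, (i) specificity index τ > 0.9, (iv)
liver mean < 1 for non-liver markers. The fixed order makes the rejection
trail deterministic: each candidate records the first criterion that
rejected it. Notes on the individual rules:

- τ = Σᵢ(1 − xᵢ/max)/(N−1), strictly-greater threshold — a profile of
  10 vs seven 1s scores exactly 0.9 and is excluded.
- The 90th percentile is nearest-rank (type 1), so "= 0" over 29 training
  samples is an exact test: with 29 samples the statistic is the 27th
  order statistic, and up to two positive samples are tolerated.
- "Most hypermethylated tissue" ties are broken by fixed tissue order
  (liver first). Ties are measure-zero on real data but routine on
  synthetic zeros.
- Tissues listed as fallback (lung and muscle, whose methylomes are less
  distinctive) are retried without the τ criterion when the strict pass
  returns nothing for them; criteria (ii)–(v) still apply.

For deconvolution, a tissue's markers are aggregated by summing all but
one. The excluded marker is the *panel-defined* largest (highest reference
MePM in the source tissue), not the per-sample maximum: a per-sample
maximum would make the aggregate non-linear in the mixing fraction and
break the linear mixture model. The per-sample mode exists behind the
`exclude=None` path of `aggregate_markers` for comparison.

The HCC-safe filter drops liver markers whose tumor-vs-adjacent one-tailed
MWW P ≤ 0.05 and non-liver markers whose tumor 90th-percentile MePM ≥ 10,
for use when profiling liver-cancer plasma. Intragenic annotation flags
markers inside gene bodies (TSS+300 to TES+300, strand-aware, half-open)
of genes whose expression z-score — computed on log2(x+1) tissue means,
the scale being otherwise unspecified — exceeds 1.5 in the marker's source
tissue.

## Deconvolution

One aggregated equation per tissue gives the square system
MP̄ᵢ = Σₖ MT̄ᵢₖ Pₖ with WBC omitted (the markers are WBC-silent by
criterion iii). The solver minimises the sum of squared residuals subject
to 0 ≤ Pₖ ≤ 1 — the objective is a design choice, standard for linear
systems — using global-best particle swarm optimization with the canonical
constriction parameters (inertia 0.729, cognitive = social = 1.49445), 50
particles, 500 iterations, particles clamped to the box with velocity
zeroed at the boundary. Two numerical details:

- *Stall restart.* On these strongly diagonal, badly scaled systems the
  swarm can collapse onto a boundary point before locating the basin
  (all personal bests equal the global best, velocities → 0, dead swarm).
  After 25 iterations without global-best improvement the velocities are
  re-randomised while personal/global-best memory is kept. This restores
  agreement with constrained least squares to ~1e-9 on noiseless systems;
  without it roughly a third of runs stagnate.
- *Median of runs.* Ten independently seeded runs are summarised by their
  element-wise median, which suppresses residual outlier runs.

Background correction uses the per-tissue WBC constants measured on
paired WBC samples: fractions below the mean+3SD threshold (liver 0.11%,
lung 0, stomach 2.0%, colon 0.082%, kidney 0.036%, pancreas 0.023%, muscle
0.57%, skin 0) are zeroed; survivors have the mean background (0.015%, 0,
0.36%, 0, 0, 0, 0.066%, 0) subtracted, floored at 0. The threshold is
applied to the *measured* fractions and subtraction to the survivors; the
alternative order differs only within one background mean of the
threshold. `WBCBackgroundModel.from_wbc_fractions` recalibrates both
constants from deconvolved WBC-only samples (used by the pipeline on
synthetic data, where the defaults would not apply).

Absolute quantification: GE/mL = fraction × cfDNA (ng/mL) × 1000 / 3.3,
taking 3.3 pg per haploid genome equivalent (configurable; the constant is
not uniquely pinned by convention — ≈6.6 pg per diploid genome).

Spike-in evaluation fits OLS of estimated vs true fraction per tissue
(slope, intercept, R²) and defines the detection limit as the smallest
grid fraction whose replicate estimates differ from WBC-only replicates by
a two-tailed Student t test at α = 0.05. The test compares *estimated
fractions* (not aggregated marker MePM); when both replicate sets are
constant the p-value degenerates to 1 (equal) or 0 (different).

## Synthetic data: what it does and does not emulate

The generator's defaults are the stated world: 146 markers
(59/8/9/20/13/18/11/8 across liver/lung/stomach/colon/kidney/pancreas/
muscle/skin), source-tissue MePM uniform in [10, 100], zero MePM in the
other tissues and WBC, 3×10⁶ mapped reads, 29 WBC training samples, 14
WBC/plasma pairs with plasma at a 1.3% liver fraction (the healthy
median) and pair duplication rates drawn from N(1.4, 0.3²) / N(1.3, 0.1²)
truncated at 1. FMM counts are Poisson with rate reads/10⁶ × mixture MePM
— the natural model for rare-molecule counts; no noise model is otherwise
prescribed. Mixing is done at the count level with configurable
replicates per level. Marker coordinates are synthetic (chr1..chr22,
10 kb spacing, anchor-to-CpG distances 2–58 bp); decoy markers violating
single criteria (distance ≥ 60 bp, shared-tissue τ ≤ 0.9, WBC-leaky) are
available to exercise the selection filters, with the shared-tissue decoy
pinned to a second-tissue level ≥ 0.75× so its τ = (7−r)/7 stays below
0.9.

The generator does **not** emulate: raw reads or bisulfite conversion
errors, PCR duplication family structure (duplicates are iid Poisson
copies), fragment lengths, inter-individual reference variation (tissue
MT̄ are point values), cross-tissue marker correlation, or mapping
artefacts. A green spike-in test therefore establishes that the solver and
statistics recover the stated generative model at realistic counting
noise — not that the assay performs identically on real libraries, where
reference-panel mismatch and background leakage add error.

Tests and the acceptance script sequence spike-ins at 3×10⁵ reads (a
scaled-down stand-in for the 3×10⁶-read experiment, noted wherever used)
to stay inside desk-scale runtime; counting noise is ~√10 larger than at
full depth, so the R² ≥ 0.95 and 0.25% detection-limit checks are run
under *harder* conditions than the full-depth design.

## Physiological worked example

With ~1000 diploid genome equivalents per mL plasma (6 ng/mL cfDNA), a
liver fraction of 1–2%, a distribution volume of 60–70 mL/kg in a 70-kg
adult and first-order clearance with a 1-hour half-life, the circulating
liver-derived pool is GE/mL × fraction × volume and its daily production
is pool × ln2/t½ × 24. Midpoint inputs give ≈1.1×10⁶ hepatocytes/day,
0.0005% (one significant figure) of 2.4×10¹¹ hepatocytes; the endpoint
interval is 0.70–1.63×10⁶. First-order kinetics is implied by a stated
half-life; a cruder pool-per-half-life mode (÷ln2 larger) is included for
comparison.

## Degenerate inputs and tie-breaks (summary)

- `total_reads = 0`: empty molecule table; MePM is undefined and
  `compute_mepm` refuses a zero denominator.
- All-zero tissue profile: τ undefined, signalled.
- Identical constant groups: MWW p = 1 (no rank separation).
- Tissue with zero retained markers: its equation is dropped with a
  warning and its fraction reported as 0.
- Seeds: every stochastic step (generation, sequencing, duplicate
  downsampling, PSO runs) takes an explicit seed or Generator; PSO runs
  derive per-run seeds from a `SeedSequence` spawn.

## Known limitations

- The deconvolution assumes the reference panel is exact; panel noise
  propagates directly into fraction estimates and is not modelled.
- The detection-limit t test assumes approximately normal replicate
  estimates; at the lowest spike levels estimates are strongly discrete
  (a few Poisson counts), making the test conservative-ish rather than
  exact.
- Cohort-scale results on real data (total marker counts on real
  methylomes, 77 plasma-hyper loci, healthy-median liver fraction 1.3%,
  34 GE/mL) require the deposited sequencing data and are documented as
  non-desk benchmarks only; nothing in this repository recomputes them.
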