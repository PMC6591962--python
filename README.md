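# mctamap

Tissue-of-origin mapping of plasma cell-free DNA (cfDNA) from MCTA-Seq
methylation data.

Plasma cfDNA is released by dying cells, overwhelmingly white blood cells
(WBC); the interesting clinical signal is the small remainder shed by solid
tissues (liver, pancreas, ...), which rises when those tissues are injured.
MCTA-Seq amplifies methylated CpG-island loci anchored at a CGCGCGG 7-mer
and reports, per sequenced molecule, the methylation of up to 10 CpGs
downstream of the anchor. `mctamap` implements the complete downstream
analysis:

- **Quantification** — counting fully methylated molecules (FMMs: every CpG
  from the anchor through CpG *j* methylated) and normalising to
  **MePM** (methylated alleles per million mapped reads), including paired
  plasma/WBC duplication-rate equalisation.
- **Differential methylation** — plasma vs WBC volcano screening
  (two-tailed Mann-Whitney-Wilcoxon, Benjamini-Hochberg FDR, group-mean
  fold change > 5 at FDR < 0.05).
- **Marker selection** — tissue-specific hypermethylated markers across 8
  tissues via five criteria (specificity index τ > 0.9; source MePM > 10;
  WBC training 90th-percentile MePM = 0; liver cross-reactivity < 1 MePM;
  CpG < 60 bp from the anchor), with a τ-free fallback for lung/muscle, an
  HCC-safe subset filter, and intragenic tissue-specific-gene annotation.
- **Deconvolution** — per-tissue cfDNA fractions from the linear mixture
  model MP̄ᵢ = Σₖ MT̄ᵢₖ·Pₖ, solved by particle swarm optimization under
  0 ≤ Pₖ ≤ 1 (median of 10 runs), with WBC background subtraction,
  mean+3SD zeroing thresholds, and conversion to absolute haploid genome
  equivalents (GE) per mL plasma.
- **Synthetic data** — a seeded generator producing reference panels, WBC
  cohorts, plasma mixtures and spike-in dilution series with Poisson
  molecule counts, so the whole pipeline is testable without sequencing
  data.
- **Reporting** — a config-driven end-to-end pipeline plus the
  hepatocyte-turnover worked example (how many liver cells per day a 1–2%
  liver fraction implies).

## Worked example

```python
from mctamap import (SimulationConfig, generate_reference_panel,
                     select_tissue_markers, simulate_sample, compute_mepm,
                     deconvolve, PSOConfig, absolute_ge)

cfg = SimulationConfig(total_mapped_reads=300_000, seed=7)
bundle = generate_reference_panel(cfg)
markers = select_tissue_markers(bundle.panel, bundle.wbc_training,
                                bundle.marker_info["distance_bp"])
print(markers.counts())
# {'liver': 59, 'lung': 8, 'stomach': 9, 'colon': 20, 'kidney': 13,
#  'pancreas': 18, 'muscle': 11, 'skin': 8}

mol, meta, _ = simulate_sample(bundle, {"liver": 0.02}, 300_000, seed=1,
                               sample_id="s1")
mepm = compute_mepm(mol, meta, bundle.sites)
res = deconvolve(markers, bundle.panel, mepm["s1"].loc[bundle.markers],
                 pso=PSOConfig(seed=0), background=None)
print(round(res.raw_fractions["liver"], 4))   # 0.0268
print(round(absolute_ge(res.raw_fractions, 6.5)["liver"], 1))  # 52.8
```

The selection recovers all 146 planted markers with the per-tissue counts
of the panel design. A 2% liver spike sequenced at 3×10⁵ reads comes back
as a 2.68% estimate (Poisson counting noise at this scaled-down depth); at
6.5 ng/mL cfDNA that fraction corresponds to ≈53 liver GE per mL plasma.

```sh
$ mctamap turnover
{"cells_per_day": 1135375.08..., "fraction_of_liver": 4.7307e-06, ...}
```

≈1.1 million hepatocytes dying into the blood per day — about 0.0005% of
the liver.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the spike-in performance of the deconvolution on
the synthetic world: it generates the full-size reference panel, selects
markers, simulates a liver-into-WBC dilution series (0.25–16%, 10
replicates per level, 3×10⁵ mapped reads) plus 10 WBC-only replicates,
deconvolves every sample, and reports the R² of estimated-vs-true liver
fraction and the smallest fraction statistically distinguishable from the
WBC background (two-tailed t test, P < 0.05).

## Command line

`mctamap pipeline --config cfg.yaml --out run/` drives simulate → quantify
→ differential → markers → deconvolve → report from one config file;
`mctamap deconv`, `mctamap deconv-eval`, `mctamap simulate` and
`mctamap turnover` expose the individual stages. See `docs/methods.md` for
the model details and design choices.
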