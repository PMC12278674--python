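# ptmflux

Multi-omics quantification and integration for nitrogen-limitation studies
in oleaginous yeast: multiplexed TMT proteomics (global protein abundance,
cysteine thiol-oxidation sites, phosphosites), lipidomics normalization,
empirical-Bayes differential statistics, set enrichment, and a
correlation-based integration of oxidized cysteine sites with storage-lipid
trajectories.

## The problem

Under carbon-replete, nitrogen-limited growth (high C:N), oleaginous yeasts
such as *Rhodotorula toruloides* reroute carbon into triacylglycerols (TG).
Much of that regulation happens not through enzyme abundance but through
post-translational modifications: reversible cysteine thiol oxidation
(redox PTMs) and phosphorylation. Quantifying those signals from a
multiplexed TMT experiment requires a careful normalization chain, because
site-level reporter intensities confound PTM stoichiometry with protein
abundance, TMT channel loading, and between-plex batch effects.

`ptmflux` implements that chain as a tested, reusable pipeline, and ships a
synthetic-study generator with known ground truth so every stage is
verifiable without any raw mass-spectrometry data.

## The model

For a site *s* on protein *p*, measured in channel *c* of plex *b*, the
measurement model behind both the generator and the normalization is

```
I(s,c)  ∝  π(s, cond(c)) · 2^{A_p(cond(c))} · ε_s · L_{b,c} · B_b · η,   η ~ LogNormal(CV)
```

where π is the thiol-oxidation occupancy (or phospho stoichiometry), `A_p`
the protein log2 abundance, `ε_s` a peptide ionization efficiency, `L` the
channel loading, and `B` a plex batch factor. The pipeline removes each
nuisance term in a fixed order:

* **global**: sum peptide reporter intensities per protein → log2 →
  bridge-channel batch correction → per-channel median centering;
* **PTM sites**: aggregate per site → log2 → channel-loading scaling
  (median offsets of the un-batch-corrected global *peptide* matrix) →
  median centering → batch correction → subtraction of the parent
  protein's per-condition mean abundance;
* **occupancy**: on loading-scaled *linear* intensities,
  `%occ(s, k) = 100 · mean(thiol-ox channels of condition k) / mean(pooled
  total-thiol duplicates)` — the per-site constant ε_s cancels;
* **lipids**: blank/zero → missing → 1, probabilistic quotient
  normalization on linear peak heights, log2, subclass sums and row
  z-scaling for class-trend views;
* **statistics**: moderated t-tests with a scaled inverse-χ² variance prior
  fitted by trigamma inversion (`t = log2FC / (s̃·√(1/n_A+1/n_B))`,
  `s̃² = (d₀s₀² + df·s²)/(d₀+df)`), the factorial model
  `~ Nitrogen + Time + Nitrogen:Time`, Benjamini–Hochberg adjustment;
* **enrichment/integration**: exact hypergeometric ORA within a declared
  universe, rank-based lipid set enrichment, Pearson correlation of
  per-condition site means against lipid-subclass sums, and selection of
  sites with r > 0.80 against both TG and DG and |log2FC| ≥ 0.8.

## Worked example

```python
from ptmflux import (SimConfig, simulate_study, rollup_protein, rollup_peptide,
                     log2_transform, bridge_batch_correct, median_center_channels,
                     channel_loading_offsets, aggregate_sites,
                     apply_loading_scaling_linear, compute_occupancy, ModeratedTTest)

study = simulate_study(SimConfig(seed=11))          # two TMT-18 plexes per assay

designs = study.designs_by_assay["global"]
proteins = median_center_channels(bridge_batch_correct(log2_transform(
    rollup_protein(study.psm["global"], designs))))

peptides = log2_transform(rollup_peptide(study.psm["global"], designs))
offsets = channel_loading_offsets(peptides)
linear = apply_loading_scaling_linear(
    aggregate_sites(study.psm["redox"], study.designs_by_assay["redox"], "redox"),
    offsets)
occupancy = compute_occupancy(linear)
print(occupancy.group_means().round(1))

results = ModeratedTTest(proteins, "low_72h", "high_72h").fit()
print(results.summary())
```

prints

```
condition
high_24h     9.6
high_48h    11.1
high_72h    14.4
low_24h     12.6
low_48h     14.5
low_72h     15.9
Name: mean_percent_oxidation, dtype: float64
Differential results
============================================================
features tested : 300
contrasts       : ['low_72h vs high_72h']
prior           : d0=inf, s0_sq=0.008182035613604564
significant     : 17 up / 8 down (adj p <= 0.05, |log2FC| >= 0.0)
skipped features: 0
============================================================
feature_id            contrast  log2FC      t  df          p      adj_p  n_a  n_b
   RT_0066 low_72h vs high_72h   -2.82 -38.18 inf 5.177e-319 1.553e-316    3    3
   ...
```

The group means show thiol oxidation in the 10–15% range, higher under
nitrogen limitation at 24/48 h and rising ~1.5-fold from 24 h to 72 h —
the behavior the generator's defaults encode. The infinite prior degrees of
freedom `d0=inf` are correct here: the generator is homoscedastic, so the
empirical-Bayes estimator collapses all residual variances onto `s0_sq`.

The whole analysis (simulate → quantify → occupancy → differential →
enrichment → integration, with a run manifest) is one call:

```sh
ptmflux run-all --seed 11 --outdir out/
```

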