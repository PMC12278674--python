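# Methods

This note documents the models, estimators, defaults and numerical choices
behind `ptmflux`, and what the synthetic-study generator does and does not
emulate.

## Study structure

The pipeline targets a 2×3 factorial timecourse: nitrogen availability
(high vs low, i.e. carbon-replete vs nitrogen-limited medium) crossed with
sampling time (24, 48, 72 h), n = 3 biological replicates per cell. Three
assays share the same TMT-labeled material: global protein abundance,
cysteine thiol-oxidation sites enriched after NEM blocking of free thiols
(+NEM), and phosphosites enriched by IMAC. Each assay spans two TMT-18
plexes. The six 24 h samples are split into technical replicates and
labeled in *both* plexes ("bridge" channels); each plex also carries
duplicate channels of a pooled total-thiol (−NEM) reference and empty
buffer channels that separate the low-intensity +NEM channels from the
brighter pool channels. Channels are classed as `sample`, `bridge`,
`total_thiol_pool` or `empty`; empty channels never enter any
quantitative operation.

## Normalization chains

**Global:** protein intensity is the *sum* of its FDR-passing peptides'
reporter intensities per channel (missing peptide values are skipped, never
zeroed; a protein is missing in a channel only when all of its peptides
are). Then log2 (zeros → missing with a logged count), bridge batch
correction, per-channel median centering. Each step appends itself to
`applied_steps`; re-running a step raises, which freezes the chain order.

**Batch correction.** The mechanism is feature-wise bridge alignment: for
feature *f* and plex *p*, `offset(f,p) = mean(f over p's bridge channels) −
mean(f over all plexes' bridge channels)`, subtracted from all of *p*'s
channels. Features unobserved in a plex's bridges fall back to that plex's
median offset across features. Because the offset is constant within a
plex, within-plex channel differences — and therefore every within-plex
contrast — are invariant under the correction. A per-plex median fallback
is available from the CLI for designs without bridges.

**PTM sites:** site intensity is the sum over peptides carrying the
identical site key. Composite keys with ambiguous localization (e.g.
`P_S512;T513`) are features of their own and never merge into their
single-residue neighbors. The chain is aggregate → log2 → channel-loading
scaling → median centering → batch correction → protein subtraction.

**Channel-loading scaling.** TMT channel loadings are estimated from the
log2 global *peptide* matrix before any batch correction:
`offset(channel) = median over peptides − grand median of the per-channel
medians`. The median estimator is robust to missingness and to moderate
fractions of differential features. The plex-level batch factor is
deliberately allowed to absorb into these offsets — downstream median
centering and batch correction remove it again, and the occupancy ratio
cancels any per-plex constant exactly.

**Protein subtraction.** For each site channel in condition *k*, the parent
protein's mean normalized abundance over condition-*k* channels is
subtracted. Sites whose parent protein is not quantified are left
unadjusted and listed in `orphan_sites` (flagged, not dropped). After this
step a site's fold change reflects PTM stoichiometry rather than protein
abundance. The residual that remains is the difference between the two
matrices' median-centering constants; it is a uniform per-channel shift
that shrinks roughly as 1/(feature count × density at the median) and is
why the nulling check is specified on studies of ≥500 features.

**Occupancy.** % thiol oxidation is computed on *linear*, loading-scaled
intensities, before the log2 branch and before protein subtraction:
within each plex, the mean of a condition's +NEM channels divided by the
mean of that plex's pooled total-thiol duplicates, ×100; ratios are then
averaged across the plexes in which the site appears. Within-plex ratios
cancel the plex batch factor and the per-site peptide efficiency exactly.
"Normalized raw intensities" is read as loading-corrected, un-logged; the
alternative (no loading scaling) is available by simply skipping the
scaling call. Occupancies above 100% — possible under noise — are kept and
flagged rather than clipped, preserving the distribution shape. Rows with
a zero or missing denominator are omitted with a logged count. Where a
site is quantified in both plexes, pool averaging is within-plex first,
then across plexes.

**Lipids.** Blank and zero peak heights are recorded as missing at load
(this rule applies to lipid input only; proteomics missingness is always
represented as absent values). Missing cells are set to 1, probabilistic
quotient normalization runs on linear intensities (reference spectrum =
per-feature median over samples; dilution factor = median quotient against
the reference), then originally-missing cells are restored to missing and
log2 follows. PQN-on-linear is the standard Dieterle formulation; a
log-scale variant would amount to median-offset subtraction and is not the
default. Subclass sums treat missing as 0; row z-scaling uses the sample
standard deviation (n−1) and refuses constant rows. Median ties resolve by
midpoint (pandas/numpy default).

## Differential statistics

Features must be observed in ≥2 biological replicates of at least one
condition of the tested contrast (bridge technical replicates of the same
biological sample count once — observation is per distinct `sample_id`).

The moderated two-group test squeezes each feature's pooled variance
toward a scaled inverse-χ² prior: `s̃² = (d₀s₀² + df·s²)/(d₀+df)`,
`t = log2FC/(s̃·√(1/n_A+1/n_B))` on d₀+df degrees of freedom. The prior is
fitted by method of moments on log s² with digamma/trigamma bias
corrections; the trigamma inversion uses monotone Newton iteration to a
relative step below 1e−8. When the spread of log variances does not exceed
its theoretical sampling variance, d₀ = ∞ (all variances collapse to s₀²;
the reference distribution becomes normal) — the correct answer for
homoscedastic data such as the generator's. d₀ = 0 reproduces the ordinary
Student test to numerical precision. All log2 fold changes are reported
for time-matched contrasts (low vs high nitrogen at the same timepoint).

The factorial model `~ Nitrogen + Time + Nitrogen:Time` codes nitrogen
0 = high / 1 = low and time numerically in hours centered at 24 (a
categorical coding is provided). Fits are per-feature OLS on the feature's
observed channels, with coefficient standard errors moderated by the
shared prior. A numerically exact fit (residual sum of squares below
1e−16 of the response's scale) yields t = 0, p = 1 for zero coefficients
and p → 0 for non-zero ones. Rank-deficient designs abort with the aliased
columns listed.

p-values are Benjamini–Hochberg adjusted within each result set (step-up,
input order restored).

## Enrichment and integration

ORA uses the exact hypergeometric upper tail `P(X ≥ k)` within a declared
universe; sets are intersected with the universe and must keep ≥2 members.
Reported enrichments satisfy adjusted p ≤ 0.05 **and** Storey q ≤ 0.2
jointly; q-values use fixed λ = 0.5 (`π₀ = min(1, #{p>λ}/((1−λ)m)`), which
can differ from other q-value estimators' spline-based π₀.

The lipid set test is a two-sided rank-sum of member vs non-member log2
fold changes: exact enumeration when ≤12 features are scored (no ties),
normal approximation with continuity correction otherwise; fully tied
scores give p = 1; direction is the sign of the median-rank difference.

Integration correlates per-condition means of the protein-adjusted redox
site matrix with log2 lipid-subclass sums over the six-condition grid
(Pearson, requiring ≥3 shared conditions; zero-variance trajectories are
omitted with a flag). Selected sites have r > 0.80 against **both** TG and
DG (a conjunction; `mode="any"` gives the union) and |log2FC| ≥ 0.8 on the
factorial nitrogen coefficient; the selection feeds ORA against the
quantified-site universe. Using the protein-adjusted matrix is the
default; the unadjusted matrix can be passed instead.

Filter thresholds live in one place (`FilterConfig`): adjusted p ≤ 0.05;
|log2FC| ≥ 0.8 (PTM calls / integration), ≥ 1 (KEGG ORA input, inclusive),
≥ 4 (metabolite-set ORA input); Pearson r > 0.80 (strict); q ≤ 0.2;
≥2 biological replicates; ≥2 members per set.

## The synthetic-data generator

The generator emits complete studies — plex designs, three PSM tables, a
lipid table, set collections, and serialized ground truth — under the
measurement model in the README. Defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| grid | 2×3, n = 3 | nitrogen × time, biological replicates |
| `n_proteins` / peptides | 300 / 3 | global assay size (desk-scale) |
| `n_cys_sites` / `n_phospho_sites` | 400 / 600 | PTM assay sizes |
| `noise_cv` | 0.1 | log-normal multiplicative noise, mean 1 |
| protein baseline | N(20, 2) log2 | reporter-intensity scale ~10⁶ |
| π baseline | 2^N(log2 0.095, 0.45) | site thiol-oxidation occupancy |
| `pi_low_n_factor` | 1.2 (24/48 h) | low-N occupancy increase |
| `pi_time_factors` | 1 / 1.15 / 1.45 | occupancy drift over time |
| `channel_loading_log2_sd` | 0.15 | per-channel loading spread |
| `batch_log2_offsets` | plex2 +0.3 | between-plex batch factor |
| effects | 10–15% differential, N(0,1) log2 | per-omic nitrogen effects |
| lipidome | 206 species | class counts fixed at 172 GP+GL / 19 SL / 14 FA / 1 PR |
| `lipid_dropout_quantile` | 0.02 | low-intensity cells → missing |

These defaults put the six group mean occupancies in the ~10–15% band,
~25–35% higher under low nitrogen at 24/48 h and ~1.5× higher at 72 h than
at 24 h. Twenty cysteine sites are "TG-coupled": their log2 occupancy is
affine in the TG subclass trajectory (from half their baseline, so the
trajectory stays physiological), giving the integration stage a known
positive set. Effect sizes are Normal(0, sd) per omic; a ±fixed-magnitude
mode draws exactly balanced signs, used for nulling scenarios where an
unbalanced sign draw would shift channel medians.

What the generator does **not** emulate: spectral-level artifacts (isotope
impurity, co-isolation interference — the empty-channel rationale is
represented only by the channel class), enrichment losses (RAC/IMAC are
treated as lossless), peptide-level missingness mechanisms for proteomics
(the pipeline filters at ≥2 replicates instead), protein-inference
ambiguity, and retention-time or identification errors. Passing tests
therefore demonstrate the correctness of the quantification arithmetic and
the statistical calibration under the stated model, not robustness to raw
mass-spectrometry artifacts.

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives all
draws in a fixed order; identical seeds give byte-identical outputs. The
null generator switches every condition effect off (flat π, flat
stoichiometry, no lipid trends, no coupled sites) while keeping the
technical structure, and is the basis of the type-I-error and FDR checks.

## Problem sizes and runtime

Synthetic studies are run desk-scale by choice: 300 proteins / 400 cysteine
sites / 600 phosphosites against the study's 2,804 / 5,926 / 17,195
identifications, with the lipidome kept at the real 206 species. The
calibration checks use 10,000 null features for the rejection rate and 20
replicate 2,000-feature studies for the FDR bound; the full test suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Occupancy inherits a bias of π·A_p(k)/Ā_p when the parent protein's
  abundance varies across conditions — a property of pool-referenced
  designs, not of the estimator; the recovery checks therefore hold protein
  abundance flat.
* Median centering removes population-wide occupancy shifts; a global rise
  in oxidation appears only in the occupancy table (which is centering-free),
  not in the normalized log2 matrices.
* The site-vs-protein median-centering constant leaves a small uniform
  per-channel residual after protein subtraction (see above).
* The LSEA statistic is a rank-sum test; weighted enrichment-score
  permutation tests are out of scope.
* Phospho stoichiometry is generated but not estimable from the design (no
  total-phospho reference exists), so phospho results are relative
  abundances only.
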