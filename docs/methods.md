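# Methods

## The analysis model

The experimental unit is a mouse in a 2×2 genotype × microbiome layout:
wild-type (WT) or α-synuclein-overexpressing (ASO) animals, raised with a
conventional microbiome (SPF) or germ-free (GF). Each animal contributes
up to ten sample types — plasma, three luminal contents, two gut tissues,
four brain regions — profiled on a targeted panel reporting absolute
concentrations (µM) with a per-metabolite lower limit of detection (LOD).

For each metabolite within a sample type we fit, by OLS,

    log2(conc) = β0 + βG·1{ASO} + βM·1{SPF} + βGxM·1{ASO∧SPF}
               + βBW·(bw − mean bw) + ε,   ε ~ N(0, σ²)

with reference cell WT-GF, so βG and βM are conditional effects in the
GF and WT strata respectively. The scientifically interesting group
differences are therefore *conditional contrasts*:

- genotype effect within SPF animals: βG + βGxM (ASO-SPF vs WT-SPF),
- microbiome effect within ASO animals: βM + βGxM (ASO-SPF vs ASO-GF).

Inference uses t-statistics with df = n − 5; contrast SE is √(cᵀΣc) with
Σ the coefficient covariance. Significance sets default to strict
p < 0.05 (a configurable `inclusive` mode uses ≤, since boundary
conventions vary between figure captions and text in this literature).
With many tissues and a modest n, FDR control at conventional levels
retains few metabolites; BH q-values are reported per sample type × term
but the primary sets are unadjusted, which the user should treat as
hypothesis-generating. Effect sizes exported for class aggregation are
the contrast/coefficient estimates on the log2 scale — the model's
natural unit (a value of +2 is a 4-fold concentration increase).

## Quality control

Filtering pools the sample types of a *material type* (plasma; duodenum
+ colon; the three luminal contents; the four brain regions), because
detectability is a property of the matrix, not of the anatomical site. A
metabolite is retained iff strictly more than 30 % of its SPF
measurements in that material type lie strictly above the LOD; "above"
is `value > LOD` (a censored token marks ≤ LOD), the denominator is all
SPF measurements (censored or not), and retention decided on SPF animals
is applied to all samples. Censored cells of retained metabolites are
imputed at LOD/2, then values are log2-transformed. No batch correction
is applied (each material type is assumed measured on one plate). The
strict `>` at 30 % and the strict `>` at the LOD are deliberate: both
invariants are exercised at the boundary in the tests. Filtering is
monotone in the threshold, and filter∘impute = impute∘filter on the
retained set because the filter reads censoring flags, never values.

## Distance-based permutation tests

PERMANOVA is implemented directly rather than wrapped. With A = (d²ᵢⱼ)
and J = I − 11ᵀ/n, the Gower matrix is G = −½ J A J; the SS explained by
adding term k to the design is tr((H_k − H_{k−1})G) with H_k the hat
matrix of the incrementally built model matrix. Terms enter sequentially
(Type I) in the fixed order Genotype, Microbiome, Interaction — the
order in which the model is written — so SS sums exactly to tr(G).
Pseudo-F per term is (SS/df)/(SS_res/df_res). The null distribution
comes from unrestricted permutation of sample labels (no blocking exists
in the design), implemented as conjugation of G by a permutation with
all hat matrices held fixed; p = (1 + #{F* ≥ F}) / (1 + n_perm), which
is bounded below by 1/(n_perm+1) and exact under exchangeability. The
default 10,000 permutations give a Monte-Carlo SE below 0.005 for p
near 0.05.

The dispersion test embeds D by principal coordinates, computes each
sample's distance to its group's spatial median (Weiszfeld iteration;
centroid optional), applies the standard negative-eigenvalue correction
d² = d₊² − d₋² (a no-op for Euclidean input), and permutes group labels
over the resulting distances under a one-way ANOVA F. Permuting the
fixed per-sample distances is equivalent, in the one-way layout, to the
residual-permutation scheme of the reference R implementation.

Both tests are validated three ways: closed-form one-factor
decompositions, exhaustive enumeration of all 720 label orders at n = 6,
and numerical agreement with R vegan's `adonis2` and `betadisper`
(via `Rscript`) on a fixture.

## Sets and network

Significance sets are intersected across sample types with UpSet
"distinct" semantics — every metabolite belongs to exactly the
combination of sample types whose sets contain it, so the combinations
partition the union (an inclusive mode is provided). The gut region is
{duodenum, colon, duodenal/cecal/colonic contents}, the brain region the
four brain regions; plasma belongs to neither. Class summaries average
the log2 effect of each class's significant members; an exact zero mean
is reported as "balanced" rather than forced into a direction.

The network stage pairs samples by animal, pools all animals regardless
of group (one ρ per metabolite–tissue pair), and uses Spearman's ρ with
midranks. Edges require ρ > 0.75 strictly (one-sided: the question is
positive concordance with plasma) and ≥ 5 complete pairs — a guard
against spurious |ρ| = 1 at tiny overlap, chosen well below the 23
available animals. Constant vectors make ρ undefined and are excluded.
Degree ties are broken by maximum ρ, then lexicographically.

## The synthetic-data generator

The generator is the model run forwards. Defaults encode the study
conditions: group sizes 5 (WT-SPF), 6 (ASO-SPF), 6 (WT-GF), 6 (ASO-GF);
ten sample types; a 630-metabolite panel over 26 biochemical classes.
Body-weight distributions (WT-SPF 30±2 g, ASO-SPF 28±2, WT-GF 31±2,
ASO-GF 29±2) are realistic 4-month mouse weights with a modest ASO
deficit and slight GF elevation. Cross-tissue correlation is planted via
an animal-level latent factor — one Normal(0, factor_sd) draw per animal
added, scaled by a per-tissue loading, to every tissue of that animal —
the structure a molecule circulating from gut to brain would produce.
The default scenario includes a TMAO-like amine oxide (strong SPF
elevation, latent factor loading plasma + six sites) and three
metabolites with gut-and-brain interaction effects (±2 log2 units,
σ = 0.5), alongside background metabolites with sparse random effects
(8 % genotype, 15 % microbiome, 5 % interaction; magnitudes 0.6–1.8 log2
units). Censoring places the LOD at a per-metabolite quantile of the
simulated values within each material type; the default scenario mixes
well-detected (quantile 0–0.2) and poorly detected (0.75–0.95)
metabolites, with the poorly-detected share largest in brain tissue
(0.50) and smallest in plasma (0.12), emulating matrix-dependent
detectability. Censored cells keep their true value in memory — flagged,
never analyzed — so tests can measure imputation error; on disk they are
written only as the `<LOD` token.

What the generator does *not* emulate: litter effects, plate/batch
structure, assay drift, heteroscedastic or heavy-tailed noise, and
correlated metabolites within a pathway. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data features.

## Numerical and reproducibility choices

- Degenerate fits (residual variance ~ 0, e.g. a constant response)
  report p = 1 rather than NaN so set operations stay total; a missing
  design cell or zero residual df is a hard error.
- Rank computations use midranks; Euclidean distances use `scipy`
  pdist; OLS uses `statsmodels` (validated against normal equations).
- All randomness flows through `numpy` Generators. The pipeline expands
  one global seed into per-stage substreams by hashing stage names
  (stable across runs and insertion order); reruns with the same config
  reproduce byte-identical outputs, recorded as sha256 checksums in
  `manifest.json`. The CLI accepts `--threads` for interface stability,
  but the implementation is single-threaded and results never depend
  on it.
- CSV floats are written with 12 significant digits: write→read→write
  is byte-stable and values round-trip well within 1e-9.
- Problem sizes in the test suite are scaled to keep the full run fast:
  500 replicates for coefficient recovery, 1000 metabolites for the
  null-calibration check, 200 datasets for permutation-test calibration,
  200 simulations for network recovery, and 2000 sampled permutations
  against the 720-order exhaustive enumeration. These sizes give
  Monte-Carlo error comfortably inside each asserted band.

## Known limitations

- Inputs are assumed to be final concentrations; vendor export formats
  and dilution bookkeeping are out of scope (the reader targets this
  package's CSV dialect; mapping a deposited dataset onto it is a user
  step).
- The per-metabolite models assume independent samples; with multiple
  tissues per animal, cross-tissue analyses (the network stage) use the
  animal pairing explicitly, but per-tissue models do not share
  information.
- Permutation tests assume exchangeability under the null; unequal
  dispersions can inflate PERMANOVA location signals, which is why the
  dispersion test is provided alongside.
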