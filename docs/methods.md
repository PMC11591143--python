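# Methods

This note records the models, conventions and numerical choices behind
`ch4rumen`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data can and cannot show.

## Phenotyping model

An LMD trace is a noisy baseline (ambient + respiratory methane column
density) punctuated by eructation peaks. The phenotype extraction makes
three assumptions: (i) readings below 200 or above 8000 ppm × m are
instrument artifacts and are removed (bounds kept — "below/above" read as
strict); (ii) the informative readings are those strictly above the
session's mean + 1 SD, whose average is the session phenotype; (iii) a
cow's phenotype is the plain mean of ≥ 2 session phenotypes, with a
single-pass mean ± 3 SD population QC afterwards.

Conventions worth stating because they are easy to get silently wrong:

* **All SDs are sample SDs (n − 1)**, matching R's `sd`, the lingua
  franca of the animal-science groups that run these campaigns.
* The peak threshold and the QC/selection cutoffs use **strict**
  inequalities for exclusion; ties at a threshold are not retained.
* Sessions with < 2 in-range readings or a zero-variance trace have no
  defined peak mean and are discarded (the ≥ 2-sessions rule then decides
  whether the cow survives).
* Population QC runs **once**, not iterated to convergence; a second
  pass can in principle remove more points (trimming shrinks the SD) and
  deliberately is not taken.
* Extreme groups use mean ± 0.65 SD cutoffs. The reference population
  for those cutoffs is the **full QC'd herd** by default; computing them
  on the eligible (milk 30–40 kg, parity 1–2) subset instead is a
  `reference="eligible"` flag, since either reading of the protocol is
  defensible and the choice moves the cut points.
* Group comparisons use Welch's unequal-variance t-test (R's `t.test`
  default). Reported CVs are sd/mean × 100 rounded half-up to 2 decimals.

## Synthetic data

The generators exist so that every downstream stage has inputs with
known ground truth; their defaults are fixed to the study conditions the
pipeline is validated under, and are not tuned per experiment.

**Traces** (`TraceSimSpec`): 60 cows × 3 sessions × 180 readings.
Baseline N(450, 60²) ppm × m; Poisson(4) eructation events per session,
each a 10-reading boxcar (≈ 10 s at ~1 Hz — the visible length of a belch
plume) of amplitude N(L_c, 100²), where the cow's latent level
L_c ~ N(600, 284²) truncated at 10% of the mean. The 284 ppm × m
between-cow spread mirrors the full-cohort phenotype SD (CV ≈ 33%)
reported for large LMD-screened Holstein herds; the peak-picking
estimator itself contributes roughly 100 ppm × m of noise per cow at 3
sessions, so rank recovery of L_c plateaus near Spearman ρ ≈ 0.95.
Omitted on purpose: respiratory periodicity, drift, operator/device
effects, diurnal structure — so recovery numbers here are an upper bound
on what field traces allow.

**ASV tables** (`CommunitySimSpec`): per sample, proportions ~
Dirichlet(θ·p) with θ = 50 and p a power-law (1/rank) baseline over 200
taxa; counts ~ Multinomial(depth ~ Poisson(20 000)). Group effects
multiply the concentration of chosen taxa by 2^log2FC in HME. This gives
exact row-sum control and realistic overdispersion, but not real
phylogenetic correlation structure: lineages are synthetic labels drawn
from the dominant rumen phyla (Firmicutes, Bacteroidetes, ...), each ASV
its own genus. Note the compositional consequence exploited in the
examples: spiking one abundant taxon up genuinely pushes every other
relative abundance down, so a strong single spike produces legitimate
opposite-side hits.

**KO tables** (`FunctionSimSpec`): 300 KOs in 30 level-3 pathways (10
each, 5 level-3 per level-2), per-sample counts Poisson with
gamma-multiplied rates (CV 0.2), pathway effects as rate multipliers,
KO reference lengths uniform 500–3000 bp.

Same seed ⇒ byte-identical outputs, and ground truth is returned (and
written as a sidecar TSV) rather than re-derived by tests.

## Community metrics

* **Chao1** is the bias-corrected form S + F1(F1 − 1)/(2(F2 + 1)); the
  classic F1²/(2F2) variant is a flag. **Simpson** is reported as the
  Gini–Simpson index 1 − Σp². **Shannon** uses natural log, which cancels
  out of Pielou's H/ln S. Pielou is undefined (missing) at S = 1.
* **Rarefaction** is the analytic hypergeometric expectation
  E[S_n] = Σ_i [1 − C(N − N_i, n)/C(N, n)], computed with log-gamma for
  stability; counts are never rarefied before computing indices.
* **β diversity** defaults to Bray–Curtis; unweighted UniFrac (via
  scikit-bio) is used when a rooted tree is available. Features absent
  from the tree are a hard error listing the offenders.
* **PCoA** eigendecomposes the Gower-centered −D²/2 matrix directly;
  variance fractions are taken over positive eigenvalues only and
  negative eigenvalues (non-Euclidean dissimilarities) are reported
  unchanged rather than corrected.
* **NMDS** minimizes Kruskal stress-1 by monotone-regression descent
  (sklearn's SMACOF with nonmetric disparities), initialised from the
  PCoA configuration, max 300 iterations, stress tolerance 1e−7.
* **PERMANOVA** uses the standard pseudo-F from pairwise squared
  distances, R² = SS_between/SS_total, and the +1 permutation p-value
  convention; an exact enumeration mode over all label splits (n ≤ 16)
  serves as its own oracle. Degenerate all-zero distance matrices return
  p = 1 with an undefined F.

## Differential abundance

The screen collapses the original LEfSe class/subclass cascade to the
two-class case with no subclasses: per rank, Kruskal–Wallis (tie
corrected, χ² df = 1, with an exact enumeration option for pooled
n ≤ 10) → BH-FDR **within that rank** (features at different ranks are
nested, not exchangeable) → LDA effect size. The effect of feature j is
0.5(|Δm_j| + |ŵ_j (ŵ·Δm)|): the mean of its raw between-class mean
difference and its share of the discriminant-projected difference, with
ŵ the unit Fisher direction from the pooled within-class covariance
regularized by a trace-scaled ridge (necessary whenever features ≥
samples; deterministic). Effects are clamped at 1 before log10 so null
features score 0 rather than −∞. For a single feature the score reduces
exactly to the raw mean difference.

Abundances are normalized to one million per sample before scoring —
this is what makes "log10(LDA) > 3" mean "a ≥ 0.1% absolute shift in
relative abundance" and makes the screen sequencing-depth invariant.
Deterministic single-fit scoring is the default so identical inputs give
byte-identical tables; the original tool's 30-round, 2/3-subsample
bootstrap averaging is available behind a seed.

Spearman networks take the top-10 taxa by mean relative abundance
*within* each group, midrank-tied Spearman ρ, BH across the 45 pairs;
constant taxa yield missing entries rather than zeros.

## Function profiling

RPKM for *predicted* KO abundances is a convention, not a physical
quantity, and is pinned down as: length = the KO's reference gene length
from a supplied table, library size = the per-sample KO total, rpkm =
count × 10⁹/(length × library). Pathway abundance is the sum over member
KOs, with multi-pathway KOs counted in full in each pathway (the common
KEGG-rollup practice; aggregation is conservative exactly when the
mapping is a partition). Screening runs on RPKM values directly — the
per-million rescaling is disabled on this path, so "log10(LDA) > 1"
means a > 10 RPKM shift. Both the permissive (> 1) and strict (> 2)
cuts are exposed because both are in common use.

## Problem sizes and determinism

Validation experiments run at 60 cows × 3 sessions for phenotyping and
30 + 30 samples × 200 taxa × 20 000 reads for community screens, with 50
replicates for calibration — sizes at which every contract checked is
stable across seeds while the whole suite stays interactive. All
randomness flows through explicit integer seeds (numpy `default_rng`);
PERMANOVA, NMDS, the bootstrap and every simulator are reproducible
bit-for-bit under a fixed seed, and the pipeline manifest records file
checksums to prove it.

## Known limitations

* The phenotype is a methane *column density* proxy (ppm × m), not an
  emission rate; no conversion to g/day is attempted.
* The LEfSe reimplementation is two-class only; no subclass
  stratification, no multi-class one-vs-all.
* Unweighted UniFrac requires a user-supplied rooted tree; no tree
  inference, no weighted UniFrac.
* The simulators do not emulate chimeras, contamination, batch effects
  or archaeal communities; calibration results on them bound, but do not
  guarantee, behavior on real sequencing runs.
* Compositionality is handled by convention (per-million / RPKM), not by
  log-ratio methods; strong spikes necessarily ripple into other taxa.
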