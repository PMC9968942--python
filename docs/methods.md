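# Methods

`gutassembly` analyses a leveled (rarefied) OTU table from a two-site
microbial survey — the motivating design is fecal 16S data from two primate
populations in habitat fragments of different quality — and quantifies how
the communities differ (diversity, composition, discriminability) and how
they assemble (stochastic vs deterministic, via the Sloan neutral model).
This note records the models, conventions, parameter choices and known
limits of each stage.

## Data model and leveling

The single source of truth is an integer count matrix oriented taxa ×
samples, with one six-rank lineage (domain…genus) per OTU and one metadata
row (`site`, `social_group`) per sample. Placeholder taxonomy labels
(`norank_…`, `unclassified_…`) are ordinary labels: family-level analyses
must be able to report rows such as `norank_o__Clostridia_UCG-014`
verbatim, so nothing is ever coerced to missing below the domain rank.

Leveling subsamples every sample, without replacement, to a common depth —
a multivariate hypergeometric draw per sample, seeded and reproducible.
Sampling without replacement is what "leveling" means operationally: reads
are removed, never duplicated, so rarefied counts never exceed the
originals and the expected rarefied count is `original × depth/total`.
Survey pipelines sometimes describe leveling "twice"; whether that means
two independent draws averaged or a re-leveling after domain filtering is
not well defined, so the package does one rarefaction to the minimum depth
by default and exposes `rarefy_rounds` (pipeline) /
`mean_alpha_over_rounds` to average index estimates over repeated draws for
users who want the literal reading. Neither reading changes any
downstream contract.

## Alpha diversity

Per-sample indices follow the mothur conventions common in mammal-gut 16S
work:

* Shannon `H = −Σ p_i ln p_i` in natural log (a `shannon_base` argument
  exists; default is e because published langur-gut values of ~4.8–5.0 on
  ~3,000 OTUs are only consistent with nats);
* inverse Simpson `1/Σ p_i²`;
* Chao1 in the bias-corrected form `S_obs + n₁(n₁−1)/(2(n₂+1))`, which is
  defined even with no doubletons (it can differ from uncorrected mothur
  output exactly when n₂ = 0);
* ACE with the standard rare/abundant cutoff of 10 reads and the γ²
  heterogeneity term floored at 0; when every rare taxon is a singleton the
  estimator's coverage term is zero and ACE is reported as NaN rather than
  an arbitrary fallback;
* Good's coverage `1 − singletons/reads`.

Rarefaction curves are Monte-Carlo means over seeded subsampling
replicates; for observed richness an analytic alternative is available
(`method="exact"`): `E[S_obs(d)] = Σ_i (1 − C(N−N_i, d)/C(N, d))`, computed
in log-gamma space. The analytic curve is exactly monotone in depth and is
the oracle the Monte-Carlo path is tested against.

The intersite comparison fits a Gaussian linear mixed model to
`log10(index)` — site as the fixed factor, social group as a random
intercept — and tests the site effect by a likelihood-ratio test against
the intercept-only model, both fitted by maximum likelihood (not REML, so
the likelihoods are comparable across fixed-effect structures); the LRT
statistic is referred to χ²(1). The log10 transform is applied exactly as
stated; the indices are bounded below by 1 (or by 0 for coverage, which is
not compared this way), so no offset is needed. The response is
continuous, hence the Gaussian LMM; if the mixed fit fails (singular
random-effects structure), the result degrades to a Wilcoxon rank-sum
p-value and is flagged via its `method` field. With few clusters the χ²(1)
reference is asymptotic; the calibration tests use 10 social groups, and
users with fewer groups should treat p-values near the threshold with
care.

## Beta diversity

Bray–Curtis dissimilarity `d(x,y) = 1 − 2Σmin(x_i,y_i)/(Σx+Σy)` is computed
on counts; at uniform post-leveling depth this equals the proportion-based
form exactly. PCoA double-centers the squared distances (Gower), takes the
eigendecomposition, and scales eigenvectors by the square root of positive
eigenvalues. Negative eigenvalues — expected for Bray–Curtis, which is not
Euclidean-embeddable — are reported as-is and excluded from the
proportion-explained denominator (denominator = sum of positive
eigenvalues); a Cailliez additive correction is available behind a flag for
users who need a fully Euclidean embedding. Ordination needs at least
three samples.

PERMANOVA is the one-factor Adonis test: `SS_total = Σ_{i<j} d²/n`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`, pseudo-F from the between/within mean
squares, and a permutation p-value over unrestricted label shuffles with
the +1 correction — 999 permutations by default, giving the conventional
p-floor of 0.001. Permutations are unrestricted (no strata), matching a
plain one-factor Adonis call. Groups of one sample are rejected.

## Composition, differential abundance, F/B

Composition summaries report per-site mean ± SD relative abundance at a
rank, pooling taxa whose overall mean is below 1% into an "others" bucket.
Differential abundance uses the two-sided Wilcoxon rank-sum (=
Mann–Whitney U) per taxon on relative abundances — exact p-values when both
sites have ≤ 8 samples, the tie-corrected normal approximation otherwise —
with Benjamini–Hochberg correction across the taxa at the tested rank
(Bonferroni and Holm available). "Corrected p-values" in survey-platform
output rarely names the procedure; BH is the default here because it is
the common platform default and the FDR interpretation suits exploratory
taxon screens. Taxa constant across all samples get p = 1 and a flag.

The Firmicutes/Bacteroidetes ratio is reported under both conventions —
ratio of (sample-size-weighted) mean relative abundances, and mean of
per-sample ratios — because published per-site and overall F/B values are
generally not derivable from a single convention. A zero Bacteroidetes
mean yields an explicit infinity with a warning, never a silent NaN.

## Sloan neutral community model

For a taxon with metacommunity relative abundance `p`, local community
size `N` (reads per sample after leveling) and migration rate `m`
(probability that a local death is replaced by an immigrant), the Sloan
continuous approximation gives the local relative abundance a
Beta(Nmp, Nm(1−p)) distribution, so the probability of detecting the taxon
above the detection limit `d` is

    freq_pred(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p)).

The package estimates the composite `Nm` by bounded nonlinear least
squares of `freq_pred` against observed occurrence frequencies over all
detected taxa, with `p` estimated as the mean relative abundance across
samples and `d = 1/N` (configurable). Three log-spaced starts guard
against flat SSE profiles; `Nm` is bounded in (0, 10N]; a non-convergent
fit raises an error carrying the SSE-vs-Nm profile. `R² = 1 − SS_res/SS_tot`
on the frequencies is read as the stochastic share of assembly (1 − R²
deterministic); it may be negative when the neutral curve fits worse than
a constant and is reported as-is, never clipped. The 95% band around the
prediction uses Wilson score intervals with n = number of samples (robust
at frequencies near 0 or 1, mirroring the binconf-based implementations of
this analysis); taxa above the band are candidates for positive selection,
below for negative selection, and the three partition fractions sum to 1.
Taxa observed in no sample are excluded (they carry no occupancy
information); taxa present in every sample are retained. The model is fit
per site by default (each site is one host population with its own
metacommunity), with a pooled fit also available. OTU tables below ~50
taxa or ~10 samples trigger a warning rather than an error.

API shape: `NeutralCommunityModel.from_table(table).fit()` returns an
`NcmResults` with estimates, per-taxon records, partition proportions and
a `summary()` table, in the model/results idiom of statistical packages.

## Random-forest discrimination

Features are relative abundances at the chosen rank, columns in canonical
sorted order so importances never depend on incoming row order. The
protocol is: stratified 70/30 train/test split; 500 trees (the "many
trees" convention, recorded in the output); Gini (mean decrease in
impurity) importances from the forest trained on the training split, with
rank 1 = most important; held-out AUC from test-set class probabilities;
and a repeated stratified 10-fold × 5 cross-validated AUC on the full data
reported alongside, since published AUCs are sometimes the one and
sometimes the other. Class imbalance (the 155 vs 48 design) is handled by
stratification only — no resampling. The split, the folds and the forest
all derive from one seed. If the smallest class has fewer samples than
folds, the call errors with advice rather than silently producing
undefined fold AUCs.

ROC/AUC uses the standard threshold sweep and trapezoid rule; the AUC
equals the Mann–Whitney U statistic divided by `n_pos·n_neg`, an identity
the tests exploit as an oracle.

## Synthetic data: what it emulates and what it does not

Two generators provide ground truth for every downstream stage.

**Neutral communities.** Each taxon × sample local relative abundance is a
Beta(Nmp_i, Nm(1−p_i)) draw; the metacommunity `p` defaults to a
normalized log-normal (σ = 1.5), giving the long abundance tail the NCM
fit needs. Turning the Beta draws into integer counts is where a modelling
choice hides: Sloan's Beta describes the composition of the N-individual
local community itself, so the default (`count_model="quantize"`)
apportions exactly N reads deterministically (floor plus largest
remainder, restricted to taxa above the 1/N detection limit), making
presence in the table exactly the event `x > 1/N` that the occupancy
formula describes — the community is then neutral *as the fitter sees it*,
and the migration rate is recoverable (median relative error ≲ 8% at
m ∈ {0.05, 0.1, 0.3} with 2,000 taxa × 100 samples × N = 1000).
Alternatives are kept behind the flag: `"multinomial"` (one
Multinomial(N, ·) read sample per host; realistic sequencing noise, but
the extra observation layer smooths detection and inflates fitted Nm by
~15–60% over this m range) and `"binomial"` (textbook per-taxon
Binomial(N, x), depth varies around N). Calibration results obtained under
"quantize" therefore speak to the fitter's correctness, not to how much
sequencing noise biases NCM fits on real data — the multinomial flag
exists precisely to study that.

**Two-site surveys.** Site B taxon weights are `base × exp(effects)`;
each social group perturbs every taxon's log-weight by N(0, group_sd);
each sample's composition is Dirichlet(θ × weights) and its counts one
multinomial draw at uniform depth. Defaults mirror the motivating study
design: 3,000 taxa, 155 vs 48 samples, nine social groups (5 + 4),
uniform depth 20,000 reads (a typical post-leveling depth for ~55k-read
16S libraries), θ = 50 (strong sample-to-sample compositional noise, as
mammal-gut surveys show), group_sd = 0.3 (moderate group signatures),
log-normal σ = 1.5 base abundances. With zero effects and zero group_sd
the sites are exchangeable, which the calibration tests rely on.

Neither generator produces phylogenetic structure, taxon–taxon
correlations beyond the compositional constraint, seasonality, or
covariate-driven effects; synthetic lineages are random assignments from a
Firmicutes-dominated phylum pool. Passing tests therefore demonstrate that
the estimators, tests and the NCM fitter are correct and calibrated under
their stated assumptions — not that real langur-gut effect sizes or the
published headline numbers are reproduced, which would require the
original 203-sample sequencing data.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; module order cannot change draws.
* Rarefaction deeper than a sample's total, empty depth grids, single-site
  factors, single-sample PERMANOVA groups, single-class ROC input, all-equal
  NCM abundance vectors, and domain filters that empty the table raise
  errors naming the offending object.
* BH-corrected p-values are clipped to [raw p, 1]; the BH step-up is
  monotone in the raw p-values by construction.
* PCoA treats eigenvalues within `1e-9·|λ₁|` of zero as zero.
* The NCM band uses α = 0.05 throughout; partition labels are derived from
  the same interval the records carry, so they cannot disagree.

## Problem sizes used by the test suite and acceptance script

Simulation sizes are the package's own choices to make the checks sharp
but quick: NCM recovery uses 2,000 taxa × 100 samples × N = 1000 × 10
seeds per migration rate; LMM type-I uses 200 replicates of a 50-sample,
10-group null survey (acceptance script: 100); PERMANOVA type-I 500
replicates of a 24-sample null (script: 300) at 199 permutations; BH
calibration 200 replicates of 200 null taxa (script: 100); RF null 20
seeds (script: 10); planted-signal power 50 replicates (script: 30) of a
log-fold-2 effect on a ~1%-abundance taxon. The full-scale study-shaped
defaults (3,000 taxa, 203 samples, depth 20,000) run through the same code
paths via the pipeline and CLI.

## Known limitations

* The NCM fit assumes a single well-mixed metacommunity per fitted table
  and a uniform detection limit; non-uniform depth is handled by a mean-N
  fallback with a warning, not by per-sample limits.
* The LMM p-values rely on χ²(1) asymptotics; with very few social groups
  they can drift from nominal.
* Exact rank-sum p-values are used only up to 8 samples per side; beyond
  that the tie-corrected normal approximation is standard but approximate.
* ACE is undefined (NaN) when all rare taxa are singletons.
* The pipeline's report cache is keyed by the config hash only; editing
  input files in place without changing the config requires clearing the
  output directory.
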