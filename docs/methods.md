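# Methods

## Scope and flow

The pipeline runs in four stages on a species-level trait table (species,
clade, reproductive mode, body mass in g, measurement temperature in °C,
SMR in ml O₂/h) and a rooted newick phylogeny:

1. **Corrections** — joint least-squares fit of ln SMR = lnB₀ + b·lnM − E/kT,
   then tSMR = lnSMR + E/kT and mSMR = lnSMR − b·lnM.
2. **Scaling fits** — tSMR ~ lnM and mSMR ~ 1/kT under each requested λ
   policy (0, 1, ML), compared by AIC and a likelihood-ratio test.
3. **Factorial ANOVAs** — sequential-SS PGLS models
   tSMR ~ R×G×lnM and mSMR ~ R×G×(1/kT).
4. **Path analysis** — d-separation tests of candidate causal DAGs over
   {M, SMR, G, R, 1/kT}, Fisher's C, CICc ranking, conditional averaging.

## Model and estimation choices

**Corrections.** The temperature/mass corrections need values for b and E.
Two conventions are possible: fixing them at the canonical metabolic-theory
values (0.75, 0.65 eV) or estimating them from the data. The default is
joint estimation by the two-predictor linear model on natural-log SMR —
the only self-contained choice — with `fixed_b` / `fixed_E` options for
sensitivity analysis. E carries the sign convention that E > 0 means rates
rise with temperature. Natural logarithms throughout; temperatures
converted with +273.15; Boltzmann's constant in eV K⁻¹.

**PGLS.** The Brownian covariance has entry (i,j) equal to the shared
root-to-MRCA path length. Pagel's λ multiplies only the off-diagonal. All
fits are maximum likelihood, never REML, so log-likelihoods are comparable
across fixed-effect structures and between OLS and PGLS. The ML scale is
σ² = r′V⁻¹r/n; coefficient standard errors use the unbiased scale
(RSS/(n−p)) so the V = I case reproduces OLS output exactly. r² is computed
in the whitened space against the GLS-intercept null. AIC counts the
coefficients, the scale, and λ as one extra parameter when estimated (not
when fixed at 0 or 1).

**λ optimization.** A 101-point grid on [0,1] locates the profile-ML
optimum; a bounded scalar search between the neighbouring grid points
refines it to 1e-8, with ties broken toward smaller λ (the grid argmax
takes the first maximizer). The 95% CI is the profile set
{λ : lnL(λ) ≥ lnL(λ̂) − 1.92}, with crossings located by root finding
between grid points. A covariance that loses positive definiteness (e.g.
after λ-transforming a tree with zero-length tip branches) is regularized
by adding 1e-10 to the diagonal, with a logged warning.

**ANOVA.** Type-I (sequential) sums of squares in the whitened space, term
order: R, G, covariate, R×G, R×cov, G×cov, three-way. Binary factors are
0/1-coded (reference levels lizard, oviparous) so group coefficients read
as "snake effect" and "viviparity effect". Each term is one column (1 df);
F uses the full model's residual mean square. Under the "ml" policy λ is
estimated once, on the full model, and reused for the whole sequence.

**Path analysis.** The basis set holds one claim per non-adjacent vertex
pair, conditioned on the union of both vertices' parents. The regression
response is the vertex that is not a causal ancestor of the other; when
neither is an ancestor, the later vertex in a deterministic topological
order (ties broken by declared vertex order) responds. This matters
because the claim p-value is not symmetric in u and v. The parameter count
is q = edges + vertices — the unique rule consistent with the published
nine-model (k, q) table, where every row satisfies k + q = 15 for five
variables; implementations of this method vary on the rule, so it is
stated prominently here. Binary variables are 0/1-coded and modeled with
Gaussian PGLS in claim tests and path fits alike, mirroring the behaviour
of the R package commonly used for this analysis; this is an approximation
for discrete characters and is logged as such. Path coefficients are
standardized (z-scored variables); default intervals are Wald
(±1.96 SE) because they are deterministic, with an optional seeded
nonparametric row bootstrap for sensitivity (the resampling ignores the
phylogenetic covariance and is labeled accordingly). Conditional model
averaging over models with ΔCICc ≤ 2: each edge is averaged over the
contributing models that contain it, with CICc weights renormalized over
that subset.

**Candidate DAGs.** The published figure defining the nine candidate
structures is graphical and its topologies are not recoverable from text.
The shipped default set is therefore a *reconstruction*: it reproduces the
published edge-count signature (4,4,5,5,6,6,7,7,7 edges for models
one–nine), keeps M→SMR in every candidate, and centres on the averaged
best-model paths (M→SMR, SMR→G, SMR→R, 1/kT→SMR, 1/kT→R, 1/kT→M). Any
other set can be supplied as a text config.

## Synthetic data

The generator emulates the generative model the analysis assumes: a
pure-birth (or star) tree; lnM uniform on (−0.9, 9.7) ln g (the 0.4 g –
16.15 kg span of the empirical compilation); temperature uniform on
20–40 °C, drawn independently of clade by default; clade and parity as
symmetric two-state Markov characters (switch rate 0.5 per unit branch
length, giving a few expected transitions per root-to-tip path and hence
phylogenetically clustered groups); and

  lnSMR = lnB₀ + b·lnM − E/kT + δG·[snake] + δR·[viviparous] + ε,

with ε Brownian noise λ-transformed at λ_sim and scaled so its marginal
standard deviation equals `noise_sd`. Defaults: b = 0.75, E = 0.65 eV
(metabolic-theory canon; the study prints neither), lnB₀ = 23 (puts SMR
near 5 ml O₂/h for a 100 g animal at 30 °C), λ_sim = 0.6, noise 0.3,
δG = −0.2, δR = −0.15 (negative, matching the direction of the published
group differences; magnitudes are placeholders for power analysis, not
estimates of the real effects). Group effects enter lnSMR additively —
multiplicatively on SMR — which makes the factorial ANOVA the correct
analysis for the generated data.

A `composition` option reproduces the published group counts exactly
(80/35 oviparous/viviparous lizards, 48/33 snakes; 196 species, 128
oviparous) by thresholding latent Brownian values at the required ranks,
which preserves phylogenetic clustering while fixing the margins. What the
generator does *not* emulate: realistic life-history covariation between
mass, temperature and clade; measurement error in SMR; non-ultrametric or
calibrated trees. Passing tests therefore demonstrate correctness of the
machinery under the assumed model, not robustness to empirical
messiness.

## Numerical and degenerate-input notes

- Absent newick branch lengths default to 1, consistent with the
  equal-branch-length analysis mode (`set_branch_lengths_equal`).
- Species matching is exact after trimming and space→underscore; no fuzzy
  joins. Records with missing fields are rejected, never imputed.
- Polytomies are accepted as-is.
- Exactly noise-free data makes SMR an exact linear function of (lnM,
  1/kT), so the path-analysis regressions are rank deficient; the pipeline
  exposes `include_paths=False` for that corner rather than regularizing.
- The pooled t-test errors on zero pooled variance with unequal means and
  returns t = 0, p = 1 for identical constant groups.
- Fisher's C with any p = 0 returns (∞, 0) with a warning.
- On a unit-branch-length tree, tip–tip distances are whole edge counts:
  integers ≥ 2, even only when the two tips are equally deep below their
  MRCA.

## Problem sizes

The test suite verifies recovery at the study scale where the guarantee is
about that scale (n = 196–200; 100 replicates for λ recovery and ANOVA
power, 50 for full-pipeline recovery and model selection, 500 for the
Fisher's-C calibration) and uses 10–60 species elsewhere, keeping the
suite under a few minutes on one core.

## Known limitations

- Gaussian PGLS for binary endpoints (G, R) is an approximation; a
  threshold/phylogenetic-logistic model is out of scope.
- Only Brownian/λ correlation structures; no OU, κ or δ transforms, no
  measurement-error models, no REML.
- The λ CI is a profile-likelihood interval; boundary estimates (λ̂ = 0 or
  1) make the likelihood-ratio test of λ conservative.
- The default candidate-DAG set is a reconstruction (above), not the
  canonical published set.
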