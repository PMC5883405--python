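# squamet

Phylogenetic comparative analysis of maintenance metabolism in squamate
reptiles: do body plan (lizard vs snake) and reproductive mode (oviparous
vs viviparous) predict standard metabolic rate once body mass, measurement
temperature, and shared evolutionary history are controlled?

The package is written for comparative physiologists and methods-minded
evolutionary biologists. It implements the full analysis chain as a tested,
reusable library plus a small CLI, and ships a seeded synthetic-data
generator so every stage can be verified without access to any particular
empirical compilation.

## The model

Standard metabolic rate (SMR, ml O₂/h) is modeled with the
allometric–Arrhenius equation of metabolic theory:

    ln SMR = ln B₀ + b·ln M − E·(1/kT)

with `M` body mass (g), `T` absolute temperature, `k` Boltzmann's constant
(8.617×10⁻⁵ eV K⁻¹), `b` the allometric exponent, and `E` the activation
energy (eV). From a joint least-squares fit of (ln B₀, b, E) the two
corrected rates are

- **tSMR** = ln SMR + E/kT (temperature removed), regressed on ln M;
- **mSMR** = ln SMR − b·ln M (mass removed), regressed on 1/kT.

Group differences are assessed with phylogenetic generalized least squares
(PGLS): the error covariance is the Brownian shared-path-length matrix **V**
of a rooted phylogeny, with Pagel's λ scaling its off-diagonal
(λ = 0 independence, λ = 1 full Brownian structure), estimated by profile
maximum likelihood. OLS and PGLS fits are compared by AIC and a likelihood
ratio test; the factorial models `tSMR ~ R × G × lnM` and
`mSMR ~ R × G × (1/kT)` are tested with sequential (Type-I) sums of squares
in the whitened space.

Directionality is explored with confirmatory path analysis: each candidate
causal structure (a DAG over M, SMR, G, R, 1/kT) implies a d-separation
basis set of independence claims, each tested by one PGLS regression. The
claim p-values combine into Fisher's C = −2Σln p (χ² with 2k df under the
model), and candidates are ranked by the C-statistic information criterion
CICc = C + 2qn/(n−1−q) with q = edges + vertices; models within ΔCICc ≤ 2
are averaged with evidence weights exp(−Δ/2)/Σexp(−Δ/2).

## Worked example

Generate a 60-species synthetic dataset (λ_sim = 0.6, noise 0.3) and fit
the two scaling relationships with ML-λ PGLS:

```sh
squamet simulate --n 60 --seed 11 --out example/
squamet fit --traits example/traits.csv --tree example/tree.nwk --lambda ml
```

```
         model lambda_policy  n  slope    se    r2  lambda  lambda_lo  lambda_hi    aic     lnL        F  F_df1  F_df2     P
tSMR ~ ln_mass            ml 60  0.766 0.012 0.985   0.599      0.054      0.944 33.326 -12.663 3843.855      1     58 0.000
 mSMR ~ inv_kT            ml 60 -0.581 0.055 0.656   0.492      0.037      0.903 33.809 -12.905  110.499      1     58 0.000
```

The tSMR slope (0.766 ± 0.012) recovers the generating allometric exponent
b = 0.75; the mSMR slope (−0.581 ± 0.055) estimates −E, close to the
generating activation energy E = 0.65 eV; and λ̂ ≈ 0.6 recovers the
simulated phylogenetic signal. `squamet anova`, `squamet paths` and
`squamet all` run the factorial ANOVAs, the nine-candidate path analysis,
and the full report bundle (five TSV tables + JSON sidecars + run log).

The shipped nine-candidate DAG set is a labeled *reconstruction*: it
matches the published candidates' independence-claim/parameter signature
(k + q = 15 per model) but the exact published topologies are not
recoverable, so a custom set can be supplied as a text config
(`M -> SMR` lines, one named block per model).

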