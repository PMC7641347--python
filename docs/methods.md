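# Methods

This note documents the models and procedures `deepedna` implements, the
defaults it ships with and why, what the synthetic-data generators do and
do not emulate, and the numerical choices that make the results exactly
reproducible.

## Taxonomy assignment

Assignment works on similarity-search hits against a reference database,
joined offline to a seven-rank lineage table (kingdom → species). Using a
static lineage table rather than live database lookups keeps the pipeline
deterministic and testable: reference snapshots change, a delimited table
does not.

Each hit is scored by the **selection criterion**: percent identity ×
percent overlap / 100, so the score shares the 0–100 scale of its
factors. *Overlap* is read as query coverage, `min(100, 100·align_len /
query_len)` — the standard reading for short amplicons, where the query
is expected to sit entirely inside the reference; gapped alignments can
make the alignment longer than the query, hence the cap. Hits with
e-value above 0.001 are discarded at read time.

For each ESV: only the best hit per subject taxon is kept (so a taxon
with many database entries cannot manufacture a "tie" with itself); the
maximum score defines the tied set (ties within `tie_tol = 1e-9`, i.e.
exact ties only — search tools report identity to three decimals, so
genuinely distinct scores differ by ≥ 5·10⁻⁴); the tied lineages collapse
to their lowest common ancestor; and the lineage is truncated to the
deepest rank permitted by the score: species at 100 (within the same
tolerance), genus at ≥ 98, family at ≥ 95, all inclusive. Below 95 the
call is reported above family rank only. Whether ties should instead be
judged on bitscore is genuinely unsettled; the implementation ties on the
selection criterion, and the threshold/tie machinery is configurable via
`Thresholds`.

Spurious-hit removal (terrestrial or domestic taxa appearing in deep-sea
water) is blocklist-driven and off by default: the curation step it
replaces is a manual register lookup that cannot be automated offline.

## Depth strata and summaries

Samples stratify as shallow (< 500 m), mid (500–1400 m, both endpoints
included, matching the interval notation the strata are defined with) and
deep (> 1400 m). "Fish" means class Actinopteri or Chondrichthyes, and
group membership additionally requires a selection score ≥ 90 so marginal
matches do not inflate group counts ("metazoan" analogously, kingdom
Metazoa). A taxon is *detected* in a sample when at least one read of one
of its ESVs is present (no minimum-read filter is applied by default —
one is configurable — because presence/absence is the analysis currency
downstream); control samples (field and lab blanks) are excluded from
every statistic. Detection tables report each taxon at its assigned rank:
a genus-level row and a species-level row of the same genus are distinct
rows, and sample counts pool across markers.

## Rank-based robust ANOVA

The volume × depth comparisons use a rank-based linear model rather than
classical least squares because DNA-yield data are skewed with occasional
extreme values. Coefficients minimize Jaeckel's dispersion with Wilcoxon
scores; the model is additive (volume + depth category) by default, with
the interaction available by flag — per-factor tests are the target
inference, and the estimable interaction cells in an unbalanced field
design are fragile. Factor tests are drop-in-dispersion F-statistics
F = (RD/q)/(τ̂/2) referred to F(q, n−p−1).

**Scale estimation.** τ = (√12 ∫f²)⁻¹ is estimated from fitted residuals:
∫f² equals the density of a difference of two independent errors at zero,
estimated by a Gaussian kernel over all pairwise residual differences
with a Silverman-type bandwidth 0.9·min(sd, iqr/1.349)·n^(−1/5), times
the usual √(n/(n−p−1)) degrees-of-freedom correction. Null simulations
(1000 replicates, n = 60, 2×3 design) put the test's size at ~0.04 at
α = 0.05 — slightly conservative, inside the 0.03–0.07 calibration band
the test suite enforces.

**Numerical definition of the estimator.** The dispersion is piecewise
linear in β, so its minimizing set can be a flat polytope — two correct
minimizers can disagree on coefficients while agreeing on the minimum. The
estimator is therefore defined as the minimizer of
D(β) + λ‖β − β_LS‖² with λ = 10⁻⁵·(1 + D(β_LS)): the unique point of the
optimal face closest to the least-squares fit. λ is large enough that the
tie-break is resolvable above floating-point noise and small enough that
kink-constrained estimates move by far less than any statistical
tolerance. The problem is solved exactly via the pairwise-difference
identity D(β) = √12/(2(n+1)) Σ_{i<j} |Δy − Δx′β| by smoothing Newton
(|r| → √(r²+ε²), ε driven to 10⁻¹² of the data scale), which converges to
machine precision; the test suite cross-checks it against an independent
ADMM solver to 10⁻⁴.

**Post-hoc comparisons** merge two factor levels and re-test by drop in
dispersion, so the single comparison of a two-level factor reproduces the
factor's ANOVA test exactly; estimates and standard errors come from the
coefficient covariance τ̂²(X′X)⁻¹, and p-values are Holm-adjusted (the
adjustment is a choice — the analysis this mirrors names only a package,
not a correction). Levene's test is the classic mean-centred one-way
ANOVA on absolute deviations, with the Brown–Forsythe median option.

## Occupancy model

Detections form a binary array y[k, i, j, m] — taxon, site (station ×
sampling depth), water-sample replicate, marker. The hierarchy separates
occupancy ψ (depth as a standardized covariate on the logit scale),
per-sample availability θ, and per-marker detection p:

- z_ik ~ Bern(ψ_ik), logit ψ_ik = β0_k + β1_k·std(depth_i)
- a_ijk | z ~ Bern(z_ik·θ_k)
- y_ijmk | a ~ Bern(a_ijk·p_mk), logit p_mk = α_mk

Taxon-level parameters draw from community normal hyperpriors — per
marker for α, so each primer set has its own community mean and spread —
with Normal(0, 2²) hyperpriors on the means and Half-Normal(1) on the
SDs: weakly informative on the logit scale (±2 logits covers detection
probabilities 0.12–0.88) and configurable. θ carries no covariates.
Depth is standardized before entering the linear predictor; the depth
slope is reported on the standardized scale with the site depths stored
alongside for back-transformation.

**Sampler.** Latent-state augmentation gives closed-form Bernoulli full
conditionals for z and a; logit-scale coefficients update by adaptive
random-walk Metropolis (target acceptance 0.44, adaptation frozen after
burn-in); community means are conjugate normal draws and community SDs
random walks on the log scale. With few replicates per sample, θ_k and
α_·k are only weakly separately identified and the posterior has a long
anti-correlated ridge, so the sampler adds a per-taxon joint move that
raises availability while lowering detection in tandem; without it the
axis-aligned updates under-explore the ridge and interval estimates are
overconfident. Convergence is summarized by rank-normalized split R-hat
and effective sample size (via arviz); any parameter with R-hat ≥ 1.1
flags the fit, loudly but without discarding it.

**Validation.** On simulated surveys of 20 taxa × 30 sites × 3
replicates × 3 markers (the scale of a multi-station field campaign),
5000 post-burn-in draws × 4 chains recover per-marker community detection
means within ~0.1–0.2 logits and give ~90–93% realized coverage of
taxon-level α at nominal 95% — the shortfall is Monte-Carlo variation
across correlated parameters plus hierarchical shrinkage of extreme taxa,
and the test suite enforces the 90–100% band. Fixing θ = p = 1 reproduces
naive occupancy (posterior mean ψ within 0.02 of the observed occupied
fraction at 200 sites), the analytic perfect-detection limit.

**Missing data.** A water sample never amplified with a marker yields
missing cells (identical across taxa by construction); missing cells
contribute nothing to the likelihood, and availability indicators at
fully unobserved replicates are genuine prior draws, which keeps the
augmented chain consistent.

## Synthetic-data generators

The generators emulate the *design* of a two-season deep-sea survey: 7
small-volume (0.25 L) stations and 10 large-volume (1.5 L) stations,
each sampled at the surface, the deep scattering layer (360–536 m) and
just above the bottom (500–3000 m), in triplicate, with one field blank
per station. DNA concentration follows
baseline + 60·1[1.5 L] − 15·1[deep] + N(0, 15²), clamped at zero
(concentrations are non-negative; with these defaults the clamp is rare),
in pg/µL. The volume effect is deliberately large — a four-SD shift, the
regime the design targets — so closed-loop power checks reach ≥ 95%
rejection; the depth effect is one SD. Hit tables are simulated *at the
score level* (identity/overlap pairs engineered to land in chosen
threshold strata, with decoy hits and optional congener ties), not by
aligning sequences: no sequence evolution, chimeras or read-level noise
are modelled. Detection histories are drawn forward from the occupancy
hierarchy with community means (0.5, 0, −0.5) logits across three
markers — detection probabilities ~0.38–0.62, the range where occupancy
modelling is informative — and availability mean 1.5 logits (~0.82).

Passing closed-loop tests therefore demonstrates that the pipeline
recovers truth *under its own model assumptions and design*; it does not
validate against sequencing artefacts, reference-database gaps, taxonomic
mislabelling or spatial autocorrelation, none of which the generators
emulate.

## Reproducibility

Every stochastic routine takes an explicit seed and uses an isolated
`numpy` generator; chains spawn per-chain seeds from one seed sequence.
Identical seed and configuration give byte-identical CLI outputs and
identical posterior draws. The acceptance script derives all of its seeds
from a single `--seed` argument.

## Known limitations

- The occupancy model ignores year/volume effects on availability and any
  spatial structure among stations; sites are exchangeable given depth.
- τ̂ is a kernel estimator, not a line-by-line port of any existing
  implementation; its small-sample behaviour is certified by the
  calibration band, not by equivalence to another package.
- The assignment rule trusts the lineage table; mislabelled references
  propagate directly into calls (mitigated only by the blocklist).
- Detection above ~0.95 or below ~0.05 per marker leaves the data nearly
  uninformative about θ, and the θ/α ridge then mixes slowly even with
  the joint move; the R-hat flag is the guard rail.
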