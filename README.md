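# deepedna

Analysis pipeline for **deep-sea eDNA metabarcoding surveys of fish
communities**. Environmental DNA filtered from seawater is amplified with
several PCR primer sets, sequenced, and denoised into exact sequence
variants (ESVs); this package takes over from there. It is written for
molecular ecologists who have ESV tables and similarity-search results in
hand and want reproducible taxonomy assignment, diversity summaries and
the survey-design statistics appropriate to a depth-stratified,
multi-marker water-sampling campaign (surface / deep-scattering-layer /
bottom casts down to ~2500 m, in triplicate, at two filtered volumes).

## What it computes

**Taxonomy assignment (selection criterion + LCA).** Each similarity hit
is scored by the *selection criterion* — percent identity × percent
query–reference overlap, on a 0–100 scale. The top-scoring hits (exact
ties) are collapsed to their lowest common ancestor, and the lineage is
truncated to the deepest rank whose threshold the best score meets:

| assigned rank | minimum selection score |
|---------------|------------------------|
| species       | 100 (perfect match)    |
| genus         | ≥ 98                   |
| family        | ≥ 95                   |
| above family  | otherwise              |

**Diversity summaries.** Per-sample ESV richness; per-marker rank
resolution (how many fish ESVs were named at family / genus / species);
taxon-by-depth detection tables over the shallow (< 500 m), mid
(500–1400 m) and deep (> 1400 m) strata; and eDNA-vs-conventional-survey
overlap counts. A transcription of a published Labrador Sea survey's fish
detection table ships in `deepedna.datasets` as a worked reference.

**Rank-based robust ANOVA.** Volume and depth effects on DNA yield and
ESV richness are tested with a rank-based linear model: coefficients
minimize Jaeckel's dispersion with Wilcoxon scores,
D(β) = Σᵢ a(R(eᵢ)) eᵢ with a(i) = √12 (i/(n+1) − ½), and factors are
tested by drop-in-dispersion F-statistics F = (RD/q)/(τ̂/2). Levene's
test covers variance homogeneity; Holm-adjusted pairwise contrasts cover
post-hoc comparisons.

**Multi-species, multi-scale occupancy model.** Detection/non-detection
of each taxon per site, water-sample replicate and primer set is modelled
hierarchically,

```
z_ik  ~ Bernoulli(ψ_ik),      logit(ψ_ik) = β0_k + β1_k · depth_i
a_ijk ~ Bernoulli(z_ik θ_k)                (availability in sample j)
y_ijmk ~ Bernoulli(a_ijk p_mk), logit(p_mk) = α_mk  (detection by marker m)
```

with community normal hyperpriors on the taxon-level parameters (per
marker for α). The posterior is sampled by a latent-state Gibbs/Metropolis
sampler; `inv-logit(μ_αm)` gives each primer set's community mean
detection probability, the quantity used to compare primer sets while
accounting for false negatives.

**Synthetic data.** `deepedna.simulate` generates every input with known
ground truth — taxonomies with congeneric pairs, hit tables with scores
placed in chosen threshold strata, metadata with volume- and
depth-structured DNA concentrations, and detection histories drawn from
the occupancy hierarchy — so every stage is testable closed-loop.

## Worked example

```python
import collections
import numpy as np
from deepedna import simulate, taxonomy, diversity, robust, occupancy
from deepedna.io import HitRecord

# --- assign taxonomy to simulated ESVs ------------------------------------
tax = simulate.make_taxonomy(n_families=6, genera_per_family=2, species_per_genus=2)
truth = {f"esv{i:03d}": key for i, key in enumerate(tax)}
hits_df, expected = simulate.make_hit_table(truth, tax, seed=42)
groups = collections.defaultdict(list)
for r in hits_df.itertuples():
    groups[r.query_id].append(HitRecord(r.query_id, tax[r.taxon_key],
        r.identity_pct, r.align_len, r.query_len, r.evalue, r.bitscore))
assignments = [taxonomy.assign_esv(g, marker="12Steleo") for g in groups.values()]
print(collections.Counter(a.assigned_rank for a in assignments))
```

prints `Counter({'genus': 9, 'species': 5, 'family': 5, 'above_family': 5})`
— the generator placed best scores in all four threshold strata (ties to a
congener collapse to genus, hence the extra genus calls), and every call
matches the generator's recorded truth.

```python
# --- volume × depth effects on DNA yield ----------------------------------
samples = [s for s in simulate.make_metadata_and_concentration(seed=42)
           if not s.is_control]
y = np.array([s.dna_conc for s in samples])
vol = [f"{s.volume_l:g}L" for s in samples]
dep = [diversity.depth_category(s.depth_m) for s in samples]
print(robust.rank_fit(y, vol, dep, names=("volume", "depth")).summary())
```

```
Rank-based two-way ANOVA (Wilcoxon scores)
n = 153, dispersion = 1967.8235, tau = 14.4924

Coefficients (vs. first level):
  volume[1.5L]                     57.8150  (se 2.3818)
  depth[mid]                       14.9000  (se 3.8459)
  depth[shallow]                   15.5300  (se 3.1583)

ANOVA (drop in dispersion):
  volume               F =  388.635, df = (1, 149), p = 2.318e-43
  depth                F =   12.557, df = (2, 149), p = 9.125e-06
```

The 1.5 L samples yield ~58 pg/µL more DNA than the 0.25 L samples (the
generator's true volume effect is 60), and deep samples yield ~15 pg/µL
less than mid or shallow ones (true depth effect 15).

```python
# --- primer-set detection probabilities, corrected for false negatives ----
data, truth = simulate.make_detection_history(
    n_taxa=20, n_sites=30, n_replicates=3, n_markers=3, seed=42)
res = occupancy.fit_occupancy(data, draws=8000, burnin=3000, chains=4, seed=42)
from scipy.special import expit
for m, marker in enumerate(data.markers):
    d = res.community_mean_detection(marker)
    print(f"{marker}: community mean detection {np.mean(d):.3f} "
          f"(95% CI {np.quantile(d, 0.025):.3f}-{np.quantile(d, 0.975):.3f}), "
          f"truth {expit(truth['mu_alpha'][m]):.3f}")
s = res.summary()
print("converged:", res.converged, "| max R-hat:", round(float(np.nanmax(s['rhat'])), 3))
```

```
marker1: community mean detection 0.627 (95% CI 0.536-0.714), truth 0.622
marker2: community mean detection 0.469 (95% CI 0.382-0.554), truth 0.500
marker3: community mean detection 0.385 (95% CI 0.307-0.466), truth 0.378
converged: True | max R-hat: 1.021
```

Each primer set's community mean detection probability brackets the value
it was simulated with. `res.summary()` tabulates every parameter with
posterior mean, median, 95% interval, rank-normalized split R-hat and
effective sample size; results are flagged whenever any R-hat ≥ 1.1.

A command-line interface mirrors the library:
`edna simulate | assign | summarize | stats | occupancy`, each with
`--seed` and `--out`; seeded invocations are byte-reproducible.

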