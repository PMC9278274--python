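# aerotransfer

Compositional analysis of indoor airborne bacterial communities sampled as
settled dust, built around one question: **do bacteria move from a livestock
stable into the farmer's home?**

Settled-dust (electrostatic dust collector) samples from farmers' homes,
livestock stables, and suburban homes yield 16S amplicon feature tables
whose comparison requires care on two fronts: sequencing depth inflates
richness estimates, and count data are compositional, so naive Euclidean
geometry on proportions is misleading. `aerotransfer` implements the
analysis chain used for such studies:

1. **Fixed-depth subsampling** — every sample is rarefied without
   replacement (multivariate hypergeometric draw) to a common depth,
   typically 20,000 reads, so richness is comparable across samples.
2. **Negative-control decontamination** — each feature's presence/absence
   prevalence in true samples is contrasted against unexposed-collector /
   extraction-blank controls (two-sided Fisher exact test with a
   control-enrichment direction guard); flagged features are removed.
3. **Alpha diversity** — observed richness and Shannon index
   (H = −Σ pᵢ ln pᵢ) per sample, compared between environments with the
   Wilcoxon/Mann–Whitney rank-sum test.
4. **Beta diversity in Aitchison geometry** — counts (plus pseudocount) are
   centered-log-ratio transformed, clr(x)ᵢ = ln xᵢ − mean ln x; Euclidean
   distance between CLR vectors is the Aitchison distance. Ordination by
   PCoA (Gower double-centering + eigendecomposition) and group separation
   by ANOSIM, R = (r̄_between − r̄_within)/(n(n−1)/4), with permutation
   p-values.
5. **Matched home–stable transfer ranking** — the statistic at the heart of
   the package. Each farm links one home to one stable; the Aitchison
   distance between a home and its *own* stable is ranked among that home's
   distances to all other stables. Under no transfer the rank is uniform on
   1..n_stables; a cohort-level excess of rank-1 pairs signals bacterial
   transfer, tested by permuting the home→stable matching.

A fully seeded synthetic generator (`synthetic_data`) produces study-shaped
data — environment-specific logistic-normal communities, matched pairs with
a controllable transfer fraction τ, overdispersed depths, and
contaminant-laden negative controls — so every stage is testable without
any sequence download.

## Worked example

```python
from aerotransfer import (
    ContaminantSpec, EnvironmentSpec, LivestockLink, SyntheticScenario,
    aitchison_distance, anosim, clr_transform, generate_study,
    matched_pair_distances, subsample_to_depth, transfer_test,
)

scenario = SyntheticScenario(
    n_features=300,
    environments=[EnvironmentSpec("cow_home", 12, sigma=0.8),
                  EnvironmentSpec("cow_stable", 12, sigma=0.8)],
    links=[LivestockLink("cow", 12, tau=0.4)],   # 40% of home air from the stable
    n_controls=6, depth_mean=25_000, depth_cv=0.1, seed=42,
)
table, meta, taxonomy, truth = generate_study(scenario)

sub, dropped = subsample_to_depth(table, 20_000, seed=42)
true_ids = [s for s in sub.sample_ids if not meta[s].is_control]
dm = aitchison_distance(clr_transform(sub, pseudocount=0.5)).filter(true_ids)

res = anosim(dm, [meta.environment_of(s) for s in true_ids],
             n_permutations=999, seed=42)
print(f"ANOSIM R = {res.R:.3f}, p = {res.p_value:.3f}")

sub_m, matching, log = matched_pair_distances(dm, meta, "cow")
summary, rankings = transfer_test(sub_m, matching, n_null_draws=999, seed=42)
print(f"{summary.n_rank_one}/{summary.n_pairs} matched home-stable pairs rank 1 "
      f"(fraction {summary.fraction_rank_one:.2f}, "
      f"null {summary.null_expectation:.3f}, p = {summary.p_value:.3f})")
```

prints

```
ANOSIM R = 0.922, p = 0.001
11/12 matched home-stable pairs rank 1 (fraction 0.92, null 0.083, p = 0.001)
```

Homes and stables form clearly distinct communities (R = 0.92), yet with
τ = 0.4 almost every home is closer to its own stable than to any other
farm's stable — 11 of 12 rank-1 pairs against a null expectation of
1/12 ≈ 0.083, so the matching permutation test rejects random association at
its resolution floor (p = 0.001 with 999 draws).

The same analysis is scriptable from the shell:

```sh
aerotransfer simulate --preset study --seed 1 --out-dir sim/
aerotransfer run --config cfg.yaml        # full pipeline from a YAML config
```

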