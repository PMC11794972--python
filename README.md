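# flockherit

Quantitative-genetic decomposition of social network phenotypes in a wild
bird population, from raw RFID feeder data to multi-matrix animal models.

Wintering great tits (*Parus major*) carrying PIT tags are scanned by
RFID antennas whenever they visit automated feeders. Bursts of visits at
one feeder form **flocking events**; the number of distinct birds in an
event is the **group size**, a repeated-measures phenotype, and birds
sharing an event are taken to associate ("gambit of the group"), which
yields weekend social networks and per-bird network traits (degree,
strength, eigenvector centrality, betweenness). `flockherit` implements
the full chain needed to ask how much of the variation in these social
phenotypes is genetic, individual, spatial or developmental:

* **events / networks** — flocking-event extraction (a BIC-selected 1-D
  Gaussian-mixture detector or an inter-visit-gap rule), group-by-individual
  matrices, simple-ratio-index association networks, and node metrics;
* **pedigree** — validated multi-generation pedigrees, pruning to
  informative individuals, the additive relationship matrix **A** by the
  tabular method, and a gene-dropping Monte-Carlo oracle for it;
* **similarity** — natal spatial-proximity and environmental-similarity
  matrices (unit diagonal, `1 − d/d_max` scaling, eigenvalue-clipped to
  valid covariances);
* **lmm** — an AI-REML engine for the animal model

  y = Xβ + Σₖ Zₖuₖ + e, uₖ ~ N(0, Kₖ σ²ₖ), e ~ N(0, I σ²ₑ)

  with identity- or matrix-structured random effects (individual identity
  V_ID, additive genetic V_A via **A**, feeder V_LOG, natal section V_SECT,
  brood V_BI, natal spatial V_SPATIAL and environmental V_ENVSIM),
  average-information updates with EM fallback, boundary pinning,
  delta-method ratio standard errors, and χ²₁ likelihood-ratio tests.
  Repeatability is R = (V_ID + V_A)/V_P and narrow-sense heritability
  h² = V_A/V_P;
* **study_models** — the model ladders (Models 1–5 for event-level group
  size, Models 1–2 for weekend network traits, natal Models a–i) per
  winter and pooled with year as a fixed effect, with tidy
  variance-proportion tables;
* **simulate** — a synthetic-study generator (pedigree with immigrants,
  autocorrelated nestbox environments, phenotypes with every variance
  component, labelled visit streams) so every stage is testable against
  known ground truth.

## Worked example

```python
import numpy as np
from flockherit import (SimConfig, simulate_pedigree, simulate_site,
                        simulate_phenotypes, run_group_size_ladder)

cfg = SimConfig(seed=11, n_founders=120, n_generations=3)
rng = np.random.default_rng(cfg.seed)
ped, broods = simulate_pedigree(cfg, rng)
site = simulate_site(cfg, rng)
obs, truth = simulate_phenotypes(ped, site, cfg, broods, rng)

for r in run_group_size_ladder(obs, ped):
    if r.scope == "pooled" and r.model_id in ("1", "2", "4"):
        rep = r.ratios["repeatability"]
        print(f"Model {r.model_id}: R = {rep.value:.3f} (SE {rep.se:.3f})",
              {k: round(v, 3) for k, v in r.proportions.items()})
```

```
Model 1: R = 0.460 (SE 0.014) {'ID': 0.46, 'R': 0.54}
Model 2: R = 0.461 (SE 0.015) {'ID': 0.361, 'A': 0.1, 'R': 0.539}
Model 4: R = 0.272 (SE 0.019) {'ID': 0.272, 'LOG': 0.317, 'R': 0.411}
```

Model 1 fits individual identity only: birds are consistent in their
group size, with just under half of the phenotypic variance between
individuals. Model 2 splits that among-individual variance into a
permanent-environment part (ID) and an additive genetic part linked to
the pedigree (A) while leaving the repeatability unchanged. Model 4
adds feeder identity: about a third of the variance is explained by
*where* birds feed, and the apparent individual repeatability drops
accordingly — birds that always feed at the same logger look
individually consistent until the logger is modelled. This is the
qualitative pattern the generator's defaults emulate (true shares:
V_ID 0.20, V_LOG 0.30, V_A 0.02).

The same API scales to the full pipeline (visit streams → events →
weekend networks → trait ladders); `flockherit simulate`, `flockherit
networks`, `flockherit fit` and `flockherit pipeline` expose it from the
shell, writing provenance-stamped CSV/JSON outputs.

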