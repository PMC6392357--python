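# barcoweb

Comparing two ways of building plant–herbivore interaction networks in a
mapped forest plot: the traditional **observation** method, which links a
Lepidoptera larva to the tree it was collected from (by insecticide
fogging of focal trees), and the **molecular** method, which identifies
the larva's actual food plants by DNA-barcoding its gut contents
(chloroplast *rbcLa* and *trnL* plus nuclear ITS2) against a local plant
reference library.

The package is aimed at ecologists working on bipartite food webs who
want a tested, seeded, end-to-end pipeline for this comparison — from raw
(or simulated) barcode sequences all the way to network statistics — and
at methodologists who need the individual pieces: OTU delimitation,
marker-resolution scoring, spatial mismatch attribution, a bipartite
metric suite, and a size-matched null model.

## What it computes

- **OTU delimitation** (`seqqc_otu`): quality filter (keep sequences with
  ungapped length ≥ 80% of the expected amplicon), uncorrected
  p-distances with pairwise deletion, hierarchical clustering cut at 2%
  divergence, and taxonomy assignment combining ranked reference hits
  with morphological family (conflicting or out-of-order OTUs are
  discarded).
- **Diet identification** (`dietid`): per-marker candidate sets (all
  reference taxa at maximal identity), set-intersection across markers,
  species complexes, and per-level resolution scores in {0, ½, 1}
  averaged over diet individuals.
- **Webs and overlap** (`webs`): larva-level count matrices for both
  methods and T+M+/T+M−/T−M+ node and link overlap tables at species and
  genus level.
- **Mismatch attribution** (`mismatch`): per-larva categories — match,
  near neighbor (≤ 2 m), far neighbor (> 2 m), nontree taxon,
  low-resolution — and each method's contribution to diet mismatch.
- **Detection logistic** (`detect`): P(diet confirmed) as a function of
  the observed co-occurrence count x,
  `P(y=1) = exp(β₀+β₁x) / (1+exp(β₀+β₁x))`, with Wald tests and an
  optional body-size covariate.
- **Network metrics** (`netmetrics`): H2′ specialization (two-dimensional
  Shannon entropy standardized between its integer-marginal extremes),
  interaction evenness, qualitative/quantitative generality and
  vulnerability (effective partner numbers), NODF and weighted NODF
  nestedness, and Barber bipartite modularity
  `Q = (1/F) Σᵢⱼ (Aᵢⱼ − kᵢdⱼ/F) δ(gᵢ,gⱼ)` maximized by an LPAwb+-style
  weighted label-propagation search.
- **Null comparison** (`nullcomp`): metrics of the observation web
  against 1,000 random subwebs of the molecular web with matched insect
  and plant node counts (percentile 95% CIs), plus rare-link pruning
  (drop counts ≤ 2).
- **Synthetic data** (`syndata`): a seeded generator for a mapped 50-ha
  plot, fogged focal trees, larvae with hidden diet locations
  (focal/near/far/nontree), per-marker amplification failure and planted
  species complexes — so every stage is testable without downloads.

## Worked example

```python
from barcoweb import PipelineConfig, run_pipeline
from barcoweb.syndata import CommunityParams

cfg = PipelineConfig(community=CommunityParams(rng_seed=1),
                     n_draws=200, n_restarts=4)
r = run_pipeline(cfg)
print(f"recovery {r.recovery_rate_pct:.1f}%")
print(r.mismatch_summary.to_frame())
print(r.envelope.to_frame().round(3))
```

prints

```
recovery 42.4%
                count   pct
match             196  57.8
near_neighbor      32   9.4
far_neighbor       64  18.9
nontree            40  11.8
low_resolution      7   2.1
                      observed  null_mean  ci_2.5  ci_97.5  outside_ci
h2_prime                 0.786      0.475   0.377    0.557        True
interaction_evenness     0.585      0.647   0.627    0.672        True
generality_qual          1.743      2.554   2.286    2.886        True
vulnerability_qual       3.812      5.587   5.000    6.312        True
generality_quant         1.698      2.712   2.382    3.114        True
vulnerability_quant      4.415      5.832   5.317    6.346        True
nodf_qual               12.088     20.141  17.196   22.653        True
nodf_quant               8.060      8.636   6.148   10.524       False
modularity_q             0.699      0.552   0.496    0.603        True
```

Reading this: diets were identified for 42.4% of larvae; 57.8% of those
were confirmed to have eaten the tree they were fogged from, and most of
the mismatch is attributed to the observation method (larvae that fed on
near/far neighboring trees or on unsampled nontree taxa) rather than to
limited marker resolution.  The observation web is structurally different
from size-matched random subwebs of the molecular web for eight of the
nine metrics.

The same pipeline is available from the shell:

```bash
barcoweb run --seed 1 --outdir report/
barcoweb simulate --seed 1 --outdir synth/     # just the data
barcoweb metrics --web report/obs_web.csv      # just the metric suite
```

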