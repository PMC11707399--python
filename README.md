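# benthos

Community assessment of trawl-surveyed megabenthos (large bottom-dwelling
fish, crustaceans, mollusks and echinoderms) along estuarine gradients:
from raw swept-area catch standardization through 24 base indices to three
entropy-weighted composite scores, with the clustering, ordination and
community–environment stages a full survey analysis needs.

It is written for benthic ecologists analysing site × species density
matrices from river-mouth surveys — in particular surveys contrasting
low-flow periods against artificial-flood (water–sediment regulation)
disturbance — and ships a synthetic estuarine-gradient generator so every
stage can be exercised and validated without survey data.

## What it computes

**Base indices** (per site, or per community group):

- *Alpha diversity* — richness S, total abundance S_a (ind·km⁻²), total
  biomass S_b (kg·km⁻²), Shannon–Wiener H′, Margalef d, Pielou J′, Simpson
  D = 1 − Σp², inverse Simpson D′ = 1/Σp².
- *Phylogenetic diversity* — Faith PD, mean pairwise distance MPD, mean
  nearest-taxon distance MNTD, net relatedness index
  NRI = −(MPD_obs − MPD_null)/sd(MPD_null) under a seeded tip-shuffle null,
  and the phylogenetic species variability family PSV, PSR = PSV·S, PSE,
  PSC from the tip correlation matrix C_ij = V_ij/√(V_ii·V_jj).
- *Network stability* — per group: a signed Spearman co-occurrence network
  (|ρ| ≥ 0.6, Benjamini–Hochberg adjusted p < 0.05, ≥ 20 % occurrence, all
  configurable) with topology (average degree d, path length l, clustering
  c, modularity m); cohesion C_pos / C_neg / C_total (abundance-weighted
  mean positive/negative association); average variation degree
  AVD = Σ|z| / (n_sites · n_species); ICV = mean/sd of site totals;
  robustness to random (50 % of nodes) and dominant-species removal with
  isolated survivors counted as secondary extinctions; vulnerability
  (worst single-node drop in global efficiency).

**Composites** — each 8-index block is min–max normalized (benefit/cost
orientation per index), weighted by the entropy-weight method
(w_j ∝ 1 − e_j, where e_j is the Shannon entropy of index j's distribution
across alternatives), and summed into C-diversity and C-phyl (per site) and
C-stability (per community group).

**Structure & environment** — Bray–Curtis on log(x+1) densities, UPGMA
clustering with a flat cut at a similarity level, PCoA (negative
eigenvalues reported), PERMANOVA, dominance degree Y = (relative
abundance) × (occurrence frequency) with Y ≥ 0.02 flagged dominant,
Kruskal–Wallis + Wilcoxon post hoc, Pearson parameter screen, Mantel test,
and redundancy analysis (RDA).

## Worked example

Simulate a three-cruise estuarine survey (spring low-flow IA, summer
low-flow IB, artificial flood IC; 60 sites × 150 species) in which the
flood pulse damages the southern estuarine flank, then score community
stability for every cruise-by-group community:

```python
import pandas as pd
from benthos import ScenarioConfig, build_network, dominance, stability_record
from benthos.composite import assemble, evaluate
from benthos.synthetic import generate_study

study = generate_study(ScenarioConfig(flood=True, seed=0))
records = {}
for cruise, ds in study.items():
    for label in sorted(ds.true_groups.unique()):
        sites = list(ds.true_groups.index[ds.true_groups == label])
        if len(sites) < 4:
            continue
        sub = ds.abundance.subset_sites(sites)
        graph = build_network(sub, seed=1)
        dom = dominance(sub)
        records[f"{cruise}-{label}"] = stability_record(
            sub, graph, list(dom.index[dom["dominant"]]), reps=200, seed=2)

result = evaluate(*assemble("stability", pd.DataFrame.from_dict(records, orient="index")))
print(result.weights.round(3).to_string())
print(result.scores.round(3).to_string())
```

Output:

```
ICV              0.115
C_pos            0.139
C_neg            0.116
C_total          0.102
AVD              0.183
Robustness_R     0.149
Robustness_Y     0.122
Vulnerability    0.075

IA-E     0.610
IA-F     0.502
IB-E     0.736
IB-F     0.317
IC-EN    0.688
IC-ES    0.506
IC-F     0.278
```

The weights are the entropy weights of the eight stability indices across
the seven communities (AVD and robustness to random removal carry the most
information here). The scores are C-stability: the summer estuarine
community (IB-E, 0.736) is the most stable; after the flood the northern
estuarine flank holds up (IC-EN, 0.688) while the damaged southern flank
drops to 0.506 — the disturbance contrast the composite is built to expose.

The same machinery is available from the shell:

```sh
benthos synth --n-sites 60 --n-species 150 --flood --seed 0 --out data/
benthos run --config config.yaml --out results/
```

where `config.yaml` is a `RunConfig` (inputs or a synthetic scenario, all
stage parameters, one master seed); `benthos run` executes every stage in
dependency order and writes per-stage tables plus a self-describing JSON
report.

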