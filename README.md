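# abtox

Analysis pipeline for arrayed yeast deletion screens of amyloid-β (Aβ)
toxicity modifiers — colony-growth scoring, hit calling, ortholog
mapping, interaction-network topology, MCODE module detection,
pathway over-representation and seed-based network prioritization —
together with a synthetic-data generator that provides ground truth
for every stage.

## The problem

Expressing Aβ₁₋₄₂ in the yeast secretory pathway is strongly
cytotoxic, which turns colony growth into a genome-wide toxicity
readout: a deletion library (~5154 knock-out strains) carrying a
galactose-inducible Aβ construct is pinned in duplicate onto inducing
(galactose) and non-inducing (glucose) solid medium and scored after
3, 4 and 5 days. The per-strain statistic is the **Gal/Glu growth
ratio**

```
r_d = I_d / U_3
```

where `I_d` is the induced colony size at day *d* and `U_3` the
uninduced size at day 3. A wild-type strain with Aβ grows at
r₄ ≈ 0.09 / r₅ ≈ 0.39, while the empty-vector control (no Aβ) reaches
r₄ ≈ 1.04 / r₅ ≈ 1.83. Against that background:

- **enhancer genes** (of toxicity): deletion rescues growth —
  aggregate r₄ ≥ 0.7 (inclusive). The gene contributes to toxicity.
- **protective genes**: deletion abolishes growth — induced colonies
  below the detection threshold in every replicate at day 5 (r₅ = 0).
- strains with known galactose-deficient growth, or with observed
  deficient growth on glucose, are confounders and excluded.

Downstream, hits are projected onto mammalian orthologs (offline
table), assembled into a confidence-filtered STRING-style network
(combined score ≥ 0.4; experiments / database / gene-fusion channels),
and analyzed by degree / betweenness / average-shortest-path-length
rankings, MCODE complex detection (node score cutoff 0.2, k-core 2,
max depth 100), hypergeometric over-representation with BH FDR, and
random-walk-with-restart prioritization from seed genes.

## Worked example

```python
from abtox import (ScreenDesign, simulate_screen, compute_growth_ratios,
                   run_hit_calling)

design = ScreenDesign(n_strains=1000,
                      enhancer_fraction=0.05, protective_fraction=0.05,
                      gal_deficient_fraction=0.02, glu_deficient_fraction=0.02,
                      noise_cv=0.15, rng_seed=1)
measurements, truth = simulate_screen(design)
scores = compute_growth_ratios(measurements)            # Gal/Glu ratios
calls = run_hit_calling(scores, truth.known_gal_deficient,
                        control_strains=truth.control_strains)
print(calls["call"].value_counts().to_dict())
```

prints

```
{'no_call': 863, 'excluded': 52, 'protective_gene': 50, 'enhancer_gene': 47}
```

i.e. of 1000 library strains (plus 12 on-plate Aβ controls, reported
as excluded/control), 47 of the 50 planted enhancer-gene strains are
recovered (the rest fall just under the 0.7 ratio threshold at this
noise level), all 50 planted protective strains are recovered, and
all 40 planted gal-/glu-deficient confounders are excluded. The first
enhancer rows show the underlying numbers — rescued day-4 ratios with
their volcano annotation (log2 fold change over the Aβ-control pool,
plate-robust z, BH q):

```
 strain          call       r4       r5   log2fc         z   p   q
KO00014 enhancer_gene 0.930747 0.689564 3.387411 57.177215 0.0 0.0
KO00049 enhancer_gene 0.783794 0.814363 3.139786 47.206490 0.0 0.0
```

On the network side, a planted 8-clique in a 100-gene background
interactome (edge probability 0.03) is recovered intact as the
top-scoring MCODE module:

```python
from abtox import simulate_interactome, load_string_network, find_modules
edges, truth = simulate_interactome(100, 0.03, [(8, 1.0)], seed=3)
modules = find_modules(load_string_network(edges))
modules[0].score, modules[0].members
# (8.0, ('G0001', 'G0002', ..., 'G0008'))
```

The same operations are available from the shell:

```sh
abtox simulate-screen --n-strains 1000 --seed 1 --out-prefix demo
abtox score --measurements demo_measurements.tsv --out scores.tsv
abtox hits --scores scores.tsv --theta 0.7 --out hits.tsv
abtox network --edges edges.tsv --min-score 0.4 --out-prefix net
abtox mcode --edges edges.tsv --cutoff 0.2 --kcore 2 --max-depth 100 --out-prefix mc
abtox enrich --genes query.txt --gmt sets.gmt --out ora.tsv
abtox prioritize --edges edges.tsv --seeds seeds.txt --restart 0.5 --out-prefix prio
```

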