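# Methods

## Screen model

The pipeline analyzes an arrayed yeast deletion screen in which every
knock-out strain carries a galactose-inducible Aβ₁₋₄₂ construct routed
through the secretory pathway. Toxicity is read out as colony growth:
each strain is pinned (in duplicate) onto inducing and non-inducing
solid medium, colonies are scored at days 3/4/5 of induction and day 3
without induction, and the per-strain statistic is the Gal/Glu ratio
r_d = I_d / U_3. The denominator is the uninduced **day-3** size for
all induced days — the ratio is deliberately not day-matched, so late
ratios above ~1 simply mean continued growth under induction.

Hit calling is threshold-based. Aggregate r₄ ≥ 0.7 (inclusive) calls
an **enhancer gene**: deletion rescues growth, so the gene contributes
to toxicity. An induced colony below the detection threshold τ in
*every* replicate at day 5 calls a **protective gene**: deletion
abolishes growth, so the gene normally protects. Note the gene-level
naming: the strain phenotypes run in the opposite direction (a rescued
strain is "protected", a dead strain "enhanced" toxicity), and mixing
the two levels is a standing source of confusion in screen
descriptions; this package fixes the gene-level vocabulary everywhere
and preserves raw phenotypes in reason codes and ratio columns.

Confounders are removed before calling: strains on a user-supplied
list of known galactose-deficient deletions (their induced-medium
growth defect mimics the protective phenotype) and strains whose
uninduced day-3 size is below τ in all replicates (no usable
denominator; observed glucose deficiency).

### Detection threshold τ

τ defaults to 5% of the plate-wide median uninduced day-3 colony size,
computed per plate. A relative threshold is scanner- and
magnification-independent; the median is robust to the small planted
fraction of deficient strains. A scalar or per-plate override is
accepted.

### Replicate aggregation and the zero rule

The strain-level ratio is the arithmetic mean of finite replicate
ratios (geometric mean available as an option); with duplicate
replicates the mean is the simplest unbiased choice. A day counts as
"zero" for a strain only when the induced colony is below τ in **all**
replicates — conservative against single-pin failures in a duplicate
screen. A replicate with an unmeasurable denominator contributes
nothing (NaN) rather than an infinite ratio.

### Volcano statistic

The screen literature pairs threshold calls with a volcano plot but a
per-strain test is underdetermined at n = 2 replicates, where
per-strain variance estimates are unstable. The package therefore
annotates (and does not gate on) a plate-robust statistic: log2 fold
change log2((r₄+ε)/(r̄₄,ctrl+ε)) with ε = 10⁻³ admitting zero ratios,
z = (r₄ − r̄₄,ctrl)/s with s = 1.4826·MAD of all strain aggregates on
the plate (SD fallback when MAD = 0), two-sided normal p and BH
q-values. Output metadata flags the statistic as a stand-in.

## Synthetic screen generator

`synthetic.simulate_screen` emulates the screen's study conditions: a
5154-strain library default in 16×24 format, duplicate replicates,
induced days {3,4,5} against uninduced day 3, and four planted strain
classes among neutral strains. Neutral (and on-plate control) strains
follow the Aβ-control ratio trajectory (day 3: 0.05, day 4: 0.09,
day 5: 0.39 — strong suppression then partial recovery); the
empty-vector profile (1.04/1.83) is available as an alternative
neutral profile. Planted enhancer-gene strains grow at the rescue
level (default 0.9) from day 4; protective-gene and
galactose-deficient strains emit induced sizes drawn below the
detection floor (0.25× the floor) rather than exact zeros, modelling
residual scanner/agar signal and exercising the zero-calling rule;
glucose-deficient strains grow at 2% of baseline on glucose.

Noise is multiplicative lognormal per colony with unit mean and
configurable coefficient of variation; σ² = ln(1+CV²). The default
CV = 0.15 is a typical replicate-level size variation for pinned
colony arrays; the original screen's noise level is not reported, so
recovery rates measured here characterize the generator's conditions,
not the original data. With CV = 0 every ratio equals its configured
multiplier exactly, which the worked-example tests rely on.

What the generator does **not** model: pinning-robot artifacts,
colony morphology, spatial autocorrelation of noise, batch effects
between replicate pinnings, and day-to-day correlation of the same
colony (sizes are drawn independently per day). An optional linear
edge gradient (outer positions grow larger, default off) lets tests
exercise robustness of the per-cell background correction. Passing
recovery tests therefore demonstrate the pipeline's correctness under
the stated statistical assumptions, not performance on real plates.

Uninduced sizes are emitted at day 3 only, since the ratio definition
uses no other uninduced day.

## Plate images and quantification

`render_plate_image` draws each colony as a truncated-Gaussian disk
(σ = radius/3) whose integrated intensity above a uniform background
equals the colony size. `quantify_plate_image` inverts this without
segmentation: colonies sit on a declared lattice (GridSpec: four
corner centers, bilinear interpolation, fixed integration radius), so
per cell the background is the median of a ring just outside the
integration radius and the size is the clamped background-subtracted
pixel sum. Per-cell background tolerates smooth plate gradients and
makes sizes exactly invariant to a constant intensity offset. The
round trip closes to well under 1% by construction (same distance
metric, kernel normalized within the radius). No claim of equivalence
with any specific image-analysis pipeline is made; thresholds and
modules of the software used on the original screen are unpublished.

## Ortholog mapping

Table-driven and offline for reproducibility: a TSV of
(yeast gene, human gene, source, confidence) rows. `best_score` keeps
the maximal-confidence human gene(s) per yeast gene **with ties
kept** — yeast→human orthology is many-to-many and arbitrary tie
breaking would silently drop genes; `all` keeps every pair. Output is
deduplicated per human gene; conflicting inherited labels mark the
gene `ambiguous` rather than picking a side. A toy demonstration
table ships with the package; it is illustrative, not a curated
resource.

## Interaction network

`load_string_network` consumes a STRING-style scored edge list and
keeps an edge iff combined score ≥ 0.4 (medium confidence) **and** at
least one selected evidence channel (experiments, curated database,
gene fusion) is positive — dropping, e.g., text-mining-only edges
with high combined scores. Score scale (0–1 vs 0–1000) is
auto-detected from the maximum and logged; channel-name dialects
("database"/"databases", "fusion"/"gene_fusion") are accepted. With
an input gene list the network is restricted to it (no additional
interactors) and isolated input genes remain as nodes.

Topology metrics: degree; exact unnormalized betweenness (each
unordered endpoint pair contributes 1, split evenly over its shortest
paths, endpoints excluded); and per-node average shortest path length
over reachable nodes only, with component ids reported so "highest
ASPL" rankings are interpretable on disconnected graphs. Rankings are
deterministic with lexicographic tie-breaks. Interpretation of high
ASPL (peripheral vs "close to others") is left to the user; the
package reports the raw quantity.

The naive evidence handling here deliberately omits prior-corrected
probabilistic combination of channels; the combined score column is
taken as given.

## MCODE

Vertex weight = k_max × density of the highest k-core of the vertex's
**closed** neighborhood (the vertex included — the original
definition; the open-neighborhood variant scores K3 vertices
differently and was rejected). Density is 2E/(V(V−1)). Complex
growth: seeds descend by weight; from seed s, breadth-limited
expansion (depth ≤ 100) admits unvisited neighbors with weight
> weight(s)×(1−0.2). Every touched vertex is marked visited even if
its complex is later discarded — this prevents re-seeding loops and
keeps complexes vertex-disjoint. Post-processing: discard complexes
lacking a 2-core; haircut iteratively shaves degree-1 members
(default on); fluff (default off) adds boundary vertices whose closed
neighborhood density exceeds the fluff cutoff and may overlap between
complexes, so fluffed vertices are reported separately. Score =
density × size; ranking and all internal iterations are
lexicographically tie-broken, so output is deterministic across runs
and node orderings. The defaults (cutoff 0.2, k-core 2, depth 100)
are the settings used in the screen's network analysis; haircut/fluff
flags are recorded in CLI output since the original run did not state
them.

## Over-representation analysis

Exact upper-tail hypergeometric p = P(X ≥ k) via the survival
function; enrichment ratio ER = (k/n)/(K/N), satisfying
ER·(K/N)·n = k identically. The universe defaults to all genes
annotated anywhere in the GMT collection — reference-set behavior of
web ORA tools varies by version, so the policy is explicit and logged
in output metadata; an explicit universe list is accepted. Sets with
in-universe size outside [5, 2000] are skipped; BH runs over tested
sets only; rows are ordered by FDR, then p, then ER descending.
Numeric agreement with any specific web service or pathway-database
release is not claimed.

## Prioritization

Random walk with restart: p ← (1−r)Wp + r·p₀, W column-stochastic by
degree, p₀ the normalized seed vector, default restart r = 0.5
(balanced local/global exploration), L1 tolerance 10⁻⁶, cap 1000
iterations. Mass on degree-0 nodes is redistributed to p₀, keeping
the iteration exactly probability-conserving; convergence is
geometric with ratio ≤ (1−r). The iterative solution matches the
direct solve of (I−(1−r)W)p = r·p₀ to < 10⁻⁸ on the tested graphs.
RWR is a stand-in for service-based guilt-by-association scorers
whose exact algorithms are not reproducible offline; output metadata
records this. Subnetwork extraction takes the seeds plus the top
(m − #seeds) non-seed genes by score, so m equal to the seed count
returns the seed-induced subgraph.

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale problem
sizes chosen to exercise every code path with known truth: screens of
200–1000 strains (the full 5154-strain default runs in seconds but
adds no coverage), interactomes of ~100 genes with planted cliques,
oracle sweeps of 500 random graphs ≤ 7 nodes (MCODE weights) and 100
graphs ≤ 10 nodes (betweenness), and hypergeometric universes ≤ 60
for brute-force summation. All randomness flows through explicit
integer seeds; identical seeds give byte-identical TSV outputs.

## Known limitations

- Recovery metrics are conditional on the generator's noise model;
  no calibration to the original screen's (unpublished) raw data is
  possible, and the original hit lists/counts are not reproduction
  targets.
- The volcano statistic, ORA universe and RWR scheme are principled
  stand-ins where the original analyses used unspecified or
  service-bound methods; each is flagged in output metadata.
- The hit-calling boundary (whether the 0.7 cutoff applied to the
  replicate mean or to each replicate) is unstated in the source
  protocol; this package applies it to the aggregate and reads it as
  inclusive.
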