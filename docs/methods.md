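# Methods

## The spatial Moran model

The proliferative (basal) compartment of squamous epithelium is modelled as
a fixed population of progenitor cells on a `height × width` hexagonal
lattice wrapped into a torus. Each simulation step is one
differentiation/division event: a cell chosen uniformly at random leaves the
proliferative pool, and one of its six neighbours divides to fill the gap,
chosen with probability proportional to fitness. This is the standard
spatial Moran caricature of a homeostatic epithelium: the population size
never changes, and clone growth is only possible at the expense of
neighbours.

**Time scale.** With division rate λ per progenitor per week and N lattice
sites, one week corresponds to λ·N steps, so a run of T weeks executes
`round(λ·N·T)` steps (each step is exactly one division). The neutral
conditions use λ = 0.5/week and mutation rate μ = 10⁻³ per division; the
non-neutral conditions use λ = 0.033/week (so the fittest clones stay
comparable in size to neutral ones) and μ = 1.5 × 10⁻² (so clone numbers
stay comparable), both for 3000 weeks (~58 years). The division rates are
inputs, not fitted quantities; conclusions are about distribution shapes,
not absolute sizes.

**Mutation and fitness.** During each division, with probability μ the
daughter occupying the vacated site acquires one new mutation; the parent
site is untouched. A mutation is non-neutral with probability
`non_neutral_fraction`, in which case a fitness increment is drawn from a
configurable distribution (default N(0.1, 0.1); uniform, exponential and
constant families are available for robustness checks) and added to the
cell's fitness. Fitness effects combine additively along a lineage and
fitness is clamped at 0 after each addition — a cell of fitness 0 can never
be chosen to divide unless all six candidates are 0, in which case the
choice is uniform. Neutral mutations leave fitness unchanged; a
configurable proportion of them can be *labelled* as non-neutral, which
gives a purely neutral ensemble a well-defined dN/dS readout.

**Genotypes.** Per-cell mutation sets are stored as a persistent lineage
forest: each mutation is a node pointing at the genotype in which it arose,
and a cell stores only its leaf node. Clone sizes for every mutation are
recovered in one reverse sweep (parents always have smaller ids than
children), so snapshots are O(cells + mutations) and never touch the random
stream — configurations differing only in snapshot times evolve
identically.

**Hex geometry.** Sites use the axial (rhombus) embedding of the triangular
lattice: neighbour offsets {(0,±1), (±1,0), (−1,+1), (+1,−1)} taken modulo
the lattice shape. Because the offset set is closed under negation the
neighbour relation is symmetric on any torus, unlike odd-row offset
coordinates, which break symmetry at the seam when the number of rows is
odd. Both dimensions must be ≥ 3 for the six neighbours to be distinct.

**Determinism.** One seeded generator drives each simulation; the draw
order within a step (site, neighbour, mutation test, label, effect) is
fixed, so identical (config, seed) reproduce outputs bit for bit.
Replicate seeds are derived from a master seed with
`numpy.random.SeedSequence((master, replicate))`.

## The single-progenitor branching demo

The non-spatial counterpart: each division yields two progenitors
(probability r + d), one progenitor and one differentiated cell (1 − 2r),
or two differentiated cells (r − d), with r = 0.25 and d the cumulative
fate imbalance of the clone (probabilities clipped to [0, 1]). With d = 0
the progenitor count is a martingale; a persistent imbalance d gives mean
growth (1 + 2d) per division. Mutations (rate μ per division) add imbalance
draws from N(0.25%, 1.25%). Without spatial constraint, replicates that
accumulate net-positive imbalance grow exponentially — the behaviour the
spatial model is built to correct.

## Virtual biopsy and sequencing

Square biopsies are cut from the lattice — by default 25 non-overlapping
70 × 70-cell squares on the 500-lattice, placed on a regular 5 × 5 grid
with 100-cell pitch (30-cell gaps); random non-overlapping placement is
available. At ~10⁴ basal cells/mm² with half of them progenitors, a
70 × 70 patch is roughly 1 mm² of epithelium. Each biopsy is analysed
independently: a clone spanning several biopsies yields several independent
observations (spaced-sample semantics; merging across samples exists only
in the cohort module, where gridded designs allow it).

For each mutation in a biopsy with cell fraction f, the true VAF is 0.5·f
(heterozygous; f under LOH), the observed read count is one draw from
Binomial(depth = 1000, true VAF), and the mutation is reported only when
reads ≥ 10 (the threshold is inclusive — "a requirement of 10 reads as a
minimum" — and configurable). Observed VAF is reads/depth and the inferred
clone size is 2·VAF·(biopsy cells) for heterozygous clones (VAF·cells under
LOH), capped at the biopsy size. No base-calling error model is included:
the detection minimum is the operative distortion.

## Clone-size statistics

* **First incomplete moment.** μ₁(n) = Σ_{m≥n} m·P_m / Σ_m m·P_m evaluated
  on the observed support; μ₁ = 1 at and below the smallest observed size m.
  Works in any positive size unit (cells or mm²).
* **Constrained straightness R².** Least squares of y = log μ₁ against
  x = n − m with the line forced through (m, 0): slope = Σxy/Σx². One point
  per distinct observed size enters by default (the curve, not the clone
  multiset, is what is being fitted); count-weighted fitting is available
  as a knob. R² = 1 − SS_res/SS_tot with SS_tot about the mean of the
  fitted y values — because of the anchor the fit can be worse than the
  horizontal mean line, so R² can be negative. `fraction_used = 0.75`
  restricts the fit to support points at or below the 75th percentile of
  the clone-size multiset ("smallest 75% of clones"); if that leaves fewer
  than two points the full support is used. Fits require ≥ 2 distinct
  sizes; ensembles drop (and count) replicates without a defined fit.
* **Tail deviation.** For detection-limited time courses the summary is the
  RMS residual of the visible log μ₁ about the line fitted to the smallest
  75% of visible clones.
* **Curve averaging** uses the union of supports with step-function
  interpolation (μ₁ = 1 below a curve's support, 0 beyond its largest
  clone).
* **Simulation dN/dS** = N/(a·S), where N and S are observed non-neutral
  and neutral clone counts and a is the known intake ratio of the labels
  (p/(1−p) for non-neutral fraction p; the neutral ensembles label 50% of
  neutral mutations, a = 1). Survival bias of selected clones, not
  mutation-model corrections, is the object of study.
* **ROC/AUC** treats R² as a classifier score with *low* R² voting
  non-neutral; the trapezoidal AUC over the threshold sweep equals the
  rank-based (Mann–Whitney) estimator with ties counting ½
  (scikit-learn provides the sweep; tests verify pair-counting
  equivalence independently).
* **Rank-sum comparisons** use the one-sided Mann–Whitney U test
  (exact for small tie-free samples, normal approximation with tie
  correction otherwise, via scipy).

## Cohort tables

Mutation calls (donor, grid position, gene, variant, effect class, VAF,
depth, 2 mm² sample area) are validated on read; rows with impossible VAFs
are rejected and unknown effect classes coerce to "other" (protein-
altering), both logged. Analyses keep autosomes only. Protein-altering
NOTCH1 mutations are assumed to carry LOH (clone area = VAF·area — the
conservative, smaller estimate, since LOH frequently co-occurs with them);
everything else is heterozygous (area = 2·VAF·area), always capped at the
sample area. Clones sharing a variant key in rook-adjacent samples of one
donor are merged into connected components with summed area (queen
adjacency available; the merging rule of the original gridded study is not
restated there, so edge adjacency is the documented, conservative choice).
The neutral-proxy subset keeps synonymous calls and calls in 0.0-TPM genes
(packaged expression table; genes missing from it count as expressed, with
a warning), excluding the splice-affecting synonymous TP53 variant T125T.

## The synthetic cohort generator

`generate_cohort_fixture` emulates the statistical structure the cohort
analyses assume: a dominant bulk of small neutral clones
(400 per donor, areas ~ Exp(0.15 mm²), single-sample) plus a minority of
large selected-gene clones (20 per donor, areas ~ LogNormal(median 4 mm²,
σ_log 0.7)) planted as rook-connected patches on a 10 × 10 grid of 2 mm²
samples, each sample only partially occupied (fill fraction ~ U(0.3, 0.7)).
Per-sample VAFs follow the heterozygous area scaling with binomial read
noise at 1000× and a 10-read detection minimum. These defaults place most
mutant *mass* in the small-clone bulk with a distinct large-clone tail —
the regime in which gridded merging reveals curvature that spaced
per-sample readout hides. The generator does not emulate panel-specific
coverage variation, shared mutation hotspots, UV/mutagen spectra, or
donor-level age structure, so passing fixture tests demonstrates the
pipeline's behaviour under the assumed clone-size mixture, not performance
on any particular real cohort.

## Scale of the shipped experiments

The full 500 × 500 × 3000-week conditions are cluster-scale (3.75 × 10⁸
steps per neutral replicate). The packaged experiments use `*_scaled`
presets: 100 × 100 lattices with identical rates and duration (divisions
per cell preserved) and a geometrically scaled biopsy design (25 spaced
14 × 14-cell squares at 20-cell pitch, same 1000×/10-read sequencing
model). Ensembles of 100 replicates per scenario and 5000 drift runs for
the fixation check are the shipped problem sizes. On the small lattice a
single clone often spans several biopsies, so the observed clone count can
exceed the surviving clone count; the "subsample the full data to match"
readout clamps the match at the available clones. The published full-scale
AUC targets and their ±0.03 Monte-Carlo tolerance are pinned
machine-readably in `experiments.FULL_SCALE_ROC_TARGETS` for cluster
reruns; desk-scale ensembles are expected to show the same *ordering*
(matched-subsample AUC well above biopsy-plus-sequencing AUC), not the same
values. One quantitative caveat of the scale-down: because clone sizes are
unchanged while biopsies shrink from 4900 to 196 cells, the spaced-sample
truncation is ~25× harsher relative to clones than in the full design. The
cap on inferred sizes curves the *neutral* observed LFIM more than the
heavily colonized 25% one, so the 25%-scenario biopsy AUC lands slightly
*below* chance (≈ 0.33–0.45 across seeds at 100 + 100 replicates) instead
of just above it — an inversion, and an extreme form of sampling masking
selection that the full-scale geometry does not show.

## Known limitations

- 2D basal layer only: no suprabasal structure, no explicit cell cycle, no
  mutation-spectrum model.
- dN/dS is computed only on simulations with known labels; real-data dN/dS
  values are external inputs.
- LOH is a rule (NOTCH1 protein-altering), not an inference from copy
  number.
- The branching demo clips fate probabilities to [0, 1] after imbalance
  shifts; with the default N(0.25%, 1.25%) draws clipping is essentially
  never active.
- At most one mutation per division; multi-allele collisions in a biopsy
  are not modelled.
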