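# Methods

This note documents the models, conventions and numerical choices behind
`famnet`, what the synthetic data generator does and does not emulate, and
the known limitations.

## 1. Synthetic populations (`famnet.simulate`)

The generator exists to give every downstream stage a ground truth.  It
emulates a range-resident polygamous mammal population sampled
noninvasively:

* **Demography.** Discrete, non-overlapping generations.  Founders
  (generation 0) are split round-robin across labelled spatial clusters
  and placed with isotropic Gaussian scatter (`spread`, default 4–6 map
  units) around the cluster centre.  Each female of generation *g*
  produces `Poisson(mean_offspring_per_female)` offspring (default 2);
  under polygamy (default) every offspring draws its sire uniformly at
  random from the males of generation *g*, so half-sibships arise on both
  the maternal and paternal side.  No inbreeding avoidance is applied.
  A generation without survivors (or without males) ends reproduction and
  is recorded in `TruePopulation.empty_generations` instead of raising.
* **Genotypes.** Per-locus allele frequencies are drawn from a symmetric
  Dirichlet (concentration 1), keeping loci exchangeable; defaults are 15
  loci with 8 alleles each, the typical information content of a
  microsatellite panel used for wildlife parentage.  Founders are
  Hardy–Weinberg draws; offspring receive one allele per locus from each
  parent.
* **Space.** Offspring settle at the dam's location plus an isotropic
  Gaussian displacement with sex-specific scale (defaults: females 30,
  males 50 map units on a nominal 100 × 100 map) shrunk by the natal
  cluster's *philopatry* level `φ ∈ [0,1]`: effective scale
  `= scale × (1 − φ)`.  `φ = 0.9` produces tight family clusters;
  `φ = 0.1` produces genuine dispersal (displacements larger than a
  typical local-area polygon).  The scales were chosen so that the
  philopatric/dispersing contrast is a property of the scenario, not of
  the polygon size.
* **Sampling and error.** Individuals are sampled independently with
  probability `sampling_fraction` (default 0.20, a realistic noninvasive
  coverage of a wild population); a `replicate_fraction` (default 0.3) of
  sampled individuals is amplified twice with independent error draws,
  emulating re-amplification for error-rate estimation.  Error processes
  per allele: **allelic dropout** (default 0.0077 — the highest
  per-stratum rate in the kind of survey this emulates) deletes one
  allele of a heterozygote, which then reads as a false homozygote (both
  alleles dropping makes the locus missing); **false alleles** (default
  3.2e-4) substitute a random different allele of the locus; whole-locus
  amplification failure (default 0.02) makes loci missing so that the
  ≥ 5-loci retention rule is exercised.

Not emulated: overlapping generations, survival/age structure, habitat
or disturbance covariates, sex-biased sampling, genotyping artifacts
beyond the two error classes (stutter, null alleles), and spatial range
shifts.  Tests passing on this generator therefore validate the
*machinery* (matching, likelihoods, graph measures, spatial accounting),
not the field realism of any particular dataset.

## 2. Consolidation and QC (`famnet.genotypes`)

Samples typed at fewer than `min_loci` (default 5) loci are excluded and
reported.  The rest are grouped single-linkage on a mismatch graph: two
profiles are linked when their mismatch score over comparable loci is
≤ `max_mismatch` (default 2).  The score is **dropout-aware**: a locus
where the unordered pairs differ scores 1, *except* the single-dropout
signature — one sample homozygous, its allele contained in the other's
pair — which scores 0.5.  Rationale: at realistic dropout rates a strict
count splits replicate pairs of the same individual often enough to make
exact recovery of the individual count unreliable, while ignoring the
signature entirely lets parent–offspring pairs (which accumulate
hom-containment loci) slip under the threshold.  With 0.5 the replicate
pairs of one individual essentially never split and relatives essentially
never merge at 15-locus panels.  Missing loci never count.

Consensus genotypes are per-locus majority votes over member samples;
ties resolve toward the heterozygote (dropout manufactures false
homozygotes), then lexicographically.  Sex is the member majority, with
conflicts demoted to "unknown" plus a warning.  Grouping and labelling
are order-independent (groups processed by smallest member sample id).

QC follows the standard noninvasive-genetics accounting: per-stratum
genotyping success = scored/collected × 100 (1 decimal; undefined, not
zero, for empty strata), and the overall figure is the *unweighted* mean
of stratum percentages.  Dropout and false-allele rates come from
replicate pairs: at each comparable locus a het-vs-hom discordance whose
homozygote's allele lies in the het pair is a dropout event (at-risk
denominator: two allele observations per heterozygous genotype observed);
any other discordant allele is a false-allele event over all four allele
observations at the locus.

## 3. Parentage (`famnet.parentage`)

Full-likelihood sibship reconstruction (COLONY-style MCMC) is replaced by
a transparent two-stage assignment that preserves the pedigree semantics
(every individual ends with exactly one dam and one sire, sampled or
inferred; polygamy allowed; 50% prior that a parent was sampled) while
remaining exactly testable:

* **Exclusion pre-filter.** A candidate parent sharing no allele with the
  offspring at more than `max_exclusions` (default 1, tolerating one
  dropout artifact) comparable loci is discarded.
* **Joint likelihood.** For each offspring, all (dam, sire), (dam, —),
  (—, sire) and (—, —) configurations over surviving candidates are
  scored.  Per locus the offspring receives one allele from each slot —
  from a stated parent either observed allele with probability ½; from an
  unknown parent an allele drawn from the population frequencies (the
  Hardy–Weinberg marginal of a transmitted allele).  The observed
  offspring pair relates to the transmitted pair through a per-allele
  error model `P(obs o | true t) = (1−ε)·1[o=t] + ε·f_o` (default
  ε = 0.01, the order of observed genotyping error rates; ε = 0 turns
  Mendelian impossibilities into −∞).  Loci multiply; missing loci are
  skipped.  Each filled slot adds `log p`, each empty slot `log(1−p)`
  with `p = prob_parent_sampled = 0.5`.  The maximum wins; ties break
  lexicographically; the row's confidence is the log-likelihood margin
  over the runner-up.
* **Orientation.** No age data are used, so a true parent–offspring pair
  is symmetric: each may select the other, creating a 2-cycle.  Cycles
  are broken post hoc by discarding the lower-confidence edge (the freed
  slot reverts to an inferred placeholder) with a summary warning.
* **Inferred parents.** Per parental slot, offspring with placeholders
  are greedily agglomerated into shared inferred parents.  Merges are
  ordered by descending allele-sharing score (number of comparable loci
  with a common allele), ties lexicographic, and accepted only when every
  cross-group pair shares an allele at *every* comparable locus and a
  single ≤ 2-allele parental genotype per locus remains consistent with
  the whole group.  The pairwise sharing requirement is deliberately
  stricter than bare genotype-consistency, which any two offspring
  satisfy trivially (one transmitted allele can be chosen per offspring)
  and which would therefore merge all parentless offspring under a single
  phantom parent.  The conservative rule under-merges true half-sibs —
  the recovered fraction is reported against simulator truth rather than
  guaranteed — but never fabricates large phantom families.

Fitness of an individual is the number of pedigree rows naming it as dam
or sire.

## 4. The familial network (`famnet.pednet`)

Nodes are all sampled individuals plus all inferred parents; each
pedigree row contributes its two parent→offspring edges.  Structural
contract (asserted): the graph is a DAG; sampled nodes have in-degree
exactly 2 and inferred nodes in-degree 0; a node's two in-edges come from
one female and one male; self-loops and parallel edges are impossible by
construction.  Component structure is reported under weak connectivity
with sizes descending and the largest-component share as a percentage
(1 decimal).

## 5. Centrality (`famnet.centrality`)

Conventions, stated because tools differ:

* **Alpha centrality** respects direction and is solved exactly as the
  sparse linear system `(I − α Aᵀ) x = e` (solver tolerance at machine
  precision; singular systems — cyclic input at α at/above the reciprocal
  spectral radius — raise).  Defaults α = 1, e = 1 are valid on any
  pedigree DAG because its adjacency is nilpotent.
* **Betweenness, harmonic closeness, eccentricity** use the *undirected*
  view: in a directed pedigree most ordered pairs are mutually
  unreachable, and the core-vs-peripheral reading of eccentricity only
  coheres undirected.  Betweenness counts unordered pairs, endpoints
  excluded, fractional split across tied shortest paths, unnormalised.
  Harmonic closeness is the raw sum of reciprocal distances (a
  normalised variant is behind a flag).  Eccentricity is the maximum
  finite distance, an integer, 0 for isolated nodes.
* **Degree** is direction-aware: in-degree (parents, 2 for sampled
  nodes), out-degree (offspring — the fitness proxy), total.
* The pipeline computes node centralities **on the primary (largest)
  component** by default (`centrality_on_primary_component`).  On the
  whole disconnected graph, members of small satellite components score
  eccentricity ≈ 0 and read as artificially central, inverting the
  peripheral-individual interpretation and the sign of area-level
  ratio–eccentricity relationships.
* **Correlations** are Pearson, symmetric with unit diagonal;
  zero-variance measures yield flagged NaNs, never silent zeros.
* **PCA selection** standardises measures to zero mean and unit variance;
  the contribution of measure *j* to component *k* is its squared
  loading share × 100 (each component's contributions sum to 100).  The
  reference line is the expected average contribution 100/p for *p*
  measures; a measure is "selected" when it exceeds the reference on any
  of the first three components.  With fewer nodes than measures the
  component count is truncated with a warning.

## 6. Cohesion by edge removal (`famnet.community`)

Edge betweenness is tabulated into a score → count distribution
(non-integer scores binned at 1e-6).  `distribution_summary` reports the
share of edges at the minimum score and the share above a threshold, 2
decimals.  Removal has two modes: **static** (score once, strip
everything above the threshold — scores binned so the removed set is
consistent with the tabulated distribution at boundaries) and
**recompute** (Girvan–Newman: repeatedly remove all edges tied at the
current maximum and re-score until the maximum is at or below the
threshold; within a step edges go in sorted endpoint order for
reproducibility).  The trace records every removed edge with its score at
removal and component sizes after each step; the static removed fraction
equals the distribution's above-threshold share by construction.

The default threshold (4) matches the published removal rule it mirrors;
note that raw betweenness grows with network size, so on small synthetic
networks this value removes a much larger edge fraction — the threshold
is a configuration field, not a constant of nature.  One reading
ambiguity is resolved in favour of arithmetic consistency: edges *above*
the threshold are the removed set (their share of the published score
table is exactly the published removed percentage), even though the prose
rule could be parsed the opposite way.

## 7. Spatial analysis (`famnet.spatial`)

Local areas are supplied either as GeoJSON polygons (boundary-inclusive
point-in-polygon membership; overlapping claims are an error) or as
explicit member lists — areas drawn "by eye" in a GIS are not
reproducible, so both interfaces are first-class.  Only sampled
individuals can be members; inferred parents have no coordinates and
enter only through first-neighbor expansion (members plus all in- and
out-neighbors).  The edge-to-node ratio `E/n` is bounded by 2 (each
internal edge is the in-edge of a member; in-degree ≤ 2), asserted on
every computation.  Expansion reports the expanded ratio and the share of
*area members* inside the largest weak component of the expanded
subnetwork.  Group comparison labels the k highest- and k lowest-ratio
areas (default k = 4, clamped to half the area count by the pipeline),
summarises each centrality over member nodes per group
(mean/median/quartiles), and reports the Pearson correlation between area
ratio and area-mean centrality — descriptive only, no hypothesis tests;
constant inputs yield flagged NaNs.

## 8. Pipeline and reproducibility (`famnet.pipeline`, `famnet.cli`)

A single `PipelineConfig` (YAML or constructed) drives the stage chain
simulate/ingest → qc → parentage → network → centrality → community →
spatial → report.  Configuration is validated before any stage runs; a
stage failure still writes the partial manifest with a failure record.
Every artifact is a text format (CSV/JSON/GraphML) hashed with SHA-256
into `manifest.json`; all randomness flows from explicit seeds, so a
fixed configuration reproduces every artifact byte-for-byte.  The genotype
CSV schema is `sample_id, area, year, source, sex, x, y`, then two columns
per locus (`<locus>_a1`, `<locus>_a2`; empty cell = missing allele).
Coordinates are planar projected units; no CRS handling is performed.
Percentages are reported to 1 decimal, distribution shares to 2.

## 9. Test problem sizes

The suite validates the graph measures against exhaustive enumeration on
200 random graphs of ≤ 8 nodes, and the recovery properties on
populations of 40–64 founders over 2–3 generations (20–50 seeds per
property; dropout recovery uses a single-generation population large
enough for > 10⁵ heterozygous allele observations).  These sizes give the
Monte-Carlo assertions comfortable margins while keeping the whole suite
in the low minutes on one CPU.

## 10. Known limitations

* The parentage stand-in scores candidate pairs independently per
  offspring; it does not share information across sibships the way a
  full-likelihood sampler does, and makes no attempt to match COLONY's
  output on real data.
* Without age data, parent–offspring orientation rests on the likelihood
  margin alone; the cycle-breaking heuristic resolves the resulting
  2-cycles but can orient an edge wrongly when the margin is small.
* Inferred-parent grouping is conservative by design; reported sib-group
  recovery on simulated data is low, and real half-sib structure will be
  under-merged accordingly.
* Edge-betweenness thresholds do not transfer across network sizes (raw
  scores scale with n); users should inspect the score distribution
  before choosing a removal threshold.
* The simulator's demographic simplifications (Section 1) mean that
  quantitative rates measured on synthetic data (assignment accuracy,
  sib recovery) characterise the algorithms under those conditions, not
  expected field performance.
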