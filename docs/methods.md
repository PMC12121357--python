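# Methods

## Overview

The pipeline chains six stages: simulate → cluster → classify →
community → indicators → report. Every stage is a pure function of its
input tables and the run configuration; a fixed seed reproduces every
output byte for byte. Provenance headers on each artifact record the
configuration hash and seed; wall-clock timestamps appear only in the log
stream, never in data files, precisely so reruns are byte-identical.

## Synthetic study design

The generator emulates an Arctic ice-camp time series: samples enumerate
the full grid of 6 layers (ICE_0 = bottom 0–3 cm, ICE_1 = 3–10 cm,
WATER_1..4 depth levels) × 3 size fractions (pico 0.2–3 µm, nano
3–20 µm, micro 20–100 µm) × 9 dates — three per bloom stage, including
the stage boundary dates (2016-05-01, 2016-06-03, 2016-06-15,
2016-07-18) so the half-open stage intervals are exercised at their
edges. Stage I (before 3 June) is the dark phase, stages II + III the
light phase.

Counts follow a log-normal/multinomial compositional model: taxon *i*
has baseline abundance bᵢ ~ LogNormal(0, σ), σ = 1.5 by default, which
reproduces a realistic dominance/rarity spread (a handful of taxa carry
most reads) without modelling ecology. In a sample with substrate s and
phase φ, the expected composition is proportional to bᵢ · eᵃ, where the
affinity boost a = log(affinity_effect) applies when the taxon's planted
affinity (ice, water, dark or light) matches the sample; reads are a
single multinomial draw of exactly `library_size` (default 20 000) over
that composition, so per-sample totals are fixed and proportions always
sum to 1.

Sequences are uniform random A/C/G/T strings of 380 nt (dada2-style ASVs
carry no ambiguity codes); `ecotype_pairs` pairs differ at exactly one
position, and the construction verifies all other pairs sit at Hamming
distance ≥ 2. Ecotype pair members receive contrasting ice/water
affinities, mirroring ice/pelagic ecotype pairs seen in nature.
Taxonomy strings come from a fixed catalogue of Arctic lineages (diatoms,
Mamiellophyceae, haptophytes, cryptophytes, pelagophytes, plus
heterotrophic and mixotrophic groups), several ASVs per species so
species-level aggregation is non-trivial.

The reference corpus draws `n_ref_samples` (default 300) samples whose
latitudes come from the zone pools given by `zone_mix` (default roughly
equal thirds, so every zone's classification path is exercised); one
dataset is a repeated station — ~n/10 samples jittered within ±0.02° of
one coordinate — to exercise geographic deduplication. Each taxon present
in the reference (90% of taxa by default) occurs in a reference sample of
its true zone with probability `home_rate` = 0.8 and elsewhere with
`stray_rate` = 0.02. Reference sequences are exact copies, truncations
(5–40 nt per end) or extensions (5–25 random nt per end) of the study
sequence; ecotype members always get exact copies, because a truncation
that removed the single differing site would legitimately match both pair
members and merge them.

What the generator does **not** emulate: sequencing error, chimeras,
PCR/primer bias, unequal library sizes, environmental covariates, spatial
autocorrelation of reference sampling, or any real taxonomic abundance
structure. Passing recovery tests therefore demonstrate that the
*computations* are correct under a known model, not that the statistical
procedures are robust to real-data artifacts.

## Clustering (cASVs)

Two sequences match when identical over their overlap: one is a substring
of the other (any length), or a suffix of one equals a prefix of the
other over ≥ `min_overlap` nt (default 100) with zero mismatches.
Matching is gapless: ASVs of one locus differ by primer trimming, not
indels. Reference ASVs merge transitively (connected components); each
study ASV then joins the matching reference cluster. A study ASV matching
several clusters joins the one whose *matching study ASVs* carry the most
total reads — computed over the full match relation before any
assignment, so the outcome is independent of input order — with ties
broken by smallest cASV id (the lexicographically smallest member id of
the cluster). Study ASVs never merge with each other directly; unmatched
ones found singleton cASVs. An exhaustive k-gram prefilter (any match
implies the first `min_overlap` nt of one sequence occur verbatim in the
other) prunes candidate pairs; a brute-force all-shifts matcher plus
connected components serves as the independent oracle in the tests.

## Biogeography classification

Occurrences are deduplicated within (cASV, dataset) on coordinates
rounded to multiples of `dedup_precision` (default 0.1°, collapsing
station re-occupations and GPS jitter without merging distinct stations),
then binned: polar |φ| ≥ 66°, temperate 23° ≤ |φ| < 66°, tropical
|φ| < 23° (boundaries resolve upward: 66 is polar, 23 temperate).
Categories use non-strict 90% thresholds evaluated in integer arithmetic
(10·x ≥ 9·total), so the boundary is exact. Rule order: occurrence floor
(`min_samples` = 5, counted after deduplication); single-zone rules
(polar, temperate, tropical); two-zone rules (polar-temperate,
temperate-tropical); cosmopolitan (all three zones occupied); otherwise
unallocated. Single-zone rules must precede two-zone rules — a two-zone
share always dominates its single-zone shares, so the reverse order could
never assign a pure temperate or tropical distribution its own category.
Polar+tropical mixtures that fit no rule are unallocated with a logged
warning. No Arctic/Antarctic split is attempted within "polar".

## Community statistics

Relative abundances are per-sample proportions after aggregating ASVs to
the species rank (the last lineage field; undescribed clades keep their
placeholder names). The trophic-mode filter walks each lineage
species-first and keeps phototrophs and mixotrophs at the deepest
matching rank, so a heterotrophic genus inside a mixotrophic class is
dropped; lineages absent from the lookup are dropped with a logged count.
Top taxa are the minimal read-ranked prefix reaching the coverage
threshold (default 75%), ties by name.

Bray–Curtis is computed by scipy (`pdist`, algebraically identical to
1 − 2Σmin/(Σ+Σ)); an all-zero sample pair is undefined and reported as 0
with a warning rather than NaN. ANOSIM is implemented in-package: tied
ranks over all off-diagonal pairs, R = (r̄_B − r̄_W)/(n(n−1)/4) ∈ [−1, 1],
one-sided permutation p with a seeded generator (scikit-bio's
implementation, which exposes no seed, is the cross-check in the tests).
Default 9999 permutations everywhere; p can never fall below
1/(N + 1).

## Indicator analysis

"IndVal" here is the group-size-corrected form: specificity
A = x̄_target / Σ_g x̄_g uses group *means*, so unbalanced designs do not
inflate the larger group, and B is the presence frequency within the
target group. The screen runs on per-sample relative abundances (library
sizes should not masquerade as specificity); A is scale-free and B
presence-based, so the statistic is invariant to rescaling counts. The
permutation null recomputes the *best-group* statistic per shuffle —
conservative for the selected group — and an ASV absent everywhere gets
stat 0 with an `absent` flag. The screen tests the `top_n` (default 20)
most abundant photosynthetic ASVs against substrate (ice/water) and phase
(dark/light), stars raw p at 0.05/0.01/0.001, and additionally emits a
Holm-corrected column per comparison that is not used for the flags. A
float tolerance of 1e-12 when comparing permuted to observed statistics
keeps exact ties (e.g. a constant taxon, whose p must be 1) from being
broken by rounding noise.

## Problem sizes and numerical choices

The default study (300 taxa × 162 samples, 300 reference samples) runs
end-to-end in under a minute on one CPU. The test-suite and acceptance
experiments use scaled designs chosen as the smallest sizes at which each
property is statistically meaningful: oracle equivalence on 50 instances
of 30–200 sequences (40–60 nt, min_overlap 20, mixing copies,
truncations, extensions and point mutants); ecotype preservation and
label recovery over 20 seeds (recovery at the stated reference size of
300 samples, scoring taxa with ≥ 10 deduplicated occurrences); indicator
type-I error over 1000 null ASVs at 999 permutations against the binomial
99% band around 0.05; power over 100 seeds with affinity_effect 8 and
12 + 12 samples; ANOSIM null mean over 200 relabelings.

Seeds: every stochastic step takes an explicit seed derived
deterministically from the run seed; permutation engines use numpy
Generators, never global state.

## Limitations

- The clustering tie-break (summed study reads, then id) is one of
  several defensible conventions; cluster membership is unaffected, only
  the multi-match assignment.
- Classification treats reference sampling as exchangeable; real corpora
  oversample coastal time series, which deduplication only partly
  offsets.
- The permutation null for indicators is unstratified; designs with
  strong nuisance structure (e.g. paired depths) would need restricted
  permutations.
- Simulated communities have identical library sizes; the relative-
  abundance normalisation is therefore exercised but not stressed.
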