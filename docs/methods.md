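# Methods

This note documents the models, parameter choices and numerical decisions
behind `vegclass`, and what the synthetic test system does and does not
demonstrate.

## Relevé model and cover handling

A relevé holds at most one record per (taxon, layer) with cover as a
fraction in [0, 1]. Cover-abundance codes are converted to class midpoints
through a named, user-replaceable scale; the packaged Braun-Blanquet
default is r → 0.1 %, + → 0.5 %, 1 → 2.5 %, 2 → 15 %, 3 → 37.5 %,
4 → 62.5 %, 5 → 87.5 % (an extended dialect with the 2m/2a/2b split is
also shipped). Field practice varies, so the scale is an explicit input
rather than a hidden constant.

Whenever several covers must be collapsed into one — a species recorded in
several layers, or taxa merged into an aggregate — the independence
formula `1 − Π(1 − cᵢ)` is used, the combined cover under random overlap.
The same formula defines the total-cover (`TC`) group operator, keeping
layer pooling, taxon merging and the rule engine mutually consistent.
Taxon names are matched after whitespace normalization and case folding;
there is no fuzzy matching, by design — determinism beats convenience in a
classification pipeline.

Plot-level filters mirror standard archive hygiene: plots without
coordinates are dropped when coordinates are required, areas outside
[1, 100] m² are dropped with *inclusive* bounds (the exclusion rule is
"smaller than 1 / greater than 100"), and records of cultivated species
are removed without discarding the plot. Plots with *unknown* area are
excluded whenever area bounds are enforced, mirroring the coordinate rule;
pass `min_area=None, max_area=None` to keep them.

## The rule engine

Formulas follow a small grammar (`TC`/`SC`/`COV` comparisons with `>` or
`>=`, `SOC` presence, `AND`/`OR`/`NOT`, parentheses); group names may
contain spaces and run to the closing parenthesis. Packaged definitions
use strict `>` thresholds. The sociological-group presence rule — at
least half the members, rounded up — is the common convention where no
explicit minimum is published; it can be overridden per group
(`min_members`) in the group file.

Unequivocal classification evaluates all association definitions first
(name-sorted, so conflict reports are deterministic): exactly one match
assigns the association plus its ancestors; zero matches fall through to
the alliance rank and then the class; two or more matches at a rank set
the conflict flag, record the contenders, and fall through. This makes
the "at most one unit per rank" guarantee explicit while still using the
hierarchy as a safety net.

The packaged definition set for the ephemeral dwarf-wetland class is a
*reconstruction*: class and alliances gate on their total-cover groups at
25 %, associations pair a sociological group or a 25 % single-species
dominance clause with the alliance total-cover gate (one `NOT` clause
separates the two associations that share cyperoid dominants). Every
threshold sits in one editable YAML file; users with access to a published
expert-system file should transcribe it there.

## Fidelity and species roles

Fidelity is the phi coefficient of the presence/absence 2×2 table, unit
against all remaining relevés of the analysed (post-stratification) set,
with no group-size standardization (a standardized variant would change
phi values across unit sizes; the classical coefficient is the default
and the one the thresholds below were calibrated for). Zero denominators
(ubiquitous or absent species, empty or universal units) return phi = 0 by
convention. Significance is the one-sided Fisher exact test for
over-representation — the field convention when a two-sided test is not
explicitly requested.

Role thresholds are boundary-exact as usually printed: diagnostic or
differential at phi ≥ 0.20 (alliances) / ≥ 0.25 (associations) with
p < 0.001 — diagnostic only for species on the preselected 63-name class
list, differential otherwise; constant at frequency ≥ 40 %; dominant at
cover ≥ 25 % in ≥ 5 % of the unit's relevés. Class-rank units reuse the
alliance threshold (no separate class threshold is published). Reported
frequencies are rounded to one decimal, but all role decisions use
unrounded values.

## Stratification

Grid cells are 1.25 × 0.75 *arc-minutes* (≈ 1.4 × 1.4 km at 52° N; a
degree-sized cell would be ~85 km and could not match that footprint),
anchored at (0° E, 0° N) — the origin is a convention, exposed in
`GridSpec`. Sampling keeps at most `per_cell` (default 3) plots per
(cell, unit) stratum, uniformly without replacement under a seeded
generator; strata and plot ids are visited in sorted order so a seed fully
determines the sample, and sampling a sample returns it unchanged.

## Ordination

Correspondence analysis is computed by SVD of the standardized residual
matrix `(P − rcᵀ)/sqrt(rcᵀ)`; row/column scores are standard coordinates
(weighted mean 0, weighted sum of squares 1), which satisfy the transition
formulas up to the `sqrt(eigenvalue)` factor.

DCA extracts axis 1 as plain CA axis 1. Each later axis runs reciprocal
averaging started from the corresponding CA axis (deterministic, seed-free
initialization), detrending the site scores against *every* previously
extracted axis at each iteration by the segment-means method with 26
segments; detrending annihilates both the trivial constant vector and any
structure expressible as a function of earlier axes, so no separate
centering step is needed and the returned axes have segment means at
machine zero. Convergence tolerance is 1e-10 on the maximum score change
with at most 10,000 iterations; non-convergence raises, naming the axis —
this occurs when the requested axis lies in a near-degenerate
tiny-eigenvalue subspace (e.g. axis 3 of a noise-free single gradient),
where no meaningful direction exists; request fewer axes. Hill's
nonlinear rescaling is not implemented: the detrending-by-segments step is
specified by segment count alone, rescaling is a separate procedure with
its own conventions, and omitting it keeps reported scores in the
weighted unit-variance scaling stated above. Axis-share-of-variance
percentages printed in ordination diagrams elsewhere are therefore not
comparable outputs of this package.

Ellenberg indicator values enter as plot-level community-weighted means
(CWM), `Σ cᵢvᵢ / Σ cᵢ` over the species with a value for the indicator
(an unweighted mode exists; CWM is the default as the more specific
convention). Plots where no species carries a value are flagged undefined
and dropped from the supplementary fit. Supplementary fitting regresses
each indicator on the site scores (least squares with intercept), reports
the unit coefficient direction and r², and a permutation p-value
(default 999 permutations, seeded); constant indicators get r² = 0, p = 1.
The packaged indicator table is a **synthetic stand-in**
(`eiv_synthetic.csv`) with plausible values for the species the generator
emits — published indicator tables are not redistributable, and nothing in
the test suite depends on specific indicator values.

## Synthetic data

The generator emulates the *structure* of a classified vegetation-plot
archive. Each of the 14 unit profiles draws its core species — the
members of the unit's sociological group, or its dominant diagnostic for
dominance-defined units — at high occurrence probability (0.85–1.0) with
log-uniform covers chosen so the packaged definitions fire (sociological
cores at 15–80 %, dominance cores at 30–90 %), plus unit companions and a
20-species background pool shared across all units (common wetland
companions such as *Juncus bufonius* and *Gnaphalium uliginosum*, at low
covers capped so that background alone never reaches the class total-cover
gate). Log-uniform covers reflect the many-low/few-high cover pattern of
ephemeral vegetation. Coordinates are Gaussian around unit-specific
centers inside Poland's bounding box (scatter 0.05–0.8°, so grid strata
are non-trivial); areas are uniform on [1, 100] m²; default plot counts
are the published unit sizes (sum 541), overridable per run. Everything
is driven by one seed and regenerates bit-identically.

`perturb` degrades a dataset — record dropout, multiplicative log-normal
cover jitter, and injection of background-only plots — to model the
impoverished relevés that real archives classify only at alliance or
class level.

What passing tests show: the engine, statistics and ordination are
correct on data whose generating process matches the model assumptions
(well-separated units, independent species draws). What they do not show:
performance on real archives, where species co-occur, richness varies,
covers are code-quantized and units intergrade. The balanced 14 × 50
configuration used for the recovery checks measures machinery, not field
accuracy.

## Problem sizes and defaults in the checks

The test suite and `scripts/acceptance.py` use: exhaustive 2×2 oracle
sweeps to N = 30 (tests) / N = 20 (script); CA oracle matrices up to
20 × 30; 10,000 random relevés for the engine-invariant sweep; 14 × 50
plots for label recovery; 200 seeds for the stratification χ² check
(α = 0.01); a 50-plot, 20-species noise-free coenocline for DCA rank
recovery. These sizes give stable verdicts in seconds on one CPU while
leaving every algorithm path exercised.

## Known limitations

- The packaged definition set is a plausible reconstruction, not a
  transcription of any published expert-system file.
- No Turboveg/XML ingestion and no taxonomic backbone resolution; names
  must already be canonical (a merge map handles aggregates).
- DCA omits nonlinear rescaling (see above); eigenvalue-share percentages
  are not produced.
- GeoJSON export is WGS84 lon/lat points only; cartography is out of
  scope.
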