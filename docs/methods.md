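# Methods

This note records the modeling conventions, defaults, and numerical
choices behind the package, and what the synthetic-data tests do and do
not demonstrate.

## Object and region model

Cells are points in a continuous micrometer plane; no pixel grid is
assumed. Each carries a base marker (Ki67 single-positive, CD4, CD8) and a
proliferation flag; Ki67 single-positive cells are proliferating by
definition, so the atomic cell categories are Ki67, CD4±, CD8± (five in
total). Regions are shapely polygons: the *entire tissue* is the annotated
tissue with exclusion polygons subtracted before anything else happens;
the *tumor* compartment is entire ∩ annotated tumor; *non-tumor* is the
remainder. Objects outside the entire tissue are dropped at load time.
Areas are reported in mm² so densities come out in 1/mm².

Boundary convention: regions are closed — a point on a polygon boundary is
inside — and tumor takes precedence over non-tumor on their shared
boundary, so every retained object belongs to exactly one compartment.
Implemented with boundary-inclusive point-in-polygon tests
(`shapely.intersects_xy`).

## Cell-set catalog

The default catalog has 10 entries: the 7 named types (Ki67; CD4 and CD8
each as any / proliferating / non-proliferating) plus 3 combined T-cell
sets (CD4 ∪ CD8 in the same three variants). Ratio features draw operands
from these 10 plus 3 union sets (all cells; all proliferating cells =
Ki67 ∪ proliferating T; Ki67 ∪ CD8); all ordered distinct pairs of the 13
operands give the 156-pair ratio catalog. These enumerations are the
package's own defaults — the catalog is config-overridable, and any list
of named membership predicates works.

## Distance criteria

`dist(ω, Ω)` is the Euclidean distance to the nearest member of Ω,
computed slide-wide with a KD-tree. Two conventions matter:

* **Self-exclusion.** When ω ∈ Ω (overlapping sets such as CD8^any used as
  reference for a CD8^prolif count), ω is never its own neighbor;
  membership is decided by object identity, so genuinely coincident
  points of different cells still count. Without this, every ≤θ criterion
  over an overlapping reference set would be trivially true.
* **Empty reference sets** have distance +∞ everywhere: ≤θ criteria count
  0 and >θ criteria count everything, the limiting behavior of the
  comparison.

Multi-reference criteria apply OR/AND across the *individual comparisons*
(⋁ dist ≤ θ means "some reference set within θ"). Consequently the
complement of an OR-≤ criterion is the AND-> criterion (De Morgan), and OR
dominates AND in both directions; the property suite asserts exactly
these identities.

The default distance-combination catalog is a systematic enumeration —
LE fractions, LE counts, GT counts, GT fractions, each over the 10
numerator sets × 7 single-reference sets, followed by paired OR/AND
references — truncated deterministically to 279 combinations, which
crossed with the 7-threshold grid and 3 regions yields 5,859 global
distance features and preserves the catalog arithmetic of the standard
configuration (6,387 global features overall). The truncation point keeps
all LE fractions and counts; OR/AND pair references are fully supported
and tested but enter the default catalog only when the configured size is
raised.

Ratios may carry the criterion on the numerator only (a "fraction of cells
near …" feature has an unrestricted denominator) or on both sides; both
forms are in the catalog (`criterion_on_denominator` flag). Numerator and
denominator always share one criterion; independent criteria per side are
out of scope.

## Unavailability

A feature value on a slide is either a finite number or explicitly
unavailable with a reason: `region_missing` (compartment absent or zero
area) or `nonfinite` (zero denominator in a global ratio, or fewer than
two finite tile values / zero normalizer in a heterogeneity measure).
Global non-finite ratios are mapped to unavailable immediately; per-tile
values instead keep IEEE semantics (x/0 = ∞ for x ≠ 0, 0/0 = NaN) and the
non-finite values are filtered just before a dispersion measure is
computed. In the slides × features matrix, unavailable entries are NaN;
this is unambiguous because every available value is finite by
construction.

## Tiling and heterogeneity measures

Square axis-aligned tiles, edge 250 / 500 / 1000 µm, anchored at the
tissue bounding-box minimum (the anchor is configurable as an offset,
since tiling phase is a known source of variability). A tile is retained
when its overlap with the entire tissue is at least 10 % of the tile area
(configurable); tumor-scope grids additionally require the tile to lie
entirely inside the tumor compartment. Each object belongs to exactly one
tile by floor-division binning (indices clamped at the outer bounding-box
edge), so per-tile counts partition region counts on exactly tiled
tissue. Tile areas used for densities are the tile ∩ tissue overlap areas.

Eight measures per (base feature, tile size, scope):

* COV — sample standard deviation (n−1 normalization) / mean; undefined
  when mean = 0;
* QCD — (p75 − p25)/(p75 + p25); undefined when p75 + p25 = 0;
* RP{3,5,10,90,95,97} — percentile / median; undefined when median = 0.

Percentiles interpolate linearly between order statistics (numpy's
default), and every measure requires at least two finite tile values —
dispersion of fewer points is meaningless. These two conventions are
declared here because results are mildly sensitive to them; the test
oracles implement them independently.

## Ranking and significance

Folded ROC-AUC is computed from midranks (ties count ½, identical to the
trapezoidal ROC rule and to `sklearn.metrics.roc_auc_score`, against which
the implementation is cross-checked); AUC < 0.5 is reflected. OPM
multiplies the rescaled folded AUC by the two per-class availability
fractions; features with zero availability in either class are flagged
unrankable and score 0 rather than erroring. Ranking is by descending OPM
with ties broken by canonical feature id, so output order is fully
deterministic.

The null model draws a fully available uniform(0, 1) matrix with the
cohort's class assignment. Uniformity is without loss of generality for
any continuous feature distribution because the AUC is rank-based;
availability patterns are *not* simulated — a documented simplification.
For a 19 vs. 53 cohort, OPM ≥ 0.6 at full availability is exactly folded
AUC ≥ 0.8, a far tail of the Mann–Whitney distribution: the property suite
verifies that the empirical null rate stays below 10⁻³ per feature at 10⁵
features. The screening threshold 0.6 is a configurable default, and for
very small cohorts the null histogram shows it is not meaningful (see the
README example).

## Synthetic slides

The verification generator emulates the designed two-group experiment:
1 mm² square tissue, no tumor compartment, 1,000 Ki67 and 50 proliferating
CD8 placed uniformly by sequential rejection sampling (per-object retry
budget, default 10,000 — densities are far below jamming so this
converges). Group A enforces Ki67–CD8 distances > 15 µm for all CD8;
group B for 45, while 5 violator CD8 are placed 10–15 µm from five
distinct Ki67 anchors; all pairwise distances are ≥ 10 µm in both groups.
The target fraction is therefore exactly 0 on every A slide and ≥ 5/1000
on every B slide, giving AUC 1 at any cohort size. Every generated slide
is certified by an independent O(n²) brute-force constraint check before
being returned, and generation is bit-reproducible given (config, seed).
Note one wrinkle in the stated design: a CD8-denominated reading of the
group-B construction would give 5/50 = 0.1; the generator enforces the
Ki67-denominated feature that is actually ranked, which is positive either
way, so the discrimination result does not depend on the reading.

The generic generator is a homogeneous Poisson process per cell type
(defaults: Ki67 800/mm², CD4 30 + 150/mm², CD8 40 + 180/mm² for
proliferating + non-proliferating — a moderately inflamed specimen), with
an optional centered-square tumor compartment and circular hotspots
implemented as additional Poisson points at (multiplier − 1) × base
intensity inside a disc. It exercises compartments and heterogeneity
machinery; it does *not* emulate cell-cell interaction structure, realistic
tissue shapes, annotation noise, or staining variability, so passing tests
demonstrate computational correctness on idealized geometry, not
robustness to real-data artifacts.

## Pipeline and problem sizes

Slides are analyzed independently (process-level parallelism), each into
its own sqlite store, merged at the end; results are identical for any
worker count, and re-runs are cached on (slide content hash, config
hash). The test suite runs the full default catalog (108,579 features) on
a 10+10 verification cohort — about 40 s on one CPU — and checks oracle
equivalence on 50 random slides of 40–200 objects against a pure-Python
brute-force implementation with a reduced-breadth catalog (3 thresholds,
2 tile sizes, OR/AND pair references, all 8 measures) covering every
feature class and code path.

## Known limitations

* Tumor-scope tiles must lie entirely in the tumor, so tumor margins are
  under-represented at large tile sizes (an intersection-weighted variant
  is a noted alternative, not implemented).
* Overlap-weighted dispersion statistics, hexagonal/ring tilings, and
  texture measures over the tile lattice are out of scope.
* Single-feature screening only: no multi-feature classifiers or
  cross-validation.
* The 279-combination distance catalog is a generated stand-in sized to
  the standard configuration; studies with a curated combination list
  should supply it via the catalog config.
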