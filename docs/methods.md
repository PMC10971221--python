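# Methods

## Model and rationale

The object of analysis is a wide matrix of normalized mass-spectral peak
areas: P proteins × (D donors × C conditions), with the *same* D donors in
every condition. Working per protein and condition, the D log abundances
form one point in a D-dimensional donor space. Two properties of this
representation drive the whole design:

* same-donor pairing means a protein's displacement between two
  conditions cancels donor-level offsets — the Euclidean distance between
  its two points measures how far the *actual* donor values moved, taking
  both magnitude and direction into account;
* with D = 3 the space is low-dimensional, where the Euclidean metric is
  well behaved (for much larger donor panels a different metric should be
  considered).

The workflow is descriptive, not inferential: it ranks and flags proteins
by observed displacement instead of estimating population effects, which
is the appropriate posture at n = 3 per group. t-test p-values are still
computed and tiered, but they annotate the anomaly lists rather than gate
them.

## Pipeline stages and parameters

### Log transform (`preprocess`)

Default base 2, so downstream log fold changes read in doublings. The
base is recorded and configurable (2/10/e); all bases are equivalent up to
a global scale, and the distance threshold is scale-equivariant, so the
flagged set does not depend on the base.

Non-positive raw areas (possible in chromatographic quantification, e.g.
co-eluting compounds producing negative peaks) are not log-transformable.
Policies: `drop_protein` (default — a protein that is not consistently
quantified is treated as not analyzable rather than imputed), `drop_cell`,
or `epsilon_floor(ε)`. Missing cells stay missing; a protein missing a
value in a condition simply emits no donor point there and is excluded
from comparisons that need it (no imputation anywhere).

### Density filter (`density`)

All conditions' points are pooled and ordered by OPTICS
(scikit-learn; Euclidean metric; core distance = distance to the
min_pts-th nearest neighbor with the neighborhood including the point
itself, the DBSCAN counting convention). Clusters are extracted at a fixed
reachability radius eps — the DBSCAN-equivalent extraction, not the
ξ-steepness method, because the quoted "reachability parameter" reads as a
radius. Defaults min_pts = 50, eps = 0.05 (the values used on the
motivating dataset). eps is in log-abundance units and therefore only
meaningful at a given data scale; `suggest_eps` adapts it as
`inflation × quantile(k-distance, q)` with q = 0.98 and inflation = 2.
The intent of the filter is to separate *distinct point clouds* (different
biological populations, e.g. a secondary low-abundance cloud), not to trim
the periphery of the main cloud — periphery points are exactly what the
outlier stage must see — hence an eps above nearly all within-cloud
k-distances.

The retained ("primary") cluster is, by default, the most populous cluster
whose member points have strictly positive raw peak areas in all donors
(`largest_all_positive`; falls back to `largest` with a warning). A
protein enters a comparison only if its points in *both* conditions are
members (`membership_rule: both`; `either` available) — mixing an
in-cluster point with an unfiltered one would compare across populations.

### Isolation forest (`forest`)

Per condition, on the cluster-retained points. scikit-learn's
IsolationForest provides the trees; scores are reported on the standard
anomaly scale s(x) = 2^(−E[h(x)]/c(n)) ∈ (0, 1), higher = more anomalous,
with c(n) = 2·H(n−1) − 2(n−1)/n computed in-package (exact harmonic sums
up to n = 10 000, ln(n−1) + γ above). Defaults: 500 trees, subsample
min(256, n), seed 1337 fanned out from the run seed. Flagging: the top
⌈contamination·n⌉ scores (contamination = 0.10 by default; "auto" flags
s > 0.5). Ties break by input order for determinism. A comparison carries
forward the **union** of the two conditions' outlier sets: a protein
extreme in either condition can produce a large displacement.

### Distance threshold (`distance`)

For each eligible protein, d = ‖x_treatment − x_reference‖₂ (the diagonal
of the cross-condition distance matrix) and logFC = mean(treatment) −
mean(reference) on the log scale. The anomaly threshold is
τ = mean(d) + k·sd(d) with k = 1 and the *sample* SD (ddof = 1, the
small-n convention; both configurable). Flagging is strictly d > τ, so
ties at τ are not flagged, and a degenerate all-equal distance set flags
nothing. Fewer than two distance records is an error (no SD). In a normal
distribution about 68% of values fall within one SD of the mean, which is
the intuition behind the cut-off; k is exposed because the cut-off is an
empirical choice, not a significance level.

### Descriptive layer (`descriptives`)

Student's pooled-variance two-sample t-test by default (Welch optional);
tiers on half-open intervals [0, 0.05) / [0.05, 0.1) / [0.1, 1]. Zero
pooled variance: p = 1 for equal means, p = 0 (the limit) otherwise,
logged. Within-group variance and CV use ddof = 1 on the same log-scale
values as the rest of the pipeline. The quadratic logFC-vs-distance fit is
an ordinary least-squares degree-2 polynomial; R² is defined as 0 for
constant response. Venn region counts use exact accession strings
(isoforms such as P24821-4 are distinct from their parent). No
multiple-testing correction is applied: p-values annotate, they do not
gate.

## Synthetic data (`synthetic`)

The generator states a world matching the pipeline's assumptions, on the
log₂ scale:

ℓ(p, d, c) = μ_p + δ_d + β_{p,c} + ε,  raw = 2^ℓ

| parameter | default | meaning |
|---|---|---|
| μ₀, σ_p | 20, 0.75 | protein baselines μ_p ~ N(μ₀, σ_p); the main cloud models one homogeneous expression cluster, so baseline spread sits modestly above noise |
| σ_d | 0.5 | donor offsets δ_d, shared across proteins and conditions (they translate the cloud and cancel in displacements) |
| σ_ε | 0.5 | per-cell noise; 0.5 log₂ units ≈ 35% CV, consistent with commonly reported 20–30% technical CVs plus donor-level biological noise |
| f, Δ | 0.02, 3.0 | fraction of planted anomalies and their shift (random sign) in the doped condition only: Δ = 6σ_ε = 3 log₂ units, an 8-fold, genuinely "extremely changing" effect |
| contaminant fraction/offset | 0, −8 | optional secondary low-abundance cloud (baselines shifted by the offset) to exercise the density filter |

Closed form used in tests: a null protein's displacement per donor is
N(0, 2σ_ε²), so d = σ_ε√2·χ_D and E[d] = 2σ_ε·Γ((D+1)/2)/Γ(D/2)
(≈ 2.2568·σ_ε at D = 3).

What the generator does **not** emulate: missing-value mechanisms of LFQ
match-between-runs, intensity-dependent noise, correlated protein blocks,
or acquisition artifacts. A green recovery test therefore establishes that
the pipeline's stages compose correctly and detect planted multiplicative
shifts well above noise in a homogeneous cloud — not that it would attain
the same recall on real data with structured noise.

## Numerical and design choices

* Anomalies are planted only in the treatment (doped) condition; the other
  conditions share the null profile, mirroring the causal design where
  expression changes against the matched control are attributed to the
  treatment (ion doping).
* Determinism: one global run seed fans out to per-condition forest seeds
  by fixed offsets; OPTICS and all other stages are deterministic given
  input order; neighbor and score ties break by (value, input index).
  Identical config + seed reproduce output files byte for byte.
* OPTICS extraction vs DBSCAN: equivalence holds exactly on core points
  and definite noise; border points are order-dependent in both
  algorithms, and tests compare on the unambiguous points.
* Abundance tables accept any finite real value (not just non-negative):
  negative chromatographic peak areas occur in practice and are precisely
  what the non-positive policies and the all-positive cluster rule handle.
* Reported tables render p-values with 5 decimals and variances with 2;
  rounding happens at report time only.

## Limitations

* The mean + k·SD threshold is a single global cut-off; natural gaps in
  the sorted distances may suggest per-protein judgment that the tool
  deliberately leaves to the analyst (the sorted-bar export exists for
  exactly that inspection).
* Euclidean distance is appropriate at D = 3 but degrades with many
  donors (curse of dimensionality); no alternative metrics are
  implemented.
* The forest's contamination default (0.10) encodes how large the
  "extreme minority" per condition is assumed to be; there is no
  data-driven estimate of it.
* Only the eps-radius OPTICS extraction is implemented (no ξ method, no
  alternative clusterers), and only the isolation forest as detector.
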