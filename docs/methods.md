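# Methods

## Data model

The atomic datum is a quadrat record: one species observed in one
1 m × 1 m plot, with mean height (any length unit; only relative
heights are used), fractional ground cover in [0, 1] (percent inputs
are divided by 100 on read), and an abundance count of individuals or
clumps. Quadrats nest in transects, transects in sites, and every
record belongs to one of three degradation stages S1–S3 (healthy swamp
wetland → slightly degraded wet meadow → degraded dry meadow), the
space-for-time gradient the analysis is organized around. The key
(stage, quadrat, species) must be unique. Species names are
canonicalized by collapsing whitespace, capitalizing the genus and
lower-casing the remaining tokens; infraspecific rank markers
("subsp.", "var.") are kept, and no external taxonomy service is
consulted. Genus counts are derived as distinct first tokens; family
counts are not derivable from binomials and are out of scope.

## Resource states and utilization

Niche indices need a species × resource-state utilization matrix. The
survey design does not define resource states explicitly, so the
package treats sampling units as states: by default every quadrat of a
stage (pooled across sites) is one state; a "transect" option pools
each transect's quadrats by summing. Quadrat-level states are the
finest unit the survey defines and give breadths on the scale of the
published tables (up to ~6.6). The utilization measure is abundance by
default; a per-quadrat importance component (the within-quadrat mean of
relative height, cover and abundance) is available where abundance
alone is considered too crude. Species absent from every state of a
stage are dropped there; rows are then normalized to the profiles
p_ij used by all indices. Pairs involving a species absent at a stage
are simply not formed — they are never zero-filled.

## Importance values

IV_i = (RH_i + RC_i + RF_i)/3. Heights and covers are species means
over occupied quadrats only (absence is already carried by the
frequency term); frequency is the fraction of the stage's quadrats
occupied. Two relativizations are offered. "sum" divides each metric by
its stage total, so each relative metric and the IVs sum to 1. "max"
(the default) divides by the stage maximum; this matches the magnitude
scale of published dominance tables in which several species carry
IV > 0.5 per stage, which is impossible under sum-relativization. The
exact relativization used by any given published table is rarely
printed, so both remain available and outputs record which was used.

## Niche breadth and overlap

Levins breadth B = 1/Σp² is bounded by [1, r] and reported raw
(matching published magnitudes), with the standardized (B−1)/(r−1)
alongside. Overlap defaults to Pianka's symmetric index — bounded in
[0, 1] and consistent with the 0.3/0.8 interval scheme — while the
directed Levins variant is retained as an option; the two Levins
directions satisfy the reciprocity identity O_ik·Σp_i² = O_ki·Σp_k²,
which the tests exercise on random profiles. Interval classification
places the boundary values 0.3 and 0.8 in the middle bin ("<0.3",
"0.3–0.8", ">0.8"). The mean overlap averages unordered pairs once for
Pianka and all ordered pairs for Levins. The IV-versus-breadth
regression is ordinary least squares with R² the squared Pearson
correlation; a constant response is reported as slope 0, R² = 0 rather
than an error, while zero variance in the predictor is an error.

## Overlap networks and modules

Every species of a stage is a node; an edge joins two species whose
symmetrized overlap strictly exceeds a threshold (default 0, i.e. all
positive overlaps become edges, since no published pruning rule
exists), weighted by that overlap. Levins pairs are symmetrized by the
mean of the two directions by default (max/min available); Pianka needs
none. Isolated nodes are retained.

Module detection maximizes weighted Newman–Girvan modularity. The
default algorithm is a deterministic greedy agglomeration: start from
singletons, repeatedly merge the community pair with the largest
positive gain ΔQ = w_ab/m − S_a·S_b/2m², breaking ties by the
lexicographically smallest community pair, then run single-node move
refinement to convergence in sorted node order. A seeded Louvain
("multilevel") alternative is provided, and an exhaustive enumeration
of all set partitions (restricted-growth order, ≤ 12 connected nodes)
serves as the exact oracle; the greedy result never exceeds the
exhaustive optimum and attains it on structured test graphs
(disconnected cliques, weak-bridge barbells). Isolated nodes form
singleton modules but are excluded from the reported module count,
mirroring how published module counts show unconnected species outside
any module. Modularity of an edgeless network is undefined (error); a
partition over an edgeless node set is reported with Q = NaN and zero
modules.

Stable groups: two species are stably co-moduled when they co-occur in
at least `min_shared_stages` stages (default 2) and share a module in
*every* stage where both occur. Reported groups are maximal cliques of
this relation, made disjoint greedily largest-first with lexicographic
tie-break; singletons are not reported. When the published group-ID
table is the input, species present but unassigned are placed in
private singleton modules so that "unassigned" never counts as shared
membership.

## Synthetic communities

The generator emulates the survey's statistical structure — a
specialist/generalist mix and overlap that rises with degradation —
without claiming to model any real wetland. Per stage with n quadrats,
species i draws a latent profile q_i ~ Dirichlet(α_i·1_n); α_i is
drawn log-uniformly from (0.01, 0.15), a range chosen so true Levins
breadths span roughly 1–6.6 over 54 quadrats, the magnitude range of
the published width table. The stage's shared optimum
u_s ~ Dirichlet(2·1_n) and the truth profile is the blend
p_i = (1−h_s)·q_i + h_s·u_s with stage homogenization h_s (defaults
0.1/0.4/0.7, non-decreasing; h = 1 makes all overlaps exactly 1).
Abundance is Poisson with mean `abundance_scale·n·p_ij`, so
`abundance_scale` (default 50) is the expected count per quadrat for a
perfectly even species; zero counts are genuine absences, which is how
frequencies below 1 arise. Heights are log-normal per species (median
15, species-level σ_log 0.4, quadrat jitter 0.15); cover saturates with
abundance as 1 − exp(−a/abundance_scale), capped at 0.999. Defaults use
46 species and 54 quadrats per stage, laid out as 6 sites × 3
transects × 3 quadrats. One master seed drives everything; per-stage
sub-streams are spawned from it, so adding a stage never perturbs
earlier stages, and identical seeds give identical records.

What the generator does **not** emulate: spatial autocorrelation among
quadrats, soil/hydrology covariates, grazing disturbance, or any real
species' traits. Passing recovery tests therefore shows the estimators
are correct under the stated sampling model, not that field conclusions
at any particular site are reproduced — the published stage-level
overlap means and module counts depend on undeposited raw data and are
only matched in qualitative direction (mean overlap rising S1→S3).

## Pipeline and verification

`run_pipeline` chains records → IV → widths → overlaps → interval
spectrum → network → modules → stable groups, driven by a YAML config
in which every analysis choice (state definition, IV normalization,
overlap method, threshold, symmetrization, module algorithm,
min-shared-stages, seed) is an explicit key; a JSON manifest echoes
them all plus per-stage summaries, and reruns with the same config are
byte-identical. A single-stage run skips the stable-group step with a
logged notice. `verify_fixture` recomputes the quantities derivable
from the packaged species table — 46 species, 33 genera, the S1
maximum width 4.92 with IV 0.07, and the *Triglochin palustre* width
decreases (computed 79.67% and 40.65% from 2-d.p. table entries against
published 79.66% / 40.70%, tolerance 0.05 points) — and exits non-zero
on any mismatch. The packaged table is integrity-checked by SHA-256 at
load; one cell whose printed width reads "100" next to widths of ~1–6
is transcribed as 1.00 with the raw string preserved in a comment
column.

## Problem sizes in the test suite

Unit and property tests run on toy communities (≤ 12 species, ≤ 10
quadrats) and random graphs of ≤ 8 nodes, where the exhaustive
modularity oracle (≤ 4140 partitions) is cheap. Estimator-recovery
tests use 40 species × 30 quadrats × 3 stages at abundance scale 50,
three fixed seeds; the acceptance script uses the full default scale
(46 species × 54 quadrats) and 100 random oracle graphs. The whole
suite completes in well under a minute.
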