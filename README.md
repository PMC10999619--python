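# nichecomm

Niche analysis of plant communities surveyed in quadrats along a
degradation gradient: species importance values, Levins niche breadth,
pairwise niche overlap (Pianka and Levins variants), overlap-interval
spectra, weighted niche-overlap networks with modularity-based module
detection, and cross-stage *stable module groups* — species that stay
co-moduled in every degradation stage where they co-occur.

It is aimed at vegetation ecologists working with space-for-time
designs (e.g. alpine lake riparian wetlands sampled as healthy S1,
slightly degraded S2 and degraded S3 stages), and ships a synthetic
community generator with known ground truth so every estimator can be
validated without field data.

## The indices

With `p_ij` the row-normalized utilization of species *i* over the
*r* sampling units (resource states) of a stage:

- **Importance value**  IV_i = (RH_i + RC_i + RF_i) / 3, the mean of the
  species' relative height, relative cover and relative frequency
  (relative to the stage maximum by default, or to the stage total).
- **Levins niche breadth**  B_i = 1 / Σ_j p_ij², from 1 (specialist) to
  r (perfect generalist); standardized B_std = (B−1)/(r−1).
- **Niche overlap**  Pianka: O_ik = Σ_j p_ij p_kj / √(Σ_j p_ij² · Σ_j p_kj²)
  (the cosine similarity of profiles, symmetric, in [0, 1]);
  Levins: O_ik = Σ_j p_ij p_kj / Σ_j p_ij² (directed).
  Overlaps are classified into the conventional intervals < 0.3,
  0.3–0.8 and > 0.8.
- **Modularity**  Q = (1/2m) Σ_ik [A_ik − k_i k_k / 2m] δ(c_i, c_k) on the
  weighted overlap network, maximized by a deterministic greedy
  agglomeration with node-move refinement (an exhaustive search over
  all partitions is available as an exact oracle on ≤ 12 nodes).

## Worked example

The package includes a transcription of a published 46-species table
(importance value / niche width / group ID per stage). Verifying it:

```sh
$ nichecomm verify-fixture
ok   n_species: computed 46.0000, expected 46 (tol 0)
ok   n_genera: computed 33.0000, expected 33 (tol 0)
ok   max_s1_width: computed 4.9200, expected 4.92 (tol 0.005)
ok   max_s1_width_iv: computed 0.0700, expected 0.07 (tol 0.005)
ok   triglochin_decrease_s1_s2_pct: computed 79.6748, expected 79.66 (tol 0.05)
ok   triglochin_decrease_s1_s3_pct: computed 40.6504, expected 40.7 (tol 0.05)
```

The 46 species span 33 genera; the widest S1 niche (B = 4.92,
*Triglochin palustre*) belongs to a species of low dominance
(IV = 0.07), and its breadth collapses by ~79.7% at S2 — the published
percentages are reproduced from the rounded table entries to within
0.05 points. Applying the stable-group search to the table's per-stage
group partitions recovers the five published groups: a 7-species and a
6-species herb group plus three sedge–halophyte pairs.

Running the full pipeline on a synthetic survey:

```python
from nichecomm import run_pipeline

result = run_pipeline({
    "seed": 3,
    "input": {"kind": "synthetic",
              "synthetic": {"n_species": 20, "n_quadrats_per_stage": 12}},
    "output": {"dir": "out"},
})
for stage, rep in result.stage_reports.items():
    print(stage, rep.richness, round(rep.mean_overlap, 3), rep.n_modules)
```

prints

```
S1 20 0.192 4
S2 20 0.294 4
S3 20 0.667 3
```

— 20 species per stage, with mean Pianka overlap rising along the
degradation gradient (the generator's homogenization default pulls all
species toward a shared resource optimum as degradation advances) and
the overlap network's module count shifting as the community
homogenizes. Per-stage CSVs, GraphML/TSV networks, a stable-group table
and a run manifest land in `out/`.

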