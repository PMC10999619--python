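"""Synthetic quadrat surveys with known niche structure.

Generates three-stage degradation series whose ground truth (per-species
utilization profiles, Levins breadths, pairwise overlaps) is recorded
alongside the sampled records, so every estimator in the package can be
validated against the quantities it targets.

Model
-----
For each stage s with n quadrats:

* each species i draws a latent profile q_i ~ Dirichlet(alpha_i * 1_n)
  over the quadrats; a small species-specific concentration alpha_i
  produces a specialist (mass on few quadrats), a large one a
  generalist;
* the stage has a shared resource optimum u_s ~ Dirichlet(a0 * 1_n);
  the true profile is the blend p_i = (1 - h_s) q_i + h_s u_s, where
  h_s in [0, 1] is the stage's homogenization.  Raising h_s pulls all
  species toward the same optimum, which raises mean niche overlap —
  the degradation signature the series emulates;
* abundance in quadrat j is Poisson with mean
  abundance_scale * n * p_ij (so a perfectly even species averages
  abundance_scale individuals per quadrat); zero counts are genuine
  absences;
* per-species mean height is log-normal around 15 with quadrat-level
  jitter; cover saturates with abundance as 1 - exp(-a / abundance_scale).

Sub-streams per stage are spawned from the master seed, so adding a
stage never perturbs the records of earlier stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .niche_metrics import levins_width, niche_overlap
from .survey_io import STAGES, QuadratRecord


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated survey: 46
    species, 3 stages, 6 sites x 3 transects x 3 quadrats = 54 quadrats
    per stage, with homogenization rising along the gradient."""

    n_species: int = 46
    n_quadrats_per_stage: int = 54
    stages: tuple[str, ...] = STAGES
    breadth_mix: tuple[float, float] = (0.01, 0.15)  # log-uniform Dirichlet concentration range
    homogenization: tuple[float, ...] = (0.1, 0.4, 0.7)
    abundance_scale: float = 50.0
    shared_optimum_conc: float = 2.0
    mean_height: float = 15.0
    height_sd_log: float = 0.4
    height_jitter_log: float = 0.15
    monotone_check: bool = True

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_quadrats_per_stage < 2:
            raise ValueError("n_quadrats_per_stage must be >= 2")
        if len(self.stages) != len(self.homogenization):
            raise ValueError("need one homogenization value per stage")
        if any(not 0.0 <= h <= 1.0 for h in self.homogenization):
            raise ValueError("homogenization values must lie in [0, 1]")
        if self.monotone_check and list(self.homogenization) != sorted(self.homogenization):
            raise ValueError(
                "homogenization must be non-decreasing across stages "
                "(set monotone_check=False to override)"
            )
        if self.abundance_scale <= 0:
            raise ValueError("abundance_scale must be positive")
        lo, hi = self.breadth_mix
        if not (0 < lo <= hi):
            raise ValueError("breadth_mix must be 0 < low <= high")


@dataclass
class StageTruth:
    """Ground truth for one stage: profiles (species x quadrat), Levins
    breadth per species, pairwise Pianka overlap."""

    profiles: pd.DataFrame
    breadth: pd.Series
    overlap: pd.DataFrame

    @property
    def mean_overlap(self) -> float:
        vals = self.overlap.to_numpy()
        iu = np.triu_indices(vals.shape[0], k=1)
        return float(vals[iu].mean())


@dataclass
class SyntheticCommunity:
    """Sampled records plus the truth they were sampled from."""

    records: list[QuadratRecord]
    truth: dict[str, StageTruth]
    config: SyntheticConfig
    seed: int


def _species_names(n: int) -> list[str]:
    return [f"Species sp{i + 1:02d}" for i in range(n)]


def _stage_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _quadrat_layout(q: int) -> tuple[str, str, str]:
    """Map a quadrat index to (site, transect, quadrat) labels: 3
    quadrats per transect, 3 transects per site."""
    site = q // 9 + 1
    transect = q // 3 + 1
    return f"site{site}", f"T{transect}", f"Q{q + 1:03d}"


def generate_community(config: SyntheticConfig, seed: int) -> SyntheticCommunity:
    """Draw one multi-stage community; identical seeds give identical output."""
    config.validate()
    n_sp, n_q = config.n_species, config.n_quadrats_per_stage
    names = _species_names(n_sp)

    rng0 = _stage_rng(seed, 0)  # species-level parameters, shared across stages
    lo, hi = config.breadth_mix
    conc = np.exp(rng0.uniform(np.log(lo), np.log(hi), size=n_sp))
    height_mu = rng0.normal(np.log(config.mean_height), config.height_sd_log, size=n_sp)

    records: list[QuadratRecord] = []
    truth: dict[str, StageTruth] = {}
    for s_idx, (stage, h) in enumerate(zip(config.stages, config.homogenization)):
        rng = _stage_rng(seed, s_idx + 1)
        shared = rng.dirichlet(np.full(n_q, config.shared_optimum_conc))
        profiles = np.empty((n_sp, n_q))
        for i in range(n_sp):
            q_i = rng.dirichlet(np.full(n_q, conc[i]))
            profiles[i] = (1.0 - h) * q_i + h * shared

        lam = config.abundance_scale * n_q * profiles
        counts = rng.poisson(lam)
        heights = np.exp(
            height_mu[:, None] + rng.normal(0.0, config.height_jitter_log, size=(n_sp, n_q))
        )
        cover = np.minimum(0.999, 1.0 - np.exp(-counts / config.abundance_scale))

        for i in range(n_sp):
            for j in range(n_q):
                if counts[i, j] == 0:
                    continue
                site, transect, quadrat = _quadrat_layout(j)
                records.append(
                    QuadratRecord(
                        site_id=site,
                        transect_id=transect,
                        stage=stage,
                        quadrat_id=quadrat,
                        species=names[i],
                        height=float(heights[i, j]),
                        cover=float(cover[i, j]),
                        abundance=int(counts[i, j]),
                    )
                )

        quadrat_ids = [_quadrat_layout(j)[2] for j in range(n_q)]
        prof_df = pd.DataFrame(profiles, index=names, columns=quadrat_ids)
        breadth = pd.Series(
            [levins_width(profiles[i]).b for i in range(n_sp)], index=names, name="b"
        )
        ov = np.ones((n_sp, n_sp))
        for i in range(n_sp):
            for k in range(i + 1, n_sp):
                ov[i, k] = ov[k, i] = niche_overlap(profiles[i], profiles[k], "pianka")
        truth[stage] = StageTruth(
            profiles=prof_df,
            breadth=breadth,
            overlap=pd.DataFrame(ov, index=names, columns=names),
        )
    return SyntheticCommunity(records=records, truth=truth, config=config, seed=seed)


def degradation_series(config: SyntheticConfig, seed: int) -> dict[str, SyntheticCommunity]:
    """Per-stage view of one community along the degradation gradient.

    Requires strictly increasing homogenization so the true mean overlap
    has an increasing trend to recover.
    """
    config.validate()
    hs = config.homogenization
    if config.monotone_check and any(b <= a for a, b in zip(hs, hs[1:])):
        raise ValueError("degradation series requires strictly increasing homogenization")
    full = generate_community(config, seed)
    out: dict[str, SyntheticCommunity] = {}
    for stage in config.stages:
        out[stage] = SyntheticCommunity(
            records=[r for r in full.records if r.stage == stage],
            truth={stage: full.truth[stage]},
            config=config,
            seed=seed,
        )
    return out


def true_mean_overlaps(community: SyntheticCommunity) -> dict[str, float]:
    """Stage -> mean true pairwise Pianka overlap."""
    return {stage: t.mean_overlap for stage, t in community.truth.items()}
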