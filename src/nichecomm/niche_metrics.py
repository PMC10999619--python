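"""Levins niche breadth, pairwise niche overlap, overlap-interval
spectra, and the importance-value-versus-breadth regression.

Profiles p_i are row-normalized utilization vectors over r resource
states (here: sampling units within a degradation stage).

Indices
-------
Levins breadth              B_i   = 1 / sum_j p_ij^2,   1 <= B_i <= r
Standardized breadth        B_std = (B_i - 1) / (r - 1)
Levins overlap (asymmetric) O_ik  = sum_j p_ij p_kj / sum_j p_ij^2
Pianka overlap (symmetric)  O_ik  = sum_j p_ij p_kj /
                                    sqrt(sum_j p_ij^2 * sum_j p_kj^2)

Pianka's index is the cosine similarity of the two profiles, in [0, 1],
equal to 1 iff the profiles are proportional.  The two Levins directions
satisfy the reciprocity identity
O_ik * sum_j p_ij^2 = O_ki * sum_j p_kj^2 (both equal sum_j p_ij p_kj).

Overlap values are classified into the conventional intervals
< 0.3 (low), 0.3-0.8 (moderate, both endpoints included), > 0.8 (high).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey_io import (
    STAGES,
    CommunityMatrix,
    QuadratRecord,
    SpeciesStageTable,
    SurveyError,
    community_matrix,
)

OverlapMethod = Literal["pianka", "levins"]


@dataclass(frozen=True)
class NicheWidthResult:
    """Levins breadth for one species' profile over r resource states."""

    b: float
    b_std: float
    r: int


def levins_width(profile: Sequence[float]) -> NicheWidthResult:
    """Levins niche breadth B = 1 / sum(p^2) of one utilization profile.

    The profile is normalized to proportions first; its length r must be
    at least 2 and its sum positive.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("profile must be a 1-D vector of length >= 2")
    if (p < 0).any():
        raise ValueError("profile has negative entries")
    total = p.sum()
    if total <= 0:
        raise ValueError("profile sums to zero; breadth undefined")
    p = p / total
    b = 1.0 / float(np.square(p).sum())
    r = p.size
    return NicheWidthResult(b=b, b_std=(b - 1.0) / (r - 1.0), r=r)


def niche_overlap(
    profile_i: Sequence[float],
    profile_k: Sequence[float],
    method: OverlapMethod = "pianka",
) -> float:
    """Niche overlap of two equal-length normalized profiles.

    ``pianka`` is symmetric in [0, 1]; ``levins`` is the directed value
    O_ik of species k's profile onto species i's.
    """
    pi = np.asarray(profile_i, dtype=float)
    pk = np.asarray(profile_k, dtype=float)
    if pi.shape != pk.shape:
        raise ValueError(f"profile length mismatch: {pi.shape} vs {pk.shape}")
    pi = pi / pi.sum()
    pk = pk / pk.sum()
    cross = float(pi @ pk)
    if method == "pianka":
        return cross / float(np.sqrt((pi @ pi) * (pk @ pk)))
    if method == "levins":
        return cross / float(pi @ pi)
    raise ValueError(f"unknown overlap method {method!r}")


@dataclass
class OverlapMatrix:
    """All pairwise overlaps among a stage's species.

    ``values[i, k]`` holds O_ik (directed for ``levins``, symmetric for
    ``pianka``); the diagonal is NaN.
    """

    stage: str
    species: list[str]
    method: OverlapMethod
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.species)

    def pair_values(self) -> np.ndarray:
        """Off-diagonal overlap values: unordered pairs once for pianka,
        all ordered pairs for levins."""
        if self.method == "pianka":
            iu = np.triu_indices(self.n, k=1)
            return self.values[iu]
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]

    def iter_pairs(self) -> Iterator[tuple[str, str, float]]:
        for i, k in combinations(range(self.n), 2):
            yield self.species[i], self.species[k], float(self.values[i, k])
            if self.method == "levins":
                yield self.species[k], self.species[i], float(self.values[k, i])


def overlap_matrix(matrix: CommunityMatrix, method: OverlapMethod = "pianka") -> OverlapMatrix:
    """Pairwise niche overlap among all retained species of a stage."""
    if len(matrix.species) < 2:
        raise SurveyError("overlap needs at least 2 species")
    p = matrix.profiles
    cross = p @ p.T
    sq = np.square(p).sum(axis=1)
    if method == "pianka":
        vals = cross / np.sqrt(np.outer(sq, sq))
    elif method == "levins":
        vals = cross / sq[:, None]
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    np.fill_diagonal(vals, np.nan)
    return OverlapMatrix(stage=matrix.stage, species=list(matrix.species), method=method, values=vals)


@dataclass(frozen=True)
class OverlapClassification:
    """Overlap-interval spectrum: counts/proportions of pair overlaps in
    the bins < 0.3, 0.3-0.8 (endpoints included) and > 0.8, plus the
    arithmetic mean overlap."""

    counts: tuple[int, int, int]
    proportions: tuple[float, float, float]
    mean_overlap: float
    n_pairs: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": ["<0.3", "0.3-0.8", ">0.8"],
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


def classify_overlaps(matrix: OverlapMatrix) -> OverlapClassification:
    """Bin a stage's pair overlaps into the low/moderate/high intervals."""
    vals = matrix.pair_values()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise SurveyError("empty overlap matrix; nothing to classify")
    low = int((vals < 0.3).sum())
    high = int((vals > 0.8).sum())
    mid = int(vals.size) - low - high
    n = int(vals.size)
    return OverlapClassification(
        counts=(low, mid, high),
        proportions=(low / n, mid / n, high / n),
        mean_overlap=float(vals.mean()),
        n_pairs=n,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def iv_width_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of niche breadth on importance value.

    R^2 is the squared Pearson correlation; x must have positive
    variance and at least 3 paired observations are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    if np.var(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=int(x.size))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(x.size),
    )


def niche_width_table(
    records: Sequence[QuadratRecord],
    state_def: Literal["quadrat", "transect"] = "quadrat",
    measure: Literal["abundance", "iv_component"] = "abundance",
) -> pd.DataFrame:
    """Levins breadth of every species at every stage where it occurs.

    Returns a tidy DataFrame with columns stage, species, b, b_std, r.
    """
    out = []
    stages = sorted({r.stage for r in records}, key=STAGES.index)
    for stage in stages:
        cm = community_matrix(records, stage, state_def=state_def, measure=measure)
        for sp, row in zip(cm.species, cm.profiles):
            res = levins_width(row)
            out.append({"stage": stage, "species": sp, "b": res.b, "b_std": res.b_std, "r": res.r})
    return pd.DataFrame(out, columns=["stage", "species", "b", "b_std", "r"])


def width_change_report(
    widths: SpeciesStageTable | pd.DataFrame,
    species: str,
    ref_stage: str,
    cmp_stage: str,
) -> float:
    """Percent decrease in Levins breadth from ``ref_stage`` to
    ``cmp_stage``: 100 * (B_ref - B_cmp) / B_ref (negative = increase).

    Accepts either the published species table or a
    :func:`niche_width_table` frame; errors if the species is absent
    from either stage.
    """

    def lookup(stage: str) -> float:
        if isinstance(widths, SpeciesStageTable):
            val = widths.width(species, stage)
        else:
            hit = widths[(widths["species"] == species) & (widths["stage"] == stage)]
            val = float(hit["b"].iloc[0]) if len(hit) else float("nan")
        if np.isnan(val):
            raise SurveyError(f"{species!r} absent at stage {stage!r}")
        return val

    b_ref = lookup(ref_stage)
    b_cmp = lookup(cmp_stage)
    return 100.0 * (b_ref - b_cmp) / b_ref
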