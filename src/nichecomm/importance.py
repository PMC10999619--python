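"""Species importance values from quadrat surveys.

The importance value (IV) of a species in a stage is the mean of its
relative height, relative cover and relative frequency:

    IV_i = (RH_i + RC_i + RF_i) / 3

where height and cover are first averaged over the quadrats in which the
species occurs, frequency is the fraction of the stage's quadrats it
occupies, and each metric is then relativized within the stage.  Two
relativizations are offered: "max" (divide by the stage maximum, the
default, which yields IVs on the magnitude scale of published dominance
tables where several species can exceed 0.5) and "sum" (divide by the
stage total, so IVs sum to 1).
"""

from __future__ import annotations

from typing import Literal, Sequence

import pandas as pd

from .survey_io import QuadratRecord, SurveyError


def species_frequency(records: Sequence[QuadratRecord], stage: str) -> pd.Series:
    """Fraction of the stage's quadrats each species occupies, in [0, 1]."""
    rows = [r for r in records if r.stage == stage]
    if not rows:
        raise SurveyError(f"no records at stage {stage!r}")
    n_quadrats = len({r.quadrat_id for r in rows})
    occ = (
        pd.DataFrame({"species": [r.species for r in rows], "quadrat": [r.quadrat_id for r in rows]})
        .drop_duplicates()
        .groupby("species")
        .size()
    )
    return (occ / n_quadrats).rename("frequency").sort_index()


def importance_value(
    records: Sequence[QuadratRecord],
    stage: str,
    normalization: Literal["max", "sum"] = "max",
) -> pd.DataFrame:
    """Per-species relative height, cover, frequency and IV for one stage.

    Returns a DataFrame indexed by species with columns ``rel_height``,
    ``rel_cover``, ``rel_frequency``, ``iv``.  Heights and covers are
    species means over occupied quadrats before relativization.
    """
    rows = [r for r in records if r.stage == stage]
    if not rows:
        raise SurveyError(f"no records at stage {stage!r}")
    df = pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "height": [r.height for r in rows],
            "cover": [r.cover for r in rows],
        }
    )
    means = df.groupby("species")[["height", "cover"]].mean().sort_index()
    freq = species_frequency(records, stage)
    metrics = pd.DataFrame(
        {"height": means["height"], "cover": means["cover"], "frequency": freq}
    )

    if normalization == "max":
        base = metrics.max(axis=0)
    elif normalization == "sum":
        base = metrics.sum(axis=0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    zero = base.index[base <= 0]
    if len(zero):
        raise SurveyError(f"metric {zero[0]!r} is zero for every species at stage {stage!r}")

    rel = metrics / base
    out = pd.DataFrame(
        {
            "rel_height": rel["height"],
            "rel_cover": rel["cover"],
            "rel_frequency": rel["frequency"],
        }
    )
    out["iv"] = out.mean(axis=1)
    return out
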