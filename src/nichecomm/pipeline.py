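"""End-to-end stage-wise analysis: records -> importance values ->
niche widths -> overlaps -> interval spectra -> overlap network ->
modules -> cross-stage stable groups, with deterministic outputs and a
run manifest.

Also hosts the fixture verification: quantities derivable from the
packaged species table (taxon counts, stage-maximum widths, width-change
percentages) recomputed and compared against their published values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .importance import importance_value
from .niche_metrics import (
    classify_overlaps,
    niche_width_table,
    overlap_matrix,
    width_change_report,
)
from .overlap_network import (
    ModulePartition,
    StableGroupSet,
    build_network,
    detect_modules,
    export_network,
    stable_groups,
)
from .survey_io import (
    STAGES,
    QuadratRecord,
    community_matrix,
    count_taxa,
    load_species_table_fixture,
    read_survey_records,
    write_survey_records,
)
from .synthetic_data import SyntheticConfig, generate_community

log = logging.getLogger("nichecomm")

DEFAULT_ANALYSIS: dict[str, Any] = {
    "state_def": "quadrat",  # resource states: quadrats, or transects pooling them
    "measure": "abundance",
    "iv_normalization": "max",
    "overlap_method": "pianka",
    "threshold": 0.0,
    "symmetrize": "mean",
    "module_method": "greedy",
    "min_shared_stages": 2,
}


@dataclass
class StageReport:
    """Per-stage results and the files they were written to."""

    stage: str
    richness: int
    iv_table: pd.DataFrame
    width_table: pd.DataFrame
    classification: pd.DataFrame
    mean_overlap: float
    n_nodes: int
    n_edges: int
    n_modules: int
    q: float
    artifacts: dict[str, Path] = field(default_factory=dict)


@dataclass
class PipelineResult:
    stage_reports: dict[str, StageReport]
    stable_groups: StableGroupSet | None
    manifest: dict[str, Any]
    outdir: Path


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _get_records(cfg: dict, outdir: Path, seed: int) -> list[QuadratRecord]:
    inp = cfg.get("input", {})
    kind = inp.get("kind", "synthetic")
    if kind == "csv":
        path = inp.get("csv")
        if not path:
            raise FileNotFoundError("config input.kind=csv but no input.csv path given")
        return read_survey_records(path)
    if kind == "synthetic":
        gen_cfg = SyntheticConfig(**inp.get("synthetic", {}))
        community = generate_community(gen_cfg, seed)
        write_survey_records(community.records, outdir / "synthetic_survey.csv")
        return community.records
    raise ValueError(f"unknown input kind {kind!r}")


def run_pipeline(config: str | Path | Mapping, outdir: str | Path | None = None) -> PipelineResult:
    """Run the whole analysis chain from a YAML config (or mapping).

    Writes per stage: importance values, niche widths, overlap pairs,
    interval classification, the overlap network (GraphML + TSV) with
    module assignments; across stages: stable groups; plus a
    ``manifest.json`` echoing every parameter.  Outputs are
    deterministic given the config and seed.
    """
    cfg = _load_config(config)
    params = {**DEFAULT_ANALYSIS, **cfg.get("analysis", {})}
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("output", {}).get("dir", "nichecomm_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    records = _get_records(cfg, outdir, seed)
    stages = [s for s in STAGES if any(r.stage == s for r in records)]
    if not stages:
        raise ValueError("no records in any recognized stage")

    reports: dict[str, StageReport] = {}
    partitions: dict[str, dict] = {}
    presence: dict[str, set] = {}
    for stage in stages:
        log.info("analyzing stage %s", stage)
        try:
            rep = _run_stage(records, stage, params, seed, outdir)
        except Exception as err:
            raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err
        reports[stage] = rep
        presence[stage] = set(rep.width_table["species"])

    for stage in stages:
        partitions[stage] = reports[stage].artifacts.pop("_membership")  # type: ignore[assignment]

    groups: StableGroupSet | None = None
    if len(stages) >= 2:
        groups = stable_groups(partitions, presence, params["min_shared_stages"])
        rows = [
            {"group": i + 1, "size": len(g), "species": "; ".join(sorted(g))}
            for i, g in enumerate(groups.groups)
        ]
        pd.DataFrame(rows, columns=["group", "size", "species"]).to_csv(
            outdir / "stable_groups.csv", index=False
        )
    else:
        log.info("single stage run: stable-group step skipped")

    manifest = {
        "package": "nichecomm",
        "version": __version__,
        "seed": seed,
        "analysis": params,
        "input": cfg.get("input", {}),
        "stages": stages,
        "stage_summaries": {
            s: {
                "richness": reports[s].richness,
                "mean_overlap": reports[s].mean_overlap,
                "n_edges": reports[s].n_edges,
                "n_modules": reports[s].n_modules,
                "q": reports[s].q,
            }
            for s in stages
        },
        "n_stable_groups": len(groups.groups) if groups else None,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(stage_reports=reports, stable_groups=groups, manifest=manifest, outdir=outdir)


def _run_stage(
    records: Sequence[QuadratRecord],
    stage: str,
    params: Mapping[str, Any],
    seed: int,
    outdir: Path,
) -> StageReport:
    iv = importance_value(records, stage, normalization=params["iv_normalization"])
    cm = community_matrix(records, stage, state_def=params["state_def"], measure=params["measure"])
    widths = niche_width_table(
        [r for r in records if r.stage == stage],
        state_def=params["state_def"],
        measure=params["measure"],
    )
    om = overlap_matrix(cm, method=params["overlap_method"])
    cls = classify_overlaps(om)
    net = build_network(om, threshold=params["threshold"], symmetrize=params["symmetrize"])
    part = detect_modules(net, method=params["module_method"], seed=seed)

    artifacts: dict[str, Path] = {}
    iv_path = outdir / f"{stage}_importance.csv"
    iv.round(6).to_csv(iv_path)
    artifacts["importance"] = iv_path
    w_path = outdir / f"{stage}_niche_widths.csv"
    widths.round(6).to_csv(w_path, index=False)
    artifacts["widths"] = w_path
    pairs = pd.DataFrame(om.iter_pairs(), columns=["species_i", "species_k", "overlap"])
    p_path = outdir / f"{stage}_overlap_pairs.csv"
    pairs.round(6).to_csv(p_path, index=False)
    artifacts["overlap_pairs"] = p_path
    c_path = outdir / f"{stage}_overlap_classification.csv"
    cls_frame = cls.as_frame()
    cls_frame["mean_overlap"] = cls.mean_overlap
    cls_frame.round(6).to_csv(c_path, index=False)
    artifacts["classification"] = c_path
    for fmt in ("graphml", "tsv"):
        n_path = outdir / f"{stage}_network.{fmt}"
        export_network(net, part, n_path, format=fmt)
        artifacts[f"network_{fmt}"] = n_path

    rep = StageReport(
        stage=stage,
        richness=len(cm.species),
        iv_table=iv,
        width_table=widths,
        classification=cls_frame,
        mean_overlap=cls.mean_overlap,
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        n_modules=part.n_modules,
        q=part.q,
        artifacts=artifacts,
    )
    rep.artifacts["_membership"] = part.membership  # consumed by the stable-group step
    return rep


# ---------------------------------------------------------------------------
# Fixture verification
# ---------------------------------------------------------------------------

# Published values the packaged table must reproduce.  Width-change
# percentages are recomputed from 2-d.p. table entries, hence the
# half-percentage-point tolerances.
FIXTURE_CHECKS: tuple[tuple[str, float, float], ...] = (
    ("n_species", 46, 0),
    ("n_genera", 33, 0),
    ("max_s1_width", 4.92, 0.005),
    ("max_s1_width_iv", 0.07, 0.005),
    ("triglochin_decrease_s1_s2_pct", 79.66, 0.05),
    ("triglochin_decrease_s1_s3_pct", 40.70, 0.05),
)


@dataclass
class VerificationCheck:
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def ok(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance


@dataclass
class VerificationSummary:
    checks: list[VerificationCheck]

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.checks)

    def failures(self) -> list[VerificationCheck]:
        return [c for c in self.checks if not c.ok]


def fixture_quantities() -> dict[str, float]:
    """Recompute the fixture-derivable quantities from the packaged table."""
    table = load_species_table_fixture()
    taxa = count_taxa(table)
    widths_s1 = {
        sp: table.width(sp, "S1") for sp in table.species_names() if table.present(sp, "S1")
    }
    max_sp = max(widths_s1, key=widths_s1.get)
    return {
        "n_species": float(taxa.n_species),
        "n_genera": float(taxa.n_genera),
        "max_s1_width": widths_s1[max_sp],
        "max_s1_width_iv": table.iv(max_sp, "S1"),
        "triglochin_decrease_s1_s2_pct": width_change_report(
            table, "Triglochin palustre", "S1", "S2"
        ),
        "triglochin_decrease_s1_s3_pct": width_change_report(
            table, "Triglochin palustre", "S1", "S3"
        ),
    }


def verify_fixture() -> VerificationSummary:
    """Compare fixture-derived quantities with their published values."""
    got = fixture_quantities()
    checks = [
        VerificationCheck(name, got[name], expected, tol)
        for name, expected, tol in FIXTURE_CHECKS
    ]
    return VerificationSummary(checks=checks)
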