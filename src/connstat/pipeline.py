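"""End-to-end orchestration: metrics -> AUC -> inference -> associations -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import connstat
from connstat.association import ASSOC_COVARIATE_DEFAULT, associate_limbic
from connstat.demographics import table_one
from connstat.inference import GROUP_COVARIATE_DEFAULT, compare_groups, compare_volumes
from connstat.io import Cohort, write_results
from connstat.metrics import METRIC_NAMES, NodalFeatureTable, SparsityGrid, compute_nodal_features

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    grid: SparsityGrid = field(default_factory=SparsityGrid.default)
    n_perm: int = 1000
    seed: int = 0
    group_covariates: tuple[str, ...] = GROUP_COVARIATE_DEFAULT
    assoc_covariates: tuple[str, ...] = ASSOC_COVARIATE_DEFAULT
    q: float = 0.05
    metrics: tuple[str, ...] = METRIC_NAMES
    scores: tuple[str, ...] = ("MADRS",)
    p_source: str = "perm"  # what feeds FDR: "perm" or "parametric"

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for reported runs")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "grid" in raw and isinstance(raw["grid"], str):
            raw["grid"] = SparsityGrid.from_spec(raw["grid"])
        for key in ("group_covariates", "assoc_covariates", "metrics", "scores"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = self.grid.values.tolist()
        return d


class StageError(RuntimeError):
    """Pipeline stage failure, labeled with the stage name."""


def _stage(name, fn, *args, **kwargs):
    logger.info("stage %s: start", name)
    try:
        return fn(*args, **kwargs)
    except Exception as e:
        raise StageError(f"stage '{name}' failed: {e}") from e


def run_pipeline(cohort: Cohort, config: RunConfig, out_dir=None) -> dict:
    """Execute the full analysis; returns (and optionally writes) the bundle.

    Bundle keys: features, group_comparison, volume_comparison,
    associations (dict score -> table), demographics, run_metadata.
    """
    features = _stage("metrics", compute_nodal_features, cohort, config.grid, config.metrics)
    group_results = _stage(
        "group_comparison",
        compare_groups,
        features,
        cohort,
        covariates=config.group_covariates,
        n_perm=config.n_perm,
        seed=config.seed,
        q=config.q,
        p_source=config.p_source,
    )
    has_volumes = any(s.region_volumes is not None for s in cohort.subjects)
    has_limbic = len(cohort.region_table.family_indices("hippocampus")) > 0
    volume_results = (
        _stage("volume_comparison", compare_volumes, cohort) if has_volumes and has_limbic else None
    )
    associations = {}
    if has_limbic:
        for score in config.scores:
            associations[score] = _stage(
                "association",
                associate_limbic,
                features,
                cohort,
                score_name=score,
                covariates=config.assoc_covariates,
                q=config.q,
                corrected=(score != "episode_duration"),
            )
    demographics = _stage("demographics", table_one, cohort)
    metadata = {
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "n_mdd": int((cohort.group_labels == "MDD").sum()),
        "n_hc": int((cohort.group_labels == "HC").sum()),
        "n_regions": len(cohort.region_table),
        "package_version": connstat.__version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    bundle = {
        "features": features,
        "group_comparison": group_results,
        "volume_comparison": volume_results,
        "associations": associations,
        "demographics": demographics,
        "run_metadata": metadata,
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["features"].to_csv(out / "nodal_features.csv")
    write_results(bundle["group_comparison"], out / "group_comparison.csv")
    if bundle["volume_comparison"] is not None:
        write_results(bundle["volume_comparison"], out / "volume_comparison.csv")
    for score, table in bundle["associations"].items():
        write_results(table, out / f"association_{score}.csv")
    bundle["demographics"].to_csv(out / "demographics.csv", index=False)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(bundle["run_metadata"], fh, indent=2)


def _md_table(df: pd.DataFrame) -> str:
    """Minimal GitHub-style pipe table (no external deps)."""
    cells = df.map(lambda v: f"{v:.4g}" if isinstance(v, float) else str(v))
    widths = [max(len(c), *(len(x) for x in cells[c])) if len(cells) else len(c) for c in cells.columns]
    head = "| " + " | ".join(c.ljust(w) for c, w in zip(cells.columns, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    body = [
        "| " + " | ".join(str(row[c]).ljust(w) for c, w in zip(cells.columns, widths)) + " |"
        for _, row in cells.iterrows()
    ]
    return "\n".join([head, sep, *body])


def render_report(bundle: dict) -> str:
    """Deterministic markdown report assembled from a complete bundle."""
    required = ("group_comparison", "associations", "demographics", "run_metadata")
    missing = [k for k in required if k not in bundle or bundle[k] is None]
    if missing:
        raise ValueError(f"incomplete bundle: missing {missing}")
    lines = ["# Connectome nodal-centrality analysis report", ""]
    meta = bundle["run_metadata"]
    lines += [
        f"Subjects: {meta['n_subjects']} ({meta['n_mdd']} MDD / {meta['n_hc']} HC); "
        f"regions: {meta['n_regions']}; permutations: {meta['config']['n_perm']}; "
        f"seed: {meta['config']['seed']}; FDR q: {meta['config']['q']}.",
        "",
        "## Demographics",
        "",
        _md_table(bundle["demographics"]),
        "",
        "## Group comparison (FDR-corrected nodal features)",
        "",
    ]
    gc = bundle["group_comparison"]
    for metric in sorted(gc["metric"].unique()):
        sub = gc[(gc["metric"] == metric) & gc["significant"]].sort_values("region_index")
        lines.append(f"### {metric}")
        lines.append("")
        if len(sub) == 0:
            lines.append("Zero FDR discoveries.")
        else:
            cols = ["region", "t", "df", "cohen_d", "p_perm", "q_fdr", "direction"]
            lines.append(_md_table(sub[cols]))
        lines.append("")
    if bundle.get("volume_comparison") is not None:
        vc = bundle["volume_comparison"]
        sig = vc[vc["p"] < 0.05]
        lines += [
            "## Subregion volumes",
            "",
            f"{len(sig)} of {len(vc)} subregion volume tests at p < 0.05 (uncorrected).",
            "",
        ]
    lines += ["## Symptom associations (patients only)", ""]
    for score in sorted(bundle["associations"]):
        table = bundle["associations"][score]
        lines.append(f"### {score}")
        lines.append("")
        if "q_fdr" in table.columns:
            sig = table[table["significant"]].sort_values("region_index")
            if len(sig) == 0:
                lines.append("Zero FDR discoveries.")
            else:
                lines.append(
                    _md_table(sig[["region", "metric", "rho", "p", "q_fdr", "n_used"]])
                )
        else:
            sig = table[table["p"] < 0.05].sort_values("region_index")
            lines.append(f"Uncorrected exploration: {len(sig)} associations at p < 0.05.")
            if len(sig):
                lines.append("")
                lines.append(_md_table(sig[["region", "metric", "rho", "p", "n_used"]]))
        lines.append("")
    return "\n".join(lines)
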