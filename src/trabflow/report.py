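"""Result bundling: manifests, summary tables and human-readable reports.

A ResultBundle collects scenario results and comparison tables from one
configured run; ``report`` emits them as CSV + JSON (every table row
carries the config hash of the run that produced it) and a plain-text
summary in the style of the study's comparison figures.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .scenarios import ComparisonTable, ScenarioResult

__all__ = ["ResultBundle", "ReportError", "report"]


class ReportError(RuntimeError):
    pass


@dataclass
class ResultBundle:
    config: RunConfig
    scenarios: list[ScenarioResult] = field(default_factory=list)
    tables: dict[str, ComparisonTable] = field(default_factory=dict)

    def manifest(self, files: list[str]) -> dict:
        return {
            "package": "trabflow",
            "version": __version__,
            "config_hash": self.config.hash(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "files": files,
        }


def report(bundle: ResultBundle, outdir) -> dict:
    """Write summary tables (CSV + JSON) and the manifest; returns the
    manifest. Raises if the bundle contains no completed runs."""
    if not bundle.scenarios and not bundle.tables:
        raise ReportError("nothing to report: no completed scenario runs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = bundle.config.hash()
    files: list[str] = []

    if bundle.scenarios:
        df = pd.DataFrame([r.to_dict() for r in bundle.scenarios])
        df["config_hash"] = chash
        p = outdir / "scenarios.csv"
        df.to_csv(p, index=False)
        files.append(p.name)
        (outdir / "scenarios.json").write_text(
            df.to_json(orient="records", indent=2))
        files.append("scenarios.json")
        # per-region tables (TAWSS / OSI in the style of the ridge-vs-groove
        # comparison figure)
        region_rows = []
        for r in bundle.scenarios:
            t = r.table.copy()
            t.insert(0, "seed", r.spec.seed)
            t.insert(0, "scenario",
                     f"{r.spec.geometry}/{r.spec.motion_variant}/{r.spec.viscosity}")
            region_rows.append(t)
        rt = pd.concat(region_rows, ignore_index=True)
        rt["config_hash"] = chash
        p = outdir / "region_metrics.csv"
        rt.to_csv(p, index=False)
        files.append(p.name)

    for name, table in bundle.tables.items():
        df = table.data.copy()
        df["config_hash"] = chash
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        files.append(p.name)
        payload = {"comparisons": table.comparisons, "meta": table.meta,
                   "config_hash": chash}
        (outdir / f"{name}_stats.json").write_text(
            json.dumps(payload, indent=2, default=float))
        files.append(f"{name}_stats.json")

    manifest = bundle.manifest(files)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    missing = [f for f in files if not (outdir / f).exists()]
    if missing:
        raise ReportError(f"manifest references missing files: {missing}")
    return manifest
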