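"""Readers, writers, run manifest and the end-to-end pipeline.

Tree tables are CSV with header ``tree_id, concession_id, x, y, dbh_cm`` and
either ``seed_kg`` or ``seed_latas`` (auto-converted, one lata ~ 11.66 kg);
windows are a GeoJSON FeatureCollection of Polygons with a ``concession_id``
property, in the same projected metric coordinates as the trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from . import allometry
from .envelopes import EnvelopeConfig
from .geometry import DBH_MIN_CM, MarkedPattern
from .scaling import ScalingConfig, scaling_curve
from .synthetic import ScenarioConfig, generate_dataset, scenario_presets

__all__ = [
    "read_trees",
    "read_windows",
    "write_trees",
    "write_windows",
    "load_pattern",
    "RunManifest",
    "PipelineConfig",
    "run_pipeline",
]


def read_trees(
    path, params: allometry.AllometryParams = allometry.AllometryParams()
) -> pd.DataFrame:
    """Validated tree table from CSV.

    A ``seed_latas`` column is converted to ``seed_kg``; a missing ``agb_kg``
    column is filled from ``dbh_cm`` via the allometric model.  Validation
    failures raise a ``ValueError`` naming the offending data line numbers
    (header = line 1).
    """
    df = pd.read_csv(path)
    required = {"tree_id", "concession_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "seed_kg" not in df.columns and "seed_latas" not in df.columns:
        raise ValueError(f"{path}: need a seed_kg or seed_latas column")

    lines = df.index + 2  # 1-based, after the header
    problems: list[str] = []

    def check(bad_mask, message):
        if bad_mask.any():
            problems.append(f"{message} (lines {list(lines[bad_mask])[:10]})")

    for c in ("x", "y"):
        vals = pd.to_numeric(df[c], errors="coerce")
        check(vals.isna(), f"non-numeric {c}")
        df[c] = vals
    check(df["tree_id"].astype(str).duplicated(), "duplicate tree_id")
    if "seed_latas" in df.columns:
        latas = pd.to_numeric(df["seed_latas"], errors="coerce")
        check(latas.isna() | (latas < 0), "invalid seed_latas")
        df["seed_kg"] = allometry.latas_to_kg(latas.fillna(0.0).to_numpy(), params)
    seed = pd.to_numeric(df["seed_kg"], errors="coerce")
    check(seed.isna() | (seed < 0), "invalid seed_kg")
    if "dbh_cm" in df.columns:
        dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
        bad = df["dbh_cm"].notna() & dbh.isna()
        check(bad, "non-numeric dbh_cm")
        check(dbh.notna() & (dbh < DBH_MIN_CM), f"dbh_cm below the {DBH_MIN_CM} cm threshold")
        df["dbh_cm"] = dbh
    else:
        df["dbh_cm"] = np.nan
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    if "agb_kg" not in df.columns:
        df["agb_kg"] = np.where(
            df["dbh_cm"].notna(), allometry.agb_from_dbh(df["dbh_cm"].to_numpy(), params), np.nan
        )
    return df[["tree_id", "concession_id", "x", "y", "dbh_cm", "seed_kg", "agb_kg"]]


def read_windows(path) -> dict:
    """Concession polygons from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    windows = {}
    for feat in gj["features"]:
        cid = str(feat["properties"]["concession_id"])
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"window {cid!r}: expected Polygon, got {geom.geom_type}")
        windows[cid] = geom
    return windows


def write_trees(pattern: MarkedPattern, path) -> None:
    pattern.trees.to_csv(path, index=False)


def write_windows(windows, path) -> None:
    feats = []
    for cid, win in windows.items():
        poly = getattr(win, "boundary", win)  # ConcessionWindow or Polygon
        feats.append(
            {
                "type": "Feature",
                "properties": {"concession_id": cid},
                "geometry": mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def load_pattern(trees_csv, windows_geojson, **kw) -> MarkedPattern:
    return MarkedPattern(read_trees(trees_csv, **kw), read_windows(windows_geojson))


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Traceability record written alongside every pipeline run."""

    config: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)  # per-stage row accounting
    outputs: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["# markcorr run manifest", f"seed: {self.seed}", "config:"]
        lines += [f"  {k}: {v}" for k, v in sorted(self.config.items())]
        lines.append("inputs:")
        lines += [f"  {k}: sha256:{v}" for k, v in sorted(self.input_digests.items())]
        lines.append("counts:")
        lines += [f"  {k}: {v}" for k, v in self.counts.items()]
        lines.append("outputs:")
        lines += [f"  {p}" for p in self.outputs]
        return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    scenario: str | None = "null"  # preset name; None to read files instead
    trees_csv: str | None = None
    windows_geojson: str | None = None
    seed: int = 0
    marks: tuple[str, ...] = ("seed", "agb")
    functions: tuple[str, ...] = ("f1", "f2", "f3", "f4")
    scheme: str = "near_5"
    n_sim: int = 199
    shuffle_scope: str = "global"
    run_scaling: bool = True
    scaling: ScalingConfig = field(default_factory=ScalingConfig)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """simulate (optional) -> normalize -> mark functions with envelopes for
    both marks -> scaling curve -> manifest.  Deterministic given the seed."""
    from .model import MarkCorrelationAnalysis  # deferred: model imports io types

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)

    if config.scenario is not None:
        scen = scenario_presets()[config.scenario]
        pattern = generate_dataset(scen, config.seed)
        write_trees(pattern, out / "trees.csv")
        write_windows(pattern.windows, out / "windows.geojson")
        manifest.outputs += ["trees.csv", "windows.geojson"]
    else:
        pattern = load_pattern(config.trees_csv, config.windows_geojson)
        manifest.input_digests = {
            "trees": _digest(config.trees_csv),
            "windows": _digest(config.windows_geojson),
        }
    manifest.counts["trees_in"] = pattern.n_trees

    env = EnvelopeConfig(
        n_sim=config.n_sim, rng_seed=config.seed, shuffle_scope=config.shuffle_scope
    )
    for mark in config.marks:
        analysis = MarkCorrelationAnalysis(pattern, mark=mark)
        res = analysis.fit(functions=config.functions, scheme=config.scheme, envelope=env)
        manifest.counts[f"{mark}_trees_used"] = analysis.n_used
        manifest.counts[f"{mark}_trees_excluded_no_dbh"] = analysis.n_excluded
        manifest.counts[f"{mark}_edge_drop_fraction"] = round(res.dropped_fraction, 4)
        fname = f"markfunctions_{mark}_{config.scheme}.csv"
        res.to_frame().to_csv(out / fname, index=False)
        manifest.outputs.append(fname)
        if config.run_scaling:
            sc = scaling_curve(pattern, mark=mark, config=config.scaling)
            fname = f"scaling_{mark}.csv"
            sc.table.to_csv(out / fname, index=False)
            manifest.outputs.append(fname)

    (out / "manifest.txt").write_text(manifest.to_text())
    return manifest
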