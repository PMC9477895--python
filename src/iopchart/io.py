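"""Disk formats: ground-truth sidecars, entry tables, templates, provenance.

CSV outputs are UTF-8, comma-separated, with a header row and "." decimal;
files written by the command-line pipeline start with a ``#`` provenance
comment line (tool version, seed, config hash) that pandas skips with
``comment="#"``.  JSON uses explicit nulls for missing measurements.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .extract import ExtractionConfig
from .layout import ChartLayout, GroundTruth


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(seed=None, config=None) -> dict:
    return {"tool": f"iopchart {__version__}", "seed": seed,
            "config_hash": config_hash(config or {})}


def provenance_line(seed=None, config=None) -> str:
    p = provenance(seed, config)
    return f"# {p['tool']} seed={p['seed']} config={p['config_hash']}\n"


def write_csv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_line(seed, config))
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_truth_sidecar(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def load_truth_sidecar(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def load_template(path) -> tuple[ChartLayout, ExtractionConfig]:
    """Read a YAML template carrying layout expectations and thresholds."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    layout = ChartLayout.from_dict(doc["layout"]) if "layout" in doc \
        else ChartLayout()
    cfg = doc.get("extraction", {})
    for key in ("red_hue_deg", "blue_hue_deg", "marker_area_px"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    config = ExtractionConfig(**cfg)
    return layout, config


def save_template(path, layout: ChartLayout | None = None,
                  config: ExtractionConfig | None = None) -> None:
    doc = {"layout": (layout or ChartLayout()).to_dict(),
           "extraction": vars(config or ExtractionConfig())}
    doc["extraction"] = {k: list(v) if isinstance(v, tuple) else v
                         for k, v in doc["extraction"].items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
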