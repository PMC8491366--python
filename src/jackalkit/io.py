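"""Readers and writers for the pipeline's text formats.

CSV outputs carry ``#`` header comments with the package version, the run
seed, and a hash of the effective configuration, so any result file is
traceable to the exact run that made it (and reruns are byte-identical).
JSON outputs carry the same information under a ``_meta`` key. The ESRI ASCII
grid format admits no comments, so UD rasters are written bare.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .homerange import UtilizationDistribution
from .synthetic import LandscapeLayers

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "read_relocations",
    "write_relocations",
    "read_scats",
    "read_cf_table",
    "read_landscape",
    "write_landscape",
    "write_ud_asc",
    "polygons_to_geojson",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: int | None, config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# jackalkit {__version__}\n# seed={seed} config_hash={h}\n"


def write_csv(
    frame: pd.DataFrame, path: str | Path, seed: int | None = None, config: dict | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, config))
        frame.to_csv(fh, index=False)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def read_relocations(path: str | Path) -> pd.DataFrame:
    frame = read_csv(path)
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"relocations file missing columns {sorted(missing)}")
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    if "source" not in frame.columns:
        frame["source"] = "gps"
    return frame


def write_relocations(
    frame: pd.DataFrame, path: str | Path, seed: int | None = None, config: dict | None = None
) -> None:
    out = frame.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    write_csv(out, path, seed=seed, config=config)


def read_scats(path: str | Path) -> pd.DataFrame:
    frame = read_csv(path)
    required = {"scat_id", "date", "dry_weight_g", "taxon", "volume_percent"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"scats file missing columns {sorted(missing)}")
    return frame


def read_cf_table(path: str | Path):
    from .diet import CorrectionFactorTable

    return CorrectionFactorTable.from_frame(read_csv(path))


def read_landscape(path: str | Path) -> LandscapeLayers:
    return LandscapeLayers.from_geojson(Path(path).read_text())


def write_landscape(
    layers: LandscapeLayers, path: str | Path, seed: int | None = None, config: dict | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = json.loads(layers.to_geojson())
    doc["_meta"] = {
        "package": f"jackalkit {__version__}",
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }
    path.write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def write_ud_asc(ud: UtilizationDistribution, path: str | Path) -> None:
    """Write a utilization distribution as an ESRI ASCII grid (row 1 = north)."""
    g = ud.grid
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.nx}\n")
        fh.write(f"nrows {g.ny}\n")
        fh.write(f"xllcorner {g.x0:.6g}\n")
        fh.write(f"yllcorner {g.y0:.6g}\n")
        fh.write(f"cellsize {g.cell:.6g}\n")
        fh.write("NODATA_value -9999\n")
        for row in ud.masses[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _geom_mapping(geom) -> dict:
    import shapely
    from shapely.geometry import mapping

    return mapping(shapely.set_precision(geom, 0.001))


def polygons_to_geojson(
    named_polygons: dict[str, object],
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write labelled polygons (e.g. isopleths, MCPs) as one FeatureCollection."""
    feats = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": _geom_mapping(geom),
        }
        for name, geom in named_polygons.items()
    ]
    doc = {
        "type": "FeatureCollection",
        "features": feats,
        "_meta": {
            "package": f"jackalkit {__version__}",
            "seed": seed,
            "config_hash": config_hash(config or {}),
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))
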