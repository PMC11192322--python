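"""File formats and run configuration.

Everything on disk is plain text: point tables and grid maps are CSV,
metadata travels in JSON sidecars, configuration is YAML/JSON.
Coordinates pass through unchanged — unit-square simulation data and
projected-CRS km offsets are both just planar numbers here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gridmaps import GridMap, PredictionGrid
from .inference import InferenceConfig
from .kriging import PriorConfig
from .sdm import SdmSpec
from .simulation import SimulationConfig

__all__ = [
    "read_point_table",
    "write_grid_map",
    "read_grid_map",
    "make_fixture",
    "RunConfig",
]


def read_point_table(path, value_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV point table with columns x, y plus named value columns.

    Missing values (empty cells / NA) are parsed as NaN and their count
    is recorded in ``df.attrs["n_missing"]``.  Errors name the offending
    column or row.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty point table (0 rows)")
    required = ["x", "y"] + list(value_columns or [])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"{path}: non-numeric or missing coordinate in column {col!r} "
                f"at row {row + 2} (1-based, incl. header)"
            )
        df[col] = vals
    n_missing = 0
    for col in value_columns or []:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        n_missing += int(df[col].isna().sum())
    df.attrs["n_missing"] = n_missing
    return df


def write_grid_map(grid_map: GridMap, path, metadata: dict | None = None) -> None:
    """Write a grid map CSV plus a JSON sidecar of grid spec and metadata.

    Masked cells are written with explicit empty (NA) mean/sd fields.
    """
    path = Path(path)
    grid_map.to_frame().to_csv(path, index=False, na_rep="NA")
    sidecar = {
        "grid": grid_map.grid.to_dict(),
        "quantity": grid_map.quantity,
        "n_masked": grid_map.n_masked,
        "version": __version__,
        **(metadata or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=_json_default) + "\n")


def read_grid_map(path) -> GridMap:
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA"])
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = PredictionGrid.from_dict(sidecar["grid"])
    mean = df["mean"].to_numpy(dtype=float)
    sd = df["sd"].to_numpy(dtype=float)
    mask = np.isnan(mean) if np.isnan(mean).any() else None
    if mask is not None:
        mean = np.where(mask, 0.0, mean)
        sd = np.where(mask, 0.0, sd)
    return GridMap(grid=grid, mean=mean, sd=sd,
                   quantity=sidecar.get("quantity", "value"), mask=mask)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

_FIXTURE_SIZES = {
    "tiny": {"n_species": 200, "n_abiotic": 40},
    "paper": {"n_species": 1000, "n_abiotic": 100},
}


def make_fixture(kind: str, size: str, seed: int, out_dir) -> dict:
    """Write a deterministic simulated dataset to ``out_dir``.

    ``kind`` is "aligned" or "misaligned"; ``size`` "tiny" (N=200,
    M=40, for fast tests) or "paper" (N=1000, M=100).  Files:
    species.csv (x, y, y_obs plus any aligned covariate columns) and
    abiotic_<name>.csv per covariate, plus a manifest JSON.  Returns
    the file-path mapping.
    """
    from .simulation import generate_dataset

    if kind not in ("aligned", "misaligned"):
        raise ValueError(f"kind must be aligned|misaligned, got {kind!r}")
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"size must be tiny|paper, got {size!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(
        misaligned=(kind == "misaligned"), seed=seed, **_FIXTURE_SIZES[size]
    )
    data = generate_dataset(config, run_seed=seed)

    files = {}
    sp = pd.DataFrame({"x": data.species.points[:, 0],
                       "y": data.species.points[:, 1],
                       "y_obs": data.species.y.astype(int)})
    for col in data.species.covariates.columns:
        sp[col] = data.species.covariates[col]
    sp_path = out_dir / "species.csv"
    sp.to_csv(sp_path, index=False, float_format="%.10g")
    files["species"] = str(sp_path)
    for name, fr in data.abiotic.items():
        p = out_dir / f"abiotic_{name}.csv"
        fr.to_frame().to_csv(p, index=False, float_format="%.10g")
        files[f"abiotic_{name}"] = str(p)
    manifest = {
        "kind": kind, "size": size, "seed": seed, "version": __version__,
        "config": asdict(config), "files": files,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default) + "\n")
    return files


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for a CLI run.

    Unknown keys anywhere in the file are rejected outright; every
    section maps onto one of the package's dataclasses.
    """

    seed: int = 0
    species_path: str | None = None
    abiotic_paths: dict = field(default_factory=dict)
    sdm: SdmSpec = field(default_factory=lambda: SdmSpec(linear_terms=("x1", "x2")))
    priors: PriorConfig = field(default_factory=PriorConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grid: PredictionGrid = field(default_factory=lambda: PredictionGrid.unit_square(25))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        sections = {
            "sdm": SdmSpec, "priors": PriorConfig, "inference": InferenceConfig,
            "simulation": SimulationConfig, "grid": PredictionGrid,
        }
        for key, val in raw.items():
            if key in sections:
                kwargs[key] = _build_section(sections[key], val, key)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=_json_default).encode()
        ).hexdigest()[:16]

    def manifest(self, command: str) -> dict:
        """Reproducibility manifest written next to every CLI output."""
        return {
            "command": command,
            "config_hash": self.content_hash(),
            "seed": self.seed,
            "version": __version__,
            "config": self.to_dict(),
        }


def _build_section(cls, raw: dict, name: str):
    if not isinstance(raw, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    kwargs = dict(raw)
    for key in ("linear_terms", "spline_terms", "betas", "origin"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "priors" in kwargs and isinstance(kwargs["priors"], dict):
        kwargs["priors"] = _build_section(PriorConfig, kwargs["priors"], "priors")
    return cls(**kwargs)
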