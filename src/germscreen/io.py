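"""Configuration, table I/O and packaged reference data.

All tabular I/O is comma-delimited UTF-8 with a header row; simulated
output files carry a leading comment line recording the seed and a
parameter digest so every file is regenerable from (inputs, config,
seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .screen import ScreenSummary

__all__ = [
    "RunConfig", "load_config", "write_table", "read_table",
    "file_digest", "params_digest", "packaged_library_path",
    "load_screen_folds", "summaries_from_fold_table",
]


@dataclass
class RunConfig:
    """Run-level configuration shared by all pipeline stages."""

    seed: int = 1
    scenario: str = "paper-default"
    out_dir: str = "germscreen_out"
    alpha: float = 0.05
    n_events: int = 450
    n_replicates: int = 3
    n_gonads: int = 100
    n_mothers: int = 15
    benchmark: str = "BPA"
    calibration_file: str | None = None
    library_file: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML key-value config file, applying keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def file_digest(path: str | Path) -> str:
    """Short SHA-256 digest of a file's bytes."""
    h = hashlib.sha256(Path(path).read_bytes())
    return h.hexdigest()[:12]


def params_digest(params: dict) -> str:
    """Short SHA-256 digest of a JSON-serializable parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                params: dict | None = None) -> None:
    """Write a CSV with an optional seed/parameter-digest comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None or params is not None:
            digest = params_digest(params or {})
            fh.write(f"# seed={seed} params_digest={digest}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# packaged data

def packaged_library_path() -> Path:
    """Path of the packaged synthetic 46-chemical library table."""
    return Path(resources.files("germscreen.data") / "library_synthetic.csv")


def load_screen_folds(path: str | Path | None = None) -> pd.DataFrame:
    """Load a per-replicate fold table (default: the packaged synthetic
    stand-in for the published screen readout)."""
    if path is None:
        path = resources.files("germscreen.data") / "screen_folds_synthetic.csv"
    df = pd.read_csv(path, comment="#")
    fold_cols = [c for c in df.columns if c.startswith("fold_rep")]
    if "name" not in df.columns or not fold_cols:
        raise ValueError("fold table needs a 'name' column and fold_rep* "
                         "columns")
    return df


def summaries_from_fold_table(df: pd.DataFrame) -> list[ScreenSummary]:
    """Build per-chemical summaries from a fold table (no p-values:
    the table carries folds only)."""
    fold_cols = sorted(c for c in df.columns if c.startswith("fold_rep"))
    out = []
    for row in df.itertuples(index=False):
        folds = [float(getattr(row, c)) for c in fold_cols]
        mean = sum(folds) / len(folds)
        sem = (pd.Series(folds).std(ddof=1) / len(folds) ** 0.5
               if len(folds) > 1 else 0.0)
        out.append(ScreenSummary(
            chemical=str(row.name), folds=folds, mean_fold=mean,
            sem_fold=float(sem), p_value=float("nan"),
            category=getattr(row, "category", None)))
    return out
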