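"""File I/O: delimited tables, indicator configs and run metadata.

All delimited outputs are comma-separated UTF-8 with a mandatory header
row; metadata (seed, config hash, package version) is written as leading
``#`` comment lines that every reader here skips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .topsis import DecisionMatrix, Indicator, TopsisError, TopsisResult
from .trial import TrialDataset, TrialError

__all__ = [
    "RunConfig",
    "read_indicator_config",
    "write_indicator_config",
    "read_decision_matrix",
    "write_decision_matrix",
    "read_trial_dataset",
    "write_trial_dataset",
    "read_taxon_table",
    "write_taxon_table",
    "write_topsis_report",
    "write_table",
]


@dataclass
class RunConfig:
    """Options shared by the command-line entry points."""

    seed: int = 0
    normalization: str = "vector"
    weighting: str = "config"  # "config" | "equal" | "entropy"
    alpha: float = 0.05
    ndigits: int = 3
    out_dir: Path = Path("results")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)

    def digest(self) -> str:
        # out_dir does not affect the computation, so it is not part of the hash
        payload = {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _meta_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, object] | None = None, *, index: bool = False) -> Path:
    """Write a DataFrame as CSV with optional ``#`` metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, index=index)
    return path


# --- indicator configs -----------------------------------------------------

def write_indicator_config(indicators: Sequence[Indicator], path: str | Path) -> Path:
    """Write an indicator config as YAML.

    Weights are serialized via ``repr`` (shortest round-tripping float
    form), so reading the file back restores them bit-exactly.
    """
    doc = {}
    for ind in indicators:
        entry: dict[str, object] = {"direction": ind.direction, "weight": float(ind.weight)}
        if ind.direction == "interval":
            entry["interval"] = [float(ind.interval_low), float(ind.interval_high)]
        doc[ind.name] = entry
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def read_indicator_config(path: str | Path) -> list[Indicator]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise TopsisError(f"indicator config {path} is empty or not a mapping")
    out = []
    for name, entry in raw.items():
        direction = entry.get("direction", "benefit")
        weight = float(entry.get("weight", 1.0))
        low = high = None
        if "interval" in entry:
            low, high = (float(v) for v in entry["interval"])
        out.append(Indicator(str(name), direction, weight=weight,
                             interval_low=low, interval_high=high))
    return out


# --- decision matrices -----------------------------------------------------

def write_decision_matrix(matrix: DecisionMatrix, path: str | Path,
                          meta: Mapping[str, object] | None = None) -> Path:
    df = matrix.values.rename_axis(index="treatment").reset_index()
    return write_table(df, path, meta)


def read_decision_matrix(path: str | Path, indicators: Sequence[Indicator]) -> DecisionMatrix:
    """Read a treatments × indicators CSV (first column = treatment label)
    and bind it to an indicator config."""
    df = pd.read_csv(path, comment="#")
    if df.empty or df.shape[1] < 2:
        raise TopsisError(f"decision matrix {path} is empty")
    df = df.set_index(df.columns[0])
    df.index.name = None
    names = [ind.name for ind in indicators]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise TopsisError(f"decision matrix {path} lacks indicator columns: {missing}")
    return DecisionMatrix(values=df[names].astype(float), indicators=list(indicators))


# --- trial datasets --------------------------------------------------------

def write_trial_dataset(dataset: TrialDataset, path: str | Path,
                        meta: Mapping[str, object] | None = None) -> Path:
    df = dataset.data.copy()
    df["is_control"] = [
        dataset.controls[r] == t for r, t in zip(df["region"], df["treatment"])
    ]
    return write_table(df, path, meta)


def read_trial_dataset(path: str | Path) -> TrialDataset:
    df = pd.read_csv(path, comment="#")
    if "is_control" not in df.columns:
        raise TrialError(f"trial table {path} lacks the is_control column")
    controls = {}
    for region, sub in df[df["is_control"]].groupby("region"):
        ctrls = sub["treatment"].unique()
        if len(ctrls) != 1:
            raise TrialError(f"region {region!r} flags {len(ctrls)} controls")
        controls[region] = str(ctrls[0])
    return TrialDataset(data=df.drop(columns=["is_control"]), controls=controls)


# --- taxon tables ----------------------------------------------------------

def write_taxon_table(table: pd.DataFrame, path: str | Path,
                      meta: Mapping[str, object] | None = None) -> Path:
    """Write samples × taxa counts in profiler layout (taxa rows, sample
    columns)."""
    df = table.T.rename_axis(index="taxon").reset_index()
    return write_table(df, path, meta)


def read_taxon_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df = df.set_index(df.columns[0])
    return df.T


# --- reports ---------------------------------------------------------------

def write_topsis_report(result: TopsisResult, path: str | Path,
                        meta: Mapping[str, object] | None = None,
                        *, ndigits: int = 3) -> tuple[Path, Path]:
    """Write the rounded report (layout: treatment, d_plus, d_minus,
    closeness, rank) plus a full-precision companion ``<stem>_raw.csv``."""
    path = Path(path)
    rounded = write_table(result.to_frame(ndigits=ndigits), path, meta)
    raw = write_table(result.to_frame(), path.with_name(path.stem + "_raw.csv"), meta)
    return rounded, raw
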