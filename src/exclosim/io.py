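"""Readers, writers and run configuration.

CSV dialect everywhere: UTF-8, comma-separated, "." decimal, mandatory
header row.  Units are embedded in column names: biomass in grams
(``biomass_g``), cover in percent (``cover_pct``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TREATMENT_COLUMNS
from .simulate import PAPER_VC, VarianceComponents

__all__ = ["read_biomass", "read_cover", "RunConfig", "write_provenance"]

_BIOMASS_REQUIRED = ["site_id", "block_id", "plot_id", *TREATMENT_COLUMNS, "biomass_g"]
_COVER_REQUIRED = ["site_id", "block_id", "plot_id", "species", "cover_pct"]
_YEAR_COLUMNS = ["year_since_start", "calendar_year"]


def _check_headers(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def _coerce_treatments(df: pd.DataFrame, path) -> None:
    for col in TREATMENT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(
                f"{path}: non-binary value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} (file row {row}); treatment flags must be 0 or 1"
            )
        df[col] = vals.astype(int)


def _reject_duplicates(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup.idxmax(), keys].to_dict()
        raise ValueError(f"{path}: duplicated key {first} (keys: {keys})")


def read_biomass(path) -> pd.DataFrame:
    """Read and validate a plot-level biomass sheet.

    Requires columns ``site_id, block_id, plot_id, insecticide, fungicide,
    molluscicide, biomass_g`` (optional ``year_since_start`` /
    ``calendar_year``); rejects duplicate plot(-year) keys and non-binary
    treatment flags.
    """
    df = pd.read_csv(path)
    _check_headers(df, _BIOMASS_REQUIRED, path)
    _coerce_treatments(df, path)
    df["biomass_g"] = pd.to_numeric(df["biomass_g"])
    keys = ["site_id", "block_id", "plot_id"] + [c for c in _YEAR_COLUMNS[:1] if c in df.columns]
    _reject_duplicates(df, keys, path)
    return df


def read_cover(path) -> pd.DataFrame:
    """Read and validate a long-format species-cover sheet.

    Total cover per plot may exceed 100% (species are estimated
    independently and can overlap), but individual covers must be >= 0.
    """
    df = pd.read_csv(path)
    _check_headers(df, _COVER_REQUIRED, path)
    if set(TREATMENT_COLUMNS).issubset(df.columns):
        _coerce_treatments(df, path)
    df["cover_pct"] = pd.to_numeric(df["cover_pct"])
    if (df["cover_pct"] < 0).any():
        raise ValueError(f"{path}: negative cover_pct values")
    keys = ["site_id", "block_id", "plot_id", "species"] + [
        c for c in _YEAR_COLUMNS[:1] if c in df.columns
    ]
    _reject_duplicates(df, keys, path)
    return df


@dataclass
class RunConfig:
    """Seed, design, variance and model options of one reproducible run."""

    seed: int = 0
    n_sites: int = 35
    n_blocks_per_site: int = 3
    sd_site: float = PAPER_VC.sd_site
    sd_block: float = PAPER_VC.sd_block
    sd_plot: float = PAPER_VC.sd_plot
    baseline: float = 100.0
    n_sim: int = 300
    n_iter: int = 10_000
    alpha: float = 0.05
    coding: str = "indicator"
    transform: str = "identity"

    def __post_init__(self) -> None:
        VarianceComponents(self.sd_site, self.sd_block, self.sd_plot)  # validates
        if self.n_sites < 1 or self.n_blocks_per_site < 1:
            raise ValueError("n_sites and n_blocks_per_site must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.coding not in ("indicator", "effect"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def vc(self) -> VarianceComponents:
        return VarianceComponents(self.sd_site, self.sd_block, self.sd_plot)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(path, config: RunConfig, **extra) -> None:
    """Write a JSON provenance record (seed, config hash, counts)."""
    record = {"seed": config.seed, "config_hash": config.config_hash(),
              "config": asdict(config), **extra}
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
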