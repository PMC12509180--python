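"""Experimental layout for multi-site factorial consumer-exclusion experiments.

The design is a randomized complete block design replicated across sites:
each site holds ``n_blocks_per_site`` blocks, and every block contains all
eight combinations of the 2x2x2 factorial of three biocide treatments
(insecticide, fungicide, molluscicide), i.e. 24 plots per site for the
default three blocks.  Plot positions within a block are randomized with a
per-block seeded generator so designs are reproducible and extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentCombo",
    "DesignSpec",
    "FULL_FACTORIAL",
    "TREATMENT_COLUMNS",
    "TERM_ORDER",
    "build_design",
    "encode_treatments",
    "write_plot_table",
    "InvalidDesignError",
]

#: Names of the three binary treatment flags, in canonical column order.
TREATMENT_COLUMNS = ("insecticide", "fungicide", "molluscicide")

#: Canonical order of the seven factorial model terms.
TERM_ORDER = ("i", "f", "m", "f:m", "i:m", "i:f", "i:f:m")

_TERM_FACTORS = {
    "i": ("insecticide",),
    "f": ("fungicide",),
    "m": ("molluscicide",),
    "f:m": ("fungicide", "molluscicide"),
    "i:m": ("insecticide", "molluscicide"),
    "i:f": ("insecticide", "fungicide"),
    "i:f:m": ("insecticide", "fungicide", "molluscicide"),
}


class InvalidDesignError(ValueError):
    """Raised when a design specification is not realizable."""


@dataclass(frozen=True)
class TreatmentCombo:
    """One cell of the 2^3 biocide factorial.

    Flags are 1 when the biocide is applied (the consumer group is reduced)
    and 0 when it is not; ``(0, 0, 0)`` is the untreated control.
    """

    insecticide: int
    fungicide: int
    molluscicide: int

    def __post_init__(self) -> None:
        for name in TREATMENT_COLUMNS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise InvalidDesignError(f"{name} flag must be 0 or 1, got {v!r}")

    @property
    def n_reduced(self) -> int:
        """Number of consumer groups reduced on this plot (0-3)."""
        return self.insecticide + self.fungicide + self.molluscicide

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.insecticide, self.fungicide, self.molluscicide)


#: All eight treatment combinations, control first.
FULL_FACTORIAL: tuple[TreatmentCombo, ...] = tuple(
    TreatmentCombo(i, f, m) for i, f, m in product((0, 1), repeat=3)
)


@dataclass(frozen=True)
class DesignSpec:
    """Layout parameters of a multi-site randomized complete block factorial.

    Parameters
    ----------
    n_sites
        Number of experimental sites.
    n_blocks_per_site
        Blocks per site; every block receives the full factorial once, so a
        site holds ``8 * n_blocks_per_site`` plots (24 for the default 3).
    rng_seed
        Master seed for the within-block plot randomization.
    """

    n_sites: int
    n_blocks_per_site: int = 3
    treatments: tuple[TreatmentCombo, ...] = field(default=FULL_FACTORIAL)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidDesignError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.n_blocks_per_site < 1:
            raise InvalidDesignError(
                f"n_blocks_per_site must be >= 1, got {self.n_blocks_per_site}"
            )
        if len(set(self.treatments)) != 8:
            raise InvalidDesignError("treatments must be the 8 distinct factorial combos")

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.n_blocks_per_site * len(self.treatments)


def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Construct the plot table for a design specification.

    Returns a long-format table with one row per plot and columns
    ``site_id, block_id, plot_id, insecticide, fungicide, molluscicide``.
    Within every block the eight treatment combinations appear exactly once,
    in an order drawn from a generator seeded by
    ``(rng_seed, site_index, block_index)``, so the same seed reproduces the
    same design and adding sites never reshuffles existing ones.
    """
    rows = []
    n_combos = len(spec.treatments)
    for s in range(spec.n_sites):
        site_id = f"S{s + 1:02d}"
        for b in range(spec.n_blocks_per_site):
            rng = np.random.default_rng([spec.rng_seed, s, b])
            order = rng.permutation(n_combos)
            for plot, idx in enumerate(order, start=1):
                combo = spec.treatments[idx]
                rows.append(
                    (site_id, f"B{b + 1}", plot, *combo.as_tuple())
                )
    table = pd.DataFrame(
        rows, columns=["site_id", "block_id", "plot_id", *TREATMENT_COLUMNS]
    )
    return table


def encode_treatments(table: pd.DataFrame, scheme: str = "indicator") -> pd.DataFrame:
    """Return the seven factorial design-matrix columns for a plot table.

    ``scheme="indicator"`` keeps the 0/1 flags; ``scheme="effect"`` recodes
    them to -1/+1 (absent/applied), the sum-to-zero contrast under which
    main-effect coefficients are half-differences of marginal means.
    Interaction columns are elementwise products of the coded main columns.
    """
    if scheme not in ("indicator", "effect"):
        raise ValueError(f"unknown coding scheme {scheme!r}; use 'indicator' or 'effect'")
    missing = [c for c in TREATMENT_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"plot table lacks treatment columns: {missing}")
    coded = {}
    for name in TREATMENT_COLUMNS:
        col = table[name].to_numpy(dtype=float)
        coded[name] = 2.0 * col - 1.0 if scheme == "effect" else col
    out = {}
    for term in TERM_ORDER:
        cols = [coded[f] for f in _TERM_FACTORS[term]]
        out[term] = np.prod(cols, axis=0) if len(cols) > 1 else cols[0]
    return pd.DataFrame(out, index=table.index)


def write_plot_table(table: pd.DataFrame, path) -> None:
    """Serialize a plot table to CSV (UTF-8, comma-separated, header row)."""
    table.to_csv(path, index=False)


def check_balance(table: pd.DataFrame) -> None:
    """Assert the randomized-complete-block invariant.

    Every (site, block) must contain each of the eight factorial combos
    exactly once.  Raises :class:`InvalidDesignError` otherwise.
    """
    full = {c.as_tuple() for c in FULL_FACTORIAL}
    grouped = table.groupby(["site_id", "block_id"], sort=False)
    for (site, block), g in grouped:
        combos = list(zip(g["insecticide"], g["fungicide"], g["molluscicide"]))
        if len(combos) != 8 or set(combos) != full:
            raise InvalidDesignError(
                f"block ({site}, {block}) does not contain the full factorial exactly once"
            )
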