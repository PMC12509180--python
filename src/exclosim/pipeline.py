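"""Pre-registered analysis stages for the multi-site exclusion experiment.

Covers construction of plot-level response variables from species-cover
tables (richness, Shannon diversity, functional-group cover percentages),
the per-site factorial model, the cross-site longitudinal mixed model, the
context-dependency model with a standardized per-site driver, backward
stepwise simplification of interactions by likelihood-ratio tests, and the
number-of-excluded-groups recoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .design import TREATMENT_COLUMNS
from .lmm import FitResult, ModelSpec, fit_lmm, lrt_test

__all__ = [
    "shannon",
    "richness",
    "group_cover",
    "build_response_table",
    "fit_site_model",
    "fit_overall_model",
    "fit_context_model",
    "simplify_model",
    "n_groups_recode",
    "SimplifyStep",
    "SimplifyResult",
]

logger = logging.getLogger(__name__)

_KEYS = ["site_id", "block_id", "plot_id"]


def shannon(cover: Sequence[float]) -> float:
    """Shannon diversity H = -sum(p ln p) in nats over positive covers."""
    x = np.asarray(cover, dtype=float)
    if np.any(x < 0):
        raise ValueError("covers must be >= 0")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("Shannon diversity is undefined for an all-zero cover vector")
    p = x / x.sum()
    return float(_sstats.entropy(p))  # natural log


def richness(cover: Sequence[float]) -> int:
    """Number of species with positive cover."""
    x = np.asarray(cover, dtype=float)
    return int(np.count_nonzero(x > 0))


def group_cover(
    cover: Mapping[str, float], groups: Mapping[str, str]
) -> dict[str, float]:
    """Percent of total cover per functional group.

    ``groups`` maps species to a group label; species missing from the
    mapping are assigned to ``"other"`` (logged once per call).
    """
    totals: dict[str, float] = {}
    missing = []
    total = 0.0
    for sp, c in cover.items():
        if c <= 0:
            continue
        g = groups.get(sp)
        if g is None:
            missing.append(sp)
            g = "other"
        totals[g] = totals.get(g, 0.0) + float(c)
        total += float(c)
    if missing:
        logger.warning("species without group mapping assigned to 'other': %s", sorted(missing))
    if total == 0.0:
        return {}
    return {g: 100.0 * c / total for g, c in totals.items()}


def build_response_table(
    cover: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    biomass: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate a long cover table into one row per plot/year.

    Adds ``richness`` and ``shannon`` columns, a ``<group>_pct`` column per
    functional group when a mapping is given, and merges ``biomass_g`` when
    a biomass table is supplied.  Empty plots get richness 0 and NaN for
    the diversity and group responses (flagged with ``empty_plot=True``).
    """
    keys = _KEYS + [c for c in ("year_since_start", "calendar_year") if c in cover.columns]
    carry = [c for c in TREATMENT_COLUMNS if c in cover.columns]
    rows = []
    for key_vals, g in cover.groupby(keys, sort=False):
        vec = g["cover_pct"].to_numpy(dtype=float)
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        for c in carry:
            row[c] = g[c].iloc[0]
        rich = richness(vec)
        row["richness"] = rich
        row["empty_plot"] = rich == 0
        row["shannon"] = shannon(vec) if rich > 0 else np.nan
        if groups is not None:
            gc = group_cover(dict(zip(g["species"], vec)), groups)
            for grp in sorted(set(groups.values()) | {"other"}):
                row[f"{grp}_pct"] = gc.get(grp, 0.0) if rich > 0 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if biomass is not None:
        out = out.merge(biomass[keys + ["biomass_g"]], on=keys, how="left")
    return out


_FACTORIAL_TERMS = ("i", "f", "m", "f:m", "i:m", "i:f", "i:f:m")


def _year_crossed_terms() -> tuple[str, ...]:
    """Fixed terms of year_since_start x i x f x m (full crossing)."""
    terms = ["year_since_start", *_FACTORIAL_TERMS]
    terms += [f"year_since_start:{t}" for t in _FACTORIAL_TERMS]
    return tuple(terms)


def fit_site_model(
    site_data: pd.DataFrame,
    response: str = "biomass_g",
    criterion: str = "reml",
    coding: str = "indicator",
) -> FitResult:
    """Single-site factorial model.

    With one time point this is the fixed-effects model
    ``response ~ block + i*f*m`` (block as a categorical covariate, ordinary
    least squares).  With several years the longitudinal variant
    ``response ~ year_since_start * i * f * m`` with random intercepts for
    calendar year and plot is fitted instead.
    """
    for col in TREATMENT_COLUMNS:
        if col not in site_data.columns:
            raise KeyError(f"missing treatment column {col!r}")
    if site_data["site_id"].nunique() != 1:
        raise ValueError("fit_site_model expects data from a single site")
    years = site_data["year_since_start"].nunique() if "year_since_start" in site_data else 1
    if years == 1:
        spec = ModelSpec(
            response=response,
            fixed_terms=("block_id", *_FACTORIAL_TERMS),
            random_intercepts=(),
            coding=coding,
        )
        return fit_lmm(site_data, spec, criterion=criterion)
    spec = ModelSpec(
        response=response,
        fixed_terms=_year_crossed_terms(),
        random_intercepts=("calendar_year:site", "plot"),
        coding=coding,
    )
    return fit_lmm(site_data, spec, criterion=criterion)


def _has_year_variation(all_data: pd.DataFrame) -> bool:
    return (
        "year_since_start" in all_data.columns
        and all_data["year_since_start"].nunique() >= 2
    )


def _longitudinal_terms(all_data: pd.DataFrame) -> tuple[str, ...]:
    """Year-crossed factorial terms, or the plain factorial when the data
    hold a single time point (year terms would be inestimable)."""
    if not _has_year_variation(all_data):
        logger.warning("single time point: omitting year_since_start terms")
        return _FACTORIAL_TERMS
    return _year_crossed_terms()


def _overall_random_intercepts(all_data: pd.DataFrame) -> tuple[str, ...]:
    res = ["site", "block", "plot", "calendar_year:site"]
    if "calendar_year" not in all_data.columns or all_data["calendar_year"].nunique() < 2:
        logger.warning("single calendar year: dropping the calendar_year:site random intercept")
        res.remove("calendar_year:site")
    n_per_plot = all_data.groupby(["site_id", "block_id", "plot_id"]).size()
    if n_per_plot.max() < 2:
        # one record per plot: the plot intercept is the residual
        res.remove("plot")
    return tuple(res)


def fit_overall_model(
    all_data: pd.DataFrame,
    response: str = "biomass_g",
    criterion: str = "reml",
    coding: str = "indicator",
) -> FitResult:
    """Cross-site longitudinal mixed model.

    ``response ~ year_since_start * i * f * m`` with random intercepts for
    site, block-within-site, plot-within-block and calendar-year-within-site
    (the last dropped, with a logged warning, for single-year data).
    ``year_since_start`` is 0 at baseline, so in noise-free data the
    intercept equals the baseline control mean.
    """
    spec = ModelSpec(
        response=response,
        fixed_terms=_longitudinal_terms(all_data),
        random_intercepts=_overall_random_intercepts(all_data),
        coding=coding,
    )
    return fit_lmm(all_data, spec, criterion=criterion)


def fit_context_model(
    all_data: pd.DataFrame,
    driver: pd.DataFrame | Mapping[str, float],
    response: str = "biomass_g",
    driver_name: str = "driver",
    criterion: str = "reml",
) -> FitResult:
    """Context-dependency model with a standardized per-site driver.

    ``response ~ (driver + year_since_start) * i * f * m`` with the overall
    model's random structure.  ``driver`` maps ``site_id`` to one value per
    site (e.g. mean annual temperature, soil pH, or mean control biomass);
    it is centered and scaled before entering the interactions.
    """
    if isinstance(driver, pd.DataFrame):
        if not {"site_id", "value"}.issubset(driver.columns):
            raise ValueError("driver frame needs columns site_id, value")
        mapping = dict(zip(driver["site_id"].astype(str), driver["value"].astype(float)))
    else:
        mapping = {str(k): float(v) for k, v in driver.items()}
    sites = all_data["site_id"].astype(str)
    missing = sorted(set(sites) - set(mapping))
    if missing:
        raise ValueError(f"driver value missing for sites: {missing}")
    vals = sites.map(mapping).to_numpy(dtype=float)
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError(
            f"driver {driver_name!r} is constant across sites; its treatment "
            "interactions are inestimable"
        )
    data = all_data.copy()
    data["_driver_z"] = (vals - vals.mean()) / sd
    with_year = _has_year_variation(all_data)
    terms = ["_driver_z"] + (["year_since_start"] if with_year else []) + list(_FACTORIAL_TERMS)
    terms += [f"_driver_z:{t}" for t in _FACTORIAL_TERMS]
    if with_year:
        terms += [f"year_since_start:{t}" for t in _FACTORIAL_TERMS]
    spec = ModelSpec(
        response=response,
        fixed_terms=tuple(terms),
        random_intercepts=_overall_random_intercepts(all_data),
        coding="indicator",
    )
    return fit_lmm(data, spec, criterion=criterion)


@dataclass(frozen=True)
class SimplifyStep:
    term: str
    statistic: float
    df: int
    pvalue: float
    dropped: bool


@dataclass
class SimplifyResult:
    final: FitResult
    steps: list[SimplifyStep] = field(default_factory=list)

    @property
    def retained_terms(self) -> tuple[str, ...]:
        return self.final.spec.fixed_terms


def _order(term: str) -> int:
    return term.count(":") + 1


def _factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def simplify_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    final_criterion: str = "reml",
) -> SimplifyResult:
    """Backward elimination of nonsignificant interactions.

    Starting from the highest interaction order, each currently removable
    interaction (one not contained in a retained higher-order term) is
    tested with a likelihood-ratio test of the model with and without it
    (ML fits); the least significant removable term (largest p) is dropped
    while its p-value exceeds ``alpha``, until only significant
    interactions remain.  Main effects (order-1 terms) are always kept.
    Returns the final model refitted under ``final_criterion`` together with
    the ordered elimination log.
    """
    current = spec
    steps: list[SimplifyStep] = []
    fit_full = fit_lmm(data, current, criterion="ml")
    while True:
        interactions = [t for t in current.fixed_terms if _order(t) >= 2]
        removable = [
            t
            for t in interactions
            if not any(
                _factors(t) < _factors(o) for o in interactions if o != t
            )
        ]
        if not removable:
            break
        tests = []
        for t in removable:
            reduced = fit_lmm(data, current.drop_term(t), criterion="ml")
            tests.append((t, lrt_test(fit_full, reduced), reduced))
        term, lrt, reduced_fit = max(tests, key=lambda x: x[1].pvalue)
        if lrt.pvalue > alpha:
            steps.append(SimplifyStep(term, lrt.statistic, lrt.df, lrt.pvalue, True))
            current = current.drop_term(term)
            fit_full = reduced_fit
        else:
            for t, l, _ in sorted(tests, key=lambda x: -x[1].pvalue):
                steps.append(SimplifyStep(t, l.statistic, l.df, l.pvalue, False))
            break
    final = fit_lmm(data, current, criterion=final_criterion)
    return SimplifyResult(final=final, steps=steps)


def n_groups_recode(table: pd.DataFrame) -> pd.Series:
    """Number of consumer groups reduced per plot (0-3): sum of the flags."""
    missing = [c for c in TREATMENT_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"missing treatment columns: {missing}")
    return table[list(TREATMENT_COLUMNS)].sum(axis=1).astype(int)
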