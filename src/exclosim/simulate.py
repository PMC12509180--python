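"""Hierarchical data-generating models for the exclusion experiment.

Biomass for each plot is generated additively on the gram scale::

    biomass = b0 + bi*i + bf*f + bm*m
              + bfm*f*m + bim*i*m + bif*i*f + bifm*i*f*m
              + site_effect + block_effect + plot_effect

with 0/1 treatment indicators and independent Gaussian random effects at the
site, block-within-site and plot-within-block levels.  The plot-level draw is
the observation-level noise (one observation per plot), so its SD doubles as
the residual SD when the model is refitted.

Default variance components (site 372.7 g, block 7.82 g, plot 15.33 g around
a 100 g baseline) describe the between-site, between-block and between-plot
variation of baseline biomass in a globally distributed grassland network;
they are the conditions under which the power and calibration presets run.

Three effect families are provided:

* ``main_only`` - each biocide alone raises biomass by ``effect_pct`` % of
  baseline, no interactions;
* ``superadditive`` - mains as above plus an extra ``effect_pct`` % when
  fungicide and molluscicide are combined (synergy on that pair);
* ``compensatory`` - each biocide alone raises biomass, but any combination
  of two or three biocides shows no increase over the control (perfect
  antagonism: every pairwise coefficient is -2*delta and the three-way
  coefficient +3*delta, which zeroes all multi-biocide cells).

A separate community generator produces multi-site, multi-year species-cover
tables (with a derived biomass column) so the downstream diversity and
composition models can be exercised without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design import FULL_FACTORIAL, TREATMENT_COLUMNS, TreatmentCombo

__all__ = [
    "VarianceComponents",
    "EffectScenario",
    "CommunityScenario",
    "PAPER_VC",
    "scenario_from_preset",
    "expected_mean",
    "expected_means",
    "simulate_experiment",
    "simulate_community",
]

PRESET_FAMILIES = ("null", "main_only", "superadditive", "compensatory")

#: Effect sizes (percent of baseline) used in the replication presets.
PRESET_EFFECT_PCTS = (0.0, 5.0, 7.5, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class VarianceComponents:
    """Standard deviations (g) of the nested Gaussian random effects."""

    sd_site: float
    sd_block: float
    sd_plot: float

    def __post_init__(self) -> None:
        for name in ("sd_site", "sd_block", "sd_plot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


#: Baseline variance components of the 35-site design presets.
PAPER_VC = VarianceComponents(sd_site=372.7, sd_block=7.82, sd_plot=15.33)


@dataclass(frozen=True)
class EffectScenario:
    """Fixed-effect coefficients (g) of the biomass generating model."""

    baseline_beta0: float = 100.0
    beta_i: float = 0.0
    beta_f: float = 0.0
    beta_m: float = 0.0
    beta_fm: float = 0.0
    beta_im: float = 0.0
    beta_if: float = 0.0
    beta_ifm: float = 0.0
    family: str = "null"
    effect_pct: float = 0.0

    def coefficients(self) -> np.ndarray:
        """Coefficient vector in term order (b0, i, f, m, f:m, i:m, i:f, i:f:m)."""
        return np.array(
            [
                self.baseline_beta0,
                self.beta_i,
                self.beta_f,
                self.beta_m,
                self.beta_fm,
                self.beta_im,
                self.beta_if,
                self.beta_ifm,
            ]
        )


def scenario_from_preset(
    family: str,
    effect_pct: float,
    baseline: float = 100.0,
    *,
    all_pairs: bool = False,
) -> EffectScenario:
    """Build an :class:`EffectScenario` from a named effect family.

    Parameters
    ----------
    family
        One of ``null``, ``main_only``, ``superadditive``, ``compensatory``.
    effect_pct
        Effect size as a percent of ``baseline``; each preset converts it to
        an additive delta in grams (``delta = effect_pct * baseline / 100``).
    all_pairs
        For the superadditive family only: inject the synergy on all three
        pairs instead of the default fungicide x molluscicide pair
        (sensitivity-analysis variant).
    """
    if family not in PRESET_FAMILIES:
        raise ValueError(f"unknown scenario family {family!r}; use one of {PRESET_FAMILIES}")
    if baseline < 0:
        raise ValueError(f"baseline must be >= 0, got {baseline}")
    delta = effect_pct * baseline / 100.0
    base = EffectScenario(baseline_beta0=baseline, family=family, effect_pct=effect_pct)
    if family == "null":
        return base
    mains = dict(beta_i=delta, beta_f=delta, beta_m=delta)
    if family == "main_only":
        return replace(base, **mains)
    if family == "superadditive":
        inter = (
            dict(beta_fm=delta, beta_im=delta, beta_if=delta)
            if all_pairs
            else dict(beta_fm=delta)
        )
        return replace(base, **mains, **inter)
    # compensatory: singles gain delta, every multi-biocide cell equals b0
    return replace(
        base,
        **mains,
        beta_fm=-2.0 * delta,
        beta_im=-2.0 * delta,
        beta_if=-2.0 * delta,
        beta_ifm=3.0 * delta,
    )


def expected_mean(scenario: EffectScenario, combo: TreatmentCombo) -> float:
    """Noise-free expected biomass (g) of one treatment cell."""
    i, f, m = combo.as_tuple()
    return float(
        scenario.baseline_beta0
        + scenario.beta_i * i
        + scenario.beta_f * f
        + scenario.beta_m * m
        + scenario.beta_fm * f * m
        + scenario.beta_im * i * m
        + scenario.beta_if * i * f
        + scenario.beta_ifm * i * f * m
    )


def expected_means(scenario: EffectScenario, table: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`expected_mean` over the rows of a plot table."""
    i = table["insecticide"].to_numpy(dtype=float)
    f = table["fungicide"].to_numpy(dtype=float)
    m = table["molluscicide"].to_numpy(dtype=float)
    return (
        scenario.baseline_beta0
        + scenario.beta_i * i
        + scenario.beta_f * f
        + scenario.beta_m * m
        + scenario.beta_fm * f * m
        + scenario.beta_im * i * m
        + scenario.beta_if * i * f
        + scenario.beta_ifm * i * f * m
    )


def simulate_experiment(
    design: pd.DataFrame,
    scenario: EffectScenario,
    vc: VarianceComponents,
    seed: int | np.random.SeedSequence | Sequence[int] = 0,
) -> pd.DataFrame:
    """Simulate one biomass realization of the experiment.

    Draws one Gaussian offset per site, one per (site, block) shared by all
    plots of that block, and one per plot (the observation-level noise), adds
    them to the fixed-effect cell means, and returns a copy of ``design``
    with a ``biomass_g`` column.  Seeded runs are bit-reproducible.
    """
    if not isinstance(vc, VarianceComponents):
        vc = VarianceComponents(*vc)
    rng = np.random.default_rng(seed)
    out = design.reset_index(drop=True).copy()
    mu = expected_means(scenario, out)

    site_codes, sites = pd.factorize(out["site_id"], sort=False)
    block_key = out["site_id"].astype(str) + "\x1f" + out["block_id"].astype(str)
    block_codes, blocks = pd.factorize(block_key, sort=False)

    site_eff = rng.normal(0.0, vc.sd_site, size=len(sites))
    block_eff = rng.normal(0.0, vc.sd_block, size=len(blocks))
    plot_eff = rng.normal(0.0, vc.sd_plot, size=len(out))

    out["biomass_g"] = mu + site_eff[site_codes] + block_eff[block_codes] + plot_eff
    return out


# ---------------------------------------------------------------------------
# Community generator


@dataclass(frozen=True)
class CommunityScenario:
    """Parameters of the synthetic multi-species cover generator.

    Species covers are drawn log-normally around species-specific baseline
    abundances from a site pool; a fraction of the most abundant (dominant)
    species is suppressed multiplicatively wherever its consumers are present
    (i.e., on plots where the matching biocide is NOT applied), which is how
    consumer pressure on dominants translates into evenness differences
    between control and exclusion plots.
    """

    n_species: int = 24
    pool_overlap: float = 0.6  # fraction of the global pool shared by every site
    lognormal_mu: float = 1.5  # log-scale mean of baseline percent cover
    lognormal_sigma: float = 1.0  # log-scale SD of baseline cover across species
    dominant_fraction: float = 0.2  # top share of species counted as dominant
    dominant_multiplier: float = 1.0  # cover factor for dominants under consumers
    subordinate_multiplier: float = 1.0  # cover factor for the rest under consumers
    species_site_sd: float = 0.4  # log-scale SD of per-site species abundances
    target_treatment: str = "insecticide"  # biocide whose absence applies multipliers
    n_years: int = 1
    obs_noise_sd: float = 0.3  # log-scale observation noise per plot/year
    year_trend: float = 0.0  # multiplicative cover trend per year since start
    start_year: int = 2021

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.pool_overlap <= 1.0:
            raise ValueError("pool_overlap must be in [0, 1]")
        if self.target_treatment not in TREATMENT_COLUMNS:
            raise ValueError(f"target_treatment must be one of {TREATMENT_COLUMNS}")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


def _round_cover(x: np.ndarray) -> np.ndarray:
    # field convention: covers are reported to 0.1% at minimum
    return np.maximum(np.round(x, 1), 0.1)


def simulate_community(
    design: pd.DataFrame,
    cs: CommunityScenario,
    seed: int | np.random.SeedSequence | Sequence[int] = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format cover table and a derived biomass table.

    Returns ``(cover, biomass)``.  ``cover`` has one row per
    (site, block, plot, year, species) with percent cover; ``biomass`` has
    one row per (site, block, plot, year) with ``biomass_g`` proportional to
    summed cover.  Covers are independent across years apart from a common
    multiplicative trend.
    """
    rng = np.random.default_rng(seed)
    species_pool = np.array([f"sp{j + 1:03d}" for j in range(cs.n_species)])
    n_shared = int(round(cs.pool_overlap * cs.n_species))
    shared = species_pool[:n_shared]
    rest = species_pool[n_shared:]

    # species baseline covers, shared across sites so pools are comparable
    base_cover = np.exp(rng.normal(cs.lognormal_mu, cs.lognormal_sigma, cs.n_species))
    dominance_rank = np.argsort(-base_cover)
    n_dom = max(1, int(round(cs.dominant_fraction * cs.n_species)))
    is_dominant = np.zeros(cs.n_species, dtype=bool)
    is_dominant[dominance_rank[:n_dom]] = True
    cover_of = dict(zip(species_pool, base_cover))
    dom_of = dict(zip(species_pool, is_dominant))

    sites = design["site_id"].unique()
    site_pool: dict[str, np.ndarray] = {}
    site_cover: dict[str, dict[str, float]] = {}
    for s in sites:
        n_extra = min(len(rest), max(0, cs.n_species - n_shared) // 2)
        extra = rng.choice(rest, size=n_extra, replace=False) if n_extra else rest[:0]
        pool = np.concatenate([shared, extra])
        site_pool[s] = pool
        # sites share the species pool but differ in relative abundances
        dev = np.exp(rng.normal(0.0, cs.species_site_sd, size=len(pool)))
        site_cover[s] = {sp: cover_of[sp] * d for sp, d in zip(pool, dev)}

    cover_rows = []
    biomass_rows = []
    for year in range(cs.n_years):
        trend = (1.0 + cs.year_trend) ** year
        for row in design.itertuples(index=False):
            present = getattr(row, cs.target_treatment) == 0  # consumers active
            noise = np.exp(rng.normal(0.0, cs.obs_noise_sd, size=len(site_pool[row.site_id])))
            total = 0.0
            for sp, eps in zip(site_pool[row.site_id], noise):
                mult = 1.0
                if present:
                    mult = cs.dominant_multiplier if dom_of[sp] else cs.subordinate_multiplier
                cov = site_cover[row.site_id][sp] * mult * trend * eps
                cov = float(_round_cover(np.array([cov]))[0])
                total += cov
                cover_rows.append(
                    (
                        row.site_id,
                        row.block_id,
                        row.plot_id,
                        row.insecticide,
                        row.fungicide,
                        row.molluscicide,
                        year,
                        cs.start_year + year,
                        sp,
                        cov,
                    )
                )
            biomass_rows.append(
                (
                    row.site_id,
                    row.block_id,
                    row.plot_id,
                    row.insecticide,
                    row.fungicide,
                    row.molluscicide,
                    year,
                    cs.start_year + year,
                    round(2.0 * total, 2),  # ~2 g biomass per % summed cover
                )
            )
    key_cols = ["site_id", "block_id", "plot_id", *TREATMENT_COLUMNS]
    cover = pd.DataFrame(
        cover_rows,
        columns=[*key_cols, "year_since_start", "calendar_year", "species", "cover_pct"],
    )
    biomass = pd.DataFrame(
        biomass_rows,
        columns=[*key_cols, "year_since_start", "calendar_year", "biomass_g"],
    )
    return cover, biomass
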