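"""Monte-Carlo power analysis for the factorial exclusion design.

For each replicate a fresh biomass dataset is simulated from the
hierarchical generating model (all site, block and plot draws are redrawn
every replicate, using counter-based child seeds of the master seed), the
full factorial mixed model is fitted by maximum likelihood, and the tested
term is assessed with a log-likelihood-ratio test against the model with
that term removed.  Power is the fraction of replicates with p below alpha,
reported with an exact (Clopper-Pearson) binomial confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, TERM_ORDER, build_design
from .lmm import ModelSpec, fit_lmm, lrt_test
from .simulate import (
    EffectScenario,
    PAPER_VC,
    VarianceComponents,
    scenario_from_preset,
    simulate_experiment,
)

__all__ = [
    "PowerResult",
    "estimate_power",
    "clopper_pearson",
    "power_table",
    "PAPER_POWER_PRESETS",
]

logger = logging.getLogger(__name__)

#: The 15 scenario presets of the replication power table: three effect
#: families at effect sizes 20, 15, 10, 7.5 and 5 percent of baseline.
PAPER_POWER_PRESETS: tuple[tuple[str, float], ...] = tuple(
    (family, pct)
    for family in ("main_only", "superadditive", "compensatory")
    for pct in (20.0, 15.0, 10.0, 7.5, 5.0)
)


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo rejection count for one scenario/term combination."""

    family: str
    effect_pct: float
    term: str
    n_sim: int
    n_reject: int
    power_pct: float
    ci_lo_pct: float
    ci_hi_pct: float
    n_retried: int = 0
    n_failed: int = 0

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "effect_pct": self.effect_pct,
            "term": self.term,
            "n_sim": self.n_sim,
            "n_reject": self.n_reject,
            "power_pct": self.power_pct,
            "ci_lo_pct": self.ci_lo_pct,
            "ci_hi_pct": self.ci_hi_pct,
        }


def clopper_pearson(n_reject: int, n_sim: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion.

    Returns ``(lo, hi)`` on the proportion scale, from the beta-quantile
    form: ``lo = BetaInv(alpha/2; x, n-x+1)``, ``hi = BetaInv(1-alpha/2;
    x+1, n-x)``, with ``lo = 0`` at ``x = 0`` and ``hi = 1`` at ``x = n``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if n_sim < 1 or not 0 <= n_reject <= n_sim:
        raise ValueError(f"need 0 <= n_reject <= n_sim with n_sim >= 1, got {n_reject}/{n_sim}")
    alpha = 1.0 - level
    lo = 0.0 if n_reject == 0 else float(stats.beta.ppf(alpha / 2, n_reject, n_sim - n_reject + 1))
    hi = 1.0 if n_reject == n_sim else float(
        stats.beta.ppf(1 - alpha / 2, n_reject + 1, n_sim - n_reject)
    )
    return lo, hi


_FULL_MODEL = ModelSpec(response="biomass_g", fixed_terms=TERM_ORDER,
                        random_intercepts=("site", "block"), coding="indicator")


def estimate_power(
    scenario: EffectScenario,
    vc: VarianceComponents = PAPER_VC,
    design: DesignSpec | None = None,
    term: str = "i",
    n_sim: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power to detect ``term`` at significance ``alpha``.

    Each replicate simulates a new dataset under ``scenario``/``vc`` on the
    ``design`` layout (default: 35 sites x 3 blocks x 8 treatments), fits
    the full i*f*m factorial mixed model with site and block-within-site
    random intercepts by ML, and applies a likelihood-ratio test of the
    model without ``term``.  A replicate whose fit fails to converge is
    retried once with a fresh draw, then counted as a non-rejection.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if term not in TERM_ORDER:
        raise ValueError(f"term must be one of {TERM_ORDER}, got {term!r}")
    if design is None:
        design = DesignSpec(n_sites=35, n_blocks_per_site=3, rng_seed=seed)
    layout = build_design(design)
    full_spec = _FULL_MODEL
    red_spec = full_spec.drop_term(term)

    n_reject = 0
    n_retried = 0
    n_failed = 0
    for r in range(n_sim):
        p = None
        for attempt in range(2):
            sim = simulate_experiment(
                layout, scenario, vc,
                seed=np.random.SeedSequence(entropy=seed, spawn_key=(r, attempt)),
            )
            try:
                full = fit_lmm(sim, full_spec, criterion="ml")
                red = fit_lmm(sim, red_spec, criterion="ml")
                if not (full.converged and red.converged):
                    raise RuntimeError("fit did not converge")
                p = lrt_test(full, red).pvalue
                break
            except Exception as exc:  # noqa: BLE001 - replicate-level recovery
                if attempt == 0:
                    n_retried += 1
                    logger.warning("replicate %d failed (%s); retrying with a new draw", r, exc)
                else:
                    n_failed += 1
                    logger.warning("replicate %d failed twice; counted as non-rejection", r)
        if p is not None and p < alpha:
            n_reject += 1
    lo, hi = clopper_pearson(n_reject, n_sim)
    return PowerResult(
        family=scenario.family,
        effect_pct=scenario.effect_pct,
        term=term,
        n_sim=n_sim,
        n_reject=n_reject,
        power_pct=100.0 * n_reject / n_sim,
        ci_lo_pct=100.0 * lo,
        ci_hi_pct=100.0 * hi,
        n_retried=n_retried,
        n_failed=n_failed,
    )


def default_term_for(family: str) -> str:
    """Tested term per effect family: the insecticide main effect for
    main-effect scenarios, the fungicide:molluscicide interaction for the
    interaction families."""
    return "i" if family in ("null", "main_only") else "f:m"


def power_table(
    presets: Sequence[tuple[str, float]] = PAPER_POWER_PRESETS,
    *,
    design: DesignSpec | None = None,
    vc: VarianceComponents = PAPER_VC,
    baseline: float = 100.0,
    n_sim: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`estimate_power` for a list of (family, effect_pct) presets.

    Returns one row per preset with the power estimate and its exact 95%
    confidence interval, on the percent scale.
    """
    rows = []
    for idx, (family, pct) in enumerate(presets):
        scenario = scenario_from_preset(family, pct, baseline)
        res = estimate_power(
            scenario,
            vc=vc,
            design=design,
            term=default_term_for(family),
            n_sim=n_sim,
            alpha=alpha,
            seed=seed + idx,
        )
        rows.append(res.as_dict())
    return pd.DataFrame(rows, columns=[
        "family", "effect_pct", "term", "n_sim", "n_reject",
        "power_pct", "ci_lo_pct", "ci_hi_pct",
    ])
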