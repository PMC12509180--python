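"""Fitting and testing contract for the linear and linear mixed models.

All downstream stages (power analysis, permutation calibration, the analysis
pipeline) talk to the same three operations:

* :func:`fit_lmm` - fit a fixed-effects or mixed model described by a
  :class:`ModelSpec` and return a :class:`FitResult`;
* :func:`lrt_test` - log-likelihood-ratio test between two nested fits made
  under the unrestricted (ML) criterion;
* :func:`wald_summary` - two-sided per-term p-values from estimate/SE
  against the standard normal reference.

Two fitting back ends stand behind the contract.  For the canonical layout
of the exclusion experiment - one observation per plot, complete balanced
blocks, random intercepts for site and block-within-site, fixed effects
whose non-intercept columns are within-block contrasts - generalized least
squares coincides with ordinary least squares and the (RE)ML variance
components have closed forms from the orthogonal site / block / within-block
strata of the covariance matrix.  ``fit_lmm`` detects this case numerically
and solves it exactly, which makes the Monte-Carlo loops (hundreds to tens
of thousands of refits) cheap.  Every other model is delegated to
statsmodels ``MixedLM`` (or OLS when no random intercepts are requested).
The two routes are interchangeable and are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import TERM_ORDER, TREATMENT_COLUMNS

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "fit_lmm",
    "lrt_test",
    "wald_summary",
    "CollinearityError",
]

_LETTER_TO_COLUMN = {"i": "insecticide", "f": "fungicide", "m": "molluscicide"}


class CollinearityError(ValueError):
    """Raised when the fixed-effect design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a (mixed) linear model.

    Parameters
    ----------
    response
        Name of the response column.
    fixed_terms
        Ordered fixed-effect term labels, intercept implied.  A label is a
        factorial treatment term (``i``, ``f``, ``m``, ``f:m``, ``i:m``,
        ``i:f``, ``i:f:m``), a data column (numeric entered as-is,
        categorical expanded to treatment-contrast dummies), or a ``:``
        product of such components (e.g. ``year_since_start:i``).
    random_intercepts
        Grouping labels in nesting order, drawn from ``site``, ``block``,
        ``plot`` and ``calendar_year:site``.  Empty means ordinary least
        squares.
    coding
        ``indicator`` (0/1) or ``effect`` (-1/+1) coding of treatment flags.
    transform
        ``identity`` or ``log``; ``offset`` grams are added before a log.
    """

    response: str
    fixed_terms: tuple[str, ...] = TERM_ORDER
    random_intercepts: tuple[str, ...] = ("site", "block")
    coding: str = "indicator"
    transform: str = "identity"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.coding not in ("indicator", "effect"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        known = {"site", "block", "plot", "calendar_year:site"}
        unknown = set(self.random_intercepts) - known
        if unknown:
            raise ValueError(f"unknown random intercept labels: {sorted(unknown)}")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_intercepts", tuple(self.random_intercepts))

    def drop_term(self, term: str) -> "ModelSpec":
        """Spec with one fixed term removed (for LRT reduced models)."""
        if term not in self.fixed_terms:
            raise ValueError(f"term {term!r} not in model")
        return ModelSpec(
            response=self.response,
            fixed_terms=tuple(t for t in self.fixed_terms if t != term),
            random_intercepts=self.random_intercepts,
            coding=self.coding,
            transform=self.transform,
            offset=self.offset,
        )


@dataclass
class FitResult:
    """Estimates, tests and variance components of one fitted model."""

    terms: tuple[str, ...]  # column labels incl. "(Intercept)"
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    vcomp: dict  # variance components (variances, incl. "residual")
    llf: float  # log-likelihood under `criterion`
    criterion: str  # "ml" or "reml"
    converged: bool
    singular: bool
    n_obs: int
    df_fixed: int  # number of fixed-effect columns incl. intercept
    method: str  # "balanced-exact" | "mixedlm" | "ols"
    spec: ModelSpec
    llf_ml: float | None = None
    llf_reml: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        """Tidy per-term table (term, estimate, se, stat, p)."""
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "stat": self.zvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


@dataclass(frozen=True)
class LRTResult:
    """Log-likelihood-ratio test between two nested ML fits."""

    statistic: float
    df: int
    pvalue: float


# ---------------------------------------------------------------------------
# design-matrix construction


def _resolve_component(df: pd.DataFrame, comp: str, coding: str) -> dict[str, np.ndarray]:
    """Columns for a single (non-product) term component."""
    if comp in _LETTER_TO_COLUMN:
        comp_col = _LETTER_TO_COLUMN[comp]
        raw = df[comp_col].to_numpy(dtype=float)
        return {comp: 2.0 * raw - 1.0 if coding == "effect" else raw}
    if comp in df.columns:
        col = df[comp]
        if pd.api.types.is_numeric_dtype(col):
            return {comp: col.to_numpy(dtype=float)}
        levels = pd.unique(col.astype(str))
        levels_sorted = sorted(levels)
        out = {}
        for lev in levels_sorted[1:]:  # first level is the reference
            out[f"{comp}[{lev}]"] = (col.astype(str) == lev).to_numpy(dtype=float)
        return out
    raise KeyError(f"term component {comp!r} is neither a treatment code nor a column")


def build_fixed_matrix(
    df: pd.DataFrame, fixed_terms: Sequence[str], coding: str
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build the fixed-effect matrix (intercept first).

    Returns ``(X, column_labels, term_to_columns)`` where ``term_to_columns``
    maps each requested term label to the indices of its columns in ``X``.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels: list[str] = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {}
    for term in fixed_terms:
        parts = term.split(":") if term not in TERM_ORDER else [term]
        if term in TERM_ORDER and len(term) > 1:
            parts = term.split(":")  # factorial interaction: product of flags
        expanded: dict[str, np.ndarray] = {}
        for part in parts:
            comp_cols = _resolve_component(df, part, coding)
            if not expanded:
                expanded = comp_cols
            else:
                expanded = {
                    f"{n1}:{n2}": v1 * v2
                    for n1, v1 in expanded.items()
                    for n2, v2 in comp_cols.items()
                }
        idx = []
        for name, values in expanded.items():
            idx.append(len(cols))
            cols.append(values)
            labels.append(name)
        term_cols[term] = idx
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending terms by incremental rank
        bad = []
        r_prev, used = 1, [0]
        for term, idx in term_cols.items():
            r_new = np.linalg.matrix_rank(X[:, used + idx])
            if r_new < r_prev + len(idx):
                bad.append(term)
            used += idx
            r_prev = r_new
        raise CollinearityError(f"fixed-effect matrix is rank deficient; terms involved: {bad}")
    return X, labels, term_cols


def _group_labels(df: pd.DataFrame, label: str) -> pd.Series:
    if label == "site":
        return df["site_id"].astype(str)
    if label == "block":
        return df["site_id"].astype(str) + ":" + df["block_id"].astype(str)
    if label == "plot":
        return (
            df["site_id"].astype(str)
            + ":"
            + df["block_id"].astype(str)
            + ":"
            + df["plot_id"].astype(str)
        )
    if label == "calendar_year:site":
        return df["site_id"].astype(str) + ":" + df["calendar_year"].astype(str)
    raise ValueError(label)


def _response_vector(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    y = df[spec.response].to_numpy(dtype=float) + spec.offset
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError(
                "log transform requires strictly positive response values; "
                "supply a positive `offset` in the ModelSpec or use the "
                "identity transform"
            )
        y = np.log(y)
    return y


# ---------------------------------------------------------------------------
# exact solver for the balanced nested site/block layout


def _balanced_structure(df: pd.DataFrame, spec: ModelSpec):
    """Return (site_codes, block_codes, s, b, k) if the fast path applies."""
    if set(spec.random_intercepts) != {"site", "block"}:
        return None
    needed = {"site_id", "block_id", "plot_id"}
    if not needed.issubset(df.columns):
        return None
    block_lbl = _group_labels(df, "block")
    site_lbl = _group_labels(df, "site")
    block_codes, blocks = pd.factorize(block_lbl, sort=False)
    site_codes, sites = pd.factorize(site_lbl, sort=False)
    s = len(sites)
    if s < 3:
        return None
    sizes = np.bincount(block_codes)
    if sizes.min() != sizes.max() or sizes.min() < 2:
        return None
    k = int(sizes[0])
    # blocks per site must be constant and >= 2
    site_of_block = np.zeros(len(blocks), dtype=int)
    site_of_block[block_codes] = site_codes
    bl_per_site = np.bincount(site_of_block, minlength=s)
    if bl_per_site.min() != bl_per_site.max() or bl_per_site.min() < 2:
        return None
    b = int(bl_per_site[0])
    return site_codes, block_codes, s, b, k


def _fit_balanced(
    y: np.ndarray,
    X: np.ndarray,
    labels: list[str],
    struct,
    criterion: str,
    spec: ModelSpec,
) -> FitResult | None:
    site_codes, block_codes, s, b, k = struct
    n, p = X.shape
    nb = s * b

    # block/site means of y and X
    by = np.bincount(block_codes, weights=y, minlength=nb) / k
    site_of_block = np.zeros(nb, dtype=int)
    site_of_block[block_codes] = site_codes
    sy = np.bincount(site_codes, weights=y, minlength=s) / (b * k)
    gy = y.mean()

    Xb = np.empty((nb, p))
    for j in range(p):
        Xb[:, j] = np.bincount(block_codes, weights=X[:, j], minlength=nb) / k
    # fast path requires every non-intercept column to have a constant block
    # mean (within-block contrast plus constant), else GLS != OLS
    if p > 1:
        spread = Xb[:, 1:].max(axis=0) - Xb[:, 1:].min(axis=0)
        scale = np.maximum(np.abs(X[:, 1:]).max(axis=0), 1.0)
        if np.any(spread > 1e-10 * scale):
            return None

    # within-block projections
    yw = y - by[block_codes]
    Xw = X - Xb[block_codes, :]  # intercept column becomes 0
    Xw = Xw[:, 1:]
    cbar = Xb[0, 1:] if p > 1 else np.empty(0)

    if p > 1:
        XtX = Xw.T @ Xw
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            raise CollinearityError(
                f"within-block design is singular for terms {labels[1:]}"
            ) from None
        beta_w = XtX_inv @ (Xw.T @ yw)
        resid_w = yw - Xw @ beta_w
    else:
        XtX_inv = np.empty((0, 0))
        beta_w = np.empty(0)
        resid_w = yw
    ss_w = float(resid_w @ resid_w)
    ss_b = float(k * np.sum((by - sy[site_of_block]) ** 2))
    ss_s = float(b * k * np.sum((sy - gy) ** 2))

    d_w_full = nb * (k - 1)
    if criterion == "ml":
        dims_log = np.array([s, s * (b - 1), d_w_full], dtype=float)
        dims_div = np.array([s, s * (b - 1), d_w_full], dtype=float)
    else:
        dims_log = np.array([s - 1.0, s * (b - 1), d_w_full - (p - 1)])
        dims_div = dims_log.copy()
    ss = np.array([ss_s, ss_b, ss_w])

    # (RE)ML eigenvalue estimates with non-negativity of the variance
    # components enforced by pooling adjacent strata at the boundary
    def crit(lam: np.ndarray) -> float:
        return float(np.sum(dims_log * np.log(lam) + ss / lam))

    candidates = []
    lam_free = ss / dims_div
    patterns = [
        ((0,), (1,), (2,)),  # interior
        ((0,), (1, 2)),  # sigma_block = 0
        ((0, 1), (2,)),  # sigma_site = 0
        ((0, 1, 2),),  # both at boundary
    ]
    for pat in patterns:
        lam = np.empty(3)
        ok = True
        for group in pat:
            g = list(group)
            lam_g = ss[g].sum() / dims_div[g].sum()
            if lam_g <= 0:
                ok = False
                break
            lam[g] = lam_g
        if not ok:
            continue
        if lam[0] >= lam[1] - 1e-12 * lam[1] and lam[1] >= lam[2] - 1e-12 * lam[2]:
            candidates.append((crit(lam), pat, lam))
    if not candidates:  # degenerate (e.g. zero residual); clamp tiny floor
        lam = np.maximum(lam_free, 1e-300)
        lam = np.maximum.accumulate(lam[::-1])[::-1]
        candidates.append((crit(lam), ((0,), (1,), (2,)), lam))
    _, pattern, lam = min(candidates, key=lambda t: t[0])
    lam_s, lam_b, lam_w = lam
    sigma2 = lam_w
    sigma2_b = max((lam_b - lam_w) / k, 0.0)
    sigma2_s = max((lam_s - lam_b) / (b * k), 0.0)
    singular = len(pattern) < 3

    # log-likelihood value (REML convention matches lme4's logLik)
    quad = ss_s / lam_s + ss_b / lam_b + ss_w / lam_w
    if criterion == "ml":
        logdet = s * np.log(lam_s) + s * (b - 1) * np.log(lam_b) + d_w_full * np.log(lam_w)
        llf = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    else:
        logdet = (
            (s - 1) * np.log(lam_s)
            + s * (b - 1) * np.log(lam_b)
            + (d_w_full - (p - 1)) * np.log(lam_w)
        )
        sign, logdet_xtx = (1.0, 0.0) if p == 1 else np.linalg.slogdet(XtX)
        llf = -0.5 * (
            (n - p) * np.log(2 * np.pi) + logdet + quad + np.log(n) + logdet_xtx
        )

    # fixed effects (GLS = OLS under balance) and their covariance
    beta0 = gy - float(cbar @ beta_w) if p > 1 else gy
    params = np.concatenate([[beta0], beta_w])
    cov = np.zeros((p, p))
    if p > 1:
        Cw = lam_w * XtX_inv
        cov[1:, 1:] = Cw
        cov[0, 0] = lam_s / n + float(cbar @ Cw @ cbar)
        cov[0, 1:] = -(Cw @ cbar)
        cov[1:, 0] = cov[0, 1:]
    else:
        cov[0, 0] = lam_s / n

    return _assemble_result(
        labels,
        params,
        np.sqrt(np.diag(cov)),
        {"site": sigma2_s, "block": sigma2_b, "residual": sigma2},
        llf,
        criterion,
        converged=True,
        singular=singular,
        n_obs=n,
        method="balanced-exact",
        spec=spec,
    )


# ---------------------------------------------------------------------------
# statsmodels back ends


def _fit_mixedlm(
    df: pd.DataFrame,
    y: np.ndarray,
    X: np.ndarray,
    labels: list[str],
    spec: ModelSpec,
    criterion: str,
) -> FitResult:
    import statsmodels.api as sm

    work = pd.DataFrame({f"x{j}": X[:, j + 1] for j in range(X.shape[1] - 1)})
    work["y"] = y
    res = [r for r in spec.random_intercepts]
    if "site" in res:
        groups = _group_labels(df, "site").to_numpy()
        vc_terms = [r for r in res if r != "site"]
        re_formula = "1"
    else:
        groups = _group_labels(df, res[0]).to_numpy()
        vc_terms = res[1:]
        re_formula = "1"
    work["_groups"] = groups
    vc_formula = {}
    vc_names = {}  # formula-safe name -> original label
    for r in vc_terms:
        safe = r.replace(":", "_")
        col = "_vc_" + safe
        work[col] = _group_labels(df, r).to_numpy()
        vc_formula[safe] = f"0 + C({col})"
        vc_names[safe] = r
    rhs = " + ".join([f"x{j}" for j in range(X.shape[1] - 1)]) or "1"
    model = sm.MixedLM.from_formula(
        f"y ~ {rhs}",
        groups="_groups",
        re_formula=re_formula,
        vc_formula=vc_formula or None,
        data=work,
    )
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    # optimizer/boundary chatter is reported through the converged/singular
    # flags of the FitResult instead of loose warnings
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", UserWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(reml=(criterion == "reml"), method=["lbfgs", "bfgs"])
        fe = np.asarray(fit.fe_params)
        bse = np.asarray(fit.bse_fe)
    vcomp: dict[str, float] = {}
    grp_label = "site" if "site" in res else res[0]
    vcomp[grp_label] = float(np.asarray(fit.cov_re)[0, 0])
    if vc_formula:
        ordered = list(getattr(fit.model.exog_vc, "names", vc_formula.keys()))
        for name, v in zip(ordered, np.atleast_1d(fit.vcomp)):
            vcomp[vc_names.get(name, name)] = float(v)
    vcomp["residual"] = float(fit.scale)
    singular = any(v < 1e-8 * vcomp["residual"] for v in vcomp.values())
    return _assemble_result(
        labels,
        fe,
        bse,
        vcomp,
        float(fit.llf),
        criterion,
        converged=bool(fit.converged),
        singular=singular,
        n_obs=len(y),
        method="mixedlm",
        spec=spec,
    )


def _fit_ols(
    y: np.ndarray, X: np.ndarray, labels: list[str], spec: ModelSpec, criterion: str
) -> FitResult:
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if criterion == "ml":
        sigma2 = rss / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) if sigma2 > 0 else np.inf
    else:
        dof = max(n - p, 1)
        sigma2 = rss / dof
        if sigma2 > 0:
            sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
            llf = -0.5 * (
                (n - p) * (np.log(2 * np.pi) + np.log(sigma2))
                + rss / sigma2
                + logdet_xtx
            )
        else:
            llf = np.inf
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return _assemble_result(
        labels,
        beta,
        np.sqrt(np.diag(cov)),
        {"residual": sigma2},
        llf,
        criterion,
        converged=True,
        singular=sigma2 == 0.0,
        n_obs=n,
        method="ols",
        spec=spec,
    )


def _assemble_result(
    labels, params, bse, vcomp, llf, criterion, *, converged, singular, n_obs, method, spec
) -> FitResult:
    params = pd.Series(np.asarray(params, dtype=float), index=labels)
    bse = pd.Series(np.asarray(bse, dtype=float), index=labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    z = z.where(bse > 0, np.where(params == 0, 0.0, np.inf * np.sign(params)))
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=labels)
    pvals = pvals.where(bse > 0, np.where(params == 0, 1.0, 0.0))
    return FitResult(
        terms=tuple(labels),
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=pvals,
        vcomp={k: float(v) for k, v in vcomp.items()},
        llf=float(llf),
        criterion=criterion,
        converged=converged,
        singular=singular,
        n_obs=n_obs,
        df_fixed=len(labels),
        method=method,
        spec=spec,
        llf_ml=float(llf) if criterion == "ml" else None,
        llf_reml=float(llf) if criterion == "reml" else None,
    )


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, criterion: str = "reml") -> FitResult:
    """Fit the model described by ``spec`` to ``data``.

    ``criterion`` is ``"reml"`` (restricted, the default for reporting) or
    ``"ml"`` (unrestricted, required for likelihood-ratio comparisons).
    On a balanced design with indicator coding the fixed-effect estimates
    equal the corresponding cell-mean contrasts.
    """
    if criterion not in ("ml", "reml"):
        raise ValueError(f"criterion must be 'ml' or 'reml', got {criterion!r}")
    if len(data) == 0:
        raise ValueError("empty data")
    y = _response_vector(data, spec)
    X, labels, _ = build_fixed_matrix(data, spec.fixed_terms, spec.coding)
    if not spec.random_intercepts:
        return _fit_ols(y, X, labels, spec, criterion)
    struct = _balanced_structure(data, spec)
    if struct is not None:
        result = _fit_balanced(y, X, labels, struct, criterion, spec)
        if result is not None:
            return result
    return _fit_mixedlm(data, y, X, labels, spec, criterion)


def lrt_test(full: FitResult, reduced: FitResult) -> LRTResult:
    """Chi-squared log-likelihood-ratio test of nested ML fits.

    The statistic is ``2 * (llf_full - llf_reduced)`` clamped at zero and
    referred to a chi-squared distribution with degrees of freedom equal to
    the difference in fixed-effect column counts.
    """
    if full.criterion != "ml" or reduced.criterion != "ml":
        raise ValueError("lrt_test requires both fits under the unrestricted (ml) criterion")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits use different data (n_obs differs)")
    if not set(reduced.spec.fixed_terms).issubset(full.spec.fixed_terms):
        raise ValueError("models are not nested (reduced terms not a subset of full terms)")
    df = full.df_fixed - reduced.df_fixed
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    if df == 0:
        return LRTResult(statistic=stat, df=0, pvalue=1.0)
    return LRTResult(statistic=stat, df=df, pvalue=float(stats.chi2.sf(stat, df)))


def wald_summary(fit: FitResult) -> pd.Series:
    """Two-sided per-term p-values (estimate/SE vs the standard normal)."""
    if not fit.converged:
        raise ValueError("wald_summary requires a converged fit")
    return fit.pvalues.copy()
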