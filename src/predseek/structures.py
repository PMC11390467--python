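"""Exhaustive sign-assigned interaction-structure search with Conformity Rate.

Each candidate impact function is a nonempty signed subset of the six
structural factors of its equation, giving 3^6 - 1 = 728 candidates per
equation (each of the six factors is absent, positive, or negative, minus
the empty choice).  Every candidate is fit by dynamic regression — growing
prefix windows from half the series to the full cycle — across an ensemble
of regions, each fit is scored by the three-part test battery, and the
candidate is ranked by its Conformity Rate

    CR = Np / Ntotal,

the fraction of attempted dynamic regressions that pass all three tests.
Ties are broken by mean R², then parsimony (fewer factors), then the
canonical structure id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import scipy.linalg

from .containers import CumulativePair
from .dynamics import CONSULT_FACTORS, SEARCH_FACTORS, _FACTOR_FUNCS
from .regression import InsufficientDataError, decide_tests

__all__ = [
    "EQUATIONS",
    "StructureSpec",
    "ConformityResult",
    "PatternConfig",
    "equation_factors",
    "enumerate_structures",
    "build_candidate_design",
    "dynamic_windows",
    "conformity_rate",
    "pattern_detect",
    "select_structure",
    "structure_from_coefficients",
]

EQUATIONS = ("search", "consult")

#: baseline logistic regressors always included, with their required signs
_BASELINE_SIGNS = (1.0, -1.0)


def equation_factors(equation: str) -> tuple[str, ...]:
    if equation == "search":
        return SEARCH_FACTORS
    if equation == "consult":
        return CONSULT_FACTORS
    raise ValueError(f"unknown equation {equation!r}; use 'search' or 'consult'")


@dataclass(frozen=True)
class StructureSpec:
    """A signed subset of one equation's six structural factors.

    The empty subset is allowed as an explicit representation of the
    baseline (interaction-free) logistic equation; the enumeration of
    candidate interaction structures starts at one factor.
    """

    equation: str
    factors: tuple[str, ...] = ()
    signs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        table = equation_factors(self.equation)
        if len(self.factors) > 6:
            raise ValueError("a structure includes at most 6 factors")
        if len(self.signs) != len(self.factors):
            raise ValueError("one sign per included factor")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")
        idx = [table.index(f) for f in self.factors]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise ValueError("factors must be distinct and in canonical order")

    @property
    def factor_indices(self) -> tuple[int, ...]:
        table = equation_factors(self.equation)
        return tuple(table.index(f) for f in self.factors)

    @property
    def id(self) -> str:
        return "".join(
            ("+" if s > 0 else "-") + f for f, s in zip(self.factors, self.signs)
        )

    def coefficient_vector(self, values) -> np.ndarray:
        """Scatter per-factor values into a full length-6 coefficient vector."""
        out = np.zeros(6)
        for i, v in zip(self.factor_indices, values):
            out[i] = v
        return out


@dataclass
class ConformityResult:
    """Ensemble-level score of one candidate structure."""

    structure: StructureSpec
    n_pass: int
    n_total: int
    cr: float
    mean_r2: float

    @property
    def rank_key(self):
        cr = self.cr if np.isfinite(self.cr) else -1.0
        mr2 = self.mean_r2 if np.isfinite(self.mean_r2) else -np.inf
        return (-cr, -mr2, len(self.structure.factors), self.structure.id)


@dataclass
class PatternConfig:
    """Thresholds and window rule for the pattern-detection experiment."""

    r2_min: float = 0.9
    alpha: float = 0.05
    start_fraction: float = 0.5
    stride: int = 1
    min_cr: float = 0.5
    cr_pooling: str = "pooled"  # or "per-region"

    def __post_init__(self) -> None:
        if not (0 < self.r2_min < 1) or not (0 < self.alpha < 1) or not (0 < self.min_cr < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if not (0 < self.start_fraction <= 1):
            raise ValueError("start_fraction must lie in (0, 1]")
        if self.stride < 1:
            raise ValueError("stride must be a positive integer")
        if self.cr_pooling not in ("pooled", "per-region"):
            raise ValueError("cr_pooling must be 'pooled' or 'per-region'")


def enumerate_structures(equation: str) -> list[StructureSpec]:
    """All 728 signed nonempty factor subsets, deterministically ordered.

    Order: subset size ascending, then lexicographic factor positions, then
    sign patterns with ``+`` before ``-`` per factor.
    """
    table = equation_factors(equation)
    out: list[StructureSpec] = []
    for k in range(1, 7):
        for subset in combinations(range(6), k):
            names = tuple(table[i] for i in subset)
            for signs in product((1, -1), repeat=k):
                out.append(StructureSpec(equation=equation, factors=names, signs=signs))
    return out


def build_candidate_design(
    pair: CumulativePair, structure: StructureSpec, window_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Design/response of a candidate equation on the prefix ``[1..window_len]``.

    Column order: the baseline logistic regressors (x, x²) of the target
    variable, then the structure's factors in canonical order, all evaluated
    at the lagged state.
    """
    if window_len > len(pair):
        raise ValueError("window_len exceeds the series length")
    if window_len < 2:
        raise InsufficientDataError("window must span at least 2 days")
    x1 = pair.x1[:window_len]
    x2 = pair.x2[:window_len]
    target = x1 if structure.equation == "search" else x2
    lag1, lag2 = x1[:-1], x2[:-1]
    tlag = target[:-1]
    cols = [tlag, tlag**2] + [_FACTOR_FUNCS[f](lag1, lag2) for f in structure.factors]
    # dof feasibility is enforced at fit time; the matrix itself only needs rows
    return np.column_stack(cols), np.diff(target)


def dynamic_windows(n: int, start_fraction: float = 0.5, stride: int = 1) -> list[int]:
    """Prefix-window lengths: from ceil(start_fraction·n) up to n, step ``stride``."""
    if n < 4:
        raise ValueError("need at least 4 days for dynamic regression")
    w0 = math.ceil(start_fraction * n)
    return list(range(w0, n + 1, stride))


def conformity_rate(n_pass: int, n_total: int) -> float:
    """Exact ratio Np / Ntotal; NaN when the structure was never attemptable."""
    if not (0 <= n_pass <= n_total):
        raise ValueError("need 0 <= n_pass <= n_total")
    if n_total == 0:
        return float("nan")
    return n_pass / n_total


@dataclass
class _RegionCache:
    """Prefix cross-products of the full 8-column candidate design.

    For one region and equation, ``gram[w]`` is X'X of the unit-normalised
    full design restricted to the first ``w`` rows (window length ``w+1``),
    allowing any candidate's normal equations on any window to be read off
    by sub-indexing instead of re-accumulated.
    """

    norms: np.ndarray
    gram: np.ndarray  # (m, 8, 8) prefix sums of outer products
    xty: np.ndarray  # (m, 8)
    yty: np.ndarray  # (m,)


def _region_cache(pair: CumulativePair, equation: str) -> _RegionCache:
    table = equation_factors(equation)
    lag1, lag2 = pair.x1[:-1], pair.x2[:-1]
    target = pair.x1 if equation == "search" else pair.x2
    tlag = target[:-1]
    y = np.diff(target)
    F = np.column_stack([tlag, tlag**2] + [_FACTOR_FUNCS[f](lag1, lag2) for f in table])
    norms = np.linalg.norm(F, axis=0)
    norms[norms == 0] = 1.0
    Fs = F / norms
    gram = np.cumsum(Fs[:, :, None] * Fs[:, None, :], axis=0)
    xty = np.cumsum(Fs * y[:, None], axis=0)
    yty = np.cumsum(y * y)
    return _RegionCache(norms=norms, gram=gram, xty=xty, yty=yty)


def _window_fit(cache: _RegionCache, cols: np.ndarray, rows: int):
    """Solve the normal equations on the first ``rows`` design rows.

    Returns ``(coefficients_scaled, p_values, r2)`` or None when the
    sub-Gram is not positive definite (collinear window).
    """
    ix = np.ix_(cols, cols)
    G = cache.gram[rows - 1][ix]
    c = cache.xty[rows - 1][cols]
    yy = cache.yty[rows - 1]
    k = len(cols)
    dof = rows - k
    try:
        chol = scipy.linalg.cho_factor(G, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        return None
    beta = scipy.linalg.cho_solve(chol, c, check_finite=False)
    rss = max(yy - float(beta @ c), 0.0)
    r2 = 1.0 - rss / yy if yy > 0 else np.nan
    inv_diag = np.diag(scipy.linalg.cho_solve(chol, np.eye(k), check_finite=False))
    se = np.sqrt(np.maximum(rss / dof * inv_diag, 0.0))
    from .regression import _pvalues_from_t

    p = _pvalues_from_t(beta, se, dof)
    return beta, p, r2


def _batched_window_stats(cache: _RegionCache, cols: np.ndarray, rows: np.ndarray):
    """Fit one structure on many windows of one region at once.

    Returns ``(beta, p, r2, attempted_ok)`` stacked over windows, or None if
    any window's sub-Gram is singular (the caller falls back to the scalar
    path so collinear windows can be counted as attempted-and-failed).
    """
    from scipy.special import stdtr

    k = len(cols)
    idx = rows - 1
    G = cache.gram[idx][:, cols][:, :, cols]
    c = cache.xty[idx][:, cols]
    yy = cache.yty[idx]
    try:
        beta = np.linalg.solve(G, c[:, :, None])[:, :, 0]
        inv_diag = np.diagonal(np.linalg.inv(G), axis1=1, axis2=2)
    except np.linalg.LinAlgError:
        return None
    rss = np.maximum(yy - np.einsum("wk,wk->w", beta, c), 0.0)
    dof = (rows - k).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(yy > 0, 1.0 - rss / yy, np.nan)
        se = np.sqrt(np.maximum((rss / dof)[:, None] * inv_diag, 0.0))
        p = 2.0 * stdtr(dof[:, None], -np.abs(beta / se))
    degenerate = se == 0
    p = np.where(degenerate, np.where(beta != 0, 0.0, 1.0), p)
    return beta, p, r2


def pattern_detect(
    ensemble: list[CumulativePair], equation: str, config: PatternConfig | None = None
) -> list[ConformityResult]:
    """Score every candidate structure over regions × prefix windows.

    For each structure, region and window the candidate equation is fit by
    no-intercept least squares and judged by the three-part battery with the
    baseline signs (+x, -x²) prepended to the structure's signs.  Windows
    whose residual dof would be < 1 are skipped (not counted in Ntotal);
    collinear windows count as attempted-and-failed.  Results are returned
    ranked (CR desc, mean R² desc, parsimony, id) and are deterministic for
    fixed inputs.
    """
    if not ensemble:
        raise ValueError("ensemble must contain at least one region")
    cfg = config or PatternConfig()
    caches = [_region_cache(pair, equation) for pair in ensemble]
    windows_per_region = [
        dynamic_windows(len(pair), cfg.start_fraction, cfg.stride) for pair in ensemble
    ]
    results: list[ConformityResult] = []
    for structure in enumerate_structures(equation):
        cols = np.array((0, 1) + tuple(2 + i for i in structure.factor_indices))
        signs = np.array(_BASELINE_SIGNS + tuple(float(s) for s in structure.signs))
        k = len(cols)
        n_pass_total = n_total = 0
        # per-region partial sums, combined in sorted region order so the
        # result is independent of ensemble iteration order
        region_r2: dict[str, tuple[float, int]] = {}
        region_rates = []
        for pair, cache, windows in zip(ensemble, caches, windows_per_region):
            # dof-infeasible windows are skipped, excluded from Ntotal
            rows = np.array([w - 1 for w in windows if (w - 1) - k >= 1])
            if len(rows) == 0:
                continue
            rp = 0
            rt = len(rows)
            reg_sum, reg_cnt = 0.0, 0
            batch = _batched_window_stats(cache, cols, rows)
            if batch is not None:
                beta, p, r2 = batch
                finite = np.isfinite(r2)
                reg_sum = float(r2[finite].sum())
                reg_cnt = int(finite.sum())
                # column scaling is positive, so scaled signs match raw signs
                structural = np.all(signs[None, :] * beta > 0, axis=1)
                correl = finite & (r2 > cfg.r2_min)
                signif = np.all(np.isfinite(p) & (p < cfg.alpha), axis=1)
                rp = int(np.sum(structural & correl & signif))
            else:
                # some window is exactly collinear: scalar path, counting
                # collinear windows as attempted-and-failed
                for row in rows:
                    fit = _window_fit(cache, cols, int(row))
                    if fit is None:
                        continue
                    beta, p, r2 = fit
                    if np.isfinite(r2):
                        reg_sum += r2
                        reg_cnt += 1
                    if decide_tests(beta, p, r2, signs, cfg.r2_min, cfg.alpha).overall_pass:
                        rp += 1
            n_pass_total += rp
            n_total += rt
            key = pair.region_id
            region_r2[key] = (reg_sum, reg_cnt)
            if rt > 0:
                region_rates.append((key, rp / rt))
        if cfg.cr_pooling == "pooled":
            cr = conformity_rate(n_pass_total, n_total)
        elif region_rates:
            cr = float(np.mean([rate for _, rate in sorted(region_rates)]))
        else:
            cr = float("nan")
        r2_sum = sum(region_r2[key][0] for key in sorted(region_r2))
        r2_count = sum(region_r2[key][1] for key in sorted(region_r2))
        mean_r2 = r2_sum / r2_count if r2_count else float("nan")
        results.append(
            ConformityResult(
                structure=structure,
                n_pass=n_pass_total,
                n_total=n_total,
                cr=cr,
                mean_r2=mean_r2,
            )
        )
    results.sort(key=lambda res: res.rank_key)
    return results


def select_structure(
    ranked: list[ConformityResult], min_cr: float = 0.5
) -> StructureSpec | None:
    """Top-ranked structure if its CR clears the gate, else None."""
    if not ranked:
        raise ValueError("ranked results must be nonempty")
    top = ranked[0]
    if np.isfinite(top.cr) and top.cr >= min_cr:
        return top.structure
    return None


def structure_from_coefficients(equation: str, coeffs) -> StructureSpec:
    """The signed structure realised by a full length-6 coefficient vector."""
    coeffs = np.asarray(coeffs, dtype=float)
    table = equation_factors(equation)
    idx = [i for i in range(6) if coeffs[i] != 0]
    if not idx:
        raise ValueError("coefficient vector has no active factors")
    return StructureSpec(
        equation=equation,
        factors=tuple(table[i] for i in idx),
        signs=tuple(1 if coeffs[i] > 0 else -1 for i in idx),
    )
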