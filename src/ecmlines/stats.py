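"""Statistical layer: axial circular statistics, correlation and variance
tests, and a two-response general linear model with multivariate term tests
and dual-direction AIC selection.

Orientation data here are axial (a line or an elongated cell has no
head/tail, so angles live modulo 180°). Axial samples are analyzed by
doubling the angles, applying ordinary circular statistics on the doubled
values, and halving the results: the mean resultant length R of the doubled
angles measures concentration, the axial mean is half the doubled-angle
circular mean, and the angular deviation is ``√(2(1−R))/2`` radians
(≈ 40.5° at maximum, when the doubled angles balance out).

The regression layer models two responses (cell orientation and aspect
ratio) jointly as a general linear model in pattern width, alignment and
density plus interactions. Each term is tested by comparing the full model
against the term-deleted model through Pillai's trace with Rao's F
approximation, and models of different sizes are compared with a Gaussian
log-determinant AIC, searched by dual-direction (drop/re-add) stepwise
moves that respect model hierarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "AxialStats",
    "MvRegressionSpec",
    "MvRegressionResult",
    "TermTest",
    "circ_axial_stats",
    "axial_mean_deg",
    "axial_deviation_deg",
    "pearson_corr",
    "levene_test",
    "anova_bonferroni",
    "mv_regress",
    "aic_stepwise",
]

#: Maximum axial angular deviation, degrees: √2 rad halved.
MAX_AXIAL_DEVIATION_DEG = math.degrees(math.sqrt(2.0) / 2.0)


@dataclass(frozen=True)
class AxialStats:
    """Summary of an axial (mod-180°) angle sample."""

    n: int
    mean_deg: float  # axial circular mean, (−90, 90]
    resultant_length: float  # R of the doubled angles, in [0, 1]
    angular_deviation_deg: float  # √(2(1−R))/2 in degrees, [0, 40.5]


def circ_axial_stats(angles_deg: Sequence[float]) -> AxialStats:
    """Axial circular statistics by angle doubling.

    Raises ``ValueError`` on an empty sample.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    doubled = np.deg2rad(2.0 * a)
    C = float(np.mean(np.cos(doubled)))
    S = float(np.mean(np.sin(doubled)))
    R = min(1.0, math.hypot(C, S))
    mean = math.degrees(0.5 * math.atan2(S, C))
    if mean <= -90.0:
        mean += 180.0
    dev = math.degrees(math.sqrt(max(0.0, 2.0 * (1.0 - R))) / 2.0)
    return AxialStats(
        n=int(a.size), mean_deg=mean, resultant_length=R, angular_deviation_deg=dev
    )


def axial_mean_deg(angles_deg: Sequence[float]) -> float:
    return circ_axial_stats(angles_deg).mean_deg


def axial_deviation_deg(angles_deg: Sequence[float]) -> float:
    return circ_axial_stats(angles_deg).angular_deviation_deg


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson product-moment correlation: returns ``(r, r², p)``.

    Two-sided p from ``t = r·√((n−2)/(1−r²))`` on n−2 degrees of freedom.
    Requires n ≥ 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    res = scipy.stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def levene_test(
    groups: Iterable[Sequence[float]], center: str = "mean"
) -> tuple[float, float]:
    """Levene's test for equality of variances across groups: ``(W, p)``.

    ``center`` selects the classic test (``"mean"``) or the Brown–Forsythe
    median variant. p from F(k−1, N−k).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    W, p = scipy.stats.levene(*gs, center=center)
    return float(W), float(p)


def anova_bonferroni(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA followed by Bonferroni-adjusted pairwise t tests.

    Returns ``{"F", "p", "pairwise"}`` where ``pairwise`` maps group-index
    pairs to ``{"t", "p_raw", "p_adj", "significant"}``; adjusted p values
    are ``min(1, raw·m)`` with m the number of comparisons.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    F, p = scipy.stats.f_oneway(*gs)
    pairs = list(combinations(range(len(gs)), 2))
    m = len(pairs)
    pairwise = {}
    for i, j in pairs:
        t, praw = scipy.stats.ttest_ind(gs[i], gs[j])
        padj = min(1.0, float(praw) * m)
        pairwise[(i, j)] = {
            "t": float(t),
            "p_raw": float(praw),
            "p_adj": padj,
            "significant": padj < alpha,
        }
    return {"F": float(F), "p": float(p), "pairwise": pairwise}


# ---------------------------------------------------------------------------
# two-response general linear model

#: Term grammar: main effects are column names; interactions join them with ':'.
def _term_columns(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def _term_order(term: str) -> int:
    return len(_term_columns(term))


def _hierarchy_ok(terms: Sequence[str]) -> bool:
    tset = set(terms)
    for t in terms:
        cols = _term_columns(t)
        if len(cols) == 1:
            continue
        for k in range(1, len(cols)):
            for sub in combinations(cols, k):
                # any lower-order sub-term must be present in some order
                if not any(set(_term_columns(u)) == set(sub) for u in tset):
                    return False
    return True


@dataclass(frozen=True)
class MvRegressionSpec:
    """Model specification: response columns, predictor terms, data table."""

    responses: tuple[str, str]
    terms: tuple[str, ...]
    data: pd.DataFrame = dc_field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if "intercept" not in self.terms:
            raise ValueError("model must contain an intercept term")
        others = [t for t in self.terms if t != "intercept"]
        if not _hierarchy_ok(others):
            raise ValueError("model violates hierarchy: interaction lacks a main effect")

    def with_terms(self, terms: Sequence[str]) -> "MvRegressionSpec":
        return MvRegressionSpec(self.responses, tuple(terms), self.data)


@dataclass(frozen=True)
class TermTest:
    term: str
    pillai: float
    approx_F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class MvRegressionResult:
    spec: MvRegressionSpec
    coefficients: pd.DataFrame  # index = terms, columns = responses
    residual_sscp: np.ndarray
    term_tests: tuple[TermTest, ...]
    aic: float
    n: int

    def table(self) -> pd.DataFrame:
        """Report in the layout of a per-term regression summary table:
        term, per-response coefficients, approximate F, p."""
        rows = []
        tests = {t.term: t for t in self.term_tests}
        for term in self.spec.terms:
            row = {"term": term}
            for resp in self.spec.responses:
                row[f"coef[{resp}]"] = self.coefficients.loc[term, resp]
            tt = tests.get(term)
            row["approx_F"] = tt.approx_F if tt else np.nan
            row["p"] = tt.p if tt else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(data)))
        else:
            prod = np.ones(len(data))
            for c in _term_columns(t):
                prod = prod * data[c].to_numpy(dtype=float)
            cols.append(prod)
    return np.column_stack(cols)


def _fit_sscp(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residual SSCP; raises on rank deficiency."""
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("design matrix is rank deficient (collinear terms)")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    return B, resid.T @ resid


def _pillai_F(H: np.ndarray, E: np.ndarray, q_h: int, n: int, q_full: int):
    """Pillai's trace for hypothesis SSCP H vs error SSCP E, with Rao's
    approximate F transform. ``q_h`` = hypothesis df, ``q_full`` = rank of
    the full design."""
    m = E.shape[0]
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(q_h, m)
    mm = 0.5 * (abs(q_h - m) - 1.0)
    nn = 0.5 * (n - q_full - m - 1.0)
    df1 = s * (2.0 * mm + s + 1.0)
    df2 = s * (2.0 * nn + s + 1.0)
    denom = s - V
    if denom <= 0 or df2 <= 0:
        return V, math.inf, df1, df2, 0.0
    F = (df2 / df1) * (V / denom)
    p = float(scipy.stats.f.sf(F, df1, df2))
    return V, F, df1, df2, p


def mv_regress(spec: MvRegressionSpec) -> MvRegressionResult:
    """Fit the two-response linear model and test each term.

    Coefficients are ordinary least squares per response. Each non-intercept
    term (and the intercept itself) is tested by the extra residual SSCP of
    the term-deleted fit — Pillai's trace with Rao's approximate F. AIC is
    ``n·ln det(E/n) + 2k`` with E the residual SSCP and k the number of
    regression parameters (terms × responses).
    """
    data = spec.data
    Y = data.loc[:, list(spec.responses)].to_numpy(dtype=float)
    n, m = Y.shape
    q = len(spec.terms)
    if n <= q:
        raise ValueError("need more observations than terms")
    X = _design_matrix(data, spec.terms)
    B, E = _fit_sscp(X, Y)

    tests = []
    for term in spec.terms:
        keep = [t for t in spec.terms if t != term]
        if keep:
            Xr = _design_matrix(data, keep)
            _, Er = _fit_sscp(Xr, Y)
        else:
            Er = Y.T @ Y
        H = Er - E
        V, F, df1, df2, p = _pillai_F(H, E, 1, n, q)
        tests.append(TermTest(term=term, pillai=V, approx_F=F, df1=df1, df2=df2, p=p))

    coef = pd.DataFrame(B, index=list(spec.terms), columns=list(spec.responses))
    aic = n * float(np.log(np.linalg.det(E / n))) + 2.0 * (q * m)
    return MvRegressionResult(
        spec=spec,
        coefficients=coef,
        residual_sscp=E,
        term_tests=tuple(tests),
        aic=aic,
        n=n,
    )


def _deletable(terms: Sequence[str]) -> list[str]:
    """Non-intercept terms whose removal keeps the model hierarchical."""
    out = []
    for t in terms:
        if t == "intercept":
            continue
        rest = [u for u in terms if u not in (t, "intercept")]
        if _hierarchy_ok(rest):
            out.append(t)
    return out


def _addable(terms: Sequence[str], dropped: Sequence[str]) -> list[str]:
    out = []
    for t in dropped:
        cand = [u for u in terms if u != "intercept"] + [t]
        if _hierarchy_ok(cand):
            out.append(t)
    return out


def aic_stepwise(
    spec: MvRegressionSpec, direction: str = "both"
) -> tuple[MvRegressionSpec, list[dict]]:
    """Dual-direction stepwise AIC model selection.

    From the initial model, repeatedly evaluates single-term deletions
    (``direction`` 'backward' or 'both') and re-additions of previously
    dropped terms ('forward' or 'both'), each respecting hierarchy, and
    accepts the move with the lowest AIC while it improves on the current
    model. Returns the selected spec and the step trace (each entry records
    the move and the AIC after it; the trace is non-increasing in AIC).
    """
    if direction not in ("both", "backward", "forward"):
        raise ValueError("direction must be 'both', 'backward' or 'forward'")
    current = spec
    current_aic = mv_regress(current).aic
    dropped: list[str] = []
    trace = [{"move": "start", "term": None, "aic": current_aic, "terms": current.terms}]
    while True:
        moves: list[tuple[float, str, str]] = []
        if direction in ("both", "backward"):
            for t in _deletable(current.terms):
                cand = current.with_terms([u for u in current.terms if u != t])
                moves.append((mv_regress(cand).aic, "drop", t))
        if direction in ("both", "forward"):
            for t in _addable(current.terms, dropped):
                cand = current.with_terms(list(current.terms) + [t])
                moves.append((mv_regress(cand).aic, "add", t))
        if not moves:
            break
        best_aic, kind, term = min(moves, key=lambda m: m[0])
        if best_aic >= current_aic:
            break
        if kind == "drop":
            current = current.with_terms([u for u in current.terms if u != term])
            dropped.append(term)
        else:
            current = current.with_terms(list(current.terms) + [term])
            dropped.remove(term)
        current_aic = best_aic
        trace.append({"move": kind, "term": term, "aic": best_aic, "terms": current.terms})
    return current, trace
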