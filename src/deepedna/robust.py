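"""Rank-based robust ANOVA for the volume x depth comparisons.

The survey compares DNA yield and ESV richness between filtered-volume
groups and depth strata with a rank-based linear model: coefficients
minimize Jaeckel's dispersion

    D(beta) = sum_i a(R(e_i)) * e_i,   e = y - X beta,

with Wilcoxon scores a(i) = sqrt(12) * (i/(n+1) - 1/2).  Factor effects are
tested by drop-in-dispersion F-type statistics,

    F = (reduction in dispersion / q) / (tau_hat / 2),

where tau_hat is the scale parameter of the rank estimate (proportional to
1 / integral of the squared error density), estimated from the fitted
residuals by a kernel density estimate of the pairwise-difference density
at zero with a degrees-of-freedom correction.  Pairwise post-hoc
comparisons merge two factor levels and re-test by drop in dispersion, so
a two-level factor's single comparison is exactly the factor test.

Levene's test (variance homogeneity across groups) rounds out the module;
it is the classic one-way ANOVA on absolute deviations from the group
center (mean by default, median for the Brown-Forsythe variant).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

SQRT12 = np.sqrt(12.0)


def wilcoxon_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    return SQRT12 * (ranks / (n + 1.0) - 0.5)


def rank_dispersion(resid: np.ndarray) -> float:
    """Jaeckel dispersion of a residual vector under Wilcoxon scores."""
    n = resid.size
    ranks = stats.rankdata(resid)
    return float(np.sum(wilcoxon_scores(ranks, n) * resid))


def estimate_tau(resid: np.ndarray, n_params: int) -> float:
    """Scale parameter for rank-based inference.

    tau = 1 / (sqrt(12) * integral f^2) where f is the error density; the
    integral equals the density of a difference of two independent errors
    at zero, estimated here by a Gaussian kernel on all pairwise residual
    differences (Silverman-type bandwidth in the number of residuals), with
    the usual sqrt(n / (n - p - 1)) small-sample correction.
    """
    e = np.asarray(resid, dtype=float)
    n = e.size
    if n < 3:
        raise ValueError("need at least 3 residuals to estimate tau")
    diffs = (e[:, None] - e[None, :])[np.triu_indices(n, k=1)]
    spread = min(np.std(diffs), stats.iqr(diffs) / 1.349) or np.std(diffs)
    if spread == 0:
        raise ValueError("degenerate residuals: zero spread")
    h = 0.9 * spread * n ** (-0.2)
    # symmetric sample: kernel mass at zero from the i<j half counts fully
    g0 = float(np.mean(stats.norm.pdf(diffs / h)) / h)
    tau = 1.0 / (SQRT12 * g0)
    return tau * np.sqrt(n / max(n - n_params - 1, 1))


#: Relative weight of the quadratic tie-break in the dispersion objective.
#: The dispersion is piecewise linear in beta, so its minimizing set can be
#: a flat polytope; an infinitesimal ridge toward the least-squares fit
#: makes the minimizer unique without materially moving it.
TIE_BREAK_LAMBDA = 1e-5


def pairwise_differences(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All i<j differences of the response and design rows.

    The Wilcoxon-score dispersion equals
    sqrt(12) / (2 (n+1)) * sum_{i<j} |(y_i - y_j) - (x_i - x_j)' beta|,
    so rank regression is an L1 fit through pairwise differences.
    """
    iu, ju = np.triu_indices(len(y), k=1)
    return y[iu] - y[ju], X[iu] - X[ju]


def dispersion_objective(y: np.ndarray, X: np.ndarray, anchor: np.ndarray):
    """The tie-broken objective rank_fit minimizes:
    D(beta) + lambda * ||beta - anchor||^2, anchored at least squares."""
    lam = TIE_BREAK_LAMBDA * (1.0 + abs(rank_dispersion(y - X @ anchor)))

    def obj(beta: np.ndarray) -> float:
        return rank_dispersion(y - X @ beta) + lam * float(np.sum((beta - anchor) ** 2))

    return obj


def _minimize_dispersion(y: np.ndarray, X: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Minimize the tie-broken dispersion by smoothing Newton.

    Works on the pairwise-difference L1 form: |r| is replaced by
    sqrt(r^2 + eps^2) and eps driven to ~1e-12 of the data scale; each
    subproblem is smooth and strictly convex (the ridge tie-break bounds
    the Hessian away from zero), so damped Newton converges to machine
    precision and the overall minimizer is unique and reproducible.
    """
    anchor = np.asarray(x0, dtype=float)
    n = len(y)
    dy, dX = pairwise_differences(y, X)
    w = SQRT12 / (2.0 * (n + 1.0))
    lam = TIE_BREAK_LAMBDA * (1.0 + abs(rank_dispersion(y - X @ anchor)))
    scale = np.median(np.abs(dy)) or 1.0
    beta = anchor.copy()
    p = X.shape[1]
    for eps in scale * 10.0 ** np.arange(-1, -13, -1):
        for _ in range(60):
            r = dy - dX @ beta
            phi = np.sqrt(r * r + eps * eps)
            grad = -w * (dX.T @ (r / phi)) + 2.0 * lam * (beta - anchor)
            H = w * (dX.T * (eps * eps / phi**3)) @ dX + 2.0 * lam * np.eye(p)
            step = np.linalg.solve(H, grad)
            # damped backtracking on the smoothed objective
            f0 = w * phi.sum() + lam * np.sum((beta - anchor) ** 2)
            t = 1.0
            for _ in range(40):
                cand = beta - t * step
                rc = dy - dX @ cand
                fc = w * np.sqrt(rc * rc + eps * eps).sum() + lam * np.sum(
                    (cand - anchor) ** 2
                )
                if fc <= f0 - 1e-4 * t * float(grad @ step):
                    break
                t *= 0.5
            beta = beta - t * step
            if np.linalg.norm(t * step) < 1e-14 * (1.0 + np.linalg.norm(beta)):
                break
    return beta


@dataclass(frozen=True)
class LeveneResult:
    """Levene's test for homogeneity of variance across groups."""

    statistic: float
    df: tuple[int, int]
    pvalue: float
    center: str


def levene_test(groups: Sequence[np.ndarray], center: str = "mean") -> LeveneResult:
    """Levene's W: one-way ANOVA F on |x - center(group)|.

    ``center`` is ``"mean"`` (classic) or ``"median"`` (Brown-Forsythe).
    Requires at least two groups with two observations each; groups with no
    within-group deviation anywhere make the statistic undefined and raise.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("levene_test needs at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    centered = [
        np.abs(g - (np.mean(g) if center == "mean" else np.median(g))) for g in arrays
    ]
    if all(np.allclose(z, 0) for z in centered):
        raise ValueError("degenerate input: no within-group deviation in any group")
    w, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    return LeveneResult(statistic=float(w), df=(k - 1, n - k), pvalue=float(p), center=center)


class RankTwoWayANOVA:
    """Rank-based linear model for a response over two crossed factors.

    Factors are dummy-coded against their first (sorted) level; the model
    is additive by default, with an optional interaction.  ``fit`` returns
    a :class:`RankFitResults` carrying estimates, the scale parameter tau,
    drop-in-dispersion ANOVA and post-hoc comparisons.
    """

    def __init__(
        self,
        response: np.ndarray,
        factor_a: Sequence,
        factor_b: Sequence,
        names: tuple[str, str] = ("factor_a", "factor_b"),
        interaction: bool = False,
    ) -> None:
        y = np.asarray(response, dtype=float)
        fa = np.asarray(factor_a)
        fb = np.asarray(factor_b)
        if not (y.size == fa.size == fb.size):
            raise ValueError("response and factors must have equal length")
        if np.ptp(y) == 0:
            raise ValueError("constant response: rank dispersion is degenerate")
        self.response = y
        self.names = names
        self.interaction = interaction
        self.levels = (sorted(set(fa.tolist())), sorted(set(fb.tolist())))
        if len(self.levels[0]) < 2 or len(self.levels[1]) < 2:
            raise ValueError("each factor needs at least 2 levels")
        self.factors = (fa, fb)
        self.exog, self.param_names = self._design(fa, fb, interaction)
        n, p = self.exog.shape
        if n <= p + 1:
            raise ValueError(f"too few observations (n={n}) for {p} parameters")
        if np.linalg.matrix_rank(self.exog - self.exog.mean(0)) < p:
            raise ValueError("singular design: factor levels are confounded")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        factors: tuple[str, str],
        interaction: bool = False,
    ) -> "RankTwoWayANOVA":
        return cls(
            df[response].to_numpy(),
            df[factors[0]],
            df[factors[1]],
            names=factors,
            interaction=interaction,
        )

    def _dummies(self, values: np.ndarray, levels: list, label: str):
        cols, names = [], []
        for lev in levels[1:]:
            cols.append((values == lev).astype(float))
            names.append(f"{label}[{lev}]")
        return cols, names

    def _design(self, fa, fb, interaction):
        cols_a, names_a = self._dummies(fa, self.levels[0], self.names[0])
        cols_b, names_b = self._dummies(fb, self.levels[1], self.names[1])
        cols = cols_a + cols_b
        names = names_a + names_b
        if interaction:
            for ca, na in zip(cols_a, names_a):
                for cb, nb in zip(cols_b, names_b):
                    cols.append(ca * cb)
                    names.append(f"{na}:{nb}")
        return np.column_stack(cols), names

    def fit(self) -> "RankFitResults":
        y, X = self.response, self.exog
        x0, *_ = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)
        beta = _minimize_dispersion(y, X, x0)
        resid = y - X @ beta
        intercept = float(np.median(resid))
        tau = estimate_tau(resid, X.shape[1])
        return RankFitResults(self, beta, intercept, tau, resid)


class RankFitResults:
    """Fitted rank-based two-way model: estimates, scale, tests."""

    def __init__(self, model, params, intercept, tau, resid):
        self.model = model
        self.params = pd.Series(params, index=model.param_names)
        self.intercept = intercept
        self.tau = tau
        self.resid = resid
        self.dispersion = rank_dispersion(resid)
        n, p = model.exog.shape
        self.nobs = n
        self.df_resid = n - p - 1
        Xc = model.exog - model.exog.mean(0)
        self.cov_params = tau**2 * np.linalg.inv(Xc.T @ Xc)

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.model.param_names)

    # -- drop-in-dispersion machinery -------------------------------------

    def _reduced_dispersion(self, keep_cols: list[int]) -> float:
        y = self.model.response
        if not keep_cols:
            return rank_dispersion(y - np.median(y))
        X = self.model.exog[:, keep_cols]
        x0, *_ = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)
        beta = _minimize_dispersion(y, X, x0)
        return rank_dispersion(y - X @ beta)

    def _drop_test(self, drop_cols: list[int]) -> tuple[float, int, float]:
        keep = [j for j in range(self.model.exog.shape[1]) if j not in drop_cols]
        rd = self._reduced_dispersion(keep) - self.dispersion
        q = len(drop_cols)
        f = max(rd, 0.0) / q / (self.tau / 2.0)
        p = float(stats.f.sf(f, q, self.df_resid))
        return f, q, p

    def _factor_columns(self, factor: str) -> list[int]:
        if factor not in self.model.names:
            raise ValueError(f"unknown factor {factor!r}; model has {self.model.names}")
        prefix = f"{factor}["
        return [
            j
            for j, name in enumerate(self.model.param_names)
            if name.startswith(prefix) and ":" not in name
        ]

    def anova(self) -> pd.DataFrame:
        """F-type test per factor (and interaction when present)."""
        rows = []
        for factor in self.model.names:
            f, q, p = self._drop_test(self._factor_columns(factor))
            rows.append({"term": factor, "F": f, "df1": q, "df2": self.df_resid, "p": p})
        if self.model.interaction:
            inter = [
                j for j, name in enumerate(self.model.param_names) if ":" in name
            ]
            f, q, p = self._drop_test(inter)
            rows.append(
                {"term": ":".join(self.model.names), "F": f, "df1": q, "df2": self.df_resid, "p": p}
            )
        return pd.DataFrame(rows)

    def posthoc(self, factor: str, adjust: str = "holm") -> pd.DataFrame:
        """All pairwise level comparisons for one factor.

        Each pair is tested by merging the two levels into one and
        measuring the drop in dispersion against the full fit, so the
        single comparison of a two-level factor reproduces the factor's
        ANOVA test exactly.  Estimated differences and their standard
        errors come from the coefficient covariance; p-values are
        multiplicity-adjusted (Holm by default).
        """
        idx = 0 if factor == self.model.names[0] else 1
        if factor not in self.model.names:
            raise ValueError(f"unknown factor {factor!r}")
        levels = self.model.levels[idx]
        if len(levels) < 2:
            raise ValueError("post-hoc comparison needs at least 2 levels")
        names = self.model.param_names
        rows = []
        for la, lb in itertools.combinations(levels, 2):
            contrast = np.zeros(len(names))
            for lev, sign in ((la, 1.0), (lb, -1.0)):
                cname = f"{factor}[{lev}]"
                if cname in names:
                    contrast[names.index(cname)] = sign
            est = float(contrast @ self.params.to_numpy())
            se = float(np.sqrt(contrast @ self.cov_params @ contrast))
            _, _, p = self._merged_levels_test(idx, la, lb)
            rows.append({"level_a": la, "level_b": lb, "estimate": est, "se": se, "p": p})
        out = pd.DataFrame(rows)
        if len(out) > 1:
            out["p_adj"] = multipletests(out["p"], method=adjust)[1]
        else:
            out["p_adj"] = out["p"]
        return out

    def _merged_levels_test(self, idx: int, la, lb) -> tuple[float, int, float]:
        """Drop-in-dispersion test of 'levels la and lb share an effect'."""
        model = self.model
        fa, fb = model.factors
        merged = (fa if idx == 0 else fb).astype(object).copy()
        merged[(merged == la) | (merged == lb)] = f"{la}+{lb}"
        pair = (merged, fb) if idx == 0 else (fa, merged)
        cols = []
        for values in pair:
            levels = sorted(set(values.tolist()), key=str)
            for lev in levels[1:]:
                cols.append((values == lev).astype(float))
        y = model.response
        if cols:
            X = np.column_stack(cols)
            x0, *_ = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)
            beta = _minimize_dispersion(y, X, x0)
            reduced_disp = rank_dispersion(y - X @ beta)
        else:
            reduced_disp = rank_dispersion(y)
        rd = reduced_disp - self.dispersion
        f = max(rd, 0.0) / (self.tau / 2.0)
        p = float(stats.f.sf(f, 1, self.df_resid))
        return f, 1, p

    def summary(self) -> str:
        lines = [
            "Rank-based two-way ANOVA (Wilcoxon scores)",
            f"n = {self.nobs}, dispersion = {self.dispersion:.4f}, tau = {self.tau:.4f}",
            "",
            "Coefficients (vs. first level):",
        ]
        bse = self.bse()
        for name in self.model.param_names:
            lines.append(f"  {name:<28s} {self.params[name]:>10.4f}  (se {bse[name]:.4f})")
        lines.append("")
        lines.append("ANOVA (drop in dispersion):")
        for _, row in self.anova().iterrows():
            lines.append(
                f"  {row['term']:<20s} F = {row['F']:8.3f}, df = ({row['df1']:.0f}, {row['df2']:.0f}), p = {row['p']:.4g}"
            )
        return "\n".join(lines)


def rank_fit(
    response,
    factor_a,
    factor_b,
    names: tuple[str, str] = ("factor_a", "factor_b"),
    interaction: bool = False,
) -> RankFitResults:
    """Fit the rank-based two-way model (convenience wrapper)."""
    return RankTwoWayANOVA(response, factor_a, factor_b, names, interaction).fit()


def rank_anova(results: RankFitResults) -> pd.DataFrame:
    """Drop-in-dispersion ANOVA table of a fitted rank model."""
    return results.anova()


def posthoc_pairwise(results: RankFitResults, factor: str, adjust: str = "holm") -> pd.DataFrame:
    """Pairwise post-hoc comparisons for one factor of a fitted model."""
    return results.posthoc(factor, adjust=adjust)
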