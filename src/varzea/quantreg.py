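"""Quantile regression of site diversity on climate, and biome comparisons.

The conditional tau-quantile of the response is modeled as a line
``Q(tau | x) = b0(tau) + b1(tau) x``; coefficients minimize the pinball
(check) loss ``sum rho_tau(y - b0 - b1 x)`` and are obtained *exactly* from
the linear-programming formulation (HiGHS).  The family of fits over a tau
grid (the quantile process) can be inverted into a conditional density at any
covariate value; crossing quantiles are repaired by monotone rearrangement
before differencing.

Biome-level mean comparisons use one-way ANOVA on log alpha with
Tukey-Kramer adjusted pairwise differences and a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "QuantileFit",
    "quantile_fit",
    "QuantileProcess",
    "quantile_process",
    "BootstrapResult",
    "bootstrap_qr",
    "DensityEstimate",
    "conditional_density",
    "AnovaTukeyResult",
    "anova_log_alpha",
    "paired_t",
    "pinball_loss",
]


def pinball_loss(y: np.ndarray, x: np.ndarray, b0: float, b1: float, tau: float) -> float:
    """Check-function loss of a candidate line at level tau."""
    u = np.asarray(y, float) - b0 - b1 * np.asarray(x, float)
    return float(np.sum(u * (tau - (u < 0))))


def _clean_xy(y, x) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    keep = ~(np.isnan(y) | np.isnan(x))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d incomplete (y, x) pairs", n_dropped)
    return y[keep], x[keep]


@dataclass
class QuantileFit:
    tau: float
    intercept: float
    slope: float
    n: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def quantile_fit(y, x, tau: float, min_n: int = 10) -> QuantileFit:
    """Exact linear quantile regression at level tau via linear programming.

    min over (b0, b1, u+, u-) of ``tau * sum(u+) + (1-tau) * sum(u-)``
    subject to ``y = b0 + b1 x + u+ - u-``, ``u+, u- >= 0``.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    y, x = _clean_xy(y, x)
    n = len(y)
    if n < min_n:
        raise ValueError(f"need at least {min_n} complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    # variables: [b0, b1, u+ (n), u- (n)]
    c = np.concatenate([[0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack(
        [np.ones((n, 1)), x[:, None], np.eye(n), -np.eye(n)]
    )
    bounds = [(None, None), (None, None)] + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    b0, b1 = float(res.x[0]), float(res.x[1])
    return QuantileFit(tau=tau, intercept=b0, slope=b1, n=n)


@dataclass
class QuantileProcess:
    """Coefficient paths b0(tau), b1(tau) over a strictly increasing tau grid."""

    taus: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray
    covariate: str = "x"

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        if np.any(np.diff(self.taus) <= 0) or self.taus.min() <= 0 or self.taus.max() >= 1:
            raise ValueError("tau grid must be strictly increasing within (0, 1)")

    def quantile_curve(self, x0: float) -> np.ndarray:
        return self.intercepts + self.slopes * x0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.taus, "intercept": self.intercepts, "slope": self.slopes}
        )


def quantile_process(y, x, taus: np.ndarray | None = None, covariate: str = "x") -> QuantileProcess:
    """Independent quantile fits at each tau of a grid (no cross-tau smoothing)."""
    if taus is None:
        taus = np.arange(0.01, 0.995, 0.01)
    taus = np.asarray(taus, dtype=float)
    fits = [quantile_fit(y, x, t) for t in taus]
    return QuantileProcess(
        taus=taus,
        intercepts=np.array([f.intercept for f in fits]),
        slopes=np.array([f.slope for f in fits]),
        covariate=covariate,
    )


@dataclass
class BootstrapResult:
    tau: float
    se_intercept: float
    se_slope: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    B: int
    draws: pd.DataFrame  # per-replicate (intercept, slope)


def bootstrap_qr(y, x, tau: float, B: int = 1000, seed: int | None = None,
                 ci_level: float = 0.95) -> BootstrapResult:
    """xy-pair bootstrap of the quantile-regression coefficients.

    Resamples (y, x) pairs with replacement B times, refits exactly, and
    reports per-coefficient standard deviations and percentile intervals.
    Degenerate resamples (constant covariate) are redrawn with a logged count.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if seed is None:
        raise ValueError("bootstrap requires a seed")
    y, x = _clean_xy(y, x)
    n = len(y)
    rng = np.random.default_rng(seed)
    rows = []
    n_redrawn = 0
    while len(rows) < B:
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0:
            n_redrawn += 1
            continue
        f = quantile_fit(y[idx], x[idx], tau, min_n=2)
        rows.append((f.intercept, f.slope))
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)
    draws = pd.DataFrame(rows, columns=["intercept", "slope"])
    lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    return BootstrapResult(
        tau=tau,
        se_intercept=float(draws["intercept"].std(ddof=1)),
        se_slope=float(draws["slope"].std(ddof=1)),
        ci_intercept=tuple(np.percentile(draws["intercept"], [lo, hi])),
        ci_slope=tuple(np.percentile(draws["slope"], [lo, hi])),
        B=B,
        draws=draws,
    )


@dataclass
class DensityEstimate:
    """Conditional density of the response at covariate value x0.

    Estimated as the numerical inverse-derivative of the conditional quantile
    function: f(Q(tau_mid)) ~= d tau / d Q at grid midpoints.
    """

    grid: np.ndarray      # response values (midpoints of the quantile curve)
    density: np.ndarray
    x0: float
    rearranged: bool

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def conditional_density(proc: QuantileProcess, x0: float) -> DensityEstimate:
    """Conditional density at x0 from the quantile process.

    The fitted quantile curve Q(tau | x0) is monotone-rearranged (sorted) if
    any crossing is detected, then differenced: density = dtau/dQ at
    midpoints.  Zero-width steps are skipped with a warning.
    """
    q = proc.quantile_curve(x0)
    q_sorted = np.sort(q)
    rearranged = bool(np.any(q != q_sorted))
    if rearranged:
        logger.info("quantile crossing at x0=%g repaired by monotone rearrangement", x0)
    dq = np.diff(q_sorted)
    dtau = np.diff(proc.taus)
    keep = dq > 0
    if not keep.all():
        logger.warning("%d zero-width quantile steps skipped", int((~keep).sum()))
    mids = (q_sorted[:-1] + q_sorted[1:]) / 2.0
    return DensityEstimate(
        grid=mids[keep], density=dtau[keep] / dq[keep], x0=x0, rearranged=rearranged
    )


# ---------------------------------------------------------------------------
# biome comparisons


@dataclass
class AnovaTukeyResult:
    F: float
    df1: int
    df2: int
    p: float
    group_means: pd.Series
    tukey: pd.DataFrame      # pairwise adjusted comparisons
    letters: dict[str, str]  # compact letter display
    n_used: int
    n_excluded: int


def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Greedy letter insertion over the non-significant pair graph.

    Groups sharing no letter differ at the family-wise level; groups whose
    pair is non-significant always share at least one letter.
    """
    letters: dict[str, list[str]] = {g: [] for g in groups}
    symbols = "abcdefghijklmnopqrstuvwxyz"
    next_sym = 0
    for i, g in enumerate(groups):
        for h in groups[i + 1:]:
            if frozenset((g, h)) not in not_different:
                continue
            if set(letters[g]) & set(letters[h]):
                continue
            sym = symbols[next_sym]
            next_sym += 1
            # give the new letter to every group compatible with both
            member: list[str] = []
            for cand in groups:
                if all(
                    frozenset((cand, m)) in not_different or cand == m for m in member + [g, h]
                ):
                    member.append(cand)
            for m in member:
                letters[m].append(sym)
    for g in groups:  # isolated groups still need a letter of their own
        if not letters[g]:
            letters[g] = [symbols[next_sym]]
            next_sym += 1
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def anova_log_alpha(
    alpha: pd.Series, labels: pd.Series, family_alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA + Tukey-Kramer on natural-log Fisher's alpha by biome.

    Records with undefined alpha (NaN) are excluded with a logged count.
    Tukey-Kramer handles unequal group sizes; the compact letter display
    summarizes which biomes differ at the family-wise level.
    """
    df = pd.DataFrame({"alpha": alpha, "label": labels}).dropna(subset=["label"])
    n_total = len(df)
    df = df[np.isfinite(df["alpha"]) & (df["alpha"] > 0)]
    n_excluded = n_total - len(df)
    if n_excluded:
        logger.info("excluded %d records with undefined/non-positive alpha", n_excluded)
    df["log_alpha"] = np.log(df["alpha"])
    sizes = df.groupby("label")["log_alpha"].size()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError(f"groups with n < 2: {list(sizes[sizes < 2].index)}")
    groups = [g["log_alpha"].to_numpy() for _, g in df.groupby("label")]
    F, p = stats.f_oneway(*groups)
    df1 = len(sizes) - 1
    df2 = len(df) - len(sizes)
    tk = pairwise_tukeyhsd(df["log_alpha"], df["label"], alpha=family_alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    not_diff = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in tukey.iterrows()
        if not bool(r["reject"])
    }
    group_names = sorted(sizes.index.astype(str))
    letters = _compact_letters(group_names, not_diff)
    return AnovaTukeyResult(
        F=float(F), df1=df1, df2=df2, p=float(p),
        group_means=df.groupby("label")["log_alpha"].mean(),
        tukey=tukey, letters=letters, n_used=len(df), n_excluded=n_excluded,
    )


def paired_t(values_a, values_b) -> tuple[float, float, int, float]:
    """Classical paired t-test: (mean difference, t, df, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences; t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(diff.mean()), float(t), len(a) - 1, float(p)
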