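"""The statistical procedures used by the arbor pipeline, from first
principles: two-way ANOVA (type-II sums of squares), Tukey's HSD with
studentized-range adjusted p-values, Welch "multiple t-tests" with a Holm
column, and exact binomial penetrance estimation.

Sums of squares, the Welch statistic, Holm's step-down and the
Clopper–Pearson interval are computed here directly; scipy supplies only
the reference distributions (F, t, studentized range, beta).

Factorial samples are tidy pandas DataFrames: one row per observation
with a value column and one column per factor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaError",
    "two_way_anova",
    "tukey_hsd",
    "multiple_t_tests",
    "holm_adjust",
    "clopper_pearson",
    "PenetranceResult",
    "penetrance",
    "score_phenotype",
]


class AnovaError(ValueError):
    pass


def _design(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded (first level dropped) dummy matrix."""
    eye = np.eye(n_levels, dtype=float)[:, 1:]
    return eye[codes]


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    sample: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "region",
) -> pd.DataFrame:
    """Two-way ANOVA with type-II sums of squares.

    Type II is invariant to cell imbalance (animal numbers vary across
    genotypes) and coincides with type I/III on balanced designs. The
    interaction is always included; with exactly one observation per cell
    it is not estimable and an error is raised, as is an empty cell.

    Returns a table indexed by (factor_a, factor_b, "interaction",
    "residual") with columns SS, df, MS, F, p.
    """
    df = sample[[value, factor_a, factor_b]].dropna()
    y = df[value].to_numpy(float)
    a_codes, a_levels = pd.factorize(df[factor_a], sort=True)
    b_codes, b_levels = pd.factorize(df[factor_b], sort=True)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise AnovaError("each factor needs at least 2 levels")
    cell_n = np.bincount(a_codes * b + b_codes, minlength=a * b)
    if np.any(cell_n == 0):
        missing = [
            (a_levels[i // b], b_levels[i % b]) for i in np.nonzero(cell_n == 0)[0]
        ]
        raise AnovaError(f"empty design cell(s): {missing}; the interaction is not estimable")
    n = len(y)
    df_res = n - a * b
    if df_res < 2:
        raise AnovaError(f"only {df_res} residual df; need at least 2 (replicate within cells)")

    ones = np.ones((n, 1))
    Xa = _design(a_codes, a)
    Xb = _design(b_codes, b)
    Xab = np.einsum("ij,ik->ijk", Xa, Xb).reshape(n, -1)

    rss_ab = _rss(y, np.hstack([ones, Xa, Xb]))
    rss_b = _rss(y, np.hstack([ones, Xb]))
    rss_a = _rss(y, np.hstack([ones, Xa]))
    rss_full = _rss(y, np.hstack([ones, Xa, Xb, Xab]))

    ss = {
        factor_a: rss_b - rss_ab,
        factor_b: rss_a - rss_ab,
        "interaction": rss_ab - rss_full,
        "residual": rss_full,
    }
    dfs = {
        factor_a: a - 1,
        factor_b: b - 1,
        "interaction": (a - 1) * (b - 1),
        "residual": df_res,
    }
    ms_res = ss["residual"] / dfs["residual"]
    rows = []
    for key in (factor_a, factor_b, "interaction", "residual"):
        ms = ss[key] / dfs[key]
        if key == "residual":
            f_stat, p = np.nan, np.nan
        else:
            f_stat = ms / ms_res if ms_res > 0 else np.inf
            p = float(sps.f.sf(f_stat, dfs[key], dfs["residual"]))
        rows.append({"source": key, "SS": max(ss[key], 0.0), "df": dfs[key], "MS": ms, "F": f_stat, "p": p})
    return pd.DataFrame(rows).set_index("source")


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: float) -> float:
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


def tukey_hsd(
    sample: pd.DataFrame,
    value: str = "value",
    factor: str = "genotype",
    alpha: float = 0.05,
    ms_resid: float | None = None,
    df_resid: int | None = None,
    p_values: bool = True,
) -> pd.DataFrame:
    """All pairwise level comparisons with studentized-range adjusted
    p-values and simultaneous confidence intervals (Tukey–Kramer for
    unequal group sizes).

    ``ms_resid``/``df_resid`` may come from a surrounding two-way ANOVA;
    by default the one-way within-group mean square is used. With
    ``p_values=False`` the (slow) studentized-range survival function is
    skipped: ``p_adj`` is NaN but ``reject`` (q > critical q) and the
    simultaneous CIs are unchanged.
    """
    df = sample[[value, factor]].dropna()
    groups = {k: g[value].to_numpy(float) for k, g in df.groupby(df[factor].astype(str))}
    k = len(groups)
    if k < 2:
        raise AnovaError("Tukey HSD needs at least 2 levels")
    if ms_resid is None:
        df_resid = sum(len(v) - 1 for v in groups.values())
        if df_resid < 1:
            raise AnovaError("no residual degrees of freedom")
        ms_resid = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values()) / df_resid
    if df_resid is None:
        raise AnovaError("df_resid required when ms_resid is supplied")

    rows = []
    q_crit = _q_crit(alpha, k, float(df_resid))
    for (na, va), (nb, vb) in itertools.combinations(sorted(groups.items()), 2):
        diff = float(va.mean() - vb.mean())
        se = math.sqrt(ms_resid / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        if p_values:
            p_adj = min(float(sps.studentized_range.sf(q, k, df_resid)), 1.0)
        else:
            p_adj = np.nan
        hw = q_crit * se
        rows.append(
            {
                "level_a": na,
                "level_b": nb,
                "diff": diff,
                "se": se,
                "q": q,
                "p_adj": p_adj,
                "ci_low": diff - hw,
                "ci_high": diff + hw,
                "reject": q > q_crit,
            }
        )
    return pd.DataFrame(rows)


def multiple_t_tests(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Welch t-test per pair, with unadjusted and Holm-adjusted p-values.

    ``pairs`` maps a comparison name to a (group1, group2) tuple. The
    unadjusted column mirrors the Prism-style "multiple t-tests"
    convention; the Holm column is provided for family-wise control.
    Degenerate pairs (a group with n < 2, or both groups with zero
    variance) are flagged in the ``error`` column rather than raising.
    """
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 2 or len(y) < 2:
            rows.append({"pair": name, "t": np.nan, "df": np.nan, "p": np.nan, "error": "group with n < 2"})
            continue
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0 and vy == 0:
            rows.append({"pair": name, "t": np.nan, "df": np.nan, "p": np.nan, "error": "zero variance"})
            continue
        se2 = vx / len(x) + vy / len(y)
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        dof = se2**2 / (vx**2 / (len(x) ** 2 * (len(x) - 1)) + vy**2 / (len(y) ** 2 * (len(y) - 1)))
        p = 2.0 * float(sps.t.sf(abs(t), dof))
        rows.append({"pair": name, "t": t, "df": dof, "p": min(p, 1.0), "error": ""})
    out = pd.DataFrame(rows).set_index("pair")
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; NaNs pass through."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    valid = np.nonzero(np.isfinite(p))[0]
    m = len(valid)
    order = valid[np.argsort(p[valid])]
    running = 0.0
    for rank, idx in enumerate(order):
        adj = (m - rank) * p[idx]
        running = max(running, adj)
        out[idx] = min(running, 1.0)
    return out


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class PenetranceResult:
    """Fraction of animals in a cohort exhibiting the phenotype."""

    n_total: int
    n_phenotypic: int
    ci_low: float
    ci_high: float

    @property
    def fraction(self) -> float:
        return self.n_phenotypic / self.n_total


def score_phenotype(
    cohort: pd.DataFrame,
    reference_bci: dict[str, float],
    regions: tuple[str, ...] = ("-1", "+1"),
    threshold: float = 0.5,
) -> pd.Series:
    """Per-animal phenotype call: BCI below ``threshold`` × the wild-type
    reference mean in *every* listed region.

    ``cohort`` is the tidy per-(animal, region) table from the arbor
    pipeline; ``reference_bci`` maps region label to the wild-type mean.
    """
    calls = {}
    for animal, sub in cohort.groupby("animal_id"):
        by_region = sub.set_index("region")["bci"]
        try:
            calls[animal] = all(
                by_region[r] < threshold * reference_bci[r] for r in regions
            )
        except KeyError as exc:
            raise ValueError(f"animal {animal!r} missing region {exc}") from None
    return pd.Series(calls, name="phenotypic")


def penetrance(
    cohort: pd.DataFrame,
    reference_bci: dict[str, float],
    regions: tuple[str, ...] = ("-1", "+1"),
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> PenetranceResult:
    """Penetrance of the branch-loss phenotype in a cohort, with an exact
    (Clopper–Pearson) binomial confidence interval."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    calls = score_phenotype(cohort, reference_bci, regions=regions, threshold=threshold)
    k, n = int(calls.sum()), len(calls)
    lo, hi = clopper_pearson(k, n, alpha=alpha)
    return PenetranceResult(n_total=n, n_phenotypic=k, ci_low=lo, ci_high=hi)
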