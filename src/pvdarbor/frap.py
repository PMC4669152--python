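"""FRAP trace normalization, recovery fitting, and group comparison.

A FRAP experiment bleaches a small region of the primary dendrite at
t = 0 and images recovery every second for five minutes. Traces are
normalized to their pre-bleach mean and fit with a single-exponential
recovery

    F(t) = f0 + (f_inf - f0) * (1 - exp(-t / tau)),

from which the mobile fraction is (f_inf - f0) / (1 - f0), the plateau
clamped at the pre-bleach level so noise cannot push the mobile fraction
above 1. Faster (smaller tau) and more complete (larger mobile fraction)
recovery indicates a larger freely-diffusing pool of the bleached
protein — membrane-inserted receptor rather than receptor trapped in
intracellular organelles.

An optional reference-region correction for acquisition photobleaching
(double normalization) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import stats as pvstats

__all__ = [
    "FrapTrace",
    "FrapFit",
    "FrapFitError",
    "normalize_trace",
    "fit_recovery",
    "compare_recovery",
    "read_traces_csv",
    "write_traces_csv",
]


class FrapFitError(RuntimeError):
    """Recovery fit failed to converge; carries the initial guesses."""

    def __init__(self, message, p0=None, residual=None):
        super().__init__(message)
        self.p0 = p0
        self.residual = residual


@dataclass
class FrapTrace:
    """One bleach-recovery time series.

    Time is in seconds with pre-bleach frames at t < 0 and the bleach at
    t = 0; intensity is in arbitrary units until normalized.
    """

    time: np.ndarray
    intensity: np.ndarray
    animal_id: str = ""
    genotype: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same shape")
        if not np.any(self.time < 0):
            raise ValueError("trace has no pre-bleach frames (t < 0)")
        post = self.time[self.time >= 0]
        if np.any(np.diff(post) <= 0):
            raise ValueError("post-bleach sampling must be strictly increasing in t")


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters on the normalized scale."""

    f0: float
    f_inf: float
    tau: float
    rss: float

    @property
    def mobile_fraction(self) -> float:
        f_inf = min(self.f_inf, 1.0)  # plateau clamped at pre-bleach level
        if self.f0 >= 1.0:
            return 0.0
        return float(np.clip((f_inf - self.f0) / (1.0 - self.f0), 0.0, 1.0))


def normalize_trace(raw: FrapTrace, reference: FrapTrace | None = None) -> FrapTrace:
    """Divide intensities by the pre-bleach mean (maps it to 1).

    With ``reference`` (an unbleached region imaged in parallel), each
    frame is first divided by the reference's same-frame intensity
    relative to its own pre-bleach mean — the double-normalization
    correction for acquisition photobleaching.
    """
    intensity = raw.intensity.astype(float)
    if reference is not None:
        ref_pre = reference.intensity[reference.time < 0].mean()
        if ref_pre <= 0:
            raise ValueError("reference trace has non-positive pre-bleach mean")
        ref = np.interp(raw.time, reference.time, reference.intensity) / ref_pre
        intensity = intensity / np.where(ref > 0, ref, np.nan)
    pre = intensity[raw.time < 0]
    pre_mean = pre.mean()
    if not np.isfinite(pre_mean) or pre_mean <= 0:
        raise ValueError(f"pre-bleach mean must be positive, got {pre_mean}")
    return replace(raw, intensity=intensity / pre_mean)


def _model(t, f0, f_inf, tau):
    return f0 + (f_inf - f0) * (1.0 - np.exp(-t / tau))


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Least-squares single-exponential fit over post-bleach frames.

    Initialization: f0 at the first post-bleach value, f_inf at the mean
    of the last decile, tau at the time to half recovery.

    Raises :class:`FrapFitError` on non-convergence, carrying the initial
    guesses and their residual.
    """
    mask = trace.time >= 0
    t = trace.time[mask]
    y = trace.intensity[mask]
    if len(t) < 10:
        raise ValueError(f"need >= 10 post-bleach frames, got {len(t)}")

    f0_0 = float(y[0])
    f_inf_0 = float(y[max(1, int(0.9 * len(y))):].mean())
    half = 0.5 * (f0_0 + f_inf_0)
    crossing = np.nonzero(y >= half)[0] if f_inf_0 > f0_0 else np.array([])
    tau_0 = float(t[crossing[0]]) if len(crossing) and t[crossing[0]] > 0 else float(t[-1] / 3)
    tau_0 = max(tau_0, float(t[1] - t[0]))
    p0 = (f0_0, f_inf_0, tau_0)

    if np.allclose(y, y.mean(), atol=1e-12):  # flat trace: no recovery
        return FrapFit(f0=float(y.mean()), f_inf=float(y.mean()), tau=tau_0, rss=0.0)

    try:
        popt, _ = curve_fit(
            _model,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        residual = float(np.sum((_model(t, *p0) - y) ** 2))
        raise FrapFitError(f"recovery fit did not converge: {exc}", p0=p0, residual=residual) from None
    rss = float(np.sum((_model(t, *popt) - y) ** 2))
    return FrapFit(f0=float(popt[0]), f_inf=float(popt[1]), tau=float(popt[2]), rss=rss)


def compare_recovery(
    group_a: list[FrapTrace],
    group_b: list[FrapTrace],
    label_a: str | None = None,
    label_b: str | None = None,
    time_grid: np.ndarray | None = None,
):
    """Compare two genotypes' recovery curves with a two-way ANOVA
    (factors: genotype and time) plus per-timepoint group means ± SEM.

    Traces are interpolated onto a common post-bleach grid (the first
    group-A trace's grid by default, or ``time_grid``, which can be used
    to coarsen the 1 s sampling for speed).

    Returns a dict with keys ``anova`` (table), ``curves`` (DataFrame of
    mean ± SEM per genotype × time), and the group labels.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 animals")
    label_a = label_a or (group_a[0].genotype or "A")
    label_b = label_b or (group_b[0].genotype or "B")
    if time_grid is None:
        ta = group_a[0].time
        time_grid = ta[ta >= 0]
    time_grid = np.asarray(time_grid, dtype=float)

    rows = []
    for label, group in ((label_a, group_a), (label_b, group_b)):
        for k, tr in enumerate(group):
            mask = tr.time >= 0
            y = np.interp(time_grid, tr.time[mask], tr.intensity[mask])
            for tt, vv in zip(time_grid, y):
                rows.append({"value": vv, "genotype": label, "time": tt, "replicate": f"{label}-{k}"})
    df = pd.DataFrame(rows)
    table = pvstats.two_way_anova(df, value="value", factor_a="genotype", factor_b="time")
    curves = (
        df.groupby(["genotype", "time"])["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return {"anova": table, "curves": curves, "labels": (label_a, label_b)}


def read_traces_csv(path) -> list[FrapTrace]:
    """Read traces from CSV columns t, intensity, animal_id, genotype
    (negative t = pre-bleach)."""
    df = pd.read_csv(path, comment="#")
    traces = []
    for (animal, genotype), sub in df.groupby(["animal_id", "genotype"], sort=False):
        sub = sub.sort_values("t")
        traces.append(
            FrapTrace(
                time=sub["t"].to_numpy(float),
                intensity=sub["intensity"].to_numpy(float),
                animal_id=str(animal),
                genotype=str(genotype),
            )
        )
    return traces


def write_traces_csv(traces: list[FrapTrace], path, header: str | None = None) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.time, tr.intensity):
            rows.append({"t": t, "intensity": v, "animal_id": tr.animal_id, "genotype": tr.genotype})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)
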