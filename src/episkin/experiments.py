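"""Scenario suite and tissue-level analytics.

Steady-state thickness estimation, migration velocity and turnover
statistics, free-enzyme totals, inhibitor sweeps with linear fits
(reduced-inhibitor disease scenarios) and heterogeneous-recovery sweeps
with quadratic fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coupling import ModelParams, RealisationResult, run_simulation

__all__ = [
    "ScenarioSpec",
    "FitResult",
    "steady_state_thickness",
    "migration_velocity_stats",
    "turnover_statistics",
    "total_free_enzyme",
    "inhibitor_sweep",
    "recovery_sweep",
    "desquamation_threshold",
    "harmonic_mean",
    "expected_velocity",
    "expected_transit_time",
    "fit_polynomial",
    "check_stationarity",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Inhibitor scenario: homogeneous fraction i_T/e_T, or a heterogeneous
    mix where a fraction of stem lineages carry full inhibitor (i_T = e_T)
    and the rest carry none."""

    inhibitor_fraction: float = 1.0
    normal_stem_fraction: float | None = None
    proliferation_mode: str = "single"

    def __post_init__(self):
        if not 0.0 <= self.inhibitor_fraction <= 1.0:
            raise ValueError("inhibitor_fraction must be in [0, 1]")
        if self.normal_stem_fraction is not None and not 0.0 <= self.normal_stem_fraction <= 1.0:
            raise ValueError("normal_stem_fraction must be in [0, 1]")

    def apply(self, mp: ModelParams) -> ModelParams:
        return replace(mp, inhibitor_fraction=self.inhibitor_fraction,
                       normal_stem_fraction=self.normal_stem_fraction)


@dataclass(frozen=True)
class FitResult:
    """Least-squares polynomial fit over scenario means."""

    model: str                 # "linear" | "quadratic"
    coefficients: tuple        # highest degree first (numpy.polyfit order)
    r_squared: float
    x: tuple
    y: tuple

    def predict(self, x):
        return np.polyval(self.coefficients, x)


def fit_polynomial(x, y, degree: int) -> FitResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 1:
        raise ValueError("not enough points for the requested fit")
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(model="linear" if degree == 1 else "quadratic",
                     coefficients=tuple(coef), r_squared=r2,
                     x=tuple(x), y=tuple(y))


def steady_state_thickness(results: list[RealisationResult] | pd.DataFrame,
                           window_days: float | None = None,
                           column: str = "corneum_thickness_CD") -> tuple[float, float, float]:
    """(mean, min, max) thickness over realisations and the sampling window.

    The mean is the time-and-realisation average; min/max give the ribbon
    over the per-realisation time means. ``window_days`` restricts to the
    trailing window of each series.
    """
    if isinstance(results, pd.DataFrame):
        series_list = [results]
    else:
        series_list = [r.thickness for r in results]
    means = []
    for df in series_list:
        if len(df) == 0:
            raise ValueError("empty thickness series")
        if window_days is not None:
            t_end = df["t_hr"].iloc[-1]
            df = df[df["t_hr"] > t_end - window_days * 24.0]
            if len(df) == 0:
                raise ValueError("window selects no samples")
        means.append(float(df[column].mean()))
    return float(np.mean(means)), float(np.min(means)), float(np.max(means))


def migration_velocity_stats(velocity_records: list, window_hr: float = 24.0) -> dict:
    """Distribution of per-cell mean vertical velocities (CD/hr).

    Velocities are Dz/Dt between hourly records ``window_hr`` apart,
    excluding stem cells and cells flagged as surface cells (those feel the
    removal force) at either end of the window.
    """
    if len(velocity_records) < 2:
        return {"mean": float("nan"), "n": 0}
    vels = []
    lag = max(int(round(window_hr)), 1)
    for a in range(0, len(velocity_records) - lag, lag):
        t0, ids0, z0, stem0, surf0 = velocity_records[a]
        t1, ids1, z1, stem1, surf1 = velocity_records[a + lag]
        common, i0, i1 = np.intersect1d(ids0, ids1, return_indices=True)
        ok = ~stem0[i0] & ~stem1[i1] & ~surf0[i0] & ~surf1[i1]
        if np.any(ok):
            vels.append((z1[i1][ok] - z0[i0][ok]) / (t1 - t0))
    if not vels:
        return {"mean": float("nan"), "n": 0}
    v = np.concatenate(vels)
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
        "n": int(v.size),
    }


def turnover_statistics(removal_events: list, entry_ages: list) -> dict:
    """Median/quartile turnover statistics (hours).

    ``removal_events`` carry the age at removal; ``entry_ages`` are ages at
    first corneum entry. Corneum transit is the difference of the medians.
    """
    if len(removal_events) == 0:
        raise ValueError("no removal events")
    ages = np.array([e.age for e in removal_events], dtype=float)
    out = {
        "median_age_at_removal": float(np.median(ages)),
        "q25_age_at_removal": float(np.percentile(ages, 25)),
        "q75_age_at_removal": float(np.percentile(ages, 75)),
        "n_removals": int(ages.size),
    }
    if entry_ages:
        entry = np.asarray(entry_ages, dtype=float)
        out["median_age_at_entry"] = float(np.median(entry))
        out["median_corneum_transit"] = out["median_age_at_removal"] - out["median_age_at_entry"]
    return out


def total_free_enzyme(results: list[RealisationResult]) -> float:
    """Time-averaged total free enzyme over corneum cells, averaged over
    realisations (sum of per-cell e below the cached corneum height)."""
    totals = []
    for r in results:
        if r.free_enzyme_series:
            totals.append(float(np.mean([v for _, v in r.free_enzyme_series])))
    if not totals:
        return 0.0
    return float(np.mean(totals))


def inhibitor_sweep(fractions, base: ModelParams,
                    realisations: int | None = None) -> tuple[pd.DataFrame, FitResult | None]:
    """Run homogeneous-inhibitor scenarios and fit thickness vs fraction.

    Seeds are shared across sweep points (matched realisations) to
    variance-reduce comparisons. Returns a tidy table (fraction,
    realisation, thickness) and a linear fit over scenario means (None with
    fewer than two fractions).
    """
    rows = []
    for f in fractions:
        mp = ScenarioSpec(inhibitor_fraction=float(f)).apply(base)
        for r in run_simulation(mp, realisations, record_hourly_observables=False):
            mean, _, _ = steady_state_thickness([r])
            rows.append({"inhibitor_fraction": float(f),
                         "realisation": r.realisation,
                         "corneum_thickness_CD": mean})
    table = pd.DataFrame(rows)
    fit = None
    if table["inhibitor_fraction"].nunique() >= 2:
        means = table.groupby("inhibitor_fraction")["corneum_thickness_CD"].mean()
        fit = fit_polynomial(means.index.to_numpy(), means.to_numpy(), 1)
    return table, fit


def recovery_sweep(normal_stem_fractions, base: ModelParams,
                   realisations: int | None = None
                   ) -> tuple[pd.DataFrame, FitResult | None, FitResult | None]:
    """Heterogeneous-recovery scenarios: a fraction of stem lineages carry
    full inhibitor, the rest none.

    Returns the tidy thickness table, a quadratic fit over scenario means
    and the linear baseline expected from homogeneous recovery through the
    two endpoints.
    """
    rows = []
    for f in normal_stem_fractions:
        mp = ScenarioSpec(inhibitor_fraction=0.0, normal_stem_fraction=float(f)).apply(base)
        for r in run_simulation(mp, realisations, record_hourly_observables=False):
            mean, _, _ = steady_state_thickness([r])
            rows.append({"normal_stem_fraction": float(f),
                         "realisation": r.realisation,
                         "corneum_thickness_CD": mean})
    table = pd.DataFrame(rows)
    quad = lin = None
    if table["normal_stem_fraction"].nunique() >= 3:
        means = table.groupby("normal_stem_fraction")["corneum_thickness_CD"].mean()
        quad = fit_polynomial(means.index.to_numpy(), means.to_numpy(), 2)
        x = means.index.to_numpy()
        lin = fit_polynomial([x.min(), x.max()],
                             [means.iloc[np.argmin(x)], means.iloc[np.argmax(x)]], 1)
    return table, quad, lin


def desquamation_threshold(F_D: float, F_max: float, n_bonds: int) -> float:
    """Critical remaining-substrate fraction s* = F_D / (n_bonds * F_max)
    at which the removal force breaks ``n_bonds`` peak adhesion bonds."""
    if F_D < 0 or F_max <= 0 or n_bonds <= 0:
        raise ValueError("F_D >= 0, F_max > 0 and n_bonds > 0 required")
    return F_D / (n_bonds * F_max)


def harmonic_mean(cycle_times) -> float:
    """Harmonic mean n / sum(1/T_i) of cell cycle times."""
    t = np.asarray(cycle_times, dtype=float)
    if t.size == 0 or np.any(t <= 0):
        raise ValueError("cycle times must be positive and non-empty")
    return float(t.size / np.sum(1.0 / t))


def expected_velocity(layer_thickness: float = 0.8, mean_cycle: float = 15.0) -> float:
    """Vertical velocity implied by one division per cycle pushing the
    column up one packing layer (CD/hr)."""
    return layer_thickness / mean_cycle


def expected_transit_time(corneum_thickness: float, velocity: float) -> float:
    """Expected corneum transit time (hr) = thickness / velocity."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    return corneum_thickness / velocity


def check_stationarity(thickness: pd.DataFrame, block_days: float = 5.0,
                       alpha: float = 0.05) -> bool:
    """True when block means of the thickness series show no significant
    linear trend (slope t-test at level ``alpha``)."""
    from scipy import stats

    t = thickness["t_hr"].to_numpy()
    y = thickness["corneum_thickness_CD"].to_numpy()
    block = block_days * 24.0
    edges = np.arange(t.min(), t.max() + block, block)
    means, centers = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (t >= a) & (t < b)
        if m.sum() >= 2:
            means.append(y[m].mean())
            centers.append(t[m].mean())
    if len(means) < 3:
        return True
    res = stats.linregress(centers, means)
    return bool(res.pvalue > alpha)
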