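"""The ten standard parameter sweeps and their derived statistics.

Each preset mirrors one row of the study design: which parameter is
varied (diffusivity contrast, confined-domain area, domain merging,
crowder count, crowder disintegration, global diffusivity, receptor
density, or the reaction-rate grid) and over which values, holding the
standard setup fixed (47 receptor monomers, k_b = 0.05, k_d = 0.01,
a 30-unit periodic box, 200,000 ticks with the last 50,000 averaged,
3 replicates).

Derived statistics: Pearson correlation (crowder-disintegration trend),
ordinary-least-squares inversion of the fraction-inside vs domain-area
line (confined-area estimation), and the k_b x k_d dimer-fraction grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    DomainSpec,
    OBSERVABLES,
    SimConfig,
    SummaryStat,
    run_replicates,
)
from .membrane import BoxSpec, DomainSet, MotionParams, make_domains
from .reactions import ReactionParams

__all__ = [
    "SweepSpec",
    "SweepResult",
    "preset",
    "apply_point",
    "run_sweep",
    "pearson",
    "AreaEstimate",
    "estimate_area_at_half_inside",
    "split_domains",
    "kbkd_grid",
    "PRESET_DESCRIPTIONS",
]

#: Reference number of equal domains for the merging sweep: fold f
#: merges the reference layout of 8 domains into round(8/f) domains at
#: fixed 35% total area (fold 8 -> 1 domain, fold 0.5 -> 16 domains).
MERGE_REFERENCE_DOMAINS = 8

#: Crowder-disintegration sweep: total crowder area fixed at one circle
#: of diameter half the box (radius L/4), split into n equal discs.
SPLIT_TOTAL_RADIUS_FRACTION = 0.25

PRESET_DESCRIPTIONS = {
    1: "receptor localisation in the confined domain vs D_out:D_in (no reactions)",
    2: "dimerisation vs D_out:D_in with a 35% confined domain",
    3: "dimerisation vs confined-domain area x D_out:D_in",
    4: "dimerisation vs confined-domain merging fold (total area fixed)",
    5: "dimerisation vs number of added inert crowder proteins",
    6: "dimerisation vs crowder disintegration (total crowder area fixed)",
    7: "dimerisation vs global receptor diffusivity (no confined domain)",
    8: "fraction inside vs confined-domain area at 10:1 contrast (area estimation)",
    9: "dimerisation vs receptor surface density (% of 9600 copies)",
    10: "dimerisation vs k_b x k_d (60-140% of defaults)",
}


@dataclass
class SweepSpec:
    """One experiment: a base configuration plus varied parameter(s)."""

    base: SimConfig
    varied: dict[str, list]
    preset_id: int | None = None
    description: str = ""

    def points(self) -> list[dict[str, object]]:
        """Cartesian product of the varied parameter values."""
        names = list(self.varied)
        if not names:
            return [{}]
        for n in names:
            if not self.varied[n]:
                raise ValueError(f"varied parameter '{n}' has no values")
        return [dict(zip(names, combo))
                for combo in product(*(self.varied[n] for n in names))]


@dataclass
class SweepResult:
    """Tidy per-(point, observable) results: mean +/- SD over replicates."""

    df: pd.DataFrame
    spec: SweepSpec | None = None

    def observable(self, name: str) -> pd.DataFrame:
        return self.df[self.df["observable"] == name].reset_index(drop=True)


def _with_domains(cfg: SimConfig, count: int, percent: float) -> SimConfig:
    return replace(cfg, domains=DomainSpec(
        count=count, occupied_percent=percent,
        layout="central" if count <= 1 else "uniform"))


def apply_point(base: SimConfig, point: dict[str, object]) -> SimConfig:
    """Apply one sweep point's parameter overrides to the base config."""
    cfg = base
    for name, value in point.items():
        v = float(value)  # type: ignore[arg-type]
        if name == "d_in":
            cfg = replace(cfg, motion=replace(cfg.motion, d_in=v))
        elif name == "ratio":  # D_out : D_in contrast at d_out fixed
            cfg = replace(cfg, motion=replace(cfg.motion,
                                              d_in=cfg.motion.d_out / v))
        elif name == "d_global":
            cfg = replace(cfg, motion=replace(cfg.motion, d_out=v, d_in=v))
        elif name == "occupied_percent":
            count = cfg.domains.count if v > 0 else 0
            cfg = _with_domains(cfg, max(count, 1) if v > 0 else 0, v)
        elif name == "fold":
            n = max(1, round(MERGE_REFERENCE_DOMAINS / v))
            cfg = _with_domains(cfg, n, cfg.domains.occupied_percent)
        elif name == "n_inert":
            cfg = replace(cfg, n_inert=int(v))
        elif name == "inert_parts":
            n = int(v)
            radius = SPLIT_TOTAL_RADIUS_FRACTION * cfg.box.length / math.sqrt(n)
            cfg = replace(cfg, n_inert=n, inert_radius=radius)
        elif name == "receptor_percent":
            cfg = replace(cfg, n_receptor_monomers=int(round(47 * v / 100.0)))
        elif name == "k_b":
            cfg = replace(cfg, reactions=replace(cfg.reactions, k_b=v))
        elif name == "k_b_with_kd_fifth":  # area-estimation rows: k_d = k_b/5
            cfg = replace(cfg, reactions=replace(cfg.reactions,
                                                 k_b=v, k_d=v / 5.0))
        elif name == "k_d":
            cfg = replace(cfg, reactions=replace(cfg.reactions, k_d=v))
        elif name == "k_b_percent":
            cfg = replace(cfg, reactions=replace(cfg.reactions,
                                                 k_b=0.05 * v / 100.0))
        elif name == "k_d_percent":
            cfg = replace(cfg, reactions=replace(cfg.reactions,
                                                 k_d=0.01 * v / 100.0))
        else:
            raise ValueError(f"unknown sweep parameter '{name}'")
    return cfg


def preset(row_id: int, base: SimConfig | None = None) -> SweepSpec:
    """Sweep specification for one of the ten standard experiments."""
    if row_id not in PRESET_DESCRIPTIONS:
        raise ValueError(f"unknown preset {row_id!r}: valid ids are 1-10")
    cfg = base if base is not None else SimConfig()
    std = replace(cfg)  # 35% single central domain, defaults otherwise
    nocd = _with_domains(cfg, 0, 0.0)
    halving = [2.0**-k for k in range(11)]  # 1, 2^-1, ..., 2^-10

    if row_id == 1:
        spec = SweepSpec(
            replace(std, reactions=replace(std.reactions, k_b=0.0, k_d=0.0)),
            {"d_in": halving})
    elif row_id == 2:
        spec = SweepSpec(std, {"d_in": halving})
    elif row_id == 3:
        spec = SweepSpec(std, {
            "occupied_percent": [float(p) for p in range(0, 85, 5)],
            "d_in": [2.0**-k for k in range(6)]})
    elif row_id == 4:
        spec = SweepSpec(
            replace(std, motion=replace(std.motion, d_in=0.1)),
            {"fold": [0.5 + 0.5 * k for k in range(16)]})  # 0.5, 1, ..., 8
    elif row_id == 5:
        spec = SweepSpec(nocd, {"n_inert": [25.0 * k for k in range(9)]})
    elif row_id == 6:
        spec = SweepSpec(nocd, {"inert_parts": [2.0**k for k in range(9)]})
    elif row_id == 7:
        spec = SweepSpec(nocd, {"d_global": [2.0**k for k in range(-5, 6)]})
    elif row_id == 8:
        spec = SweepSpec(
            replace(std, motion=replace(std.motion, d_in=0.1)),
            {"occupied_percent": [float(p) for p in range(15, 23)],
             "k_b_with_kd_fifth": [0.0, 0.01, 0.005, 0.0025, 0.00125,
                                   0.000625]})
    elif row_id == 9:
        spec = SweepSpec(
            replace(std, motion=replace(std.motion, d_in=0.1)),
            {"receptor_percent": [25.0 * k for k in range(1, 9)]})
    else:  # 10
        levels = [60.0 + 10.0 * k for k in range(9)]
        spec = SweepSpec(
            replace(std, motion=replace(std.motion, d_in=0.1)),
            {"k_b_percent": levels, "k_d_percent": levels})
    spec.preset_id = row_id
    spec.description = PRESET_DESCRIPTIONS[row_id]
    return spec


def run_sweep(spec: SweepSpec, backend: str = "numba",
              progress: bool = False) -> SweepResult:
    """Run replicates at every sweep point; tidy mean +/- SD table."""
    rows = []
    points = spec.points()
    for k, point in enumerate(points):
        cfg = apply_point(spec.base, point)
        if progress:  # pragma: no cover - cosmetic
            print(f"  point {k + 1}/{len(points)}: {point}", flush=True)
        stats_by_obs = run_replicates(cfg, backend=backend)
        for obs in OBSERVABLES:
            s: SummaryStat = stats_by_obs[obs]
            row = dict(point)
            row.update(observable=obs, mean=s.mean,
                       sd=s.sd if s.sd is not None else np.nan,
                       n_replicates=s.n_replicates)
            rows.append(row)
    return SweepResult(pd.DataFrame(rows), spec)


def pearson(xs, ys) -> float:
    """Sample Pearson correlation coefficient."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValueError("pearson needs two equal-length lists of >= 3 values")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("undefined correlation: zero variance input")
    return float(stats.pearsonr(xs, ys).statistic)


@dataclass(frozen=True)
class AreaEstimate:
    """OLS inversion of fraction-inside vs confined-area percentage."""

    crossing_percent: float
    slope: float
    intercept: float
    r_value: float
    target_fraction: float
    warnings: tuple[str, ...] = ()


def estimate_area_at_half_inside(
    sweep: SweepResult | pd.DataFrame,
    target_fraction: float = 0.5,
    area_column: str = "occupied_percent",
) -> AreaEstimate:
    """Confined-domain area (%) at which the fitted fraction-inside line
    reaches ``target_fraction``.

    Fits fraction_inside vs %CD by ordinary least squares over the swept
    range and solves for the crossing.  A non-positive slope or a
    crossing outside the swept range +/- 25% attaches a warning rather
    than raising.
    """
    df = sweep.df if isinstance(sweep, SweepResult) else sweep
    if "observable" in df.columns:
        df = df[df["observable"] == "fraction_inside"]
    xs = df[area_column].to_numpy(dtype=float)
    ys = df["mean"].to_numpy(dtype=float)
    fit = stats.linregress(xs, ys)
    warnings = []
    if fit.slope <= 0:
        warnings.append("non-positive slope: fraction inside does not "
                        "increase with domain area")
        crossing = math.nan
    else:
        crossing = (target_fraction - fit.intercept) / fit.slope
        lo, hi = float(np.min(xs)), float(np.max(xs))
        margin = 0.25 * (hi - lo)
        if not lo - margin <= crossing <= hi + margin:
            warnings.append(
                f"extrapolation: crossing {crossing:.1f}% lies outside the "
                f"swept range [{lo:g}, {hi:g}] +/- 25%")
    return AreaEstimate(crossing, float(fit.slope), float(fit.intercept),
                        float(fit.rvalue), target_fraction, tuple(warnings))


def split_domains(total_area_fraction: float, n_parts: int, box: BoxSpec,
                  rng: np.random.Generator | None = None) -> DomainSet:
    """``n_parts`` equal non-overlapping circles of fixed total area."""
    return make_domains(total_area_fraction, n_parts, box, rng)


def kbkd_grid(base: SimConfig | None = None,
              scale_levels: list[float] | None = None,
              backend: str = "numba") -> pd.DataFrame:
    """Equilibrium dimeric fraction over a k_b x k_d scaling grid.

    Rows are k_d scale levels (percent of default), columns k_b levels.
    """
    if base is None:
        base = preset(10).base
    levels = scale_levels if scale_levels is not None else [
        60.0 + 10.0 * k for k in range(9)]
    for lv in levels:
        if not 0.0 <= lv < 200.0:
            raise ValueError("scale levels must lie in [0, 200) percent")
    spec = SweepSpec(base, {"k_b_percent": list(levels),
                            "k_d_percent": list(levels)})
    result = run_sweep(spec, backend=backend)
    df = result.observable("fraction_dimeric")
    return df.pivot(index="k_d_percent", columns="k_b_percent",
                    values="mean")
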