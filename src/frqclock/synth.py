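"""Seeded synthetic-data generators.

Every analysis stage in the package can be exercised without any
experimental data: these generators emit noisy FRQ densitometry
series (Western-blot quantification sampled every few hours), race
tube records (24 h growth marks plus conidiation band centers), and
two-population conidium morphometry, with the statistical structure
the corresponding analyses assume.

Conidiation-band timing in :func:`gen_race_tube` follows the forcing
period directly — an hourglass read-out — because conidiation banding
under short LD cycles persists in clock-null strains and stops in
constant darkness; it is driven, not clock-generated.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParameters
from .phenotype import ConidiumMeasure, RaceTubeRecord, MARK_INTERVAL_H
from .protocols import LDProtocol
from .rhythms import default_discard
from .simulate import simulate

__all__ = [
    "GeneratorConfig",
    "gen_densitometry",
    "gen_race_tube",
    "gen_morphometry",
    "gen_condition_panel",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings.

    densitometry_noise_sd: SD of the multiplicative log-normal noise on
    blot intensities (dimensionless; blot errors scale with signal).
    band_jitter_sd_mm: positional jitter of band centers and growth
    marks.  interval_h/duration_h: densitometry sampling grid — blot
    time courses are sampled every few hours over two days.
    """

    seed: int = 0
    densitometry_noise_sd: float = 0.1
    band_jitter_sd_mm: float = 0.3
    interval_h: float = 3.0
    duration_h: float = 48.0

    def __post_init__(self) -> None:
        for name in ("densitometry_noise_sd", "band_jitter_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_densitometry(
    params: ModelParameters,
    protocol: LDProtocol,
    interval: float = 3.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    duration: float = 48.0,
    dt: float = 0.02,
    component: str = "F",
    rescale: bool = True,
) -> pd.DataFrame:
    """Noisy sampled FRQ time course, as from quantified Western blots.

    Simulates the model through its transient, then samples ``component``
    every ``interval`` h over ``duration`` h starting at a lights-on
    (t=0 in the output).  Multiplicative log-normal noise of SD
    ``noise_sd`` is applied and, when ``rescale`` is set, the series is
    normalized to max = 1 as densitometry conventionally is.

    Returns a DataFrame with columns ``time_h`` and ``value``.
    """
    if interval < dt:
        raise ValueError("sampling interval must be >= the simulation dt")
    lead_in = default_discard(protocol)
    if protocol.periodic:  # start sampling exactly at a lights-on
        lead_in = np.ceil(lead_in / protocol.T) * protocol.T
    traj = simulate(params, protocol, lead_in + duration, dt=dt)
    t_samp = np.arange(0.0, duration + 1e-9, interval)
    values = np.interp(lead_in + t_samp, traj.times, traj.component(component))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values * rng.lognormal(mean=0.0, sigma=noise_sd, size=values.shape)
    if rescale:
        peak = values.max()
        if peak > 0:
            values = values / peak
    return pd.DataFrame({"time_h": t_samp, "value": values})


def gen_race_tube(
    period: float,
    growth_speed: float,
    days: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
    condition: str = "",
) -> RaceTubeRecord:
    """Synthetic race tube with a band every ``period`` hours.

    The front grows at constant ``growth_speed`` (mm/h); marks sit at
    24 h intervals and band centers at the positions the front occupied
    at times period, 2*period, ...  Seeded Gaussian jitter (SD
    ``jitter_sd`` mm) perturbs marks (except the inoculation origin)
    and bands.  If jitter disorders the bands the draw is repeated with
    a warning; after 10 attempts monotonicity is enforced by sorting.
    """
    if not period > 0:
        raise ValueError("period must be > 0")
    if days < 2:
        raise ValueError("need days >= 2")
    if not growth_speed > 0:
        raise ValueError("growth_speed must be > 0")
    rng = np.random.default_rng(seed)
    t_total = days * MARK_INTERVAL_H
    mark_times = np.arange(0.0, t_total + 1e-9, MARK_INTERVAL_H)
    band_times = np.arange(period, t_total - period / 2, period)

    for attempt in range(10):
        marks = mark_times * growth_speed
        if jitter_sd > 0:
            marks = marks + np.concatenate([[0.0], rng.normal(0, jitter_sd, len(marks) - 1)])
        bands = band_times * growth_speed
        if jitter_sd > 0:
            bands = bands + rng.normal(0, jitter_sd, len(bands))
        bands = np.clip(bands, marks[0], marks[-1])
        ok_marks = np.all(np.diff(marks) > 0)
        ok_bands = np.all(np.diff(bands) > 0)
        if ok_marks and ok_bands:
            break
        warnings.warn(
            "band/mark jitter disordered positions; regenerating",
            stacklevel=2,
        )
    else:
        marks = np.sort(marks)
        bands = np.sort(bands)
    return RaceTubeRecord(tuple(marks), tuple(bands), condition=condition)


def gen_morphometry(
    n: int,
    micro_fraction: float,
    seed: int = 0,
) -> list[ConidiumMeasure]:
    """Two-population conidium morphometry mixture.

    Each conidium is a microconidium with probability ``micro_fraction``
    (aspect ratio uniform in [1.0, 1.4]: nearly round) and otherwise a
    macroconidium (aspect ratio log-uniform in [2.0, 5.0]: elongated).
    Widths are log-normal around typical spore sizes (medians ~3 µm
    micro, ~4 µm macro).  The expected classified proportion under the
    1.5 aspect-ratio criterion equals ``micro_fraction``.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0.0 <= micro_fraction <= 1.0:
        raise ValueError("micro_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_micro = rng.random(n) < micro_fraction
    ratios = np.where(
        is_micro,
        rng.uniform(1.0, 1.4, n),
        np.exp(rng.uniform(np.log(2.0), np.log(5.0), n)),
    )
    widths = np.where(
        is_micro,
        rng.lognormal(np.log(3.0), 0.15, n),
        rng.lognormal(np.log(4.0), 0.15, n),
    )
    return [ConidiumMeasure(length=r * w, width=w) for r, w in zip(ratios, widths)]


def peaked_micro_effect(half_period: float) -> float:
    """Default microconidia effect model: proportion rises with cycle
    length, maximal at the 12 h half-period (24 h day)."""
    return 0.05 + 0.25 * min(half_period, 12.0) / 12.0


def flat_micro_effect(half_period: float) -> float:
    """Null effect model: cycle-length-independent proportion."""
    return 0.15


def gen_condition_panel(
    half_periods=(1.0, 2.0, 3.0, 4.0, 6.0, 12.0),
    effect_model=peaked_micro_effect,
    seed: int = 0,
    n_tubes: int = 3,
    n_conidia: int = 300,
    growth_speed: float = 1.5,
    days: int = 5,
    jitter_sd: float = 0.3,
) -> pd.DataFrame:
    """Per-condition phenotype panel across LD cycles.

    For each symmetric half-period generates ``n_tubes`` race tubes
    (banding at the forcing period 2*half_period, condition-independent
    growth speed with small per-tube variation) and one morphometry
    sample whose true micro-fraction follows ``effect_model``.

    Returns a tidy DataFrame with one row per condition carrying the
    cycle length, mean daily growth, and classified microconidia
    proportion — the inputs to the cycle-length correlation analyses.
    """
    from .phenotype import daily_growth, microconidia_proportion

    half_periods = list(half_periods)
    if len(half_periods) < 3:
        raise ValueError("need >= 3 conditions")
    rng = np.random.default_rng(seed)
    rows = []
    for hp in half_periods:
        frac = float(effect_model(hp))
        speeds = growth_speed * (1.0 + rng.normal(0, 0.05, n_tubes))
        tubes = [
            gen_race_tube(2.0 * hp, s, days, jitter_sd,
                          seed=int(rng.integers(2**31)),
                          condition=f"LD{hp:g}:{hp:g}")
            for s in speeds
        ]
        measures = gen_morphometry(n_conidia, frac, seed=int(rng.integers(2**31)))
        rows.append({
            "half_period_h": hp,
            "cycle_length_h": 2.0 * hp,
            "micro_fraction_true": frac,
            "micro_proportion": microconidia_proportion(measures),
            "mean_daily_growth_mm": float(np.mean([daily_growth(tb).mean() for tb in tubes])),
        })
    return pd.DataFrame(rows)
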