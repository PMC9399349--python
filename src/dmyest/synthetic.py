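"""Synthetic paired AM/PM milking records.

The generator emulates the statistical structure of restricted US
Holstein/Jersey test-day data so the estimators and the cross-validation
engine can be exercised end to end:

* AM milking intervals are longer than PM intervals on average (the two
  must sum to ~24 h on twice-daily milking, up to interval-recording noise);
* daily yield depends on days in milk (DIM), a cow effect, and a lognormal
  residual (kept multiplicative so yields stay strictly positive — the
  exponential regression model takes logs);
* the split of the daily total between AM and PM follows a *saturating*
  within-udder accumulation ``g(t) = 1 − exp(−t/τ)``, so the session yield
  is concave, not linear, in the milking interval.  The AM share is
  ``g(t_AM)/(g(t_AM)+g(t_PM))`` jittered on the logit scale, which conserves
  the daily total exactly.

Profiles calibrate the interval and yield means to the published
Holstein/Jersey summaries; a "symmetric" profile centers both sessions at
12 h for structural checks of the correction factors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import RECORD_COLUMNS

__all__ = [
    "SyntheticConfig",
    "PROFILES",
    "get_profile",
    "sample_intervals",
    "lactation_mean",
    "partition_daily_yield",
    "generate_dataset",
    "generate_exponential_model_data",
]

#: Reference DIM at which the lactation curve is anchored.
_D0 = 158.0
_YIELD_FLOOR_KG = 0.5


@dataclass
class SyntheticConfig:
    """Parameters of one breed profile.

    All intervals in hours, yields in kg, DIM in days.  ``residual_cv`` is
    the coefficient of variation of the day-level multiplicative residual;
    ``share_jitter_sd`` perturbs the AM share on the logit scale;
    ``tau_h`` is the time constant of the saturating udder-fill curve
    (large ``tau_h`` → yield ∝ interval).
    """

    n_cows: int = 3000
    records_per_cow: int = 2
    mean_am_interval_h: float = 12.34
    sd_interval_h: float = 1.0
    interval_bounds_h: tuple[float, float] = (6.0, 20.0)
    mean_daily_yield_kg: float = 31.7
    cow_effect_sd_kg: float = 4.0
    residual_cv: float = 0.08
    dim_slope_kg_per_day: float = -0.02
    wood_curve: tuple[float, float, float] | None = None
    tau_h: float = 30.0
    share_jitter_sd: float = 0.08
    interval_noise_sd_h: float = 0.15
    parity_probs: tuple[float, ...] = (0.35, 0.64, 0.01)
    dim_range: tuple[int, int] = (5, 310)
    breed: str = "Holstein"
    herd_id: str = "H1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.interval_bounds_h
        if not (0.0 < lo < hi < 24.0):
            raise ValueError("interval bounds must lie inside (0, 24)")
        if not (lo <= self.mean_am_interval_h <= hi):
            raise ValueError("mean AM interval must lie inside its bounds")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        for name in ("sd_interval_h", "cow_effect_sd_kg", "residual_cv",
                     "share_jitter_sd", "interval_noise_sd_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def _holstein() -> SyntheticConfig:
    return SyntheticConfig()


def _jersey() -> SyntheticConfig:
    # interval gap 2·12.95 − 24 = 1.90 h; yield scale 23.7/31.7 of Holstein
    return SyntheticConfig(
        mean_am_interval_h=12.95,
        mean_daily_yield_kg=23.7,
        cow_effect_sd_kg=3.0,
        breed="Jersey",
    )


def _symmetric() -> SyntheticConfig:
    return SyntheticConfig(mean_am_interval_h=12.0)


PROFILES = {"holstein": _holstein, "jersey": _jersey, "symmetric": _symmetric}


def get_profile(name: str, **overrides) -> SyntheticConfig:
    """Named profile with optional field overrides."""
    try:
        cfg = PROFILES[name.lower()]()
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
    return cfg.replace(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------


def sample_intervals(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired (t_AM, t_PM) milking intervals in hours.

    t_AM is truncated-normal inside ``interval_bounds_h``; t_PM is the
    complement to 24 h plus independent recording noise, clamped to (0, 24).
    With zero noise the pair sums to 24 exactly.
    """
    lo, hi = config.interval_bounds_h
    if config.sd_interval_h == 0:
        t_am = np.full(n, config.mean_am_interval_h)
    else:
        a = (lo - config.mean_am_interval_h) / config.sd_interval_h
        b = (hi - config.mean_am_interval_h) / config.sd_interval_h
        t_am = stats.truncnorm.rvs(
            a, b, loc=config.mean_am_interval_h, scale=config.sd_interval_h,
            size=n, random_state=rng,
        )
    t_pm = 24.0 - t_am
    if config.interval_noise_sd_h > 0:
        t_pm = t_pm + rng.normal(0.0, config.interval_noise_sd_h, size=n)
    eps = 1e-6
    return t_am, np.clip(t_pm, eps, 24.0 - eps)


def lactation_mean(
    dim: np.ndarray | float,
    parity: np.ndarray | int,
    cow_effect: np.ndarray | float,
    config: SyntheticConfig,
) -> np.ndarray:
    """Expected daily yield (kg) at a given DIM for a given cow.

    Default is linear in DIM around the reference day 158; if
    ``wood_curve=(a, b, c)`` is set, the Wood lactation curve
    ``a·dim^b·exp(−c·dim)`` is used instead, rescaled so its value at
    DIM 158 equals ``mean_daily_yield_kg + cow_effect``.  Parity is accepted
    for signature stability but does not shift the mean.  Negative means are
    floored at 0.5 kg.
    """
    dim = np.asarray(dim, dtype=float)
    if np.any(dim < 1):
        raise ValueError("dim must be >= 1")
    base = config.mean_daily_yield_kg + np.asarray(cow_effect, dtype=float)
    if config.wood_curve is None:
        mean = base + config.dim_slope_kg_per_day * (dim - _D0)
    else:
        a, b, c = config.wood_curve
        shape = a * dim**b * np.exp(-c * dim)
        shape_at_d0 = a * _D0**b * np.exp(-c * _D0)
        mean = base * shape / shape_at_d0
    return np.maximum(mean, _YIELD_FLOOR_KG)


def _fill_fraction(t: np.ndarray, tau_h: float) -> np.ndarray:
    # -expm1 keeps precision in the linear (tau -> inf) limit
    return -np.expm1(-np.asarray(t, dtype=float) / tau_h)


def partition_daily_yield(
    daily_kg: np.ndarray,
    t_am: np.ndarray,
    t_pm: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Split daily totals into (x_AM, x_PM) via the saturating fill curve.

    The AM share ``p = g(t_AM)/(g(t_AM)+g(t_PM))`` is perturbed on the logit
    scale with SD ``share_jitter_sd``; the split conserves the daily total
    exactly.
    """
    daily = np.asarray(daily_kg, dtype=float)
    t_am = np.asarray(t_am, dtype=float)
    t_pm = np.asarray(t_pm, dtype=float)
    if np.any(daily < 0):
        raise ValueError("daily yield must be >= 0")
    if np.any(t_am <= 0) or np.any(t_pm <= 0):
        raise ValueError("milking intervals must be positive")
    g_am = _fill_fraction(t_am, config.tau_h)
    g_pm = _fill_fraction(t_pm, config.tau_h)
    p = g_am / (g_am + g_pm)
    if config.share_jitter_sd > 0:
        logit = np.log(p / (1.0 - p)) + rng.normal(
            0.0, config.share_jitter_sd, size=p.shape
        )
        p = 1.0 / (1.0 + np.exp(-logit))
    x_am = p * daily
    return x_am, daily - x_am


def _lactation_month(dim: np.ndarray) -> np.ndarray:
    return np.clip((dim - 1) // 30 + 1, 1, 11).astype(int)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a table of paired test-day records (interchange columns).

    Per cow: a parity and a cow effect ~ N(0, cow_effect_sd²); per record:
    intervals sampled, daily yield = lactation mean × mean-one lognormal
    residual, partitioned into sessions; ``measured_session`` alternates
    AM/PM across a cow's successive records (random phase per cow).
    Deterministic given ``config.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cows, m = config.n_cows, config.records_per_cow
    if n_cows == 0 or m == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    n = n_cows * m
    cow_idx = np.repeat(np.arange(n_cows), m)
    parity_cow = rng.choice(
        np.arange(1, len(config.parity_probs) + 1),
        size=n_cows,
        p=np.asarray(config.parity_probs) / np.sum(config.parity_probs),
    )
    cow_effect_cow = rng.normal(0.0, config.cow_effect_sd_kg, size=n_cows)
    dim = rng.integers(config.dim_range[0], config.dim_range[1] + 1, size=n)

    t_am, t_pm = sample_intervals(config, n, rng)
    mean = lactation_mean(dim, parity_cow[cow_idx], cow_effect_cow[cow_idx], config)
    sigma2_log = np.log1p(config.residual_cv**2)
    eps = rng.normal(0.0, np.sqrt(sigma2_log), size=n)
    daily = mean * np.exp(eps - sigma2_log / 2.0)  # E[multiplier] = 1
    x_am, x_pm = partition_daily_yield(daily, t_am, t_pm, config, rng)

    phase = rng.integers(0, 2, size=n_cows)
    rec_no = np.tile(np.arange(m), n_cows)
    measured = np.where((rec_no + phase[cow_idx]) % 2 == 0, "AM", "PM")

    return pd.DataFrame(
        {
            "cow_id": [f"C{i:05d}" for i in cow_idx],
            "herd_id": config.herd_id,
            "breed": config.breed,
            "parity": parity_cow[cow_idx],
            "lactation_month": _lactation_month(dim),
            "dim": dim,
            "am_interval_h": t_am,
            "pm_interval_h": t_pm,
            "am_yield_kg": x_am,
            "pm_yield_kg": x_pm,
            "measured_session": measured,
        }
    )


def generate_exponential_model_data(
    n: int,
    rng: np.random.Generator,
    *,
    alpha_am: float = 1.86,
    beta: float = -0.065,
    gamma: float = -2e-4,
    b: float = 0.86,
    resid_sd: float = 0.05,
    d0: float = _D0,
) -> pd.DataFrame:
    """Records drawn exactly from the exponential-regression data model
    ``y = x^b · exp(α_j + β t + γ(d−d0) + ε)`` — a known-truth fixture for
    parameter-recovery checks.

    Each row carries a single-session draw; the complementary session's
    yield is set to ``y − x`` so the pair sums to the generated daily yield
    (only the measured session is used by fits on this fixture).
    """
    t_am = rng.normal(12.3, 1.0, size=n).clip(6, 20)
    t_pm = (24.0 - t_am).clip(4, 20)
    dim = rng.integers(5, 311, size=n)
    x_am = rng.lognormal(mean=np.log(16.0), sigma=0.25, size=n)
    y = x_am**b * np.exp(
        alpha_am + beta * t_am + gamma * (dim - d0)
        + rng.normal(0.0, resid_sd, size=n)
    )
    x_pm = np.maximum(y - x_am, 0.05)
    return pd.DataFrame(
        {
            "cow_id": [f"E{i:05d}" for i in range(n)],
            "herd_id": "SIM",
            "breed": "other",
            "parity": 1,
            "lactation_month": _lactation_month(dim),
            "dim": dim,
            "am_interval_h": t_am,
            "pm_interval_h": t_pm,
            "am_yield_kg": x_am,
            "pm_yield_kg": x_pm,
            "measured_session": "AM",
        }
    )
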