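"""Domain types and plumbing for paired AM/PM test-day milking records.

A *record* is one cow-test-day carrying both the morning (AM) and evening
(PM) milking interval (hours since the previous milking) and yield (kg),
together with the covariates every estimator uses: parity, lactation month,
and days in milk (DIM).  The daily milk yield (DMY) is always the derived
sum ``am_yield_kg + pm_yield_kg`` and is never stored independently.

Records live in a plain :class:`pandas.DataFrame` with the columns of
:data:`RECORD_COLUMNS`; the delimited-text interchange format is read and
written by :func:`read_records` / :func:`write_records`.

Milking-interval classes (MIC) discretize the interval axis into contiguous
half-open bins.  The default grid uses 1-h bins whose midpoints fall on
integer hours (edges 5.5, 6.5, ..., 20.5), so the class containing 12 h is
centered at exactly 12.0 h — the interval at which AM and PM milkings are
symmetric and every multiplicative factor is ≈ 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RECORD_COLUMNS",
    "SESSIONS",
    "EmptyDataError",
    "SingularDesignError",
    "MICGrid",
    "ModelSpec",
    "MODEL_VARIANTS",
    "ValidationReport",
    "build_mic_grid",
    "assign_mic",
    "assign_mic_array",
    "validate_records",
    "read_records",
    "write_records",
    "daily_yield",
    "to_session_long",
    "measured_view",
    "summarize_paired_data",
]

#: Exact column order of the milking-record interchange file.
RECORD_COLUMNS = [
    "cow_id",
    "herd_id",
    "breed",
    "parity",
    "lactation_month",
    "dim",
    "am_interval_h",
    "pm_interval_h",
    "am_yield_kg",
    "pm_yield_kg",
    "measured_session",
]

NUMERIC_COLUMNS = [
    "parity",
    "lactation_month",
    "dim",
    "am_interval_h",
    "pm_interval_h",
    "am_yield_kg",
    "pm_yield_kg",
]

SESSIONS = ("AM", "PM")

#: Default MIC grid span (hours).  Midpoints fall on integer hours 6..20.
DEFAULT_GRID_MIN_H = 5.5
DEFAULT_GRID_MAX_H = 20.5
DEFAULT_GRID_WIDTH_H = 1.0

#: Reference days-in-milk used to center DIM in every regression.
DEFAULT_D0 = 158.0


class EmptyDataError(ValueError):
    """Raised when an operation receives no usable records."""


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when a regression design matrix is rank deficient beyond
    the drop-constant-columns rule."""


# ---------------------------------------------------------------------------
# Milking-interval classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MICGrid:
    """Contiguous half-open interval bins ``[e_k, e_{k+1})`` for one session."""

    session: str
    edges: np.ndarray  # strictly increasing, hours

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least two edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("grid edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width_h(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def containing(self, interval_h: float) -> int:
        """Bin index of the class containing ``interval_h`` (clamped)."""
        k, _ = assign_mic(interval_h, self)
        return k


def build_mic_grid(
    min_h: float = DEFAULT_GRID_MIN_H,
    max_h: float = DEFAULT_GRID_MAX_H,
    width_h: float = DEFAULT_GRID_WIDTH_H,
    session: str = "AM",
) -> MICGrid:
    """Build an equal-width MIC grid spanning ``[min_h, max_h)``.

    ``max_h - min_h`` must be an integer multiple of ``width_h`` (to a
    1e-9 tolerance).
    """
    if width_h <= 0:
        raise ValueError("bin width must be positive")
    if not min_h < max_h:
        raise ValueError("min_h must be < max_h")
    n = (max_h - min_h) / width_h
    n_bins = int(round(n))
    if abs(n - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("(max_h - min_h) must be a multiple of width_h")
    edges = min_h + width_h * np.arange(n_bins + 1)
    return MICGrid(session=session, edges=edges)


def assign_mic(interval_h: float, grid: MICGrid) -> tuple[int, bool]:
    """Map one interval to its bin index.

    Returns ``(k, out_of_grid)``.  Intervals below the first edge or at/above
    the last edge are clamped to the nearest terminal bin and flagged.
    """
    k_arr, flag_arr = assign_mic_array(np.asarray([interval_h], float), grid)
    return int(k_arr[0]), bool(flag_arr[0])


def assign_mic_array(
    intervals_h: np.ndarray, grid: MICGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`assign_mic`: returns (indices, out_of_grid flags)."""
    t = np.asarray(intervals_h, dtype=float)
    k = np.searchsorted(grid.edges, t, side="right") - 1
    out = (k < 0) | (k >= grid.n_bins)
    k = np.clip(k, 0, grid.n_bins - 1)
    return k, out


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

_FACTOR_ONLY = {"M0", "M1", "M5", "M6"}
_DIRECT_ONLY = {"M4"}


@dataclass(frozen=True)
class ModelSpec:
    """Identifies one estimator variant.

    ``strategy`` distinguishes direct prediction from the fitted
    coefficients at the record's exact covariates ("direct", the "A"
    variants) from prediction through a per-MIC factor table built at bin
    midpoints ("factor", the "B" variants).  ``session_scope`` chooses
    between one joint fit with session-specific intercepts and fully
    separate per-session fits.
    """

    model_id: str
    strategy: str = "factor"
    session_scope: str = "joint"
    d0: float = DEFAULT_D0

    def __post_init__(self) -> None:
        if self.model_id not in {f"M{i}" for i in range(9)}:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.strategy not in ("direct", "factor"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.session_scope not in ("joint", "separate"):
            raise ValueError(f"unknown session_scope {self.session_scope!r}")
        if self.model_id in _FACTOR_ONLY and self.strategy != "factor":
            raise ValueError(f"{self.model_id} admits only the factor strategy")
        if self.model_id in _DIRECT_ONLY and self.strategy != "direct":
            raise ValueError(f"{self.model_id} admits only direct prediction")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


#: The thirteen evaluated model/strategy variants.
MODEL_VARIANTS: dict[str, ModelSpec] = {
    "M0": ModelSpec("M0"),
    "M1": ModelSpec("M1"),
    "M2A": ModelSpec("M2", strategy="direct"),
    "M2B": ModelSpec("M2", strategy="factor"),
    "M3A": ModelSpec("M3", strategy="direct"),
    "M3B": ModelSpec("M3", strategy="factor"),
    "M4": ModelSpec("M4", strategy="direct"),
    "M5": ModelSpec("M5"),
    "M6": ModelSpec("M6"),
    "M7A": ModelSpec("M7", strategy="direct"),
    "M7B": ModelSpec("M7", strategy="factor"),
    "M8A": ModelSpec("M8", strategy="direct"),
    "M8B": ModelSpec("M8", strategy="factor"),
}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_records`."""

    n_input: int
    n_kept: int
    drop_counts: dict[str, int] = field(default_factory=dict)
    records: pd.DataFrame | None = None

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def _normalize_breed(values: pd.Series) -> pd.Series:
    low = values.astype(str).str.strip().str.lower()
    out = pd.Series("other", index=values.index)
    out[low == "holstein"] = "Holstein"
    out[low == "jersey"] = "Jersey"
    return out


def validate_records(raw: pd.DataFrame) -> ValidationReport:
    """Validate a raw record table, dropping invalid rows with reasons.

    Each dropped row is counted once under its first failing rule, in the
    order: missing field, malformed numeric field, interval out of range,
    negative yield, dim out of range, parity out of range, lactation month
    out of range, invalid measured session.  Never silently coerces: a
    non-numeric entry in a numeric column drops the row.

    Raises
    ------
    EmptyDataError
        If the input table has no rows or lacks required columns.
    """
    missing_cols = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise EmptyDataError(f"input table lacks columns {missing_cols}")
    if len(raw) == 0:
        raise EmptyDataError("input table has no records")

    df = raw[RECORD_COLUMNS].copy()
    # track missing-before-coercion vs malformed
    originally_missing = df[NUMERIC_COLUMNS].isna() | (
        df[NUMERIC_COLUMNS].astype(str).apply(lambda s: s.str.strip()) == ""
    )
    for col in NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    missing_id = df["cow_id"].isna() | df["measured_session"].isna()

    coerced_na = df[NUMERIC_COLUMNS].isna()
    rule_missing = originally_missing.any(axis=1) | missing_id
    rule_malformed = (coerced_na & ~originally_missing).any(axis=1)

    session = df["measured_session"].astype(str).str.strip().str.upper()
    checks = [
        ("missing field", rule_missing),
        ("malformed numeric field", rule_malformed),
        (
            "interval out of range",
            ~(
                (df["am_interval_h"] > 0)
                & (df["am_interval_h"] < 24)
                & (df["pm_interval_h"] > 0)
                & (df["pm_interval_h"] < 24)
            ),
        ),
        ("negative yield", (df["am_yield_kg"] < 0) | (df["pm_yield_kg"] < 0)),
        ("dim out of range", ~(df["dim"] >= 1)),
        ("parity out of range", ~(df["parity"] >= 1)),
        (
            "lactation month out of range",
            ~((df["lactation_month"] >= 1) & (df["lactation_month"] <= 11)),
        ),
        ("invalid measured session", ~session.isin(SESSIONS)),
    ]

    dropped = pd.Series(False, index=df.index)
    drop_counts: dict[str, int] = {}
    for reason, mask in checks:
        mask = mask.fillna(True) & ~dropped
        n = int(mask.sum())
        if n:
            drop_counts[reason] = n
        dropped |= mask

    kept = df[~dropped].copy()
    kept["breed"] = _normalize_breed(kept["breed"])
    kept["measured_session"] = session[~dropped]
    for col in ("parity", "lactation_month", "dim"):
        kept[col] = kept[col].astype(int)
    kept.reset_index(drop=True, inplace=True)
    return ValidationReport(
        n_input=len(df), n_kept=len(kept), drop_counts=drop_counts, records=kept
    )


# ---------------------------------------------------------------------------
# File format
# ---------------------------------------------------------------------------


def read_records(path) -> pd.DataFrame:
    """Read a milking-record file (comma-delimited, header row).

    Lines starting with ``#`` are treated as metadata comments.  Missing
    values are empty fields.  The returned table is *not* validated; pass it
    through :func:`validate_records`.
    """
    df = pd.read_csv(path, comment="#", dtype={"cow_id": str, "herd_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise EmptyDataError(f"{path}: missing columns {missing}")
    return df[RECORD_COLUMNS]


def write_records(df: pd.DataFrame, path, header_comments: Sequence[str] = ()) -> None:
    """Write records in the interchange format, optionally with ``#`` metadata
    comment lines above the header."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df[RECORD_COLUMNS].to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Derived views
# ---------------------------------------------------------------------------


def daily_yield(df: pd.DataFrame) -> pd.Series:
    """Daily milk yield y = AM + PM, the estimand of every model."""
    return df["am_yield_kg"] + df["pm_yield_kg"]


def to_session_long(df: pd.DataFrame, sessions: Iterable[str] = SESSIONS) -> pd.DataFrame:
    """Stack paired records into one row per (record, session).

    Columns: ``record``, ``session``, ``x`` (session yield), ``t`` (session
    interval), ``dim``, ``lactation_month``, ``y`` (daily yield).  Training
    always uses this view — on a test day both milkings are weighed, so each
    paired record informs both the AM and the PM side of a fit.
    """
    y = daily_yield(df)
    frames = []
    for s in sessions:
        pre = s.lower()
        frames.append(
            pd.DataFrame(
                {
                    "record": df.index,
                    "session": s,
                    "x": df[f"{pre}_yield_kg"].to_numpy(),
                    "t": df[f"{pre}_interval_h"].to_numpy(),
                    "dim": df["dim"].to_numpy(),
                    "lactation_month": df["lactation_month"].to_numpy(),
                    "y": y.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def measured_view(df: pd.DataFrame) -> pd.DataFrame:
    """One row per record using only its *measured* session, as at
    prediction time in an AM-PM plan.  Same columns as
    :func:`to_session_long` (``y`` retained as ground truth)."""
    is_am = df["measured_session"].to_numpy() == "AM"
    x = np.where(is_am, df["am_yield_kg"], df["pm_yield_kg"])
    t = np.where(is_am, df["am_interval_h"], df["pm_interval_h"])
    return pd.DataFrame(
        {
            "record": df.index,
            "session": np.where(is_am, "AM", "PM"),
            "x": x,
            "t": t,
            "dim": df["dim"].to_numpy(),
            "lactation_month": df["lactation_month"].to_numpy(),
            "y": daily_yield(df).to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# Paired summaries
# ---------------------------------------------------------------------------


def _paired_stats(diff: np.ndarray) -> dict:
    n = len(diff)
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        return {
            "mean_diff": mean,
            "sd_diff": 0.0,
            "t": None,
            "p": None,
            "ci95": (mean, mean),
            "degenerate": True,
        }
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    t, p = stats.ttest_1samp(diff, 0.0)
    return {
        "mean_diff": mean,
        "sd_diff": sd,
        "t": float(t),
        "p": float(p),
        "ci95": (mean - tcrit * se, mean + tcrit * se),
        "degenerate": False,
    }


def summarize_paired_data(df: pd.DataFrame) -> dict:
    """Per-session summaries plus paired AM−PM interval and yield tests.

    Returns a nested dict: ``sessions[session][variable]`` holds mean,
    median, min, max; ``interval_diff`` and ``yield_diff`` hold the paired
    mean difference, SD, t statistic, p-value and 95% CI (t distribution).
    A zero-variance difference is reported as degenerate, not an error.
    """
    if len(df) < 2:
        raise EmptyDataError("need at least 2 records to summarize")
    out: dict = {"n": len(df), "sessions": {}}
    for s in SESSIONS:
        pre = s.lower()
        out["sessions"][s] = {}
        for var, col in (("interval_h", f"{pre}_interval_h"), ("yield_kg", f"{pre}_yield_kg")):
            v = df[col].to_numpy(dtype=float)
            out["sessions"][s][var] = {
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
            }
    out["interval_diff"] = _paired_stats(
        (df["am_interval_h"] - df["pm_interval_h"]).to_numpy(dtype=float)
    )
    out["yield_diff"] = _paired_stats(
        (df["am_yield_kg"] - df["pm_yield_kg"]).to_numpy(dtype=float)
    )
    return out
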