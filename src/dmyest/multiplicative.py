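"""Multiplicative daily-yield estimators (ratio / correction-factor models).

The multiplicative family estimates daily milk yield (DMY) as a factor F
times the single measured milking, with F ≈ 2 at equal 12–12 h intervals:

* **M5** — Shook–Jensen–Dickinson ratio factors: per-MIC bulk proportion
  ``P_j(k) = Σx / Σy`` smoothed by a quadratic in the bin midpoint;
  ``F = 1/(α + β₁t̄ + β₂t̄²)``.  AM and PM are fitted directly and
  separately.
* **M6** — DeLorenzo–Wiggans: per-MIC no-intercept regression of ``y`` on
  ``x`` and ``(d − d0)``; the reciprocals ``1/b̂_j(k)`` are smoothed by a
  straight line in the midpoint, ``F = 1/(α + β t̄)``; the per-bin DIM
  slope γ̂_jk is kept for prediction.
* **M7** — Wiggans ratio regression: ``x/y = α_j + β t + γ(d − d0) + ε``;
  direct (M7A, ``ŷ = x / (α̂_j + β̂t + γ̂(d−d0))``) or via factors (M7B,
  ``F = 1/(α̂_j + β̂ t̄)``).
* **M8** — exponential regression ``y = x^b e^{α_j + βt + γ(d−d0) + ε}``,
  fitted by OLS on the natural-log scale; direct (M8A) or via per-MIC
  factors with the lognormal moment correction ρ (M8B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import ols_fit
from .additive import Prediction, _grids
from .data_model import (
    EmptyDataError,
    ModelSpec,
    SESSIONS,
    assign_mic_array,
    to_session_long,
    measured_view,
)

__all__ = [
    "RatioFit",
    "MCFTable",
    "fit_m5",
    "fit_m6",
    "fit_m7",
    "mcf_from_ratio_fit",
    "fit_m8",
    "mcf_m8",
    "predict_multiplicative",
]

MCF_COLUMNS = [
    "session",
    "bin_lo",
    "bin_hi",
    "midpoint",
    "F",
    "rho",
    "n_train",
    "Ex",
    "Vx",
    "Ey",
    "Vy",
    "gamma",
    "d0",
    "imputed_flag",
    "model_id",
]


@dataclass
class RatioFit:
    """Coefficients of one multiplicative-family fit.

    ``params[session]`` holds alpha/beta/gamma (plus ``b`` and
    ``resid_var`` for M8, ``beta2`` for M5's quadratic smoother); joint
    fits store shared slopes under both sessions.  M6 keeps its per-bin
    coefficients in ``per_bin`` (columns session, mic, b, gamma, n) in
    addition to the reciprocal-smoothing line in ``params``.
    """

    spec: ModelSpec
    params: dict[str, dict[str, float]] = field(default_factory=dict)
    se: dict[str, dict[str, float]] = field(default_factory=dict)
    per_bin: pd.DataFrame | None = None
    resid_var: float = float("nan")
    nobs: int = 0
    n_excluded: int = 0
    warning: str | None = None


@dataclass
class MCFTable:
    """Per-MIC multiplicative factors F_j(k) for one model.

    Carries per-bin training moments (Ex, Vx, Ey, Vy) and ρ where the
    exponential model uses them, plus γ and d0 for the residual DIM
    adjustment.  Bins without training data are imputed from the smoothing
    function (or nearest-bin moments for M8) and flagged.
    """

    table: pd.DataFrame
    d0: float
    model_id: str

    def __post_init__(self) -> None:
        if np.any(self.table["F"].to_numpy() <= 0):
            bad = self.table[self.table["F"] <= 0]
            raise ValueError(
                f"non-positive factor in bins {bad['midpoint'].tolist()}"
            )

    def factor(self, session: str, k: int) -> float:
        sub = self.table[self.table["session"] == session].sort_values("bin_lo")
        return float(sub["F"].to_numpy()[k])

    def to_csv(self, path, header_comments=()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.table[MCF_COLUMNS].to_csv(fh, index=False)


def _bin_moments(long: pd.DataFrame, grids) -> pd.DataFrame:
    """Per (session, bin) training statistics used by the factor tables."""
    rows = []
    for s in SESSIONS:
        g = grids[s]
        sub = long[long["session"] == s]
        k, _ = assign_mic_array(sub["t"].to_numpy(), g)
        x = sub["x"].to_numpy()
        y = sub["y"].to_numpy()
        d = sub["dim"].to_numpy(dtype=float)
        for kk in range(g.n_bins):
            m = k == kk
            n = int(m.sum())
            rows.append(
                {
                    "session": s,
                    "mic": kk,
                    "bin_lo": g.edges[kk],
                    "bin_hi": g.edges[kk + 1],
                    "midpoint": g.midpoints[kk],
                    "n": n,
                    "sum_x": x[m].sum(),
                    "sum_y": y[m].sum(),
                    "Ex": x[m].mean() if n else np.nan,
                    "Vx": x[m].var(ddof=1) if n > 1 else np.nan,
                    "Ey": y[m].mean() if n else np.nan,
                    "Vy": y[m].var(ddof=1) if n > 1 else np.nan,
                    "mean_dim": d[m].mean() if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# M5: bulk proportions with quadratic smoothing
# ---------------------------------------------------------------------------


def fit_m5(
    records: pd.DataFrame, grid, weighted: bool = False
) -> tuple[RatioFit, MCFTable]:
    """Shook–Jensen–Dickinson factors from per-bin bulk proportions.

    Per bin the session's bulk proportion of the daily total is
    ``P_j(k) = Σx / Σy``; a quadratic in the bin midpoint is fitted to the
    populated bins (optionally weighted by bin counts) and
    ``F_j(k) = 1/(quadratic at t̄)``.  Sessions are fitted separately.
    Requires ≥3 populated bins per session; a non-positive smoothed
    denominator on any populated bin is an error.
    """
    if len(records) == 0:
        raise EmptyDataError("no training records for M5")
    grids = _grids(grid)
    long = to_session_long(records)
    mom = _bin_moments(long, grids)

    fit = RatioFit(spec=ModelSpec("M5", session_scope="separate"))
    rows = []
    for s in SESSIONS:
        sub = mom[(mom["session"] == s) & (mom["n"] > 0)]
        if len(sub) < 3:
            raise EmptyDataError(
                f"M5 needs >=3 populated {s} bins, got {len(sub)}"
            )
        tbar = sub["midpoint"].to_numpy()
        prop = (sub["sum_x"] / sub["sum_y"]).to_numpy()
        w = sub["n"].to_numpy(dtype=float) if weighted else None
        c2, c1, c0 = np.polyfit(tbar, prop, deg=2, w=w)
        fit.params[s] = {"alpha": float(c0), "beta": float(c1), "beta2": float(c2)}
        allbins = mom[mom["session"] == s]
        denom = c0 + c1 * allbins["midpoint"] + c2 * allbins["midpoint"] ** 2
        populated = allbins["n"].to_numpy() > 0
        if np.any(denom.to_numpy()[populated] <= 0):
            raise ValueError(f"M5 smoothed proportion non-positive in {s} bins")
        for (_, r), dn in zip(allbins.iterrows(), denom):
            if dn <= 0:  # unpopulated tail bin beyond the quadratic's root
                continue
            rows.append(
                {
                    "session": s,
                    "bin_lo": r["bin_lo"],
                    "bin_hi": r["bin_hi"],
                    "midpoint": r["midpoint"],
                    "F": 1.0 / dn,
                    "rho": np.nan,
                    "n_train": r["n"],
                    "Ex": r["Ex"],
                    "Vx": r["Vx"],
                    "Ey": r["Ey"],
                    "Vy": r["Vy"],
                    "gamma": 0.0,
                    "d0": fit.spec.d0,
                    "imputed_flag": r["n"] == 0,
                    "model_id": "M5",
                }
            )
    fit.nobs = len(long)
    return fit, MCFTable(pd.DataFrame(rows), d0=fit.spec.d0, model_id="M5")


# ---------------------------------------------------------------------------
# M6: per-bin no-intercept regression with reciprocal smoothing
# ---------------------------------------------------------------------------


def _no_intercept_ols(x, y, dc, with_dim: bool):
    """Closed-form no-intercept OLS of y on x (and d − d0)."""
    if with_dim and np.ptp(dc) > 1e-12:
        X = np.column_stack([x, dc])
    else:
        X = x[:, None]
        with_dim = False
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        return None
    coef = np.linalg.solve(xtx, X.T @ y)
    b = float(coef[0])
    g = float(coef[1]) if with_dim else 0.0
    return b, g


def fit_m6(records: pd.DataFrame, grid) -> tuple[RatioFit, MCFTable]:
    """DeLorenzo–Wiggans factors via per-MIC no-intercept regressions.

    Within each populated bin (≥2 records), ``y = b_jk·x + γ_jk(d−d0) + ε``
    is fitted without intercept; the reciprocals 1/b̂ are then smoothed by
    a straight line in the bin midpoint, giving ``F_j(k) = 1/(α̂ + β̂t̄)``.
    Bins where Σx² is zero are skipped and marked; smoothing needs ≥2
    usable bins per session.
    """
    if len(records) == 0:
        raise EmptyDataError("no training records for M6")
    grids = _grids(grid)
    long = to_session_long(records)
    mom = _bin_moments(long, grids)

    fit = RatioFit(spec=ModelSpec("M6", session_scope="separate"))
    per_bin_rows = []
    rows = []
    for s in SESSIONS:
        g = grids[s]
        sub = long[long["session"] == s]
        k, _ = assign_mic_array(sub["t"].to_numpy(), g)
        usable_t, usable_recip = [], []
        bin_gamma = np.zeros(g.n_bins)
        bin_b = np.full(g.n_bins, np.nan)
        for kk in range(g.n_bins):
            m = k == kk
            if m.sum() < 2:
                continue
            x = sub["x"].to_numpy()[m]
            y = sub["y"].to_numpy()[m]
            dc = sub["dim"].to_numpy(dtype=float)[m] - fit.spec.d0
            if np.sum(x**2) <= 0:
                continue  # skipped and marked by the nan in bin_b
            res = _no_intercept_ols(x, y, dc, with_dim=True)
            if res is None:
                continue
            b_jk, g_jk = res
            bin_b[kk], bin_gamma[kk] = b_jk, g_jk
            per_bin_rows.append(
                {"session": s, "mic": kk, "b": b_jk, "gamma": g_jk,
                 "n": int(m.sum())}
            )
            if b_jk > 0:
                usable_t.append(g.midpoints[kk])
                usable_recip.append(1.0 / b_jk)
        if len(usable_t) < 2:
            raise EmptyDataError(
                f"M6 reciprocal smoothing needs >=2 usable {s} bins"
            )
        line_b, line_a = np.polyfit(usable_t, usable_recip, deg=1)
        fit.params[s] = {"alpha": float(line_a), "beta": float(line_b)}
        allbins = mom[mom["session"] == s]
        for _, r in allbins.iterrows():
            denom = line_a + line_b * r["midpoint"]
            if denom <= 0:
                if r["n"] > 0:
                    raise ValueError(
                        f"M6 smoothed reciprocal non-positive at {s} "
                        f"midpoint {r['midpoint']}"
                    )
                continue
            kk = int(r["mic"])
            rows.append(
                {
                    "session": s,
                    "bin_lo": r["bin_lo"],
                    "bin_hi": r["bin_hi"],
                    "midpoint": r["midpoint"],
                    "F": 1.0 / denom,
                    "rho": np.nan,
                    "n_train": r["n"],
                    "Ex": r["Ex"],
                    "Vx": r["Vx"],
                    "Ey": r["Ey"],
                    "Vy": r["Vy"],
                    "gamma": bin_gamma[kk],
                    "d0": fit.spec.d0,
                    "imputed_flag": bool(np.isnan(bin_b[kk])),
                    "model_id": "M6",
                }
            )
    fit.per_bin = pd.DataFrame(per_bin_rows)
    fit.nobs = len(long)
    return fit, MCFTable(pd.DataFrame(rows), d0=fit.spec.d0, model_id="M6")


# ---------------------------------------------------------------------------
# M7: ratio regression
# ---------------------------------------------------------------------------


def fit_m7(records: pd.DataFrame, spec: ModelSpec | None = None) -> RatioFit:
    """OLS of the single-to-daily ratio x/y on session intercepts, t, d−d0.

    Records with y = 0 are excluded (counted in ``n_excluded``).
    """
    if spec is None:
        spec = ModelSpec("M7", strategy="direct")
    if spec.model_id != "M7":
        raise ValueError("fit_m7 fits model M7")
    if len(records) == 0:
        raise EmptyDataError("no training records for M7")
    long = to_session_long(records)
    ok = long["y"].to_numpy() > 0
    n_excluded = int((~ok).sum())
    long = long[ok]
    if len(long) == 0:
        raise EmptyDataError("all records had zero daily yield")
    ratio = long["x"].to_numpy() / long["y"].to_numpy()

    fit = RatioFit(spec=spec, n_excluded=n_excluded)
    if spec.session_scope == "joint":
        groups = [(SESSIONS, long, ratio)]
    else:
        groups = [
            ((s,), long[long["session"] == s],
             ratio[(long["session"] == s).to_numpy()])
            for s in SESSIONS
        ]
    resid_vars = []
    for sessions, sub, resp in groups:
        cols = {f"alpha_{s}": (sub["session"] == s).to_numpy(float) for s in sessions}
        cols["beta"] = sub["t"].to_numpy(float)
        cols["gamma"] = sub["dim"].to_numpy(float) - spec.d0
        res = ols_fit(cols, resp, tuple(f"alpha_{s}" for s in sessions))
        for s in sessions:
            fit.params[s] = {
                "alpha": res["params"][f"alpha_{s}"],
                "beta": res["params"]["beta"],
                "gamma": res["params"]["gamma"],
            }
            fit.se[s] = {
                "alpha": res["se"][f"alpha_{s}"],
                "beta": res["se"]["beta"],
                "gamma": res["se"]["gamma"],
            }
        fit.nobs += res["nobs"]
        resid_vars.append(res["resid_var"])
    fit.resid_var = float(np.mean(resid_vars))
    return fit


def mcf_from_ratio_fit(
    fit: RatioFit, grid, training_records: pd.DataFrame | None = None,
    dim_adjust: bool = True,
) -> MCFTable:
    """Discretize an M7 fit: ``F_j(k) = 1/(α̂_j + β̂·t̄_j(k))``.

    The fitted ratio line must be positive over every populated bin (or
    every bin when no training records are given); a violating bin is
    named in the error.  ``dim_adjust=False`` zeroes the γ carried into
    prediction (the ratio-scale γ̂ applied on the kg scale is the cited
    construction but dimensionally questionable).
    """
    if fit.spec.model_id != "M7":
        raise ValueError("mcf_from_ratio_fit expects an M7 fit")
    grids = _grids(grid)
    mom = (
        _bin_moments(to_session_long(training_records), grids)
        if training_records is not None
        else None
    )
    rows = []
    for s in SESSIONS:
        g = grids[s]
        p = fit.params[s]
        for kk in range(g.n_bins):
            tbar = g.midpoints[kk]
            denom = p["alpha"] + p["beta"] * tbar
            r = (
                mom[(mom["session"] == s) & (mom["mic"] == kk)].iloc[0]
                if mom is not None
                else None
            )
            n = int(r["n"]) if r is not None else 0
            if denom <= 0:
                if mom is None or n > 0:
                    raise ValueError(
                        f"M7 ratio line non-positive at {s} midpoint {tbar}"
                    )
                continue  # unpopulated tail bin beyond the line's root
            rows.append(
                {
                    "session": s,
                    "bin_lo": g.edges[kk],
                    "bin_hi": g.edges[kk + 1],
                    "midpoint": tbar,
                    "F": 1.0 / denom,
                    "rho": np.nan,
                    "n_train": n,
                    "Ex": r["Ex"] if r is not None else np.nan,
                    "Vx": r["Vx"] if r is not None else np.nan,
                    "Ey": r["Ey"] if r is not None else np.nan,
                    "Vy": r["Vy"] if r is not None else np.nan,
                    "gamma": p["gamma"] if dim_adjust else 0.0,
                    "d0": fit.spec.d0,
                    "imputed_flag": mom is not None and n == 0,
                    "model_id": "M7",
                }
            )
    return MCFTable(pd.DataFrame(rows), d0=fit.spec.d0, model_id="M7")


# ---------------------------------------------------------------------------
# M8: exponential regression
# ---------------------------------------------------------------------------


def fit_m8(records: pd.DataFrame, spec: ModelSpec | None = None) -> RatioFit:
    """OLS of log y on session intercepts, t, d−d0, and log x (natural log).

    Records with non-positive x or y are excluded and counted; if more than
    1% are excluded a warning is attached to the fit (``fit.warning``).
    """
    if spec is None:
        spec = ModelSpec("M8", strategy="direct")
    if spec.model_id != "M8":
        raise ValueError("fit_m8 fits model M8")
    if len(records) == 0:
        raise EmptyDataError("no training records for M8")
    long = to_session_long(records)
    ok = (long["x"].to_numpy() > 0) & (long["y"].to_numpy() > 0)
    n_excluded = int((~ok).sum())
    frac = n_excluded / len(long)
    long = long[ok]
    if len(long) == 0:
        raise EmptyDataError("all records had non-positive yields")

    fit = RatioFit(spec=spec, n_excluded=n_excluded)
    if frac > 0.01:
        fit.warning = (
            f"{n_excluded} records ({frac:.1%}) excluded for non-positive yields"
        )
    if spec.session_scope == "joint":
        groups = [(SESSIONS, long)]
    else:
        groups = [((s,), long[long["session"] == s]) for s in SESSIONS]
    resid_vars = []
    for sessions, sub in groups:
        cols = {f"alpha_{s}": (sub["session"] == s).to_numpy(float) for s in sessions}
        cols["beta"] = sub["t"].to_numpy(float)
        cols["gamma"] = sub["dim"].to_numpy(float) - spec.d0
        cols["b"] = np.log(sub["x"].to_numpy(float))
        res = ols_fit(
            cols, np.log(sub["y"].to_numpy(float)),
            tuple(f"alpha_{s}" for s in sessions),
        )
        for s in sessions:
            fit.params[s] = {
                "alpha": res["params"][f"alpha_{s}"],
                "beta": res["params"]["beta"],
                "gamma": res["params"]["gamma"],
                "b": res["params"]["b"],
            }
            fit.se[s] = {
                "alpha": res["se"][f"alpha_{s}"],
                "beta": res["se"]["beta"],
                "gamma": res["se"]["gamma"],
                "b": res["se"]["b"],
            }
        fit.nobs += res["nobs"]
        resid_vars.append(res["resid_var"])
    fit.resid_var = float(np.mean(resid_vars))
    return fit


def mcf_m8(fit: RatioFit, grid, training_records: pd.DataFrame) -> MCFTable:
    """Per-MIC factors for the exponential model with lognormal correction.

    ``ρ_j(k) = exp(½(V(y)/E(y)² − b̂·V(x)/E(x)²))`` and
    ``F_j(k) = E(x)^{b̂−1} · ρ_j(k) · exp(α̂_j + β̂·t̄_j(k))``, with per-bin
    moments from the training records.  A bin with fewer than two records
    (variance undefined) is treated as unpopulated and borrows the nearest
    populated bin's moments, flagged imputed.
    """
    if fit.spec.model_id != "M8":
        raise ValueError("mcf_m8 expects an M8 fit")
    grids = _grids(grid)
    mom = _bin_moments(to_session_long(training_records), grids)
    rows = []
    for s in SESSIONS:
        g = grids[s]
        p = fit.params[s]
        sub = mom[mom["session"] == s].set_index("mic")
        populated = sub.index[sub["n"] >= 2].to_numpy()
        if len(populated) == 0:
            raise EmptyDataError(f"no {s} bin has >=2 training records")
        for kk in range(g.n_bins):
            imputed = kk not in populated
            src = (
                int(populated[np.argmin(np.abs(populated - kk))])
                if imputed
                else kk
            )
            r = sub.loc[src]
            rho = float(
                np.exp(0.5 * (r["Vy"] / r["Ey"] ** 2 - p["b"] * r["Vx"] / r["Ex"] ** 2))
            )
            F = (
                r["Ex"] ** (p["b"] - 1.0)
                * rho
                * np.exp(p["alpha"] + p["beta"] * g.midpoints[kk])
            )
            rows.append(
                {
                    "session": s,
                    "bin_lo": g.edges[kk],
                    "bin_hi": g.edges[kk + 1],
                    "midpoint": g.midpoints[kk],
                    "F": float(F),
                    "rho": rho,
                    "n_train": int(sub.loc[kk]["n"]) if kk in sub.index else 0,
                    "Ex": r["Ex"],
                    "Vx": r["Vx"],
                    "Ey": r["Ey"],
                    "Vy": r["Vy"],
                    "gamma": p["gamma"],
                    "d0": fit.spec.d0,
                    "imputed_flag": imputed,
                    "model_id": "M8",
                }
            )
    return MCFTable(pd.DataFrame(rows), d0=fit.spec.d0, model_id="M8")


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_multiplicative(
    records: pd.DataFrame,
    fit: RatioFit,
    mcf_table: MCFTable | None = None,
    grid=None,
) -> Prediction:
    """Estimate DMY for each record from its measured session.

    * M5: ŷ = F_j(k)·x
    * M6: ŷ = F_j(k)·x + γ̂_jk(d − d0)
    * M7 direct: ŷ = x/(α̂_j + β̂t + γ̂(d−d0)); a non-positive denominator
      is an error naming the offending record
    * M7 factor: ŷ = F_j(k)·x + γ̂(d − d0)
    * M8 direct: ŷ = x^b̂·exp(α̂_j + β̂t + γ̂(d−d0))
    * M8 factor: ŷ = F_j(k)·x·exp(γ̂(d − d0))

    Factor strategies clamp out-of-grid intervals to the terminal bin and
    flag the estimate.
    """
    spec = fit.spec
    mv = measured_view(records)
    x = mv["x"].to_numpy()
    t = mv["t"].to_numpy()
    dc = mv["dim"].to_numpy(dtype=float) - spec.d0
    out_flags = np.zeros(len(mv), dtype=bool)
    yhat = np.empty(len(mv))

    if spec.model_id == "M7" and spec.strategy == "direct":
        for s in SESSIONS:
            mask = (mv["session"] == s).to_numpy()
            if not mask.any():
                continue
            p = fit.params[s]
            denom = p["alpha"] + p["beta"] * t[mask] + p["gamma"] * dc[mask]
            if np.any(denom <= 0):
                bad = mv.loc[mask].index[denom <= 0][0]
                raise ValueError(
                    f"M7A denominator non-positive for record {bad} "
                    f"(t={t[mask][denom <= 0][0]:.2f} h)"
                )
            yhat[mask] = x[mask] / denom
        return Prediction(yhat, out_flags)

    if spec.model_id == "M8" and spec.strategy == "direct":
        for s in SESSIONS:
            mask = (mv["session"] == s).to_numpy()
            if not mask.any():
                continue
            p = fit.params[s]
            yhat[mask] = x[mask] ** p["b"] * np.exp(
                p["alpha"] + p["beta"] * t[mask] + p["gamma"] * dc[mask]
            )
        return Prediction(yhat, out_flags)

    # factor strategies: M5, M6, M7B, M8B
    if mcf_table is None or grid is None:
        raise ValueError("factor-strategy prediction needs an MCFTable and grid")
    grids = _grids(grid)
    for s in SESSIONS:
        mask = (mv["session"] == s).to_numpy()
        if not mask.any():
            continue
        g = grids[s]
        sub = mcf_table.table[mcf_table.table["session"] == s].sort_values("bin_lo")
        if len(sub) != g.n_bins:
            # table truncated where the smoothing function crossed zero
            sub_edges = sub["bin_lo"].to_numpy()
            k_all, out = assign_mic_array(t[mask], g)
            idx = np.searchsorted(sub_edges, g.edges[:-1][k_all], side="right") - 1
            out |= idx < 0
            idx = np.clip(idx, 0, len(sub) - 1)
        else:
            idx, out = assign_mic_array(t[mask], g)
        out_flags[mask] = out
        F = sub["F"].to_numpy()[idx]
        gam = sub["gamma"].to_numpy()[idx]
        base = F * x[mask]
        if spec.model_id in ("M6", "M7"):
            yhat[mask] = base + gam * dc[mask]
        elif spec.model_id == "M8":
            yhat[mask] = base * np.exp(gam * dc[mask])
        else:  # M5
            yhat[mask] = base
    return Prediction(yhat, out_flags)
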