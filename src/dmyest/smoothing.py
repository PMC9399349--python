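"""Cubic smoothing splines and mean-curve comparisons over milking interval.

A cubic smoothing spline minimizes ``Σ(yᵢ − f(xᵢ))² + λ∫f″(x)²dx`` over
twice-differentiable functions: λ → 0 interpolates, λ → ∞ tends to the
straight least-squares line.  Here splines serve as a weak-assumption
reference curve — the "CSS mean" of a response (daily yield, or per-record
R² accuracy) as a function of milking interval — against which each
model's implied mean-yield curve is compared by average absolute
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .data_model import EmptyDataError, MICGrid, assign_mic_array, build_mic_grid

__all__ = [
    "SplineFit",
    "fit_css",
    "css_mean_curve",
    "model_mean_curve",
    "curve_deviation",
    "default_interval_grid",
]

def default_interval_grid(
    lo: float = 9.0, hi: float = 15.0, step: float = 0.1
) -> np.ndarray:
    """Evaluation abscissae for interval curves (hours), 9–15 h by default."""
    return np.round(np.arange(lo, hi + step / 2, step), 10)


@dataclass
class SplineFit:
    """A fitted cubic smoothing spline, callable at arbitrary intervals."""

    spline: object  # scipy BSpline
    lam: float | None
    method: str
    x_range: tuple[float, float]

    def __call__(self, x) -> np.ndarray:
        return np.asarray(self.spline(np.asarray(x, dtype=float)))


def fit_css(xs, ys, method: str = "GCV", lam: float | None = None) -> SplineFit:
    """Fit a cubic smoothing spline of ``ys`` on ``xs``.

    Duplicate abscissae are collapsed to their mean with multiplicity
    weights before fitting.  ``method`` selects λ: ``"GCV"`` (generalized
    cross-validation, the default), or ``"fixed"`` with an explicit
    ``lam``.  REML selection is not provided; requesting it raises.
    Needs at least 4 distinct x values.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D arrays")
    df = pd.DataFrame({"x": xs, "y": ys}).groupby("x")["y"].agg(["mean", "count"])
    if len(df) < 5:
        raise EmptyDataError(
            f"need >=5 distinct x values for a cubic smoothing spline, got {len(df)}"
        )
    x = df.index.to_numpy()
    y = df["mean"].to_numpy()
    w = df["count"].to_numpy(dtype=float)
    if method == "GCV":
        lam_used = None
    elif method == "fixed":
        if lam is None or lam < 0:
            raise ValueError("fixed-λ fitting needs lam >= 0")
        lam_used = lam
    elif method == "REML":
        raise NotImplementedError(
            "REML smoothing-parameter selection is not provided; use GCV or fixed λ"
        )
    else:
        raise ValueError(f"unknown λ selection method {method!r}")
    spline = make_smoothing_spline(x, y, w=w, lam=lam_used)
    return SplineFit(
        spline=spline, lam=lam_used, method=method,
        x_range=(float(x[0]), float(x[-1])),
    )


def css_mean_curve(
    records: pd.DataFrame,
    response: str,
    session: str,
    grid_points: np.ndarray | None = None,
    values: np.ndarray | None = None,
    method: str = "GCV",
    lam: float | None = None,
    round_x_h: float = 0.05,
) -> pd.DataFrame:
    """CSS mean of a response versus one session's milking interval.

    Intervals are pre-rounded to ``round_x_h`` (default 0.05 h, ~3 min —
    finer than any interval-recording resolution) so repeated abscissae
    collapse to weighted means; GCV on thousands of densely spaced distinct
    abscissae is numerically ill-posed.

    ``response="daily_yield"`` smooths the actual daily yield;
    ``response="individual_r2"`` smooths externally supplied per-record
    values (``values``, aligned with ``records``) — typically per-record R²
    accuracies from a :class:`~dmyest.evaluation.CVReport`.  The curve is
    evaluated on ``grid_points`` (default 9–15 h by 0.1 h) truncated to the
    observed interval range: no extrapolation.

    Returns a DataFrame with columns ``interval_h`` and ``value``.
    """
    t = records[f"{session.lower()}_interval_h"].to_numpy(dtype=float)
    if response == "daily_yield":
        resp = (records["am_yield_kg"] + records["pm_yield_kg"]).to_numpy(float)
    elif response == "individual_r2":
        if values is None:
            raise ValueError("individual_r2 smoothing needs the per-record values")
        resp = np.asarray(values, dtype=float)
        if len(resp) != len(records):
            raise ValueError("values must align with records")
    else:
        raise ValueError(f"unknown response {response!r}")
    if round_x_h and round_x_h > 0:
        t = np.round(t / round_x_h) * round_x_h
    fit = fit_css(t, resp, method=method, lam=lam)
    grid = default_interval_grid() if grid_points is None else np.asarray(grid_points)
    inside = (grid >= fit.x_range[0]) & (grid <= fit.x_range[1])
    grid = grid[inside]
    return pd.DataFrame({"interval_h": grid, "value": fit(grid)})


def model_mean_curve(
    fitted_variant,
    records: pd.DataFrame,
    session: str,
    grid_points: np.ndarray | None = None,
    window_grid: MICGrid | None = None,
    plug_in_means: bool = False,
) -> pd.DataFrame:
    """Model-implied mean DMY as a function of one session's interval.

    At each grid interval t, the model's prediction is averaged over the
    empirical (x, d) distribution of the records whose ``session`` interval
    falls in the MIC bin containing t (the local window); with
    ``plug_in_means=True`` the prediction is instead evaluated once at the
    window's mean covariates.  Grid points with an empty window are
    omitted.  ``fitted_variant`` is a :class:`~dmyest.evaluation.FittedVariant`.
    """
    from .evaluation import predict_variant

    grid = default_interval_grid() if grid_points is None else np.asarray(grid_points)
    window_grid = window_grid if window_grid is not None else build_mic_grid()
    pre = session.lower()
    t_all = records[f"{pre}_interval_h"].to_numpy(dtype=float)
    k_all, out = assign_mic_array(t_all, window_grid)
    k_all = np.where(out, -1, k_all)  # out-of-grid records join no window

    rows = []
    for t in grid:
        k, t_out = (
            assign_mic_array(np.asarray([t]), window_grid)[0][0],
            assign_mic_array(np.asarray([t]), window_grid)[1][0],
        )
        if t_out:
            continue
        members = records[k_all == k]
        if len(members) == 0:
            continue
        pseudo = members.copy()
        pseudo[f"{pre}_interval_h"] = t
        pseudo["measured_session"] = session.upper()
        if plug_in_means:
            pseudo = pseudo.iloc[[0]].copy()
            pseudo[f"{pre}_yield_kg"] = members[f"{pre}_yield_kg"].mean()
            pseudo["dim"] = int(round(members["dim"].mean()))
        est = predict_variant(fitted_variant, pseudo)
        rows.append({"interval_h": float(t), "value": float(np.mean(est))})
    return pd.DataFrame(rows)


def curve_deviation(
    model_curve: pd.DataFrame, css_curve: pd.DataFrame, atol: float = 1e-9
) -> float:
    """Mean absolute deviation (kg) between two curves on their common grid.

    Curves are ``interval_h``/``value`` frames; grid points are matched to
    ``atol``.  Disjoint grids are an error.
    """
    a = model_curve.set_index(model_curve["interval_h"].round(6))["value"]
    b = css_curve.set_index(css_curve["interval_h"].round(6))["value"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("curves share no grid points")
    return float(np.mean(np.abs(a.loc[common].to_numpy() - b.loc[common].to_numpy())))


def plot_curves(curves: dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Write a simple overlay plot of interval curves (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, cur in curves.items():
        ax.plot(cur["interval_h"], cur["value"], label=name)
    ax.set_xlabel("milking interval (h)")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
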