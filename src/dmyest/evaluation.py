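"""Replicated k-fold cross-validation of the daily-yield estimators.

Every model/strategy variant is fitted on the training folds only (factor
tables and bin statistics included — no test leakage) and evaluated on the
held-out fold; each record is therefore tested exactly once per replicate.
Replicating the whole rotation with fresh random partitions separates the
two error sources: across replicates, the mean squared error decomposes as

    MSE = Var + Bias²,

with ``Var = (1/nm)ΣᵢΣᵣ(ŷᵢᵣ − ȳ̂ᵢ)²`` (spread of a record's estimates
across replicates: precision) and ``Bias² = (1/n)Σᵢ(ȳ̂ᵢ − yᵢ)²`` (distance
of the replicate-mean estimate from the truth).  Accuracy is reported as
``R² = σ²/(σ² + MSE)``, which — unlike correlation — penalizes bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import additive, multiplicative
from .data_model import (
    EmptyDataError,
    MICGrid,
    MODEL_VARIANTS,
    build_mic_grid,
    daily_yield,
)

__all__ = [
    "CVPlan",
    "CVReport",
    "make_folds",
    "run_crossval",
    "decompose_mse",
    "r2_accuracy",
    "individual_accuracy",
    "compare_models",
    "render_table",
    "fit_variant",
    "predict_variant",
]


@dataclass(frozen=True)
class CVPlan:
    """k folds × replicates; ``unit`` partitions by record or by cow."""

    k: int = 10
    replicates: int = 30
    unit: str = "record"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.unit not in ("record", "cow"):
            raise ValueError("fold unit must be 'record' or 'cow'")


def make_folds(
    units: np.ndarray | int, plan: CVPlan, rng: np.random.Generator
) -> np.ndarray:
    """Random fold labels (0..k−1) for each unit, sizes within one of
    each other."""
    n = units if isinstance(units, (int, np.integer)) else len(units)
    if plan.k > n:
        raise ValueError(f"k={plan.k} folds exceed {n} units")
    labels = np.resize(np.arange(plan.k), n)
    return labels[rng.permutation(n)]


# ---------------------------------------------------------------------------
# Variant fitting/prediction dispatch
# ---------------------------------------------------------------------------


@dataclass
class FittedVariant:
    name: str
    fit: object = None
    table: object = None
    grid: object = None


def fit_variant(
    name: str,
    train: pd.DataFrame,
    grid: MICGrid | dict | None = None,
    options: dict | None = None,
) -> FittedVariant:
    """Fit one named variant (M0, M1, M2A..M8B) on a training table.

    ``options`` may set ``session_scope``, ``d0``, ``acf_convention``,
    ``m5_weighted``, ``m7b_dim_adjust``.
    """
    if name not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {name!r}")
    opts = dict(options or {})
    grid = grid if grid is not None else build_mic_grid()
    spec = MODEL_VARIANTS[name]
    overrides = {
        k: opts[k] for k in ("session_scope", "d0") if k in opts
    }
    if overrides:
        import dataclasses

        spec = dataclasses.replace(spec, **overrides)
    fv = FittedVariant(name=name, grid=grid)

    if name == "M0":
        return fv
    if name == "M1":
        fv.fit = additive.fit_m1(train, grid)
    elif name in ("M2A", "M2B", "M3A", "M3B", "M4"):
        fv.fit = additive.fit_additive_regression(train, spec)
        if spec.strategy == "factor":
            fv.table = additive.acf_from_fit(
                fv.fit, grid, train, convention=opts.get("acf_convention", "text")
            )
    elif name == "M5":
        fv.fit, fv.table = multiplicative.fit_m5(
            train, grid, weighted=opts.get("m5_weighted", False)
        )
    elif name == "M6":
        fv.fit, fv.table = multiplicative.fit_m6(train, grid)
    elif name in ("M7A", "M7B"):
        fv.fit = multiplicative.fit_m7(train, spec)
        if spec.strategy == "factor":
            fv.table = multiplicative.mcf_from_ratio_fit(
                fv.fit, grid, train,
                dim_adjust=opts.get("m7b_dim_adjust", True),
            )
    elif name in ("M8A", "M8B"):
        fv.fit = multiplicative.fit_m8(train, spec)
        if spec.strategy == "factor":
            fv.table = multiplicative.mcf_m8(fv.fit, grid, train)
    return fv


def predict_variant(fv: FittedVariant, test: pd.DataFrame) -> np.ndarray:
    """Point estimates of DMY for the test records' measured sessions."""
    if fv.name == "M0":
        from .data_model import measured_view

        return additive.predict_m0(measured_view(test)["x"].to_numpy())
    if fv.name in ("M1", "M2A", "M2B", "M3A", "M3B", "M4"):
        return additive.predict_additive(
            test, fv.fit, acf_table=fv.table, grid=fv.grid
        ).estimate
    return multiplicative.predict_multiplicative(
        test, fv.fit, mcf_table=fv.table, grid=fv.grid
    ).estimate


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------


def decompose_mse(estimates: np.ndarray, actual: np.ndarray) -> dict:
    """Variance / squared-bias decomposition across replicates.

    ``estimates`` is (n records × m replicates).  Both routes to the MSE —
    direct double sum and Var + Bias² — are computed and their identity
    asserted to 1e-8 relative tolerance.
    """
    est = np.asarray(estimates, dtype=float)
    y = np.asarray(actual, dtype=float)
    if est.ndim != 2 or est.shape[0] != len(y):
        raise ValueError("estimates must be (n records, m replicates)")
    if est.shape[1] == 0 or np.isnan(est).any():
        raise ValueError("every record needs >=1 replicate estimate")
    n, m = est.shape
    rec_mean = est.mean(axis=1)
    var = float(np.sum((est - rec_mean[:, None]) ** 2) / (n * m))
    bias2 = float(np.mean((rec_mean - y) ** 2))
    mse = float(np.sum((est - y[:, None]) ** 2) / (n * m))
    if not np.isclose(var + bias2, mse, rtol=1e-8, atol=1e-12):
        raise AssertionError("MSE decomposition identity violated")
    return {"var": var, "bias2": bias2, "mse": mse}


def r2_accuracy(mse: float | np.ndarray, sigma2: float) -> float | np.ndarray:
    """R² accuracy = σ²/(σ² + MSE); σ² is the error-free DMY variance."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    mse = np.asarray(mse, dtype=float)
    if np.any(mse < 0):
        raise ValueError("MSE must be >= 0")
    out = sigma2 / (sigma2 + mse)
    return float(out) if out.ndim == 0 else out


def individual_accuracy(mse_i: np.ndarray, sigma2: float) -> dict:
    """Per-record R² from replicate-averaged per-record MSE, with
    distribution summaries (mean, median, SD, fraction ≥ 0.90)."""
    r2 = r2_accuracy(np.asarray(mse_i, dtype=float), sigma2)
    return {
        "r2": r2,
        "mean": float(np.mean(r2)),
        "median": float(np.median(r2)),
        "sd": float(np.std(r2, ddof=1)) if len(r2) > 1 else 0.0,
        "frac_ge_090": float(np.mean(r2 >= 0.90)),
    }


# ---------------------------------------------------------------------------
# The cross-validation engine
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Everything the replicated cross-validation produced.

    ``estimates[model]`` is the (n × m) matrix of test-fold estimates;
    ``per_replicate`` holds pooled per-replicate MSE/R²/correlation;
    ``summary`` one row per model with the Var/Bias²/MSE decomposition and
    mean (SD) accuracy and correlation across replicates.
    """

    plan: CVPlan
    sigma2: float
    actual: np.ndarray
    estimates: dict[str, np.ndarray] = field(default_factory=dict)
    per_replicate: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    failures: list = field(default_factory=list)

    def individual(self, model: str) -> dict:
        """Per-record accuracy summaries for one model."""
        est = self.estimates[model]
        mse_i = np.mean((est - self.actual[:, None]) ** 2, axis=1)
        return individual_accuracy(mse_i, self.sigma2)


def run_crossval(
    records: pd.DataFrame,
    model_names: list[str],
    plan: CVPlan,
    grid: MICGrid | dict | None = None,
    options: dict | None = None,
    sigma2_mode: str = "full",
    custom_estimators: dict | None = None,
) -> CVReport:
    """Replicated k-fold cross-validation over the named variants.

    ``custom_estimators`` maps extra names to ``(fit_fn, predict_fn)`` test
    hooks with the :func:`fit_variant`/:func:`predict_variant` signatures.
    A model-fit failure on a split is recorded in ``report.failures`` and
    that (model, replicate) is excluded from the decomposition; the run
    continues.
    """
    if len(records) == 0:
        raise EmptyDataError("no records for cross-validation")
    if sigma2_mode not in ("full", "fold"):
        raise ValueError("sigma2_mode must be 'full' or 'fold'")
    records = records.reset_index(drop=True)
    grid = grid if grid is not None else build_mic_grid()
    custom = custom_estimators or {}
    y = daily_yield(records).to_numpy(dtype=float)
    n = len(records)
    sigma2 = float(np.var(y, ddof=1))
    rng = np.random.default_rng(plan.seed)

    report = CVReport(plan=plan, sigma2=sigma2, actual=y)
    est = {m: np.full((n, plan.replicates), np.nan) for m in model_names}
    bad = {m: np.zeros(plan.replicates, dtype=bool) for m in model_names}
    fold_sigma2 = np.empty(plan.replicates)

    cows = records["cow_id"].to_numpy()
    for r in range(plan.replicates):
        if plan.unit == "cow":
            uniq = pd.unique(cows)
            cow_fold = dict(zip(uniq, make_folds(len(uniq), plan, rng)))
            folds = np.array([cow_fold[c] for c in cows])
        else:
            folds = make_folds(n, plan, rng)
        sig_parts = []
        for j in range(plan.k):
            test_mask = folds == j
            train = records[~test_mask]
            test = records[test_mask]
            if len(test) == 0:
                continue
            sig_parts.append(np.var(y[test_mask], ddof=1))
            for m in model_names:
                try:
                    if m in custom:
                        fit_fn, pred_fn = custom[m]
                        fv = fit_fn(m, train, grid, options)
                        est[m][test_mask, r] = pred_fn(fv, test)
                    else:
                        fv = fit_variant(m, train, grid, options)
                        est[m][test_mask, r] = predict_variant(fv, test)
                except Exception as exc:  # noqa: BLE001 — recorded, not fatal
                    report.failures.append(
                        {"model": m, "replicate": r, "fold": j, "error": str(exc)}
                    )
                    bad[m][r] = True
        fold_sigma2[r] = float(np.mean(sig_parts))

    # per-replicate pooled metrics
    rep_rows = []
    for m in model_names:
        for r in range(plan.replicates):
            if bad[m][r] or np.isnan(est[m][:, r]).any():
                continue
            e = est[m][:, r]
            mse_r = float(np.mean((e - y) ** 2))
            s2 = sigma2 if sigma2_mode == "full" else float(fold_sigma2[r])
            rep_rows.append(
                {
                    "model": m,
                    "replicate": r,
                    "mse": mse_r,
                    "r2": r2_accuracy(mse_r, s2),
                    "cor": float(np.corrcoef(e, y)[0, 1]),
                }
            )
    report.per_replicate = pd.DataFrame(rep_rows)

    # decomposition over clean replicates
    sum_rows = []
    for m in model_names:
        ok = ~bad[m]
        est_ok = est[m][:, ok]
        report.estimates[m] = est_ok
        if est_ok.shape[1] == 0 or np.isnan(est_ok).any():
            sum_rows.append({"model": m, "var": np.nan, "bias2": np.nan,
                             "mse": np.nan, "acc_mean": np.nan,
                             "acc_sd": np.nan, "cor_mean": np.nan,
                             "cor_sd": np.nan, "n_replicates": 0})
            continue
        dec = decompose_mse(est_ok, y)
        pr = report.per_replicate
        sub = pr[pr["model"] == m]
        sum_rows.append(
            {
                "model": m,
                "var": dec["var"],
                "bias2": dec["bias2"],
                "mse": dec["mse"],
                "acc_mean": float(sub["r2"].mean()),
                "acc_sd": float(sub["r2"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "cor_mean": float(sub["cor"].mean()),
                "cor_sd": float(sub["cor"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "n_replicates": int(est_ok.shape[1]),
            }
        )
    report.summary = pd.DataFrame(sum_rows)
    return report


def compare_models(
    report: CVReport, model_a: str, model_b: str, level: str = "replicate"
) -> dict:
    """Paired t-test between two models' accuracies.

    ``level="replicate"`` pairs per-replicate pooled R²;
    ``level="individual"`` pairs per-record R².  Zero-variance differences
    are reported as degenerate rather than crashing.
    """
    if level == "replicate":
        pr = report.per_replicate
        a = pr[pr["model"] == model_a].sort_values("replicate")["r2"].to_numpy()
        b = pr[pr["model"] == model_b].sort_values("replicate")["r2"].to_numpy()
        if len(a) != len(b):
            raise ValueError("models were not evaluated on the same replicates")
    elif level == "individual":
        a = individual_accuracy(
            np.mean((report.estimates[model_a] - report.actual[:, None]) ** 2, axis=1),
            report.sigma2,
        )["r2"]
        b = individual_accuracy(
            np.mean((report.estimates[model_b] - report.actual[:, None]) ** 2, axis=1),
            report.sigma2,
        )["r2"]
    else:
        raise ValueError("level must be 'replicate' or 'individual'")
    diff = a - b
    if np.std(diff, ddof=1) == 0 or len(diff) < 2:
        return {
            "t": None,
            "df": len(diff) - 1,
            "p": None,
            "mean_diff": float(np.mean(diff)),
            "degenerate": True,
        }
    t, p = stats.ttest_rel(a, b)
    return {
        "t": float(t),
        "df": len(diff) - 1,
        "p": float(p),
        "mean_diff": float(np.mean(diff)),
        "degenerate": False,
    }


def render_table(report: CVReport) -> pd.DataFrame:
    """Readable report: model, Var, Bias², MSE, Acc (SE), Cor (SE)."""
    s = report.summary
    return pd.DataFrame(
        {
            "model": s["model"],
            "Var": s["var"].round(4),
            "Bias2": s["bias2"].round(3),
            "MSE": s["mse"].round(3),
            "Acc (SE)": [
                f"{a:.3f} ({sd:.4f})" for a, sd in zip(s["acc_mean"], s["acc_sd"])
            ],
            "Cor (SE)": [
                f"{c:.3f} ({sd:.4f})" for c, sd in zip(s["cor_mean"], s["cor_sd"])
            ],
        }
    )
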