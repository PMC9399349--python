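"""Internal least-squares helper shared by the model families.

Wraps statsmodels OLS with the package's degenerate-design rule: a
zero-variation covariate column (constant, hence collinear with the
intercept block) is dropped with coefficient 0 rather than crashing; any
*remaining* rank deficiency raises :class:`SingularDesignError`.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .data_model import SingularDesignError

_PTP_TOL = 1e-12


def ols_fit(
    columns: dict[str, np.ndarray],
    y: np.ndarray,
    intercept_names: tuple[str, ...],
) -> dict:
    """OLS of ``y`` on the named columns.

    ``intercept_names`` identify the indicator/intercept block, which is
    never dropped.  Returns ``{"params": {name: est}, "se": {name: se},
    "resid_var": s2, "nobs": n, "dropped": [names]}`` with dropped
    covariates reported at coefficient 0 and SE nan.
    """
    y = np.asarray(y, dtype=float)
    names = list(columns)
    dropped = [
        n
        for n in names
        if n not in intercept_names
        and np.ptp(np.asarray(columns[n], dtype=float)) < _PTP_TOL
    ]
    kept = [n for n in names if n not in dropped]
    X = np.column_stack([np.asarray(columns[n], dtype=float) for n in kept])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (columns: {kept})"
        )
    res = sm.OLS(y, X).fit()
    with np.errstate(divide="ignore", invalid="ignore"):  # df_resid may be 0
        params = {n: float(res.params[i]) for i, n in enumerate(kept)}
        se = {n: float(res.bse[i]) for i, n in enumerate(kept)}
    for n in dropped:
        params[n] = 0.0
        se[n] = float("nan")
    return {
        "params": params,
        "se": se,
        "resid_var": 0.0 if res.df_resid <= 0 else float(res.mse_resid),
        "nobs": int(res.nobs),
        "dropped": dropped,
    }
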