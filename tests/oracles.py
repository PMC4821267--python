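"""Independent brute-force oracles used by the test suite.

The mixed-model oracle evaluates the exact Gaussian log-likelihood with
dense covariance matrices (explicit inversion and slogdet) on a fine grid of
the variance ratio, with closed-form GLS at each grid point.  It shares no
code with the package's grouped profile-likelihood implementation.
"""

import numpy as np
import pandas as pd


def lmm_design(table: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    col_of = {"TLN": "tln_m", "time": "time_of_day", "day": "day", "previsual": "previsual_m"}
    cols = ["diff_m", "individual_id"] + [col_of[t] for t in terms]
    sub = table[cols].dropna()
    y = sub["diff_m"].to_numpy(float)
    X = np.column_stack([np.ones(len(sub))] + [sub[col_of[t]].to_numpy(float) for t in terms])
    codes = pd.factorize(sub["individual_id"])[0]
    Z = np.zeros((len(sub), codes.max() + 1))
    Z[np.arange(len(sub)), codes] = 1.0
    return y, X, Z


def profile_loglik_dense(theta: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                         reml: bool) -> float:
    """Exact profiled log-likelihood at variance ratio theta, dense algebra."""
    n, p = X.shape
    V0 = np.eye(n) + theta * Z @ Z.T
    V0inv = np.linalg.inv(V0)
    _, logdetV0 = np.linalg.slogdet(V0)
    XtVX = X.T @ V0inv @ X
    beta = np.linalg.solve(XtVX, X.T @ V0inv @ y)
    r = y - X @ beta
    quad = float(r @ V0inv @ r)
    if reml:
        dof = n - p
        sigma2 = quad / dof
        _, logdetXVX = np.linalg.slogdet(XtVX)
        return -0.5 * (dof * np.log(2 * np.pi) + dof * np.log(sigma2)
                       + logdetV0 + logdetXVX + dof)
    sigma2 = quad / n
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdetV0 + n)


def grid_max_loglik(table: pd.DataFrame, terms: tuple[str, ...] = ("TLN",),
                    reml: bool = False, n_grid: int = 200) -> float:
    """Best profiled log-likelihood over a fine grid of the variance ratio."""
    y, X, Z = lmm_design(table, terms)
    thetas = np.concatenate([[0.0], np.geomspace(1e-6, 1e3, n_grid - 1)])
    return max(profile_loglik_dense(t, y, X, Z, reml) for t in thetas)
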