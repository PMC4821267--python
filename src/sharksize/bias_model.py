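"""Mixed-model quantification of size-dependent error in visual length estimates.

The response is ``diff``, the absolute difference between a sighting's visual
length estimate and its (collapsed) stereo-video length TLN.  Candidate
models are Gaussian linear mixed-effects models with a random intercept for
shark identity,

    diff_ij = x_ij' beta + b_i + eps_ij,
    b_i ~ N(0, sigma2_id),  eps_ij ~ N(0, sigma2_eps),

where i indexes individuals and j repeat sightings.  Fixed-effect predictors
are drawn from {TLN, time of day, field-day index, previous visual estimate}.
Models are ranked by AICc and BIC weights and described by Nakagawa's
marginal/conditional R².

Fitting profiles the (restricted) likelihood over the single variance ratio
``theta = sigma2_id / sigma2_eps``: for fixed theta the GLS fixed effects and
the residual variance have closed forms, so the optimisation is a
deterministic one-dimensional bounded search with no random initialisation.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: formula term -> column of the paired table
TERM_COLUMNS: dict[str, str] = {
    "TLN": "tln_m",
    "time": "time_of_day",
    "day": "day",
    "previsual": "previsual_m",
}
RESPONSE_COLUMN = "diff_m"
GROUP_COLUMN = "individual_id"

#: the five candidate formulas of the default comparison set
DEFAULT_MODEL_SET = (
    "diff ~ TLN + (1|ID)",
    "diff ~ TLN + time + (1|ID)",
    "diff ~ TLN + time + day + (1|ID)",
    "diff ~ TLN + time + day + previsual + (1|ID)",
    "diff ~ 1 + (1|ID)",
)

_FORMULA_RE = re.compile(
    r"^\s*(?P<resp>\w+)\s*~\s*(?P<rhs>.+?)\s*\+\s*\(\s*1\s*\|\s*(?P<group>\w+)\s*\)\s*$"
)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: ordered fixed-effect terms plus a random intercept.

    The intercept is always included and is not listed in ``fixed_terms``.
    """

    fixed_terms: tuple[str, ...] = ()
    random_intercept_group: str = "ID"

    def __post_init__(self) -> None:
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError(f"duplicate fixed terms in {self.fixed_terms}")
        unknown = [t for t in self.fixed_terms if t not in TERM_COLUMNS]
        if unknown:
            raise ValueError(f"unknown model terms {unknown}; known: {sorted(TERM_COLUMNS)}")

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse e.g. ``"diff ~ TLN + time + (1|ID)"``."""
        m = _FORMULA_RE.match(formula)
        if not m:
            raise ValueError(
                f"cannot parse formula {formula!r}; expected 'diff ~ terms + (1|ID)'"
            )
        if m.group("resp") != "diff":
            raise ValueError(f"response must be 'diff', got {m.group('resp')!r}")
        terms = tuple(t.strip() for t in m.group("rhs").split("+") if t.strip() != "1")
        return cls(fixed_terms=terms, random_intercept_group=m.group("group"))

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"diff ~ {rhs} + (1|{self.random_intercept_group})"

    @property
    def n_fixed(self) -> int:
        return 1 + len(self.fixed_terms)

    @property
    def k(self) -> int:
        """Parameter count: fixed coefficients + random-intercept variance
        + residual variance."""
        return self.n_fixed + 2


@dataclass(frozen=True)
class LMMFit:
    """A fitted random-intercept mixed model."""

    spec: ModelSpec
    beta: np.ndarray           # (intercept, then spec.fixed_terms), metres per unit
    beta_names: tuple[str, ...]
    sigma2_id: float           # between-individual variance, m^2
    sigma2_eps: float          # residual variance, m^2
    loglik: float
    criterion_type: str        # "ML" or "REML"
    n_obs: int
    k: int
    fixed_predictor: np.ndarray  # X @ beta over the rows actually fitted

    @property
    def theta(self) -> float:
        return self.sigma2_id / self.sigma2_eps


@dataclass(frozen=True)
class ModelComparisonRow:
    """One candidate model's row in the ranked comparison table."""

    spec: ModelSpec
    aicc: float
    bic: float
    w_aicc: float
    w_bic: float
    rm2: float
    rc2: float
    loglik: float
    n_obs: int


@dataclass(frozen=True)
class BiasLine:
    """Ordinary least-squares line of diff on stereo length (the bias trend)."""

    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class SpearmanScreen:
    """Rank-correlation collinearity screen over candidate predictors."""

    matrix: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    undefined: list[tuple[str, str]]
    threshold: float


def _design(spec: ModelSpec, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise complete design for one spec: (y, X, group codes)."""
    cols = [RESPONSE_COLUMN, GROUP_COLUMN] + [TERM_COLUMNS[t] for t in spec.fixed_terms]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"paired table lacks columns {missing}")
    sub = table[cols].dropna()
    n_dropped = len(table) - len(sub)
    if n_dropped:
        logger.info("%s: dropped %d rows with missing model variables", spec.formula, n_dropped)
    y = sub[RESPONSE_COLUMN].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[TERM_COLUMNS[t]].to_numpy(dtype=float) for t in spec.fixed_terms]
    )
    groups = pd.factorize(sub[GROUP_COLUMN])[0]
    return y, X, groups


def _profile(theta: float, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
             reml: bool) -> tuple[float, np.ndarray, float]:
    """Profiled objective at a variance ratio theta >= 0.

    Returns (loglik, beta_hat, sigma2_eps_hat).  Uses the grouped Woodbury
    form (I + theta*J)^-1 = I - theta/(1 + n_g*theta) * J per individual, so
    each evaluation is O(n).
    """
    n, p = X.shape
    XtWX = X.T @ X
    XtWy = X.T @ y
    yWy = float(y @ y)
    logdetV = 0.0
    for g in np.unique(groups):
        idx = groups == g
        ng = int(idx.sum())
        c = theta / (1.0 + ng * theta)
        sx = X[idx].sum(axis=0)
        sy = float(y[idx].sum())
        XtWX -= c * np.outer(sx, sx)
        XtWy -= c * sx * sy
        yWy -= c * sy * sy
        logdetV += math.log1p(ng * theta)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(yWy - 2.0 * float(beta @ XtWy) + float(beta @ XtWX @ beta), 1e-300)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdetXWX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (dof * math.log(2 * math.pi) + dof * math.log(sigma2)
                     + logdetV + logdetXWX + dof)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + logdetV + n)
    return ll, beta, sigma2


def fit_lmm(
    spec: ModelSpec,
    table: pd.DataFrame,
    criterion_type: str = "ML",
    fixed_ratio: float | None = None,
) -> LMMFit:
    """Fit a random-intercept LMM by profiling over the variance ratio.

    Parameters
    ----------
    spec
        Fixed-effect terms and grouping.
    table
        Paired analysis table; rows with missing model variables are dropped
        row-wise (and counted in the log).
    criterion_type
        ``"ML"`` (default, comparable across fixed-effect structures) or
        ``"REML"``.
    fixed_ratio
        If given, the variance ratio ``sigma2_id/sigma2_eps`` is held at this
        value instead of estimated; ``fixed_ratio=0`` reproduces ordinary
        least squares.

    Raises
    ------
    ValueError
        If every individual is a singleton (the two variance components are
        then unidentifiable), or if fewer rows than parameters remain.
    """
    if criterion_type not in ("ML", "REML"):
        raise ValueError("criterion_type must be 'ML' or 'REML'")
    y, X, groups = _design(spec, table)
    n, p = X.shape
    if n < spec.k + 1:
        raise ValueError(f"{spec.formula}: {n} rows is fewer than k+1 = {spec.k + 1} parameters")
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ValueError("need at least 2 individuals")
    counts = np.bincount(groups)
    reml = criterion_type == "REML"
    if fixed_ratio is None and counts.max() == 1:
        raise ValueError(
            "every individual appears exactly once: the between-individual and "
            "residual variances are unidentifiable (no replicate structure)"
        )

    if fixed_ratio is not None:
        theta = float(fixed_ratio)
        ll, beta, sigma2 = _profile(theta, y, X, groups, reml)
    else:
        # deterministic bounded search on log(theta), plus the theta=0 boundary
        def negll_log(phi: float) -> float:
            return -_profile(math.exp(phi), y, X, groups, reml)[0]

        res = optimize.minimize_scalar(
            negll_log, bounds=(-14.0, 14.0), method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(math.exp(res.x))
        ll, beta, sigma2 = _profile(theta, y, X, groups, reml)
        ll0, beta0, sigma2_0 = _profile(0.0, y, X, groups, reml)
        if ll0 >= ll:
            theta, ll, beta, sigma2 = 0.0, ll0, beta0, sigma2_0
    sigma2 = max(sigma2, 1e-300)
    fit = LMMFit(
        spec=spec,
        beta=beta,
        beta_names=("intercept",) + spec.fixed_terms,
        sigma2_id=theta * sigma2,
        sigma2_eps=sigma2,
        loglik=ll,
        criterion_type=criterion_type,
        n_obs=n,
        k=spec.k,
        fixed_predictor=X @ beta,
    )
    logger.debug("fitted %s: loglik=%.4f sigma2_id=%.4f sigma2_eps=%.4f",
                 spec.formula, ll, fit.sigma2_id, fit.sigma2_eps)
    return fit


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction:
    ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion ``-2 loglik + k ln(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * math.log(n)


def ic_weights(ic_values: Sequence[float]) -> np.ndarray:
    """Normalised evidence weights ``exp(-delta_i/2) / sum_j exp(-delta_j/2)``.

    Invariant under adding a constant to every criterion value.
    """
    ic = np.asarray(ic_values, dtype=float)
    if ic.size == 0:
        raise ValueError("empty criterion list")
    if not np.all(np.isfinite(ic)):
        raise ValueError("non-finite information criterion value")
    rel = np.exp(-0.5 * (ic - ic.min()))
    return rel / rel.sum()


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional R² for a random-intercept LMM.

    With ``sigma2_f`` the variance of the fixed-effect linear predictor over
    the fitted rows::

        Rm² = sigma2_f / (sigma2_f + sigma2_id + sigma2_eps)
        Rc² = (sigma2_f + sigma2_id) / (sigma2_f + sigma2_id + sigma2_eps)
    """
    sigma2_f = float(np.var(fit.fixed_predictor))  # population variance of X beta
    total = sigma2_f + fit.sigma2_id + fit.sigma2_eps
    if total <= 0:
        raise ValueError("zero total variance: R² undefined")
    return sigma2_f / total, (sigma2_f + fit.sigma2_id) / total


def rank_models(
    specs: Sequence[ModelSpec | str] | None = None,
    table: pd.DataFrame | None = None,
    criterion_type: str = "ML",
) -> list[ModelComparisonRow]:
    """Fit a candidate set on a common row set and rank by AICc weight.

    All specs are fitted on the same rows: any row missing a variable used by
    *any* spec in the set is dropped globally, so criteria are comparable.
    Specs that fail to fit are excluded from the weights with a warning.
    Defaults to the five-model candidate set in :data:`DEFAULT_MODEL_SET`.
    """
    if table is None:
        raise ValueError("rank_models requires the paired table")
    resolved = [
        ModelSpec.from_formula(s) if isinstance(s, str) else s
        for s in (specs if specs is not None else DEFAULT_MODEL_SET)
    ]
    used_cols = {RESPONSE_COLUMN, GROUP_COLUMN}
    for spec in resolved:
        used_cols.update(TERM_COLUMNS[t] for t in spec.fixed_terms)
    common = table.dropna(subset=[c for c in used_cols if c in table.columns])
    logger.info("model set fitted on %d of %d rows (global row-wise deletion)", len(common), len(table))

    fits: list[tuple[ModelSpec, LMMFit]] = []
    for spec in resolved:
        try:
            fits.append((spec, fit_lmm(spec, common, criterion_type=criterion_type)))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("excluding %s from comparison: %s", spec.formula, exc)
    if not fits:
        raise ValueError("no model in the set could be fitted")
    aicc_vals = [aicc(f.loglik, f.k, f.n_obs) for _, f in fits]
    bic_vals = [bic(f.loglik, f.k, f.n_obs) for _, f in fits]
    w_a = ic_weights(aicc_vals)
    w_b = ic_weights(bic_vals)
    rows = []
    for (spec, f), a, b, wa, wb in zip(fits, aicc_vals, bic_vals, w_a, w_b):
        rm2, rc2 = r2_nakagawa(f)
        rows.append(ModelComparisonRow(spec, a, b, float(wa), float(wb), rm2, rc2,
                                       f.loglik, f.n_obs))
    rows.sort(key=lambda r: r.w_aicc, reverse=True)
    return rows


def comparison_frame(rows: Sequence[ModelComparisonRow]) -> pd.DataFrame:
    """Ranked comparison as a DataFrame (model, wAICc, wBIC, Rm2, Rc2, ...)."""
    return pd.DataFrame(
        {
            "model": [r.spec.formula for r in rows],
            "wAICc": [r.w_aicc for r in rows],
            "wBIC": [r.w_bic for r in rows],
            "Rm2": [r.rm2 for r in rows],
            "Rc2": [r.rc2 for r in rows],
            "AICc": [r.aicc for r in rows],
            "BIC": [r.bic for r in rows],
            "loglik": [r.loglik for r in rows],
            "n": [r.n_obs for r in rows],
        }
    )


def ols_bias_line(table: pd.DataFrame, signed: bool = False) -> BiasLine:
    """OLS regression of the visual-estimate error on stereo length.

    ``signed=True`` regresses the signed error (TLN − visual) instead of the
    absolute difference.  R² is the squared Pearson correlation.
    """
    col = "signed_diff_m" if signed else RESPONSE_COLUMN
    sub = table[[col, "tln_m"]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    x = sub["tln_m"].to_numpy(dtype=float)
    y = sub[col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("stereo length is constant: slope undefined")
    res = stats.linregress(x, y)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue) ** 2
    return BiasLine(slope=float(res.slope), intercept=float(res.intercept), r2=r2)


def spearman_screen(
    table: pd.DataFrame,
    predictors: Sequence[str] = ("TLN", "time", "day", "previsual"),
    threshold: float = 0.7,
) -> SpearmanScreen:
    """Pairwise Spearman rank correlations among candidate predictors.

    A pair is flagged as collinear when ``|rho| >= threshold``; constant
    predictors make the correlation undefined and are reported separately.
    """
    cols = {p: TERM_COLUMNS[p] for p in predictors}
    matrix = pd.DataFrame(np.eye(len(predictors)), index=list(predictors), columns=list(predictors))
    flagged: list[tuple[str, str, float]] = []
    undefined: list[tuple[str, str]] = []
    names = list(predictors)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sub = table[[cols[a], cols[b]]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete rows for predictor pair ({a}, {b})")
            xa = sub[cols[a]].to_numpy(dtype=float)
            xb = sub[cols[b]].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                matrix.loc[a, b] = matrix.loc[b, a] = np.nan
                undefined.append((a, b))
                continue
            rho = float(stats.spearmanr(xa, xb).statistic)
            matrix.loc[a, b] = matrix.loc[b, a] = rho
            if abs(rho) >= threshold:
                flagged.append((a, b, rho))
    return SpearmanScreen(matrix=matrix, flagged=flagged, undefined=undefined,
                          threshold=float(threshold))
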