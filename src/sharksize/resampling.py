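"""Bootstrap procedures for method comparison and mean uncertainty.

Two 10,000-iteration nonparametric bootstraps:

* :func:`resample_mean_difference` — the difference of mean lengths between
  the two measurement methods: each iteration independently resamples each
  method's sample with replacement (resample size = original size) and
  records ``mean(b*) - mean(a*)``; positive values mean the second sample
  (stereo) exceeds the first (visual), i.e. visual underestimation.
* :func:`bootstrap_mean_se` — the bootstrap standard error of a sample mean:
  the standard deviation of 10,000 resampled means.

Percentile intervals use the nearest-order-statistic (inverse empirical CDF)
quantile rule so that endpoints are always order statistics of the draws and
results are reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_ITER = 10_000


@dataclass(frozen=True)
class ResampleResult:
    """Distribution of a bootstrapped statistic with a percentile interval."""

    statistic_name: str
    n_iter: int
    draws: np.ndarray
    point: float          # mean of draws
    se: float             # standard deviation of draws
    interval: tuple[float, float]
    level: float
    seed: int

    def summary(self) -> str:
        lo, hi = self.interval
        return (
            f"{self.statistic_name}: {self.point:.3f} +/- {self.se:.3f} "
            f"({100 * self.level:.0f}% percentile interval {lo:.3f} to {hi:.3f}; "
            f"{self.n_iter} iterations, seed {self.seed})"
        )


def percentile_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Central percentile bounds at the given coverage level.

    Uses the inverse-empirical-CDF rule: both endpoints are order statistics
    of ``draws`` at the (1-level)/2 and 1-(1-level)/2 quantiles.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    if not np.all(np.isfinite(draws)):
        raise ValueError("non-finite draws")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo = float(np.quantile(draws, alpha, method="inverted_cdf"))
    hi = float(np.quantile(draws, 1.0 - alpha, method="inverted_cdf"))
    return lo, hi


def _check_sample(sample: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} holds non-finite values")
    return arr


def resample_mean_difference(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    level: float = 0.95,
    seed: int = 0,
) -> ResampleResult:
    """Bootstrap distribution of ``mean(sample_b) - mean(sample_a)``.

    By convention ``sample_a`` is the visual sample and ``sample_b`` the
    stereo sample, so positive draws quantify visual underestimation.
    """
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    means_a = a[rng.integers(0, a.size, size=(n_iter, a.size))].mean(axis=1)
    means_b = b[rng.integers(0, b.size, size=(n_iter, b.size))].mean(axis=1)
    draws = means_b - means_a
    return ResampleResult(
        statistic_name="mean difference (stereo - visual)",
        n_iter=int(n_iter),
        draws=draws,
        point=float(draws.mean()),
        se=float(draws.std(ddof=1)) if n_iter > 1 else 0.0,
        interval=percentile_interval(draws, level) if n_iter > 1 else (float(draws[0]),) * 2,
        level=float(level),
        seed=int(seed),
    )


def bootstrap_mean_se(
    sample: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    level: float = 0.95,
    seed: int = 0,
) -> ResampleResult:
    """Bootstrap the mean of a sample; ``se`` is the sd of the resampled means.

    For a sample with standard deviation s the bootstrap SE converges to the
    plug-in value ``sqrt((n-1)/n) * s / sqrt(n)`` as the iteration count grows.
    """
    arr = _check_sample(sample, "sample")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws = arr[rng.integers(0, arr.size, size=(n_iter, arr.size))].mean(axis=1)
    return ResampleResult(
        statistic_name="bootstrapped mean",
        n_iter=int(n_iter),
        draws=draws,
        point=float(draws.mean()),
        se=float(draws.std(ddof=1)) if n_iter > 1 else 0.0,
        interval=percentile_interval(draws, level) if n_iter > 1 else (float(draws[0]),) * 2,
        level=float(level),
        seed=int(seed),
    )


def normal_sample_with_moments(
    n: int,
    mean: float,
    sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """A normal-shaped sample rescaled to the exact sample mean and sd.

    Draws n standard-normal values, then applies the affine map that makes
    the sample mean equal ``mean`` and the sample standard deviation (ddof=1)
    equal ``sd`` exactly.  Used to reconstruct bootstrap results from
    published summary statistics when the raw sample is unavailable.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n)
    s = z.std(ddof=1)
    if s == 0:  # pragma: no cover - probability zero
        raise ValueError("degenerate draw")
    return mean + (z - z.mean()) * (sd / s)
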