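"""The four simulation studies, as parameterized, seeded experiment drivers.

1. Subtractive sweep — (A, E) bivariate normal, I = A - E, regression
   I ~ E against the beta = -1 benchmark across a correlation grid: the
   benchmark is rejected at far above the nominal rate whenever A and E
   covary, although additivity holds by construction.
2. Independent sweep — (I, E) bivariate normal at several SD ratios,
   regression I ~ E against beta = 0: the slope is rho * sigma_I/sigma_E,
   unconstrained by additivity.
3. Shared-error study — a fixed population generated from
   I = p_i (r - E) with measurement noise, three pairwise population
   slopes (I~E, E~A, I~A) plus their bootstrap distributions at small n.
4. Loose-additivity study — A regressed on the noisy composite
   I_obs + E_obs across a measurement-noise grid, showing regression
   dilution of the slope-1 benchmark.

Every driver keys its PRNG substreams by condition parameters (see
:mod:`slopebench.rng`), emits per-condition Monte Carlo standard errors,
and carries an analytic expected-slope column from
:mod:`slopebench.theory` so simulation and closed form can be compared
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generate import TriadSample, make_shared_error_population
from .regression import fit_slope, fit_slopes_batch
from .rng import child_seed, key_from_float, substream
from .theory import (
    CovarianceSpec,
    SharedErrorParams,
    SharedErrorSlopes,
    attenuation_expected_slope,
    expected_slope_independent,
    expected_slope_subtractive,
    shared_error_expected_slopes,
)

__all__ = [
    "SweepResult",
    "BootstrapSlopes",
    "LooseAdditivityResult",
    "ResidualDiagnostics",
    "default_rho_grid",
    "run_subtractive_sweep",
    "run_independent_sweep",
    "run_shared_error_study",
    "run_loose_additivity_study",
    "residual_diagnostics",
]

# substream tags, one per experiment family
_TAG_SUBTRACTIVE = 1
_TAG_INDEPENDENT = 2
_TAG_SHARED = 3
_TAG_LOOSE = 4


def default_rho_grid() -> np.ndarray:
    """Correlation grid -0.9 .. 0.9 in steps of 0.1."""
    return np.round(np.arange(-9, 10) / 10.0, 10)


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point summary of a slope-benchmark sweep."""

    rho_grid: np.ndarray
    expected_slope: np.ndarray
    mean_slope: np.ndarray
    sd_slope: np.ndarray
    rejection_rate: np.ndarray
    n: int
    iterations: int
    benchmark: float
    alpha: float
    seed: int
    design: str  # "subtractive" | "independent"
    variance_ratio: float | None = None

    def __post_init__(self) -> None:
        m = len(self.rho_grid)
        for name in ("expected_slope", "mean_slope", "sd_slope", "rejection_rate"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} must match the grid length")
        rr = np.asarray(self.rejection_rate)
        if np.any((rr < 0) | (rr > 1)):
            raise ValueError("rejection rates must lie in [0, 1]")

    @property
    def mc_se_slope(self) -> np.ndarray:
        """Monte Carlo SE of the mean simulated slope, per grid point."""
        return np.asarray(self.sd_slope) / np.sqrt(self.iterations)

    @property
    def rejection_se(self) -> np.ndarray:
        """Binomial SE of the rejection-rate estimate, per grid point."""
        p = np.asarray(self.rejection_rate)
        return np.sqrt(p * (1.0 - p) / self.iterations)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rho": self.rho_grid,
                "expected_slope": self.expected_slope,
                "mean_slope": self.mean_slope,
                "sd_slope": self.sd_slope,
                "mc_se_slope": self.mc_se_slope,
                "rejection_rate": self.rejection_rate,
                "rejection_se": self.rejection_se,
            }
        )
        df["n"] = self.n
        df["iterations"] = self.iterations
        df["benchmark"] = self.benchmark
        df["alpha"] = self.alpha
        df["design"] = self.design
        if self.variance_ratio is not None:
            df["variance_ratio"] = self.variance_ratio
        return df


@dataclass(frozen=True)
class BootstrapSlopes:
    """Population slopes and their bootstrap distributions (shared-error)."""

    slopes_i_on_e: np.ndarray
    slopes_e_on_a: np.ndarray
    slopes_i_on_a: np.ndarray
    population_slopes: SharedErrorSlopes
    expected_slopes: SharedErrorSlopes
    population_n: int
    n_sub: int
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        for name in ("slopes_i_on_e", "slopes_e_on_a", "slopes_i_on_a"):
            if len(getattr(self, name)) != self.iterations:
                raise ValueError(f"{name} must have `iterations` entries")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "slope_i_on_e": self.slopes_i_on_e,
                "slope_e_on_a": self.slopes_e_on_a,
                "slope_i_on_a": self.slopes_i_on_a,
            }
        )

    def iqr(self, which: str) -> tuple[float, float]:
        """Bootstrap interquartile range of one slope distribution."""
        arr = getattr(self, f"slopes_{which}")
        return tuple(np.quantile(arr, [0.25, 0.75]))


@dataclass(frozen=True)
class LooseAdditivityResult:
    """Attenuation of the A ~ (I_obs + E_obs) slope across noise levels."""

    noise_grid: np.ndarray
    predicted_slope: np.ndarray
    slopes: np.ndarray  # shape (len(noise_grid), iterations)
    n_sub: int
    iterations: int
    seed: int

    def median_slope(self) -> np.ndarray:
        return np.median(self.slopes, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: one row per (noise level, iteration)."""
        m = len(self.noise_grid)
        return pd.DataFrame(
            {
                "noise_sd_deg": np.repeat(self.noise_grid, self.iterations),
                "predicted_slope": np.repeat(self.predicted_slope, self.iterations),
                "iteration": np.tile(np.arange(self.iterations), m),
                "slope": self.slopes.ravel(),
            }
        )

    def summary(self) -> pd.DataFrame:
        q25, q75 = np.quantile(self.slopes, [0.25, 0.75], axis=1)
        sd = self.slopes.std(axis=1, ddof=1)
        return pd.DataFrame(
            {
                "noise_sd_deg": self.noise_grid,
                "predicted_slope": self.predicted_slope,
                "mean_slope": self.slopes.mean(axis=1),
                "median_slope": self.median_slope(),
                "sd_slope": sd,
                "mc_se_slope": sd / np.sqrt(self.iterations),
                "q25": q25,
                "q75": q75,
                "n_sub": self.n_sub,
                "iterations": self.iterations,
            }
        )


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Structure of the additivity residual epsilon = A - I - E.

    Under exact additivity the residual is identically zero; a
    multiplicative gating term shows up as correlation with I*E, a
    saturating combination as correlation with I+E.
    """

    mean_residual: float
    corr_with_i: float
    corr_with_e: float
    corr_with_product: float
    corr_with_sum: float


def _sample_bivariate_stack(
    spec: CovarianceSpec, iterations: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(iterations, n) stacked draws; C-order so longer runs extend shorter."""
    if abs(spec.rho) == 1.0:
        z = rng.standard_normal((iterations, n))
        x = spec.mean_x + spec.sd_x * z
        y = spec.mean_y + spec.sd_y * np.copysign(1.0, spec.rho) * z
        return x, y
    z = rng.standard_normal((iterations, n, 2))
    x = spec.mean_x + spec.sd_x * z[..., 0]
    y = spec.mean_y + spec.sd_y * (
        spec.rho * z[..., 0] + np.sqrt(1.0 - spec.rho**2) * z[..., 1]
    )
    return x, y


def _validate_grid(rho_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(rho_grid, dtype=float)
    if grid.size == 0 or np.any(np.abs(grid) >= 1.0):
        raise ValueError("rho grid must be non-empty with |rho| < 1")
    return grid


def run_subtractive_sweep(
    spec_base: CovarianceSpec,
    rho_grid: np.ndarray | None = None,
    n: int = 25,
    iterations: int = 10_000,
    benchmark: float = -1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> SweepResult:
    """Monte Carlo sweep of the I ~ E slope under subtractive logic.

    ``spec_base`` gives the moments of (A, E); its rho field is ignored in
    favour of each grid value.  Per grid point, `iterations` datasets of
    size ``n`` are drawn, I = A - E computed, OLS of I on E fitted, and
    the fraction of (1 - alpha) CIs excluding ``benchmark`` recorded.
    """
    grid = _validate_grid(default_rho_grid() if rho_grid is None else rho_grid)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    expected, mean_s, sd_s, rej = [], [], [], []
    for rho in grid:
        try:
            spec = CovarianceSpec(
                spec_base.mean_x, spec_base.mean_y, spec_base.sd_x, spec_base.sd_y, rho
            )
            rng = substream(seed, _TAG_SUBTRACTIVE, key_from_float(rho))
            a, e = _sample_bivariate_stack(spec, iterations, n, rng)
            slope, _, lo, hi = fit_slopes_batch(e, a - e, alpha)
        except ValueError as err:
            raise ValueError(f"subtractive sweep failed at rho={rho}: {err}") from err
        expected.append(expected_slope_subtractive(rho, spec.sd_x, spec.sd_y))
        mean_s.append(slope.mean())
        sd_s.append(slope.std(ddof=1) if iterations > 1 else 0.0)
        rej.append(np.mean((benchmark < lo) | (benchmark > hi)))
    return SweepResult(
        rho_grid=grid,
        expected_slope=np.array(expected),
        mean_slope=np.array(mean_s),
        sd_slope=np.array(sd_s),
        rejection_rate=np.array(rej),
        n=n,
        iterations=iterations,
        benchmark=benchmark,
        alpha=alpha,
        seed=seed,
        design="subtractive",
    )


def run_independent_sweep(
    spec_base: CovarianceSpec,
    rho_grid: np.ndarray | None = None,
    variance_ratio: float = 1.0,
    n: int = 25,
    iterations: int = 10_000,
    benchmark: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> SweepResult:
    """Sweep of the I ~ E slope under independent measurement.

    ``variance_ratio`` is sigma_I / sigma_E; sigma_I in ``spec_base`` is
    overridden by ``variance_ratio * sd_y``.  The default benchmark is 0,
    the expected slope when the processes are uncorrelated.
    """
    grid = _validate_grid(default_rho_grid() if rho_grid is None else rho_grid)
    if not variance_ratio > 0:
        raise ValueError("variance_ratio must be > 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    sd_i = variance_ratio * spec_base.sd_y
    expected, mean_s, sd_s, rej = [], [], [], []
    for rho in grid:
        try:
            spec = CovarianceSpec(
                spec_base.mean_x, spec_base.mean_y, sd_i, spec_base.sd_y, rho
            )
            rng = substream(
                seed,
                _TAG_INDEPENDENT,
                key_from_float(variance_ratio),
                key_from_float(rho),
            )
            i_arr, e_arr = _sample_bivariate_stack(spec, iterations, n, rng)
            slope, _, lo, hi = fit_slopes_batch(e_arr, i_arr, alpha)
        except ValueError as err:
            raise ValueError(f"independent sweep failed at rho={rho}: {err}") from err
        expected.append(expected_slope_independent(rho, sd_i, spec.sd_y))
        mean_s.append(slope.mean())
        sd_s.append(slope.std(ddof=1) if iterations > 1 else 0.0)
        rej.append(np.mean((benchmark < lo) | (benchmark > hi)))
    return SweepResult(
        rho_grid=grid,
        expected_slope=np.array(expected),
        mean_slope=np.array(mean_s),
        sd_slope=np.array(sd_s),
        rejection_rate=np.array(rej),
        n=n,
        iterations=iterations,
        benchmark=benchmark,
        alpha=alpha,
        seed=seed,
        design="independent",
        variance_ratio=variance_ratio,
    )


def run_shared_error_study(
    params: SharedErrorParams,
    population_n: int = 1000,
    n_sub: int = 25,
    iterations: int = 10_000,
    seed: int = 0,
) -> BootstrapSlopes:
    """Population slopes and bootstrap distributions under shared error.

    One population of ``population_n`` is generated; the three pairwise
    population slopes (I~E, E~A, I~A) are fitted on it; then ``n_sub``
    individuals are resampled with replacement ``iterations`` times and
    all three slopes refitted per resample.
    """
    if population_n < 2 or n_sub > population_n:
        raise ValueError("need 2 <= n_sub <= population_n")
    if n_sub < 3:
        raise ValueError("n_sub must be >= 3 to fit slopes")
    pop = make_shared_error_population(
        params, population_n, child_seed(seed, _TAG_SHARED, 0)
    )
    pop_slopes = SharedErrorSlopes(
        i_on_e=fit_slope(pop.explicit, pop.implicit).slope,
        e_on_a=fit_slope(pop.total, pop.explicit).slope,
        i_on_a=fit_slope(pop.total, pop.implicit).slope,
    )
    rng = substream(seed, _TAG_SHARED, 1)
    idx = rng.integers(0, population_n, size=(iterations, n_sub))
    i_s, e_s, a_s = pop.implicit[idx], pop.explicit[idx], pop.total[idx]
    s_ie, *_ = fit_slopes_batch(e_s, i_s)
    s_ea, *_ = fit_slopes_batch(a_s, e_s)
    s_ia, *_ = fit_slopes_batch(a_s, i_s)
    return BootstrapSlopes(
        slopes_i_on_e=s_ie,
        slopes_e_on_a=s_ea,
        slopes_i_on_a=s_ia,
        population_slopes=pop_slopes,
        expected_slopes=shared_error_expected_slopes(params),
        population_n=population_n,
        n_sub=n_sub,
        iterations=iterations,
        seed=seed,
    )


def run_loose_additivity_study(
    spec_IE: CovarianceSpec,
    noise_grid: np.ndarray | None = None,
    n_sub: int = 25,
    iterations: int = 10_000,
    seed: int = 0,
) -> LooseAdditivityResult:
    """Regression dilution of the A ~ (I_obs + E_obs) slope.

    Per noise level sigma: draw `iterations` fresh datasets of ``n_sub``
    (I, E) pairs from ``spec_IE`` with A = I + E exact, add independent
    N(0, sigma) measurement noise to each component, and regress A on the
    noisy composite.  The predicted column is the closed-form reliability
    ratio from :func:`slopebench.theory.attenuation_expected_slope`.
    """
    grid = (
        np.round(np.arange(0.0, 5.01, 0.5), 10)
        if noise_grid is None
        else np.asarray(noise_grid, dtype=float)
    )
    if np.any(grid < 0):
        raise ValueError("noise SDs must be >= 0")
    if n_sub < 3:
        raise ValueError("n_sub must be >= 3")
    predicted = np.array(
        [
            attenuation_expected_slope(spec_IE.sd_x, spec_IE.sd_y, spec_IE.rho, s, s)
            for s in grid
        ]
    )
    slopes = np.empty((len(grid), iterations))
    for k, sigma in enumerate(grid):
        try:
            # separate substreams for the base sample and the noise, so a
            # longer run extends a shorter one row-for-row
            rng_base = substream(seed, _TAG_LOOSE, key_from_float(sigma), 0)
            rng_noise = substream(seed, _TAG_LOOSE, key_from_float(sigma), 1)
            i_arr, e_arr = _sample_bivariate_stack(spec_IE, iterations, n_sub, rng_base)
            a_arr = i_arr + e_arr
            noise = rng_noise.standard_normal((iterations, n_sub, 2)).sum(axis=-1)
            slopes[k], *_ = fit_slopes_batch(a_arr + sigma * noise, a_arr)
        except ValueError as err:
            raise ValueError(
                f"loose-additivity study failed at noise={sigma}: {err}"
            ) from err
    return LooseAdditivityResult(
        noise_grid=grid,
        predicted_slope=predicted,
        slopes=slopes,
        n_sub=n_sub,
        iterations=iterations,
        seed=seed,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, reported as 0 when either argument has zero variance."""
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def residual_diagnostics(sample: TriadSample) -> ResidualDiagnostics:
    """Fingerprint statistics of the additivity residual A - I - E."""
    if len(sample) < 3:
        raise ValueError("need at least 3 individuals for residual diagnostics")
    i, e = sample.implicit, sample.explicit
    # evaluate as A - (I + E): exactly zero whenever total was constructed
    # as the float sum of the stored components
    eps = sample.total - (i + e)
    return ResidualDiagnostics(
        mean_residual=float(eps.mean()),
        corr_with_i=_safe_corr(eps, i),
        corr_with_e=_safe_corr(eps, e),
        corr_with_product=_safe_corr(eps, i * e),
        corr_with_sum=_safe_corr(eps, i + e),
    )
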