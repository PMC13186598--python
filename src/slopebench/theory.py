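"""Closed-form expected regression slopes for additive adaptation models.

Total adaptation ``A`` in a visuomotor-rotation task is conventionally
decomposed into an implicit recalibration component ``I`` and an explicit
re-aiming strategy ``E`` that sum at expression, ``A = I + E``.  Between-
subject regression slopes among these quantities are fully determined by
their covariance structure, not by whether the components sum:

* subtractive logic (``I = A - E`` derived):
  ``beta(I ~ E) = rho_AE * sigma_A / sigma_E - 1``;
* independent measurement of ``I`` and ``E``:
  ``beta(I ~ E) = rho_IE * sigma_I / sigma_E``;
* shared-error coupling at steady state, ``I = p_i * (r - E)``, with
  independent Gaussian measurement noise on both components;
* regression dilution of the "loose additivity" test, ``A`` regressed on
  the noisy composite ``I_obs + E_obs``.

All angles are in degrees throughout; slopes are dimensionless ratios of
degree-valued quantities.  These formulas are the analytic oracles against
which every simulation in :mod:`slopebench.experiments` is checked; the
shared-error forms are themselves validated against a large-sample
simulation oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "CovarianceSpec",
    "SharedErrorParams",
    "SharedErrorSlopes",
    "expected_slope_subtractive",
    "expected_slope_independent",
    "shared_error_expected_slopes",
    "attenuation_expected_slope",
]


def _check_sd(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _check_rho(rho: float) -> None:
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho!r}")


@dataclass(frozen=True)
class CovarianceSpec:
    """First and second moments of a bivariate normal over two learning
    measures (degrees).

    The (x, y) pair is (A, E) for subtractive designs and (I, E) for
    independent-measurement designs.
    """

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    rho: float

    def __post_init__(self) -> None:
        _check_sd(self.sd_x, "sd_x")
        _check_sd(self.sd_y, "sd_y")
        _check_rho(self.rho)

    @property
    def covariance(self) -> float:
        """Cov(x, y) in squared degrees."""
        return self.rho * self.sd_x * self.sd_y


@dataclass(frozen=True)
class SharedErrorParams:
    """Parameters of the steady-state shared-error generative model.

    The explicit strategy is drawn per individual, ``E ~ N(mu_E, sigma_E)``,
    and the implicit system recalibrates in proportion to the residual
    error left after strategy: ``I = p_i * (r - E)``, where ``r`` is the
    rotation magnitude (degrees) and ``p_i`` in [0, 1] the implicit
    steady-state capacity.  Independent Gaussian measurement noise with SDs
    ``tau_I`` and ``tau_E`` corrupts the observed components.
    """

    r: float
    p_i: float
    mu_E: float
    sigma_E: float
    tau_I: float = 0.0
    tau_E: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_i <= 1.0:
            raise ValueError(f"p_i must lie in [0, 1], got {self.p_i!r}")
        _check_sd(self.sigma_E, "sigma_E")
        if self.tau_I < 0 or self.tau_E < 0:
            raise ValueError("measurement-noise SDs must be >= 0")


class SharedErrorSlopes(NamedTuple):
    """Population regression slopes among observed shared-error measures."""

    i_on_e: float
    e_on_a: float
    i_on_a: float


def expected_slope_subtractive(rho: float, sigma_A: float, sigma_E: float) -> float:
    """Expected OLS slope of derived implicit (I = A - E) on explicit.

    Because the derived variable contains ``-E``, the slope is
    ``rho * sigma_A / sigma_E - 1``: it equals the intuitive -1 tradeoff
    only when total adaptation is uncorrelated with the explicit measure.

    Parameters
    ----------
    rho : correlation between A and E, in [-1, 1].
    sigma_A, sigma_E : SDs of total adaptation and explicit strategy
        (degrees, > 0).
    """
    _check_sd(sigma_A, "sigma_A")
    _check_sd(sigma_E, "sigma_E")
    _check_rho(rho)
    return rho * sigma_A / sigma_E - 1.0


def expected_slope_independent(rho: float, sigma_I: float, sigma_E: float) -> float:
    """Expected OLS slope of independently measured implicit on explicit.

    With both components measured directly the slope is just the
    correlation scaled by the SD ratio, ``rho * sigma_I / sigma_E`` —
    a quantity the additive combination rule places no constraint on.
    """
    _check_sd(sigma_I, "sigma_I")
    _check_sd(sigma_E, "sigma_E")
    _check_rho(rho)
    return rho * sigma_I / sigma_E


def shared_error_expected_slopes(params: SharedErrorParams) -> SharedErrorSlopes:
    """Population OLS slopes among noisy shared-error measures.

    Observed total adaptation is the sum of the noisy component measures,
    ``A_obs = I_obs + E_obs``, mirroring how additivity is assessed from
    data.  Writing ``v = sigma_E**2`` and ``a = 1 - p_i``, covariance
    algebra on the generative model gives

    * ``beta(I_obs ~ E_obs) = -p_i * v / (v + tau_E**2)``
    * ``beta(E_obs ~ A_obs) = (a*v + tau_E**2) / (a**2*v + tau_I**2 + tau_E**2)``
    * ``beta(I_obs ~ A_obs) = (-p_i*a*v + tau_I**2) / (a**2*v + tau_I**2 + tau_E**2)``

    Raises
    ------
    ValueError
        If the observed total has zero variance (``p_i = 1`` with no
        measurement noise), which makes the A-regressions degenerate.
    """
    p, v = params.p_i, params.sigma_E**2
    a = 1.0 - p
    ti2, te2 = params.tau_I**2, params.tau_E**2
    var_a_obs = a**2 * v + ti2 + te2
    if var_a_obs <= 0.0:
        raise ValueError(
            "observed total adaptation has zero variance "
            "(p_i = 1 with no measurement noise); slopes on A are undefined"
        )
    return SharedErrorSlopes(
        i_on_e=-p * v / (v + te2),
        e_on_a=(a * v + te2) / var_a_obs,
        i_on_a=(-p * a * v + ti2) / var_a_obs,
    )


def attenuation_expected_slope(
    sigma_I: float, sigma_E: float, rho: float, tau_I: float, tau_E: float
) -> float:
    """Expected slope of A on the noisy composite (I_obs + E_obs).

    Under exact additivity ``A = I + E``, regressing ``A`` on the sum of
    noise-corrupted component measures yields the classical reliability
    ratio (regression dilution)::

        V_true / (V_true + tau_I**2 + tau_E**2),
        V_true = Var(I + E) = sigma_I**2 + sigma_E**2 + 2*rho*sigma_I*sigma_E

    which is 1 only with noise-free measurement and shrinks toward 0 as
    noise grows — slopes below 1 therefore do not indicate non-additivity.
    """
    _check_sd(sigma_I, "sigma_I")
    _check_sd(sigma_E, "sigma_E")
    _check_rho(rho)
    if tau_I < 0 or tau_E < 0:
        raise ValueError("measurement-noise SDs must be >= 0")
    v_true = sigma_I**2 + sigma_E**2 + 2.0 * rho * sigma_I * sigma_E
    v_true = max(v_true, 0.0)  # guard FP sign error at rho = -1, equal SDs
    denom = v_true + tau_I**2 + tau_E**2
    if denom <= 0.0 or not math.isfinite(denom):
        raise ValueError("composite predictor has zero variance; slope undefined")
    return v_true / denom
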