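"""Seeded generators for every population structure the experiments use.

Each generator returns a :class:`TriadSample` — paired arrays of implicit,
explicit and total adaptation (degrees) — in which the additive identity
``total = implicit + explicit`` holds *exactly by construction*.  That is
deliberate: the point of the downstream experiments is that regression
slopes deviate from the naive benchmarks anyway.

Three constructions are provided:

* subtractive — (A, E) sampled from a bivariate normal, I derived as A - E
  (aim-report designs);
* independent — (I, E) sampled, A derived as I + E (independent
  measurement of the components);
* shared_error — E drawn per individual, I = p_i * (r - E) from the
  residual error, measurement noise added to both, A_obs = I_obs + E_obs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .theory import CovarianceSpec, SharedErrorParams

__all__ = [
    "Provenance",
    "TriadSample",
    "sample_bivariate",
    "make_subtractive_triad",
    "make_independent_triad",
    "make_shared_error_population",
    "make_iso_A_scenarios",
]

Provenance = Literal["subtractive", "independent", "shared_error"]

_PROVENANCES = ("subtractive", "independent", "shared_error")


@dataclass(frozen=True)
class TriadSample:
    """Paired implicit / explicit / total adaptation values (degrees)."""

    implicit: np.ndarray
    explicit: np.ndarray
    total: np.ndarray
    provenance: Provenance
    seed: int

    def __post_init__(self) -> None:
        n = len(self.total)
        if not (len(self.implicit) == len(self.explicit) == n):
            raise ValueError("implicit, explicit and total must have equal length")
        if n < 2:
            raise ValueError("a triad sample needs at least 2 individuals")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.total)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "implicit_deg": self.implicit,
                "explicit_deg": self.explicit,
                "total_deg": self.total,
                "provenance": self.provenance,
                "seed": self.seed,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the sample as UTF-8 CSV with a units comment header."""
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write("# implicit_deg, explicit_deg, total_deg in degrees of hand angle\n")
            self.to_dataframe().to_csv(fh, index=False)


def sample_bivariate(
    spec: CovarianceSpec, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` pairs from the bivariate normal defined by ``spec``.

    |rho| = 1 is handled as an exact linear map of a single normal draw
    rather than a near-singular matrix factorization, so the conceptual
    boundary cases (perfect coupling) are exact.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if abs(spec.rho) == 1.0:
        z = rng.standard_normal(n)
        x = spec.mean_x + spec.sd_x * z
        y = spec.mean_y + spec.sd_y * np.copysign(1.0, spec.rho) * z
        return x, y
    z = rng.standard_normal((n, 2))
    # 2x2 lower-Cholesky factor of the correlation matrix, applied in closed form
    x = spec.mean_x + spec.sd_x * z[:, 0]
    y = spec.mean_y + spec.sd_y * (
        spec.rho * z[:, 0] + np.sqrt(1.0 - spec.rho**2) * z[:, 1]
    )
    return x, y


def make_subtractive_triad(
    spec_AE: CovarianceSpec, n: int, seed: int
) -> TriadSample:
    """Aim-report construction: sample (A, E), derive I = A - E.

    The stored total is re-expressed as implicit + explicit so the
    additive identity is exact in floating point (the re-expression
    differs from the sampled A by at most one rounding step).
    """
    total, explicit = sample_bivariate(spec_AE, n, seed)
    implicit = total - explicit
    return TriadSample(
        implicit=implicit,
        explicit=explicit,
        total=implicit + explicit,
        provenance="subtractive",
        seed=seed,
    )


def make_independent_triad(
    spec_IE: CovarianceSpec, n: int, seed: int
) -> TriadSample:
    """Independent measurement: sample (I, E), derive A = I + E."""
    implicit, explicit = sample_bivariate(spec_IE, n, seed)
    return TriadSample(
        implicit=implicit,
        explicit=explicit,
        total=implicit + explicit,
        provenance="independent",
        seed=seed,
    )


def make_shared_error_population(
    params: SharedErrorParams, n: int, seed: int | np.random.Generator
) -> TriadSample:
    """Shared-error population with measurement noise on both components.

    E_true ~ N(mu_E, sigma_E) (untruncated: negative aims are allowed),
    I_true = p_i * (r - E_true), then independent Gaussian noise with SDs
    tau_I / tau_E is added to each component; the observed total is the
    sum of the noisy measures.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_tag = seed if isinstance(seed, int) else -1
    e_true = params.mu_E + params.sigma_E * rng.standard_normal(n)
    i_true = params.p_i * (params.r - e_true)
    i_obs = i_true + params.tau_I * rng.standard_normal(n)
    e_obs = e_true + params.tau_E * rng.standard_normal(n)
    return TriadSample(
        implicit=i_obs,
        explicit=e_obs,
        total=i_obs + e_obs,
        provenance="shared_error",
        seed=seed_tag,
    )


def make_iso_A_scenarios() -> dict[str, TriadSample]:
    """Three fixed 3-individual demos: additivity never constrains corr(I, E).

    a. total adaptation constant, proportions vary -> corr(I, E) = -1
       (all individuals on one iso-A contour);
    b. total varies, proportions fixed -> corr(I, E) = +1;
    c. total varies and proportions shift -> corr(I, E) = -1 again.

    The bar heights are illustrative choices; only the correlations and
    the additive identity are contractual.
    """
    def triad(i: list[float], e: list[float]) -> TriadSample:
        imp = np.asarray(i, dtype=float)
        exp = np.asarray(e, dtype=float)
        return TriadSample(imp, exp, imp + exp, provenance="independent", seed=0)

    return {
        "a": triad([15.0, 10.0, 5.0], [5.0, 10.0, 15.0]),   # A = 20 for all
        "b": triad([6.0, 12.0, 18.0], [4.0, 8.0, 12.0]),    # A = 10/20/30, I:E fixed
        "c": triad([14.0, 12.0, 10.0], [4.0, 8.0, 12.0]),   # A = 18/20/22, tradeoff
    }
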