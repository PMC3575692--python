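"""Synthetic cohorts for studying the incremental value of a novel marker.

Each cohort has a continuous base covariate ``x_c ~ Normal(0, sigma_c^2)``, a
marker ``x_rf`` that is either binary (Bernoulli with prevalence
``p_binary``) or standard normal, optionally a second base covariate ``x_b ~
Bernoulli(0.5)``, and a binary outcome drawn from

    logit(p_i) = intercept + beta_c * x_c_i + beta_rf * x_rf_i [+ beta_b * x_b_i]

with ``intercept = -1`` by default and each beta the log of the
corresponding odds ratio.

A positive correlation between marker and base covariate is induced by
drawing ``(x_c, z)`` from a bivariate normal with unit marker/latent variance
and correlation rho; binary markers are obtained by thresholding the latent
``z`` at the standard-normal quantile that yields the target prevalence.

Seven scenario families form full factorial grids over
``exp(beta_c) in {1.00, 1.25, ..., 4.00}`` (13 values),
``sigma_c in {0.25, 0.50, ..., 4.00}`` (16 values),
``exp(beta_rf) in {1.25, 1.5, 2, 3, 5}`` and, for binary markers,
``p_binary in {0.1, 0.25, 0.5}``: 3120 binary-marker or 1040
continuous-marker scenarios per family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit, ndtri

__all__ = [
    "ScenarioSpec",
    "SimulatedCohort",
    "FAMILIES",
    "latent_threshold",
    "draw_covariates",
    "simulate_outcomes",
    "simulate_cohort",
    "factorial_grid",
]

# grid axes of the factorial design
OR_C_GRID = tuple(np.round(np.arange(1.0, 4.0 + 1e-9, 0.25), 2))  # 13 values
SIGMA_C_GRID = tuple(np.round(np.arange(0.25, 4.0 + 1e-9, 0.25), 2))  # 16 values
OR_RF_GRID = (1.25, 1.5, 2.0, 3.0, 5.0)
P_BINARY_GRID = (0.1, 0.25, 0.5)

#: family name -> (marker_type, correlation, base_model)
FAMILIES = {
    "binary_independent": ("binary", 0.0, "univariate"),
    "continuous_independent": ("continuous", 0.0, "univariate"),
    "binary_rho05": ("binary", 0.5, "univariate"),
    "binary_rho08": ("binary", 0.8, "univariate"),
    "continuous_rho05": ("continuous", 0.5, "univariate"),
    "continuous_rho08": ("continuous", 0.8, "univariate"),
    "two_covariate": ("binary", 0.0, "two_covariate"),
}

VALID_CORRELATIONS = (0.0, 0.5, 0.8)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial simulation design.

    Parameters
    ----------
    marker_type : {"binary", "continuous"}
    exp_beta_c : float
        Odds ratio of the continuous base covariate (per unit).
    exp_beta_rf : float
        Odds ratio of the marker.
    sigma_c : float
        Standard deviation of the base covariate.
    p_binary : float or None
        Marker prevalence; required iff the marker is binary.
    correlation : {0.0, 0.5, 0.8}
        Correlation between the base covariate and the marker (continuous)
        or its latent variable (binary).
    base_model : {"univariate", "two_covariate"}
        The two-covariate base model adds an independent Bernoulli(0.5)
        covariate x_b whose odds ratio is half the continuous covariate's
        (see ``two_covariate_rule``); it requires a binary, uncorrelated
        marker.
    two_covariate_rule : {"half_or", "half_beta"}
        Whether exp(beta_b) = exp(beta_c)/2 (literal halved odds ratio,
        default) or beta_b = beta_c/2.
    """

    marker_type: str
    exp_beta_c: float
    exp_beta_rf: float
    sigma_c: float
    p_binary: Optional[float] = None
    correlation: float = 0.0
    base_model: str = "univariate"
    intercept: float = -1.0
    n_subjects: int = 1000
    n_replicates: int = 1000
    seed: int = 0
    two_covariate_rule: str = "half_or"

    def __post_init__(self):
        if self.marker_type not in ("binary", "continuous"):
            raise ValueError(f"unknown marker_type {self.marker_type!r}")
        if self.marker_type == "binary":
            if self.p_binary is None:
                raise ValueError("binary marker requires p_binary")
            if not 0.0 < self.p_binary < 1.0:
                raise ValueError(f"p_binary must be in (0, 1), got {self.p_binary}")
        elif self.p_binary is not None:
            raise ValueError("p_binary only applies to binary markers")
        if self.correlation not in VALID_CORRELATIONS:
            raise ValueError(
                f"correlation must be one of {VALID_CORRELATIONS}, got {self.correlation}"
            )
        if self.base_model not in ("univariate", "two_covariate"):
            raise ValueError(f"unknown base_model {self.base_model!r}")
        if self.base_model == "two_covariate" and (
            self.marker_type != "binary" or self.correlation != 0.0
        ):
            raise ValueError(
                "the two-covariate base model is defined for an uncorrelated binary marker"
            )
        if self.two_covariate_rule not in ("half_or", "half_beta"):
            raise ValueError(f"unknown two_covariate_rule {self.two_covariate_rule!r}")
        for name in ("exp_beta_c", "exp_beta_rf", "sigma_c"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.n_subjects < 2 or self.n_replicates < 1:
            raise ValueError("n_subjects >= 2 and n_replicates >= 1 required")

    @property
    def beta_c(self) -> float:
        return math.log(self.exp_beta_c)

    @property
    def beta_rf(self) -> float:
        return math.log(self.exp_beta_rf)

    @property
    def beta_b(self) -> Optional[float]:
        """Log-OR of the binary base covariate (two-covariate family only)."""
        if self.base_model != "two_covariate":
            return None
        if self.two_covariate_rule == "half_or":
            return math.log(self.exp_beta_c / 2.0)
        return self.beta_c / 2.0

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedCohort:
    """One replicate: covariates, marker, true probabilities and outcomes."""

    x_c: np.ndarray
    x_rf: np.ndarray
    p_true: np.ndarray
    y: np.ndarray
    x_b: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.y.shape[0]


def latent_threshold(p_binary: float) -> float:
    """Standard-normal cutoff t with P(Z > t) = p_binary.

    Thresholding a unit-variance latent Gaussian at t yields a binary marker
    with expected prevalence ``p_binary``.
    """
    if not 0.0 < p_binary < 1.0:
        raise ValueError(f"p_binary must be in (0, 1), got {p_binary}")
    return float(ndtri(1.0 - p_binary))


def draw_covariates(spec: ScenarioSpec, rng: np.random.Generator):
    """Draw (x_c, x_rf[, x_b]) for one cohort according to the spec.

    Returns
    -------
    (x_c, x_rf, x_b) where ``x_b`` is None unless the spec uses the
    two-covariate base model.
    """
    n = spec.n_subjects
    rho = spec.correlation
    # (x_c, z) bivariate normal with SDs (sigma_c, 1) and correlation rho,
    # built from two shared standard-normal draws.  Because the same draws
    # are consumed for every correlation, prevalence, and marker odds ratio,
    # matched scenarios share common random numbers, which sharpens the
    # Monte Carlo contrasts across those factors without biasing any mean.
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    x_c = spec.sigma_c * a
    z = rho * a + math.sqrt(1.0 - rho * rho) * b
    if spec.marker_type == "binary":
        x_rf = (z > latent_threshold(spec.p_binary)).astype(np.int64)
    else:
        x_rf = z
    x_b = None
    if spec.base_model == "two_covariate":
        x_b = (rng.random(n) < 0.5).astype(np.int64)
    return x_c, x_rf, x_b


def simulate_outcomes(
    spec: ScenarioSpec, x_c, x_rf, x_b, rng: np.random.Generator
) -> SimulatedCohort:
    """Draw Bernoulli outcomes from the true logistic model."""
    eta = spec.intercept + spec.beta_c * np.asarray(x_c) + spec.beta_rf * np.asarray(x_rf)
    if x_b is not None:
        eta = eta + spec.beta_b * np.asarray(x_b)
    p_true = expit(eta)
    y = (rng.random(spec.n_subjects) < p_true).astype(np.int64)
    return SimulatedCohort(
        x_c=np.asarray(x_c, dtype=float),
        x_rf=np.asarray(x_rf),
        p_true=p_true,
        y=y,
        x_b=None if x_b is None else np.asarray(x_b),
    )


def simulate_cohort(spec: ScenarioSpec, rng: np.random.Generator) -> SimulatedCohort:
    """Draw covariates and outcomes for one replicate."""
    x_c, x_rf, x_b = draw_covariates(spec, rng)
    return simulate_outcomes(spec, x_c, x_rf, x_b, rng)


def factorial_grid(
    family: str,
    n_subjects: int = 1000,
    n_replicates: int = 1000,
    or_c_values=OR_C_GRID,
    sigma_c_values=SIGMA_C_GRID,
    or_rf_values=OR_RF_GRID,
    p_binary_values=P_BINARY_GRID,
    **overrides,
) -> list[ScenarioSpec]:
    """Enumerate the full factorial design of one scenario family.

    Binary-marker families cross 13 base ORs x 16 SDs x 5 marker ORs x 3
    prevalences = 3120 scenarios; continuous-marker families drop the
    prevalence axis (1040 scenarios).  The axis keyword arguments allow
    reduced grids for desk-scale runs.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    marker_type, correlation, base_model = FAMILIES[family]
    p_values = tuple(p_binary_values) if marker_type == "binary" else (None,)
    specs = []
    for or_c in or_c_values:
        for sigma in sigma_c_values:
            for or_rf in or_rf_values:
                for p in p_values:
                    specs.append(
                        ScenarioSpec(
                            marker_type=marker_type,
                            exp_beta_c=float(or_c),
                            exp_beta_rf=float(or_rf),
                            sigma_c=float(sigma),
                            p_binary=p,
                            correlation=correlation,
                            base_model=base_model,
                            n_subjects=n_subjects,
                            n_replicates=n_replicates,
                            **overrides,
                        )
                    )
    return specs


def cohort_to_frame(cohort: SimulatedCohort):
    """Export a cohort as a DataFrame (columns x_c, x_rf, [x_b,] p_true, y)."""
    import pandas as pd

    data = {"x_c": cohort.x_c, "x_rf": cohort.x_rf}
    if cohort.x_b is not None:
        data["x_b"] = cohort.x_b
    data["p_true"] = cohort.p_true
    data["y"] = cohort.y
    return pd.DataFrame(data)
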