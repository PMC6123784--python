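"""Physics of the nanocellulose (CNF) filter joining the two compartments.

Three things live here:

* the bridge from device geometry to the model's coupling term — a
  quasi-steady Fickian exchange rate ``k_x = 60 * D * A_f / (L_f * V_c)``
  (per minute),
* the AHL diffusion-time estimate ``tau = L_eff^2 / (2 D)`` (1-D
  mean-first-passage convention), used to argue that signal coupling
  across the filter is much faster than transcription-factor coupling,
* particle sieving through the filter and inference of the pore-size
  cutoff from the sizes of particles recovered after passage — the
  porosity assay run with polydisperse silica nanoparticles.

Defaults describe the shipped device: AHL diffusivity 490 um^2/s (a
standard literature value for acyl-homoserine lactones in water), filter
cross-section 48 um^2 (30 um filter width x 1.6 um trap height), filter
thickness 10 um, compartment volume 16000 um^3, effective sender-to-
receiver path 100 um.  High-pressure (HP) packed filters cut off near
24 nm, low-pressure (LP) ones near 42 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EstimationError, InputDomainError

__all__ = [
    "FilterGeometry",
    "SieveModel",
    "PorositySample",
    "CutoffEstimate",
    "exchange_rate",
    "diffusion_time",
    "sieve",
    "estimate_cutoff",
    "HP_CUTOFF_NM",
    "LP_CUTOFF_NM",
]

HP_CUTOFF_NM = 24.0  # high-pressure packed filter
LP_CUTOFF_NM = 42.0  # low-pressure packed filter


@dataclass(frozen=True)
class FilterGeometry:
    """Device geometry and AHL diffusivity used by the transport estimates."""

    D_AHL: float = 490.0     # AHL diffusivity, um^2/s
    A_f: float = 48.0        # filter cross-sectional area, um^2
    L_f: float = 10.0        # filter thickness, um
    V_c: float = 16000.0     # compartment volume, um^3
    L_eff: float = 100.0     # effective sender-to-receiver path, um

    def __post_init__(self) -> None:
        for name in ("D_AHL", "A_f", "L_f", "V_c", "L_eff"):
            v = getattr(self, name)
            if not v > 0 or not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class SieveModel:
    """Sieving behaviour of a packed filter.

    ``ideal`` passes a particle iff its diameter is at most the cutoff
    (inclusive).  ``logistic`` passes with probability
    1 / (1 + exp((d - cutoff)/width)), a soft cutoff for imperfectly
    packed filters; ``width`` is ignored in ideal mode.
    """

    cutoff: float            # nm
    mode: str = "ideal"      # "ideal" | "logistic"
    width: float = 1.0       # nm, logistic softness

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError(f"cutoff must be > 0, got {self.cutoff}")
        if self.mode not in ("ideal", "logistic"):
            raise ConfigurationError(
                f"mode must be 'ideal' or 'logistic', got {self.mode!r}"
            )
        if self.mode == "logistic" and self.width <= 0:
            raise ConfigurationError(f"width must be > 0, got {self.width}")

    def pass_probability(self, diameters: np.ndarray) -> np.ndarray:
        d = np.asarray(diameters, dtype=float)
        if self.mode == "ideal":
            return (d <= self.cutoff).astype(float)
        return 1.0 / (1.0 + np.exp((d - self.cutoff) / self.width))


@dataclass
class PorositySample:
    """A collection of particle diameters before or after the filter."""

    diameters: np.ndarray
    stage: str = "pre_filter"  # "pre_filter" | "post_filter"

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.stage not in ("pre_filter", "post_filter"):
            raise ConfigurationError(
                f"stage must be 'pre_filter' or 'post_filter', got {self.stage!r}"
            )
        if self.diameters.size and (
            np.any(self.diameters <= 0) or not np.all(np.isfinite(self.diameters))
        ):
            raise InputDomainError("all diameters must be finite and > 0")

    @property
    def n(self) -> int:
        return int(self.diameters.size)


@dataclass(frozen=True)
class CutoffEstimate:
    """Inferred sieving cutoff (nm) with the sample size behind it."""

    cutoff_hat: float
    n_passed: int
    method: str

    def __post_init__(self) -> None:
        if self.cutoff_hat <= 0:
            raise EstimationError(f"cutoff_hat must be > 0, got {self.cutoff_hat}")
        if self.n_passed < 1:
            raise EstimationError(f"n_passed must be >= 1, got {self.n_passed}")


def exchange_rate(geometry: FilterGeometry) -> float:
    """Inter-compartment AHL exchange rate k_x in 1/min.

    Quasi-steady Fickian flux through the filter divided by compartment
    volume: k_x = 60 * D * A_f / (L_f * V_c).  With the default geometry
    this gives 8.82 per minute — fast enough that the two compartments
    track each other on the minute scale.
    """
    return 60.0 * geometry.D_AHL * geometry.A_f / (geometry.L_f * geometry.V_c)


def diffusion_time(geometry: FilterGeometry) -> float:
    """Characteristic sender-to-receiver diffusion time in seconds.

    1-D mean-first-passage estimate tau = L_eff^2 / (2 D).  For the
    default geometry (100 um path, 490 um^2/s) this is ~10 s, well under
    a minute and far below the ~30 min of transcription-and-translation
    based coupling.
    """
    return geometry.L_eff ** 2 / (2.0 * geometry.D_AHL)


def sieve(sample: PorositySample, model: SieveModel,
          seed: int | None = None) -> PorositySample:
    """Pass a pre-filter particle sample through a sieve model.

    Ideal mode is deterministic (d <= cutoff passes); logistic mode draws
    independent Bernoulli passages and is reproducible given ``seed``.
    An empty post-filter sample is returned as such (n = 0), not raised.
    """
    if sample.stage != "pre_filter":
        raise ConfigurationError(
            f"sieve expects a pre_filter sample, got stage {sample.stage!r}"
        )
    p = model.pass_probability(sample.diameters)
    if model.mode == "ideal":
        passed = p >= 0.5
    else:
        rng = np.random.default_rng(seed)
        passed = rng.random(sample.n) < p
    return PorositySample(sample.diameters[passed], stage="post_filter")


def estimate_cutoff(post: PorositySample, method: str = "max") -> CutoffEstimate:
    """Infer the sieving cutoff from the particles found after passage.

    ``max`` uses the largest passed diameter — conservative: it can only
    underestimate the true cutoff of an ideal sieve, and converges to it
    as the sample grows.  ``quantile99`` uses the 99th percentile and is
    more robust when the post-filter sample may contain contaminants.
    """
    if post.stage != "post_filter":
        raise ConfigurationError(
            f"estimate_cutoff expects a post_filter sample, got {post.stage!r}"
        )
    if post.n == 0:
        raise EstimationError("cannot estimate a cutoff from an empty sample")
    if method == "max":
        cut = float(post.diameters.max())
    elif method == "quantile99":
        cut = float(np.quantile(post.diameters, 0.99))
    else:
        raise ConfigurationError(
            f"unknown method {method!r}; valid: 'max', 'quantile99'"
        )
    return CutoffEstimate(cutoff_hat=cut, n_passed=post.n, method=method)
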