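"""Synthetic inputs: noisy reporter traces and polydisperse particle samples.

Everything the analysis pipeline consumes can be generated here without
any external data: simulated fluorescence traces degraded with a simple
measurement-noise model (multiplicative + additive Gaussian, clamped at
zero), and particle-diameter samples spanning the 10-100 nm range used
in the filter-porosity assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as llio
from .circuit import build_configuration, get_params
from .errors import ConfigurationError, InputDomainError
from .traces import TraceSet
from .transport import (
    HP_CUTOFF_NM,
    LP_CUTOFF_NM,
    PorositySample,
    SieveModel,
    sieve,
)

__all__ = ["NoiseModel", "noisy_traces", "sample_particles", "make_fixture",
           "FIXTURES"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: out = clean*(1+eps_rel) + eps_abs, clamped at 0.

    Defaults (5% relative, 0.5 a.u. additive) give trace roughness
    comparable to measured trap-averaged intensities.
    """

    sigma_rel: float = 0.05
    sigma_abs: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise ConfigurationError("noise SDs must be >= 0")


def noisy_traces(clean: TraceSet, noise: NoiseModel) -> TraceSet:
    """Apply the noise model independently to every channel sample."""
    rng = np.random.default_rng(noise.seed)
    channels = {}
    for name, values in clean.channels.items():
        eps_rel = rng.normal(0.0, noise.sigma_rel, size=values.shape) \
            if noise.sigma_rel > 0 else 0.0
        eps_abs = rng.normal(0.0, noise.sigma_abs, size=values.shape) \
            if noise.sigma_abs > 0 else 0.0
        channels[name] = np.maximum(values * (1.0 + eps_rel) + eps_abs, 0.0)
    meta = dict(clean.metadata)
    meta.update(sigma_rel=noise.sigma_rel, sigma_abs=noise.sigma_abs,
                noise_seed=noise.seed)
    return TraceSet(clean.times.copy(), channels, meta)


def sample_particles(n: int, d_min: float = 10.0, d_max: float = 100.0,
                     distribution: str = "uniform",
                     seed: int | None = None) -> PorositySample:
    """Draw a polydisperse nanoparticle sample (diameters in nm).

    ``uniform`` matches the nominal 10-100 nm polydisperse range;
    ``loguniform`` is offered because TEM size distributions are often
    right-skewed.
    """
    if n < 1:
        raise InputDomainError(f"n must be >= 1, got {n}")
    if not 0 < d_min < d_max:
        raise InputDomainError(
            f"need 0 < d_min < d_max, got d_min={d_min}, d_max={d_max}"
        )
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        d = rng.uniform(d_min, d_max, size=n)
    elif distribution == "loguniform":
        d = np.exp(rng.uniform(np.log(d_min), np.log(d_max), size=n))
    else:
        raise ConfigurationError(
            f"unknown distribution {distribution!r}; valid: uniform, loguniform"
        )
    return PorositySample(d, stage="pre_filter")


FIXTURES = ("osc-a-noisy", "ind-pair", "porosity-hp", "porosity-lp")


def make_fixture(name: str, seed: int = 0, out_dir: str | Path = ".") -> list[Path]:
    """Write a named, fully synthetic input bundle as CSV files.

    * ``osc-a-noisy``  — OSC_A simulation over 1800 min, resampled to the
      3-min imaging grid, default noise;
    * ``ind-pair``     — IND and IND_BLOCKED runs resampled to 6 min;
    * ``porosity-hp`` / ``porosity-lp`` — 1000-particle pre/post samples
      sieved at the HP (24 nm) / LP (42 nm) cutoff.

    Returns the list of written files; a ``manifest.txt`` with key=value
    lines records names, seeds and parameters.
    """
    from .analysis import resample          # local import: avoids cycle
    from .solver import simulate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, object] = {"fixture": name, "seed": seed}

    if name == "osc-a-noisy":
        trace = simulate(build_configuration("OSC_A"), get_params(),
                         t_end=1800.0)
        noisy = noisy_traces(resample(trace, 3.0), NoiseModel(seed=seed))
        path = out / "osc_a_noisy.csv"
        llio.write_traces(path, noisy)
        written.append(path)
        manifest.update(interval_min=3.0, t_end_min=1800.0)
    elif name == "ind-pair":
        for topo in ("IND", "IND_BLOCKED"):
            trace = simulate(build_configuration(topo), get_params(),
                             t_end=1800.0)
            path = out / f"{topo.lower()}.csv"
            llio.write_traces(path, resample(trace, 6.0))
            written.append(path)
        manifest.update(interval_min=6.0, t_end_min=1800.0)
    elif name in ("porosity-hp", "porosity-lp"):
        cutoff = HP_CUTOFF_NM if name.endswith("hp") else LP_CUTOFF_NM
        pre = sample_particles(1000, seed=seed)
        post = sieve(pre, SieveModel(cutoff=cutoff))
        tag = name.split("-")[1]
        for stage, sample in (("pre", pre), ("post", post)):
            path = out / f"particles_{tag}_{stage}.csv"
            llio.write_particles(path, sample)
            written.append(path)
        manifest.update(cutoff_nm=cutoff, n=1000)
    else:
        raise ConfigurationError(
            f"unknown fixture {name!r}; valid names: {list(FIXTURES)}"
        )

    mpath = out / "manifest.txt"
    lines = [f"{k}={v}" for k, v in manifest.items()]
    lines += [f"file={p.name}" for p in written]
    mpath.write_text("\n".join(lines) + "\n")
    written.append(mpath)
    return written
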