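"""Time-series container for fluorescence (and auxiliary) channels.

A :class:`TraceSet` is the unit every analysis stage consumes: a strictly
increasing time grid in minutes plus named channels (``F_sender``,
``F_receiver``, optionally ``H_*``, ``rho_*``) and free-form metadata
(topology, parameter-set name, dt, seed ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["TraceSet"]


@dataclass
class TraceSet:
    times: np.ndarray
    channels: dict[str, np.ndarray]
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ConfigurationError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        if not self.channels:
            raise ConfigurationError("TraceSet needs at least one channel")
        clean = {}
        for name, values in self.channels.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise ConfigurationError(
                    f"channel {name!r} has length {arr.size}, expected {self.times.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"channel {name!r} contains NaN/Inf")
            clean[name] = arr
        self.channels = clean

    def __len__(self) -> int:
        return len(self.times)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigurationError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None

    @property
    def step(self) -> float:
        """Native grid step (min); grids are uniform in practice."""
        return float(self.times[1] - self.times[0]) if len(self) > 1 else 0.0

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "TraceSet":
        """Sub-trace restricted to t_min <= t <= t_max."""
        m = (self.times >= t_min) & (self.times <= t_max)
        return TraceSet(
            self.times[m],
            {k: v[m] for k, v in self.channels.items()},
            dict(self.metadata),
        )

    def with_channels(self, channels: dict[str, np.ndarray]) -> "TraceSet":
        return TraceSet(self.times.copy(), channels, dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times})
        for name, values in self.channels.items():
            df[name] = values
        return df

    def equals(self, other: "TraceSet") -> bool:
        return (
            np.array_equal(self.times, other.times)
            and self.channel_names == other.channel_names
            and all(np.array_equal(self.channels[k], other.channels[k])
                    for k in self.channels)
        )
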