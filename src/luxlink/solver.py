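"""Fixed-step delay-differential integrator and period calibration.

The coupled circuit is a delay system: promoter drive depends on the
*sensed* (intracellular) AHL level a fixed delay ``tau_d`` in the past.
We integrate with a classical 4th-order Runge-Kutta scheme on a fixed
grid, storing the sensed-AHL history of both populations at every step
and linearly interpolating into it for the delayed values (stage times
fall mid-step).  History for t < 0 is the constant initial state
(density rho0, everything else zero), so delayed lookups before
``tau_d`` clamp to zero.

Fixed stepping keeps the delayed lookup trivial and the output
bit-reproducible; the delay (>= 5 min) is resolved by >= 100 steps at
the default dt = 0.05 min.  Values driven to the negative side by
round-off (within -1e-9) are clamped to zero; anything more negative
aborts with the time and field, since that signals instability rather
than rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import (
    CircuitConfig,
    ModelParams,
    PopulationCircuit,
)
from .errors import CalibrationError, ConfigurationError, IntegrationError
from .traces import TraceSet

__all__ = ["simulate", "calibrate_period", "CalibrationResult",
           "DEFAULT_DT", "DEFAULT_RECORD_EVERY", "TRANSIENT_DISCARD_MIN"]

DEFAULT_DT = 0.05             # min
DEFAULT_RECORD_EVERY = 1.0    # min
TRANSIENT_DISCARD_MIN = 300.0  # transient discarded before period analysis
NEGATIVE_CLAMP_TOL = -1e-9

_STATE_NAMES = (
    "rho_sender", "I_sender", "A_sender", "G_sender", "H_sender",
    "rho_receiver", "I_receiver", "A_receiver", "G_receiver", "H_receiver",
)


def _drive_code(circ: PopulationCircuit) -> tuple[bool, float]:
    """(is_plux, induction_time)."""
    return (circ.driver == "plux", circ.induction_time)


def simulate(config: CircuitConfig, params: ModelParams, t_end: float,
             dt: float = DEFAULT_DT,
             record_every: float = DEFAULT_RECORD_EVERY,
             initial=None) -> TraceSet:
    """Integrate the coupled system over [0, t_end] minutes.

    Returns a TraceSet with fluorescence channels ``F_sender`` and
    ``F_receiver`` plus the auxiliary channels ``H_*`` (AHL, nM) and
    ``rho_*`` (density).  Deterministic: identical inputs give
    bit-identical output.

    ``initial`` optionally overrides the default initial state (density
    rho0, all proteins and AHL at zero); it may be a
    :class:`~luxlink.circuit.SystemState` or a 10-element sequence in
    solver layout.  The constant pre-history for delayed lookups is
    taken from the initial state.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    if params.tau_d > 0 and dt > params.tau_d:
        raise ConfigurationError(
            f"dt={dt} under-resolves the delay tau_d={params.tau_d}"
        )
    if t_end < params.tau_d:
        raise ConfigurationError(
            f"t_end={t_end} must be >= tau_d={params.tau_d}"
        )
    ratio = record_every / dt
    if record_every <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            f"record_every={record_every} must be a positive multiple of dt={dt}"
        )
    rec_stride = int(round(ratio))
    n_steps = int(round(t_end / dt))

    # unpack everything into plain floats: this loop is the hot path
    delta, alpha, C0, nh = params.delta, params.alpha, params.C0, params.n_hill
    kI, kA = params.kappa_I, params.kappa_A
    kG_pop = (params.kappa_G, params.kappa_G_receiver)
    gE, Kclp, mu = params.gamma_E, params.K_clp, params.mu_dil
    gA, KAd = params.gamma_A, params.K_A_deg
    b, Ksyn = params.b, params.K_syn
    kcat, KM, kin, muH = params.k_cat, params.K_M, params.k_in, params.mu_H
    r = params.r_growth
    kx = params.k_x if config.coupling_enabled else 0.0
    flags = tuple(
        (float(c.has_luxI), float(c.has_aiiA), float(c.has_reporter))
        + _drive_code(c)
        for c in (config.sender, config.receiver)
    )

    def sensed(H: float, A: float) -> float:
        vA = kcat * A / kin
        bq = KM + vA - H
        return 0.5 * (-bq + math.sqrt(bq * bq + 4.0 * H * KM))

    if initial is None:
        y0 = [0.0] * 10
        y0[0] = y0[5] = params.rho0
    elif hasattr(initial, "as_array"):
        y0 = [float(v) for v in initial.as_array()]
    else:
        y0 = [float(v) for v in initial]
        if len(y0) != 10:
            raise ConfigurationError("initial state must have 10 components")

    lag = params.tau_d / dt  # delay in (fractional) steps
    hS = np.zeros(n_steps + 1)
    hR = np.zeros(n_steps + 1)
    hS[0] = sensed(y0[4], y0[2])
    hR[0] = sensed(y0[9], y0[7])
    h_pre = (hS[0], hR[0])  # constant pre-history for t < 0

    def delayed(i: float) -> tuple[float, float]:
        j = i - lag
        if j <= 0.0:
            return h_pre
        j0 = int(j)
        f = j - j0
        if f == 0.0:
            return hS[j0], hR[j0]
        return (hS[j0] * (1.0 - f) + hS[j0 + 1] * f,
                hR[j0] * (1.0 - f) + hR[j0 + 1] * f)

    def rhs(t, y, hd):
        out = [0.0] * 10
        for ip in range(2):
            o = 5 * ip
            rho, I, A, G, H = y[o], y[o + 1], y[o + 2], y[o + 3], y[o + 4]
            fI, fA, fG, is_plux, t_ind = flags[ip]
            if is_plux:
                x = (hd[ip] / C0) ** nh
                D = delta + alpha * x / (1.0 + x)
            else:
                D = 1.0 if t >= t_ind else 0.0
            deg = gE / (1.0 + (I + G) / Kclp) + mu
            degA = gA / (KAd + A) + mu
            out[o] = r * rho * (1.0 - rho)
            out[o + 1] = fI * kI * D - deg * I
            out[o + 2] = fA * kA * D - degA * A
            out[o + 3] = fG * kG_pop[ip] * D - deg * G
            H_other = y[9 - 5 * ip]
            out[o + 4] = (b * I / (1.0 + I / Ksyn) * rho
                          - kcat * A * rho * H / (KM + H)
                          - muH * H + kx * (H_other - H))
        return out

    y = list(y0)
    half = dt / 2.0
    sixth = dt / 6.0

    n_rec = n_steps // rec_stride + 1
    recorded = np.empty((n_rec, 10))
    recorded[0] = y
    rec_i = 1

    for i in range(n_steps):
        t = i * dt
        hd0 = delayed(float(i))
        hd1 = delayed(i + 0.5)
        hd2 = delayed(i + 1.0)
        k1 = rhs(t, y, hd0)
        y2 = [y[j] + half * k1[j] for j in range(10)]
        k2 = rhs(t + half, y2, hd1)
        y3 = [y[j] + half * k2[j] for j in range(10)]
        k3 = rhs(t + half, y3, hd1)
        y4 = [y[j] + dt * k3[j] for j in range(10)]
        k4 = rhs(t + dt, y4, hd2)
        y = [y[j] + sixth * (k1[j] + 2.0 * (k2[j] + k3[j]) + k4[j])
             for j in range(10)]
        for j in range(10):
            v = y[j]
            if v != v or v == math.inf or v == -math.inf:
                raise IntegrationError(
                    f"non-finite {_STATE_NAMES[j]} at t={t + dt:.3f} min"
                )
            if v < 0.0:
                if v < NEGATIVE_CLAMP_TOL:
                    raise IntegrationError(
                        f"{_STATE_NAMES[j]}={v} went negative at "
                        f"t={t + dt:.3f} min (instability; reduce dt)"
                    )
                y[j] = 0.0
        hS[i + 1] = sensed(y[4], y[2])
        hR[i + 1] = sensed(y[9], y[7])
        if (i + 1) % rec_stride == 0:
            recorded[rec_i] = y
            rec_i += 1

    times = np.arange(n_rec) * (rec_stride * dt)
    channels = {
        "F_sender": recorded[:, 0] * recorded[:, 3],
        "F_receiver": recorded[:, 5] * recorded[:, 8],
        "H_sender": recorded[:, 4],
        "H_receiver": recorded[:, 9],
        "rho_sender": recorded[:, 0],
        "rho_receiver": recorded[:, 5],
    }
    metadata = {
        "topology": config.name,
        "param_set": params.name,
        "dt": dt,
        "record_every": record_every,
        "t_end": t_end,
    }
    return TraceSet(times, channels, metadata)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a period calibration grid search."""

    params: ModelParams
    achieved_period: float
    target_period: float
    tau_d: float
    gamma_E: float
    n_evaluated: int


def calibrate_period(config: CircuitConfig, base: ModelParams,
                     target_period: float,
                     tau_grid, gamma_grid,
                     t_end: float = 1200.0,
                     dt: float = DEFAULT_DT,
                     transient: float = TRANSIENT_DISCARD_MIN,
                     return_details: bool = False):
    """Grid-search (tau_d, gamma_E) for a target oscillation period.

    Simulates each grid point, discards the transient, estimates the
    sender-channel period (median inter-peak interval at the default
    detection settings) and returns the parameter set minimising the
    absolute period error.  Deterministic: grid order decides ties
    (first-found wins).  Raises :class:`CalibrationError` when no grid
    point yields at least three detected peaks.
    """
    from .analysis import detect_peaks, estimate_period  # avoid module cycle

    tau_grid = [float(t) for t in tau_grid]
    gamma_grid = [float(g) for g in gamma_grid]
    if not tau_grid or not gamma_grid:
        raise ConfigurationError("calibration grids must be non-empty")
    if target_period <= 0:
        raise ConfigurationError(
            f"target_period must be > 0, got {target_period}"
        )

    best = None
    n_eval = 0
    for tau in tau_grid:
        for gamma in gamma_grid:
            cand = base.replace(tau_d=tau, gamma_E=gamma)
            trace = simulate(config, cand, t_end=t_end, dt=dt)
            n_eval += 1
            tail = trace.window(t_min=transient)
            peaks = detect_peaks(tail.times, tail.channel("F_sender"))
            if len(peaks) < 3:
                continue
            period = estimate_period(peaks)
            err = abs(period - target_period)
            if best is None or err < best[0] - 1e-12:
                best = (err, tau, gamma, period)
    if best is None:
        raise CalibrationError(
            f"no grid point over tau_d={tau_grid} x gamma_E={gamma_grid} "
            f"produced >= 3 peaks; the circuit does not oscillate there"
        )
    _, tau, gamma, period = best
    params = base.replace(tau_d=tau, gamma_E=gamma,
                          name=f"calibrated(tau_d={tau:g},gamma_E={gamma:g})")
    if return_details:
        return CalibrationResult(params, period, target_period, tau, gamma,
                                 n_eval)
    return params
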