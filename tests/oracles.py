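"""Independent reference implementations used only as test oracles.

The forward-Euler delay integrator below is coded separately from the
package solver (different scheme, different code path) and serves as the
cross-check for the RK4 implementation.  Its first-order discretization
error is removed by Richardson extrapolation (two runs at dt and dt/2),
which keeps the oracle independent while making it accurate enough to
resolve solver defects.
"""

from __future__ import annotations

import math

import numpy as np


def euler_dde(config, p, t_end: float, dt: float,
              record_every: float = 1.0) -> np.ndarray:
    """First-order Euler integration of the two-population delay model.

    Returns the recorded state array with rows (rho, I, A, G, H) for the
    sender then the receiver, one row per ``record_every`` minutes.
    """
    flags = []
    for c in (config.sender, config.receiver):
        flags.append((1.0 if c.has_luxI else 0.0,
                      1.0 if c.has_aiiA else 0.0,
                      1.0 if c.has_reporter else 0.0,
                      c.driver == "plux", c.induction_time))
    kx = p.k_x if config.coupling_enabled else 0.0
    kG = (p.kappa_G, p.kappa_G_receiver)
    n = int(round(t_end / dt))
    stride = int(round(record_every / dt))
    lagn = int(round(p.tau_d / dt))
    hs = [0.0] * (n + 1)
    hr = [0.0] * (n + 1)
    y = [0.0] * 10
    y[0] = y[5] = p.rho0
    rec = [list(y)]

    def sensed(H, A):
        vA = p.k_cat * A / p.k_in
        bq = p.K_M + vA - H
        return 0.5 * (-bq + math.sqrt(bq * bq + 4.0 * H * p.K_M))

    for i in range(n):
        t = i * dt
        j = i - lagn
        hd = (hs[j] if j > 0 else 0.0, hr[j] if j > 0 else 0.0)
        dy = [0.0] * 10
        for ip in range(2):
            o = 5 * ip
            rho, I, A, G, H = y[o:o + 5]
            fI, fA, fG, plux, tind = flags[ip]
            if plux:
                x = (hd[ip] / p.C0) ** p.n_hill
                D = p.delta + p.alpha * x / (1.0 + x)
            else:
                D = 1.0 if t >= tind else 0.0
            deg = p.gamma_E / (1.0 + (I + G) / p.K_clp) + p.mu_dil
            degA = p.gamma_A / (p.K_A_deg + A) + p.mu_dil
            dy[o] = p.r_growth * rho * (1 - rho)
            dy[o + 1] = fI * p.kappa_I * D - deg * I
            dy[o + 2] = fA * p.kappa_A * D - degA * A
            dy[o + 3] = fG * kG[ip] * D - deg * G
            Ho = y[9 - 5 * ip]
            dy[o + 4] = (p.b * I / (1.0 + I / p.K_syn) * rho
                         - p.k_cat * A * rho * H / (p.K_M + H)
                         - p.mu_H * H + kx * (Ho - H))
        y = [max(0.0, y[k] + dt * dy[k]) for k in range(10)]
        hs[i + 1] = sensed(y[4], y[2])
        hr[i + 1] = sensed(y[9], y[7])
        if (i + 1) % stride == 0:
            rec.append(list(y))
    return np.array(rec)


def euler_dde_richardson(config, p, t_end: float, dt: float = 0.002,
                         record_every: float = 1.0) -> np.ndarray:
    """Richardson-extrapolated Euler oracle (second-order accurate)."""
    coarse = euler_dde(config, p, t_end, dt, record_every)
    fine = euler_dde(config, p, t_end, dt / 2.0, record_every)
    return 2.0 * fine - coarse
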