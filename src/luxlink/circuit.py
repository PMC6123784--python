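"""Gene-circuit model of two quorum-sensing populations coupled by diffusion.

Two *E. coli* populations — a *sender* and a *receiver* — grow in separate
microfluidic compartments joined by a molecule-permeable nanocellulose
filter.  Each population carries some subset of three genes:

* ``luxI`` — synthase producing the diffusible signal AHL
  (acyl-homoserine lactone),
* ``aiiA`` — lactonase hydrolysing AHL (the negative-feedback element),
* a fluorescent reporter (CFP/GFP/sfGFP, modelled identically up to the
  synthesis rate of the cassette).

Genes are driven either by the AHL-activated *lux* promoter (with a
transcription-translation delay) or by an arabinose-inducible promoter
modelled as an ideal step.  LuxR is constitutive and non-limiting and is
folded into the Hill activation function.

Dynamical variables per population: cell density ``rho`` (fraction of
trap capacity, logistic growth), protein levels ``I`` (LuxI), ``A``
(AiiA), ``G`` (reporter) in arbitrary units, and compartment AHL
concentration ``H`` in nM.

Kinetic structure (see docs/methods.md for the reasoning):

* LuxI and the reporter carry LAA tags and share saturable ClpXP
  degradation, rate ``gamma_E * X / (1 + (I+G)/K_clp)`` plus dilution;
* AiiA is degraded through its own saturable pathway,
  ``gamma_A * A / (K_A_deg + A)`` plus dilution — its turnover does not
  load the ClpXP queue shared by the tagged proteins;
* AHL synthesis saturates in LuxI (substrate limitation):
  ``b * I / (1 + I/K_syn) * rho``;
* AHL is hydrolysed intracellularly; the compartment sees the
  Michaelis-Menten lactonase sink ``k_cat*A*rho*H/(K_M+H)``, and the
  *promoter* sees the intracellular AHL level ``h`` obtained from a
  quasi-steady balance between membrane influx ``k_in*(H - h)`` and
  intracellular hydrolysis — high lactonase levels shield the promoter
  even when compartment AHL is high;
* compartments exchange AHL at rate ``k_x`` (zero when the filter is
  replaced by a solid block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from .errors import ConfigurationError, InputDomainError, NumericalStateError

__all__ = [
    "PopulationState",
    "PopulationCircuit",
    "CircuitConfig",
    "ModelParams",
    "SystemState",
    "promoter_activity",
    "sensed_ahl",
    "build_configuration",
    "model_rhs",
    "observable",
    "get_params",
    "TOPOLOGIES",
    "PARAM_SETS",
]

#: canonical ordering of the flat state vector used by the solver
STATE_FIELDS = ("rho", "I", "A", "G", "H")
POPULATIONS = ("sender", "receiver")


@dataclass
class PopulationState:
    """State of one population: density, proteins, local AHL.

    rho is dimensionless (fraction of trap capacity, in [0, 1]); I, A, G
    are protein amounts in arbitrary units per trap; H is the AHL
    concentration in the compartment, nM.
    """

    rho: float
    I: float
    A: float
    G: float
    H: float

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise NumericalStateError(f"non-finite value in field {name!r}: {v}")
            if v < 0:
                raise InputDomainError(f"{name} must be >= 0, got {v}")
        if self.rho > 1.0:
            raise InputDomainError(f"rho must be <= 1, got {self.rho}")

    def as_array(self) -> np.ndarray:
        return np.array([self.rho, self.I, self.A, self.G, self.H], dtype=float)


@dataclass(frozen=True)
class PopulationCircuit:
    """Gene content of one population.

    ``driver`` is the promoter driving this population's expression
    cassette (every gene the population carries): ``"plux"`` for the
    AHL-activated lux promoter, ``"arabinose"`` for the inducible step.
    In every experimental layout modelled here the genes of a population
    sit behind a single promoter, so one driver per population suffices.
    """

    has_luxI: bool = False
    has_aiiA: bool = False
    has_reporter: bool = False
    driver: str = "plux"
    induction_time: float = 0.0  # min; used only when driver == "arabinose"

    def __post_init__(self) -> None:
        if self.driver not in ("plux", "arabinose"):
            raise ConfigurationError(
                f"driver must be 'plux' or 'arabinose', got {self.driver!r}"
            )
        if self.induction_time < 0:
            raise ConfigurationError(
                f"induction_time must be >= 0, got {self.induction_time}"
            )


@dataclass(frozen=True)
class CircuitConfig:
    """Topology of the two-population system (sender, receiver, coupling)."""

    sender: PopulationCircuit
    receiver: PopulationCircuit
    coupling_enabled: bool = True
    name: str = "custom"

    def population(self, which: str) -> PopulationCircuit:
        if which not in POPULATIONS:
            raise ConfigurationError(
                f"unknown population {which!r}; expected one of {POPULATIONS}"
            )
        return self.sender if which == "sender" else self.receiver

    def produces_ahl(self, which: str) -> bool:
        """A population produces AHL iff it carries luxI (whatever drives it)."""
        return self.population(which).has_luxI


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the delay model.

    Time in minutes, AHL in nM, proteins in arbitrary units (a.u.).
    The shipped set "default-v1" is calibrated so the full oscillator
    (topology OSC_A) cycles with a period close to one hour.
    """

    delta: float = 0.02        # basal promoter activity, dimensionless
    alpha: float = 1.0         # maximal induced promoter activity, dimensionless
    C0: float = 30.0           # AHL half-activation, nM
    n_hill: float = 2.0        # Hill coefficient
    tau_d: float = 5.0        # transcription-translation delay, min
    kappa_I: float = 7.0       # LuxI synthesis rate, a.u./min
    kappa_A: float = 15.0      # AiiA synthesis rate, a.u./min
    kappa_G: float = 3.2       # sender reporter synthesis rate, a.u./min
    kappa_G_receiver: float = 14.0  # receiver (sfGFP) synthesis rate, a.u./min
    gamma_E: float = 3.5       # maximal ClpXP degradation rate, a.u./min
    K_clp: float = 1.0         # ClpXP saturation constant, a.u.
    gamma_A: float = 2.25       # maximal AiiA degradation rate, a.u./min
    K_A_deg: float = 1.0       # AiiA degradation saturation constant, a.u.
    mu_dil: float = 0.005       # protein dilution/washout, 1/min
    b: float = 56.0            # AHL synthesis per unit LuxI, nM/(min a.u.)
    K_syn: float = 1.2         # LuxI level at half-maximal AHL synthesis, a.u.
    k_cat: float = 2.0         # lactonase turnover, 1/(min a.u.)
    K_M: float = 50.0          # lactonase Michaelis constant, nM
    k_in: float = 0.7          # cell-membrane AHL exchange, 1/min
    mu_H: float = 0.05         # AHL washout, 1/min
    k_x: float = 8.8           # inter-compartment exchange, 1/min
    r_growth: float = math.log(81.0) / 180.0  # logistic growth, 1/min
    rho0: float = 0.1          # initial density, dimensionless
    name: str = "custom"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "name":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(
                    f"parameter {f.name} must be finite and >= 0, got {v}"
                )
        if self.n_hill < 1:
            raise ConfigurationError(f"n_hill must be >= 1, got {self.n_hill}")
        for positive in ("C0", "K_clp", "K_M", "K_A_deg", "K_syn", "k_in"):
            if getattr(self, positive) <= 0:
                raise ConfigurationError(f"{positive} must be > 0")
        if self.rho0 > 1:
            raise ConfigurationError(f"rho0 must be <= 1, got {self.rho0}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def kappa_G_for(self, which: str) -> float:
        if which == "sender":
            return self.kappa_G
        if which == "receiver":
            return self.kappa_G_receiver
        raise ConfigurationError(f"unknown population {which!r}")


@dataclass
class SystemState:
    """Full state of the coupled system at time t (min)."""

    sender: PopulationState
    receiver: PopulationState
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InputDomainError(f"t must be >= 0, got {self.t}")

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.sender.as_array(), self.receiver.as_array()])

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "SystemState":
        s = PopulationState(*y[:5])
        r = PopulationState(*y[5:10])
        return cls(sender=s, receiver=r, t=t)


def promoter_activity(H_delayed: float, params: ModelParams) -> float:
    """Lux promoter activity for a (delayed, sensed) AHL level.

    Hill activation with basal leak: P(H) = delta + alpha*H^n/(C0^n+H^n).
    Output is bounded in [delta, delta + alpha] and monotone in H.
    """
    if H_delayed < 0:
        raise InputDomainError(f"H_delayed must be >= 0, got {H_delayed}")
    hn = (H_delayed / params.C0) ** params.n_hill
    return params.delta + params.alpha * hn / (1.0 + hn)


def sensed_ahl(H: float, A: float, params: ModelParams) -> float:
    """Intracellular AHL level seen by LuxR, given compartment AHL and AiiA.

    Quasi-steady balance of membrane influx k_in*(H - h) against
    intracellular hydrolysis k_cat*A*h/(K_M + h); the positive root of
    the resulting quadratic.  With no lactonase (A = 0) the cytoplasm
    simply tracks the compartment (h = H); high AiiA levels deplete
    intracellular AHL far below the compartment concentration.
    """
    if H < 0 or A < 0:
        raise InputDomainError("H and A must be >= 0")
    vA = params.k_cat * A / params.k_in
    bq = params.K_M + vA - H
    return 0.5 * (-bq + math.sqrt(bq * bq + 4.0 * H * params.K_M))


# ---------------------------------------------------------------------------
# Named experimental topologies.
#
#  IND          sender: arabinose -> LuxI + CFP (induced at 180 min);
#               receiver: plux -> GFP.  Filter present.
#  IND_BLOCKED  as IND but the filter is a solid block (no exchange).
#  OSC_A        sender: plux -> luxI + aiiA + gfp (full oscillator);
#               receiver: plux -> aiiA + sfGFP.
#  OSC_B        OSC_A without receiver aiiA (no negative feedback in the
#               responder -> reporter accumulates).
#  OSC_C        OSC_A without sender aiiA (responder aiiA quenches the
#               signal -> reporter suppressed).
# ---------------------------------------------------------------------------

def _topologies() -> dict[str, CircuitConfig]:
    plux = dict(driver="plux")
    osc_sender = PopulationCircuit(has_luxI=True, has_aiiA=True, has_reporter=True, **plux)
    return {
        "IND": CircuitConfig(
            sender=PopulationCircuit(
                has_luxI=True, has_reporter=True,
                driver="arabinose", induction_time=180.0,
            ),
            receiver=PopulationCircuit(has_reporter=True, **plux),
            coupling_enabled=True, name="IND",
        ),
        "IND_BLOCKED": CircuitConfig(
            sender=PopulationCircuit(
                has_luxI=True, has_reporter=True,
                driver="arabinose", induction_time=180.0,
            ),
            receiver=PopulationCircuit(has_reporter=True, **plux),
            coupling_enabled=False, name="IND_BLOCKED",
        ),
        "OSC_A": CircuitConfig(
            sender=osc_sender,
            receiver=PopulationCircuit(has_aiiA=True, has_reporter=True, **plux),
            coupling_enabled=True, name="OSC_A",
        ),
        "OSC_B": CircuitConfig(
            sender=osc_sender,
            receiver=PopulationCircuit(has_reporter=True, **plux),
            coupling_enabled=True, name="OSC_B",
        ),
        "OSC_C": CircuitConfig(
            sender=PopulationCircuit(has_luxI=True, has_reporter=True, **plux),
            receiver=PopulationCircuit(has_aiiA=True, has_reporter=True, **plux),
            coupling_enabled=True, name="OSC_C",
        ),
    }


TOPOLOGIES: dict[str, CircuitConfig] = _topologies()


def build_configuration(name: str) -> CircuitConfig:
    """Return one of the named experimental topologies (see module docs)."""
    try:
        return TOPOLOGIES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown topology {name!r}; valid names: {sorted(TOPOLOGIES)}"
        ) from None


def _drive(circ: PopulationCircuit, h_delayed: float, t: float,
           params: ModelParams) -> float:
    """Promoter drive D(t) for a population's cassette."""
    if circ.driver == "plux":
        return promoter_activity(h_delayed, params)
    return 1.0 if t >= circ.induction_time else 0.0


def rhs_array(t: float, y: np.ndarray, delayed_H: tuple[float, float],
              config: CircuitConfig, params: ModelParams) -> np.ndarray:
    """Time derivative of the flat state vector.

    Layout: (rho, I, A, G, H) for the sender followed by the receiver.
    ``delayed_H`` holds the *sensed* (intracellular) AHL at time
    t - tau_d for (sender, receiver).  No validation — solver hot path.
    """
    dy = np.empty(10)
    kx = params.k_x if config.coupling_enabled else 0.0
    for ip, (circ, pop) in enumerate(
        zip((config.sender, config.receiver), POPULATIONS)
    ):
        o = 5 * ip
        rho, I, A, G, H = y[o], y[o + 1], y[o + 2], y[o + 3], y[o + 4]
        D = _drive(circ, delayed_H[ip], t, params)
        deg = params.gamma_E / (1.0 + (I + G) / params.K_clp) + params.mu_dil
        deg_A = params.gamma_A / (params.K_A_deg + A) + params.mu_dil
        dy[o] = params.r_growth * rho * (1.0 - rho)
        dy[o + 1] = (params.kappa_I * D if circ.has_luxI else 0.0) - deg * I
        dy[o + 2] = (params.kappa_A * D if circ.has_aiiA else 0.0) - deg_A * A
        dy[o + 3] = ((params.kappa_G_for(pop) * D if circ.has_reporter else 0.0)
                     - deg * G)
        H_other = y[9 - 5 * ip]
        dy[o + 4] = (
            params.b * I / (1.0 + I / params.K_syn) * rho
            - params.k_cat * A * rho * H / (params.K_M + H)
            - params.mu_H * H
            + kx * (H_other - H)
        )
    return dy


def model_rhs(state: SystemState, delayed_H: tuple[float, float],
              config: CircuitConfig, params: ModelParams,
              t: float | None = None) -> SystemState:
    """Derivative of the coupled system, returned as a SystemState-shaped object.

    ``delayed_H`` are the sensed AHL levels (sender, receiver) at time
    t - tau_d; for t < tau_d the caller clamps to the initial history
    (zero).
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        pop = POPULATIONS[bad // 5]
        raise NumericalStateError(
            f"non-finite state in {pop}.{STATE_FIELDS[bad % 5]}"
        )
    for h in delayed_H:
        if h < 0 or not math.isfinite(h):
            raise InputDomainError(f"delayed H must be finite and >= 0, got {h}")
    tt = state.t if t is None else t
    dy = rhs_array(tt, y, tuple(delayed_H), config, params)
    # derivative components may be negative, so bypass the state validators
    s = PopulationState.__new__(PopulationState)
    r = PopulationState.__new__(PopulationState)
    for i, fname in enumerate(STATE_FIELDS):
        setattr(s, fname, float(dy[i]))
        setattr(r, fname, float(dy[5 + i]))
    out = SystemState.__new__(SystemState)
    out.sender, out.receiver, out.t = s, r, tt
    return out


def observable(state: SystemState, population: str) -> float:
    """Trap-averaged fluorescence F = rho * G for one population.

    Mirrors how mean intensities are measured over the whole trap area:
    per-cell reporter level times the fraction of the trap that is cells.
    """
    pop = getattr(state, population, None)
    if population not in POPULATIONS or pop is None:
        raise ConfigurationError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        )
    return pop.rho * pop.G


# Named parameter sets.  "base-v1" is the uncalibrated base; "default-v1"
# fixes (tau_d, gamma_E) = (5, 3.5), the output of solver.calibrate_period
# on OSC_A against a 60-minute target over tau_d in {5..20} and gamma_E in
# {3.0, 3.5, 4.0}; see docs/methods.md and tests for the regeneration check.
CALIBRATION_TAU_GRID = (5.0, 8.0, 11.0, 14.0, 17.0, 20.0)
CALIBRATION_GAMMA_GRID = (3.0, 3.5, 4.0)
CALIBRATION_TARGET_MIN = 60.0

PARAM_SETS: dict[str, ModelParams] = {
    "base-v1": ModelParams(name="base-v1"),
    "default-v1": ModelParams(tau_d=5.0, gamma_E=3.5, name="default-v1"),
}


def get_params(name: str = "default-v1") -> ModelParams:
    """Look up a named, shipped parameter set."""
    try:
        return PARAM_SETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown parameter set {name!r}; valid names: {sorted(PARAM_SETS)}"
        ) from None
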