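"""Dynamic-clamp-style membrane simulator.

Simulates the current-clamp response of a high-impedance cultured cell into
which a Hodgkin-Huxley sodium current (and optionally a delayed-rectifier
potassium current) is injected, the numerical analogue of a dynamic-clamp
experiment: the passive cell supplies only leak and capacitance, every
voltage-gated current is "injected" by the model.

Units follow the patch-clamp convention used throughout the package:
millivolts, milliseconds, picofarads, gigaohms, nanosiemens and picoamperes
(a consistent set: pF*mV/ms = pA, mV/GOhm = pA, nS*mV = pA).

The gating rate functions are the classical squid-axon forms expressed on a
shifted voltage axis.  ``v_shift`` moves the whole kinetic scheme so that the
depolarized resting potential of immature cultured cells (about -30 mV) maps
onto the operating point of the classical scheme; the default shift of
+35.3 mV places a cell resting at -29.7 mV exactly at the classical -65 mV
resting point.  ``tau_scale`` divides every rate (alpha and beta together),
which leaves the steady-state activation curves untouched and stretches all
time constants uniformly -- the construction used to turn a "fast" (mature)
sodium current into a "slow" (immature) one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, NumericalInstabilityError, ProtocolError

__all__ = [
    "PassiveMembrane",
    "NaKinetics",
    "KKinetics",
    "StimProtocol",
    "VoltageTrace",
    "na_current",
    "gating_rates",
    "steady_state_gates",
    "simulate_current_clamp",
]

#: Classical squid-axon rate-function coefficients (rates in 1/ms, voltages in
#: mV on the unshifted axis where the resting potential is -65 mV).
DEFAULT_RATE_PARAMS: dict[str, float] = {
    "am_scale": 0.1, "am_v0": -40.0, "am_k": 10.0,
    "bm_scale": 4.0, "bm_v0": -65.0, "bm_k": 18.0,
    "ah_scale": 0.07, "ah_v0": -65.0, "ah_k": 20.0,
    "bh_v0": -35.0, "bh_k": 10.0,
}

DEFAULT_K_RATE_PARAMS: dict[str, float] = {
    "an_scale": 0.01, "an_v0": -55.0, "an_k": 10.0,
    "bn_scale": 0.125, "bn_v0": -65.0, "bn_k": 80.0,
}


def _linoid(v: np.ndarray | float, scale: float, v0: float, k: float):
    """scale*(v-v0)/(1-exp(-(v-v0)/k)) with the removable singularity at v0 filled in."""
    x = np.asarray(v, dtype=float) - v0
    with np.errstate(over="ignore", invalid="ignore"):
        out = scale * x / (1.0 - np.exp(-x / k))
    # L'Hopital at x -> 0: limit is scale*k
    out = np.where(np.abs(x) < 1e-7, scale * k, out)
    return out if out.ndim else float(out)


@dataclass
class PassiveMembrane:
    """Passive electrical properties of a cultured cell.

    capacitance in pF, input_resistance in GOhm, resting_potential in mV.
    """

    capacitance: float = 18.3
    input_resistance: float = 3.3
    resting_potential: float = -29.7

    def __post_init__(self):
        if self.capacitance <= 0:
            raise DomainError(f"capacitance must be positive, got {self.capacitance}")
        if self.input_resistance <= 0:
            raise DomainError(f"input_resistance must be positive, got {self.input_resistance}")
        if not -90.0 <= self.resting_potential <= 10.0:
            raise DomainError(
                f"resting_potential {self.resting_potential} mV outside [-90, +10] mV"
            )

    @property
    def tau_ms(self) -> float:
        """Membrane time constant R_in * C_m in ms (GOhm * pF = ms)."""
        return self.input_resistance * self.capacitance

    @property
    def leak_conductance_ns(self) -> float:
        return 1.0 / self.input_resistance


@dataclass
class NaKinetics:
    """Parameters of the simulated sodium current I_Na = g_max m^p h^q (V - V_Na).

    ``tau_scale`` >= 1 slows every gating transition uniformly (1 = "fast",
    larger = "slow") without changing steady states.  ``v_shift`` translates
    the classical rate functions along the voltage axis so that the scheme
    operates correctly around the depolarized resting potential of cultured
    cells.
    """

    g_na_max: float = 2200.0          # nS; classical 120 mS/cm2 density at 18.3 pF
    reversal: float = 50.0            # mV
    activation_exponent: int = 3
    inactivation_exponent: int = 1
    tau_scale: float = 1.0
    v_shift: float = 35.3             # mV; maps V_rest = -29.7 onto classical -65
    rate_params: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATE_PARAMS))

    def __post_init__(self):
        if self.g_na_max < 0:
            raise DomainError("g_na_max must be >= 0")
        if self.tau_scale < 1:
            raise DomainError("tau_scale must be >= 1")
        if self.activation_exponent < 1:
            raise DomainError("activation_exponent must be >= 1")
        if self.inactivation_exponent < 0:
            raise DomainError("inactivation_exponent must be >= 0")


@dataclass
class KKinetics:
    """Optional delayed-rectifier current I_K = g_max n^p (V - E_K).

    Off by default throughout the API (``g_k_max`` must be supplied); it models
    the native repolarizing conductance of the host cell, which the dynamic
    clamp does not inject but which shapes the recorded action potential.
    """

    g_k_max: float = 660.0            # nS; classical 36 mS/cm2 density at 18.3 pF
    reversal: float = -41.7           # mV; classical -77 mV shifted by +35.3
    activation_exponent: int = 4
    tau_scale: float = 1.0
    v_shift: float = 35.3
    rate_params: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_K_RATE_PARAMS))

    def __post_init__(self):
        if self.g_k_max < 0:
            raise DomainError("g_k_max must be >= 0")
        if self.tau_scale < 1:
            raise DomainError("tau_scale must be >= 1")

    def rates(self, v):
        p, vv = self.rate_params, np.asarray(v, dtype=float) - self.v_shift
        alpha_n = _linoid(vv, p["an_scale"], p["an_v0"], p["an_k"])
        beta_n = p["bn_scale"] * np.exp(-(vv - p["bn_v0"]) / p["bn_k"])
        return alpha_n / self.tau_scale, beta_n / self.tau_scale


@dataclass
class StimProtocol:
    """A rectangular current step: amplitude in pA, times in ms."""

    step_amplitude: float = 100.0
    onset: float = 10.0
    duration: float = 5.0
    total_time: float = 120.0
    dt: float = 0.025

    def __post_init__(self):
        if self.dt <= 0:
            raise ProtocolError(f"dt must be positive, got {self.dt}")
        if self.duration < 0 or self.onset < 0:
            raise ProtocolError("onset and duration must be non-negative")
        if self.onset + self.duration > self.total_time + 1e-12:
            raise ProtocolError(
                f"onset+duration ({self.onset + self.duration} ms) exceeds "
                f"total_time ({self.total_time} ms)"
            )

    def current(self, t: np.ndarray) -> np.ndarray:
        """Injected current in pA at times t (ms)."""
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.onset) & (t < self.onset + self.duration),
                        self.step_amplitude, 0.0)


@dataclass
class VoltageTrace:
    """A membrane-voltage time series on a uniform grid (times ms, vm mV)."""

    times: np.ndarray
    vm: np.ndarray
    dt: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.times.shape != self.vm.shape:
            raise DomainError("times and vm must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=1e-9, atol=1e-9):
                raise DomainError("times must increase with constant spacing dt")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.vm])
        np.savetxt(path, arr, delimiter=",", header="time_ms,vm_mV", comments="", fmt="%.9g")

    @classmethod
    def from_csv(cls, path) -> "VoltageTrace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        t = arr[:, 0]
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(times=t, vm=arr[:, 1], dt=dt)


def na_current(v, m, h, k: NaKinetics):
    """Sodium current in pA; negative = inward (depolarizing).

    I = g_max * m^p * h^q * (v - V_Na).
    """
    m_arr, h_arr = np.asarray(m, dtype=float), np.asarray(h, dtype=float)
    if np.any((m_arr < 0) | (m_arr > 1)) or np.any((h_arr < 0) | (h_arr > 1)):
        raise DomainError("gating variables m and h must lie in [0, 1]")
    out = (k.g_na_max * m_arr ** k.activation_exponent
           * h_arr ** k.inactivation_exponent * (np.asarray(v, dtype=float) - k.reversal))
    return float(out) if out.ndim == 0 else out


def gating_rates(v, k: NaKinetics):
    """Rate constants (alpha_m, beta_m, alpha_h, beta_h) in 1/ms at voltage v.

    Both alpha and beta are divided by ``tau_scale`` so a slow current has the
    same steady states as its fast counterpart with uniformly longer time
    constants.
    """
    p = k.rate_params
    vv = np.asarray(v, dtype=float) - k.v_shift
    alpha_m = _linoid(vv, p["am_scale"], p["am_v0"], p["am_k"])
    beta_m = p["bm_scale"] * np.exp(-(vv - p["bm_v0"]) / p["bm_k"])
    alpha_h = p["ah_scale"] * np.exp(-(vv - p["ah_v0"]) / p["ah_k"])
    beta_h = 1.0 / (1.0 + np.exp(-(vv - p["bh_v0"]) / p["bh_k"]))
    s = k.tau_scale
    return alpha_m / s, beta_m / s, alpha_h / s, beta_h / s


def steady_state_gates(v: float, k: NaKinetics) -> tuple[float, float]:
    """(m_inf, h_inf) at voltage v."""
    am, bm, ah, bh = gating_rates(v, k)
    return float(am / (am + bm)), float(ah / (ah + bh))


def simulate_current_clamp(
    mem: PassiveMembrane,
    na: NaKinetics | None,
    proto: StimProtocol,
    kdr: KKinetics | None = None,
    hold_at_rest: bool = True,
    record_gates: bool = False,
):
    """Integrate the current-clamp response of the cell.

    C dV/dt = -(V - V_rest)/R_in - I_Na - I_K + I_inj(t) + I_hold

    With ``na`` absent (and no ``kdr``) this is a plain RC response.  Gates are
    advanced by exponential (Rush-Larsen) updates; the voltage is advanced by
    an exponential update with conductances frozen over the step, which is
    exact for the passive cell and unconditionally stable at the 40 kHz
    command rate even at full sodium conductance.

    ``hold_at_rest`` adds the constant bias current that balances the injected
    conductances at V_rest, so the recorded resting potential is an exact
    equilibrium of the model (the experimental resting potential is measured
    with all native currents in place).

    Returns a :class:`VoltageTrace`; with ``record_gates=True`` returns
    ``(trace, gates)`` where ``gates`` maps 'm', 'h' (and 'n') to arrays.
    """
    n_steps = int(round(proto.total_time / proto.dt))
    times = np.arange(n_steps + 1) * proto.dt
    i_inj = proto.current(times)

    v_rest = mem.resting_potential
    g_leak = mem.leak_conductance_ns
    c = mem.capacitance
    dt = proto.dt

    vm = np.empty(n_steps + 1)
    vm[0] = v_rest

    m = h = n_gate = 0.0
    if na is not None:
        m, h = steady_state_gates(v_rest, na)
    if kdr is not None:
        an, bn = kdr.rates(v_rest)
        n_gate = an / (an + bn)

    i_hold = 0.0
    if hold_at_rest:
        if na is not None:
            i_hold += na_current(v_rest, m, h, na)
        if kdr is not None:
            i_hold += kdr.g_k_max * n_gate ** kdr.activation_exponent * (v_rest - kdr.reversal)

    gates = {"m": np.empty(n_steps + 1), "h": np.empty(n_steps + 1)} if record_gates else None
    if record_gates:
        gates["m"][0], gates["h"][0] = m, h
        if kdr is not None:
            gates["n"] = np.empty(n_steps + 1)
            gates["n"][0] = n_gate

    v = v_rest
    # non-finite states are detected and reported explicitly below
    np_err = np.errstate(invalid="ignore", over="ignore")
    with np_err:
        for i in range(n_steps):
            # conductance-weighted equilibrium voltage for the frozen-coefficient step
            g_tot = g_leak
            gv_sum = g_leak * v_rest
            if na is not None:
                g_na = na.g_na_max * m ** na.activation_exponent * h ** na.inactivation_exponent
                g_tot += g_na
                gv_sum += g_na * na.reversal
            if kdr is not None:
                g_k = kdr.g_k_max * n_gate ** kdr.activation_exponent
                g_tot += g_k
                gv_sum += g_k * kdr.reversal
            v_inf = (gv_sum + i_inj[i] + i_hold) / g_tot
            v = v_inf + (v - v_inf) * np.exp(-dt * g_tot / c)

            if not np.isfinite(v):
                raise NumericalInstabilityError(
                    f"non-finite membrane voltage at t = {times[i + 1]:.4f} ms (step {i + 1})",
                    time_ms=float(times[i + 1]), step=i + 1,
                )

            if na is not None:
                am, bm, ah, bh = gating_rates(v, na)
                m_inf, tau_m = am / (am + bm), 1.0 / (am + bm)
                h_inf, tau_h = ah / (ah + bh), 1.0 / (ah + bh)
                m = m_inf + (m - m_inf) * np.exp(-dt / tau_m)
                h = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
            if kdr is not None:
                an, bn = kdr.rates(v)
                n_inf, tau_n = an / (an + bn), 1.0 / (an + bn)
                n_gate = n_inf + (n_gate - n_inf) * np.exp(-dt / tau_n)

            vm[i + 1] = v
            if record_gates:
                gates["m"][i + 1], gates["h"][i + 1] = m, h
                if kdr is not None:
                    gates["n"][i + 1] = n_gate

    trace = VoltageTrace(times=times, vm=vm, dt=dt)
    return (trace, gates) if record_gates else trace
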