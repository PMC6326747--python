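"""Balloon-Windkessel hemodynamics and the BOLD observation equation.

Synaptic activity S_i in each region drives a vasodilatory signal z_i;
blood inflow f_i follows the signal, distending venous volume v_i and
diluting deoxyhemoglobin q_i:

    dz/dt = S - kappa z - gamma (f - 1)
    df/dt = z
    dv/dt = (f - v^(1/alpha)) / tau
    dq/dt = (f E(f)/rho - q v^(1/alpha - 1)) / tau,   E(f) = 1 - (1-rho)^(1/f)

with baseline (z, f, v, q) = (0, 1, 1, 1) an exact fixed point. The BOLD
signal is the static observation

    BOLD = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ]

with k1 = 4.3 theta0 rho TE, k2 = epsilon r0 rho TE, k3 = 1 - epsilon and
theta0 = 28.265 B0 the frequency offset at the outer surface of magnetized
vessels. Defaults are the standard 3 T values with TE = 33.1 ms. Each
region's balloon is independent (no vascular coupling) and is integrated
with the same Euler scheme and step as the neural model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NeuralTrajectory, njit
from .io import ROITimeSeries

__all__ = [
    "HemoParams",
    "BalloonState",
    "k_constants",
    "balloon_derivatives",
    "bold_from_state",
    "simulate_bold",
]


def k_constants(B0: float = 3.0, TE: float = 0.0331, rho: float = 0.34,
                epsilon: float = 0.47, r0: float = 110.0):
    """Field- and sequence-dependent BOLD observation constants (k1, k2, k3)."""
    if min(B0, TE, rho, epsilon, r0) <= 0:
        raise ValueError("all inputs must be positive")
    theta0 = 28.265 * B0
    k1 = 4.3 * theta0 * rho * TE
    k2 = epsilon * r0 * rho * TE
    k3 = 1.0 - epsilon
    return k1, k2, k3


@dataclass
class HemoParams:
    """Hemodynamic model constants (3 T defaults).

    kappa : vasodilatory signal decay rate, 1/s
    gamma_f : flow-dependent elimination rate, 1/s
    tau_h : hemodynamic transit time, s
    alpha : Grubb's vessel stiffness exponent
    rho : resting oxygen extraction fraction
    V0 : resting blood volume fraction
    B0, TE : field strength (T) and echo time (s)
    r0 : intravascular relaxation rate, Hz
    epsilon : intra/extravascular signal ratio
    """

    kappa: float = 0.65
    gamma_f: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    V0: float = 0.02
    B0: float = 3.0
    TE: float = 0.0331
    r0: float = 110.0
    epsilon: float = 0.47

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_f", "tau_h", "alpha", "rho", "V0",
                     "B0", "TE", "r0", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k(self):
        return k_constants(self.B0, self.TE, self.rho, self.epsilon, self.r0)


@dataclass
class BalloonState:
    """Per-region hemodynamic state (vasodilatory signal, inflow, volume,
    deoxyhemoglobin); baseline is (0, 1, 1, 1)."""

    z: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def baseline(cls, n: int) -> "BalloonState":
        return cls(z=np.zeros(n), f=np.ones(n), v=np.ones(n), q=np.ones(n))


def balloon_derivatives(state: BalloonState, s_neural, p: HemoParams):
    """Time derivatives (dz, df, dv, dq) for neural drive ``s_neural``."""
    z, f, v, q = (np.asarray(x, dtype=float) for x in (state.z, state.f, state.v, state.q))
    s = np.asarray(s_neural, dtype=float)
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("inflow, volume and deoxyhemoglobin must stay positive")
    dz = s - p.kappa * z - p.gamma_f * (f - 1.0)
    df = z
    dv = (f - v ** (1.0 / p.alpha)) / p.tau_h
    extraction = 1.0 - (1.0 - p.rho) ** (1.0 / f)
    dq = (f * extraction / p.rho - q * v ** (1.0 / p.alpha - 1.0)) / p.tau_h
    return dz, df, dv, dq


def bold_from_state(q, v, p: HemoParams):
    """BOLD = V0 [k1 (1-q) + k2 (1 - q/v) + k3 (1-v)]; 0 at baseline."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("blood volume must be positive")
    k1, k2, k3 = p.k
    out = p.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _integrate_balloon(S, dt, kappa, gamma_f, tau_h, alpha, rho, V0, k1, k2, k3):
    n, K = S.shape
    bold = np.empty((n, K))
    inv_alpha = 1.0 / alpha
    one_m_rho = 1.0 - rho
    for i in range(n):
        z = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for k in range(K):
            extraction = 1.0 - one_m_rho ** (1.0 / f)
            dz = S[i, k] - kappa * z - gamma_f * (f - 1.0)
            df = z
            dv = (f - v ** inv_alpha) / tau_h
            dq = (f * extraction / rho - q * v ** (inv_alpha - 1.0)) / tau_h
            z += dz * dt
            f += df * dt
            v += dv * dt
            q += dq * dt
            if f < 1e-6:
                f = 1e-6
            if v < 1e-6:
                v = 1e-6
            if q < 1e-6:
                q = 1e-6
            bold[i, k] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return bold


def simulate_bold(traj: NeuralTrajectory, p: HemoParams | None = None,
                  burn_in: float = 120.0, tr: float = 0.72) -> ROITimeSeries:
    """Neural gating trajectory -> downsampled BOLD time series.

    The balloon system starts from baseline (0, 1, 1, 1) and is Euler-
    integrated at the trajectory's own step; BOLD is evaluated at every
    step, the first ``burn_in`` seconds are discarded (hemodynamic and
    neural transients), and the remainder is point-sampled on the TR grid.
    """
    p = p or HemoParams()
    dt = traj.dt
    ratio = tr / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"tr={tr} must be an integer multiple of dt={dt}")
    stride = int(round(ratio))
    burn_steps = int(round(burn_in / dt))
    if burn_steps >= traj.n_steps:
        raise ValueError("trajectory shorter than the burn-in period")
    k1, k2, k3 = p.k
    bold = _integrate_balloon(np.ascontiguousarray(traj.S), float(dt),
                              p.kappa, p.gamma_f, p.tau_h, p.alpha, p.rho,
                              p.V0, k1, k2, k3)
    kept = bold[:, burn_steps::stride]
    return ROITimeSeries(values=kept, tr=tr)
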