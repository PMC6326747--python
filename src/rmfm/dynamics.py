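"""Relaxed dynamic mean-field model of coupled cortical regions.

Each region i carries one state variable, the average synaptic gating
fraction S_i in [0, 1], obeying the reduced (Wong-Wang) mean-field SDE

    dS_i = [ -S_i/tau_s + r (1 - S_i) H(x_i) ] dt + sigma dW_i
    x_i  = w_i J S_i + G J sum_j C_ij S_j + I_i
    H(x) = (a x - b) / (1 - exp(-d (a x - b)))

where H is the population input-output (firing rate) function, C is the
structural connectivity, and the "relaxed" part is that the recurrent
strength w_i and the excitatory subcortical input I_i are region-specific
while G (global coupling) and sigma (noise amplitude) are shared scalars.

Integration is Euler-Maruyama at a fixed step (10 ms by default elsewhere),
with S clipped to [0, 1] after every step since the gating variable is a
fraction and noise can push it out of range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "MFMParams",
    "NeuralTrajectory",
    "firing_rate",
    "input_current",
    "neural_drift",
    "step_euler_maruyama",
    "simulate_neural",
    "fixed_point_uncoupled",
    "parameter_count",
]


@dataclass
class MFMParams:
    """Free and fixed parameters of the relaxed mean-field model.

    Parameters
    ----------
    w : (n,) array
        Recurrent (within-region) connection strength, dimensionless.
    I : (n,) array
        Excitatory subcortical input, nA.
    G : float
        Global coupling scaling inter-regional input, dimensionless.
    sigma : float
        Amplitude of the per-region Gaussian noise, dimensionless.

    The remaining attributes are biophysical constants of the mean-field
    reduction and are normally left at their defaults: synaptic coupling
    J = 0.2609 nA, input-output parameters a = 270 n/C, b = 108 Hz,
    d = 0.154 s, and gating kinetics r = 0.641, tau_s = 0.1 s.
    """

    w: np.ndarray
    I: np.ndarray
    G: float = 1.0
    sigma: float = 0.001
    J: float = 0.2609
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    r: float = 0.641
    tau_s: float = 0.1

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        self.I = np.atleast_1d(np.asarray(self.I, dtype=float))
        if self.w.shape != self.I.shape:
            raise ValueError("w and I must have the same length")
        if np.any(self.w <= 0) or np.any(self.I <= 0):
            raise ValueError("w and I must be strictly positive")
        if self.G < 0 or self.sigma < 0:
            raise ValueError("G and sigma must be nonnegative")

    @property
    def n(self) -> int:
        return self.w.size

    @classmethod
    def uniform(cls, n: int, w: float = 0.5, I: float = 0.3,
                G: float = 1.0, sigma: float = 0.001) -> "MFMParams":
        """All regions share the same w and I (the non-relaxed model)."""
        return cls(w=np.full(n, float(w)), I=np.full(n, float(I)), G=G, sigma=sigma)

    def replace(self, **kwargs) -> "MFMParams":
        return replace(self, **kwargs)


@dataclass
class NeuralTrajectory:
    """Synaptic gating trajectory: ``S[i, k]`` is region i after step k+1."""

    S: np.ndarray
    dt: float

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def n_steps(self) -> int:
        return self.S.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt


@njit(cache=True)
def _h_scalar(x: float, a: float, b: float, d: float) -> float:
    u = a * x - b
    du = d * u
    if abs(du) < 1e-8:
        # series limit at the removable singularity u = 0: H -> 1/d
        return (1.0 / d) * (1.0 + 0.5 * du)
    if du < -500.0:
        # rearranged to avoid exp overflow for strongly hyperpolarized input
        e = np.exp(du)
        return u * e / (e - 1.0)
    return u / (1.0 - np.exp(-du))


def firing_rate(x, params: MFMParams | None = None):
    """Population firing rate H(x) in Hz for total input current x (nA).

    H(x) = (a x - b) / (1 - exp(-d (a x - b))), continuous at the removable
    singularity a x = b where it equals 1/d. Strictly increasing and
    nonnegative everywhere.
    """
    p = params or MFMParams.uniform(1)
    x = np.asarray(x, dtype=float)
    u = p.a * x - p.b
    du = p.d * u
    small = np.abs(du) < 1e-8
    very_neg = du < -500.0
    safe_du = np.where(small | very_neg, 1.0, du)
    with np.errstate(over="ignore"):
        out = np.where(small, (1.0 / p.d) * (1.0 + 0.5 * du),
                       u / (1.0 - np.exp(-safe_du)))
    if np.any(very_neg):
        e = np.exp(np.where(very_neg, du, -1.0))  # placeholder keeps e-1 != 0
        out = np.where(very_neg, u * e / (e - 1.0), out)
    return float(out) if out.ndim == 0 else out


def input_current(S: np.ndarray, params: MFMParams, sc) -> np.ndarray:
    """Total input current x_i = w_i J S_i + G J (C S)_i + I_i (nA)."""
    S = np.asarray(S, dtype=float)
    C = sc.values if hasattr(sc, "values") else np.asarray(sc, dtype=float)
    if S.shape != (params.n,) or C.shape != (params.n, params.n):
        raise ValueError(
            f"dimension mismatch: S {S.shape}, C {C.shape}, n={params.n}"
        )
    return params.w * params.J * S + params.G * params.J * (C @ S) + params.I


def neural_drift(S: np.ndarray, params: MFMParams, sc) -> np.ndarray:
    """Deterministic part of dS/dt: -S/tau_s + r (1 - S) H(x(S))."""
    x = input_current(S, params, sc)
    return -S / params.tau_s + params.r * (1.0 - S) * firing_rate(x, params)


def step_euler_maruyama(S: np.ndarray, params: MFMParams, sc, dt: float,
                        noise: np.ndarray) -> np.ndarray:
    """One Euler-Maruyama step; the noise argument is standard normal.

    S' = clip(S + drift dt + sigma sqrt(dt) noise, 0, 1).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    S1 = S + neural_drift(S, params, sc) * dt + params.sigma * np.sqrt(dt) * noise
    return np.clip(S1, 0.0, 1.0)


@njit(cache=True)
def _integrate_neural(S0, noise, C, w, I, G, sigma, J, a, b, d, r, tau_s, dt):
    n = S0.size
    K = noise.shape[0]
    out = np.empty((n, K))
    S = S0.copy()
    sq = sigma * np.sqrt(dt)
    for k in range(K):
        x = w * J * S + G * J * (C @ S) + I
        for i in range(n):
            h = _h_scalar(x[i], a, b, d)
            S[i] += (-S[i] / tau_s + r * (1.0 - S[i]) * h) * dt + sq * noise[k, i]
            if S[i] < 0.0:
                S[i] = 0.0
            elif S[i] > 1.0:
                S[i] = 1.0
        out[:, k] = S
    return out


def simulate_neural(sc, params: MFMParams, duration: float, dt: float = 0.01,
                    seed: int | None = 0) -> NeuralTrajectory:
    """Integrate the stochastic mean-field model for ``duration`` seconds.

    The initial gating state is uniform on [0, 1), drawn from the seeded
    generator, followed by K = round(duration/dt) Euler-Maruyama steps. The
    same seed gives a bit-identical trajectory.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need duration >= dt > 0")
    C = sc.values if hasattr(sc, "values") else np.asarray(sc, dtype=float)
    n = params.n
    if C.shape != (n, n):
        raise ValueError(f"SC shape {C.shape} does not match n={n}")
    K = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    S0 = rng.random(n)
    noise = rng.standard_normal((K, n)) if params.sigma > 0 else np.zeros((K, n))
    S = _integrate_neural(S0, noise, np.ascontiguousarray(C, dtype=float),
                          params.w, params.I, float(params.G), float(params.sigma),
                          params.J, params.a, params.b, params.d, params.r,
                          params.tau_s, float(dt))
    return NeuralTrajectory(S=S, dt=dt)


def fixed_point_uncoupled(w: float, i_sub: float,
                          params: MFMParams | None = None) -> float:
    """Noise-free equilibrium gating of one isolated region, by bisection.

    Solves S/tau_s = r (1 - S) H(w J S + I) on [0, 1]. The drift is positive
    at S = 0 (H > 0 everywhere) and negative at S = 1, so a sign change is
    guaranteed; bisection runs until |drift| < 1e-10. If the bracket fails
    to show a sign change the nearer boundary is reported as the equilibrium.
    """
    if w <= 0 or i_sub <= 0:
        raise ValueError("w and I must be positive")
    base = params or MFMParams.uniform(1)
    p = MFMParams(w=[w], I=[i_sub], G=0.0, sigma=0.0, J=base.J, a=base.a,
                  b=base.b, d=base.d, r=base.r, tau_s=base.tau_s)
    zero_sc = np.zeros((1, 1))

    def drift(s: float) -> float:
        return float(neural_drift(np.array([s]), p, zero_sc)[0])

    lo, hi = 0.0, 1.0
    flo, fhi = drift(lo), drift(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        return lo if abs(flo) < abs(fhi) else hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = drift(mid)
        if abs(fm) < 1e-10:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def parameter_count(n_regions: int) -> int:
    """Number of free parameters: w_i and I_i per region, plus G and sigma."""
    if n_regions < 1:
        raise ValueError("need at least one region")
    return 2 * n_regions + 2
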