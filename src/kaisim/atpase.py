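"""Stochastic ATP-hydrolysis (Pi-release) events on the CI ring.

Each of the six CI domains of a hexamer cycles between an ADP-free state
and an ADP-bound state.  While ADP-free, Pi release fires with constant
hazard f0; while ADP-bound the subunit is refractory (no further events),
contributes a structural perturbation q0 pushing the hexamer toward the
competent state, and loses its ADP with the structure-dependent hazard

    1 / delta(X),    delta(X) = delta0 * (gamma - X),

so the mean residence time of ADP tracks the instantaneous structure:
ground-state hexamers (X ~ 1) recycle ADP quickly and hydrolyze more ATP,
tying the ATPase tempo to the phosphorylation phase.  Under a frozen
structure the per-subunit release rate is the renewal rate
1 / (1/f0 + delta), and inter-release intervals are hypoexponential
(an Exp(f0) wait plus an Exp(1/delta) bound period).

Both transitions are drawn per fixed time step dt as Bernoulli events
with p = 1 - exp(-rate*dt), keeping the hybrid scheme single-clocked;
exactly one uniform variate is consumed per subunit per step so that
random streams stay aligned across code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import HexamerState, ModelParams

__all__ = ["AtpaseConfig", "adp_lifetime", "step_subunits", "q_of"]


@dataclass(frozen=True)
class AtpaseConfig:
    """ATPase parameters: release frequency, perturbation and lifetime."""

    f0: float = 2.4
    q0: float = 0.8
    delta0: float = 2.5
    gamma: float = 1.5

    def __post_init__(self) -> None:
        if min(self.f0, self.q0, self.delta0) < 0:
            raise ValueError("f0, q0 and delta0 must be nonnegative")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")

    @classmethod
    def from_params(cls, params: ModelParams) -> "AtpaseConfig":
        return cls(f0=params.f0, q0=params.q0, delta0=params.delta0, gamma=params.gamma)


def adp_lifetime(X: float, cfg: AtpaseConfig) -> float:
    """Mean ADP-bound lifetime delta0*(gamma - X); shorter in the ground state."""
    if not (-1e-9 <= X <= 1 + 1e-9):
        raise ValueError(f"X = {X} outside [0, 1]")
    return cfg.delta0 * (cfg.gamma - min(max(X, 0.0), 1.0))


def _step_adp_arrays(
    adp_bound: np.ndarray,
    X,
    dt: float,
    cfg: AtpaseConfig,
    rng: np.random.Generator,
) -> int:
    """Advance ADP flags for an array of subunits in place.

    ``adp_bound`` is boolean with shape (..., 6); ``X`` broadcasts over
    the leading axes.  Returns the number of Pi-release events fired.
    One uniform variate is consumed per subunit regardless of its state.
    """
    u = rng.random(adp_bound.shape)
    lifetime = cfg.delta0 * (cfg.gamma - np.broadcast_to(np.asarray(X, dtype=float)[..., None], adp_bound.shape))
    with np.errstate(divide="ignore"):
        p_off = -np.expm1(-dt / lifetime)
    p_on = -math.expm1(-cfg.f0 * dt)
    fire = ~adp_bound & (u < p_on)
    release = adp_bound & (u < p_off)
    adp_bound[fire] = True
    adp_bound[release] = False
    return int(fire.sum())


def step_subunits(
    state: HexamerState,
    t: float,
    dt: float,
    cfg: AtpaseConfig,
    rng: np.random.Generator,
) -> int:
    """One Bernoulli step of the six CI subunits of ``state`` (in place).

    ADP-free subunits fire a Pi release with probability 1 - exp(-f0*dt)
    and become ADP-bound; ADP-bound subunits are refractory to new events
    and release their ADP with probability 1 - exp(-dt/delta(X)) using
    the current structure X.  Returns the number of Pi releases and adds
    it to ``state.release_count``.  ``t`` is accepted for signature
    symmetry with the other stepping operations; the transition
    probabilities depend only on dt and the current state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cfg.f0 * dt > 0.1:
        raise ValueError("f0*dt must be <= 0.1 for the per-step Bernoulli draw")
    n = _step_adp_arrays(state.adp_bound, np.asarray(state.X), dt, cfg, rng)
    state.release_count += n
    return n


def q_of(state: HexamerState, cfg: AtpaseConfig) -> float:
    """Structural ATPase perturbation q0 times the ADP-bound subunit count."""
    return cfg.q0 * state.n_adp_bound()
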