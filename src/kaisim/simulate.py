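"""Hybrid time stepping of the full hexamer ensemble.

The per-hexamer binding master equation and the phosphorylation level are
advanced with explicit Euler; the structure is re-evaluated algebraically
after every step (quasi-equilibrium); Pi-release events are drawn
stochastically per step.  Hexamers interact only through the shared free
KaiA and KaiB pools, recomputed from conservation at every step, which is
the KaiA-sequestration coupling that synchronizes the ensemble.

:func:`step` is a plain numpy reference implementation of one step;
:func:`simulate` runs the identical scheme through the compiled kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .binding import (
    EDGE_CLS,
    EDGE_COEFF,
    EDGE_FROM,
    EDGE_TO,
    binding_rhs,
    free_concentrations,
    rates_from_structure,
)
from .atpase import AtpaseConfig, _step_adp_arrays
from .params import EnsembleState, ModelParams, Trajectory
from .phospho import phospho_rhs, structure_X
from .states import IDX_FREE, KAIA_DIMER_COUNT, KAIB_COUNT, N_STATES, kaiB_weight_vector

__all__ = ["SimControl", "initialize", "step", "simulate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimControl:
    """Simulation controls: duration, step, sampling, transient, seed."""

    t_end: float = 2000.0
    dt: float = 0.002
    sample_every: float = 0.1
    transient: float = 500.0
    seed: int = 0
    record_hexamers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.sample_every <= self.t_end):
            raise ValueError("need 0 < dt <= sample_every <= t_end")
        if not (0 <= self.transient < self.t_end):
            raise ValueError("need 0 <= transient < t_end")

    def replace(self, **changes) -> "SimControl":
        import dataclasses

        return dataclasses.replace(self, **changes)

    @property
    def stride(self) -> int:
        return max(int(round(self.sample_every / self.dt)), 1)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


def initialize(params: ModelParams, seed: int) -> EnsembleState:
    """Fresh ensemble at t = 0: free KaiC, no ADP, desynchronized D.

    Every hexamer starts with all binding mass on free C6; the
    phosphorylation levels are drawn i.i.d. uniform on [0, 1] so that any
    ensemble-level rhythm that develops is an emergent synchronization,
    not an artifact of identical initial conditions.  X is set consistent
    with the quasi-equilibrium relation; free pools equal the totals.
    """
    rng = np.random.default_rng(seed)
    N = params.N
    P = np.zeros((N, N_STATES))
    P[:, IDX_FREE] = 1.0
    D = rng.uniform(0.0, 1.0, size=N)
    X = structure_X(D, 0.0, 0.0, 0.0, params)
    return EnsembleState(
        t=0.0,
        P=P,
        D=D,
        X=np.asarray(X, dtype=float),
        adp_bound=np.zeros((N, 6), dtype=bool),
        release_count=np.zeros(N, dtype=np.int64),
        A_free=params.A_T,
        B_free=params.B_T,
    )


def step(
    state: EnsembleState,
    params: ModelParams,
    control: SimControl,
    rng: np.random.Generator,
) -> int:
    """Advance the ensemble by one dt in place (numpy reference path).

    Returns the number of Pi-release events fired during the step.
    Raises if the per-hexamer renormalization correction exceeds 1e-3,
    which indicates the step size is too large.
    """
    dt = control.dt
    t = state.t
    cfg = AtpaseConfig.from_params(params)

    # (1) free pools from conservation over the current distributions
    A, B = free_concentrations(state.P, params)
    state.A_free, state.B_free = A, B

    # (2) binding Euler step per hexamer, clip + renormalize
    for k in range(state.N):
        rates = rates_from_structure(state.X[k], params)
        p_new = state.P[k] + dt * binding_rhs(state.P[k], A, B, rates)
        np.clip(p_new, 0.0, None, out=p_new)
        ssum = p_new.sum()
        corr = abs(ssum - 1.0)
        if corr > 1e-3:
            raise RuntimeError(
                f"normalization correction {corr:.2e} at t={t:.3f} h; reduce dt"
            )
        if corr > 1e-6:
            logger.warning("renormalization correction %.2e at t=%.3f h", corr, t)
        state.P[k] = p_new / ssum

    # (3) phosphorylation Euler step
    state.D += dt * phospho_rhs(state.D, state.P[:, 0], params)

    # (4) stochastic Pi release (refractory while ADP bound)
    released = _step_adp_arrays(state.adp_bound, state.X, dt, cfg, rng)

    # (5) structure from the updated fields
    t_new = t + dt
    pB = state.P @ kaiB_weight_vector(params.n_B)
    q = params.q0 * state.adp_bound.sum(axis=1)
    state.X = np.asarray(structure_X(state.D, state.P[:, 0], pB, q, params))
    state.t = t_new
    return released


def _pack_params(params: ModelParams) -> np.ndarray:
    pv = np.empty(21)
    pv[_kernel.P_AT] = params.A_T
    pv[_kernel.P_BT] = params.B_T
    pv[_kernel.P_V] = params.V
    pv[_kernel.P_HA0] = params.h_A0
    pv[_kernel.P_FA0] = params.f_A0
    pv[_kernel.P_HB0] = params.h_B0
    pv[_kernel.P_FB0] = params.f_B0
    pv[_kernel.P_HBA] = params.h_BA
    pv[_kernel.P_FBA] = params.f_BA
    pv[_kernel.P_KP] = params.k_p
    pv[_kernel.P_KDP] = params.k_dp
    pv[_kernel.P_A] = params.a
    pv[_kernel.P_BETA] = params.beta
    pv[_kernel.P_C0] = params.c0
    pv[_kernel.P_C1] = params.c1
    pv[_kernel.P_C2] = params.c2
    pv[_kernel.P_C3] = params.c3
    pv[_kernel.P_Q0] = params.q0
    pv[_kernel.P_F0] = params.f0
    pv[_kernel.P_DELTA0] = params.delta0
    pv[_kernel.P_GAMMA] = params.gamma
    return pv


def simulate(params: ModelParams, control: SimControl) -> Trajectory:
    """Run a full simulation and return the sampled trajectory.

    Identical seeds give bit-identical trajectories.  The Bernoulli
    Pi-release draws use a stream seeded from ``control.seed``; the
    desynchronized initial phosphorylation levels use an independent
    stream derived from the same seed.
    """
    if params.f0 * control.dt > 0.1:
        raise ValueError("f0*dt must be <= 0.1 for the per-step Bernoulli draws")
    state = initialize(params, control.seed)
    n_steps = control.n_steps
    stride = control.stride
    n_samples = n_steps // stride + 1
    rec_idx = np.asarray(control.record_hexamers, dtype=np.int64)
    if rec_idx.size and (rec_idx.min() < 0 or rec_idx.max() >= params.N):
        raise ValueError("record_hexamers indices out of range")

    out_t = np.empty(n_samples)
    out_D = np.empty(n_samples)
    out_X = np.empty(n_samples)
    out_PCA = np.empty(n_samples)
    out_PCBA = np.empty(n_samples)
    out_rel = np.zeros(n_samples, dtype=np.int64)
    out_Drec = np.empty((n_samples, rec_idx.size))
    out_free = np.empty((n_samples, 2))

    _kernel.seed_rng(int(control.seed) % (2**31 - 1))
    status, max_corr, n_written = _kernel.run_steps(
        state.P, state.D, state.X, state.adp_bound, state.release_count,
        0.0, n_steps, control.dt, stride, _pack_params(params),
        EDGE_FROM, EDGE_TO, EDGE_COEFF, EDGE_CLS,
        KAIA_DIMER_COUNT, KAIB_COUNT, kaiB_weight_vector(params.n_B),
        rec_idx, out_t, out_D, out_X, out_PCA, out_PCBA, out_rel, out_Drec,
        out_free,
    )
    if status == _kernel.STATUS_NORM:
        raise RuntimeError(
            f"normalization correction {max_corr:.2e} exceeded 1e-3; reduce dt"
        )
    if status == _kernel.STATUS_DEFICIT:
        raise RuntimeError(
            "bound KaiA/KaiB exceeded the total concentration; reduce dt"
        )
    if max_corr > 1e-6:
        logger.warning("largest per-step renormalization correction %.2e", max_corr)
    return Trajectory(
        times=out_t[:n_written],
        Dbar=out_D[:n_written],
        Xbar=out_X[:n_written],
        PCA_bar=out_PCA[:n_written],
        PCBA_bar=out_PCBA[:n_written],
        releases=out_rel[:n_written],
        D_rec=out_Drec[:n_written] if rec_idx.size else None,
        rec_indices=tuple(int(i) for i in rec_idx),
        params=params,
        control=control,
    )
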