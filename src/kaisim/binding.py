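"""Master-equation kinetics of KaiA/KaiB binding to one KaiC hexamer.

Each hexamer carries a probability vector over 29 binding states (see
:mod:`kaisim.states`).  Transitions are first-order in the state
probabilities with mass-action dependence on the shared free KaiA and
KaiB concentrations; KaiA binds as a dimer, hence the A**2 factors.
The binding/unbinding rate constants on KaiC itself are modulated by the
hexamer's structural order parameter X (ground state X ~ 1 favours KaiA
on the CII ring, competent state X ~ 0 favours KaiB on the CI ring),
whereas KaiA exchange on already-bound KaiB is structure independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .states import (
    IDX_CA,
    IDX_FREE,
    KAIA_DIMER_COUNT,
    KAIB_COUNT,
    N_STATES,
    STATE_IJ,
    index_of,
)

__all__ = ["RateSet", "rates_from_structure", "binding_rhs", "free_concentrations"]

logger = logging.getLogger(__name__)

# Transition classes (index into the per-hexamer class-rate vector):
#   0: C6 -> C6A2            rate h_A * A^2
#   1: C6A2 -> C6            rate f_A
#   2: KaiB on   (i -> i+1)  rate (6-i) * h_B * B
#   3: KaiB off  (i -> i-1)  rate (i-j) * f_B   (only KaiA-free KaiB leaves)
#   4: KaiA onto KaiB (j+1)  rate (i-j) * h_BA * A^2
#   5: KaiA off KaiB  (j-1)  rate j * f_BA
CLS_HA, CLS_FA, CLS_HB, CLS_FB, CLS_HBA, CLS_FBA = range(6)


def _build_edges():
    frm, to, coeff, cls = [], [], [], []

    def add(s_from, s_to, c, kind):
        frm.append(s_from)
        to.append(s_to)
        coeff.append(float(c))
        cls.append(kind)

    add(IDX_FREE, IDX_CA, 1.0, CLS_HA)
    add(IDX_CA, IDX_FREE, 1.0, CLS_FA)
    for (i, j) in STATE_IJ:
        s = index_of(i, j)
        if i <= 5:
            add(s, index_of(i + 1, j), 6 - i, CLS_HB)
        if i >= 1 and j <= i - 1:
            add(s, index_of(i - 1, j), i - j, CLS_FB)
        if j <= i - 1:
            add(s, index_of(i, j + 1), i - j, CLS_HBA)
        if j >= 1:
            add(s, index_of(i, j - 1), j, CLS_FBA)
    return (
        np.asarray(frm, dtype=np.int64),
        np.asarray(to, dtype=np.int64),
        np.asarray(coeff, dtype=np.float64),
        np.asarray(cls, dtype=np.int64),
    )


#: flattened transition table shared by the numpy path and the compiled kernel
EDGE_FROM, EDGE_TO, EDGE_COEFF, EDGE_CLS = _build_edges()
N_EDGES = len(EDGE_FROM)


@dataclass(frozen=True)
class RateSet:
    """Structure-modulated binding/unbinding rates of one hexamer."""

    h_A: float
    f_A: float
    h_B: float
    f_B: float
    h_BA: float
    f_BA: float


def rates_from_structure(X: float, params: ModelParams) -> RateSet:
    """Rate constants of one hexamer given its order parameter X.

    KaiA on the CII ring binds in the ground state and leaves in the
    competent state (h_A = h_A0*X, f_A = f_A0*(1-X)); KaiB does the
    opposite.  KaiA exchange on bound KaiB is copied unmodulated.
    """
    if not (-1e-9 <= X <= 1 + 1e-9):
        raise ValueError(f"X = {X} outside [0, 1]")
    X = min(max(X, 0.0), 1.0)
    return RateSet(
        h_A=params.h_A0 * X,
        f_A=params.f_A0 * (1.0 - X),
        h_B=params.h_B0 * (1.0 - X),
        f_B=params.f_B0 * X,
        h_BA=params.h_BA,
        f_BA=params.f_BA,
    )


def _class_rates(rates: RateSet, A: float, B: float) -> np.ndarray:
    A2 = A * A
    return np.array([
        rates.h_A * A2,
        rates.f_A,
        rates.h_B * B,
        rates.f_B,
        rates.h_BA * A2,
        rates.f_BA,
    ])


def binding_rhs(probs: np.ndarray, A: float, B: float, rates: RateSet) -> np.ndarray:
    """Time derivative of the 29-state probability vector.

    Accepts a raw length-29 array (or a BindingDistribution's ``probs``).
    The returned derivative sums to zero by construction.
    """
    probs = np.asarray(getattr(probs, "probs", probs), dtype=float)
    if probs.shape != (N_STATES,):
        raise ValueError("expected a length-29 probability vector")
    if A < 0 or B < 0:
        raise ValueError("free concentrations must be nonnegative")
    flux = _class_rates(rates, A, B)[EDGE_CLS] * EDGE_COEFF * probs[EDGE_FROM]
    dp = np.zeros(N_STATES)
    np.subtract.at(dp, EDGE_FROM, flux)
    np.add.at(dp, EDGE_TO, flux)
    return dp


def rate_matrix(rates: RateSet, A: float, B: float) -> np.ndarray:
    """The 29x29 generator Q with d p/dt = Q @ p (columns sum to zero)."""
    cr = _class_rates(rates, A, B)
    Q = np.zeros((N_STATES, N_STATES))
    for e in range(N_EDGES):
        r = cr[EDGE_CLS[e]] * EDGE_COEFF[e]
        Q[EDGE_FROM[e], EDGE_FROM[e]] -= r
        Q[EDGE_TO[e], EDGE_FROM[e]] += r
    return Q


def free_concentrations(P, params: ModelParams) -> tuple[float, float]:
    """Free KaiA/KaiB concentrations from total-amount conservation.

    ``P`` is an (N, 29) array of state probabilities (or an iterable of
    BindingDistribution).  Each C6A2 holds one KaiA dimer (2 monomers),
    each C6BiA2j holds i KaiB monomers and j KaiA dimers:

        A = A_T - (2/V) * sum_k [p_CA(k) + sum_ij j * p_ij(k)]
        B = B_T - (1/V) * sum_k  sum_ij i * p_ij(k)

    Slightly negative results (roundoff) are clamped to zero with a
    warning; a deficit beyond 1e-3 of the respective total raises, which
    signals an integration-step failure upstream.
    """
    if not isinstance(P, np.ndarray):
        P = np.stack([getattr(d, "probs", d) for d in P])
    bound_A = 2.0 * float((P @ KAIA_DIMER_COUNT).sum()) / params.V
    bound_B = float((P @ KAIB_COUNT).sum()) / params.V
    A = params.A_T - bound_A
    B = params.B_T - bound_B
    for name, val, total in (("KaiA", A, params.A_T), ("KaiB", B, params.B_T)):
        if val < -(1e-3 * total + 1e-9):
            raise RuntimeError(
                f"free {name} deficit {val:.6g} exceeds tolerance; "
                "occupancy is inconsistent with the total concentration "
                "(integration step too large?)"
            )
        if val < -1e-6:
            logger.warning("clamping slightly negative free %s = %.3g to 0", name, val)
    return max(A, 0.0), max(B, 0.0)
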