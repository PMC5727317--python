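"""Phosphorylation dynamics and the quasi-equilibrium structural transition.

The 12 CII phosphorylation sites of a hexamer are coarse-grained into one
continuous level D (0 = fully dephosphorylated, 1 = fully phosphorylated)
driven up while the activating C6A2 complex is present and down otherwise,
and confined near {0, 1} by a quartic soft-spin potential

    g(D) = a * D * (D - 1/2)**2 * (D - 1).

The hexamer structure is assumed to equilibrate much faster than any
reaction, so the order parameter X is an algebraic function of the
instantaneous mean field

    h = c0 - c1*D + c2*pA - c3*pB - q,
    X = (tanh(beta * h) + 1) / 2,

which is the large-cooperativity limit of a 6-spin ring of subunit
structural states; :func:`ising_ring_mean_spin` evaluates that ring
exactly by enumeration and is used to validate the limit.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .params import BindingDistribution, ModelParams
from .states import kaiB_weight_vector

__all__ = [
    "soft_spin_potential",
    "soft_spin_gradient",
    "phospho_rhs",
    "kaiB_extent",
    "structure_field",
    "structure_X",
    "ising_ring_mean_spin",
]


def soft_spin_potential(D, a: float):
    """Quartic confinement g(D) = a*D*(D-1/2)**2*(D-1)."""
    return a * D * (D - 0.5) ** 2 * (D - 1.0)


def soft_spin_gradient(D, a: float):
    """Analytic dg/dD in the factored form a*(D-1/2)*[2(D-1/2)**2 + 2D**2 - 2D]."""
    return a * (D - 0.5) * (2.0 * (D - 0.5) ** 2 + 2.0 * D * D - 2.0 * D)


def phospho_rhs(D, p_CA, params: ModelParams):
    """dD/dt: KaiA-driven phosphorylation minus confinement force.

    Phosphorylation proceeds at k_p while the hexamer is in the C6A2
    complex (probability p_CA) and dephosphorylation at k_dp otherwise.
    """
    return (
        params.k_p * p_CA
        - params.k_dp * (1.0 - p_CA)
        - soft_spin_gradient(D, params.a)
    )


def kaiB_extent(dist: BindingDistribution | np.ndarray, n_B: float) -> float:
    """Saturating KaiB-binding extent pB = sum_i tanh(i/n_B) * sum_j p[i][j]."""
    probs = np.asarray(getattr(dist, "probs", dist), dtype=float)
    return float(probs @ kaiB_weight_vector(n_B))


def structure_field(D, pA, pB, q, params: ModelParams):
    """Mean field h = c0 - c1*D + c2*pA - c3*pB - q acting on the structure."""
    return params.c0 - params.c1 * D + params.c2 * pA - params.c3 * pB - q


def structure_X(D, pA, pB, q, params: ModelParams):
    """Quasi-equilibrium order parameter X = (tanh(beta*h) + 1)/2 in (0, 1)."""
    return 0.5 * np.tanh(params.beta * structure_field(D, pA, pB, q, params)) + 0.5


def ising_ring_mean_spin(h: float, J: float, beta: float = 1.0) -> float:
    """Exact mean spin of the 6-subunit structural ring (enumeration).

    The per-hexamer free energy is

        G({x}) = -(1/6) * sum_i x_i * h - J * sum_<i,i+1> x_i x_{i+1}

    with x_i = +/-1 over the ring of 6 subunits.  Returns the Boltzmann
    average of (1/6) * sum_i x_i over all 64 configurations.  For
    J >> k_B*T this tends to tanh(beta*h), the limit used by
    :func:`structure_X`; for J = 0 the spins decouple in the field h/6.
    """
    num = 0.0
    den = 0.0
    for spins in itertools.product((-1.0, 1.0), repeat=6):
        m = sum(spins) / 6.0
        ring = sum(spins[i] * spins[(i + 1) % 6] for i in range(6))
        w = math.exp(-beta * (-(m * h) - J * ring))
        num += m * w
        den += w
    return num / den
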