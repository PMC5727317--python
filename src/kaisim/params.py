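"""Model parameters and composite state containers.

Units follow the convention V = 1 and k_B*T = 1: concentrations are
counts per volume, energies are in k_B*T, all rates in 1/h.  The default
parameter set is the reference set for which the ensemble shows a stable
circadian rhythm; sweeps perturb one or two of its entries at a time.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .states import CBA_MASK, IDX_CA, IDX_FREE, N_STATES, index_of

__all__ = [
    "ModelParams",
    "BindingDistribution",
    "HexamerState",
    "EnsembleState",
    "Trajectory",
    "default_params",
    "rescale_ensemble",
]

#: tolerance on the per-hexamer probability normalization
NORM_TOL = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """All rate, coupling and concentration constants of the model.

    Attributes
    ----------
    N, V
        Number of KaiC hexamers and system volume; the hexamer
        concentration is ``C6T = N / V``.
    A_T, B_T
        Total KaiA-monomer and KaiB-monomer concentrations.
    h_A0, f_A0
        KaiA-dimer binding/unbinding rate constants on the CII ring
        (binding carries a factor A**2, mass action for a dimer).
    h_B0, f_B0
        KaiB binding/unbinding rate constants on the CI ring.
    h_BA, f_BA
        KaiA-dimer binding/unbinding rates on already-bound KaiB;
        structure independent because this KaiA contacts KaiB only.
    k_p, k_dp
        Phosphorylation / dephosphorylation rates of the CII sites.
    a
        Strength of the quartic soft-spin potential confining D near 0/1.
    c0, c1, c2, c3
        Structure-field couplings (k_B*T): baseline bias, phosphorylation,
        KaiA-binding and KaiB-binding contributions respectively.
    beta
        Inverse temperature 1/(k_B*T).
    n_B
        Saturation level of the KaiB effect on the structure field.
    f0
        Intrinsic Pi-release (hydrolysis) frequency per CI subunit.
    q0
        Structural perturbation (k_B*T) of one ADP-bound CI subunit.
    delta0, gamma
        ADP-bound lifetime scale and offset: delta = delta0 * (gamma - X).
    """

    N: int = 1000
    V: float = 1.0
    A_T: float = 2000.0
    B_T: float = 20000.0
    h_A0: float = 1.6e-5
    h_B0: float = 7.2e-6
    h_BA: float = 1.0e-6
    f_A0: float = 0.8
    f_B0: float = 0.32
    f_BA: float = 0.2
    k_p: float = 0.4
    k_dp: float = 0.4
    a: float = 1.6
    c0: float = 10.0
    c1: float = 6.0
    c2: float = 0.0
    c3: float = 3.0
    beta: float = 1.0
    n_B: float = 1.0
    f0: float = 2.4
    q0: float = 0.8
    delta0: float = 2.5
    gamma: float = 1.5

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.V <= 0:
            raise ValueError("V must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1 so ADP lifetimes stay nonnegative")
        if self.n_B <= 0:
            raise ValueError("n_B must be positive")
        for name in (
            "A_T", "B_T", "h_A0", "h_B0", "h_BA", "f_A0", "f_B0", "f_BA",
            "k_p", "k_dp", "a", "f0", "q0", "delta0",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def C6T(self) -> float:
        """KaiC hexamer concentration N / V."""
        return self.N / self.V

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def with_ratios(self, A_ratio: float | None = None,
                    B_ratio: float | None = None) -> "ModelParams":
        """Set total concentrations via the ratios A_T/C6T and/or B_T/C6T."""
        changes = {}
        if A_ratio is not None:
            changes["A_T"] = A_ratio * self.C6T
        if B_ratio is not None:
            changes["B_T"] = B_ratio * self.C6T
        return self.replace(**changes)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write the parameter set as flat YAML (or JSON for .json paths)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def default_params() -> ModelParams:
    """The reference parameter set (A_T/C6T = 2, B_T/C6T = 20)."""
    return ModelParams()


def rescale_ensemble(params: ModelParams, N_new: int) -> ModelParams:
    """Change the ensemble size while preserving every concentration.

    V is scaled with N so C6T, A_T and B_T are untouched; per-hexamer
    dynamics are statistically identical and only the ensemble-average
    noise (~1/sqrt(N)) grows as N shrinks.
    """
    if N_new < 1:
        raise ValueError("N_new must be >= 1")
    scale = N_new / params.N
    return params.replace(N=N_new, V=params.V * scale)


class BindingDistribution:
    """Probability vector of one hexamer over the 29 binding states."""

    __slots__ = ("probs",)

    def __init__(self, probs: np.ndarray | Sequence[float], *, validate: bool = True):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} state probabilities, got shape {probs.shape}")
        if validate:
            if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
                raise ValueError("probabilities must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > NORM_TOL:
                raise ValueError(f"probabilities sum to {probs.sum():.8f}, not 1")
        self.probs = probs

    @classmethod
    def free(cls) -> "BindingDistribution":
        """All mass on free C6 (no KaiA, no KaiB bound)."""
        p = np.zeros(N_STATES)
        p[IDX_FREE] = 1.0
        return cls(p)

    @classmethod
    def point(cls, state: str | tuple[int, int]) -> "BindingDistribution":
        """All mass on one state, either ``"CA"`` or an (i, j) pair."""
        p = np.zeros(N_STATES)
        p[IDX_CA if state == "CA" else index_of(*state)] = 1.0
        return cls(p)

    @property
    def p_CA(self) -> float:
        """Probability of the C6A2 complex."""
        return float(self.probs[IDX_CA])

    def p(self, i: int, j: int) -> float:
        """Probability of the C6BiA2j state."""
        return float(self.probs[index_of(i, j)])

    @property
    def p_CBA(self) -> float:
        """Total probability of KaiA-sequestering complexes (i>=1, j>=1)."""
        return float(self.probs[CBA_MASK].sum())

    def copy(self) -> "BindingDistribution":
        return BindingDistribution(self.probs.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BindingDistribution(p_CA={self.p_CA:.4f}, p_free={self.probs[IDX_FREE]:.4f})"


@dataclass
class HexamerState:
    """Dynamic state of one KaiC hexamer.

    ``adp_bound[s]`` flags whether subunit s currently keeps ADP bound on
    its CI domain; bound subunits release at the structure-dependent rate
    1/delta(X), so no expiry time is stored.
    """

    binding: BindingDistribution
    D: float
    X: float
    adp_bound: np.ndarray
    release_count: int = 0

    def __post_init__(self) -> None:
        self.adp_bound = np.asarray(self.adp_bound, dtype=bool)
        if self.adp_bound.shape != (6,):
            raise ValueError("adp_bound must have one entry per subunit (6)")
        if not (0.0 < self.X < 1.0):
            raise ValueError("X must lie strictly inside (0, 1)")
        if not (-0.5 <= self.D <= 1.5):
            raise ValueError("D escaped the soft-spin confinement range [-0.5, 1.5]")

    def n_adp_bound(self) -> int:
        """Number of subunits currently holding ADP."""
        return int(np.sum(self.adp_bound))


@dataclass
class EnsembleState:
    """Full simulation state: N hexamers plus the shared free concentrations.

    Internally array-backed for speed: ``P`` has shape (N, 29), ``D``,
    ``X`` shape (N,), the boolean ``adp_bound`` shape (N, 6),
    ``release_count`` (N,).
    """

    t: float
    P: np.ndarray
    D: np.ndarray
    X: np.ndarray
    adp_bound: np.ndarray
    release_count: np.ndarray
    A_free: float
    B_free: float

    def __post_init__(self) -> None:
        N = self.P.shape[0]
        if self.P.shape != (N, N_STATES):
            raise ValueError("P must have shape (N, 29)")
        for name in ("D", "X"):
            if getattr(self, name).shape != (N,):
                raise ValueError(f"{name} must have shape (N,)")
        if self.adp_bound.shape != (N, 6):
            raise ValueError("adp_bound must have shape (N, 6)")
        if self.A_free < 0 or self.B_free < 0:
            raise ValueError("free concentrations must be nonnegative")

    @property
    def N(self) -> int:
        return self.P.shape[0]

    def hexamer(self, k: int) -> HexamerState:
        """View of the k-th hexamer as a HexamerState record."""
        return HexamerState(
            binding=BindingDistribution(self.P[k], validate=False),
            D=float(self.D[k]),
            X=float(self.X[k]),
            adp_bound=self.adp_bound[k],
            release_count=int(self.release_count[k]),
        )

    @property
    def hexamers(self) -> list[HexamerState]:
        return [self.hexamer(k) for k in range(self.N)]

    def copy(self) -> "EnsembleState":
        return EnsembleState(
            t=self.t,
            P=self.P.copy(),
            D=self.D.copy(),
            X=self.X.copy(),
            adp_bound=self.adp_bound.copy(),
            release_count=self.release_count.copy(),
            A_free=self.A_free,
            B_free=self.B_free,
        )


@dataclass
class Trajectory:
    """Sampled ensemble observables of one simulation run.

    ``releases`` counts Pi-release events (whole ensemble) inside each
    sampling interval; ``D_rec`` optionally carries per-hexamer D_k series
    for the recorded hexamer indices.
    """

    times: np.ndarray
    Dbar: np.ndarray
    Xbar: np.ndarray
    PCA_bar: np.ndarray
    PCBA_bar: np.ndarray
    releases: np.ndarray
    D_rec: np.ndarray | None = None
    rec_indices: tuple[int, ...] = ()
    params: ModelParams | None = None
    control: "object" = None  # SimControl; untyped to avoid an import cycle

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("Dbar", "Xbar", "PCA_bar", "PCBA_bar", "releases"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length mismatch")
        if self.D_rec is not None and self.D_rec.shape[0] != n:
            raise ValueError("D_rec length mismatch")

    @property
    def sample_every(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else math.nan

    def to_frame(self):
        """Tidy pandas frame: t, Dbar, Xbar, P_CA, P_CBA, releases, D_k...."""
        import pandas as pd

        data = {
            "t": self.times,
            "Dbar": self.Dbar,
            "Xbar": self.Xbar,
            "P_CA": self.PCA_bar,
            "P_CBA": self.PCBA_bar,
            "releases": self.releases,
        }
        if self.D_rec is not None:
            for col, k in enumerate(self.rec_indices):
                data[f"D_{k}"] = self.D_rec[:, col]
        return pd.DataFrame(data)
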