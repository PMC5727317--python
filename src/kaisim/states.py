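"""Enumeration of the 29 per-hexamer binding states.

A KaiC hexamer C6 can carry one KaiA dimer on its CII ring (the C6A2
complex) or ``i`` KaiB monomers on its CI ring, ``j`` of which hold a KaiA
dimer (the C6BiA2j complexes, 0 <= j <= i <= 6; (0, 0) is free C6).  That
gives 1 + 28 = 29 mutually exclusive states per hexamer.

The fixed state ordering used throughout the package (and in serialized
trajectories) is: index 0 = C6A2, then (i, j) in lexicographic order, so
index 1 = (0, 0) = free C6, index 2 = (1, 0), index 3 = (1, 1), ...
"""

from __future__ import annotations

import numpy as np

#: index of the C6A2 complex (KaiA dimer on the CII ring)
IDX_CA = 0
#: index of free C6 (no KaiA, no KaiB)
IDX_FREE = 1

#: (i, j) labels of the 28 C6BiA2j states in storage order (indices 1..28)
STATE_IJ: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(7) for j in range(i + 1)
)

#: total number of per-hexamer binding states
N_STATES = 1 + len(STATE_IJ)  # 29

_IJ_TO_IDX = {ij: 1 + n for n, ij in enumerate(STATE_IJ)}


def index_of(i: int, j: int) -> int:
    """Storage index of the C6BiA2j state; free C6 is ``index_of(0, 0)``."""
    try:
        return _IJ_TO_IDX[(i, j)]
    except KeyError:
        raise ValueError(f"no binding state (i={i}, j={j}); need 0 <= j <= i <= 6") from None


def _i_of() -> np.ndarray:
    """Number of bound KaiB monomers per state (0 for C6A2)."""
    arr = np.zeros(N_STATES)
    for n, (i, _) in enumerate(STATE_IJ):
        arr[1 + n] = i
    return arr


def _j_of() -> np.ndarray:
    """Number of KaiA dimers held by KaiB per state (0 for C6A2)."""
    arr = np.zeros(N_STATES)
    for n, (_, j) in enumerate(STATE_IJ):
        arr[1 + n] = j
    return arr


#: per-state count of bound KaiB monomers (i); 0 for C6A2
KAIB_COUNT = _i_of()
#: per-state count of KaiA dimers sequestered on KaiB (j); 0 for C6A2
KAIA_ON_B_COUNT = _j_of()

#: per-state count of KaiA dimers of any kind (1 for C6A2, else j) --
#: multiplied by 2 this is the number of KaiA monomers held by the state
KAIA_DIMER_COUNT = KAIA_ON_B_COUNT.copy()
KAIA_DIMER_COUNT[IDX_CA] = 1.0

#: boolean mask of the KaiB-containing KaiA complexes C6BiA2j with i>=1, j>=1
CBA_MASK = (KAIB_COUNT >= 1) & (KAIA_ON_B_COUNT >= 1)


def kaiB_weight_vector(n_B: float) -> np.ndarray:
    """Per-state weights tanh(i / n_B) entering the KaiB-binding extent pB."""
    if n_B <= 0:
        raise ValueError("n_B must be positive")
    return np.tanh(KAIB_COUNT / n_B) * (KAIB_COUNT > 0)
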