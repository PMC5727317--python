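"""Numba-compiled inner loop of the hybrid ensemble simulation.

One step applies, in this fixed order: (1) free-concentration update from
conservation, (2) explicit-Euler update of every hexamer's 29-state
binding distribution (clip negatives, renormalize), (3) Euler update of
the phosphorylation level D, (4) Bernoulli draws for Pi release (rate f0
while ADP-free) and ADP release (rate 1/delta(X) while bound), (5)
algebraic re-evaluation of the structure X from the updated fields.  The free-concentration sums for the
next step are accumulated on the fly, so each step makes a single pass
over the ensemble.

Status codes returned: 0 ok, 1 per-step normalization correction above
1e-3, 2 free-concentration deficit above 1e-3 of the respective total.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed parameter vector (see simulate._pack_params)
(P_AT, P_BT, P_V, P_HA0, P_FA0, P_HB0, P_FB0, P_HBA, P_FBA,
 P_KP, P_KDP, P_A, P_BETA, P_C0, P_C1, P_C2, P_C3,
 P_Q0, P_F0, P_DELTA0, P_GAMMA) = range(21)

STATUS_OK = 0
STATUS_NORM = 1
STATUS_DEFICIT = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def run_steps(
    P,            # (N, 29) binding probabilities, updated in place
    D,            # (N,) phosphorylation levels
    X,            # (N,) structural order parameters
    adp_bound,    # (N, 6) boolean ADP-bound flags
    release_count,  # (N,) int64 cumulative release events
    t0,           # float start time
    n_steps,      # int number of Euler steps
    dt,           # float step (h)
    stride,       # int steps per recorded sample
    pv,           # (21,) packed parameters
    edge_from, edge_to, edge_coeff, edge_cls,  # transition table
    wA, wB, wpB,  # (29,) conservation / KaiB-extent weights
    rec_idx,      # (n_rec,) int64 hexamer indices with recorded D_k
    out_t, out_D, out_X, out_PCA, out_PCBA, out_rel, out_Drec,
    out_free,     # (n_samples, 2) free A / B at sample times
):
    N = P.shape[0]
    n_states = P.shape[1]
    n_edges = edge_from.shape[0]
    n_rec = rec_idx.shape[0]

    A_T = pv[P_AT]; B_T = pv[P_BT]; V = pv[P_V]
    h_A0 = pv[P_HA0]; f_A0 = pv[P_FA0]; h_B0 = pv[P_HB0]; f_B0 = pv[P_FB0]
    h_BA = pv[P_HBA]; f_BA = pv[P_FBA]
    k_p = pv[P_KP]; k_dp = pv[P_KDP]; a = pv[P_A]
    beta = pv[P_BETA]; c0 = pv[P_C0]; c1 = pv[P_C1]; c2 = pv[P_C2]; c3 = pv[P_C3]
    q0 = pv[P_Q0]; f0 = pv[P_F0]; delta0 = pv[P_DELTA0]; gamma = pv[P_GAMMA]

    p_event = -np.expm1(-f0 * dt)

    cr = np.empty(6)
    dP = np.empty(n_states)

    # conservation sums over the current P
    sumA = 0.0
    sumB = 0.0
    for k in range(N):
        for s in range(n_states):
            sumA += wA[s] * P[k, s]
            sumB += wB[s] * P[k, s]

    rel_interval = 0
    max_corr = 0.0
    sample = 0

    # record the initial state; the CBA complexes (i>=1, j>=1) are exactly
    # the non-C6A2 states with a positive KaiA weight
    Dm = 0.0; Xm = 0.0; PCAm = 0.0; PCBAm = 0.0
    for k in range(N):
        Dm += D[k]; Xm += X[k]; PCAm += P[k, 0]
        for s in range(1, n_states):
            if wA[s] > 0.0:
                PCBAm += P[k, s]
    out_t[0] = t0
    out_D[0] = Dm / N
    out_X[0] = Xm / N
    out_PCA[0] = PCAm / N
    out_PCBA[0] = PCBAm / N
    out_rel[0] = 0
    out_free[0, 0] = max(A_T - 2.0 * sumA / V, 0.0)
    out_free[0, 1] = max(B_T - sumB / V, 0.0)
    for r in range(n_rec):
        out_Drec[0, r] = D[rec_idx[r]]
    sample = 1

    for istep in range(n_steps):
        t = t0 + istep * dt
        t_new = t0 + (istep + 1) * dt
        # (1) free concentrations from conservation
        A = A_T - 2.0 * sumA / V
        B = B_T - sumB / V
        if A < -1e-3 * A_T - 1e-9 or B < -1e-3 * B_T - 1e-9:
            return STATUS_DEFICIT, max_corr, sample
        if A < 0.0:
            A = 0.0
        if B < 0.0:
            B = 0.0
        A2 = A * A

        sumA = 0.0
        sumB = 0.0
        Dm = 0.0; Xm = 0.0; PCAm = 0.0; PCBAm = 0.0

        for k in range(N):
            x = X[k]
            # (2) binding ODE step at structure-modulated rates
            cr[0] = h_A0 * x * A2
            cr[1] = f_A0 * (1.0 - x)
            cr[2] = h_B0 * (1.0 - x) * B
            cr[3] = f_B0 * x
            cr[4] = h_BA * A2
            cr[5] = f_BA
            for s in range(n_states):
                dP[s] = 0.0
            for e in range(n_edges):
                fl = cr[edge_cls[e]] * edge_coeff[e] * P[k, edge_from[e]]
                dP[edge_from[e]] -= fl
                dP[edge_to[e]] += fl
            ssum = 0.0
            for s in range(n_states):
                v = P[k, s] + dt * dP[s]
                if v < 0.0:
                    v = 0.0
                P[k, s] = v
                ssum += v
            corr = abs(ssum - 1.0)
            if corr > max_corr:
                max_corr = corr
            if corr > 1e-3:
                return STATUS_NORM, max_corr, sample
            inv = 1.0 / ssum
            pB = 0.0
            for s in range(n_states):
                v = P[k, s] * inv
                P[k, s] = v
                sumA += wA[s] * v
                sumB += wB[s] * v
                pB += wpB[s] * v
                if s >= 1 and wA[s] > 0.0:
                    PCBAm += v
            pCA = P[k, 0]

            # (3) phosphorylation Euler step with soft-spin confinement
            d = D[k]
            gp = a * (d - 0.5) * (2.0 * (d - 0.5) * (d - 0.5) + 2.0 * d * d - 2.0 * d)
            d = d + dt * (k_p * pCA - k_dp * (1.0 - pCA) - gp)
            D[k] = d

            # (4) stochastic Pi release / structure-dependent ADP release;
            # one uniform per subunit per step keeps streams aligned
            p_off = -np.expm1(-dt / (delta0 * (gamma - x)))
            nb = 0
            for s6 in range(6):
                u = np.random.random()
                if adp_bound[k, s6]:
                    if u < p_off:
                        adp_bound[k, s6] = False
                    else:
                        nb += 1
                else:
                    if u < p_event:
                        adp_bound[k, s6] = True
                        release_count[k] += 1
                        rel_interval += 1
                        nb += 1

            # (5) quasi-equilibrium structure from the updated fields
            h = c0 - c1 * d + c2 * pCA - c3 * pB - q0 * nb
            X[k] = 0.5 * np.tanh(beta * h) + 0.5

            Dm += d
            Xm += X[k]
            PCAm += pCA

        if (istep + 1) % stride == 0:
            out_t[sample] = t_new
            out_D[sample] = Dm / N
            out_X[sample] = Xm / N
            out_PCA[sample] = PCAm / N
            out_PCBA[sample] = PCBAm / N
            out_rel[sample] = rel_interval
            out_free[sample, 0] = max(A_T - 2.0 * sumA / V, 0.0)
            out_free[sample, 1] = max(B_T - sumB / V, 0.0)
            for r in range(n_rec):
                out_Drec[sample, r] = D[rec_idx[r]]
            rel_interval = 0
            sample += 1

    return STATUS_OK, max_corr, sample
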