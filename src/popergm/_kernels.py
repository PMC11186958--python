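"""Compiled inner loops for ERGM network simulation.

The dyad-toggle Metropolis-Hastings chain dominates runtime (it runs
once per exchange update, per network, per Gibbs iteration), so it is
JIT-compiled. Randomness is pre-drawn outside the kernel so that the
chain is reproducible under a single numpy Generator.

Term codes: 0 = edges, 1 = nodematch (integer-coded labels),
2 = nodematch_homotopy, 3 = gwesp(tau).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TERM_EDGES = 0
TERM_NODEMATCH = 1
TERM_HOMOTOPY = 2
TERM_GWESP = 3


@njit(cache=True)
def _add_delta(A, i, j, term_codes, term_taus, labels, partner, out):
    """Change statistics of adding edge (i, j); A must not contain it."""
    n = A.shape[0]
    for m in range(term_codes.shape[0]):
        c = term_codes[m]
        if c == TERM_EDGES:
            out[m] = 1.0
        elif c == TERM_NODEMATCH:
            out[m] = 1.0 if labels[i] == labels[j] else 0.0
        elif c == TERM_HOMOTOPY:
            out[m] = 1.0 if partner[i] == j else 0.0
        else:
            tau = term_taus[m]
            b = 1.0 - np.exp(-tau)
            cn = 0
            d = 0.0
            for k in range(n):
                if A[i, k] == 1 and A[j, k] == 1:
                    cn += 1
                    sp_ik = 0
                    sp_jk = 0
                    for l in range(n):
                        if A[k, l] == 1:
                            if A[i, l] == 1:
                                sp_ik += 1
                            if A[j, l] == 1:
                                sp_jk += 1
                    # f(w+1) - f(w) = b^w for f(w) = e^tau (1 - b^w)
                    d += b ** sp_ik + b ** sp_jk
            d += np.exp(tau) * (1.0 - b ** cn)
            out[m] = d


@njit(cache=True)
def toggle_chain(A, theta, term_codes, term_taus, labels, partner, ii, jj, logu):
    """Run single-dyad toggle MH steps in place; returns acceptance count.

    ii/jj are the proposed dyads (i < j), logu the log of uniform
    variates deciding acceptance.
    """
    p = theta.shape[0]
    delta = np.empty(p, dtype=np.float64)
    accepted = 0
    for t in range(ii.shape[0]):
        i = ii[t]
        j = jj[t]
        present = A[i, j] == 1
        if present:
            A[i, j] = 0
            A[j, i] = 0
        _add_delta(A, i, j, term_codes, term_taus, labels, partner, delta)
        lp = 0.0
        for m in range(p):
            lp += theta[m] * delta[m]
        if present:
            lp = -lp
        if logu[t] < lp:
            accepted += 1
            if not present:
                A[i, j] = 1
                A[j, i] = 1
            # accepted removal: edge stays absent
        else:
            if present:  # rejected removal: restore
                A[i, j] = 1
                A[j, i] = 1
    return accepted
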