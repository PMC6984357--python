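"""Inner loops of the pruning likelihood, JIT-compiled when numba is present.

The numpy implementations in :mod:`likelihood` and :mod:`optimize` are the
reference; these kernels compute the same quantities with explicit loops
(pattern index innermost, contiguous) so they vectorize well.  Everything
falls back to numpy transparently if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True, fastmath=True)
def _prune(post, kptr, kidx, ntips, root, P, tips, clv, ls,
           thresh, mode):
    """Fill ``clv``/``ls`` for internal nodes in postorder.

    mode: 0 = auto scaling, 1 = always, 2 = never.
    """
    nnodes, C, ns, _ = P.shape
    npat = tips.shape[2]
    n_internal = 0
    for oi in range(post.shape[0]):
        v = post[oi]
        nk = kptr[v + 1] - kptr[v]
        if nk == 0:
            continue
        n_internal += 1
        for c in range(C):
            for i in range(ns):
                for p in range(npat):
                    clv[v, c, i, p] = 1.0
        for p in range(npat):
            ls[v, p] = 0.0
        acc = np.empty(npat)
        for j in range(kptr[v], kptr[v + 1]):
            ch = kidx[j]
            child_is_tip = kptr[ch + 1] - kptr[ch] == 0
            for c in range(C):
                for i in range(ns):
                    for p in range(npat):
                        acc[p] = 0.0
                    for s in range(ns):
                        pij = P[ch, c, i, s]
                        if child_is_tip:
                            row = tips[ch, s]
                        else:
                            row = clv[ch, c, s]
                        for p in range(npat):
                            acc[p] += pij * row[p]
                    for p in range(npat):
                        clv[v, c, i, p] *= acc[p]
            if not child_is_tip:
                for p in range(npat):
                    ls[v, p] += ls[ch, p]
        if v < ntips:  # 2-taxon case: virtual root on a tip
            for c in range(C):
                for i in range(ns):
                    for p in range(npat):
                        clv[v, c, i, p] *= tips[v, i, p]
        # checking every third internal node (and the root) is enough:
        # partials shrink by at most ~(min P entry)^2 per level, leaving
        # ample headroom between the trigger threshold and double underflow
        if mode != 2 and (mode == 1 or n_internal % 3 == 0 or v == root):
            need = mode == 1
            if not need:
                for p in range(npat):
                    m = 0.0
                    for c in range(C):
                        for i in range(ns):
                            if clv[v, c, i, p] > m:
                                m = clv[v, c, i, p]
                    if m < thresh:
                        need = True
                        break
            if need:
                for p in range(npat):
                    m = 0.0
                    for c in range(C):
                        for i in range(ns):
                            if clv[v, c, i, p] > m:
                                m = clv[v, c, i, p]
                    if m < 1e-300:
                        m = 1e-300
                    for c in range(C):
                        for i in range(ns):
                            clv[v, c, i, p] /= m
                    ls[v, p] += np.log(m)


def prune_clvs(post, kptr, kidx, ntips, root, P, tips, clv, ls, thresh, mode):
    _prune(post, kptr, kidx, ntips, root, P, tips, clv, ls, thresh, mode)
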