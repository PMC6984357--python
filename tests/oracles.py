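"""Independent reference implementations used to validate the package.

These deliberately avoid the production code paths: likelihoods are
computed by explicit summation over internal-node state assignments, and
discrete-gamma category means by numerical quadrature.
"""

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from phylosel.likelihood import (PruningEngine, eigensystems,
                                 rates_and_weights)
from phylosel.substmodels import transition_matrices


def brute_force_site_lnls(tree, paln, model, params):
    """Log-likelihood per pattern by enumerating internal-node states."""
    eigs = eigensystems(model, params)
    rates, cat_w = rates_and_weights(model, params)
    eng = PruningEngine(paln)
    ns = eng.n_states
    P = transition_matrices(eigs, tree.lengths, rates)
    pi = eigs.pi if not isinstance(eigs, list) else None
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    out = []
    for p in range(eng.n_data_patterns):
        total = 0.0
        for c in range(len(rates)):
            pic = pi if pi is not None else eigs[c].pi
            for assign in itertools.product(range(ns), repeat=len(internals)):
                st = dict(zip(internals, assign))
                val = pic[st[tree.root]]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    par = st[tree.parent[v]]
                    if tree.children[v]:
                        val *= P[v, c, par, st[v]]
                    else:
                        val *= float(P[v, c, par, :]
                                     @ eng.tip_partials[v][:, p])
                total += cat_w[c] * val
        if model.has_pinv and params.p_inv:
            cpat = float((pi if pi is not None else cat_w @ np.stack(
                [e.pi for e in eigs])) @ eng.const_comp[:, p])
            total = (1 - params.p_inv) * total + params.p_inv * cpat
        out.append(np.log(total))
    return np.array(out)


def constant_pattern_prob(tree, labels, model, params):
    """P(constant column) by brute-force enumeration of the pure patterns."""
    from phylosel.msa import Alignment, compress_patterns, states_for

    states = states_for(model.datatype)
    mat = np.array([list(states) for _ in labels], dtype="<U1")
    paln = compress_patterns(Alignment(list(labels), mat, model.datatype))
    lnls = brute_force_site_lnls(tree, paln, model, params)
    return float(np.exp(lnls).sum())


def gamma_category_means(alpha, ncat):
    """Mean-of-category rates of Gamma(alpha, alpha) by quadrature."""
    edges = [0.0] + list(gamma_dist.ppf(np.arange(1, ncat) / ncat,
                                        a=alpha, scale=1 / alpha)) + [np.inf]
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha,
                                                   scale=1 / alpha),
                      lo, hi, limit=200)
        rates.append(val * ncat)
    return np.array(rates)
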