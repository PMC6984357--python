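"""Sequence simulation under known models and the model-recovery experiment.

Alignments are evolved site-by-site along a random topology (sequential
random addition) with i.i.d. exponential branch lengths: the root state is
drawn from the stationary frequencies, each site is assigned a rate (zero
with probability p_inv, otherwise a draw from the discrete-gamma or
free-rate mixture) and propagated down every branch with the transition
matrix P(t * r).  The recovery experiment draws a generating model
uniformly from a candidate universe, simulates, runs the full selection
pipeline on the simulated alignment and scores an exact best-model name
match.  A master seed spawns independent per-replicate substreams, so any
replicate can be reproduced in isolation.

Generating-parameter ranges (documented stand-ins, configurable):
alpha ~ U[0.3, 2], p_inv ~ U[0, 0.5], exchangeability classes ~ U[0.5, 5]
with transition-containing classes doubled, frequencies ~ Dirichlet(10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .likelihood import ModelParams, eigensystems, rates_and_weights
from .msa import Alignment, compress_patterns, states_for
from .substmodels import SubstitutionModel, transition_matrices
from .tree import Tree


def simulate_tree(n_taxa: int, bl_mean: float = 0.1, seed=None,
                  rng: np.random.Generator | None = None) -> Tree:
    """Random topology by sequential random addition; exp(bl_mean) branches."""
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa to simulate a tree")
    rng = np.random.default_rng(seed) if rng is None else rng
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    root = n_taxa  # first internal node joins tips 0,1,2
    adj = {i: [] for i in range(n_taxa + 1)}
    edges = []

    def connect(u, v):
        adj[u].append(v)
        adj[v].append(u)
        edges.append((u, v))

    for tip in (0, 1, 2):
        connect(root, tip)
    next_node = n_taxa + 1
    for tip in range(3, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        mid = next_node
        next_node += 1
        adj[mid] = []
        adj[u].remove(v)
        adj[v].remove(u)
        edges.remove((u, v))
        connect(u, mid)
        connect(mid, v)
        connect(mid, tip)
    bls = rng.exponential(bl_mean, size=len(edges))
    adj_bl = {v: [] for v in adj}
    for (u, v), bl in zip(edges, bls):
        adj_bl[u].append((v, bl))
        adj_bl[v].append((u, bl))
    return Tree.from_adjacency(adj_bl, labels, root)


def _site_rates(model, params, n_sites, rng):
    rates, weights = rates_and_weights(model, params)
    cat = rng.choice(len(rates), size=n_sites, p=weights)
    r = rates[cat]
    if model.has_pinv and params.p_inv:
        r[rng.random(n_sites) < params.p_inv] = 0.0
        cat = np.where(r == 0.0, -1, cat)
    return r, cat


def simulate_alignment(tree: Tree, model: SubstitutionModel,
                       params: ModelParams, n_sites: int, seed=None,
                       rng: np.random.Generator | None = None) -> Alignment:
    """Evolve ``n_sites`` characters down ``tree`` under ``model``."""
    rng = np.random.default_rng(seed) if rng is None else rng
    states = states_for(model.datatype)
    ns = len(states)
    eigs = eigensystems(model, params)
    mixture_cats = model.mixture is not None
    rates, _ = rates_and_weights(model, params)
    site_rate, site_cat = _site_rates(model, params, n_sites, rng)
    if mixture_cats:
        pis = np.stack([e.pi for e in eigs])
        pibar = pis.mean(axis=0)  # root drawn from the average mixture pi
    else:
        pibar = eigs.pi
    seq = {tree.root: rng.choice(ns, size=n_sites, p=pibar)}
    # per-edge transition matrices for every distinct category rate
    P = transition_matrices(eigs, tree.lengths, rates)  # (nodes, C, ns, ns)
    cum = P.cumsum(axis=3)
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_state = seq[tree.parent[v]]
        child = parent_state.copy()
        variable = site_rate > 0
        if variable.any():
            cats = site_cat[variable]
            ps = parent_state[variable]
            u = rng.random(ps.shape[0])
            rowcum = cum[v, cats, ps, :]            # (nvar, ns)
            child[variable] = (u[:, None] > rowcum).sum(axis=1)
        seq[v] = child
    arr = np.array([[states[s] for s in seq[i]] for i in range(tree.n_tips)],
                   dtype="<U1")
    return Alignment(list(tree.labels), arr, model.datatype)


# ---------------------------------------------------------------------------
# Generating-parameter draws

_TRANSITION_SLOTS = (1, 4)  # AG and CT positions in the exchangeability order


def draw_generating_params(model: SubstitutionModel,
                           rng: np.random.Generator) -> ModelParams:
    params = ModelParams()
    if model.datatype == "DNA":
        k = model.n_exch_classes
        vals = rng.uniform(0.5, 5.0, size=k)
        idx = np.array([int(c) for c in model.scheme])
        for cls in set(idx[list(_TRANSITION_SLOTS)]):
            vals[cls] *= 2.0
        ref = idx[5]
        vals = vals / vals[ref]
        params.exch = vals
        params.freqs = (np.full(4, 0.25) if model.freq_mode == "equal"
                        else rng.dirichlet(np.full(4, 10.0)))
    else:
        if model.freq_mode in ("empirical", "ml"):
            params.freqs = rng.dirichlet(np.full(20, 10.0))
    if model.has_gamma:
        params.alpha = float(rng.uniform(0.3, 2.0))
    if model.has_pinv:
        params.p_inv = float(rng.uniform(0.0, 0.5))
    if model.rate_het == "R":
        k = model.n_free_rates
        from .substmodels import free_rate_categories
        r = rng.uniform(0.1, 3.0, size=k)
        w = rng.dirichlet(np.full(k, 5.0))
        params.rates, params.rate_weights = free_rate_categories(r, w)
    return params


@dataclass
class RecoveryResult:
    fraction: float
    records: pd.DataFrame     # replicate, generating model, selected model
    confusion: pd.DataFrame   # generating x selected counts

    @property
    def n_replicates(self) -> int:
        return len(self.records)


def recovery_experiment(n_replicates: int, model_universe,
                        criterion: str = "BIC", n_taxa: int = 20,
                        n_sites: int = 2000, bl_mean: float = 0.1,
                        seed: int = 0, settings=None,
                        n_workers: int = 1) -> RecoveryResult:
    """How often does selection return exactly the generating model?

    Per replicate: draw a generating model uniformly from the universe,
    draw its parameters from the stand-in ranges, simulate an alignment on
    a fresh random tree, run the full selection pipeline over the whole
    universe and score an exact name match.
    """
    from .optimize import OptimizerSettings, fit_all_models
    from .selection import select
    from .tree import jc_distance_matrix, nj_topology

    models = list(model_universe)
    if not models:
        raise ValidationError("empty model universe")
    settings = settings or OptimizerSettings()
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        gen = models[rng.integers(len(models))]
        gen_params = draw_generating_params(gen, rng)
        tree = simulate_tree(n_taxa, bl_mean=bl_mean, rng=rng)
        aln = simulate_alignment(tree, gen, gen_params, n_sites, rng=rng)
        paln = compress_patterns(aln)
        base = nj_topology(jc_distance_matrix(aln), aln.taxon_labels)
        fits = fit_all_models(paln, models, base, settings=settings,
                              n_workers=n_workers)
        result = select(fits, criteria=(criterion,))
        best = result.best_model(criterion)
        rows.append({"replicate": rep, "generating": gen.name,
                     "selected": best.model.name,
                     "match": best.model.name == gen.name})
    records = pd.DataFrame(rows)
    confusion = pd.crosstab(records["generating"], records["selected"])
    return RecoveryResult(fraction=float(records["match"].mean()),
                          records=records, confusion=confusion)
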