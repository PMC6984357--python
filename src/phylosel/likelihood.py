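"""Felsenstein pruning likelihood with rate heterogeneity and +I mixing.

Site likelihoods are computed over compressed site patterns.  Conditional
likelihood vectors (CLVs) are stored per rate category as ``(C, n_states,
n_patterns)`` arrays so each pruning step is a batched matrix product.
Numerical underflow is handled by per-node rescaling with accumulated
per-pattern log scalers; rescaling is triggered automatically once any
pattern's partials drop below a threshold, so small trees run unscaled and
produce bit-identical results either way.

The +I proportion of invariant sites mixes ``p_inv * pi_s`` (for the states
``s`` with which *every* tip of the column is compatible) with ``(1 -
p_inv)`` times the variable-rate mixture.  Ascertainment bias (Lewis
correction) conditions the likelihood on columns being variable by
dividing by ``1 - P_const``, with ``P_const`` obtained by pushing the
``n_states`` fully constant columns through the same pruning pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, OptimizationError, ValidationError
from .msa import PatternAlignment, ambiguity_map, compress_patterns, states_for
from .substmodels import (EigenSystem, SubstitutionModel, build_rate_matrix,
                          discrete_gamma_rates, eigen_decompose,
                          expand_scheme_rates, free_rate_categories,
                          load_empirical_matrix, transition_matrices)

_SCALE_THRESHOLD = 1e-120


@dataclass
class ModelParams:
    """Concrete values for a model's free (and fixed) parameters."""

    freqs: np.ndarray | None = None
    exch: np.ndarray | None = None          # per-class values, DNA
    alpha: float | None = None
    p_inv: float | None = None
    rates: np.ndarray | None = None         # free-rate categories
    rate_weights: np.ndarray | None = None

    def copy(self) -> "ModelParams":
        cp = lambda a: None if a is None else np.array(a, dtype=float)
        return ModelParams(freqs=cp(self.freqs), exch=cp(self.exch),
                           alpha=self.alpha, p_inv=self.p_inv,
                           rates=cp(self.rates),
                           rate_weights=cp(self.rate_weights))

    def as_dict(self) -> dict:
        out = {}
        if self.exch is not None:
            out["exch"] = list(map(float, self.exch))
        if self.freqs is not None:
            out["freqs"] = list(map(float, self.freqs))
        if self.alpha is not None:
            out["alpha"] = float(self.alpha)
        if self.p_inv is not None:
            out["p_inv"] = float(self.p_inv)
        if self.rates is not None:
            out["rates"] = list(map(float, self.rates))
            out["rate_weights"] = list(map(float, self.rate_weights))
        return out


@dataclass
class LikelihoodResult:
    lnL: float
    per_pattern_lnL: np.ndarray
    model_params: ModelParams


def rates_and_weights(model: SubstitutionModel, params: ModelParams):
    """Rate-category rates/weights of the variable-rate mixture."""
    if model.mixture is not None:
        k = len(model.mixture)
        if model.rate_het == "R":
            return free_rate_categories(params.rates, params.rate_weights)
        return discrete_gamma_rates(params.alpha, k)
    if model.rate_het in ("none", "I"):
        return np.array([1.0]), np.array([1.0])
    if model.rate_het in ("G", "I+G"):
        return discrete_gamma_rates(params.alpha, model.n_gamma_cats)
    if model.rate_het == "R":
        return free_rate_categories(params.rates, params.rate_weights)
    raise DomainError(f"unknown rate heterogeneity {model.rate_het!r}")


def eigensystems(model: SubstitutionModel, params: ModelParams,
                 cache: dict | None = None):
    """EigenSystem (or per-category list for mixtures) for a model.

    ``cache`` (a one-slot dict) avoids redecomposition when the matrix
    parameters did not change between likelihood evaluations, e.g. during
    branch-length or rate-heterogeneity optimization.
    """
    if cache is not None:
        key = (model.name,
               None if params.exch is None else tuple(params.exch),
               None if params.freqs is None else tuple(params.freqs))
        hit = cache.get("eig")
        if hit is not None and hit[0] == key:
            return hit[1]
        eig = eigensystems(model, params, cache=None)
        cache["eig"] = (key, eig)
        return eig
    if model.datatype == "DNA":
        full = expand_scheme_rates(model.scheme, params.exch)
        return eigen_decompose(build_rate_matrix(full, params.freqs))
    if model.mixture is not None:
        out = []
        for mat in model.mixture:
            S, mfreq = load_empirical_matrix(mat)
            pi = mfreq if model.freq_mode == "model" else params.freqs
            out.append(eigen_decompose(build_rate_matrix(S, pi)))
        return out
    S, mfreq = load_empirical_matrix(model.matrix)
    pi = mfreq if model.freq_mode == "model" else params.freqs
    return eigen_decompose(build_rate_matrix(S, pi))


def _pi_matrix(eigs, ncat):
    if isinstance(eigs, EigenSystem):
        return np.broadcast_to(eigs.pi, (ncat, len(eigs.pi)))
    return np.stack([e.pi for e in eigs])


class PruningEngine:
    """Per-alignment state reused across many likelihood evaluations."""

    def __init__(self, paln: PatternAlignment, asc: bool = False,
                 scaling: str = "auto"):
        self.datatype = paln.datatype
        self.states = states_for(self.datatype)
        self.n_states = len(self.states)
        self.n_tips = paln.n_taxa
        self.n_data_patterns = paln.n_patterns
        self.asc = asc
        self.scaling = scaling
        self.taxon_labels = list(paln.taxon_labels)
        self.n_sites = paln.n_sites

        amb = ambiguity_map(self.datatype)
        lut = np.zeros((128, self.n_states))
        for sym, compat in amb.items():
            for st in compat:
                lut[ord(sym), self.states.index(st)] = 1.0
        codes = paln.patterns.view(np.uint32).reshape(paln.patterns.shape)
        tp = lut[codes]                           # (tips, npat, ns)
        if asc:
            const = np.zeros((self.n_tips, self.n_states, self.n_states))
            const[:, np.arange(self.n_states), np.arange(self.n_states)] = 1.0
            tp = np.concatenate([tp, const.transpose(0, 2, 1)], axis=1)
        self.tip_partials = np.ascontiguousarray(tp.transpose(0, 2, 1))
        self.n_patterns = self.tip_partials.shape[2]
        w = np.zeros(self.n_patterns)
        w[:self.n_data_patterns] = paln.weights
        self.weights = w
        # state-compatibility of whole columns (ambiguity-aware)
        self.const_comp = np.all(self.tip_partials == 1.0, axis=0)  # (ns, npat)
        resolved = self.tip_partials.sum(axis=1) == 1.0             # (tips,npat)
        same = self.const_comp.any(axis=0)
        self.strictly_constant = same & resolved.all(axis=0)
        self.strictly_constant[self.n_data_patterns:] = False
        self._eig_cache: dict = {}
        self._buffers: dict = {}

    def _tree_arrays(self, tree):
        return tree.flat_arrays()

    def _clv_buffer(self, n_nodes, ncat):
        key = (n_nodes, ncat)
        buf = self._buffers.get(key)
        if buf is None:
            clv = np.empty((n_nodes, ncat, self.n_states, self.n_patterns))
            ls = np.zeros((n_nodes, self.n_patterns))
            buf = self._buffers[key] = (clv, ls)
        return buf

    # -- low-level pruning -------------------------------------------------
    def _maybe_scale(self, arr, ls):
        if self.scaling == "never":
            return
        m = arr.max(axis=(0, 1))
        if self.scaling == "always" or m.min() < _SCALE_THRESHOLD:
            np.maximum(m, 1e-300, out=m)
            arr /= m
            ls += np.log(m)

    def root_clv(self, tree, P):
        """CLV and log-scalers at the virtual root for P per node."""
        from . import _kernels

        ncat = P.shape[1]
        if _kernels.HAVE_NUMBA:
            post, kptr, kidx = self._tree_arrays(tree)
            clv, ls = self._clv_buffer(tree.n_nodes, ncat)
            mode = {"auto": 0, "always": 1, "never": 2}[self.scaling]
            _kernels.prune_clvs(post, kptr, kidx, self.n_tips, tree.root,
                                np.ascontiguousarray(P), self.tip_partials,
                                clv, ls, _SCALE_THRESHOLD, mode)
            return clv[tree.root], ls[tree.root]
        clv = [None] * tree.n_nodes
        ls = [None] * tree.n_nodes
        for v in tree.postorder():
            kids = tree.children[v]
            if not kids:
                continue
            prod = None
            acc = np.zeros(self.n_patterns)
            for c in kids:
                child_clv = (self.tip_partials[c][None] if clv[c] is None
                             else clv[c])
                msg = np.matmul(P[c], child_clv)
                prod = msg if prod is None else prod * msg
                if ls[c] is not None:
                    acc += ls[c]
            if v < self.n_tips:  # 2-taxon case: root can be a tip
                prod = prod * self.tip_partials[v][None]
            self._maybe_scale(prod, acc)
            clv[v] = prod
            ls[v] = acc
        return clv[tree.root], ls[tree.root]

    def components(self, tree, model, params):
        """Variable-rate site likelihoods plus +I ingredients.

        Returns ``(L_var, log_scalers, logC)`` where ``L_var`` are scaled
        linear likelihoods of the variable-rate mixture per pattern and
        ``logC`` the log of the invariant-class likelihood (``-inf`` for
        columns not compatible with any constant state).
        """
        eigs = eigensystems(model, params, cache=self._eig_cache)
        rates, cat_weights = rates_and_weights(model, params)
        pis = _pi_matrix(eigs, len(rates))
        P = transition_matrices(eigs, tree.lengths, rates)
        clv, ls = self.root_clv(tree, P)
        site_cat = np.einsum("cs,csp->cp", pis, clv)
        L_var = cat_weights @ site_cat
        pibar = cat_weights @ pis
        with np.errstate(divide="ignore"):
            logC = np.log(pibar @ self.const_comp)
        return L_var, ls, logC

    def per_pattern_lnl(self, tree, model, params):
        L_var, ls, logC = self.components(tree, model, params)
        return combine_invariant(L_var, ls, logC, model, params)


def combine_invariant(L_var, ls, logC, model, params):
    """Mix the variable-rate likelihood with the invariant class."""
    with np.errstate(divide="ignore"):
        log_var = np.log(L_var) + ls
        if model.has_pinv and params.p_inv is not None and params.p_inv > 0:
            p = params.p_inv
            if not 0 <= p <= 1:
                raise DomainError("p_inv must be in [0, 1]")
            return np.logaddexp(np.log1p(-p) + log_var, np.log(p) + logC)
    return log_var


def site_loglikelihoods(tree, paln, model: SubstitutionModel,
                        params: ModelParams, engine: PruningEngine | None = None
                        ) -> np.ndarray:
    """Per-pattern log-likelihood vector (no ascertainment correction)."""
    if engine is None:
        engine = PruningEngine(paln, asc=model.asc_bias)
    lnl = engine.per_pattern_lnl(tree, model, params)
    return lnl[:engine.n_data_patterns]


def ascertainment_correction(per_pattern_lnl, const_lnl):
    """Lewis-type correction: subtract log(1 - P_const) from every site.

    ``const_lnl`` holds the log-likelihoods of the ``n_states`` fully
    constant columns under the same tree/model/parameters.
    """
    p_const = float(np.exp(const_lnl).sum())
    if not np.isfinite(p_const) or p_const >= 1.0 - 1e-12:
        raise OptimizationError(
            "ascertainment correction diverges: P(constant) ~ 1")
    return per_pattern_lnl - np.log1p(-p_const)


def total_loglik(tree, paln, model: SubstitutionModel, params: ModelParams,
                 engine: PruningEngine | None = None) -> LikelihoodResult:
    """Weighted total log-likelihood (with ascertainment correction if set)."""
    if engine is None:
        paln = paln if isinstance(paln, PatternAlignment) else compress_patterns(paln)
        engine = PruningEngine(paln, asc=model.asc_bias)
    if model.asc_bias and engine.strictly_constant.any():
        raise ValidationError(
            "alignment contains constant columns; ascertainment-corrected "
            "models require variable-sites-only data")
    lnl = engine.per_pattern_lnl(tree, model, params)
    data_lnl = lnl[:engine.n_data_patterns]
    if model.asc_bias:
        data_lnl = ascertainment_correction(
            data_lnl, lnl[engine.n_data_patterns:])
    weights = engine.weights[:engine.n_data_patterns]
    total = float(weights @ data_lnl)
    return LikelihoodResult(lnL=total, per_pattern_lnL=data_lnl,
                            model_params=params.copy())
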