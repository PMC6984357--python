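"""Maximization of the log-likelihood over model parameters and branches.

Branch lengths are optimized one edge at a time by safeguarded Newton steps
using analytic first and second derivatives of the likelihood in the branch
length (via the eigendecomposition of Q), sweeping the tree in preorder
with directional CLVs that are kept exact as edges change.  Model
parameters use coordinate descent with a quadratic-interpolation line
search per parameter on a log (or logit) scale; the proportion of
invariant sites has a fast path that reuses cached site likelihoods, since
changing p_inv does not require re-running the pruning pass.

Thoroughness is controlled by ``OptimizerSettings.epsilon``: coordinate
rounds stop once a full round improves the log-likelihood by less than
epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigError, OptimizationError, ValidationError
from .likelihood import (ModelParams, PruningEngine, combine_invariant,
                         eigensystems, rates_and_weights, _pi_matrix)
from .msa import PatternAlignment
from .substmodels import SubstitutionModel, transition_matrices
from .tree import MAX_BRANCH, MIN_BRANCH, Tree

EPSILON_PRESETS = {"fast": 1.0, "default": 0.01, "thorough": 0.001}


@dataclass
class OptimizerSettings:
    epsilon: float = 0.01            # lnL convergence threshold per round
    param_epsilon: float = 1e-4      # per-parameter tolerance (transformed)
    max_rounds: int = 50
    max_bl_passes: int = 10
    min_branch: float = MIN_BRANCH
    max_branch: float = MAX_BRANCH
    alpha_bounds: tuple = (0.02, 100.0)
    exch_bounds: tuple = (1e-4, 1000.0)
    count_branch_params: bool = True

    def __post_init__(self):
        if self.epsilon <= 0 or self.param_epsilon <= 0:
            raise ConfigError("tolerances must be positive")

    @classmethod
    def from_preset(cls, preset) -> "OptimizerSettings":
        try:
            eps = EPSILON_PRESETS.get(preset, None)
            if eps is None:
                eps = float(preset)
        except (TypeError, ValueError):
            raise ConfigError(f"unknown epsilon preset {preset!r}") from None
        return cls(epsilon=eps)


@dataclass
class ModelFit:
    model: SubstitutionModel
    lnL: float
    params: ModelParams
    tree: Tree
    K: int
    n: int
    ok: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# 1-D line search: quadratic interpolation with best-point tracking.

def _maximize_scalar(f, x0, lb, ub, xtol, f0=None, max_iter=16):
    """Maximize f on [lb, ub] starting from x0; never returns a worse point."""
    x = min(max(x0, lb), ub)
    cache = {}

    def F(z):
        if z not in cache:
            cache[z] = f(z)
        return cache[z]

    fx = F(x) if f0 is None else cache.setdefault(x, f0)
    best_x, best_f = x, fx
    h = max(min(0.5, (ub - lb) / 4.0), 4.0 * xtol)
    for _ in range(max_iter):
        xp, xm = min(x + h, ub), max(x - h, lb)
        if xp - xm < xtol:
            break
        fp, fm = F(xp), F(xm)
        for cx, cf in ((xp, fp), (xm, fm)):
            if cf > best_f:
                best_x, best_f = cx, cf
        # quadratic through the three (possibly unevenly spaced) points
        d1, d2 = xm - x, xp - x
        det = d1 * d2 * (d1 - d2)
        if det == 0.0:  # x sits on a bound; probe toward the interior
            if d2 != 0.0:
                step = d2 if fp >= fx else 0.25 * d2
            elif d1 != 0.0:
                step = d1 if fm >= fx else 0.25 * d1
            else:
                break
        else:
            a = (d2 * (fm - fx) - d1 * (fp - fx)) / det
            b = (d1 * d1 * (fp - fx) - d2 * d2 * (fm - fx)) / det
            if a < 0:
                step = float(np.clip(-b / (2.0 * a), -4.0 * h, 4.0 * h))
            else:
                step = np.sign(b if b != 0 else 1.0) * 2.0 * h
        xn = min(max(x + step, lb), ub)
        fn = F(xn)
        if fn > best_f:
            best_x, best_f = xn, fn
        moved = abs(best_x - x)
        x, fx = best_x, best_f
        if moved < xtol and h <= 4.0 * xtol:
            break
        h = max(h / 4.0, xtol) if moved == 0 else max(2.0 * xtol,
                                                      min(h, moved))
    return best_x, best_f


# ---------------------------------------------------------------------------
# Branch-length optimization

class _EdgeOptimizer:
    """One preorder smoothing sweep with exact directional CLVs."""

    def __init__(self, engine: PruningEngine, tree: Tree, model, params,
                 settings: OptimizerSettings):
        self.engine = engine
        self.tree = tree
        self.model = model
        self.settings = settings
        self.eigs = eigensystems(model, params, cache=engine._eig_cache)
        self.rates, self.cat_w = rates_and_weights(model, params)
        self.C = len(self.rates)
        self.pis = _pi_matrix(self.eigs, self.C)
        ns = engine.n_states
        if isinstance(self.eigs, list):
            self.ev = np.stack([e.eigenvalues for e in self.eigs])
            self.right = np.stack([e.right for e in self.eigs])
            self.left = np.stack([e.left for e in self.eigs])
        else:
            self.ev = np.ascontiguousarray(
                np.broadcast_to(self.eigs.eigenvalues, (self.C, ns)))
            self.right = np.ascontiguousarray(
                np.broadcast_to(self.eigs.right, (self.C, ns, ns)))
            self.left = np.ascontiguousarray(
                np.broadcast_to(self.eigs.left, (self.C, ns, ns)))
        self.evr = np.ascontiguousarray(self.ev * self.rates[:, None])
        self._lam = self.evr.ravel()                      # (C*ns,)
        self._wrep = np.repeat(self.cat_w, ns)
        self.p_inv = params.p_inv if model.has_pinv and params.p_inv else 0.0
        pibar = self.cat_w @ self.pis
        self.Cpat = pibar @ engine.const_comp             # (npat,)
        self.W = engine.weights.sum()

    def _P(self, t):
        expv = np.exp(self.evr * t)                       # (C, ns)
        return np.matmul(self.right * expv[:, None, :], self.left)

    def _edge_prod(self, A, lower):
        """Spectral sum-product for one edge.

        Projecting the upper conditional A and lower CLV onto the
        eigenbasis once per edge makes every branch-length trial a single
        small matrix product: sum_cs exp(lambda_cs * t) * prod[cs, p].
        """
        low3 = (lower if lower.ndim == 3 else
                np.broadcast_to(lower, (self.C,) + lower.shape))
        M1 = np.matmul(self.right.transpose(0, 2, 1), A)   # (C, ns, npat)
        M2 = np.matmul(self.left, low3)
        npat = A.shape[-1]
        return np.ascontiguousarray((M1 * M2).reshape(-1, npat))

    def _fgh(self, t, prodflat, ls_tot):
        """lnL and its first/second derivative in the length of one edge."""
        eng = self.engine
        E = np.exp(self._lam * t) * self._wrep             # (C*ns,)
        coef = np.empty((3, len(E)))
        coef[0] = E
        coef[1] = E * self._lam
        coef[2] = coef[1] * self._lam
        V = coef @ prodflat                                # (3, npat)
        one_m = 1.0 - self.p_inv
        with np.errstate(over="ignore"):
            B = np.where(self.Cpat > 0,
                         self.p_inv * self.Cpat
                         * np.exp(np.minimum(-ls_tot, 700.0)), 0.0)
        denom = one_m * V[0] + B
        bad = denom <= 0
        if bad.any():
            denom = np.where(bad, 1e-300, denom)
        w = eng.weights
        val = float(w @ (np.log(denom) + ls_tot))
        r1 = one_m * V[1] / denom
        g = float(w @ r1)
        hh = float(w @ (one_m * V[2] / denom - r1 * r1))
        if eng.asc:
            idx = slice(eng.n_data_patterns, None)
            Lc = denom[idx] * np.exp(ls_tot[idx])
            pc = Lc.sum()
            if pc >= 1.0 - 1e-12:
                return -np.inf, 0.0, 0.0
            d1 = (one_m * V[1][idx] * np.exp(ls_tot[idx])).sum()
            d2 = (one_m * V[2][idx] * np.exp(ls_tot[idx])).sum()
            val -= self.W * np.log1p(-pc)
            g += self.W * d1 / (1.0 - pc)
            hh += self.W * (d2 / (1.0 - pc) + (d1 / (1.0 - pc)) ** 2)
        return val, g, hh

    def _newton_edge(self, t0, A, lower, ls_tot):
        s = self.settings
        prodflat = self._edge_prod(A, lower)
        t = min(max(t0, s.min_branch), s.max_branch)
        val, g, hh = self._fgh(t, prodflat, ls_tot)
        best_t, best_v = t, val
        # skip edges whose projected gain is a negligible share of epsilon
        if hh < 0 and 0.5 * g * g / (-hh) < 0.005 * s.epsilon:
            return best_t, best_v
        if t <= s.min_branch and g < 0:
            return best_t, best_v
        if t >= s.max_branch and g > 0:
            return best_t, best_v
        for _ in range(10):
            tol = max(1e-9, s.param_epsilon * max(t, 1e-2))
            if hh < 0:
                step = -g / hh
            else:
                step = np.sign(g) * max(0.1 * max(t, 1e-3), 1e-4)
            step = float(np.clip(step, -1.0 - t, 1.0 + t))
            tn = min(max(t + step, s.min_branch), s.max_branch)
            if abs(tn - t) < tol:
                vn, gn, hn = self._fgh(tn, prodflat, ls_tot)
                if vn > best_v:
                    best_t, best_v = tn, vn
                break
            vn, gn, hn = self._fgh(tn, prodflat, ls_tot)
            tries = 0
            while vn < val - 1e-9 and tries < 5:
                tn = 0.5 * (t + tn)
                vn, gn, hn = self._fgh(tn, prodflat, ls_tot)
                tries += 1
            if vn < val - 1e-9:
                break  # keep best seen; surface too awkward for Newton here
            t, val, g, hh = tn, vn, gn, hn
            if val > best_v:
                best_t, best_v = t, val
            if abs(g) < 1e-8 * (1.0 + abs(val)):
                break
        if not np.isfinite(best_v):
            # fall back to bounded search on log t
            res = minimize_scalar(
                lambda z: -self._fgh(float(np.exp(z)), prodflat, ls_tot)[0],
                bounds=(np.log(s.min_branch), np.log(s.max_branch)),
                method="bounded", options={"xatol": 1e-3})
            best_t, best_v = float(np.exp(res.x)), -float(res.fun)
        return best_t, best_v

    def sweep(self):
        """One full preorder pass; returns the exact lnL after the pass."""
        from . import _kernels

        eng, tree = self.engine, self.tree
        npat, ns, C = eng.n_patterns, eng.n_states, self.C
        P = transition_matrices(self.eigs, tree.lengths, self.rates)
        lower = [None] * tree.n_nodes
        ls_low = [np.zeros(npat) for _ in range(tree.n_nodes)]
        D = [None] * tree.n_nodes
        if _kernels.HAVE_NUMBA:
            post, kptr, kidx = eng._tree_arrays(tree)
            clv, lsbuf = eng._clv_buffer(tree.n_nodes, C)
            mode = {"auto": 0, "always": 1, "never": 2}[eng.scaling]
            from .likelihood import _SCALE_THRESHOLD
            _kernels.prune_clvs(post, kptr, kidx, eng.n_tips, tree.root,
                                np.ascontiguousarray(P), eng.tip_partials,
                                clv, lsbuf, _SCALE_THRESHOLD, mode)
            for v in range(tree.n_nodes):
                if tree.children[v]:
                    lower[v] = clv[v]
                    ls_low[v] = lsbuf[v]
                else:
                    lower[v] = eng.tip_partials[v]
                if v != tree.root:
                    D[v] = np.matmul(P[v], lower[v])
        else:
            for v in tree.postorder():
                kids = tree.children[v]
                if kids:
                    prod = None
                    acc = np.zeros(npat)
                    for c in kids:
                        prod = D[c] if prod is None else prod * D[c]
                        acc += ls_low[c]
                    if v < eng.n_tips:
                        prod = prod * eng.tip_partials[v][None]
                    eng._maybe_scale(prod, acc)
                    lower[v] = prod
                    ls_low[v] = acc
                else:
                    lower[v] = np.broadcast_to(eng.tip_partials[v],
                                               (C, ns, npat))
                if v != tree.root:
                    D[v] = np.matmul(P[v], lower[v])
        last_val = None
        E_root = np.broadcast_to(self.pis[:, :, None], (C, ns, npat))
        if tree.root < eng.n_tips:
            E_root = E_root * eng.tip_partials[tree.root][None]
        stack = [(tree.root, np.ascontiguousarray(E_root), np.zeros(npat))]
        while stack:
            u, E_u, ls_up_u = stack.pop()
            kids = tree.children[u]
            for v in kids:
                A = E_u.copy()
                ls_up = ls_up_u.copy()
                for s_ in kids:
                    if s_ is not v:
                        A = A * D[s_]
                        ls_up = ls_up + ls_low[s_]
                eng._maybe_scale(A, ls_up)
                ls_tot = ls_up + ls_low[v]
                t_new, val = self._newton_edge(tree.lengths[v], A, lower[v],
                                               ls_tot)
                tree.lengths[v] = t_new
                P_v = self._P(t_new)
                D[v] = np.matmul(P_v, lower[v])
                last_val = val
                if tree.children[v]:
                    E_v = np.matmul(P_v.transpose(0, 2, 1), A)
                    ls_v = ls_up.copy()
                    eng._maybe_scale(E_v, ls_v)
                    stack.append((v, E_v, ls_v))
        return last_val


def _total_lnl(engine, tree, model, params):
    from .likelihood import ascertainment_correction

    lnl = engine.per_pattern_lnl(tree, model, params)
    data = lnl[:engine.n_data_patterns]
    if model.asc_bias:
        data = ascertainment_correction(data, lnl[engine.n_data_patterns:])
    return float(engine.weights[:engine.n_data_patterns] @ data)


def optimize_branch_lengths(tree, paln, model, params,
                            settings: OptimizerSettings | None = None,
                            engine: PruningEngine | None = None,
                            inplace: bool = False, max_passes=None):
    """Edge-wise Newton optimization of all branch lengths.

    Returns ``(tree, lnL)`` where ``tree`` is a modified copy (or the same
    object when ``inplace``)."""
    settings = settings or OptimizerSettings()
    if engine is None:
        engine = PruningEngine(paln, asc=model.asc_bias)
    if not inplace:
        tree = tree.copy()
    np.clip(tree.lengths, settings.min_branch, settings.max_branch,
            out=tree.lengths)
    lnl = _total_lnl(engine, tree, model, params)
    if not np.isfinite(lnl):
        raise OptimizationError("non-finite log-likelihood at start of "
                                "branch-length optimization")
    for _ in range(max_passes or settings.max_bl_passes):
        new = _EdgeOptimizer(engine, tree, model, params, settings).sweep()
        if new is None:
            break
        if new - lnl < settings.epsilon:
            lnl = max(lnl, new)
            break
        lnl = new
    # in-sweep caches go slightly stale as edges move, so the sweep's
    # running value is approximate; report the exact likelihood
    return tree, _total_lnl(engine, tree, model, params)


# ---------------------------------------------------------------------------
# Model parameter optimization

def _empirical_freqs(engine: PruningEngine):
    resolved = engine.tip_partials.sum(axis=1) == 1.0     # (tips, npat)
    counts = np.einsum("tsp,tp,p->s", engine.tip_partials, resolved,
                       engine.weights)
    counts = np.maximum(counts, 1e-4)
    return counts / counts.sum()


def initial_params(model: SubstitutionModel, engine: PruningEngine
                   ) -> ModelParams:
    """Standard warm starts for the coordinate descent."""
    params = ModelParams()
    if model.datatype == "DNA":
        params.exch = np.ones(model.n_exch_classes)
        params.freqs = (np.full(4, 0.25) if model.freq_mode == "equal"
                        else _empirical_freqs(engine))
    else:
        if model.freq_mode in ("empirical", "ml"):
            params.freqs = _empirical_freqs(engine)
    if model.has_gamma:
        params.alpha = 1.0
    if model.has_pinv:
        w = engine.weights[:engine.n_data_patterns]
        const_frac = float(
            w @ engine.const_comp[:, :engine.n_data_patterns].any(axis=0)
        ) / engine.n_sites
        params.p_inv = 0.5 * const_frac
    if model.rate_het == "R":
        k = (len(model.mixture) if model.mixture else model.n_free_rates)
        from .substmodels import discrete_gamma_rates
        params.rates, params.rate_weights = discrete_gamma_rates(1.0, k)
    return params


class _Fitter:
    def __init__(self, paln, model, base_tree, settings, engine=None,
                 warm=()):
        self.model = model
        self.settings = settings
        self.engine = engine or PruningEngine(paln, asc=model.asc_bias)
        if model.asc_bias and self.engine.strictly_constant.any():
            raise ValidationError(
                "constant columns present with ascertainment correction")
        self.paln = paln
        # candidate starting states: the cold start plus any warm starts
        # carried over from already-fitted related models.  Warm starts
        # that are exact continuations (a nested model's optimum embedded
        # in this model's parameter space) make the final likelihood
        # provably no worse than the nested model's.
        candidates = [(initial_params(model, self.engine), base_tree)]
        for prev_params, prev_tree in warm:
            candidates.append((self._adopted(prev_params), prev_tree))
        best = None
        for params, tr in candidates:
            tree = tr.copy()
            np.clip(tree.lengths, settings.min_branch, settings.max_branch,
                    out=tree.lengths)
            self.params, self.tree = params, tree
            lnl = self.eval()
            if best is None or (np.isfinite(lnl) and lnl > best[0]):
                best = (lnl, params, tree)
        self.start_lnl, self.params, self.tree = best

    def _adopted(self, prev: ModelParams) -> ModelParams:
        mine = initial_params(self.model, self.engine)
        if mine.exch is not None and prev.exch is not None \
                and len(prev.exch) == len(mine.exch):
            mine.exch = prev.exch.copy()
        if mine.freqs is not None and prev.freqs is not None:
            mine.freqs = prev.freqs.copy()
        if mine.alpha is not None and prev.alpha is not None:
            mine.alpha = prev.alpha
        if mine.p_inv is not None:
            # continuing from a model without +I starts exactly at its
            # optimum (p_inv = 0)
            mine.p_inv = (min(prev.p_inv, self._pinv_ub())
                          if prev.p_inv is not None else 0.0)
        if mine.rates is not None and prev.rates is not None \
                and len(prev.rates) == len(mine.rates):
            mine.rates = prev.rates.copy()
            mine.rate_weights = prev.rate_weights.copy()
        return mine

    def _pinv_ub(self):
        eng = self.engine
        w = eng.weights[:eng.n_data_patterns]
        frac = float(w @ eng.const_comp[:, :eng.n_data_patterns].any(axis=0)
                     ) / eng.n_sites
        return max(0.0, min(frac, 0.99))

    def eval(self):
        return _total_lnl(self.engine, self.tree, self.model, self.params)

    # -- coordinate steps --------------------------------------------------
    def _opt_exch(self, lnl):
        model, s = self.model, self.settings
        ref = int(model.scheme[5])
        lo, hi = np.log(s.exch_bounds[0]), np.log(s.exch_bounds[1])
        for c in range(model.n_exch_classes):
            if c == ref:
                continue

            def f(z, c=c):
                self.params.exch[c] = np.exp(z)
                return self.eval()

            z0 = np.log(self.params.exch[c])
            z, lnl = _maximize_scalar(f, z0, lo, hi,
                                      xtol=s.param_epsilon, f0=lnl)
            self.params.exch[c] = np.exp(z)
        return lnl

    def _opt_alpha(self, lnl):
        """Line search on log(alpha), profiling out p_inv when present.

        Jointly optimizing alpha and p_inv by alternating 1-D searches is
        notoriously slow along their shared ridge; instead every alpha
        trial maximizes p_inv on the cached site likelihoods (which needs
        no extra pruning pass), so the line search sees the profile
        likelihood and the ridge disappears.
        """
        s = self.settings
        lo, hi = np.log(s.alpha_bounds[0]), np.log(s.alpha_bounds[1])
        profile_pinv = self.model.has_pinv
        eng = self.engine
        w = eng.weights[:eng.n_data_patterns]
        ub = self._pinv_ub() if profile_pinv else 0.0
        chosen_pinv = {}

        def f(z):
            self.params.alpha = float(np.exp(z))
            if not profile_pinv:
                return self.eval()
            L_var, ls, logC = eng.components(self.tree, self.model,
                                             self.params)

            def g(p):
                tmp = replace_pinv(self.params, p)
                lnl_pat = combine_invariant(L_var, ls, logC, self.model, tmp)
                return float(w @ lnl_pat[:eng.n_data_patterns])

            p_star = 0.0
            if ub > 0:
                res = minimize_scalar(lambda p: -g(p), bounds=(0.0, ub),
                                      method="bounded",
                                      options={"xatol": 1e-4})
                if -res.fun > g(0.0):
                    p_star = float(res.x)
            chosen_pinv[z] = p_star
            return g(p_star)

        z, lnl = _maximize_scalar(f, np.log(self.params.alpha), lo, hi,
                                  xtol=s.param_epsilon,
                                  f0=None if profile_pinv else lnl)
        self.params.alpha = float(np.exp(z))
        if profile_pinv:
            self.params.p_inv = chosen_pinv.get(z, self.params.p_inv)
        return lnl

    def _profiled_pinv_value(self, ub):
        """Profile likelihood over p_inv on cached site likelihoods."""
        eng = self.engine
        w = eng.weights[:eng.n_data_patterns]
        L_var, ls, logC = eng.components(self.tree, self.model, self.params)

        def g(p):
            tmp = replace_pinv(self.params, p)
            lnl_pat = combine_invariant(L_var, ls, logC, self.model, tmp)
            return float(w @ lnl_pat[:eng.n_data_patterns])

        p_star = 0.0
        if ub > 0:
            res = minimize_scalar(lambda p: -g(p), bounds=(0.0, ub),
                                  method="bounded", options={"xatol": 1e-4})
            if -res.fun > g(0.0):
                p_star = float(res.x)
        return g(p_star), p_star

    def _opt_joint(self, lnl):
        """Joint quasi-Newton step over log-exchangeabilities and log-alpha.

        Exchangeability classes, the gamma shape and the branch lengths are
        strongly correlated, so one-parameter-at-a-time sweeps contract
        slowly; a joint L-BFGS-B search over the transformed coordinates
        (with p_inv profiled out on cached site likelihoods) converges in a
        handful of gradient steps instead.
        """
        from scipy.optimize import minimize

        model, s = self.model, self.settings
        ref = int(model.scheme[5])
        free_idx = [c for c in range(model.n_exch_classes) if c != ref]
        has_a = model.has_gamma
        profile_p = model.has_pinv
        ub = self._pinv_ub() if profile_p else 0.0
        state = {"p": self.params.p_inv}
        params0 = self.params.copy()

        def unpack(z):
            for i, c in enumerate(free_idx):
                self.params.exch[c] = float(np.exp(z[i]))
            if has_a:
                self.params.alpha = float(np.exp(z[-1]))

        def obj(z):
            unpack(z)
            if profile_p:
                val, p_star = self._profiled_pinv_value(ub)
                state["p"] = p_star
                return -val
            return -self.eval()

        x0 = [np.log(self.params.exch[c]) for c in free_idx]
        bounds = [tuple(np.log(s.exch_bounds))] * len(free_idx)
        if has_a:
            x0.append(np.log(self.params.alpha))
            bounds.append(tuple(np.log(s.alpha_bounds)))
        # stop once the per-iteration gain drops well below epsilon; the
        # outer rounds pick up anything the next branch-length pass exposes
        ftol = 0.05 * s.epsilon / max(1.0, abs(lnl))
        res = minimize(obj, np.array(x0), method="L-BFGS-B", bounds=bounds,
                       options={"maxfun": 250, "ftol": ftol, "gtol": 1e-4,
                                "eps": 1e-6})
        obj(res.x)  # restore the optimizer's best point (and its p_inv)
        if profile_p:
            self.params.p_inv = state["p"]
        new = self.eval()
        if new < lnl:
            self.params = params0
            return lnl
        return new

    def _opt_pinv(self, lnl):
        """Cheap 1-D search reusing cached variable-rate site likelihoods."""
        ub = self._pinv_ub()
        if ub <= 0:
            self.params.p_inv = 0.0
            return self.eval()
        eng = self.engine
        L_var, ls, logC = eng.components(self.tree, self.model, self.params)
        w = eng.weights[:eng.n_data_patterns]

        def g(p):
            tmp = replace_pinv(self.params, p)
            lnl_pat = combine_invariant(L_var, ls, logC, self.model, tmp)
            return float(w @ lnl_pat[:eng.n_data_patterns])

        res = minimize_scalar(lambda p: -g(p), bounds=(0.0, ub),
                              method="bounded", options={"xatol": 1e-4})
        p_star = float(res.x)
        if g(p_star) >= lnl:
            self.params.p_inv = p_star
            return g(p_star)
        return lnl

    def _opt_free_rates(self, lnl):
        s = self.settings
        k = len(self.params.rates)

        def renorm():
            from .substmodels import free_rate_categories
            self.params.rates, self.params.rate_weights = \
                free_rate_categories(self.params.rates,
                                     self.params.rate_weights)

        for c in range(k):
            def fr(z, c=c):
                self.params.rates[c] = np.exp(z)
                renorm()
                return self.eval()

            z0 = np.log(self.params.rates[c])
            z, lnl = _maximize_scalar(fr, z0, np.log(1e-4), np.log(100.0),
                                      xtol=s.param_epsilon, f0=None)
            self.params.rates[c] = np.exp(z)
            renorm()
        for c in range(k - 1):
            def fw(u, c=c):
                self.params.rate_weights[c] = 1.0 / (1.0 + np.exp(-u))
                renorm()
                return self.eval()

            w0 = self.params.rate_weights[c]
            u0 = np.log(w0 / (1 - w0))
            u, lnl = _maximize_scalar(fw, u0, -12.0, 12.0,
                                      xtol=s.param_epsilon, f0=None)
            self.params.rate_weights[c] = 1.0 / (1.0 + np.exp(-u))
            renorm()
        return self.eval()

    def _opt_ml_freqs(self, lnl):
        ns = self.engine.n_states

        def f(u):
            e = np.exp(u - u.max())
            self.params.freqs = e / e.sum()
            return -self.eval()

        from scipy.optimize import minimize
        u0 = np.log(np.maximum(self.params.freqs, 1e-8))
        res = minimize(f, u0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": self.settings.epsilon / 10,
                                "maxiter": 200 * ns})
        f(res.x)
        new = self.eval()
        return max(new, lnl)

    def _opt_branches(self, max_passes=None):
        self.tree, lnl = optimize_branch_lengths(
            self.tree, None, self.model, self.params,
            settings=self.settings, engine=self.engine, inplace=True,
            max_passes=max_passes)
        return lnl

    def run(self) -> ModelFit:
        model, s = self.model, self.settings
        lnl = self.start_lnl
        if not np.isfinite(lnl):
            # degenerate start; retry from scratch lengths
            self.tree.lengths[:] = 0.1
            lnl = self.eval()
        if not np.isfinite(lnl):
            raise OptimizationError(
                f"non-finite initial log-likelihood for {model.name}")
        best = (lnl, self.params.copy(), self.tree.copy())
        has_exch = (model.datatype == "DNA" and model.n_exch_classes > 1)
        lnl = self._opt_branches()
        if lnl > best[0]:
            best = (lnl, self.params.copy(), self.tree.copy())
        rejoint = True
        for rnd in range(s.max_rounds):
            start = lnl
            if has_exch and rejoint:
                lnl = self._opt_joint(lnl)
            elif model.has_gamma:
                lnl = self._opt_alpha(lnl)
            if model.has_pinv and not (has_exch and rejoint) \
                    and not model.has_gamma:
                lnl = self._opt_pinv(lnl)
            if model.freq_mode == "ml":
                lnl = self._opt_ml_freqs(lnl)
            if model.rate_het == "R":
                lnl = self._opt_free_rates(lnl)
            # interior rounds only smooth branches briefly; the stopping
            # round has already converged jointly
            lnl = self._opt_branches(max_passes=2)
            if lnl > best[0]:
                best = (lnl, self.params.copy(), self.tree.copy())
            if lnl - start < s.epsilon:
                break
            # exchangeabilities barely move once branch lengths settle, so
            # later rounds skip the joint step unless the round moved a lot
            rejoint = (lnl - start) > 20.0 * s.epsilon
        lnl, params, tree = best
        if not np.isfinite(lnl):
            raise OptimizationError(f"optimization failed for {model.name}")
        K = model.n_free_params(n_taxa=self.engine.n_tips,
                                include_branches=s.count_branch_params)
        return ModelFit(model=model, lnL=lnl, params=params, tree=tree,
                        K=K, n=self.engine.n_sites)


def replace_pinv(params: ModelParams, p: float) -> ModelParams:
    out = params.copy()
    out.p_inv = p
    return out


def optimize_model_params(tree, paln, model, settings=None, engine=None,
                          warm=()) -> ModelFit:
    """Coordinate-descent fit of one model (parameters + branch lengths).

    ``warm`` is an optional sequence of ``(params, tree)`` starting states
    from related, already-fitted models; the best start (including the
    standard cold start) is used.
    """
    settings = settings or OptimizerSettings()
    fitter = _Fitter(paln, model, tree, settings, engine=engine, warm=warm)
    return fitter.run()


# ---------------------------------------------------------------------------
# Fitting the whole candidate set

_HET_ORDER = {"none": 0, "I": 1, "G": 2, "I+G": 3, "R": 4}
_HET_PRED = {"I": "none", "G": "none", "I+G": "G", "R": "G"}


def _chain_key(m: SubstitutionModel):
    # all DNA schemes share one chain per frequency mode, so warm starts
    # can flow along the scheme-nesting lattice
    return (m.datatype, m.matrix, m.mixture, m.freq_mode, m.asc_bias,
            m.n_gamma_cats)


def _refines(child: str, parent: str) -> bool:
    """True if the child scheme's rate classes subdivide the parent's."""
    seen = {}
    for a, b in zip(child, parent):
        if a in seen:
            if seen[a] != b:
                return False
        else:
            seen[a] = b
    return True


def _expand_exch(parent_scheme, parent_exch, child_scheme):
    """Re-express a coarser scheme's class rates in a finer scheme.

    The mapping is an exact continuation: the implied 6-vector of
    exchangeabilities (and hence the likelihood) is unchanged.
    """
    from .substmodels import expand_scheme_rates

    full = expand_scheme_rates(parent_scheme, parent_exch)
    k = max(int(c) for c in child_scheme) + 1
    vals = np.ones(k)
    for slot, d in enumerate(child_scheme):
        vals[int(d)] = full[slot]
    return vals / vals[int(child_scheme[5])]


def _model_sort_key(m: SubstitutionModel):
    return (m.n_exch_classes, m.scheme or "", _HET_ORDER.get(m.rate_het, 9),
            m.n_free_rates)


def _het_key(m: SubstitutionModel):
    return (m.rate_het, m.n_free_rates if m.rate_het == "R" else 0)


def _fit_chain(args):
    paln, models, base_tree, settings = args
    results = []
    engine = PruningEngine(paln, asc=models[0].asc_bias)
    store = {}
    for model in sorted(models, key=_model_sort_key):
        warm = []
        sk = model.scheme if model.datatype == "DNA" else model.matrix
        hk = _het_key(model)
        if model.datatype == "DNA":
            parents = [s for (s, h) in store
                       if h == hk and s != sk and _refines(sk, s)]
            if parents:
                ps = max(parents, key=lambda s: (len(set(s)), s))
                prev = store[(ps, hk)]
                if prev.ok:
                    p = prev.params.copy()
                    p.exch = _expand_exch(ps, p.exch, sk)
                    warm.append((p, prev.tree))
        pred = _HET_PRED.get(model.rate_het)
        if pred is not None and (sk, (pred, 0)) in store:
            prev = store[(sk, (pred, 0))]
            if prev.ok:
                warm.append((prev.params, prev.tree))
        try:
            fit = optimize_model_params(base_tree, paln, model,
                                        settings=settings, engine=engine,
                                        warm=warm)
        except Exception as exc:  # collected, not fatal
            fit = ModelFit(model=model, lnL=np.nan, params=ModelParams(),
                           tree=base_tree.copy(),
                           K=model.n_free_params(
                               n_taxa=base_tree.n_tips,
                               include_branches=settings.count_branch_params),
                           n=paln.n_sites, ok=False, message=str(exc))
        store[(sk, hk)] = fit
        results.append(fit)
    return results


def fit_all_models(paln: PatternAlignment, models, base_tree: Tree,
                   settings: OptimizerSettings | None = None,
                   n_workers: int = 1):
    """Fit every candidate model on the common topology.

    Models are grouped into warm-start chains (same scheme/matrix and
    frequency handling, increasing rate-heterogeneity complexity) that are
    fitted sequentially; chains are independent, so results are identical
    for any worker count.  Output order matches input order.  Failed models
    are returned with ``ok=False`` and excluded from ranking by the caller.
    """
    if not models:
        raise ValidationError("empty model list")
    settings = settings or OptimizerSettings()
    chains = {}
    order = {}
    for idx, m in enumerate(models):
        chains.setdefault(_chain_key(m), []).append(m)
        order[m.name] = idx
    payloads = [(paln, chains[key], base_tree, settings) for key in chains]
    if n_workers > 1 and len(payloads) > 1:
        import multiprocessing as mp
        ctx = mp.get_context("fork" if "fork" in mp.get_all_start_methods()
                             else "spawn")
        with ctx.Pool(min(n_workers, len(payloads))) as pool:
            chunks = pool.map(_fit_chain, payloads)
    else:
        chunks = [_fit_chain(p) for p in payloads]
    fits = [None] * len(models)
    for chunk in chunks:
        for fit in chunk:
            fits[order[fit.model.name]] = fit
    for fit in fits:
        if fit is not None and not fit.ok:
            warnings.warn(f"model {fit.model.name} failed: {fit.message}")
    return fits
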