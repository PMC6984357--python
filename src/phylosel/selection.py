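"""Information-criterion ranking, model weights, importances and averages.

AIC = -2 lnL + 2K; AICc adds the small-sample correction 2K(K+1)/(n-K-1);
BIC = -2 lnL + K ln n.  The sample size n is the alignment length in sites.
The decision-theory (DT) criterion scores each model by its BIC-weighted
expected branch-length distance to the trees estimated under all other
models on the shared topology; lower is better.  Criterion weights use the
delta transform w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CRITERIA = ("BIC", "AIC", "AICc", "DT")
DEFAULT_CRITERION = "BIC"


def aic(lnL: float, K: int) -> float:
    return -2.0 * lnL + 2.0 * K


def aicc(lnL: float, K: int, n: int) -> float:
    if n <= 0:
        raise ValidationError("sample size must be positive")
    if n - K - 1 <= 0:
        warnings.warn(f"AICc undefined for K={K}, n={n}; scoring +inf")
        return np.inf
    return aic(lnL, K) + 2.0 * K * (K + 1.0) / (n - K - 1.0)


def bic(lnL: float, K: int, n: int) -> float:
    if n <= 0:
        raise ValidationError("sample size must be positive")
    return -2.0 * lnL + K * np.log(n)


def criterion_weights(scores) -> np.ndarray:
    """Akaike-style weights computed through deltas for stability."""
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValidationError("no finite criterion scores")
    deltas = scores - scores[finite].min()
    with np.errstate(over="ignore"):
        raw = np.where(finite, np.exp(-0.5 * deltas), 0.0)
    return raw / raw.sum()


def dt_scores(fits, n: int) -> np.ndarray:
    """Decision-theory risk per model (BIC-weighted tree-distance).

    All fits must carry branch-length-optimized trees on the same topology;
    the distance is Euclidean between branch-length vectors.
    """
    keys = {f.tree.topology_key() for f in fits}
    if len(keys) > 1:
        raise ValidationError("DT requires all models on a common topology")
    vecs = np.stack([f.tree.branch_vector() for f in fits])
    bics = np.array([bic(f.lnL, f.K, n) for f in fits])
    w = criterion_weights(bics)
    diff = vecs[:, None, :] - vecs[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return dist @ w


def importances_and_averages(fits, weights):
    """Parameter importances and model-averaged estimates.

    importance(theta) = sum of weights of the models that contain theta;
    the averaged estimate renormalizes over those models.
    """
    weights = np.asarray(weights, dtype=float)
    importances, averages = {}, {}

    def collect(name, present, value):
        mask = np.array(present)
        imp = float(weights[mask].sum())
        importances[name] = imp
        if imp > 0:
            vals = np.array([value(f) for f, m in zip(fits, mask) if m])
            ws = weights[mask] / imp
            averages[name] = float(ws @ vals)

    collect("p_inv", [f.model.has_pinv for f in fits],
            lambda f: f.params.p_inv)
    collect("alpha", [f.model.has_gamma for f in fits],
            lambda f: f.params.alpha)
    return importances, averages


@dataclass
class SelectionResult:
    table: pd.DataFrame                 # one row per model, per-criterion cols
    best: dict = field(default_factory=dict)         # criterion -> ModelFit
    rankings: dict = field(default_factory=dict)     # criterion -> [ModelFit]
    importances: dict = field(default_factory=dict)  # criterion -> {param: w}
    averages: dict = field(default_factory=dict)

    def best_model(self, criterion: str = DEFAULT_CRITERION):
        return self.best[criterion]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False,
                          float_format="%.6f", lineterminator="\n")


def select(fits, criteria=CRITERIA, n: int | None = None) -> SelectionResult:
    """Rank fitted models under the requested criteria."""
    usable = [f for f in fits if f.ok and np.isfinite(f.lnL)]
    dropped = [f for f in fits if not (f.ok and np.isfinite(f.lnL))]
    for f in dropped:
        warnings.warn(f"excluding failed model {f.model.name} from ranking")
    if not usable:
        raise ValidationError("no successfully fitted models to rank")
    if n is None:
        n = usable[0].n
    rows = {
        "model": [f.model.name for f in usable],
        "lnL": [f.lnL for f in usable],
        "K": [f.K for f in usable],
    }
    scores = {}
    for crit in criteria:
        if crit == "AIC":
            sc = np.array([aic(f.lnL, f.K) for f in usable])
        elif crit == "AICc":
            sc = np.array([aicc(f.lnL, f.K, n) for f in usable])
        elif crit == "BIC":
            sc = np.array([bic(f.lnL, f.K, n) for f in usable])
        elif crit == "DT":
            sc = dt_scores(usable, n)
        else:
            raise ValidationError(f"unknown criterion {crit!r}")
        scores[crit] = sc

    result = SelectionResult(table=None)
    for crit in criteria:
        sc = scores[crit]
        finite_min = sc[np.isfinite(sc)].min()
        delta = sc - finite_min
        rows[f"{crit}"] = sc
        rows[f"{crit}_delta"] = delta
        order = sorted(
            range(len(usable)),
            key=lambda i: (sc[i], usable[i].K, usable[i].model.name))
        ranking = [usable[i] for i in order]
        result.rankings[crit] = ranking
        result.best[crit] = ranking[0]
        if crit != "DT":
            w = criterion_weights(sc)
            rows[f"{crit}_weight"] = w
            imp, avg = importances_and_averages(usable, w)
            result.importances[crit] = imp
            result.averages[crit] = avg
    result.table = pd.DataFrame(rows)
    return result
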