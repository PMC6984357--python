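import numpy as np
import pytest

import phylosel as ps
from phylosel.errors import ValidationError
from phylosel.likelihood import ModelParams
from phylosel.optimize import ModelFit
from phylosel.selection import (aic, aicc, bic, criterion_weights, dt_scores,
                                importances_and_averages, select)


def test_information_criterion_formulas():
    assert aic(-100, 5) == pytest.approx(210.0, abs=1e-9)
    assert bic(-100, 5, 1000) == pytest.approx(200 + 5 * np.log(1000),
                                               abs=1e-9)
    assert aicc(-100, 5, 1000) == pytest.approx(210 + 60 / 994, abs=1e-9)


def test_aicc_small_sample_guard():
    with pytest.warns(UserWarning):
        assert aicc(-100, 10, 11) == np.inf


def test_criterion_weights():
    assert criterion_weights([123.4]).tolist() == [1.0]
    assert np.allclose(criterion_weights([7.0, 7.0]), [0.5, 0.5])
    w = criterion_weights([0.0, 2.0])
    assert np.allclose(w, [0.7310585786, 0.2689414214], atol=1e-9)
    with pytest.raises(ValidationError):
        criterion_weights([np.inf, np.inf])


def test_weight_invariance_under_lnl_shift():
    scores = np.array([100.0, 102.0, 110.0])
    assert np.allclose(criterion_weights(scores),
                       criterion_weights(scores + 1234.5))


def _fake_fits(rng, n_models=5, n_taxa=6):
    base = ps.simulate_tree(n_taxa, rng=rng)
    fits = []
    for i in range(n_models):
        tree = base.copy()
        tree.lengths[tree.lengths > 0] += rng.normal(0, 0.02,
                                                     (tree.lengths > 0).sum())
        np.clip(tree.lengths, 1e-8, None, out=tree.lengths)
        model = ps.make_dna_model("012345", "empirical",
                                  ["none", "I", "G", "I+G"][i % 4])
        if i == 4:
            model = ps.make_dna_model("000000", "equal", "none")
        params = ModelParams(
            exch=np.ones(model.n_exch_classes),
            freqs=np.full(4, 0.25),
            alpha=0.5 if model.has_gamma else None,
            p_inv=0.1 if model.has_pinv else None)
        fits.append(ModelFit(model=model, lnL=float(-1000 - 5 * i),
                             params=params, tree=tree,
                             K=model.n_free_params(n_taxa=n_taxa), n=500))
    return fits


def test_dt_identical_trees_score_zero(rng):
    fits = _fake_fits(rng)
    common = fits[0].tree
    for f in fits:
        f.tree = common.copy()
    assert np.allclose(dt_scores(fits, n=500), 0.0)


def test_dt_two_model_hand_computation(rng):
    fits = _fake_fits(rng, n_models=2)
    # equal BIC weights: same lnL and K
    fits[1].lnL = fits[0].lnL
    fits[1].K = fits[0].K
    t0 = fits[0].tree
    t1 = t0.copy()
    edge = t1.edges()[0]
    delta = 0.3
    t1.lengths[edge] += delta
    fits[1].tree = t1
    fits[0].tree = t0
    scores = dt_scores(fits, n=500)
    assert np.allclose(scores, delta / 2, atol=1e-12)


def test_dt_matches_double_loop_oracle(rng):
    fits = _fake_fits(rng)
    n = 500
    vecs = [f.tree.branch_vector() for f in fits]
    bics = [bic(f.lnL, f.K, n) for f in fits]
    w = criterion_weights(bics)
    oracle = []
    for i in range(len(fits)):
        acc = 0.0
        for j in range(len(fits)):
            acc += w[j] * np.sqrt(((vecs[i] - vecs[j]) ** 2).sum())
        oracle.append(acc)
    assert np.allclose(dt_scores(fits, n), oracle, atol=1e-12)
    # order invariance
    perm = [3, 1, 4, 0, 2]
    permuted = dt_scores([fits[i] for i in perm], n)
    assert np.allclose(permuted, np.array(oracle)[perm], atol=1e-12)


def test_dt_rejects_mismatched_topologies(rng):
    fits = _fake_fits(rng)
    fits[1].tree = ps.simulate_tree(6, rng=np.random.default_rng(99))
    fits[1].tree.labels = fits[0].tree.labels
    with pytest.raises(ValidationError):
        dt_scores(fits, n=500)


def test_importances_and_averages_hand_computation(rng):
    fits = _fake_fits(rng, n_models=3)
    weights = np.array([0.5, 0.3, 0.2])
    imp, avg = importances_and_averages(fits, weights)
    has_a = [f.model.has_gamma for f in fits]
    assert imp["alpha"] == pytest.approx(
        sum(w for w, h in zip(weights, has_a) if h))
    if imp["alpha"] > 0:
        assert avg["alpha"] == pytest.approx(0.5)  # all alphas equal 0.5
    has_i = [f.model.has_pinv for f in fits]
    assert imp["p_inv"] == pytest.approx(
        sum(w for w, h in zip(weights, has_i) if h))


def test_penalty_prefers_smaller_k_at_equal_lnl(rng):
    fits = _fake_fits(rng, n_models=2)
    fits[0].lnL = fits[1].lnL = -1000.0
    # model 0 is GTR-class (K larger), model 1 forced to fewer params
    fits[1].K = fits[0].K - 3
    for crit in ("AIC", "AICc", "BIC"):
        res = select(fits, criteria=(crit,), n=500)
        assert res.best[crit] is fits[1]


def test_select_integration_and_tsv(rng, tmp_path):
    fits = _fake_fits(rng)
    res = select(fits, n=500)
    assert set(res.best) == {"BIC", "AIC", "AICc", "DT"}
    for crit in ("AIC", "AICc", "BIC"):
        w = res.table[f"{crit}_weight"].to_numpy()
        assert w.sum() == pytest.approx(1.0)
        assert (res.table[f"{crit}_delta"] >= 0).all()
        assert res.table[f"{crit}_delta"].min() == 0.0
    out = tmp_path / "res.tsv"
    res.to_tsv(out)
    text = out.read_text()
    assert text.startswith("model\t")
    res.to_tsv(tmp_path / "res2.tsv")
    assert (tmp_path / "res2.tsv").read_bytes() == out.read_bytes()


def test_select_drops_failed_fits(rng):
    fits = _fake_fits(rng)
    fits[0].ok = False
    fits[0].lnL = np.nan
    with pytest.warns(UserWarning):
        res = select(fits, criteria=("BIC",), n=500)
    assert len(res.rankings["BIC"]) == len(fits) - 1
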