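import numpy as np
import pytest

import phylosel as ps
from phylosel.errors import ValidationError
from phylosel.msa import Alignment, compress_patterns
from phylosel.optimize import (OptimizerSettings, fit_all_models,
                               optimize_branch_lengths,
                               optimize_model_params)
from phylosel.tree import Tree


def _two_taxon(seqs):
    aln = Alignment.from_sequences(["a", "b"], seqs, "DNA")
    tree = Tree(["a", "b"], np.array([-1, 0]), [[1], []],
                np.array([0.0, 0.1]), 0)
    return compress_patterns(aln), tree


JC = ps.make_dna_model("000000")
JC_PARAMS = ps.ModelParams(exch=np.ones(1), freqs=np.full(4, 0.25))


def test_two_taxon_jc_ml_distance():
    paln, tree = _two_taxon(["A" * 90 + "C" * 10, "A" * 100])
    opt, lnl = optimize_branch_lengths(tree, paln, JC, JC_PARAMS)
    expected = -0.75 * np.log(1 - 4 / 3 * 0.1)
    assert opt.lengths[1] == pytest.approx(expected, abs=1e-6)


def test_zero_divergence_drives_branches_to_minimum(rng):
    tree = ps.simulate_tree(5, rng=rng)
    aln = ps.simulate_alignment(tree.copy(), JC, JC_PARAMS, 100,
                                rng=np.random.default_rng(0))
    # make it perfectly invariant
    aln.matrix[:] = "A"
    opt, _ = optimize_branch_lengths(tree, compress_patterns(aln), JC,
                                     JC_PARAMS)
    assert (opt.branch_vector() <= 1e-6).all()


def test_branch_optimization_is_a_fixpoint(gtrg_fixture):
    f = gtrg_fixture
    opt, lnl1 = optimize_branch_lengths(f["base"], f["paln"], f["model"],
                                        f["params"])
    opt2, lnl2 = optimize_branch_lengths(opt, f["paln"], f["model"],
                                         f["params"])
    assert lnl2 - lnl1 < OptimizerSettings().epsilon
    assert lnl2 >= lnl1 - 1e-9


def test_optimization_never_worsens(gtrg_fixture):
    f = gtrg_fixture
    start = ps.total_loglik(f["base"], f["paln"], f["model"], f["params"]).lnL
    fit = optimize_model_params(f["base"], f["paln"], f["model"])
    assert fit.lnL >= start
    assert fit.n == f["paln"].n_sites
    assert fit.K == f["model"].n_free_params(n_taxa=12)


def test_thoroughness_is_monotone(gtrg_fixture):
    f = gtrg_fixture
    lnls = []
    for eps in (1.0, 0.01, 0.001):
        fit = optimize_model_params(
            f["base"], f["paln"], f["model"],
            settings=OptimizerSettings(epsilon=eps))
        lnls.append(fit.lnL)
    assert lnls[0] <= lnls[1] + 1e-6 <= lnls[2] + 2e-6


def test_jc_needs_single_branch_pass_only(gtrg_fixture):
    fit = optimize_model_params(gtrg_fixture["base"], gtrg_fixture["paln"],
                                JC)
    assert fit.params.alpha is None and fit.params.p_inv is None
    assert np.isfinite(fit.lnL)


def test_nesting_monotonicity_through_optimizer(gtrg_fixture):
    f = gtrg_fixture
    names = ["JC", "HKY", "GTR", "GTR+G", "GTR+I+G"]
    models = [ps.make_dna_model(s, fm, h) for s, fm, h in
              [("000000", "equal", "none"), ("010010", "empirical", "none"),
               ("012345", "empirical", "none"),
               ("012345", "empirical", "G"),
               ("012345", "empirical", "I+G")]]
    fits = fit_all_models(f["paln"], models, f["base"])
    lnl = {fit.model.name: fit.lnL for fit in fits}
    assert lnl["JC"] <= lnl["HKY"] + 1e-4
    assert lnl["HKY"] <= lnl["GTR"] + 1e-4
    assert lnl["GTR"] <= lnl["GTR+G"] + 1e-4
    assert lnl["GTR+G"] <= lnl["GTR+I+G"] + 1e-4


def test_fit_all_is_deterministic_across_workers(gtrg_fixture):
    f = gtrg_fixture
    models = ps.generate_candidate_set("DNA", schemes=3)
    seq = fit_all_models(f["paln"], models, f["base"], n_workers=1)
    par = fit_all_models(f["paln"], models, f["base"], n_workers=4)
    assert [x.model.name for x in seq] == [x.model.name for x in par]
    for a, b in zip(seq, par):
        assert a.lnL == b.lnL
        assert np.array_equal(a.tree.branch_vector(), b.tree.branch_vector())


def test_fit_all_rejects_empty_model_list(gtrg_fixture):
    with pytest.raises(ValidationError):
        fit_all_models(gtrg_fixture["paln"], [], gtrg_fixture["base"])


def test_parameter_recovery_gtr_gamma(gtrg_fixture):
    """Fitting the generating model recovers alpha and exchangeabilities."""
    f = gtrg_fixture
    fit = optimize_model_params(f["base"], f["paln"], f["model"])
    assert fit.params.alpha == pytest.approx(f["params"].alpha, rel=0.5)
    est = fit.params.exch / fit.params.exch[-1]
    true = f["params"].exch / f["params"].exch[-1]
    assert np.median(np.abs(est - true) / true) < 0.5


def test_free_rate_fit_runs(rng):
    model = ps.make_dna_model("010010", "equal", "R", n_free_rates=3)
    params = ps.ModelParams(
        exch=np.array([1.0, 2.0]), freqs=np.full(4, 0.25),
        rates=np.array([0.2, 1.0, 2.5]),
        rate_weights=np.array([0.3, 0.4, 0.3]))
    from phylosel.substmodels import free_rate_categories
    params.rates, params.rate_weights = free_rate_categories(
        params.rates, params.rate_weights)
    tree = ps.simulate_tree(8, rng=rng)
    aln = ps.simulate_alignment(tree, model, params, 400, rng=rng)
    paln = compress_patterns(aln)
    base = ps.nj_topology(ps.jc_distance_matrix(aln), aln.taxon_labels)
    fit = optimize_model_params(base, paln, model)
    assert np.isfinite(fit.lnL)
    assert (fit.params.rates * fit.params.rate_weights).sum() == \
        pytest.approx(1.0)
    assert fit.K == model.n_free_params(n_taxa=8)
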