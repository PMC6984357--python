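import numpy as np
import pytest

import phylosel as ps
from oracles import brute_force_site_lnls, constant_pattern_prob
from phylosel.errors import OptimizationError, ValidationError
from phylosel.likelihood import PruningEngine
from phylosel.msa import Alignment, compress_patterns
from phylosel.tree import Tree


def _random_dna_setup(rng, n_taxa=None, n_sites=30, het=None):
    n_taxa = n_taxa or int(rng.integers(3, 6))
    scheme = ["000000", "010010", "012345"][int(rng.integers(3))]
    het = het or ["none", "G", "I", "I+G"][int(rng.integers(4))]
    model = ps.make_dna_model(scheme, "empirical", het)
    params = ps.ModelParams(
        exch=np.exp(rng.normal(0, 0.5, model.n_exch_classes)),
        freqs=rng.dirichlet(np.full(4, 5.0)),
        alpha=float(rng.uniform(0.3, 2)) if model.has_gamma else None,
        p_inv=float(rng.uniform(0, 0.5)) if model.has_pinv else None)
    tree = ps.simulate_tree(n_taxa, rng=rng)
    aln = ps.simulate_alignment(tree, model, params, n_sites, rng=rng)
    return tree, compress_patterns(aln), model, params


def test_pruning_matches_brute_force_enumeration(rng):
    """Felsenstein pruning == explicit sum over internal-node states."""
    for _ in range(25):
        tree, paln, model, params = _random_dna_setup(rng)
        eng = PruningEngine(paln)
        mine = eng.per_pattern_lnl(tree, model, params)[:eng.n_data_patterns]
        oracle = brute_force_site_lnls(tree, paln, model, params)
        assert np.abs(mine - oracle).max() < 1e-8


def test_pruning_matches_brute_force_amino_acids(rng):
    model = ps.make_aa_model("LG", "model", "G")
    params = ps.ModelParams(alpha=0.8)
    tree = ps.simulate_tree(4, rng=rng)
    aln = ps.simulate_alignment(tree, model, params, 15, rng=rng)
    paln = compress_patterns(aln)
    eng = PruningEngine(paln)
    mine = eng.per_pattern_lnl(tree, model, params)[:eng.n_data_patterns]
    oracle = brute_force_site_lnls(tree, paln, model, params)
    assert np.abs(mine - oracle).max() < 1e-8


def test_single_constant_site_zero_branches():
    aln = Alignment.from_sequences(["a", "b", "c"], ["A", "A", "A"], "DNA")
    tree = ps.simulate_tree(3, rng=np.random.default_rng(0))
    tree.lengths[:] = 0.0
    model = ps.make_dna_model("000000")
    params = ps.ModelParams(exch=np.ones(1), freqs=np.full(4, 0.25))
    res = ps.total_loglik(tree, compress_patterns(aln), model, params)
    assert res.lnL == pytest.approx(np.log(0.25), abs=1e-12)


def test_rooting_invariance(rng):
    tree, paln, model, params = _random_dna_setup(rng, n_taxa=8, n_sites=100)
    vals = [ps.total_loglik(tree.with_root(r), paln, model, params).lnL
            for r in range(tree.n_tips, tree.n_nodes)]
    assert max(vals) - min(vals) < 1e-10


def test_taxon_order_invariance(rng):
    tree, paln, model, params = _random_dna_setup(rng, n_taxa=6, n_sites=80)
    lnl0 = ps.total_loglik(tree, paln, model, params).lnL
    perm = rng.permutation(tree.n_tips)
    # rebuild with permuted labels/rows: likelihood must not change
    aln = Alignment([paln.taxon_labels[i] for i in perm],
                    paln.expand()[perm], paln.datatype)
    paln2 = compress_patterns(aln)
    tree2 = Tree.from_newick(tree.to_newick(), labels=aln.taxon_labels)
    lnl1 = ps.total_loglik(tree2, paln2, model, params).lnL
    assert lnl1 == pytest.approx(lnl0, abs=1e-8)


def test_duplicated_columns_double_the_likelihood(rng):
    tree, paln, model, params = _random_dna_setup(rng, n_taxa=5, n_sites=40)
    aln = Alignment(paln.taxon_labels, paln.expand(), "DNA")
    doubled = Alignment(paln.taxon_labels,
                        np.concatenate([aln.matrix, aln.matrix], axis=1),
                        "DNA")
    l1 = ps.total_loglik(tree, compress_patterns(aln), model, params).lnL
    l2 = ps.total_loglik(tree, compress_patterns(doubled), model, params).lnL
    assert l2 == pytest.approx(2 * l1, abs=1e-9)


def test_concatenation_additivity(rng):
    tree, paln, model, params = _random_dna_setup(rng, n_taxa=5, n_sites=60)
    mat = paln.expand()
    a = Alignment(paln.taxon_labels, mat[:, :30], "DNA")
    b = Alignment(paln.taxon_labels, mat[:, 30:], "DNA")
    whole = Alignment(paln.taxon_labels, mat, "DNA")
    la = ps.total_loglik(tree, compress_patterns(a), model, params).lnL
    lb = ps.total_loglik(tree, compress_patterns(b), model, params).lnL
    lw = ps.total_loglik(tree, compress_patterns(whole), model, params).lnL
    assert lw == pytest.approx(la + lb, abs=1e-8)


def test_compression_invariance(rng):
    """Pattern-compressed likelihood equals the per-site computation."""
    tree, paln, model, params = _random_dna_setup(rng, n_taxa=4, n_sites=50)
    mat = paln.expand()
    from phylosel.msa import PatternAlignment

    uncompressed = PatternAlignment(paln.taxon_labels, mat,
                                    np.ones(mat.shape[1], dtype=np.int64),
                                    "DNA", mat.shape[1])
    l1 = ps.total_loglik(tree, paln, model, params).lnL
    l2 = ps.total_loglik(tree, uncompressed, model, params).lnL
    assert l2 == pytest.approx(l1, abs=1e-9)


def test_degenerate_heterogeneity_equals_base(rng):
    tree, paln, _, _ = _random_dna_setup(rng, n_taxa=6, n_sites=80,
                                         het="none")
    base = ps.make_dna_model("010010", "empirical")
    params = ps.ModelParams(exch=np.array([1.0, 3.0]),
                            freqs=np.array([0.3, 0.2, 0.3, 0.2]))
    l0 = ps.total_loglik(tree, paln, base, params).lnL
    g1 = ps.SubstitutionModel(name="x", datatype="DNA", scheme="010010",
                              freq_mode="empirical", rate_het="G",
                              n_gamma_cats=1)
    p1 = params.copy(); p1.alpha = 0.5
    assert ps.total_loglik(tree, paln, g1, p1).lnL == pytest.approx(l0)
    iv = ps.make_dna_model("010010", "empirical", "I")
    p2 = params.copy(); p2.p_inv = 0.0
    assert ps.total_loglik(tree, paln, iv, p2).lnL == pytest.approx(l0)
    fr = ps.make_dna_model("010010", "empirical", "R", n_free_rates=3)
    p3 = params.copy()
    p3.rates = np.ones(3); p3.rate_weights = np.full(3, 1 / 3)
    assert ps.total_loglik(tree, paln, fr, p3).lnL == pytest.approx(l0)


def test_scaling_matches_unscaled_and_protects_large_trees(rng):
    tree, paln, model, params = _random_dna_setup(rng, n_taxa=5, n_sites=60)
    e_always = PruningEngine(paln, scaling="always")
    e_never = PruningEngine(paln, scaling="never")
    a = e_always.per_pattern_lnl(tree, model, params)
    b = e_never.per_pattern_lnl(tree, model, params)
    assert np.abs(a - b).max() < 1e-10
    # 60 taxa with short branches underflows without scaling
    big = ps.simulate_tree(60, bl_mean=0.02, rng=rng)
    m = ps.make_dna_model("000000")
    p = ps.ModelParams(exch=np.ones(1), freqs=np.full(4, 0.25))
    aln = ps.simulate_alignment(big, m, p, 100, rng=rng)
    res = ps.total_loglik(big, compress_patterns(aln), m, p)
    assert np.isfinite(res.lnL)


# ---------------------------------------------------------------------------
# ascertainment bias correction

def _variable_sites_alignment(rng, tree, model, params, n=60):
    aln = ps.simulate_alignment(tree, model, params, 3 * n, rng=rng)
    keep = [j for j in range(aln.n_sites)
            if len(set(aln.matrix[:, j])) > 1][:n]
    return Alignment(aln.taxon_labels, aln.matrix[:, keep], "DNA")


def test_ascertainment_correction_matches_enumeration(rng):
    tree = ps.simulate_tree(4, rng=rng)
    gen = ps.make_dna_model("010010", "empirical")
    params = ps.ModelParams(exch=np.array([1.0, 3.0]),
                            freqs=np.array([0.3, 0.2, 0.25, 0.25]))
    aln = _variable_sites_alignment(rng, tree, gen, params)
    paln = compress_patterns(aln)
    asc = ps.make_dna_model("010010", "empirical", asc_bias=True)
    corrected = ps.total_loglik(tree, paln, asc, params).lnL
    plain = ps.total_loglik(tree, paln, gen, params).lnL
    p_const = constant_pattern_prob(tree, aln.taxon_labels, gen, params)
    assert corrected == pytest.approx(
        plain - aln.n_sites * np.log1p(-p_const), abs=1e-8)
    # longer branches shrink P(constant) toward its stationary floor,
    # so the correction shrinks relative to a short-branch tree
    far = tree.copy(); far.lengths[far.lengths > 0] = 30.0
    near = tree.copy(); near.lengths[near.lengths > 0] = 0.01
    gap_far = abs(ps.total_loglik(far, paln, asc, params).lnL
                  - ps.total_loglik(far, paln, gen, params).lnL)
    gap_near = abs(ps.total_loglik(near, paln, asc, params).lnL
                   - ps.total_loglik(near, paln, gen, params).lnL)
    assert gap_far < 0.05 * gap_near
    p_far = constant_pattern_prob(far, aln.taxon_labels, gen, params)
    assert gap_far == pytest.approx(-aln.n_sites * np.log1p(-p_far),
                                    abs=1e-8)


def test_ascertainment_rejects_constant_columns(rng):
    tree = ps.simulate_tree(4, rng=rng)
    aln = Alignment.from_sequences(["t1", "t2", "t3", "t4"],
                                   ["AAAC", "AAAG", "AAAT", "AAAa".upper()],
                                   "DNA")
    asc = ps.make_dna_model("000000", asc_bias=True)
    params = ps.ModelParams(exch=np.ones(1), freqs=np.full(4, 0.25))
    with pytest.raises(ValidationError):
        ps.total_loglik(tree, compress_patterns(aln), asc, params)


def test_ascertainment_diverges_at_zero_branches(rng):
    tree = ps.simulate_tree(4, rng=rng)
    gen = ps.make_dna_model("000000")
    params = ps.ModelParams(exch=np.ones(1), freqs=np.full(4, 0.25))
    aln = _variable_sites_alignment(rng, tree, gen, params, n=20)
    tree.lengths[:] = 0.0  # P(constant) == 1 exactly
    asc = ps.make_dna_model("000000", asc_bias=True)
    with pytest.raises(OptimizationError):
        ps.total_loglik(tree, compress_patterns(aln), asc, params)
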