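import numpy as np
import pytest
from scipy.linalg import expm

import phylosel as ps
from oracles import gamma_category_means
from phylosel.errors import ConfigError, DomainError
from phylosel.substmodels import (AA_MATRICES, all_dna_schemes,
                                  build_rate_matrix, discrete_gamma_rates,
                                  eigen_decompose, expand_scheme_rates,
                                  free_rate_categories,
                                  generate_candidate_set,
                                  load_empirical_matrix,
                                  transition_probabilities)


# ---------------------------------------------------------------------------
# candidate sets

def test_default_dna_set_has_88_models():
    models = generate_candidate_set("DNA")
    assert len(models) == 88
    assert len({m.name for m in models}) == 88


def test_three_scheme_equal_plain_set():
    models = generate_candidate_set("DNA", schemes=3, het=("none",),
                                    freqs=("equal",))
    assert [m.name for m in models] == ["JC", "K80", "SYM"]


def test_full_aa_set_size():
    models = generate_candidate_set("AA")
    assert len(models) == len(AA_MATRICES) * 4 * 2


def test_all_203_schemes():
    codes = all_dna_schemes()
    assert len(codes) == 203
    for named in ("000000", "010010", "012345", "012210"):
        assert named in codes


def test_asc_bias_rejects_invariant_models():
    with pytest.raises(ConfigError):
        generate_candidate_set("DNA", asc_bias=True)
    ok = generate_candidate_set("DNA", het=("none", "G"), asc_bias=True)
    assert all(m.asc_bias and not m.has_pinv for m in ok)


def test_parameter_counts_against_independent_recount():
    n_taxa = 10
    for m in (generate_candidate_set("DNA")
              + generate_candidate_set("AA")
              + generate_candidate_set("DNA", het=("R",), n_free_rates=4)):
        expected = 2 * n_taxa - 3
        if m.datatype == "DNA":
            expected += len(set(m.scheme)) - 1
            if m.freq_mode != "equal":
                expected += 3
        else:
            if m.freq_mode in ("empirical", "ml"):
                expected += 19
        expected += {"none": 0, "I": 1, "G": 1, "I+G": 2,
                     "R": 2 * m.n_free_rates - 2}[m.rate_het]
        assert m.n_free_params(n_taxa=n_taxa) == expected, m.name


# ---------------------------------------------------------------------------
# rate matrices

def test_jc_rate_matrix_closed_form():
    rm = build_rate_matrix(np.ones(6), np.full(4, 0.25))
    off = rm.Q[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 1 / 3)
    assert np.allclose(np.diag(rm.Q), -1.0)


def test_rate_matrix_invariants(rng):
    for _ in range(10):
        ex = np.exp(rng.normal(0, 1, 6))
        pi = rng.dirichlet(np.full(4, 5.0))
        rm = build_rate_matrix(ex, pi)
        assert np.allclose(rm.Q.sum(axis=1), 0, atol=1e-12)
        # detailed balance
        F = rm.pi[:, None] * rm.Q
        assert np.allclose(F, F.T, atol=1e-12)
        assert -np.sum(rm.pi * np.diag(rm.Q)) == pytest.approx(1.0)


def test_empirical_matrix_normalization():
    S, freqs = load_empirical_matrix("LG")
    rm = build_rate_matrix(S, freqs)
    assert -np.sum(rm.pi * np.diag(rm.Q)) == pytest.approx(1.0)
    assert freqs.sum() == pytest.approx(1.0)


def test_all_vendored_matrices_load():
    for name in AA_MATRICES:
        S, freqs = load_empirical_matrix(name)
        assert S.shape == (20, 20) and np.allclose(S, S.T)
        assert (S >= 0).all() and freqs.min() > 0


def test_build_rate_matrix_rejects_bad_input():
    with pytest.raises(DomainError):
        build_rate_matrix(np.zeros(6), np.full(4, 0.25))
    with pytest.raises(DomainError):
        build_rate_matrix(np.ones(6), np.array([0.5, 0.5, 0.0, 0.0]))


# ---------------------------------------------------------------------------
# transition probabilities

def test_transition_probabilities_jc_analytic():
    rm = build_rate_matrix(np.ones(6), np.full(4, 0.25))
    eig = eigen_decompose(rm)
    for t in (0.01, 0.1, 1.0):
        P = transition_probabilities(eig, t)
        pii = 0.25 + 0.75 * np.exp(-4 * t / 3)
        assert np.allclose(np.diag(P), pii, atol=1e-10)
        assert np.allclose(P[0, 1], (1 - pii) / 3, atol=1e-10)


def test_transition_probabilities_limits(rng):
    ex = np.exp(rng.normal(0, 1, 6))
    pi = rng.dirichlet(np.full(4, 5.0))
    eig = eigen_decompose(build_rate_matrix(ex, pi))
    assert np.allclose(transition_probabilities(eig, 0.0), np.eye(4),
                       atol=1e-12)
    assert np.allclose(transition_probabilities(eig, 100.0),
                       np.tile(pi, (4, 1)), atol=1e-8)
    with pytest.raises(DomainError):
        transition_probabilities(eig, -0.1)


def test_eigen_route_matches_matrix_exponential(rng):
    for _ in range(10):
        ex = np.exp(rng.normal(0, 1, 6))
        pi = rng.dirichlet(np.full(4, 5.0))
        rm = build_rate_matrix(ex, pi)
        eig = eigen_decompose(rm)
        assert np.allclose(eig.reconstruct(), rm.Q, atol=1e-10)
        for t in (0.05, 0.7):
            assert np.allclose(transition_probabilities(eig, t),
                               expm(rm.Q * t), atol=1e-8)


def test_scheme_expansion():
    full = expand_scheme_rates("010010", np.array([1.0, 4.0]))
    assert full.tolist() == [1, 4, 1, 1, 4, 1]
    with pytest.raises(DomainError):
        expand_scheme_rates("010010", np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# rate heterogeneity

def test_discrete_gamma_single_category():
    r, w = discrete_gamma_rates(0.7, 1)
    assert r.tolist() == [1.0] and w.tolist() == [1.0]


def test_discrete_gamma_large_alpha_collapses():
    r, _ = discrete_gamma_rates(10000.0, 4)
    assert np.allclose(r, 1.0, atol=0.05)


@pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.0])
def test_discrete_gamma_matches_quadrature(alpha):
    r, w = discrete_gamma_rates(alpha, 4)
    oracle = gamma_category_means(alpha, 4)
    oracle /= oracle.mean()
    assert np.allclose(r, oracle, atol=1e-8)
    assert np.all(np.diff(r) > 0)
    assert (r * w).sum() == pytest.approx(1.0)
    with pytest.raises(DomainError):
        discrete_gamma_rates(-1.0, 4)


def test_free_rate_normalization():
    r, w = free_rate_categories([1.0, 1.0], [0.5, 0.5])
    assert np.allclose(r, 1) and np.allclose(w, 0.5)
    r, w = free_rate_categories([1.0, 3.0], [0.75, 0.25])
    assert np.allclose(r, [2 / 3, 2.0])
    assert (r * w).sum() == pytest.approx(1.0)
    with pytest.raises(ConfigError):
        free_rate_categories([1.0], [1.0])
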