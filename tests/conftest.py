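import numpy as np
import pytest

import phylosel as ps


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gtrg_fixture():
    """A GTR+G alignment with clear rate-variation signal (session-wide)."""
    rng = np.random.default_rng(7)
    model = ps.make_dna_model("012345", "empirical", "G")
    params = ps.ModelParams(
        exch=np.array([1.2, 3.5, 0.8, 1.1, 4.0, 1.0]),
        freqs=np.array([0.32, 0.18, 0.27, 0.23]),
        alpha=0.5,
    )
    tree = ps.simulate_tree(12, bl_mean=0.1, rng=rng)
    aln = ps.simulate_alignment(tree, model, params, 800, rng=rng)
    paln = ps.compress_patterns(aln)
    base = ps.nj_topology(ps.jc_distance_matrix(aln), aln.taxon_labels)
    return {"model": model, "params": params, "tree": tree, "aln": aln,
            "paln": paln, "base": base}


@pytest.fixture(scope="session")
def small_aln():
    """Tiny hand-made DNA alignment."""
    from phylosel.msa import Alignment

    return Alignment.from_sequences(
        ["a", "b", "c", "d"],
        ["ACGTACGTAC", "ACGTACGTCC", "ACGAACGTAC", "TCGAACGTAG"],
        "DNA")
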