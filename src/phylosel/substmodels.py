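"""Candidate substitution models, rate matrices and rate heterogeneity.

DNA models are identified by a *scheme*: a partition of the six
exchangeabilities (order AC, AG, AT, CG, CT, GT) into rate classes, written
as a restricted-growth string, e.g. ``"012345"`` for GTR and ``"010010"``
for K80/HKY.  Amino-acid models use empirical replacement matrices vendored
as PAML-layout data files (lower-triangle exchangeabilities + frequencies).

All rate matrices are time-reversible (Q_ij = s_ij * pi_j for i != j) and
normalized to one expected substitution per unit branch length.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .errors import ConfigError, DomainError, ValidationError

# --------------------------------------------------------------------------
# DNA schemes: (code, equal-frequency name, unequal-frequency name)

DNA_SCHEMES = [
    ("000000", "JC", "F81"),
    ("010010", "K80", "HKY"),
    ("010020", "TrNef", "TrN"),
    ("012210", "TPM1", "TPM1uf"),
    ("010212", "TPM2", "TPM2uf"),
    ("012012", "TPM3", "TPM3uf"),
    ("012230", "TIM1ef", "TIM1"),
    ("010232", "TIM2ef", "TIM2"),
    ("012032", "TIM3ef", "TIM3"),
    ("012314", "TVMef", "TVM"),
    ("012345", "SYM", "GTR"),
]
_SCHEME_NAMES = {code: (eq, uf) for code, eq, uf in DNA_SCHEMES}

# progressive subsets mirroring the usual 3/5/7/11 scheme options
SCHEME_SUBSETS = {
    3: ["000000", "010010", "012345"],
    5: ["000000", "010010", "010020", "012210", "012345"],
    7: ["000000", "010010", "010020", "012210", "012230", "012314", "012345"],
    11: [code for code, _, _ in DNA_SCHEMES],
}

AA_MATRICES = [
    "DAYHOFF", "JTT", "LG", "WAG", "BLOSUM62", "CPREV", "MTREV", "MTART",
    "MTZOA", "RTREV", "VT", "HIVB", "HIVW", "DCMUT", "FLU", "JTTDCMUT",
    "MTMAM",
]

RATE_HET_MODES = ("none", "I", "G", "I+G", "R")


def all_dna_schemes():
    """All 203 partitions of the 6 exchangeabilities (restricted growth)."""
    codes = []

    def rec(prefix, mx):
        if len(prefix) == 6:
            codes.append("".join(map(str, prefix)))
            return
        for d in range(mx + 2):
            rec(prefix + [d], max(mx, d))

    rec([0], 0)
    return codes


def scheme_name(code: str, equal_freqs: bool) -> str:
    if code in _SCHEME_NAMES:
        return _SCHEME_NAMES[code][0 if equal_freqs else 1]
    return f"S{code}" + ("" if equal_freqs else "uf")


# --------------------------------------------------------------------------
# Model definition

@dataclass(frozen=True)
class SubstitutionModel:
    name: str
    datatype: str                   # "DNA" | "AA"
    scheme: str | None = None       # DNA exchangeability classes
    matrix: str | None = None       # AA empirical matrix id
    mixture: tuple | None = None    # per-category AA matrix ids
    freq_mode: str = "equal"        # equal | empirical | ml | model
    rate_het: str = "none"          # none | I | G | I+G | R
    n_gamma_cats: int = 4
    n_free_rates: int = 0
    asc_bias: bool = False

    def __post_init__(self):
        if self.asc_bias and "I" in self.rate_het.split("+"):
            raise ConfigError(
                "ascertainment bias correction is incompatible with +I: "
                "invariant sites cannot occur in a variable-sites-only "
                "alignment")
        if self.rate_het == "R" and self.n_free_rates < 2:
            raise ConfigError("free-rate models need k >= 2 categories")
        if self.datatype == "DNA" and self.scheme is None:
            raise ConfigError("DNA models require a scheme")
        if self.datatype == "AA" and self.matrix is None and self.mixture is None:
            raise ConfigError("AA models require a matrix or mixture")

    @property
    def n_states(self) -> int:
        return 4 if self.datatype == "DNA" else 20

    @property
    def n_exch_classes(self) -> int:
        if self.scheme is None:
            return 0
        return len(set(self.scheme))

    @property
    def has_gamma(self) -> bool:
        return self.rate_het in ("G", "I+G") or (
            self.mixture is not None and self.rate_het != "R")

    @property
    def has_pinv(self) -> bool:
        return "I" in self.rate_het.split("+")

    @property
    def n_mixture_cats(self) -> int:
        return len(self.mixture) if self.mixture else 0

    def n_free_params(self, n_taxa=None, include_branches=True) -> int:
        """Free-parameter count K used by the information criteria."""
        k = 0
        if self.datatype == "DNA":
            k += self.n_exch_classes - 1
            if self.freq_mode in ("empirical", "ml"):
                k += 3
        else:
            if self.freq_mode in ("empirical", "ml"):
                k += 19
        het = {"none": 0, "I": 1, "G": 1, "I+G": 2}.get(self.rate_het)
        if het is None:  # R(k)
            het = 2 * self.n_free_rates - 2
        if self.mixture is not None and self.rate_het == "R":
            het = 2 * len(self.mixture) - 2
        k += het
        if include_branches:
            if n_taxa is None:
                raise ValidationError(
                    "n_taxa required when branch lengths are counted")
            k += 2 * n_taxa - 3
        return k


def _het_suffix(het: str, ncat: int, nfree: int) -> str:
    return {"none": "", "I": "+I", "G": "+G", "I+G": "+I+G",
            "R": f"+R{nfree}"}[het]


def make_dna_model(scheme: str, freq_mode: str = "equal",
                   rate_het: str = "none", n_gamma_cats: int = 4,
                   n_free_rates: int = 0, asc_bias: bool = False
                   ) -> SubstitutionModel:
    if len(scheme) != 6 or any(c not in "012345" for c in scheme):
        raise ConfigError(f"bad DNA scheme {scheme!r}")
    name = scheme_name(scheme, freq_mode == "equal")
    name += _het_suffix(rate_het, n_gamma_cats, n_free_rates)
    if asc_bias:
        name += "+ASC"
    return SubstitutionModel(name=name, datatype="DNA", scheme=scheme,
                             freq_mode=freq_mode, rate_het=rate_het,
                             n_gamma_cats=n_gamma_cats,
                             n_free_rates=n_free_rates, asc_bias=asc_bias)


def make_aa_model(matrix: str, freq_mode: str = "model",
                  rate_het: str = "none", n_gamma_cats: int = 4,
                  n_free_rates: int = 0, asc_bias: bool = False,
                  mixture: tuple | None = None) -> SubstitutionModel:
    base = matrix if mixture is None else "MIX(" + ",".join(mixture) + ")"
    name = base + _het_suffix(rate_het, n_gamma_cats, n_free_rates)
    if freq_mode in ("empirical", "ml"):
        name += "+F"
    if asc_bias:
        name += "+ASC"
    return SubstitutionModel(name=name, datatype="AA", matrix=matrix,
                             mixture=mixture, freq_mode=freq_mode,
                             rate_het=rate_het, n_gamma_cats=n_gamma_cats,
                             n_free_rates=n_free_rates, asc_bias=asc_bias)


def generate_candidate_set(datatype, schemes=11,
                           het=("none", "I", "G", "I+G"),
                           freqs=None, matrices=None, n_gamma_cats=4,
                           n_free_rates=4, asc_bias=False, template=None):
    """Deterministic, duplicate-free list of candidate models.

    ``schemes`` (DNA) is 3/5/7/11/203 or an explicit list of scheme codes;
    ``matrices`` (AA) defaults to the full vendored registry.  ``freqs``
    defaults to ``("equal", "empirical")`` for DNA and
    ``("model", "empirical")`` for AA.  When ``asc_bias`` is set, +I
    variants must not be requested.
    """
    datatype = {"nt": "DNA", "dna": "DNA", "aa": "AA"}.get(
        str(datatype).lower(), datatype)
    if asc_bias and any("I" in h.split("+") for h in het):
        raise ConfigError("asc_bias cannot be combined with +I models")
    models = []
    if datatype == "DNA":
        if freqs is None:
            freqs = ("equal", "empirical")
        if isinstance(schemes, int):
            codes = all_dna_schemes() if schemes == 203 else SCHEME_SUBSETS.get(schemes)
            if codes is None:
                raise ConfigError(f"unknown scheme count {schemes}; "
                                  "use 3, 5, 7, 11 or 203")
        else:
            codes = list(schemes)
        for code in codes:
            for fm in freqs:
                for h in het:
                    models.append(make_dna_model(
                        code, fm, h, n_gamma_cats=n_gamma_cats,
                        n_free_rates=n_free_rates, asc_bias=asc_bias))
    elif datatype == "AA":
        if freqs is None:
            freqs = ("model", "empirical")
        if matrices is None:
            matrices = list(AA_MATRICES)
        for mat in matrices:
            for fm in freqs:
                for h in het:
                    models.append(make_aa_model(
                        mat, fm, h, n_gamma_cats=n_gamma_cats,
                        n_free_rates=n_free_rates, asc_bias=asc_bias))
    else:
        raise ConfigError(f"unknown datatype {datatype!r}")
    seen = set()
    unique = []
    for m in models:
        if m.name not in seen:
            seen.add(m.name)
            unique.append(m)
    if template is not None:
        from .templates import restrict_candidates
        unique = restrict_candidates(unique, template)
    return unique


# --------------------------------------------------------------------------
# Empirical AA matrices (PAML layout: 19 lower-triangle rows + frequencies)

@functools.lru_cache(maxsize=None)
def load_empirical_matrix(name: str):
    """Return (exchangeability 20x20 symmetric matrix, frequencies)."""
    name = name.upper()
    if name not in AA_MATRICES:
        raise ConfigError(f"unknown amino-acid matrix {name!r}")
    path = resources.files("phylosel").joinpath(f"data/aa/{name}.dat")
    values = [float(tok) for tok in path.read_text().split()]
    if len(values) != 190 + 20:
        raise ValidationError(f"matrix file for {name} is malformed")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    freqs = np.array(values[190:])
    freqs = freqs / freqs.sum()
    return S, freqs


# --------------------------------------------------------------------------
# Rate matrix construction

@dataclass
class RateMatrix:
    Q: np.ndarray
    pi: np.ndarray


def expand_scheme_rates(scheme: str, class_rates) -> np.ndarray:
    """Map per-class exchangeability values onto the 6 rate slots."""
    class_rates = np.asarray(class_rates, dtype=float)
    idx = np.array([int(c) for c in scheme])
    if class_rates.shape != (idx.max() + 1,):
        raise DomainError(
            f"scheme {scheme} expects {idx.max() + 1} class rates, "
            f"got {class_rates.shape}")
    return class_rates[idx]


def build_rate_matrix(exchangeabilities, pi) -> RateMatrix:
    """Normalized reversible Q from exchangeabilities and frequencies.

    ``exchangeabilities`` is either the 6-vector (DNA, order AC AG AT CG CT
    GT) or a full symmetric n x n matrix (AA).
    """
    pi = np.asarray(pi, dtype=float)
    if (pi <= 0).any():
        raise DomainError("frequencies must be strictly positive")
    pi = pi / pi.sum()
    ex = np.asarray(exchangeabilities, dtype=float)
    if ex.ndim == 1:
        if ex.shape != (6,) or pi.shape != (4,):
            raise DomainError("DNA needs 6 exchangeabilities and 4 frequencies")
        S = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        S[iu] = ex
        S = S + S.T
        if (ex <= 0).any():
            raise DomainError("exchangeabilities must be strictly positive")
    else:
        S = ex
        if S.shape[0] != S.shape[1] or S.shape[0] != pi.shape[0]:
            raise DomainError("exchangeability matrix/frequency shape mismatch")
        # empirical replacement matrices may legitimately contain zeros
        # (replacements never observed in the training data)
        off = S[~np.eye(S.shape[0], dtype=bool)]
        if (off < 0).any() or not (off > 0).any():
            raise DomainError("exchangeability matrix must be nonnegative "
                              "and not identically zero")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.sum(pi * np.diag(Q))
    return RateMatrix(Q=Q / scale, pi=pi)


@dataclass
class EigenSystem:
    """Spectral decomposition of a reversible Q: Q = right @ diag(ev) @ left."""

    eigenvalues: np.ndarray
    right: np.ndarray
    left: np.ndarray
    pi: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return (self.right * self.eigenvalues[None, :]) @ self.left


def eigen_decompose(rm: RateMatrix) -> EigenSystem:
    d = np.sqrt(rm.pi)
    B = rm.Q * (d[:, None] / d[None, :])
    B = 0.5 * (B + B.T)  # exact symmetrization against rounding
    ev, V = np.linalg.eigh(B)
    right = V / d[:, None]
    left = V.T * d[None, :]
    return EigenSystem(eigenvalues=ev, right=right, left=left, pi=rm.pi)


def transition_probabilities(eig: EigenSystem, t: float, r: float = 1.0
                             ) -> np.ndarray:
    """P(t) = exp(Q * r * t); rows sum to one."""
    if t < 0 or r < 0:
        raise DomainError("branch length and rate must be nonnegative")
    P = (eig.right * np.exp(eig.eigenvalues * (t * r))[None, :]) @ eig.left
    return np.clip(P, 0.0, 1.0)


def transition_matrices(eigs, lengths, rates) -> np.ndarray:
    """Batched P matrices, shape (n_edges, n_cats, n, n).

    ``eigs`` is a single EigenSystem shared by all rate categories, or a
    list with one EigenSystem per category (mixture models).
    """
    lengths = np.asarray(lengths, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if (lengths < 0).any():
        raise DomainError("negative branch length")
    tr = lengths[:, None] * rates[None, :]            # (E, C)
    if isinstance(eigs, EigenSystem):
        ev = np.broadcast_to(eigs.eigenvalues, (len(rates),) + eigs.eigenvalues.shape)
        right = np.broadcast_to(eigs.right, (len(rates),) + eigs.right.shape)
        left = np.broadcast_to(eigs.left, (len(rates),) + eigs.left.shape)
    else:
        ev = np.stack([e.eigenvalues for e in eigs])
        right = np.stack([e.right for e in eigs])
        left = np.stack([e.left for e in eigs])
    expv = np.exp(ev[None, :, :] * tr[:, :, None])    # (E, C, n)
    P = np.matmul(right[None] * expv[:, :, None, :], left[None])
    np.clip(P, 0.0, 1.0, out=P)
    return P


# --------------------------------------------------------------------------
# Rate heterogeneity

def discrete_gamma_rates(alpha: float, ncat: int):
    """Mean-of-category discretization of Gamma(alpha, alpha).

    Returns (rates, weights) with equal weights 1/ncat and sum(w*r) == 1.
    """
    rates, weights = _discrete_gamma_cached(float(alpha), int(ncat))
    return rates.copy(), weights.copy()


@functools.lru_cache(maxsize=4096)
def _discrete_gamma_cached(alpha: float, ncat: int):
    if alpha <= 0:
        raise DomainError("gamma shape must be positive")
    if ncat < 1:
        raise DomainError("need at least one rate category")
    if ncat == 1:
        return np.array([1.0]), np.array([1.0])
    edges = _gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha,
                            scale=1.0 / alpha)
    # E[X ; a<X<b] for X ~ Gamma(alpha, rate alpha) is the regularized
    # incomplete gamma with shape alpha+1 evaluated at the cut points
    cuts = np.concatenate([[0.0], alpha * edges, [np.inf]])
    upper = gammainc(alpha + 1.0, cuts[1:])
    lower = gammainc(alpha + 1.0, cuts[:-1])
    rates = (upper - lower) * ncat
    weights = np.full(ncat, 1.0 / ncat)
    rates = rates / np.sum(rates * weights)
    return rates, weights


def free_rate_categories(rates, weights):
    """Validate and normalize a free-rate mixture (sum w = 1, sum w*r = 1)."""
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if rates.ndim != 1 or rates.shape != weights.shape:
        raise ConfigError("rates and weights must be equal-length vectors")
    if len(rates) < 2:
        raise ConfigError("free-rate models need k >= 2 categories")
    if (rates <= 0).any() or (weights <= 0).any():
        raise DomainError("free-rate rates and weights must be positive")
    weights = weights / weights.sum()
    rates = rates / np.sum(weights * rates)
    return rates, weights
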