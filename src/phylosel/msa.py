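"""Alignment input/output, validation, site-pattern compression and partitions.

Alignments are plain character matrices (taxa x sites).  DNA uses the
A/C/G/T state order; amino acids use the standard PAML order
``ARNDCQEGHILKMFPSTWYV``.  Ambiguity codes map to the set of compatible
states and ``-``/``?``/``N``(DNA)/``X`` map to the full state set, which is
the standard treatment of missing data in likelihood computations.  ``U`` is
read as ``T``.  Parsing is case-insensitive.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

DNA_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

_DNA_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": DNA_STATES, "X": DNA_STATES, "-": DNA_STATES, "?": DNA_STATES,
    ".": DNA_STATES,
}
_AA_AMBIG = {aa: aa for aa in AA_STATES}
_AA_AMBIG.update({
    "B": "ND", "Z": "QE", "J": "IL",
    "X": AA_STATES, "-": AA_STATES, "?": AA_STATES, ".": AA_STATES,
    "*": AA_STATES,
})


def states_for(datatype: str) -> str:
    if datatype == "DNA":
        return DNA_STATES
    if datatype == "AA":
        return AA_STATES
    raise ValidationError(f"unknown datatype {datatype!r}")


def ambiguity_map(datatype: str) -> dict:
    """Symbol -> string of compatible states for the given datatype."""
    return _DNA_AMBIG if datatype == "DNA" else _AA_AMBIG


@dataclass
class Alignment:
    """A taxa x sites character matrix with a declared datatype."""

    taxon_labels: list
    matrix: np.ndarray          # (n_taxa, n_sites), dtype '<U1', upper case
    datatype: str               # "DNA" | "AA"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        if len(self.taxon_labels) != self.matrix.shape[0]:
            raise ValidationError("label count does not match matrix rows")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ValidationError("duplicate taxon labels")
        if any((not t) for t in self.taxon_labels):
            raise ValidationError("empty taxon label")
        if self.matrix.shape[0] < 2:
            raise ValidationError("at least 2 taxa are required")
        amb = ambiguity_map(self.datatype)
        symbols = np.unique(self.matrix)
        bad = [s for s in symbols if s not in amb]
        if bad:
            raise FormatError(
                f"symbols {bad} are not valid for datatype {self.datatype}")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, labels, seqs, datatype):
        lens = {len(s) for s in seqs}
        if len(lens) > 1:
            raise FormatError(f"sequences have unequal lengths: {sorted(lens)}")
        if not seqs or next(iter(lens)) == 0:
            raise FormatError("empty alignment")
        mat = np.array([list(s.upper()) for s in seqs], dtype="<U1")
        return cls(list(labels), mat, datatype)

    def sequence(self, i) -> str:
        return "".join(self.matrix[i])


@dataclass
class PatternAlignment:
    """Unique site columns of an alignment with multiplicities."""

    taxon_labels: list
    patterns: np.ndarray        # (n_taxa, n_patterns) '<U1'
    weights: np.ndarray         # (n_patterns,) positive ints
    datatype: str
    n_sites: int

    @property
    def n_taxa(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def expand(self) -> np.ndarray:
        """Reproduce the source column multiset (columns in pattern order)."""
        return np.repeat(self.patterns, self.weights, axis=1)


def compress_patterns(aln: Alignment) -> PatternAlignment:
    """Collapse identical columns into weighted unique site patterns."""
    patterns, counts = np.unique(aln.matrix, axis=1, return_counts=True)
    return PatternAlignment(
        taxon_labels=list(aln.taxon_labels),
        patterns=patterns,
        weights=counts.astype(np.int64),
        datatype=aln.datatype,
        n_sites=aln.n_sites,
    )


# ---------------------------------------------------------------------------
# Reading / writing

def _infer_datatype(seqs) -> str:
    # >=90% of non-gap symbols among A/C/G/T/U/N -> DNA, else AA
    text = "".join(s.upper() for s in seqs)
    residues = [c for c in text if c not in "-?."]
    if not residues:
        return "DNA"
    dna_like = sum(c in "ACGTUN" for c in residues)
    return "DNA" if dna_like / len(residues) >= 0.9 else "AA"


def _parse_fasta(text: str):
    from Bio import SeqIO
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError("no sequences found in FASTA input")
    labels = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return labels, seqs


def _parse_phylip(text: str):
    from Bio import AlignIO
    last = None
    for fmt in ("phylip-relaxed", "phylip", "phylip-sequential"):
        try:
            aln = AlignIO.read(io.StringIO(text), fmt)
            return [r.id for r in aln], [str(r.seq) for r in aln]
        except Exception as exc:  # Biopython raises bare ValueError
            last = exc
    raise FormatError(f"could not parse PHYLIP input: {last}")


def read_alignment(path, datatype: str = "auto") -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    ``datatype`` is ``"DNA"``, ``"AA"`` or ``"auto"`` (the CLI spellings
    ``nt``/``aa`` are accepted too).
    """
    datatype = {"nt": "DNA", "aa": "AA", "dna": "DNA"}.get(
        str(datatype).lower(), datatype)
    text = Path(path).read_text()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"{path}: empty file")
    if stripped.startswith(">"):
        labels, seqs = _parse_fasta(text)
    elif re.match(r"^\d+\s+\d+\s*$", stripped.splitlines()[0].strip()):
        labels, seqs = _parse_phylip(text)
    else:
        raise FormatError(f"{path}: not recognizable as FASTA or PHYLIP")
    lens = {len(s) for s in seqs}
    if len(lens) > 1:
        raise FormatError(f"{path}: rows have unequal lengths {sorted(lens)}")
    if len(labels) < 3:
        raise ValidationError(f"{path}: at least 3 taxa are required")
    if datatype == "auto":
        datatype = _infer_datatype(seqs)
    return Alignment.from_sequences(labels, seqs, datatype)


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    lines = []
    if fmt == "fasta":
        for i, lab in enumerate(aln.taxon_labels):
            lines.append(f">{lab}")
            lines.append(aln.sequence(i))
    elif fmt == "phylip":
        lines.append(f"{aln.n_taxa} {aln.n_sites}")
        width = max(len(t) for t in aln.taxon_labels) + 2
        for i, lab in enumerate(aln.taxon_labels):
            lines.append(f"{lab:<{width}}{aln.sequence(i)}")
    else:
        raise ValidationError(f"unknown alignment format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Partitions (RAxML dialect: 1-based inclusive ranges, "\k" stride)

@dataclass
class Partition:
    name: str
    datatype: str
    site_ranges: list = field(default_factory=list)  # [(start, end, stride)]

    def sites(self) -> np.ndarray:
        """1-based site indices covered by this partition, in range order."""
        chunks = [np.arange(s, e + 1, k) for s, e, k in self.site_ranges]
        return np.concatenate(chunks) if chunks else np.array([], dtype=int)


_PART_LINE = re.compile(r"^\s*(DNA|AA|BIN|PROT[A-Z]*)\s*,\s*([^=\s]+)\s*=\s*(.+)$",
                        re.IGNORECASE)
_RANGE = re.compile(r"^(\d+)(?:-(\d+))?(?:\\(\d+))?$")


def _parse_range(tok: str):
    m = _RANGE.match(tok.strip())
    if not m:
        raise FormatError(f"bad partition range {tok!r}")
    start = int(m.group(1))
    end = int(m.group(2)) if m.group(2) else start
    stride = int(m.group(3)) if m.group(3) else 1
    if start < 1 or end < start or stride < 1:
        raise FormatError(f"bad partition range {tok!r}")
    return start, end, stride


def read_partitions(path) -> list:
    """Parse a RAxML-style partition file and validate disjointness."""
    parts = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _PART_LINE.match(line)
        if not m:
            raise FormatError(f"unparseable partition line: {raw!r}")
        dtype = "DNA" if m.group(1).upper() == "DNA" else "AA"
        name = m.group(2)
        ranges = [_parse_range(tok) for tok in m.group(3).split(",")]
        parts.append(Partition(name=name, datatype=dtype, site_ranges=ranges))
    if not parts:
        raise FormatError(f"{path}: no partitions found")
    seen = {}
    for p in parts:
        for s in p.sites():
            if s in seen:
                raise ValidationError(
                    f"partitions {seen[s]!r} and {p.name!r} overlap at site {s}")
            seen[s] = p.name
    names = [p.name for p in parts]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate partition names")
    return parts


def slice_partition(aln: Alignment, part: Partition) -> Alignment:
    """Extract the sub-alignment with exactly the partition's columns."""
    sites = part.sites()
    if sites.size == 0:
        raise ValidationError(f"partition {part.name!r} covers no sites")
    if sites.max() > aln.n_sites:
        raise ValidationError(
            f"partition {part.name!r} site {sites.max()} exceeds "
            f"alignment length {aln.n_sites}")
    return Alignment(list(aln.taxon_labels), aln.matrix[:, sites - 1],
                     part.datatype)
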