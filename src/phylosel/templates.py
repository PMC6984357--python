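"""Downstream-tool templates: candidate restriction and command emission.

Each supported phylogenetic inference tool has a capability entry in
``data/templates.json`` (supported DNA schemes, amino-acid matrices,
frequency handling and rate-heterogeneity modes) plus a command template.
Restricting the candidate set with a template guarantees the selected best
model can be passed straight to that tool; ``command_line`` renders the
invocation string for the winning model.
"""

from __future__ import annotations

import functools
import json
from importlib import resources

from .errors import ConfigError
from .substmodels import SubstitutionModel

_IQTREE_DNA = {
    ("000000", True): "JC", ("000000", False): "F81",
    ("010010", True): "K80", ("010010", False): "HKY",
    ("010020", True): "TNe", ("010020", False): "TN",
    ("012210", True): "K81", ("012210", False): "K81u",
    ("010212", True): "TPM2", ("010212", False): "TPM2u",
    ("012012", True): "TPM3", ("012012", False): "TPM3u",
    ("012230", True): "TIMe", ("012230", False): "TIM",
    ("010232", True): "TIM2e", ("010232", False): "TIM2",
    ("012032", True): "TIM3e", ("012032", False): "TIM3",
    ("012314", True): "TVMe", ("012314", False): "TVM",
    ("012345", True): "SYM", ("012345", False): "GTR",
}
_PHYML_DNA_EQ = {"000000": "JC69", "010010": "K80"}
_PHYML_DNA_UF = {"000000": "F81", "010010": "HKY85", "010020": "TN93",
                 "012345": "GTR"}
_MRBAYES_NST = {"000000": 1, "010010": 2, "012345": 6}


@functools.lru_cache(maxsize=1)
def _tables() -> dict:
    path = resources.files("phylosel").joinpath("data/templates.json")
    return json.loads(path.read_text())


def available_templates():
    return sorted(k for k in _tables() if not k.startswith("_"))


def _capabilities(template: str) -> dict:
    tab = _tables()
    if template not in tab or template.startswith("_"):
        raise ConfigError(
            f"unknown template {template!r}; known: {available_templates()}")
    return tab[template]


def supports(model: SubstitutionModel, template: str) -> bool:
    cap = _capabilities(template)
    het = "R" if model.rate_het == "R" else model.rate_het
    if model.mixture is not None:
        return False
    if model.asc_bias and template not in ("raxml-ng", "iqtree"):
        return False
    if model.datatype == "DNA":
        return (model.scheme in cap["dna_schemes"]
                and model.freq_mode in cap["dna_freqs"]
                and het in cap["dna_het"])
    return (model.matrix in cap["aa_matrices"]
            and model.freq_mode in cap["aa_freqs"]
            and het in cap["aa_het"])


def restrict_candidates(models, template: str):
    """Subset of ``models`` supported by the given tool."""
    _capabilities(template)  # raise on unknown template
    return [m for m in models if supports(m, template)]


def _suffix(model: SubstitutionModel, gamma: str = "+G4") -> str:
    return {"none": "", "I": "+I", "G": gamma, "I+G": "+I" + gamma,
            "R": f"+R{model.n_free_rates}"}[model.rate_het]


def _raxmlng_model(model: SubstitutionModel) -> str:
    if model.datatype == "DNA":
        base = _IQTREE_DNA.get((model.scheme, model.freq_mode == "equal"))
        s = base + _suffix(model)
        if model.freq_mode == "ml":
            s += "+FO"
    else:
        s = model.matrix + _suffix(model)
        if model.freq_mode == "empirical":
            s += "+FC"
        elif model.freq_mode == "ml":
            s += "+FO"
    if model.asc_bias:
        s += "+ASC_LEWIS"
    return s


def _iqtree_model(model: SubstitutionModel) -> str:
    if model.datatype == "DNA":
        s = _IQTREE_DNA[(model.scheme, model.freq_mode == "equal")]
        s += _suffix(model)
    else:
        s = model.matrix + _suffix(model)
        if model.freq_mode in ("empirical", "ml"):
            s += "+F"
    if model.asc_bias:
        s += "+ASC"
    return s


def _raxml_model(model: SubstitutionModel) -> str:
    if model.datatype == "DNA":
        return "GTRGAMMA" + ("I" if model.has_pinv else "")
    name = "PROTGAMMA" + ("I" if model.has_pinv else "") + model.matrix
    if model.freq_mode == "empirical":
        name += "F"
    return name


def _phyml_opts(model: SubstitutionModel) -> str:
    opts = ["-d nt" if model.datatype == "DNA" else "-d aa", "-b 0"]
    if model.datatype == "DNA":
        names = (_PHYML_DNA_EQ if model.freq_mode == "equal"
                 else _PHYML_DNA_UF)
        opts.append("-m " + names.get(model.scheme, model.scheme))
        opts.append("-f m" if model.freq_mode in ("empirical", "ml")
                    else "-f 0.25,0.25,0.25,0.25")
    else:
        opts.append(f"-m {model.matrix}")
        if model.freq_mode == "empirical":
            opts.append("-f e")
    opts.append("-v e" if model.has_pinv else "-v 0")
    if model.has_gamma:
        opts.append(f"-a e -c {model.n_gamma_cats}")
    else:
        opts.append("-c 1")
    return " ".join(opts)


def _mrbayes_opts(model: SubstitutionModel) -> str:
    rates = {"none": "equal", "I": "propinv", "G": "gamma",
             "I+G": "invgamma"}[model.rate_het]
    if model.datatype == "DNA":
        nst = _MRBAYES_NST[model.scheme]
        lset = f"lset nst={nst} rates={rates};"
        prset = ("prset statefreqpr=fixed(equal); "
                 if model.freq_mode == "equal" else "")
        return f"{lset} {prset}".strip()
    return (f"prset aamodelpr=fixed({model.matrix.lower()}); "
            f"lset rates={rates};")


def _paup_opts(model: SubstitutionModel) -> str:
    nst = _MRBAYES_NST[model.scheme]
    parts = [f"lset nst={nst}"]
    parts.append("basefreq=equal" if model.freq_mode == "equal"
                 else "basefreq=estimate")
    if nst == 6:
        parts.append("rmat=estimate")
    elif nst == 2:
        parts.append("tratio=estimate")
    rates = "gamma" if model.has_gamma else "equal"
    parts.append(f"rates={rates}")
    if model.has_gamma:
        parts.append("shape=estimate")
    parts.append("pinvar=estimate" if model.has_pinv else "pinvar=0")
    return " ".join(parts) + ";"


def command_line(best, template: str, msa_path: str) -> str:
    """Inference command for the best-fit model under a tool template."""
    model = best.model if hasattr(best, "model") else best
    if not supports(model, template):
        raise ConfigError(
            f"model {model.name} is not supported by template {template!r}")
    cap = _capabilities(template)
    cmd = cap["command"]
    if template == "raxml-ng":
        return cmd.format(msa=msa_path, model=_raxmlng_model(model))
    if template == "iqtree":
        return cmd.format(msa=msa_path, model=_iqtree_model(model))
    if template == "raxml":
        return cmd.format(msa=msa_path, model=_raxml_model(model))
    if template == "phyml":
        return cmd.format(msa=msa_path, opts=_phyml_opts(model))
    if template == "mrbayes":
        return cmd.format(opts=_mrbayes_opts(model))
    if template == "paup":
        return cmd.format(opts=_paup_opts(model))
    raise ConfigError(f"no command template for {template!r}")
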