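"""Phenotype classification of attractors and mean-threshold discretization.

A :class:`PhenotypeScheme` is an *ordered* list of marker patterns; each
pattern names a phenotype and the 0/1 values it requires of specific marker
nodes (nodes not mentioned are "don't care").  Patterns are evaluated in
declared order and the first match wins, so overlapping marker definitions
(e.g. the tumor-associated macrophage phenotypes, which both require
iNOS/Arg1 co-expression) are resolved by putting the most constrained
pattern first.  Attractors matching no pattern receive the scheme's fallback
label.

Built-in schemes cover the three VAT cell types:

* CD4+ T cells — Th0, the effector lineages Th1 (T-bet+ IFN-g+), Th2
  (GATA3+ IL-4+), Th9 (PU.1+ IL-9+), Th17 (RORgT+ IL-17+) and the regulatory
  lineages Th1R (FoxP3+ IFN-g+), Th2R (FoxP3+ IL-4+), iTreg (FoxP3+ IL-10+
  TGF-b+), Tr1 (FoxP3- IL-10+), Th3 (FoxP3- TGF-b+);
* macrophages — M0, M1 (iNOS+ Arg1-), M2 (Arg1+ iNOS-), M1-TAM (iNOS+ Arg1+
  with IL-12 or IFN-g) and M2-TAM (iNOS+ Arg1+ with neither);
* adipocytes — the eight TNF/CTGF/GLUT4 marker combinations, where TNF marks
  inflamed cells, CTGF hypertrophic cells and membrane GLUT4 insulin
  responsiveness.

The module also provides the mean-threshold discretizer for gene-by-sample
TPM matrices: a value becomes 1 iff it is >= its gene's mean across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .attractors import Attractor
from .network import BooleanNetwork

__all__ = [
    "PhenotypeScheme", "Pattern", "SchemeError", "classify_attractor",
    "builtin_schemes", "DiscretizedMatrix", "discretize",
    "load_scheme", "CYCLE_LABEL",
]

CYCLE_LABEL = "unclassified-cycle"


class SchemeError(ValueError):
    """A scheme references nodes absent from the target network."""


@dataclass(frozen=True)
class Pattern:
    label: str
    required: Mapping[str, int]  # node -> 0/1; absent nodes are "any"

    def matches(self, state: Mapping[str, int]) -> bool:
        return all(state.get(n) == v for n, v in self.required.items())


@dataclass(frozen=True)
class PhenotypeScheme:
    """Ordered first-match-wins marker patterns for one cell type."""

    cell_type: str
    patterns: tuple[Pattern, ...]
    fallback: str = "unclassified"
    aliases: Mapping[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, ...]:
        """All phenotype labels, in pattern order, plus the fallback."""
        seen: list[str] = []
        for p in self.patterns:
            if p.label not in seen:
                seen.append(p.label)
        if self.fallback not in seen:
            seen.append(self.fallback)
        return tuple(seen)

    def marker_nodes(self) -> set[str]:
        return set().union(*(set(p.required) for p in self.patterns))

    def bind(self, net: BooleanNetwork,
             aliases: Mapping[str, str] | None = None) -> "PhenotypeScheme":
        """Resolve marker names against a network, applying the alias map.

        Scheme files must survive network reconstructions with differing node
        naming, so pattern nodes are translated through ``aliases`` (scheme
        name -> network name) and validated here, at load time — a missing
        marker is a configuration error, never a classify-time surprise.
        """
        amap = dict(self.aliases)
        amap.update(aliases or {})
        new_patterns = []
        missing: set[str] = set()
        for p in self.patterns:
            req = {}
            for n, v in p.required.items():
                bound = amap.get(n, n)
                if bound not in net.nodes:
                    missing.add(n)
                req[bound] = v
            new_patterns.append(Pattern(p.label, req))
        if missing:
            raise SchemeError(
                f"scheme {self.cell_type!r} markers not in network "
                f"{net.name!r}: {sorted(missing)}")
        return PhenotypeScheme(self.cell_type, tuple(new_patterns),
                               self.fallback, amap)

    def classify_state(self, state: Mapping[str, int]) -> str:
        for p in self.patterns:
            if p.matches(state):
                return p.label
        return self.fallback

    def to_yaml(self) -> str:
        doc = {
            "cell_type": self.cell_type,
            "fallback": self.fallback,
            "patterns": [{"label": p.label, "required": dict(p.required)}
                         for p in self.patterns],
        }
        if self.aliases:
            doc["aliases"] = dict(self.aliases)
        return yaml.safe_dump(doc, sort_keys=False)


def load_scheme(source) -> PhenotypeScheme:
    """Load a scheme from a YAML string, file path or file object."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
            with open(text, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    patterns = tuple(Pattern(p["label"], {str(k): int(v)
                                          for k, v in p["required"].items()})
                     for p in doc["patterns"])
    return PhenotypeScheme(doc["cell_type"], patterns,
                           doc.get("fallback", "unclassified"),
                           doc.get("aliases", {}))


def classify_attractor(attractor: Attractor, scheme: PhenotypeScheme,
                       net: BooleanNetwork,
                       cycle_policy: str = "fallback") -> str:
    """Phenotype label of an attractor under a (bound) scheme.

    Fixed points are matched directly.  Cycles are not discussed by the
    marker definitions, so by default they get the ``unclassified-cycle``
    label (``cycle_policy="fallback"``); ``"mean"`` labels them by their
    state-average rounded to 0/1.
    """
    if attractor.is_fixed_point:
        return scheme.classify_state(attractor.state_map(net.nodes))
    if cycle_policy == "mean":
        mean = attractor.mean_state()
        state = {n: int(m >= 0.5) for n, m in zip(net.nodes, mean)}
        return scheme.classify_state(state)
    if cycle_policy == "fallback":
        return CYCLE_LABEL
    raise ValueError(f"unknown cycle_policy {cycle_policy!r}")


def label_attractors(attractors: Sequence[Attractor], scheme: PhenotypeScheme,
                     net: BooleanNetwork,
                     cycle_policy: str = "fallback") -> dict[int, str]:
    return {a.id: classify_attractor(a, scheme, net, cycle_policy)
            for a in attractors}


# --------------------------------------------------------------------------
# Built-in schemes
# --------------------------------------------------------------------------

def _p(label: str, **required: int) -> Pattern:
    return Pattern(label, required)


_CD4_MARKERS = ("TBET", "GATA3", "RORGT", "PU1", "FOXP3",
                "IFNG", "IL4", "IL9", "IL17", "IL10", "TGFB")


def builtin_schemes() -> dict[str, PhenotypeScheme]:
    """The CD4T, macrophage and adipocyte marker schemes.

    Ordering encodes specificity: the regulatory CD4 patterns (which pin
    FoxP3) precede the effector ones, iTreg (three markers) precedes
    Th1R/Th2R, and the TAM macrophage patterns precede plain M1/M2.  Node
    names are canonical identifiers (IFNG for IFN-g, RORGT for RORgT, ...);
    use ``PhenotypeScheme.bind`` with an alias map for networks that name
    them differently.
    """
    cd4 = PhenotypeScheme("CD4T", (
        _p("iTreg", FOXP3=1, IL10=1, TGFB=1),
        _p("Th1R", FOXP3=1, IFNG=1),
        _p("Th2R", FOXP3=1, IL4=1),
        _p("Th1", TBET=1, IFNG=1, FOXP3=0),
        _p("Th2", GATA3=1, IL4=1, FOXP3=0),
        _p("Th9", PU1=1, IL9=1, FOXP3=0),
        _p("Th17", RORGT=1, IL17=1, FOXP3=0),
        _p("Tr1", FOXP3=0, IL10=1),
        _p("Th3", FOXP3=0, TGFB=1),
        _p("Th0", **{m: 0 for m in _CD4_MARKERS}),
    ))
    mac = PhenotypeScheme("macrophage", (
        _p("M1-TAM", INOS=1, ARG1=1, IL12=1),
        _p("M1-TAM", INOS=1, ARG1=1, IFNG=1),
        _p("M2-TAM", INOS=1, ARG1=1, IL12=0, IFNG=0),
        _p("M1", INOS=1, ARG1=0),
        _p("M2", ARG1=1, INOS=0),
        _p("M0", INOS=0, ARG1=0, IL12=0, IFNG=0),
    ))
    # The eight marker combinations of the adipocyte model, named the way the
    # stochastic model draws them (sign string per marker).  The all-negative
    # state is written GLUT4- CTGF- TNF-.
    adip_patterns = []
    for tnf in (0, 1):
        for ctgf in (0, 1):
            for glut4 in (0, 1):
                if (tnf, ctgf, glut4) == (0, 0, 0):
                    label = "GLUT4- CTGF- TNF-"
                else:
                    label = (f"TNF{'+' if tnf else '-'} "
                             f"CTGF{'+' if ctgf else '-'} "
                             f"GLUT4{'+' if glut4 else '-'}")
                adip_patterns.append(
                    Pattern(label, {"TNF": tnf, "CTGF": ctgf, "GLUT4": glut4}))
    adip = PhenotypeScheme("adipocyte", tuple(adip_patterns))
    return {"CD4T": cd4, "macrophage": mac, "adipocyte": adip}


# --------------------------------------------------------------------------
# Mean-threshold discretizer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizedMatrix:
    """0/1 gene-by-sample matrix with the per-gene means that produced it.

    ``bits`` is 1 iff the TPM value is >= that gene's mean across samples —
    in particular a gene with all-equal values (value == mean) discretizes to
    all ones.
    """

    bits: pd.DataFrame
    gene_means: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.bits.index

    @property
    def samples(self) -> pd.Index:
        return self.bits.columns


def discretize(matrix: pd.DataFrame) -> DiscretizedMatrix:
    """Discretize a gene-by-sample TPM matrix by the >=-row-mean rule."""
    matrix = pd.DataFrame(matrix)
    if matrix.shape[1] < 1:
        raise ValueError("need at least one sample")
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("TPM values must be non-negative")
    means = values.mean(axis=1)
    bits = (values >= means[:, None]).astype(np.int8)
    return DiscretizedMatrix(
        bits=pd.DataFrame(bits, index=matrix.index, columns=matrix.columns),
        gene_means=pd.Series(means, index=matrix.index, name="mean"))
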