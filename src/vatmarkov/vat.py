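"""Bundled VAT cell models, microenvironment catalogs and scenario runner.

The three networks shipped here (adipocyte, macrophage, CD4+ T cell) are
*reconstructions*: reduced Boolean models rebuilt from the documented
causal biology of VAT-resident cells (see the comments inside each rule
file and ``metadata["provenance"]``).  Their acceptance contract is
behavioral — under the qualitative-validation grid of input conditions the
stationary phenotype distributions must satisfy the expected frequency
relations at every noise level of the robustness set — and they are meant
to be replaced by user-supplied rule files for serious modelling of a
specific dataset.

A :class:`Scenario` bundles a physiological context (lean, obese, diabetic,
or a therapy simulation) as a catalog of input clampings, optional node
toggles (force-off = neutralizing antibody / knockout, force-on =
over-activation) and an insulin setting.  ``run_scenario`` enumerates
attractors, estimates the phenotype Markov chain and solves for the
stationary distribution per microenvironment, then averages — mirroring the
fact that only the tissue-level mixture of microenvironments is observable.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .attractors import AttractorSystem
from .markov import (DistributionResult, SimulationProtocol, NOISE_LEVELS,
                     align_distribution, average_distributions,
                     estimate_markov, stationary)
from .network import BooleanNetwork, load_network
from .phenotypes import CYCLE_LABEL, PhenotypeScheme, builtin_schemes
from .validation import BinomialReport, QualitativeTrial, score_trials

__all__ = [
    "Microenvironment", "Scenario", "ScenarioResult", "load_builtin_models",
    "builtin_scenarios", "therapy_scenarios", "run_scenario",
    "table1_trial_grid", "score_table1", "condition_distributions",
]

CELL_TYPES = ("CD4T", "macrophage", "adipocyte")

_NETWORK_FILES = {"CD4T": "cd4t.bnet", "macrophage": "macrophage.bnet",
                  "adipocyte": "adipocyte.bnet"}


def _data_text(fname: str) -> str:
    return (resources.files("vatmarkov") / "data" / fname).read_text("utf-8")


@dataclass(frozen=True)
class Microenvironment:
    """A named clamping of input nodes (a chemical context of the VAT)."""

    name: str
    clamp: Mapping[str, int]


@dataclass(frozen=True)
class Scenario:
    """A physiological context or therapy simulation for one cell type."""

    name: str
    cell_type: str
    microenvironments: tuple[Microenvironment, ...]
    toggles: Mapping[str, int] = field(default_factory=dict)
    insulin: str = "both"  # present | absent | both

    def __post_init__(self):
        if self.insulin not in ("present", "absent", "both"):
            raise ValueError("insulin must be present, absent or both")

    def insulin_settings(self) -> tuple[int, ...]:
        return {"present": (1,), "absent": (0,), "both": (0, 1)}[self.insulin]


@dataclass(frozen=True)
class ScenarioResult:
    """Per-microenvironment stationary distributions and their averages."""

    scenario: Scenario
    labels: tuple[str, ...]
    distributions: Mapping[tuple[str, int], DistributionResult]
    averages: Mapping[int, DistributionResult]
    overall: DistributionResult


def load_builtin_models() -> dict[str, tuple[BooleanNetwork, PhenotypeScheme]]:
    """The bundled reconstructed networks with their bound marker schemes."""
    schemes = builtin_schemes()
    out = {}
    for cell, fname in _NETWORK_FILES.items():
        path = resources.files("vatmarkov") / "data" / fname
        with resources.as_file(path) as p:
            net = load_network(p)
        out[cell] = (net, schemes[cell].bind(net))
    return out


def full_input_clamp(net: BooleanNetwork,
                     partial: Mapping[str, int]) -> dict[str, int]:
    """Clamp of *every* declared input: unspecified inputs are absent (0).

    A microenvironment fixes the whole chemical context; an input the
    condition does not mention is considered not present, never free-running.
    Non-input nodes in ``partial`` (therapy toggles) pass through unchanged.
    """
    clamp = {n: 0 for n in net.inputs}
    clamp.update({k: int(v) for k, v in partial.items()})
    return clamp


# --------------------------------------------------------------------------
# Scenario catalog
# --------------------------------------------------------------------------

def _catalog() -> dict:
    return yaml.safe_load(_data_text("scenarios.yaml"))


def builtin_scenarios() -> dict[str, dict[str, Scenario]]:
    """lean / obese / diabetic scenarios per cell type.

    The diabetic catalog is the obese one with high plasma ceramide added to
    every microenvironment.
    """
    cat = _catalog()
    out: dict[str, dict[str, Scenario]] = {}
    for context in ("lean", "obese"):
        out[context] = {}
        for cell, envs in cat[context].items():
            mes = tuple(Microenvironment(n, dict(c)) for n, c in envs.items())
            out[context][cell] = Scenario(context, cell, mes)
    out["diabetic"] = {}
    for cell, envs in cat["obese"].items():
        mes = tuple(Microenvironment(n + " + ceramide", {**c, "CERe": 1})
                    for n, c in envs.items())
        out["diabetic"][cell] = Scenario("diabetic", cell, mes)
    return out


def therapy_scenarios() -> dict[str, Scenario]:
    """Adipocyte therapy simulations under severe inflammation + insulin."""
    cat = _catalog()["therapies"]
    base = Microenvironment("severe inflammation", dict(cat["base_condition"]))
    out = {}
    for name, toggles in cat["treatments"].items():
        out[name] = Scenario(name, "adipocyte", (base,), dict(toggles),
                             insulin="present")
    return out


def run_scenario(scenario: Scenario,
                 proto: SimulationProtocol | None = None,
                 models: Mapping[str, tuple[BooleanNetwork, PhenotypeScheme]]
                 | None = None) -> ScenarioResult:
    """Simulate a scenario: per microenvironment x insulin setting,
    enumerate attractors under the clamp, estimate the phenotype chain and
    solve for the stationary distribution; return all of them plus the
    per-insulin and overall averages."""
    proto = proto or SimulationProtocol()
    models = models or load_builtin_models()
    if scenario.cell_type not in models:
        raise KeyError(f"scenario {scenario.name!r} references unknown cell "
                       f"type {scenario.cell_type!r}")
    net, scheme = models[scenario.cell_type]
    labels = tuple(scheme.labels) + (CYCLE_LABEL,)

    distributions: dict[tuple[str, int], DistributionResult] = {}
    for me in scenario.microenvironments:
        for ins in scenario.insulin_settings():
            partial = dict(me.clamp)
            partial["INS"] = ins
            partial.update(scenario.toggles)
            clamp = full_input_clamp(net, partial)
            try:
                system = AttractorSystem(net, clamp)
                m = estimate_markov(net, clamp, system, scheme, proto)
                d = stationary(m, tol=1e-12)
            except Exception as exc:
                raise RuntimeError(
                    f"scenario {scenario.name!r}, microenvironment "
                    f"{me.name!r}, insulin={ins}: {exc}") from exc
            distributions[(me.name, ins)] = align_distribution(d, labels)

    averages = {
        ins: average_distributions(
            [distributions[(me.name, ins)] for me in scenario.microenvironments])
        for ins in scenario.insulin_settings()
    }
    overall = average_distributions(list(averages.values()))
    return ScenarioResult(scenario=scenario, labels=labels,
                          distributions=distributions, averages=averages,
                          overall=overall)


# --------------------------------------------------------------------------
# Qualitative-validation grid
# --------------------------------------------------------------------------

def table1_trial_grid() -> dict:
    """The bundled qualitative-validation grid (conditions + relations)."""
    return yaml.safe_load(_data_text("table1_trials.yaml"))


def condition_distributions(cell_type: str,
                            proto: SimulationProtocol,
                            noise_levels: Sequence[float] = NOISE_LEVELS,
                            models=None
                            ) -> dict[tuple[str, float], DistributionResult]:
    """Stationary distributions for each validation-grid condition x noise."""
    models = models or load_builtin_models()
    net, scheme = models[cell_type]
    grid = table1_trial_grid()[cell_type]
    out: dict[tuple[str, float], DistributionResult] = {}
    for cname, partial in grid["conditions"].items():
        clamp = full_input_clamp(net, partial)
        system = AttractorSystem(net, clamp)
        for q in noise_levels:
            m = estimate_markov(net, clamp, system, scheme,
                                proto.with_noise(q))
            out[(cname, float(q))] = stationary(m)
    return out


def score_table1(proto: SimulationProtocol | None = None,
                 noise_levels: Sequence[float] = NOISE_LEVELS,
                 cell_types: Sequence[str] = CELL_TYPES, models=None
                 ) -> dict[str, tuple[list[QualitativeTrial], BinomialReport]]:
    """Re-run the full qualitative validation for the bundled models.

    Returns, per cell type, the scored trials (one per relation per noise
    level) and the one-tailed binomial report of successes vs chance.
    """
    proto = proto or SimulationProtocol()
    models = models or load_builtin_models()
    grid = table1_trial_grid()
    schemes = {c: models[c][1] for c in cell_types}
    out = {}
    for cell in cell_types:
        dists = condition_distributions(cell, proto, noise_levels, models)
        trials, report = score_trials(
            dists, grid[cell]["trials"],
            valid_labels=tuple(schemes[cell].labels) + (CYCLE_LABEL,))
        out[cell] = (trials, report)
    return out
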