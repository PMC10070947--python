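"""Phenotype-level Markov chains from noise-perturbed Boolean simulations.

The simulation protocol follows the stochastic perturbation scheme used for
the VAT models: at every time step, after the synchronous rules fire, each
free (non-clamped) node independently has its freshly computed value
complemented with probability ``noise`` (one uniform draw per node per
step).  Noise levels of 3%, 8% and 13% are used for robustness analysis,
with 8% as the working default; the full protocol runs 10000 steps and 30
trajectories per initial phenotype, repeated over 10 rounds whose
row-normalized transition matrices are averaged.

Every sampled trajectory state is mapped to an attractor by noise-free
relaxation (basin membership) and thence to a phenotype label; consecutive
label pairs are accumulated into transition counts.  Attractors sharing a
phenotype label are merged into one chain state before counting, so the
chain is over phenotypes, not attractors.  Rows with no observations become
self-loops, which keeps the matrix stochastic without inventing transitions.

Stationary distributions are obtained by iterating ``x <- P^T x`` until the
L1 change falls below tolerance, cross-checked against the dominant left
eigenvector of ``P``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import AttractorSystem
from .network import BooleanNetwork, Clamping, step
from .phenotypes import PhenotypeScheme, label_attractors

__all__ = [
    "SimulationProtocol", "MarkovModel", "DistributionResult",
    "noisy_step", "estimate_markov", "evolve", "stationary",
    "average_distributions", "NOISE_LEVELS",
]

#: Robustness-analysis noise levels (flip probability per node per step).
NOISE_LEVELS = (0.03, 0.08, 0.13)


@dataclass(frozen=True)
class SimulationProtocol:
    """Parameters of the noise-perturbation protocol.

    noise       : per-node per-step flip probability, in [0, 1).
    steps       : time steps per trajectory.
    iterations  : trajectories per initial phenotype (attractor).
    rounds      : protocol repetitions whose matrices are averaged.
    seed        : root seed; per-round/per-initial-condition streams are
                  spawned from it so runs are reproducible.
    label_every : trajectory sampling stride for attractor labeling.
    noisy_inputs: whether declared input nodes that are *not* clamped are
                  perturbed like any other free node (default True); clamped
                  nodes are always exempt — a microenvironment is a boundary
                  condition, not an intracellular variable.
    pooled      : estimate P from pooled counts over all rounds instead of
                  averaging per-round row-normalized matrices.
    """

    noise: float = 0.08
    steps: int = 10000
    iterations: int = 30
    rounds: int = 10
    seed: int | None = None
    label_every: int = 1
    noisy_inputs: bool = True
    pooled: bool = False

    def __post_init__(self):
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must be in [0, 1)")
        if min(self.steps, self.iterations, self.rounds) < 1:
            raise ValueError("steps, iterations and rounds must be >= 1")
        if self.label_every < 1:
            raise ValueError("label_every must be >= 1")

    def with_noise(self, noise: float) -> "SimulationProtocol":
        return replace(self, noise=noise)


#: Reduced protocol for test-scale runs (same estimator, smaller sample).
REDUCED_PROTOCOL = SimulationProtocol(steps=2000, iterations=10, rounds=3)


@dataclass(frozen=True)
class MarkovModel:
    """Phenotype-labelled transition counts and row-stochastic matrix."""

    labels: tuple[str, ...]
    counts: np.ndarray
    P: np.ndarray
    per_round_P: tuple[np.ndarray, ...] = ()

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.shape != (len(self.labels), len(self.labels)):
            raise ValueError("P shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if np.any(P < -1e-15) or np.any(P > 1 + 1e-12):
            raise ValueError("P entries must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of P must sum to 1")

    def to_csv(self, path_or_buf=None):
        """Label-indexed CSV export of the probability matrix."""
        df = pd.DataFrame(self.P, index=self.labels, columns=self.labels)
        return df.to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "MarkovModel":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        df = pd.read_csv(path_or_buf, index_col=0)
        labels = tuple(str(x) for x in df.index)
        P = df.to_numpy(dtype=float)
        return cls(labels=labels, counts=np.zeros_like(P), P=P)


@dataclass(frozen=True)
class DistributionResult:
    """A phenotype probability vector with its provenance."""

    labels: tuple[str, ...]
    pi: np.ndarray
    t_converged: int | None = None
    initial: np.ndarray | None = None
    unique: bool = True

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("probabilities must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {l: float(p) for l, p in zip(self.labels, self.pi)}

    def __getitem__(self, label: str) -> float:
        return self.as_dict()[label]

    def to_csv(self, path_or_buf=None):
        s = pd.Series(self.pi, index=self.labels, name="probability")
        s.index.name = "phenotype"
        return s.to_csv(path_or_buf)


# --------------------------------------------------------------------------
# Noisy stepping
# --------------------------------------------------------------------------

def noisy_step(net: BooleanNetwork, state: Sequence[int],
               clamp: Mapping[str, int] | None = None,
               noise: float = 0.08,
               rng: np.random.Generator | None = None) -> tuple[int, ...]:
    """One synchronous update with independent per-node complementation.

    Each free node's rule output is complemented with probability ``noise``;
    clamped nodes always keep their clamped value.
    """
    if not (0.0 <= noise < 1.0):
        raise ValueError("noise must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    clamp = clamp or {}
    base = step(net, state, clamp)
    out = list(base)
    for i, n in enumerate(net.nodes):
        if n in clamp:
            continue
        if noise > 0 and rng.random() < noise:
            out[i] = 1 - out[i]
    return tuple(out)


# --------------------------------------------------------------------------
# Transition-matrix estimation
# --------------------------------------------------------------------------

def estimate_markov(net: BooleanNetwork,
                    clamp: Mapping[str, int] | None,
                    system: AttractorSystem | Sequence | None,
                    scheme: PhenotypeScheme,
                    proto: SimulationProtocol) -> MarkovModel:
    """Estimate the phenotype-level transition matrix by noisy simulation.

    Every attractor of the clamped dynamics serves as an initial condition;
    per round, ``iterations`` trajectories of ``steps`` noisy steps are run
    from each, each sampled state is labeled by noise-free relaxation to its
    attractor and thence to its phenotype, and consecutive label pairs are
    counted.  Per-round row-normalized matrices are averaged into ``P``
    (or pooled counts are normalized once, with ``proto.pooled``).
    """
    if isinstance(system, AttractorSystem):
        sys_ = system
    else:
        sys_ = AttractorSystem(net, clamp, mode="exhaustive")
    clamp = Clamping(clamp or {}).validate(net)
    if not sys_.attractors:
        raise ValueError("no attractors to use as initial conditions")

    scheme = scheme.bind(net)
    attr_labels = label_attractors(sys_.attractors, scheme, net)
    named = set(p.label for p in scheme.patterns)
    if not named.intersection(attr_labels.values()):
        raise ValueError(
            f"no attractor carries a {scheme.cell_type!r} phenotype label; "
            f"got {sorted(set(attr_labels.values()))}")

    # Chain states: unique phenotype labels in attractor-id order
    labels: list[str] = []
    for aid in sorted(attr_labels):
        if attr_labels[aid] not in labels:
            labels.append(attr_labels[aid])
    label_index = {l: i for i, l in enumerate(labels)}
    k = len(labels)

    succ = sys_.successor_array()
    attr_of_rank = sys_.label_array()
    # rank -> chain-state index
    state_of_rank = np.array([label_index[attr_labels[a]]
                              for a in range(len(sys_.attractors))],
                             dtype=np.int64)[attr_of_rank]

    n_free = sys_.n_free
    bit_weights = (1 << np.arange(n_free)).astype(np.int64)
    if not proto.noisy_inputs:
        exempt = [i for i, n in enumerate(sys_.free_nodes) if n in net.inputs]
        bit_weights[exempt] = 0
    init_ranks = np.array([sys_.rank_of_state(a.states[0])
                           for a in sys_.attractors], dtype=np.int64)

    root = np.random.SeedSequence(proto.seed)
    round_seeds = root.spawn(proto.rounds)

    per_round_P: list[np.ndarray] = []
    total_counts = np.zeros((k, k), dtype=np.int64)
    for r in range(proto.rounds):
        rng = np.random.default_rng(round_seeds[r])
        counts = np.zeros((k, k), dtype=np.int64)
        states = np.repeat(init_ranks, proto.iterations)
        prev = state_of_rank[states]
        for t in range(1, proto.steps + 1):
            states = succ[states]
            if proto.noise > 0:
                flips = rng.random((states.size, n_free)) < proto.noise
                states = states ^ (flips @ bit_weights)
            if t % proto.label_every == 0:
                cur = state_of_rank[states]
                np.add.at(counts, (prev, cur), 1)
                prev = cur
        total_counts += counts
        per_round_P.append(_normalize_rows(counts))

    if proto.pooled:
        P = _normalize_rows(total_counts)
    else:
        P = np.mean(per_round_P, axis=0)
        P = P / P.sum(axis=1, keepdims=True)
    return MarkovModel(labels=tuple(labels), counts=total_counts, P=P,
                       per_round_P=tuple(per_round_P))


def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    """Row-normalize counts; zero-observation rows become self-loops."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1)
    P = np.eye(counts.shape[0])
    nz = sums > 0
    P[nz] = counts[nz] / sums[nz, None]
    return P


# --------------------------------------------------------------------------
# Time evolution and stationary distributions
# --------------------------------------------------------------------------

def _as_P(m) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(m, MarkovModel):
        return np.asarray(m.P, dtype=float), m.labels
    P = np.asarray(m, dtype=float)
    return P, tuple(str(i) for i in range(P.shape[0]))


def _check_x0(x0, k: int) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (k,):
        raise ValueError(f"initial vector has length {x0.size}, expected {k}")
    if np.any(x0 < 0) or abs(x0.sum() - 1.0) > 1e-9:
        raise ValueError("initial vector must be a probability distribution")
    return x0


def evolve(m, x0, t: int) -> DistributionResult:
    """Iterated ``x <- P^T x`` for ``t`` steps (the transpose-matrix power
    acting on a column of phenotype probabilities)."""
    P, labels = _as_P(m)
    x = _check_x0(x0, P.shape[0]).copy()
    A = P.T
    for _ in range(int(t)):
        x = A @ x
    return DistributionResult(labels=labels, pi=x, t_converged=int(t),
                              initial=np.asarray(x0, dtype=float))


def stationary(m, x0=None, tol: float = 1e-12, max_t: int = 10 ** 6,
               cesaro: bool = False) -> DistributionResult:
    """Stationary distribution by power iteration on ``P^T``.

    Iterates until successive vectors differ by less than ``tol`` in L1 and
    cross-checks the result against the dominant left eigenvector of ``P``.
    For reducible chains the limit depends on ``x0``; this is detected (unit
    eigenvalue multiplicity > 1) and flagged via ``unique=False``.  Periodic
    chains do not converge pointwise; pass ``cesaro=True`` to return the
    running time-average (Cesaro) limit instead.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    P, labels = _as_P(m)
    k = P.shape[0]
    x = _check_x0(x0, k) if x0 is not None else np.full(k, 1.0 / k)
    A = P.T

    eigvals = np.linalg.eigvals(P)
    n_unit = int(np.sum(np.abs(eigvals - 1.0) < 1e-8))
    unique = n_unit <= 1

    if cesaro:
        # Cesaro averages approach stationarity only as O(1/t); stop on the
        # stationarity residual |avg P - avg|_1 rather than successive change.
        avg = x.copy()
        for t in range(1, int(max_t) + 1):
            x = A @ x
            avg = (avg * t + x) / (t + 1)
            if np.abs(avg @ P - avg).sum() < max(tol, 1e-9):
                return DistributionResult(labels, avg / avg.sum(),
                                          t, None, unique)
        raise RuntimeError(f"Cesaro average did not converge in {max_t} steps")

    for t in range(1, int(max_t) + 1):
        x_new = A @ x
        if np.abs(x_new - x).sum() < tol:
            pi = x_new / x_new.sum()
            _crosscheck_eigenvector(P, pi, unique)
            return DistributionResult(labels, pi, t,
                                      x0 if x0 is None else np.asarray(x0, float),
                                      unique)
        x = x_new
    raise RuntimeError(
        f"power iteration did not converge in {max_t} steps; the chain may "
        f"be periodic — retry with cesaro=True")


def _crosscheck_eigenvector(P: np.ndarray, pi: np.ndarray, unique: bool) -> None:
    """Independent check: pi must be a left eigenvector of P for eigenvalue 1."""
    resid = np.abs(pi @ P - pi).sum()
    if resid > 1e-8:
        raise RuntimeError(f"stationary cross-check failed: |pi P - pi|_1 = {resid:.2e}")
    if unique:
        w, v = np.linalg.eig(P.T)
        i = int(np.argmax(w.real))
        lead = np.abs(v[:, i].real)
        lead = lead / lead.sum()
        if np.abs(lead - pi).sum() > 1e-6:
            raise RuntimeError("stationary distribution disagrees with the "
                               "dominant left eigenvector")


def average_distributions(results: Sequence[DistributionResult],
                          weights: Sequence[float] | None = None
                          ) -> DistributionResult:
    """Weighted mean of distributions over microenvironments.

    This is the in-silico analog of measuring a tissue-level mixture: the
    individual microenvironments cannot be observed separately in the lab,
    so their predicted phenotype frequencies are averaged.
    """
    if not results:
        raise ValueError("no distributions to average")
    labels = results[0].labels
    for r in results[1:]:
        if r.labels != labels:
            raise ValueError(f"label sets differ: {r.labels} vs {labels}")
    if weights is None:
        weights = np.full(len(results), 1.0 / len(results))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(results),):
            raise ValueError("one weight per distribution required")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative and not all zero")
        weights = weights / weights.sum()
    pi = np.sum([w * r.pi for w, r in zip(weights, results)], axis=0)
    pi = pi / pi.sum()
    return DistributionResult(labels=labels, pi=pi)


def align_distribution(result: DistributionResult,
                       labels: Sequence[str]) -> DistributionResult:
    """Re-express a distribution over a superset label ordering (absent
    labels get probability 0) so distributions from different clampings can
    be averaged."""
    d = result.as_dict()
    unknown = sorted(set(d) - set(labels))
    if unknown:
        raise ValueError(f"distribution has labels outside the target set: {unknown}")
    pi = np.array([d.get(l, 0.0) for l in labels], dtype=float)
    return DistributionResult(labels=tuple(labels), pi=pi,
                              t_converged=result.t_converged,
                              unique=result.unique)
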