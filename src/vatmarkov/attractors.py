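"""Attractors and basins of attraction of clamped synchronous Boolean dynamics.

The central object is :class:`AttractorSystem`, which fixes a network and a
clamping and exposes the dynamics over the *free* (non-clamped) nodes.  Free
states are ranked as integers (bit ``i`` of the rank is the value of the
``i``-th free node, in network declaration order), which makes exhaustive
work a set of numpy array operations:

* the successor array ``succ[r]`` gives the synchronous image of every free
  state at once (rules are evaluated vectorized over the whole state space);
* attractors (fixed points and cycles) are found by pointer doubling on the
  successor array, basins by a single gather + bincount.

Exhaustive mode is exact for networks of up to ``max_free_nodes`` free nodes
(default cap 20, i.e. about a million states); beyond that, ``sampled`` mode
relaxes a seeded random sample of initial states and reports estimated basin
fractions.  Attractor ids are assigned deterministically by the smallest
state rank contained in the attractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import BooleanNetwork, Clamping

__all__ = ["Attractor", "AttractorSystem", "find_attractors", "relax",
           "attractor_table"]

DEFAULT_NODE_CAP = 20
DEFAULT_SAMPLES = 5000


@dataclass(frozen=True)
class Attractor:
    """A fixed point (one state) or cycle (several) of the clamped dynamics.

    ``states`` are full-node tuples in network node order, with clamped
    values filled in; cycles are rotated to start at their smallest-rank
    state.  ``basin_size`` is an exact state count in exhaustive mode;
    ``basin_fraction`` is the (estimated, in sampled mode) share of the free
    state space that relaxes to this attractor.
    """

    id: int
    states: tuple[tuple[int, ...], ...]
    basin_size: int | None = None
    basin_fraction: float | None = None

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @property
    def period(self) -> int:
        return len(self.states)

    def state_map(self, nodes: Sequence[str]) -> dict[str, int]:
        """Node -> value for fixed points (first state for cycles)."""
        return dict(zip(nodes, self.states[0]))

    def mean_state(self) -> np.ndarray:
        return np.mean(self.states, axis=0)


class AttractorSystem:
    """Clamped synchronous dynamics of one network, with attractor registry.

    In exhaustive mode the full successor array and a state->attractor label
    array are precomputed, making :meth:`relax` an O(1) lookup — this is what
    lets noisy trajectories of millions of steps be labeled cheaply.  In
    sampled mode relaxation walks trajectories with visited-state cycle
    detection and registers previously unseen attractors on the fly.
    """

    def __init__(self, net: BooleanNetwork, clamp: Mapping[str, int] | None = None,
                 mode: str = "exhaustive", n_samples: int = DEFAULT_SAMPLES,
                 seed: int | None = 0, max_free_nodes: int = DEFAULT_NODE_CAP):
        if mode not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown mode {mode!r}")
        self.net = net
        self.clamp = Clamping(clamp or {}).validate(net)
        self.mode = mode
        self.free_nodes = tuple(n for n in net.nodes if n not in self.clamp)
        self.n_free = len(self.free_nodes)
        self._free_idx = {n: i for i, n in enumerate(self.free_nodes)}
        self.attractors: list[Attractor] = []
        self._attr_of_cycle_rank: dict[int, int] = {}
        self._succ: np.ndarray | None = None
        self._label: np.ndarray | None = None

        if mode == "exhaustive":
            if self.n_free > max_free_nodes:
                raise ValueError(
                    f"exhaustive enumeration needs <= {max_free_nodes} free nodes "
                    f"({self.n_free} here); use mode='sampled'")
            self._build_exhaustive()
        else:
            self._sample(n_samples, seed)

    # -- state encoding ---------------------------------------------------

    def rank_of_state(self, state: Sequence[int]) -> int:
        """Free-bit integer rank of a full-node state."""
        r = 0
        for i, n in enumerate(self.free_nodes):
            if state[self.net.index(n)]:
                r |= 1 << i
        return r

    def state_of_rank(self, rank: int) -> tuple[int, ...]:
        """Full-node state tuple (clamped bits filled) for a free rank."""
        out = []
        for n in self.net.nodes:
            if n in self.clamp:
                out.append(int(self.clamp[n]))
            else:
                out.append((rank >> self._free_idx[n]) & 1)
        return tuple(out)

    def _env_from_ranks(self, ranks: np.ndarray) -> dict[str, np.ndarray]:
        env: dict[str, np.ndarray] = {}
        for n in self.net.nodes:
            if n in self.clamp:
                env[n] = np.full(ranks.shape, bool(self.clamp[n]))
            else:
                env[n] = ((ranks >> self._free_idx[n]) & 1).astype(bool)
        return env

    def successor_ranks(self, ranks: np.ndarray) -> np.ndarray:
        """Vectorized synchronous step on an array of free ranks."""
        if self._succ is not None:
            return self._succ[ranks]
        env = self._env_from_ranks(np.asarray(ranks))
        out = np.zeros(np.shape(ranks), dtype=np.int64)
        for i, n in enumerate(self.free_nodes):
            out |= net_eval(self.net, n, env).astype(np.int64) << i
        return out

    # -- exhaustive enumeration -------------------------------------------

    def _build_exhaustive(self) -> None:
        size = 1 << self.n_free
        ranks = np.arange(size, dtype=np.int64)
        succ = self.successor_ranks(ranks)
        self._succ = succ

        # Pointer doubling: succ^(2^n_free) maps every state into its cycle,
        # since no transient is longer than the state space.
        reach = succ.copy()
        for _ in range(max(self.n_free, 1)):
            reach = reach[reach]

        in_cycle = np.full(size, -1, dtype=np.int64)
        cycles: list[list[int]] = []
        for u in np.unique(reach):
            if in_cycle[u] >= 0:
                continue
            cyc = [int(u)]
            v = int(succ[u])
            while v != u:
                cyc.append(v)
                v = int(succ[v])
            cid = len(cycles)
            for s in cyc:
                in_cycle[s] = cid
            cycles.append(cyc)

        order = sorted(range(len(cycles)), key=lambda c: min(cycles[c]))
        remap = {old: new for new, old in enumerate(order)}
        label = np.array([remap[c] for c in range(len(cycles))],
                         dtype=np.int64)[in_cycle[reach]]
        self._label = label
        basins = np.bincount(label, minlength=len(cycles))

        self.attractors = []
        for new_id, old in enumerate(order):
            cyc = cycles[old]
            start = cyc.index(min(cyc))
            rot = cyc[start:] + cyc[:start]
            states = tuple(self.state_of_rank(r) for r in rot)
            self.attractors.append(Attractor(
                id=new_id, states=states, basin_size=int(basins[new_id]),
                basin_fraction=float(basins[new_id]) / size))
            for r in rot:
                self._attr_of_cycle_rank[r] = new_id

    # -- sampled mode ------------------------------------------------------

    def _sample(self, n_samples: int, seed: int | None) -> None:
        rng = np.random.default_rng(seed)
        hits: dict[int, int] = {}
        for _ in range(n_samples):
            r = int(rng.integers(0, 1 << min(self.n_free, 62)))
            aid = self.relax_rank(r)
            hits[aid] = hits.get(aid, 0) + 1
        # reorder deterministically by smallest contained rank
        order = sorted(range(len(self.attractors)),
                       key=lambda i: min(self.rank_of_state(s)
                                         for s in self.attractors[i].states))
        remap = {old: new for new, old in enumerate(order)}
        new_attrs = []
        for old_id in order:
            a = self.attractors[old_id]
            new_attrs.append(Attractor(
                id=remap[old_id], states=a.states,
                basin_fraction=hits.get(old_id, 0) / n_samples))
        self.attractors = new_attrs
        self._attr_of_cycle_rank = {r: remap[a]
                                    for r, a in self._attr_of_cycle_rank.items()}

    # -- relaxation --------------------------------------------------------

    def relax_rank(self, rank: int, max_steps: int | None = None) -> int:
        """Attractor id reached from a free rank under noise-free dynamics.

        With the exhaustive label array this is a lookup; otherwise the
        trajectory is walked with visited-state cycle detection, and a
        previously unseen attractor is registered with a fresh id.
        """
        if self._label is not None:
            return int(self._label[rank])
        seen: dict[int, int] = {}
        path: list[int] = []
        r = int(rank)
        steps = 0
        while True:
            if r in self._attr_of_cycle_rank:
                return self._attr_of_cycle_rank[r]
            if r in seen:
                cyc = path[seen[r]:]
                start = cyc.index(min(cyc))
                rot = cyc[start:] + cyc[:start]
                aid = len(self.attractors)
                self.attractors.append(Attractor(
                    id=aid,
                    states=tuple(self.state_of_rank(x) for x in rot)))
                for x in rot:
                    self._attr_of_cycle_rank[x] = aid
                return aid
            seen[r] = len(path)
            path.append(r)
            r = int(self.successor_ranks(np.array([r]))[0])
            steps += 1
            if max_steps is not None and steps > max_steps:
                raise RuntimeError(f"no attractor within {max_steps} steps")

    def relax(self, state: Sequence[int], max_steps: int | None = None) -> int:
        return self.relax_rank(self.rank_of_state(state), max_steps=max_steps)

    def label_array(self) -> np.ndarray:
        """state rank -> attractor id over the whole free space (exhaustive)."""
        if self._label is None:
            raise ValueError("label array requires exhaustive mode")
        return self._label

    def successor_array(self) -> np.ndarray:
        if self._succ is None:
            raise ValueError("successor array requires exhaustive mode")
        return self._succ


def net_eval(net: BooleanNetwork, node: str, env) -> np.ndarray:
    """Evaluate one node's rule on an environment of boolean arrays."""
    return np.asarray(net.rules[node].eval(env))


def find_attractors(net: BooleanNetwork, clamp: Mapping[str, int] | None = None,
                    mode: str = "exhaustive", n_samples: int = DEFAULT_SAMPLES,
                    seed: int | None = 0,
                    max_free_nodes: int = DEFAULT_NODE_CAP) -> list[Attractor]:
    """Enumerate attractors; exhaustive mode reports exact basin sizes."""
    return AttractorSystem(net, clamp, mode=mode, n_samples=n_samples,
                           seed=seed, max_free_nodes=max_free_nodes).attractors


def relax(net: BooleanNetwork, state: Sequence[int],
          clamp: Mapping[str, int] | None = None,
          max_steps: int | None = None,
          system: AttractorSystem | None = None) -> int:
    """Attractor id reached from ``state``; builds a sampled-mode registry
    when no :class:`AttractorSystem` is supplied."""
    if system is None:
        system = AttractorSystem(net, clamp, mode="sampled", n_samples=0)
    return system.relax(state, max_steps=max_steps)


def attractor_table(system: AttractorSystem,
                    labels: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Attractor export: id, phenotype, basin size, then one column per node.

    Fixed points show 0/1 per node; cycles show ``mean (period k)`` entries.
    """
    rows = []
    for a in system.attractors:
        row: dict[str, object] = {
            "id": a.id,
            "phenotype": (labels or {}).get(a.id, ""),
            "basin_size": a.basin_size if a.basin_size is not None else "",
            "basin_fraction": (round(a.basin_fraction, 6)
                               if a.basin_fraction is not None else ""),
            "period": a.period,
        }
        if a.is_fixed_point:
            row.update(zip(system.net.nodes, a.states[0]))
        else:
            mean = a.mean_state()
            row.update({n: f"{m:.2f}" for n, m in zip(system.net.nodes, mean)})
        rows.append(row)
    return pd.DataFrame(rows)
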