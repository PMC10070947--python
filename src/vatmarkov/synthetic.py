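"""Random Boolean networks and canned toy fixtures.

Every pipeline stage is testable without any external data: the generator
emits seeded random networks in the standard rule dialect, and ``fixtures``
returns tiny networks whose attractors and Markov chains are known in
closed form (a single self-sustaining bit, whose noisy chain is exactly
[[1-q, q], [q, 1-q]]; the two-node toggle switch; a three-node input-driven
chain; and an eight-state "mini-adipocyte" realizing every marker
combination of the adipocyte phenotype scheme).

Random rules are truth-table based — each node draws a random k-input truth
table whose entries are 1 with probability ``bias`` — then rendered to
expressions by minterm expansion, which keeps the bias exact rather than
approximating it through an expression grammar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, parse_network

__all__ = ["RandomNetworkSpec", "generate_random_network", "fixtures"]


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Shape of a random network: node count, in-degree, truth-table bias."""

    n_nodes: int
    k_in: int | tuple[int, int] = 2
    bias: float = 0.5
    n_inputs: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        k = self.k_in if isinstance(self.k_in, int) else max(self.k_in)
        if k > self.n_nodes:
            raise ValueError("k_in cannot exceed n_nodes")
        if not (0.0 <= self.bias <= 1.0):
            raise ValueError("bias must be in [0, 1]")
        if not (0 <= self.n_inputs <= self.n_nodes):
            raise ValueError("n_inputs out of range")


def _node_name(i: int) -> str:
    # A..Z, then N26, N27, ...
    return chr(ord("A") + i) if i < 26 else f"N{i}"


def _minterm_expression(regs: list[str], table: np.ndarray) -> str:
    """Render a truth table over ``regs`` as a sum of minterms."""
    if table.all():
        return "1"
    if not table.any():
        return "0"
    terms = []
    for row, out in enumerate(table):
        if not out:
            continue
        lits = []
        for j, r in enumerate(regs):
            lits.append(r if (row >> j) & 1 else f"! {r}")
        terms.append(" & ".join(lits) if len(lits) == 1
                     else "(" + " & ".join(lits) + ")")
    return " | ".join(terms)


def generate_random_network(spec: RandomNetworkSpec) -> BooleanNetwork:
    """Generate a seeded random network in the standard rule dialect.

    The first ``n_inputs`` nodes get the constant self-rule ``X = X`` and
    are declared inputs.  The emitted text round-trips through
    ``parse_network``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [_node_name(i) for i in range(spec.n_nodes)]
    lines = ["targets, factors"]
    for i, name in enumerate(names):
        if i < spec.n_inputs:
            lines.append(f"{name}, {name}")
            continue
        if isinstance(spec.k_in, int):
            k = spec.k_in
        else:
            lo, hi = spec.k_in
            k = int(rng.integers(lo, hi + 1))
        regs = [names[j] for j in sorted(rng.choice(spec.n_nodes, size=k,
                                                    replace=False))]
        table = rng.random(1 << k) < spec.bias
        lines.append(f"{name}, {_minterm_expression(regs, table)}")
    text = "\n".join(lines) + "\n"
    return parse_network(text, name=f"random-{spec.seed}")


# --------------------------------------------------------------------------
# Canned fixtures
# --------------------------------------------------------------------------

_SINGLE_BIT = """\
targets, factors
A, A
"""

_TOGGLE = """\
targets, factors
A, ! B
B, ! A
"""

# One environmental input driving a two-step relay: exactly one attractor
# per clamping of S.
_CHAIN3 = """\
targets, factors
S, S
M, S
G, M
"""

# Three marker genes with independent memory: all 8 marker combinations are
# fixed points, one per phenotype name of the adipocyte scheme.  The nodes
# are deliberately NOT declared inputs so that noise drives transitions.
_MINI_ADIPOCYTE = """\
targets, factors
TNF, TNF
CTGF, CTGF
GLUT4, GLUT4
"""


def fixtures() -> dict[str, BooleanNetwork]:
    """Named toy networks with brute-force-known behavior."""
    return {
        "single_bit": parse_network(_SINGLE_BIT, name="single_bit"),
        "toggle": parse_network(_TOGGLE, name="toggle"),
        "chain3": parse_network(_CHAIN3, name="chain3"),
        "mini_adipocyte": parse_network(_MINI_ADIPOCYTE, name="mini_adipocyte",
                                        inputs=()),
    }


def _tamper_check() -> None:
    """Assert fixture truth tables at import (hard-coded expectations)."""
    from .network import step

    toggle = parse_network(_TOGGLE, name="toggle")
    assert step(toggle, (0, 1)) == (0, 1)
    assert step(toggle, (1, 0)) == (1, 0)
    assert step(toggle, (0, 0)) == (1, 1)
    assert step(toggle, (1, 1)) == (0, 0)

    single = parse_network(_SINGLE_BIT, name="single_bit")
    assert step(single, (0,)) == (0,)
    assert step(single, (1,)) == (1,)

    chain3 = parse_network(_CHAIN3, name="chain3")
    assert step(chain3, (1, 0, 0)) == (1, 1, 0)
    assert step(chain3, (1, 1, 0)) == (1, 1, 1)
    assert step(chain3, (0, 1, 1)) == (0, 0, 1)

    mini = parse_network(_MINI_ADIPOCYTE, name="mini_adipocyte", inputs=())
    for s in ((0, 0, 0), (1, 0, 1), (1, 1, 1)):
        assert step(mini, s) == s


_tamper_check()
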