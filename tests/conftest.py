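import itertools

import pytest

import vatmarkov as vm


@pytest.fixture(scope="session")
def toys():
    return vm.fixtures()


@pytest.fixture()
def toggle(toys):
    return toys["toggle"]


@pytest.fixture()
def single_bit(toys):
    return toys["single_bit"]


@pytest.fixture(scope="session")
def schemes():
    return vm.builtin_schemes()


@pytest.fixture(scope="session")
def vat_models():
    from vatmarkov import vat
    return vat.load_builtin_models()


# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain trajectory walking over all 2^n
# states with the scalar `step`, no successor arrays, no pointer doubling.
# ---------------------------------------------------------------------------

def brute_force_attractors(net, clamp=None):
    """Return (attractors, assignment): attractors as a sorted list of
    state-tuples cycles (rotated to smallest state), assignment mapping each
    full state tuple to its attractor index, basins as counts."""
    clamp = clamp or {}
    free = [n for n in net.nodes if n not in clamp]
    free_pos = [i for i, n in enumerate(net.nodes) if n not in clamp]

    def rank(state):
        # integer rank: bit i is the value of the i-th free node
        return sum(state[p] << i for i, p in enumerate(free_pos))

    def all_states():
        for bits in itertools.product((0, 1), repeat=len(free)):
            s = []
            it = iter(bits)
            for n in net.nodes:
                s.append(int(clamp[n]) if n in clamp else next(it))
            yield tuple(s)

    cycles: list[tuple] = []
    cycle_index: dict[tuple, int] = {}
    assignment: dict[tuple, int] = {}
    for s0 in all_states():
        path = []
        seen = {}
        s = s0
        while True:
            if s in cycle_index:
                idx = cycle_index[s]
                break
            if s in seen:
                cyc = path[seen[s]:]
                k = min(range(len(cyc)), key=lambda j: rank(cyc[j]))
                cyc = tuple(cyc[k:] + cyc[:k])
                idx = len(cycles)
                cycles.append(cyc)
                for c in cyc:
                    cycle_index[c] = idx
                break
            seen[s] = len(path)
            path.append(s)
            s = vm.step(net, s, clamp)
        for p in path:
            assignment[p] = idx

    order = sorted(range(len(cycles)), key=lambda i: rank(cycles[i][0]))
    remap = {old: new for new, old in enumerate(order)}
    cycles = [cycles[i] for i in order]
    assignment = {s: remap[i] for s, i in assignment.items()}
    basins = [0] * len(cycles)
    for s, i in assignment.items():
        basins[i] += 1
    return cycles, assignment, basins


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_attractors
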