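import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vatmarkov as vm
from vatmarkov.attractors import Attractor
from vatmarkov.phenotypes import CYCLE_LABEL, Pattern, SchemeError


def _fp(net, **values):
    """Build a fixed-point Attractor with the given marker values (rest 0)."""
    state = tuple(values.get(n, 0) for n in net.nodes)
    return Attractor(id=0, states=(state,))


@pytest.fixture()
def marker_net():
    # a bare marker network: every scheme node is present and free
    nodes = ["TBET", "GATA3", "RORGT", "PU1", "FOXP3", "IFNG", "IL4", "IL9",
             "IL17", "IL10", "TGFB", "INOS", "ARG1", "IL12", "TNF", "CTGF",
             "GLUT4"]
    text = "targets, factors\n" + "\n".join(f"{n}, {n}" for n in nodes)
    return vm.parse_network(text, inputs=())


class TestBuiltinSchemes:
    def test_m1_macrophage(self, marker_net, schemes):
        a = _fp(marker_net, INOS=1)
        assert vm.classify_attractor(a, schemes["macrophage"], marker_net) == "M1"

    def test_m2_tam_inos_arg1_coexpression(self, marker_net, schemes):
        a = _fp(marker_net, INOS=1, ARG1=1)
        assert vm.classify_attractor(a, schemes["macrophage"], marker_net) == "M2-TAM"

    def test_m1_tam_needs_il12_or_ifng(self, marker_net, schemes):
        for extra in ({"IL12": 1}, {"IFNG": 1}):
            a = _fp(marker_net, INOS=1, ARG1=1, **extra)
            assert vm.classify_attractor(a, schemes["macrophage"],
                                         marker_net) == "M1-TAM"

    def test_m0_all_markers_off(self, marker_net, schemes):
        a = _fp(marker_net)
        assert vm.classify_attractor(a, schemes["macrophage"], marker_net) == "M0"

    def test_th0_all_zero(self, marker_net, schemes):
        a = _fp(marker_net)
        assert vm.classify_attractor(a, schemes["CD4T"], marker_net) == "Th0"

    def test_itreg_foxp3_il10_tgfb(self, marker_net, schemes):
        a = _fp(marker_net, FOXP3=1, IL10=1, TGFB=1)
        assert vm.classify_attractor(a, schemes["CD4T"], marker_net) == "iTreg"

    @pytest.mark.parametrize("values, label", [
        ({"FOXP3": 1, "IFNG": 1}, "Th1R"),
        ({"FOXP3": 1, "IL4": 1}, "Th2R"),
        ({"IL10": 1}, "Tr1"),
        ({"TGFB": 1}, "Th3"),
        ({"TBET": 1, "IFNG": 1}, "Th1"),
        ({"GATA3": 1, "IL4": 1}, "Th2"),
        ({"PU1": 1, "IL9": 1}, "Th9"),
        ({"RORGT": 1, "IL17": 1}, "Th17"),
    ])
    def test_cd4_lineages(self, marker_net, schemes, values, label):
        a = _fp(marker_net, **values)
        assert vm.classify_attractor(a, schemes["CD4T"], marker_net) == label

    def test_adipocyte_glut4_positive(self, marker_net, schemes):
        a = _fp(marker_net, GLUT4=1)
        assert vm.classify_attractor(a, schemes["adipocyte"],
                                     marker_net) == "TNF- CTGF- GLUT4+"

    def test_adipocyte_all_negative_label(self, marker_net, schemes):
        a = _fp(marker_net)
        assert vm.classify_attractor(a, schemes["adipocyte"],
                                     marker_net) == "GLUT4- CTGF- TNF-"

    def test_adipocyte_covers_all_eight_combinations(self, marker_net, schemes):
        labels = set()
        for tnf in (0, 1):
            for ctgf in (0, 1):
                for g in (0, 1):
                    a = _fp(marker_net, TNF=tnf, CTGF=ctgf, GLUT4=g)
                    labels.add(vm.classify_attractor(a, schemes["adipocyte"],
                                                     marker_net))
        assert len(labels) == 8


class TestSchemeMechanics:
    def test_first_match_wins_is_order_dependent(self, marker_net):
        s1 = vm.PhenotypeScheme("x", (Pattern("both", {"INOS": 1, "ARG1": 1}),
                                      Pattern("ino", {"INOS": 1})))
        s2 = vm.PhenotypeScheme("x", (Pattern("ino", {"INOS": 1}),
                                      Pattern("both", {"INOS": 1, "ARG1": 1})))
        a = _fp(marker_net, INOS=1, ARG1=1)
        assert vm.classify_attractor(a, s1, marker_net) == "both"
        assert vm.classify_attractor(a, s2, marker_net) == "ino"

    def test_labels_stable_under_attractor_enumeration_order(self, marker_net,
                                                             schemes):
        # permuting which attractor is classified first never changes labels
        states = [{"INOS": 1}, {"ARG1": 1}, {"INOS": 1, "ARG1": 1}, {}]
        expected = ["M1", "M2", "M2-TAM", "M0"]
        for order in ([0, 1, 2, 3], [3, 2, 1, 0], [2, 0, 3, 1]):
            got = [vm.classify_attractor(_fp(marker_net, **states[i]),
                                         schemes["macrophage"], marker_net)
                   for i in order]
            assert got == [expected[i] for i in order]

    def test_fallback_for_unmatched_state(self, marker_net, schemes):
        a = _fp(marker_net, IFNG=1)  # IFN-g alone matches no CD4 pattern
        assert vm.classify_attractor(a, schemes["CD4T"],
                                     marker_net) == "unclassified"

    def test_bind_rejects_missing_marker_at_load_time(self, toggle, schemes):
        with pytest.raises(SchemeError, match="INOS"):
            schemes["macrophage"].bind(toggle)

    def test_bind_applies_alias_map(self, schemes):
        net = vm.parse_network(
            "targets, factors\n" + "\n".join(
                f"{n}, {n}" for n in ["iNOS", "Arg1", "IL12p", "IFNgamma"]),
            inputs=())
        bound = schemes["macrophage"].bind(net, aliases={
            "INOS": "iNOS", "ARG1": "Arg1", "IL12": "IL12p",
            "IFNG": "IFNgamma"})
        a = _fp(net, iNOS=1)
        assert vm.classify_attractor(a, bound, net) == "M1"

    def test_cycle_gets_cycle_label_by_default(self, toggle, schemes):
        cyc = next(a for a in vm.find_attractors(toggle)
                   if not a.is_fixed_point)
        scheme = vm.PhenotypeScheme("t", (Pattern("on", {"A": 1}),))
        assert vm.classify_attractor(cyc, scheme, toggle) == CYCLE_LABEL

    def test_cycle_mean_policy(self, toggle):
        cyc = next(a for a in vm.find_attractors(toggle)
                   if not a.is_fixed_point)
        scheme = vm.PhenotypeScheme("t", (Pattern("half-on", {"A": 1}),))
        # cycle mean (0.5, 0.5) rounds up to 1
        assert vm.classify_attractor(cyc, scheme, toggle,
                                     cycle_policy="mean") == "half-on"

    def test_yaml_round_trip(self, schemes):
        s = schemes["macrophage"]
        again = vm.load_scheme(s.to_yaml())
        assert again == s


class TestDiscretize:
    def test_worked_example(self):
        m = pd.DataFrame([[1, 2, 3, 6]], index=["g"],
                         columns=list("abcd"))
        d = vm.discretize(m)
        assert d.bits.loc["g"].tolist() == [0, 0, 1, 1]
        assert d.gene_means["g"] == 3

    def test_constant_row_is_all_ones(self):
        m = pd.DataFrame([[5, 5, 5]], index=["g"], columns=list("abc"))
        assert vm.discretize(m).bits.loc["g"].tolist() == [1, 1, 1]

    def test_random_matrix_row_counts_match_independent_check(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.gamma(2.0, 50.0, size=(100, 10)))
        d = vm.discretize(m)
        for i in range(100):
            row = m.iloc[i].to_numpy()
            assert d.bits.iloc[i].sum() == int((row >= row.mean()).sum())

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="non-negative"):
            vm.discretize(pd.DataFrame([[-1.0, 2.0]]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            vm.discretize(pd.DataFrame(index=["g"]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1), min_size=4, max_size=4),
                    min_size=1, max_size=8))
    def test_idempotent_on_bits_with_interior_row_means(self, rows):
        m = pd.DataFrame(rows, dtype=float)
        mixed = m[(m.mean(axis=1) > 0) & (m.mean(axis=1) < 1)]
        if mixed.empty:
            return
        d = vm.discretize(mixed)
        assert (d.bits.to_numpy() == mixed.to_numpy()).all()
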