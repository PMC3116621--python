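"""Micro-state enumeration, reaction topology and detailed balance."""

import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptsei as P
from ptsei.cycle_network import (
    SubunitState,
    enumerate_states,
    state_from_label,
    wegscheider_basis,
    apparent_constants,
    export_sharing_map,
)


class TestStates:
    def test_pool_census(self):
        states = enumerate_states()
        assert len(states) == 27
        census = Counter(s.pool for s in states)
        assert census == {"Y": 3, "YP": 3, "Z": 6, "ZP": 9, "ZP2": 6}

    def test_contains_pep_bound_monomer(self):
        # the EI-with-bound-PEP monomer appears explicitly
        assert state_from_label("Y(e)") in enumerate_states()

    @given(
        st.tuples(
            st.tuples(st.booleans(), st.sampled_from(["none", "PEP", "Pyr"])),
            st.tuples(st.booleans(), st.sampled_from(["none", "PEP", "Pyr"])),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dimer_canonicalization_symmetric(self, cfgs):
        (p1, l1), (p2, l2) = cfgs
        a = P.EnzymeState("dimer", (SubunitState(p1, l1), SubunitState(p2, l2)))
        b = P.EnzymeState("dimer", (SubunitState(p2, l2), SubunitState(p1, l1)))
        assert a == b and hash(a) == hash(b)

    def test_monomer_subunit_count_enforced(self):
        with pytest.raises(ValueError):
            P.EnzymeState("monomer", (SubunitState(False, "none"),) * 2)


class TestTopology:
    def test_reaction_kind_census(self, network):
        census = Counter(r.kind for r in network.reactions)
        assert census == {
            "ligand_binding": 28,
            "dimerization": 21,
            "phosphorylation": 6,
            "hpr_transfer": 21,
        }

    def test_dimerization_families(self, network):
        dim = network.reactions_of_kind("dimerization")
        by_pool = Counter(r.reactants[0].pool for r in dim)
        # 6 unphosphorylated, 6 doubly phosphorylated, 9 mixed dissociations
        assert by_pool == {"Z": 6, "ZP2": 6, "ZP": 9}

    def test_every_reaction_balances(self, network):
        for r in network.reactions:
            r.check_balance()

    def test_reversibility_convention(self, network):
        # binding steps are quasi-equilibrated: no rate constant
        for r in network.reactions:
            if r.kind == "ligand_binding":
                assert r.k_id is None
            else:
                assert r.k_id is not None
            assert r.statistical_factor in (1, 2)

    def test_parameter_id_counts(self, network):
        assert len(network.K_ids) == 63
        assert len(network.k_ids) == 46
        assert len(network.Ea_ids) == 25

    def test_variant_masks_only_touch_transfer(self):
        nets = {v: P.build_network(v) for v in P.VARIANTS}
        for v, net in nets.items():
            non_transfer = Counter(
                r.kind for r in net.reactions if r.kind != "hpr_transfer"
            )
            assert non_transfer == {
                "ligand_binding": 28, "dimerization": 21, "phosphorylation": 6
            }
        donors = lambda net: {
            r.reactants[0].pool for r in net.reactions_of_kind("hpr_transfer")
        }
        assert donors(nets["monomer_only"]) == {"YP"}
        assert donors(nets["zp2_only"]) == {"ZP2"}
        assert donors(nets["zp_and_zp2"]) == {"ZP", "ZP2"}
        assert donors(nets["all_forms"]) == {"YP", "ZP", "ZP2"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            P.build_network("hexamer")

    def test_enumeration_is_order_stable(self, network):
        net2 = P.build_network("all_forms")
        assert [r.K_id for r in net2.reactions] == [r.K_id for r in network.reactions]
        assert tuple(net2.states) == tuple(network.states)

    def test_sharing_map_export_roundtrip(self, network, tmp_path):
        doc = export_sharing_map(network)
        assert len(set(doc["K_of_reaction"].values())) == 63
        assert len(set(doc["k_of_reaction"].values())) == 46
        import json

        path = tmp_path / "sharing.json"
        path.write_text(json.dumps(doc, default=str))
        assert json.loads(path.read_text())["variant"] == "all_forms"


class TestDetailedBalance:
    def test_independent_dependent_split(self, network):
        basis = P.detailed_balance_basis(network)
        assert len(basis.independent) == 31
        assert len(basis.dependent) == 32
        assert basis.rank == 32
        assert set(basis.independent) | set(basis.dependent) == set(network.K_ids)

    def test_triangle_has_one_cycle_condition(self):
        # abstract A <-> B <-> C <-> A loop: K3 = K1 * K2
        rows = [{0: -1, 1: 1}, {1: -1, 2: 1}, {0: -1, 2: 1}]
        basis = wegscheider_basis(rows, ["K1", "K2", "K3"], 3)
        assert len(basis.independent) == 2 and len(basis.dependent) == 1
        (dep,) = basis.dependent
        expr = dict(basis.dependency[dep])
        vals = {"K1": 2.0, "K2": 5.0, "K3": 10.0}
        # the dependent constant recomputed from the others matches K3=K1*K2
        resolved = math.prod(vals[k] ** float(e) for k, e in expr.items())
        assert resolved == pytest.approx(vals[dep])

    def test_resolve_identity_case(self, network):
        basis = P.detailed_balance_basis(network)
        ones = {k: 1.0 for k in basis.independent}
        full = P.resolve_parameters(network, ones)
        assert all(v == pytest.approx(1.0) for v in full.values())

    def test_resolve_rejects_bad_input(self, network, random_independent_values):
        bad = dict(random_independent_values)
        key = next(iter(bad))
        bad[key] = -1.0
        with pytest.raises(ValueError):
            P.resolve_parameters(network, bad)
        del bad[key]
        with pytest.raises(ValueError):
            P.resolve_parameters(network, bad)

    def test_wegscheider_cycle_products(self, network):
        """100 random draws: every declared cycle product equals one."""
        basis = P.detailed_balance_basis(network)
        rng = np.random.default_rng(7)
        for _ in range(100):
            iv = {k: float(10.0 ** rng.uniform(-4, 4)) for k in basis.independent}
            full = P.resolve_parameters(network, iv)
            for cond in basis.conditions:
                ln = sum(float(e) * math.log(full[k]) for k, e in cond.items())
                assert abs(ln) < 1e-10

    def test_statistical_factor_convention(self, network, random_independent_values):
        """Apparent constant of PEP dissociation from the doubly PEP-bound
        dimer is twice the per-site constant (K14 = 2 Ktilde14)."""
        full = P.resolve_parameters(network, random_independent_values)
        app = apparent_constants(network, full)
        for j, r in enumerate(network.reactions):
            if r.K_id == "Kb:Z(e,e)>Z(e,f)":
                assert r.sigma == Fraction(2)
                assert app[j] == pytest.approx(2.0 * full[r.K_id])
                break
        else:  # pragma: no cover
            pytest.fail("doubly PEP-bound dimer dissociation not found")

    def test_network_connected(self, network):
        assert network.is_connected()


def test_shipped_sharing_map_matches_generated(network):
    """The versioned sharing-map file in the package equals the map the
    builder generates (the reconstruction is auditable and frozen)."""
    import json
    from importlib import resources

    shipped = json.loads(
        resources.files("ptsei").joinpath("data/sharing_map.json").read_text())
    generated = json.loads(
        json.dumps(export_sharing_map(network), sort_keys=True))
    assert shipped == generated
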