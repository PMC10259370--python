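"""Compound aggregation, reaction merging, and network persistence."""

import itertools

import pytest
from hypothesis import given, strategies as st

from qcfill.molecule_io import embed_3d, parse_smiles
from qcfill.reaction_network import (
    ElementaryStep,
    ReactionNetwork,
    StepInvariantError,
)


def fresh_network(structure_cache, species):
    """Network pre-loaded with one structure per SMILES; returns it plus the
    structure ids in order."""
    net = ReactionNetwork()
    sids = [net.add_structure(structure_cache(s)) for s in species]
    return net, sids


def step(i, reactants, products, e_react, e_ts, e_prod):
    return ElementaryStep(
        id=f"st{i}",
        reactant_structure_ids=tuple(reactants),
        product_structure_ids=tuple(products),
        e_react=e_react,
        e_ts=e_ts,
        e_prod=e_prod,
    )


class TestCompoundAggregation:
    def test_conformers_share_a_compound(self, structure_cache):
        net = ReactionNetwork()
        g = parse_smiles("Oc1ccccc1")
        cid1 = net.register_structure(embed_3d(g, seed=1))
        cid2 = net.register_structure(embed_3d(g, seed=2))
        assert cid1 == cid2
        assert len(net.compounds) == 1
        assert len(net.compounds[cid1].structure_ids) == 2

    def test_different_connectivity_different_compounds(self, structure_cache):
        net, _ = fresh_network(structure_cache, ["Oc1ccccc1", "CCOc1ccccc1"])
        assert len(net.compounds) == 2

    def test_reregistration_is_idempotent_on_compounds(self, phenol):
        net = ReactionNetwork()
        net.register_structure(phenol)
        net.register_structure(phenol)
        assert len(net.compounds) == 1

    def test_membership_conservation(self, structure_cache):
        net, _ = fresh_network(
            structure_cache, ["CCI", "Oc1ccccc1", "CCI", "CCOc1ccccc1", "Oc1ccccc1"]
        )
        members = sum(len(c.structure_ids) for c in net.compounds.values())
        assert members == len(net.structures) == 5


class TestReactionMerging:
    def test_same_endpoints_merge_with_minimum_barrier(self, structure_cache):
        net, (a, b, c) = fresh_network(structure_cache, ["CCI", "Oc1ccccc1", "CCOc1ccccc1"])
        r1 = net.register_step(step(0, [a, b], [c], 0.0, 218.0, -34.0))
        r2 = net.register_step(step(1, [a, b], [c], 0.0, 250.0, -30.0))
        assert r1 == r2
        assert net.reactions[r1].best_barrier == 218.0
        assert net.reactions[r1].reaction_energy == -34.0
        assert net.summarize().n_reactions == 1
        assert net.summarize().n_steps == 2

    def test_different_products_do_not_merge(self, structure_cache):
        net, (a, b, c, d) = fresh_network(
            structure_cache, ["CCI", "Oc1ccccc1", "CCOc1ccccc1", "CCc1ccccc1O"]
        )
        r1 = net.register_step(step(0, [a, b], [c], 0.0, 218.0, -34.0))
        r2 = net.register_step(step(1, [a, b], [d], 0.0, 250.0, -48.0))
        assert r1 != r2

    def test_barrierless_limit(self, structure_cache):
        net, (a, b, c) = fresh_network(structure_cache, ["CCI", "Oc1ccccc1", "CCOc1ccccc1"])
        rid = net.register_step(step(0, [a, b], [c], -10.0, -10.0, -44.0))
        assert net.reactions[rid].best_barrier == 0.0

    @pytest.mark.parametrize(
        "e_react, e_ts, e_prod, failing",
        [(0.0, -5.0, -34.0, "E_react"), (0.0, 10.0, 20.0, "E_prod")],
    )
    def test_invariant_violations_name_the_inequality(
        self, structure_cache, e_react, e_ts, e_prod, failing
    ):
        net, (a, b, c) = fresh_network(structure_cache, ["CCI", "Oc1ccccc1", "CCOc1ccccc1"])
        with pytest.raises(StepInvariantError, match=failing):
            net.register_step(step(0, [a, b], [c], e_react, e_ts, e_prod))

    def test_identity_step_rejected(self, structure_cache):
        net, (a, b) = fresh_network(structure_cache, ["CCI", "CCI"])
        with pytest.raises(StepInvariantError, match="connectivity"):
            net.register_step(step(0, [a], [b], 0.0, 50.0, 0.0))


class TestSummaries:
    def test_empty_network(self):
        s = ReactionNetwork().summarize()
        assert (s.n_compounds, s.n_reactions, s.n_steps, s.n_endothermic) == (0, 0, 0, 0)

    def test_endothermic_count_on_mixed_network(self, structure_cache):
        net, (a, b, c, d, e) = fresh_network(
            structure_cache,
            ["CCI", "Oc1ccccc1", "CCOc1ccccc1", "CCc1ccccc1O", "CCc1ccc(O)cc1"],
        )
        net.register_step(step(0, [a, b], [c], 0.0, 218.0, -34.0))
        net.register_step(step(1, [a, b], [d], 0.0, 250.0, -48.0))
        net.register_step(step(2, [a, b], [e], 0.0, 160.0, +10.0))
        s = net.summarize()
        assert s.n_reactions == 3
        assert s.n_endothermic == 1


def _canonical_view(net):
    """Order-free view of a network's reactions for comparison."""
    return {
        (r.reactant_compounds, r.product_compounds, r.best_barrier, r.reaction_energy)
        for r in net.reactions.values()
    }


@given(perm=st.permutations(range(5)))
def test_merge_is_order_independent(perm):
    # five steps over three distinct reactions; connectivity keys are faked so
    # no embedding is needed inside the hypothesis loop
    from qcfill.molecule_io import Atom, MolGraph, Structure

    def fake_structure(tag):
        graph = MolGraph(atoms=(Atom(element="C"),), bonds=())
        return Structure(
            graph=graph,
            elements=("C",),
            coordinates=[[0.0, 0.0, 0.0]],
            charge=0,
            multiplicity=1,
        )

    steps = [
        ("A", "B", "P", 0.0, 218.0, -34.0),
        ("A", "B", "P", 0.0, 250.0, -30.0),
        ("A", "B", "Q", 0.0, 250.0, -48.0),
        ("A", "B", "Q", 0.0, 260.0, -40.0),
        ("A", "B", "R", 0.0, 160.0, 10.0),
    ]

    def build(order):
        net = ReactionNetwork()
        sids = {}
        for key in "ABPQR":
            sids[key] = net.add_structure(fake_structure(key), key=key)
        for n, idx in enumerate(order):
            a, b, p, er, ets, ep = steps[idx]
            net.register_step(step(n, [sids[a], sids[b]], [sids[p]], er, ets, ep))
        return net

    assert _canonical_view(build(range(5))) == _canonical_view(build(perm))


def test_json_round_trip_preserves_everything(structure_cache, tmp_path):
    net, (a, b, c) = fresh_network(structure_cache, ["CCI", "Oc1ccccc1", "CCOc1ccccc1"])
    net.register_step(step(0, [a, b], [c], -8400.0, -8182.0, -8434.0), provenance="C1~O0")
    path = tmp_path / "net.json"
    net.save(path)
    reloaded = ReactionNetwork.load(path)
    assert reloaded.to_dict() == net.to_dict()
    assert reloaded.reactions["r0"].best_barrier == 218.0
    assert reloaded.provenance == {"st0": "C1~O0"}


def test_edgelist_export(structure_cache, tmp_path):
    net, (a, b, c) = fresh_network(structure_cache, ["CCI", "Oc1ccccc1", "CCOc1ccccc1"])
    net.register_step(step(0, [a, b], [c], 0.0, 218.0, -34.0))
    path = tmp_path / "edges.tsv"
    net.export_edgelist(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "source\ttarget\trole"
    assert len(lines) == 4  # 2 reactant edges + 1 product edge + header
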