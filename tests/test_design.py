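import numpy as np
import pytest
from scipy.spatial.distance import cdist

from confswitch import design, topology
from confswitch.coevolution import CoevolutionPair
from confswitch.errors import DesignError
from confswitch.design import (
    MutationPlan, MutationSite, apply_mutations, escalate_plan,
    find_interface, map_coevolution_to_interface, select_mutation_sites,
)
from confswitch.structio import Atom, Residue, SequenceRecord, Structure
from confswitch.topology import MembraneFrame, TmSegment, TopologyAnnotation


def two_residue_structure(gap):
    """One N-domain and one C-domain residue, CB atoms ``gap`` Å apart."""
    s = Structure(id="pair")
    for res_seq, name, x in ((1, "ALA", -gap / 2), (2, "VAL", gap / 2)):
        r = Residue("A", res_seq, name)
        r.add(Atom("N", np.array([x, 0.0, 11.0])))
        r.add(Atom("CA", np.array([x, 1.4, 10.2])))
        r.add(Atom("C", np.array([x, 2.8, 11.0])))
        r.add(Atom("CB", np.array([x, 1.4, 8.7])))
        s.residues.append(r)
    topo = TopologyAnnotation(
        tm_segments=[TmSegment(1, 1, 1), TmSegment(2, 2, 2)],
        domain_of={1: "N", 2: "C"},
        side_of={1: "membrane", 2: "membrane"},
        frame=MembraneFrame(np.zeros(3), np.array([0, 0, 1.0])),
        chain_id="A",
    )
    return s, topo


class TestFindInterface:
    def test_contact_within_cutoff(self):
        s, topo = two_residue_structure(gap=4.0)
        contacts = find_interface(s, topo)
        assert len(contacts) == 1
        assert (contacts[0].res_n, contacts[0].res_c) == (1, 2)
        assert contacts[0].min_dist == pytest.approx(4.0)
        # the closest-atom midpoint sits above the 7.5 Å side boundary
        assert contacts[0].side == "periplasmic"

    def test_no_contact_beyond_cutoff(self):
        s, topo = two_residue_structure(gap=6.0)
        assert find_interface(s, topo) == []

    def test_matches_bruteforce_on_bundle(self, bundles, outward_topo):
        s = bundles["outward"].structure
        contacts = find_interface(s, outward_topo, cutoff=4.5)
        # brute-force: every N/C residue pair by full distance matrix
        res = {r.res_seq: r for r in s.chain("A")}
        expect = {}
        n_res = outward_topo.domain_residues("N")
        c_res = outward_topo.domain_residues("C")
        for rn in n_res:
            for rc in c_res:
                d = cdist(res[rn].heavy_coords(), res[rc].heavy_coords()).min()
                if d <= 4.5:
                    expect[(rn, rc)] = d
        got = {(c.res_n, c.res_c): c.min_dist for c in contacts}
        assert got.keys() == expect.keys()
        for key in got:
            assert got[key] == pytest.approx(expect[key], abs=1e-9)


class TestCoevolutionMapping:
    def test_planted_contact_flagged(self):
        s, topo = two_residue_structure(gap=4.0)
        contacts = find_interface(s, topo)
        pairs = [CoevolutionPair(1, 2, 0.5, 0.4, prob=0.95)]
        map_coevolution_to_interface(contacts, pairs)
        assert contacts[0].coevolving and contacts[0].prob == 0.95

    def test_threshold_above_range_flags_nothing(self):
        s, topo = two_residue_structure(gap=4.0)
        contacts = find_interface(s, topo)
        pairs = [CoevolutionPair(1, 2, 0.5, 0.4, prob=0.99)]
        map_coevolution_to_interface(contacts, pairs, prob_min=1.1)
        assert not contacts[0].coevolving

    def test_empty_pair_list_zeroes(self):
        s, topo = two_residue_structure(gap=4.0)
        contacts = map_coevolution_to_interface(find_interface(s, topo), [])
        assert contacts[0].prob == 0.0 and not contacts[0].coevolving


class TestSiteSelection:
    def test_inward_target_recovers_planted_periplasmic_sites(
        self, bundles, outward_topo
    ):
        fx = bundles["outward"]
        contacts = find_interface(fx.structure, outward_topo)
        plan = select_mutation_sites(
            fx.structure, outward_topo, contacts, "inward", n_sites=3
        )
        assert sorted(plan.positions()) == sorted(fx.planted_periplasmic)
        assert all(site.mut_aa == "W" for site in plan.sites)

    def test_outward_target_uses_cytoplasmic_side_only(
        self, bundles, outward_topo
    ):
        fx = bundles["outward"]
        contacts = find_interface(fx.structure, outward_topo)
        plan = select_mutation_sites(
            fx.structure, outward_topo, contacts, "outward", n_sites=3
        )
        assert set(plan.positions()) <= set(fx.planted_cytoplasmic)

    def test_zero_sites_is_valid(self, bundles, outward_topo):
        fx = bundles["outward"]
        plan = select_mutation_sites(
            fx.structure, outward_topo, [], "inward", n_sites=0
        )
        assert plan.sites == []

    def test_deterministic(self, bundles, outward_topo):
        fx = bundles["outward"]
        contacts = find_interface(fx.structure, outward_topo)
        p1 = select_mutation_sites(fx.structure, outward_topo, contacts,
                                   "inward", 3)
        p2 = select_mutation_sites(fx.structure, outward_topo, contacts,
                                   "inward", 3)
        assert p1.positions() == p2.positions()


class TestApplyMutations:
    def test_basic_substitution(self):
        seq = SequenceRecord("toy", "AGV")
        plan = MutationPlan("inward", [MutationSite(2, "G")])
        out = apply_mutations(seq, plan)
        assert out.seq == "AWV"
        assert out.id.endswith("_G2W")

    def test_empty_plan_is_identity(self):
        seq = SequenceRecord("toy", "AGV")
        out = apply_mutations(seq, MutationPlan("inward"))
        assert out.seq == seq.seq and out.id == seq.id

    def test_wildtype_mismatch_names_position(self):
        seq = SequenceRecord("toy", "AGV")
        plan = MutationPlan("inward", [MutationSite(3, "G")])
        with pytest.raises(DesignError, match="3"):
            apply_mutations(seq, plan)

    def test_mutate_then_revert_positions_restores_sequence(self):
        seq = SequenceRecord("toy", "ASVTGC")
        plan = MutationPlan("inward", [MutationSite(1, "A"),
                                       MutationSite(4, "T")])
        mutated = apply_mutations(seq, plan)
        chars = list(mutated.seq)
        for site in plan.sites:
            chars[site.pos - 1] = site.wt_aa
        assert "".join(chars) == seq.seq


class TestEscalation:
    def test_next_round_is_superset_with_one_more_site(
        self, bundles, outward_topo
    ):
        fx = bundles["outward"]
        contacts = find_interface(fx.structure, outward_topo)
        p1 = select_mutation_sites(fx.structure, outward_topo, contacts,
                                   "inward", 2)
        p2 = escalate_plan(p1, fx.structure, outward_topo, contacts)
        assert p2.round == p1.round + 1
        assert len(p2.sites) == len(p1.sites) + 1
        assert set(p1.positions()) <= set(p2.positions())

    def test_exhaustion_terminates_with_design_error(
        self, bundles, outward_topo
    ):
        fx = bundles["outward"]
        contacts = find_interface(fx.structure, outward_topo)
        plan = select_mutation_sites(fx.structure, outward_topo, contacts,
                                     "inward", 3)
        with pytest.raises(DesignError):
            for _ in range(40):  # must terminate, not loop forever
                plan = escalate_plan(plan, fx.structure, outward_topo,
                                     contacts)
        assert plan.round < 40
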