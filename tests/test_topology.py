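import numpy as np
import pytest

from confswitch import topology
from confswitch.errors import TopologyError
from confswitch.synthetic import (
    BundleSpec, make_bundle, make_globule, make_single_helix,
)
from confswitch.topology import (
    MembraneFrame, annotate, assign_domains, detect_tm_helices,
    fit_membrane_frame,
)

from conftest import random_rotation


def angle_to_z(normal):
    return np.degrees(np.arccos(min(1.0, abs(normal[2]))))


class TestMembraneFrame:
    def test_normal_recovers_z_axis(self, bundles):
        frame = fit_membrane_frame(bundles["occluded"].structure)
        assert angle_to_z(frame.normal) < 2.0

    def test_equivariance_under_rigid_motion(self, bundles):
        rng = np.random.default_rng(2)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, size=3)
        s = bundles["occluded"].structure.copy()
        frame0 = fit_membrane_frame(s)
        s.transform(R, t)
        frame1 = fit_membrane_frame(s)
        expected = R @ frame0.normal
        cosang = abs(float(expected @ frame1.normal))
        assert np.degrees(np.arccos(min(1.0, cosang))) < 2.0
        assert np.allclose(frame1.center, R @ frame0.center + t, atol=1.0)

    def test_too_few_residues(self):
        s = make_single_helix(40)
        with pytest.raises(TopologyError):
            fit_membrane_frame(s)

    def test_frame_validation(self):
        with pytest.raises(TopologyError):
            MembraneFrame(np.zeros(3), np.array([0, 0, 1.0]),
                          half_thickness=30.0)


class TestTmDetection:
    def test_twelve_helices_with_tight_boundaries(self, bundles):
        for state in ("inward", "outward", "occluded"):
            fx = bundles[state]
            frame = fit_membrane_frame(fx.structure)
            tms = detect_tm_helices(fx.structure, frame)
            assert len(tms) == 12
            for det, tru in zip(tms, fx.topology.tm_segments):
                assert abs(det.start - tru.start) <= 2
                assert abs(det.end - tru.end) <= 2

    def test_soluble_globule_has_no_tm(self):
        s = make_globule(seed=3)
        frame = MembraneFrame(np.zeros(3), np.array([0, 0, 1.0]))
        with pytest.raises(TopologyError):
            detect_tm_helices(s, frame)

    def test_single_ideal_helix_spans_membrane(self):
        s = make_single_helix(30)
        frame = MembraneFrame(np.zeros(3), np.array([0, 0, 1.0]))
        tms = detect_tm_helices(s, frame, min_segments=1)
        assert len(tms) == 1
        # the in-slab portion of the helix is one membrane-crossing run
        seg = tms[0]
        assert seg.end - seg.start + 1 >= 15
        z = np.array([s.residue(r, "A").coord("CA")[2]
                      for r in range(seg.start, seg.end + 1)])
        assert z.min() < 0 < z.max()
        assert np.abs(z).max() <= 15.0


class TestDomainAssignment:
    def test_six_six_split_and_cytoplasmic_linker(self, bundles):
        fx = bundles["occluded"]
        topo = annotate(fx.structure)
        helices = topo.tm_segments
        for seg in helices[:6]:
            assert topo.domain_of[seg.start + 2] == "N"
        for seg in helices[6:]:
            assert topo.domain_of[seg.start + 2] == "C"
        linker = [r for r, d in topo.domain_of.items() if d == "linker"]
        assert linker, "linker must be annotated"
        sides = {topo.side_of[r] for r in linker}
        assert "periplasmic" not in sides

    def test_matches_generator_truth_away_from_boundaries(self, bundles):
        for state in ("inward", "outward", "occluded"):
            fx = bundles[state]
            topo = annotate(fx.structure)
            truth = fx.topology.domain_of
            boundary = set()
            t_link = [r for r, d in truth.items() if d == "linker"]
            lo, hi = min(t_link), max(t_link)
            boundary = set(range(lo - 2, lo + 1)) | set(range(hi, hi + 3))
            for res_seq, d in topo.domain_of.items():
                if res_seq in boundary:
                    continue
                assert d == truth[res_seq], (state, res_seq)

    def test_four_tm_toy_splits_two_two(self):
        fx = make_bundle(BundleSpec(n_helices_per_domain=2, seed=1))
        frame = fx.topology.frame
        tms = detect_tm_helices(fx.structure, frame)
        assert len(tms) == 4
        topo = assign_domains(fx.structure, tms, frame)
        assert topo.helix_domain(tms[1]) == "N"
        assert topo.helix_domain(tms[2]) == "C"

    def test_domain_split_override(self, bundles):
        fx = bundles["occluded"]
        frame = fit_membrane_frame(fx.structure)
        tms = detect_tm_helices(fx.structure, frame)
        forced = assign_domains(fx.structure, tms, frame,
                                domain_split=tms[4].start)
        # helices starting before the override residue form the N domain
        assert forced.domain_of[tms[3].start + 2] == "N"
        assert forced.domain_of[tms[4].start + 2] == "C"

    def test_odd_tm_count_rejected(self, bundles):
        fx = bundles["occluded"]
        frame = fit_membrane_frame(fx.structure)
        tms = detect_tm_helices(fx.structure, frame)[:11]
        with pytest.raises(TopologyError):
            assign_domains(fx.structure, tms, frame)


class TestSideLabels:
    def test_rigid_invariance(self, bundles):
        fx = bundles["inward"]
        topo0 = annotate(fx.structure)
        s = fx.structure.copy()
        rng = np.random.default_rng(5)
        s.transform(random_rotation(rng), rng.uniform(-20, 20, size=3))
        topo1 = annotate(s)
        assert topo1.side_of == topo0.side_of
        assert topo1.domain_of == topo0.domain_of

    def test_flipping_frame_swaps_aqueous_sides(self, bundles):
        fx = bundles["occluded"]
        topo = fx.topology
        flipped = topo.frame.flipped()
        swap = {"cytoplasmic": "periplasmic", "periplasmic": "cytoplasmic",
                "membrane": "membrane"}
        for r, side in topo.side_of.items():
            if side == "membrane":
                continue
            res = fx.structure.residue(r, "A")
            assert topology.side_label(flipped, res.coord("CA")) == swap[side]

    def test_topology_tsv(self, tmp_path, outward_topo):
        topology.write_topology(outward_topo, tmp_path / "topo.tsv")
        lines = (tmp_path / "topo.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["res_seq", "domain", "side",
                                        "helix_index"]
        assert len(lines) == 1 + len(outward_topo.domain_of)
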