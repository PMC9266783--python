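import numpy as np
import pytest

from confswitch import compare
from confswitch.compare import (
    change_verdict, classify_state, compare_to_experiment, domain_rmsd,
    kabsch, kabsch_superpose, match_residues,
)
from confswitch.errors import AlignmentError
from confswitch.synthetic import BundleSpec, add_noise, make_bundle

from conftest import STATE_NAMES, random_rotation


def grid_oracle_rmsd(P, Q, coarse=6.0, fine=1.0):
    """Exhaustive Euler-angle rotation search (coarse scan + 1° refine)."""
    from scipy.spatial.transform import Rotation

    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def scan(alphas, betas, gammas):
        best = (np.inf, None)
        angles = np.array(
            [[a, b, g] for a in alphas for b in betas for g in gammas]
        )
        mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        moved = np.einsum("rij,nj->rni", mats, P0)
        rmsds = np.sqrt(((moved - Q0) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(rmsds))
        return float(rmsds[k]), angles[k]

    _, (a, b, g) = scan(
        np.arange(0, 360, coarse), np.arange(0, 180 + coarse, coarse),
        np.arange(0, 360, coarse),
    )
    rmsd, _ = scan(
        np.arange(a - coarse, a + coarse + fine, fine),
        np.arange(b - coarse, b + coarse + fine, fine),
        np.arange(g - coarse, g + coarse + fine, fine),
    )
    return rmsd


class TestKabsch:
    def test_identity(self, bundles):
        s = bundles["occluded"].structure
        _, _, rmsd = kabsch_superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_recovers_transform(self, bundles):
        rng = np.random.default_rng(8)
        R = random_rotation(rng)
        t = rng.uniform(-15, 15, size=3)
        s = bundles["occluded"].structure
        moved = s.copy()
        moved.transform(R, t)
        R_hat, t_hat, rmsd = kabsch_superpose(moved, s)
        assert rmsd < 1e-6
        assert np.allclose(R_hat, R.T, atol=1e-6)  # inverse of the applied R
        assert np.linalg.det(R_hat) == pytest.approx(1.0)

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(17)
        P = rng.uniform(-4, 4, size=(4, 3))
        Q = rng.uniform(-4, 4, size=(4, 3))
        _, _, rmsd = kabsch(P, Q)
        oracle = grid_oracle_rmsd(P, Q)
        assert oracle >= rmsd - 1e-9
        assert oracle - rmsd < 0.01

    def test_symmetry(self, bundles):
        a = bundles["inward"].structure
        b = bundles["outward"].structure
        _, _, r1 = kabsch_superpose(a, b)
        _, _, r2 = kabsch_superpose(b, a)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_invariance_to_pre_transformation(self, bundles):
        rng = np.random.default_rng(9)
        a = bundles["inward"].structure
        b = bundles["outward"].structure
        _, _, r0 = kabsch_superpose(a, b)
        moved = a.copy()
        moved.transform(random_rotation(rng), rng.uniform(-9, 9, 3))
        _, _, r1 = kabsch_superpose(moved, b)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(AlignmentError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDomainRmsd:
    def test_identical_structures(self, bundles, outward_topo):
        s = bundles["outward"].structure
        assert domain_rmsd(s, s, outward_topo) == pytest.approx((0.0, 0.0))

    def test_rocker_pair_rigid_domains(self, bundles, outward_topo):
        rn, rc = domain_rmsd(
            bundles["inward"].structure, bundles["outward"].structure,
            outward_topo,
        )
        assert rn < 0.1 and rc < 0.1
        _, _, rmsd = kabsch_superpose(
            bundles["inward"].structure, bundles["outward"].structure
        )
        assert rmsd >= 2.0

    def test_single_domain_motion(self, bundles, outward_topo):
        s = bundles["outward"].structure
        moved = s.copy()
        # push only the C domain sideways
        c_res = set(outward_topo.domain_residues("C"))
        for r in moved.residues:
            if r.res_seq in c_res:
                for a in r.atoms.values():
                    a.coord = a.coord + np.array([4.0, 0.0, 0.0])
        rn, rc = domain_rmsd(moved, s, outward_topo)
        assert rc == pytest.approx(0.0, abs=1e-9)
        _, _, rmsd = kabsch_superpose(moved, s)
        assert rmsd > 0.5


class TestStateClassification:
    @pytest.mark.parametrize("state", ["inward", "outward", "occluded"])
    def test_fixture_states(self, bundles, state):
        fx = bundles[state]
        called, gate_cyto, gate_peri = classify_state(
            fx.structure, fx.topology
        )
        assert called == STATE_NAMES[state]
        assert gate_cyto > 0 and gate_peri > 0

    def test_thirty_seeded_fixtures_match_truth(self):
        agree = 0
        for seed in range(10):
            for state in ("inward", "outward", "occluded"):
                fx = make_bundle(BundleSpec(state=state, seed=seed))
                called, _, _ = classify_state(fx.structure, fx.topology)
                agree += called == STATE_NAMES[state]
        assert agree == 30


class TestChangeVerdict:
    def test_identical_models_unchanged(self, bundles, outward_topo):
        s = bundles["outward"].structure
        rep = change_verdict(s, s.copy(), outward_topo)
        assert not rep.changed
        assert rep.rmsd_global == pytest.approx(0.0, abs=1e-9)

    def test_rocker_pair_changed(self, bundles, outward_topo):
        rep = change_verdict(
            bundles["outward"].structure, bundles["inward"].structure,
            outward_topo,
        )
        assert rep.changed
        assert rep.rmsd_global >= 2.0
        assert rep.rmsd_N < 1.0 and rep.rmsd_C < 1.0
        assert rep.state == "inward-open"
        assert rep.state_reference == "outward-open"

    def test_small_noise_not_a_change(self, bundles, outward_topo):
        s = bundles["outward"].structure
        noisy = add_noise(s, sigma=0.5, seed=21)
        rep = change_verdict(s, noisy, outward_topo)
        assert not rep.changed
        assert rep.rmsd_global < 1.0

    def test_noise_rmsd_monotone(self, bundles):
        s = bundles["occluded"].structure
        rmsds = []
        for sigma in (0.2, 0.6, 1.2):
            _, _, rmsd = kabsch_superpose(add_noise(s, sigma, seed=5), s)
            rmsds.append(rmsd)
        assert rmsds == sorted(rmsds)


class TestCompareToExperiment:
    def test_renumbered_copy_matches_exactly(self, bundles):
        s = bundles["inward"].structure
        renum = s.copy()
        for r in renum.residues:
            r.res_seq += 100
        rmsd, n = compare_to_experiment(renum, s)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert n == len(s.residues)

    def test_inward_outward_experimental_pair_above_3A(self, bundles):
        # synthetic stand-in for an experimentally determined state pair
        rmsd, _ = compare_to_experiment(
            bundles["inward"].structure, bundles["outward"].structure
        )
        assert rmsd >= 3.0

    def test_agrees_with_hand_matched_superposition(self, bundles):
        a, b = bundles["inward"].structure, bundles["occluded"].structure
        rmsd, _ = compare_to_experiment(a, b)
        _, _, expect = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(expect, abs=1e-12)

    def test_low_identity_rejected(self, bundles):
        fx = make_bundle(BundleSpec(state="inward", seed=99))
        other = bundles["inward"].structure
        seqs_differ = fx.sequence.seq != bundles["inward"].sequence.seq
        if seqs_differ:
            identity = np.mean([
                a == b for a, b in
                zip(fx.sequence.seq, bundles["inward"].sequence.seq)
            ])
            if identity < 0.70:
                with pytest.raises(AlignmentError):
                    compare_to_experiment(fx.structure, other)
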