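import numpy as np
import pandas as pd
import pytest

from tethercoil.builder import Conformer, SamplerConfig, ideal_helix, \
    sample_conformer
from tethercoil.complexes import (ReferenceComplex,
                                  make_synthetic_reference_complex,
                                  peptide_backbone_from_conformer)
from tethercoil.docking import (DockingConfig, DockingVerdict,
                                compare_dockable, count_clashes,
                                kabsch_superpose, screen_conformer,
                                screen_ensemble)
from tethercoil.geometry import random_rotation
from tethercoil.metrics import EnsembleTable
from tethercoil.sequences import make_docking_test_sequence
from tethercoil.torsions import default_library, with_bound_region


class TestKabsch:
    def test_identity_superposition(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot, t, rmsd = kabsch_superpose(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)
        assert rmsd < 1e-12

    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        for _ in range(10):
            true_rot = random_rotation(rng)
            true_t = rng.normal(scale=20, size=3)
            target = pts @ true_rot.T + true_t
            rot, t, rmsd = kabsch_superpose(pts, target)
            assert np.allclose(rot, true_rot, atol=1e-9)
            assert np.allclose(t, true_t, atol=1e-9)
            assert rmsd < 1e-9

    def test_optimal_vs_random_rotations(self):
        rng = np.random.default_rng(2)
        moving = rng.normal(size=(12, 3))
        target = rng.normal(size=(12, 3))
        _, _, best = kabsch_superpose(moving, target)
        mc = moving - moving.mean(axis=0)
        tc = target - target.mean(axis=0)
        for _ in range(2000):
            rot = random_rotation(rng)
            rmsd = np.sqrt(np.mean(np.sum((mc @ rot.T - tc) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(12)
        for _ in range(20):
            moving = rng.normal(size=(10, 3))
            target = rng.normal(size=(10, 3))
            rot, t, rmsd = kabsch_superpose(moving, target)
            mc = moving - moving.mean(axis=0)
            tc = target - target.mean(axis=0)
            r_sp, _ = Rotation.align_vectors(tc, mc)
            assert np.allclose(rot, r_sp.as_matrix(), atol=1e-8)

    def test_result_is_proper_rotation(self):
        # near-planar targets invite reflections; determinant must stay +1
        rng = np.random.default_rng(3)
        moving = rng.normal(size=(8, 3))
        target = moving @ np.diag([1.0, 1.0, -1.0])   # reflected copy
        rot, _, _ = kabsch_superpose(moving, target)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_to_prerotation(self):
        rng = np.random.default_rng(4)
        moving = rng.normal(size=(15, 3))
        target = rng.normal(size=(15, 3))
        _, _, ref = kabsch_superpose(moving, target)
        for _ in range(5):
            rot = random_rotation(rng)
            _, _, got = kabsch_superpose(moving @ rot.T, target)
            assert got == pytest.approx(ref, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSyntheticComplex:
    def test_seeded_determinism(self):
        a = make_synthetic_reference_complex(22, rng_seed=7)
        b = make_synthetic_reference_complex(22, rng_seed=7)
        assert np.array_equal(a.receptor_atoms, b.receptor_atoms)
        for role in a.peptide_backbone:
            assert np.array_equal(a.peptide_backbone[role],
                                  b.peptide_backbone[role])

    def test_reference_pose_is_clash_free(self):
        ref = make_synthetic_reference_complex(22, rng_seed=1)
        d = np.linalg.norm(
            ref.receptor_atoms[:, None, :]
            - ref.backbone_points(("N", "CA", "C", "O"))[None, :, :], axis=2)
        assert d.min() >= ref.clash_cutoff

    def test_minimal_complex(self):
        ref = make_synthetic_reference_complex(3, rng_seed=1)
        assert ref.peptide_length == 3

    def test_too_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_reference_complex(2, rng_seed=1)

    def test_clashing_reference_rejected(self):
        helix = ideal_helix(10)
        backbone = peptide_backbone_from_conformer(helix)
        with pytest.raises(ValueError, match="clash"):
            ReferenceComplex("bad", backbone["CA"][:1] + 0.5, backbone)


class TestClashCounting:
    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        atoms = rng.uniform(0, 20, size=(100, 3))
        receptor = rng.uniform(0, 20, size=(150, 3))
        for cutoff in (1.0, 2.5, 5.0):
            got = count_clashes(atoms, receptor, cutoff)
            d = np.linalg.norm(atoms[:, None, :] - receptor[None, :, :],
                               axis=2)
            assert got == int((d < cutoff).sum())

    def test_empty_atoms(self):
        assert count_clashes(np.zeros((0, 3)), np.zeros((5, 3)), 2.5) == 0


@pytest.fixture(scope="module")
def reference():
    return make_synthetic_reference_complex(22, rng_seed=0)


class TestScreen:
    def test_exact_pose_whole_chain_is_dockable(self, reference):
        conf = ideal_helix(22, "pose")
        cfg = DockingConfig(binding_region=(1, 22))
        verdict = screen_conformer(conf, reference, cfg)
        assert verdict.dockable
        assert verdict.rmsd < 1e-9
        assert verdict.clash_count == 0

    def test_planted_flank_clash_blocks_docking(self, reference):
        conf = ideal_helix(30, "clash")
        cfg = DockingConfig(binding_region=(1, 22))
        clean = screen_conformer(conf, reference, cfg)
        assert clean.rmsd < 1e-9
        # move one post-region atom onto a receptor atom (in the frame of
        # the reference, which the screen's superposition reproduces)
        bad = Conformer(
            sequence_id="bad", residues=conf.residues,
            coords=conf.coords.copy(), atom_res=conf.atom_res,
            atom_role=conf.atom_role, torsions=conf.torsions)
        idx = np.where(bad.atom_res == 25)[0][0]
        bad.coords[idx] = reference.receptor_atoms[0]
        verdict = screen_conformer(bad, reference, cfg)
        assert not verdict.dockable
        assert verdict.clash_count >= 1

    def test_rmsd_gate_blocks_non_pose_region(self, reference):
        rng = np.random.default_rng(6)
        from tethercoil.sequences import SequenceRecord
        from tethercoil.builder import build_chain
        torsions = [(float(rng.uniform(-180, 180)),
                     float(rng.uniform(-180, 180))) for _ in range(22)]
        conf = build_chain(SequenceRecord("coil", "A" * 22, (1, 1)), torsions)
        verdict = screen_conformer(conf, reference,
                                   DockingConfig(binding_region=(1, 22)))
        assert verdict.rmsd > 0.5
        assert not verdict.dockable
        assert verdict.clash_count == -1   # clash gate never evaluated

    def test_verdict_invariant_to_conformer_frame(self, reference,
                                                  rigid_motions):
        conf = ideal_helix(30, "frame")
        cfg = DockingConfig(binding_region=(4, 25))
        ref_verdict = screen_conformer(conf, reference, cfg)
        for rot, t in rigid_motions[:5]:
            moved = screen_conformer(conf.transformed(rot, t), reference, cfg)
            assert moved.rmsd == pytest.approx(ref_verdict.rmsd, abs=1e-9)
            assert moved.dockable == ref_verdict.dockable

    def test_threshold_monotonicity(self, reference):
        rec, region = make_docking_test_sequence("A" * 22, 60)
        lib = with_bound_region(
            default_library().with_helical_anchor(rec), region, 0.9)
        confs = [sample_conformer(rec, lib, SamplerConfig(rng_seed=(9, i)))
                 for i in range(60)]
        def dockable_set(rmsd_thr, clash_cut):
            cfg = DockingConfig(binding_region=region,
                                rmsd_threshold=rmsd_thr,
                                clash_cutoff=clash_cut)
            v = screen_ensemble(confs, reference, cfg)
            return set(v.loc[v.dockable, "conformer_id"])
        base = dockable_set(0.5, 2.5)
        assert base <= dockable_set(1.5, 2.5)     # looser RMSD gate grows
        assert dockable_set(0.5, 4.0) <= base     # stricter clash gate shrinks

    def test_region_length_mismatch_rejected(self, reference):
        conf = ideal_helix(30)
        with pytest.raises(ValueError):
            screen_conformer(conf, reference,
                             DockingConfig(binding_region=(1, 20)))

    def test_verdict_invariant_enforced(self):
        with pytest.raises(ValueError):
            DockingVerdict("x", 0.1, 3, True)


class TestCompareDockable:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(8)
        n = 400
        dockable = rng.random(n) < 0.2
        rgyr = rng.normal(30, 4, n) + 3.0 * dockable
        df = pd.DataFrame({"conformer_id": np.arange(n), "rgyr": rgyr,
                           "dockable": dockable})
        return EnsembleTable(df)

    def test_detects_planted_shift(self, table):
        comp = compare_dockable(table)
        row = comp[comp.metric == "rgyr"].iloc[0]
        assert row.mean_dockable > row.mean_nondockable
        assert row.p < 0.01
        assert row.t < 0

    def test_null_calibration_under_shuffling(self, table):
        rng = np.random.default_rng(9)
        df = table.df.copy()
        df["rgyr"] = rng.normal(30, 4, len(df))   # no real effect
        rejections = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            df["dockable"] = rng.permutation(df["dockable"].to_numpy())
            comp = compare_dockable(EnsembleTable(df))
            if comp.iloc[0].p < 0.05:
                rejections += 1
        # one-sided test at alpha=0.05: rejection rate ~ alpha under null
        assert 0.005 <= rejections / n_shuffles <= 0.12

    def test_single_group_rejected(self, table):
        df = table.df.copy()
        df["dockable"] = True
        with pytest.raises(ValueError, match="non-dockable"):
            compare_dockable(EnsembleTable(df))
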