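"""Metric implementations against brute-force / exhaustive oracles."""

from itertools import combinations

import numpy as np
import pytest

from minifold import metrics
from minifold.chemistry import Protein, residue_template
from minifold.fixtures import make_toy_structure, perturb_structure
from minifold.geometry import AtomCoordinates, apply, kabsch_superpose
from minifold.losses import tm_d0
from minifold.structure import TorsionSet


def lddt_bruteforce(pred: Protein, true: Protein, mode="ca",
                    radius=15.0, thresholds=(0.5, 1, 2, 4)):
    """O(N^2) reference straight from the definition."""
    atoms = []
    for i, r in enumerate(true.sequence):
        tmpl = residue_template(r)
        for k, name in enumerate(tmpl.atom_names):
            if mode == "ca" and name != "CA":
                continue
            if true.atom_mask[i, k] and pred.atom_mask[i, k]:
                atoms.append((i, k))
    hits, total = 0, 0
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            (ia, ka), (ib, kb) = atoms[a], atoms[b]
            if ia == ib:
                continue
            dt = np.linalg.norm(true.atom_positions[ia, ka] - true.atom_positions[ib, kb])
            if dt >= radius:
                continue
            dp = np.linalg.norm(pred.atom_positions[ia, ka] - pred.atom_positions[ib, kb])
            for t in thresholds:
                total += 1
                if abs(dt - dp) < t:
                    hits += 1
    return 100.0 * hits / total


def superpose_on_subset(x, y, subset):
    t, _ = kabsch_superpose(
        AtomCoordinates(x[subset], np.ones(len(subset), bool)),
        AtomCoordinates(y[subset], np.ones(len(subset), bool)),
    )
    return np.linalg.norm(apply(t, x) - y, axis=-1)


def gdt_exhaustive(pred: Protein, true: Protein, thresholds=(1, 2, 4, 8)):
    """Enumerate every subset of size >= 3 as the alignment set."""
    x = pred.backbone("CA").positions
    y = true.backbone("CA").positions
    n = len(x)
    fractions = []
    for thr in thresholds:
        best = 0
        for size in range(3, n + 1):
            for subset in combinations(range(n), size):
                try:
                    d = superpose_on_subset(x, y, np.array(subset))
                except Exception:
                    continue
                best = max(best, int((d < thr).sum()))
        fractions.append(best / n)
    return 100.0 * float(np.mean(fractions))


def tm_exhaustive(pred: Protein, true: Protein):
    x = pred.backbone("CA").positions
    y = true.backbone("CA").positions
    n = len(x)
    d0 = tm_d0(n)
    best = 0.0
    for size in range(3, n + 1):
        for subset in combinations(range(n), size):
            try:
                d = superpose_on_subset(x, y, np.array(subset))
            except Exception:
                continue
            best = max(best, float((1.0 / (1.0 + (d / d0) ** 2)).mean()))
    return best


def perturbed_pair(n, seed, noise, outliers=0.0, motif="mixed"):
    seq, true = make_toy_structure(n, motif, seed=seed)
    pred = perturb_structure(true, noise=noise, outlier_fraction=outliers,
                             seed=seed + 1000)
    return pred, true


class TestLddt:
    def test_identical_is_100(self):
        _, true = make_toy_structure(8, "helix", seed=0)
        score, per_res = metrics.lddt(true, true)
        assert score == 100.0
        assert np.nanmin(per_res) == 100.0

    def test_superposition_free(self):
        from scipy.spatial.transform import Rotation
        from minifold.geometry import RigidTransform

        rng = np.random.default_rng(0)
        pred, true = perturbed_pair(8, 1, 0.6)
        base, _ = metrics.lddt(pred, true)
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(scale=30, size=3))
        moved = pred.transformed(t)
        score, _ = metrics.lddt(moved, true)
        np.testing.assert_allclose(score, base, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mode", ["ca", "all"])
    def test_matches_bruteforce(self, seed, mode):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 10))
        pred, true = perturbed_pair(n, seed, float(rng.uniform(0.1, 2.0)))
        got, _ = metrics.lddt(pred, true, mode=mode)
        expect = lddt_bruteforce(pred, true, mode=mode)
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_asymmetric_in_arguments(self):
        """The inclusion set comes from the truth: scoring a mildly
        compressed copy against the original differs from the reverse
        direction, because compression pulls extra long-range pairs inside
        the truth-side inclusion radius."""
        _, true = make_toy_structure(16, "mixed", seed=2)
        squeezed = Protein(true.sequence, true.atom_positions * 0.8,
                           true.atom_mask.copy())
        a, _ = metrics.lddt(squeezed, true)
        b, _ = metrics.lddt(true, squeezed)
        assert abs(a - b) > 0.5

    def test_no_pairs_raises(self):
        _, true = make_toy_structure(4, "strand", seed=0)
        spread = Protein(true.sequence, true.atom_positions * 100, true.atom_mask)
        with pytest.raises(ValueError):
            metrics.lddt(spread, spread, inclusion_radius=0.1)


class TestGdt:
    def test_identical_is_100(self):
        _, true = make_toy_structure(10, "helix", seed=0)
        assert metrics.gdt(true, true) == 100.0

    def test_constructed_half_displacement(self):
        """Half the residues displaced 100 Å: exactly half superposable."""
        _, true = make_toy_structure(10, "strand", seed=1)
        pos = true.atom_positions.copy()
        pos[5:] += np.array([100.0, 0, 0])
        pred = Protein(true.sequence, pos, true.atom_mask.copy())
        got = metrics.gdt(pred, true)
        np.testing.assert_allclose(got, 50.0, atol=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(5, 8))
        pred, true = perturbed_pair(n, seed, float(rng.uniform(0.5, 3.0)),
                                    outliers=float(rng.choice([0.0, 0.2])))
        got = metrics.gdt(pred, true)
        expect = gdt_exhaustive(pred, true)
        np.testing.assert_allclose(got, expect, atol=1e-3)

    def test_adding_threshold_above_max_error_increases_score(self):
        pred, true = perturbed_pair(8, 3, 1.0)
        base = metrics.gdt(pred, true, thresholds=(1, 2, 4, 8))
        more = metrics.gdt(pred, true, thresholds=(1, 2, 4, 8, 1000))
        assert more >= base

    def test_too_few_residues(self):
        _, true = make_toy_structure(4, "helix", seed=0)
        small = Protein(true.sequence[:2], true.atom_positions[:2], true.atom_mask[:2])
        with pytest.raises(ValueError):
            metrics.gdt(small, small)


class TestTmScore:
    def test_identical_is_one(self):
        _, true = make_toy_structure(12, "helix", seed=0)
        np.testing.assert_allclose(metrics.tm_score(true, true), 1.0, atol=1e-12)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        from minifold.geometry import RigidTransform

        rng = np.random.default_rng(1)
        pred, true = perturbed_pair(12, 2, 0.8)
        base = metrics.tm_score(pred, true)
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(scale=50, size=3))
        np.testing.assert_allclose(metrics.tm_score(pred.transformed(t), true),
                                   base, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed + 200)
        n = int(rng.integers(5, 8))
        pred, true = perturbed_pair(n, seed, float(rng.uniform(0.3, 2.5)),
                                    outliers=float(rng.choice([0.0, 0.2])))
        got = metrics.tm_score(pred, true)
        expect = tm_exhaustive(pred, true)
        np.testing.assert_allclose(got, expect, atol=1e-3)

    def test_single_displaced_residue_of_twenty(self):
        _, true = make_toy_structure(20, "helix", seed=5)
        pos = true.atom_positions.copy()
        pos[10] += np.array([30.0, 0, 0])
        pred = Protein(true.sequence, pos, true.atom_mask.copy())
        got = metrics.tm_score(pred, true)
        # perfect except one residue: 19 kernel-1 terms, one ~0 term
        d0 = tm_d0(20)
        approx = (19 + 1.0 / (1.0 + (30.0 / d0) ** 2)) / 20
        assert abs(got - approx) < 1e-3


class TestSuperpositionHeuristic:
    """Beyond 10 residues the subset search switches from enumeration to
    the multi-seed heuristic; its gap stays negligible at the crossover."""

    @pytest.mark.parametrize("seed", range(3))
    def test_heuristic_matches_enumeration_at_crossover(self, seed):
        rng = np.random.default_rng(seed)
        pred, true = perturbed_pair(12, seed, float(rng.uniform(0.5, 3.0)),
                                    outliers=float(rng.choice([0.0, 0.15])))
        assert gdt_exhaustive(pred, true) - metrics.gdt(pred, true) <= 1.0
        assert tm_exhaustive(pred, true) - metrics.tm_score(pred, true) <= 0.005


class TestRmsd95:
    def test_identical_is_zero(self):
        _, true = make_toy_structure(24, "helix", seed=0)
        assert metrics.rmsd95(true, true) < 1e-9

    def test_outliers_excluded(self):
        """5% of residues displaced 50 Å: rmsd95 stays near zero while the
        all-atom Cα RMSD is large."""
        _, true = make_toy_structure(40, "mixed", seed=1)
        pred = perturb_structure(true, noise=0.0, outlier_fraction=0.05, seed=7)
        r95 = metrics.rmsd95(pred, true)
        x, y = pred.backbone("CA").positions, true.backbone("CA").positions
        _, full = kabsch_superpose(AtomCoordinates(x, np.ones(len(x), bool)),
                                   AtomCoordinates(y, np.ones(len(y), bool)))
        assert r95 < 0.5
        assert full > 5.0

    def test_dominates_full_rmsd(self):
        """rmsd95 never exceeds the all-atom-fit Cα RMSD."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            _, true = make_toy_structure(24, "helix", seed=seed)
            pred = perturb_structure(true, noise=float(rng.uniform(0.2, 3.0)),
                                     outlier_fraction=float(rng.choice([0, 0.1])),
                                     seed=seed + 1)
            x, y = pred.backbone("CA").positions, true.backbone("CA").positions
            _, full = kabsch_superpose(AtomCoordinates(x, np.ones(len(x), bool)),
                                       AtomCoordinates(y, np.ones(len(y), bool)))
            assert metrics.rmsd95(pred, true) <= full + 1e-9

    def test_too_few_atoms_raises(self):
        _, true = make_toy_structure(10, "helix", seed=0)
        with pytest.raises(ValueError):
            metrics.rmsd95(true, true)


class TestRotamerAccuracy:
    def make(self, angles, mask=None):
        angles = np.asarray(angles, float).reshape(1, 4)
        mask = np.ones((1, 4), bool) if mask is None else mask
        return TorsionSet(angles, mask)

    def test_exact_is_one(self):
        t = self.make([10, 20, 30, 40])
        assert metrics.rotamer_accuracy(t, t, "K") == 1.0

    def test_40_degree_boundary(self):
        true = self.make([0, 0, 0, 0])
        near = self.make([39.9, -39.9, 39.9, -39.9])
        far = self.make([40.1, -40.1, 40.1, -40.1])
        assert metrics.rotamer_accuracy(near, true, "K") == 1.0
        assert metrics.rotamer_accuracy(far, true, "K") == 0.0

    def test_circular_wraparound(self):
        true = self.make([179, 0, 0, 0], np.array([[True, False, False, False]]))
        pred = self.make([-179, 0, 0, 0], np.array([[True, False, False, False]]))
        assert metrics.rotamer_accuracy(pred, true, "K") == 1.0

    def test_symmetric_slot_nearer_image(self):
        # aspartate chi2: 170 degrees off becomes 10 via the 180 image
        mask = np.array([[True, True, False, False]])
        true = self.make([0, 0, 0, 0], mask)
        pred = self.make([0, 170, 0, 0], mask)
        assert metrics.rotamer_accuracy(pred, true, "D") == 1.0
        assert metrics.rotamer_accuracy(pred, true, "K") == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        seq = "".join(rng.choice(list("RNDEKLMQ"), size=n))
        mask = np.stack([residue_template(r).chi_valid for r in seq])
        true = TorsionSet(rng.uniform(-180, 180, (n, 4)), mask)
        pred = TorsionSet(true.angles + rng.normal(scale=40, size=(n, 4)), mask)
        got = metrics.rotamer_accuracy(pred, true, seq)

        from minifold.chemistry import CHI_PI_PERIODIC, one_to_three

        hits, total = 0, 0
        for i in range(n):
            for s in range(4):
                if not mask[i, s]:
                    continue
                total += 1
                delta = abs(pred.angles[i, s] - true.angles[i, s]) % 360
                delta = min(delta, 360 - delta)
                if s in CHI_PI_PERIODIC.get(one_to_three(seq[i]), []):
                    delta = min(delta, abs(delta - 180))
                if delta <= 40.0:
                    hits += 1
        np.testing.assert_allclose(got, hits / total, rtol=1e-12)

    def test_no_valid_slots_raises(self):
        empty = TorsionSet(np.zeros((1, 4)), np.zeros((1, 4), bool))
        with pytest.raises(ValueError):
            metrics.rotamer_accuracy(empty, empty, "G")
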