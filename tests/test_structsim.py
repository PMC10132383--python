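"""Superposition, docking RMSD, the surrogate aligner, SAR and PSI."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rnanr import (ComparisonUnavailable, alignment_ratio, compare_pair,
                   docking_rmsd, estimate_base_pairs, global_align,
                   is_redundant, kabsch_superpose, psi, structural_align)
from rnanr.config import DEFAULT_CONFIG
from rnanr.fixtures import (make_helix_chain, perturb_chain,
                            rigid_transform_chain)
from rnanr.structsim import MAX_REFINE_ITERATIONS, PairSimilarity


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Oracle: minimum RMSD over proper rotations by direct numeric
    optimization (rotation-vector parameterization, multi-start)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(a)
        return np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1)))

    best = math.inf
    for start_seed in range(8):
        rng = np.random.default_rng(start_seed)
        res = minimize(cost, rng.uniform(-2, 2, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


def surrogate_oracle(chain_a, chain_b, cutoff=4.0):
    """Independent re-implementation of the iterative superposition
    (plain lists, no shared code path beyond the seed alignment rule)."""
    aln = global_align(chain_a.sequence, chain_b.sequence)
    map_a, map_b = chain_a.coord_map(), chain_b.coord_map()
    cand = [(pa + 1, pb + 1) for pa, pb in aln.aligned_pairs
            if pa + 1 in map_a and pb + 1 in map_b]
    if len(cand) < 3:
        return None
    xa = [map_a[p] for p, _ in cand]
    xb = [map_b[p] for _, p in cand]
    inliers = list(range(len(cand)))
    dists = None
    for _ in range(MAX_REFINE_ITERATIONS):
        sub_a = np.array([xa[i] for i in inliers])
        sub_b = np.array([xb[i] for i in inliers])
        rot, trans, _ = kabsch_superpose(sub_a, sub_b)
        dists = [float(np.linalg.norm(rot @ xa[i] + trans - xb[i]))
                 for i in range(len(cand))]
        new_inliers = [i for i, d in enumerate(dists) if d < cutoff]
        if len(new_inliers) < 3:
            return None
        if new_inliers == inliers:
            break
        inliers = new_inliers
    rmsd = math.sqrt(sum(dists[i] ** 2 for i in inliers) / len(inliers))
    return rmsd, len(inliers)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        moved = pts @ rot.T + rng.uniform(-20, 20, 3)
        _, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd <= 1e-6

    def test_matches_numeric_minimization_oracle(self):
        """4-point toy set with one 2-A displacement: the closed-form SVD
        result equals direct numeric minimization over rotations."""
        a = np.array([[0.0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]])
        b = a.copy()
        b[3, 2] += 2.0
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(brute_force_min_rmsd(a, b), abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_input_gets_proper_rotation(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        b = -a  # mirror-like target
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)


class TestDockingRmsd:
    def test_self_comparison(self, helix30):
        result = docking_rmsd(helix30, helix30.copy(pdb_id="X030"))
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_aligned == helix30.n_coords

    def test_translation_removed(self, helix30):
        shifted = helix30.copy(pdb_id="X030",
                               xyz=helix30.xyz + np.array([5.0, -3.0, 12.0]))
        assert docking_rmsd(helix30, shifted).rmsd == pytest.approx(
            0.0, abs=1e-9)

    def test_subangstrom_for_noisy_copies(self, synthetic_6f4h):
        b, d, _ = synthetic_6f4h
        result = docking_rmsd(b, d)
        assert 0.0 < result.rmsd < 1.0

    def test_too_few_common_coordinates_unavailable(self, helix30):
        sparse = helix30.copy(pdb_id="X030",
                              positions=helix30.positions[:2],
                              xyz=helix30.xyz[:2])
        with pytest.raises(ComparisonUnavailable):
            docking_rmsd(helix30, sparse)


class TestSurrogateAligner:
    def test_rigid_copy_aligns_fully(self, helix30):
        # below-100%-identity route forced by a single mutation
        seq = "U" + helix30.sequence[1:] if helix30.sequence[0] != "U" \
            else "A" + helix30.sequence[1:]
        other = rigid_transform_chain(helix30, seed=4, pdb_id="X030",
                                      sequence=seq)
        result = structural_align(helix30, other)
        assert result.rmsd <= 1e-6
        assert result.n_aligned == helix30.n_coords

    def test_truncated_copy_is_exact_substructure(self, helix30):
        truncated = perturb_chain(helix30, truncate_frac=0.2, seed=0,
                                  pdb_id="X030")
        result = structural_align(helix30, truncated)
        assert result.n_aligned == truncated.n_coords
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_independent_oracle_on_noisy_fixtures(self, seed):
        """Surrogate equals an independently coded brute-force of the same
        iteration on 20 seeded noisy fixtures (<= 60 nt)."""
        n = 30 + (seed % 4) * 10
        parent = make_helix_chain(n, seed=100 + seed, pdb_id="P100")
        noisy = perturb_chain(parent, coord_sigma=3.0, mutation_rate=0.05,
                              seed=200 + seed, pdb_id="Q100")
        oracle = surrogate_oracle(parent, noisy)
        try:
            result = structural_align(parent, noisy)
        except ComparisonUnavailable:
            assert oracle is None
            return
        assert oracle is not None
        assert result.rmsd == pytest.approx(oracle[0], abs=1e-9)
        assert result.n_aligned == oracle[1]

    def test_divergent_structures_unavailable(self, helix30):
        scrambled = perturb_chain(helix30, mutation_rate=0.05, seed=3,
                                  pdb_id="X030")
        rng = np.random.default_rng(8)
        scrambled = scrambled.copy(
            xyz=scrambled.xyz[np.argsort(rng.random(scrambled.n_coords))])
        sim = compare_pair(helix30, scrambled)
        if sim.rmsd is not None:  # if comparable at all, far from redundant
            assert not is_redundant(sim)


class TestRatios:
    def test_sar_arithmetic(self, helix30):
        short = perturb_chain(helix30, truncate_frac=0.2, seed=0,
                              pdb_id="X030")  # 24 nt
        result = structural_align(helix30, short)
        assert alignment_ratio(result, helix30, short) == pytest.approx(
            result.n_aligned / short.n_coords)

    def test_update_mode_uses_new_chain_denominator(self, helix30):
        new = perturb_chain(helix30, truncate_frac=0.2, seed=0,
                            pdb_id="NEW0")
        result = structural_align(new, helix30)
        # the new chain aligns completely: SAR = 1 even though the
        # representative is longer
        assert alignment_ratio(result, new, helix30,
                               mode="update") == pytest.approx(1.0)

    def test_psi_truncation_fixture(self, helix30):
        truncated = perturb_chain(helix30, truncate_frac=0.2, seed=0,
                                  pdb_id="X030")  # 24 of 30 residues
        result = structural_align(helix30, truncated)
        assert result.n_aligned == 24
        assert psi(result, helix30, truncated) == pytest.approx(100.0)

    def test_psi_arithmetic(self, helix30):
        result = docking_rmsd(helix30, helix30.copy(pdb_id="X030"))
        assert psi(result, helix30, helix30) == pytest.approx(100.0)

    def test_noise_monotonicity_over_seeds(self, helix30):
        """SAR and PSI never increase, on average, with coordinate noise."""
        sars, psis, rmsds = {}, {}, {}
        for sigma in (0.1, 2.0):
            s_vals, p_vals, r_vals = [], [], []
            for seed in range(20):
                noisy = perturb_chain(helix30, coord_sigma=sigma,
                                      seed=300 + seed, pdb_id="X030")
                result = docking_rmsd(helix30, noisy)
                s_vals.append(alignment_ratio(result, helix30, noisy))
                p_vals.append(psi(result, helix30, noisy))
                r_vals.append(result.rmsd)
            sars[sigma], psis[sigma], rmsds[sigma] = (
                np.mean(s_vals), np.mean(p_vals), np.mean(r_vals))
        assert rmsds[0.1] < rmsds[2.0]
        assert sars[2.0] <= sars[0.1]
        assert psis[2.0] <= psis[0.1]


class TestSymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_compare_pair_symmetric(self, helix30, seed):
        noisy = perturb_chain(helix30, coord_sigma=0.5, mutation_rate=0.04,
                              seed=seed, pdb_id="Z030")
        fwd = compare_pair(helix30, noisy)
        rev = compare_pair(noisy, helix30)
        assert fwd == rev


class TestBasePairHeuristic:
    def test_no_pairs_for_tiny_chain(self):
        chain = make_helix_chain(4, seed=1)
        assert estimate_base_pairs(chain) >= 0

    def test_each_residue_used_once(self):
        chain = make_helix_chain(40, seed=2)
        count = estimate_base_pairs(chain)
        assert 0 <= count <= chain.n_coords // 2
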