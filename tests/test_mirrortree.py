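"""GM scorer: p-distances, genome distance, rescale, correction, matrix PCC."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from linkmark.mirrortree_gm import (
    DistanceMatrix,
    GmRescale,
    build_genome_distance_matrix,
    compute_rescale_factor,
    correct_distance_matrix,
    distance_matrix_from_alignment,
    genome_distance,
    gm_scores,
    read_distance_matrix,
    upper_triangle,
    write_distance_matrix,
)
from linkmark.synthetic_data import simulate_species_tree


def _dm(values, species=None, label="X", corrected=False):
    values = np.asarray(values, dtype=float)
    species = species or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(label=label, species_ids=list(species), values=values,
                          corrected=corrected)


class TestPDistance:
    def test_identical_sequences_zero(self):
        dm = distance_matrix_from_alignment({"s1": "ACDEF", "s2": "ACDEF"})
        assert dm.values[0, 1] == 0.0

    def test_fully_different_one(self):
        dm = distance_matrix_from_alignment({"s1": "AAAA", "s2": "TTTT"})
        assert dm.values[0, 1] == 1.0

    def test_one_mismatch_in_four(self):
        dm = distance_matrix_from_alignment({"s1": "ACDE", "s2": "ACDF"})
        assert dm.values[0, 1] == 0.25

    def test_gap_columns_excluded(self):
        # comparable columns: 3 (positions 2-4), one mismatch
        dm = distance_matrix_from_alignment({"s1": "A-CDE", "s2": "ABCDF"})
        assert dm.values[0, 1] == pytest.approx(1 / 4)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            distance_matrix_from_alignment({"s1": "ACD", "s2": "AC"})

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix_from_alignment({"s1": "A--", "s2": "-CC"})


class TestGenomeDistance:
    def test_self_distance_zero(self):
        assert genome_distance(7, 7, 7) == 0.0

    def test_disjoint_is_one(self):
        assert genome_distance(5, 9, 0) == 1.0

    def test_derived_example(self):
        assert genome_distance(4, 6, 2) == pytest.approx(0.5)

    def test_shared_exceeding_min_rejected(self):
        with pytest.raises(ValueError):
            genome_distance(4, 6, 5)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 50, size=2)
            n_shared = int(rng.integers(0, min(n_a, n_b) + 1))
            assert 0.0 <= genome_distance(int(n_a), int(n_b), n_shared) <= 1.0


class TestBuildGenomeDistanceMatrix:
    def test_identical_genomes_zero_matrix(self):
        dg = build_genome_distance_matrix({"A": 10, "B": 10}, {("A", "B"): 10})
        np.testing.assert_array_equal(dg.values, np.zeros((2, 2)))

    def test_disjoint_genomes_all_ones(self):
        dg = build_genome_distance_matrix(
            {"A": 4, "B": 5, "C": 6},
            {("A", "B"): 0, ("A", "C"): 0, ("B", "C"): 0})
        off = upper_triangle(dg.values)
        np.testing.assert_array_equal(off, np.ones(3))

    def test_elementwise_hand_computation(self):
        dg = build_genome_distance_matrix(
            {"A": 4, "B": 6, "C": 8},
            {("A", "B"): 2, ("A", "C"): 4, ("B", "C"): 6})
        np.testing.assert_allclose(dg.values, [[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]])

    def test_missing_pair_count_rejected(self):
        with pytest.raises(KeyError):
            build_genome_distance_matrix({"A": 4, "B": 6, "C": 8}, {("A", "B"): 2})


def _random_symmetric(n, rng, scale=1.0):
    upper = np.triu(rng.random((n, n)) * scale, k=1)
    return upper + upper.T


class TestComputeRescaleFactor:
    def test_exact_copy_gives_one(self):
        rng = np.random.default_rng(3)
        dg = _dm(_random_symmetric(5, rng), label="GENOME")
        rescale = compute_rescale_factor(dg, {"pX": _dm(dg.values, label="pX")})
        assert rescale.rho == pytest.approx(1.0)
        assert rescale.argmax_protein == "pX"

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        dg = _dm(_random_symmetric(6, rng), label="GENOME")
        noisy = dg.values * 0.5 + _random_symmetric(6, rng, scale=0.2)
        np.fill_diagonal(noisy, 0.0)
        rescale = compute_rescale_factor(dg, {
            "doubled": _dm(2.0 * dg.values, label="doubled"),
            "noisy": _dm(noisy, label="noisy"),
        })
        assert rescale.rho == pytest.approx(1.0)
        assert rescale.argmax_protein == "doubled"

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        dg = _dm(_random_symmetric(7, rng), label="GENOME")
        matrices = {f"p{i}": _dm(_random_symmetric(7, rng), label=f"p{i}") for i in range(5)}
        expected = max(
            stats.pearsonr(upper_triangle(dg.values), upper_triangle(m.values)).statistic
            for m in matrices.values())
        assert expected > 0  # fixture sanity
        rescale = compute_rescale_factor(dg, matrices)
        assert rescale.rho == pytest.approx(expected)

    def test_insufficient_overlap_rejected(self):
        dg = _dm(np.zeros((3, 3)), species=["a", "b", "c"], label="GENOME")
        dx = _dm(np.zeros((2, 2)), species=["a", "b"])
        with pytest.raises(ValueError, match="3 species"):
            compute_rescale_factor(dg, {"pX": dx})


class TestCorrectDistanceMatrix:
    def test_exact_cancellation(self):
        rng = np.random.default_rng(6)
        dg = _dm(_random_symmetric(5, rng), label="GENOME")
        rho = 0.7
        dx = _dm(rho * dg.values, label="pX")
        corrected = correct_distance_matrix(dx, dg, GmRescale(rho=rho, argmax_protein="pX"))
        np.testing.assert_allclose(corrected.values, np.zeros((5, 5)), atol=1e-12)

    def test_constant_offset(self):
        rng = np.random.default_rng(7)
        dg = _dm(_random_symmetric(4, rng), label="GENOME")
        offset = 0.3
        dx_vals = dg.values + offset
        np.fill_diagonal(dx_vals, 0.0)
        corrected = correct_distance_matrix(_dm(dx_vals, label="pX"), dg,
                                            GmRescale(rho=1.0, argmax_protein="pX"))
        np.testing.assert_allclose(upper_triangle(corrected.values),
                                   -offset * np.ones(6), atol=1e-12)

    def test_elementwise_hand_computation(self):
        rng = np.random.default_rng(8)
        dg_vals = _random_symmetric(4, rng)
        dx_vals = _random_symmetric(4, rng)
        rho = 0.54
        corrected = correct_distance_matrix(
            _dm(dx_vals, label="pX"), _dm(dg_vals, label="GENOME"),
            GmRescale(rho=rho, argmax_protein="q"))
        expected = dg_vals - dx_vals / rho
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(corrected.values, expected)
        assert corrected.corrected

    def test_restricts_to_common_species(self):
        rng = np.random.default_rng(9)
        dg = _dm(_random_symmetric(5, rng), species=list("abcde"), label="GENOME")
        dx = _dm(_random_symmetric(3, rng), species=list("bce"))
        corrected = correct_distance_matrix(dx, dg, GmRescale(rho=1.0, argmax_protein="q"))
        assert corrected.species_ids == list("bce")


class TestGmScores:
    def test_identical_matrices_score_one(self):
        rng = np.random.default_rng(10)
        values = _random_symmetric(12, rng)
        a = _dm(values, label="A", corrected=True)
        b = _dm(values.copy(), label="B", corrected=True)
        table = gm_scores([("A", "B")], {"A": a, "B": b}, min_common_species=10)
        assert table.get("A", "B") == pytest.approx(1.0)

    def test_below_min_common_species_undefined(self):
        rng = np.random.default_rng(11)
        a = _dm(_random_symmetric(5, rng), label="A", corrected=True)
        b = _dm(_random_symmetric(5, rng), label="B", corrected=True)
        table = gm_scores([("A", "B")], {"A": a, "B": b}, min_common_species=10)
        assert table.get("A", "B") == 0.0
        assert ("A", "B") in table.undefined_pairs

    def test_twelve_species_brute_force(self):
        rng = np.random.default_rng(12)
        va, vb = _random_symmetric(12, rng), _random_symmetric(12, rng)
        expected = stats.pearsonr(upper_triangle(va), upper_triangle(vb)).statistic
        table = gm_scores([("A", "B")],
                          {"A": _dm(va, label="A", corrected=True),
                           "B": _dm(vb, label="B", corrected=True)},
                          min_common_species=10)
        assert table.get("A", "B") == pytest.approx(max(0.0, expected))

    def test_constant_matrix_undefined(self):
        ones = np.ones((12, 12)) - np.eye(12)
        rng = np.random.default_rng(13)
        table = gm_scores([("A", "B")],
                          {"A": _dm(ones * 0.5, label="A", corrected=True),
                           "B": _dm(_random_symmetric(12, rng), label="B", corrected=True)},
                          min_common_species=10)
        assert ("A", "B") in table.undefined_pairs

    def test_species_permutation_invariance(self):
        rng = np.random.default_rng(14)
        species = [f"s{i}" for i in range(12)]
        va, vb = _random_symmetric(12, rng), _random_symmetric(12, rng)
        base = gm_scores([("A", "B")],
                         {"A": _dm(va, species, "A", corrected=True),
                          "B": _dm(vb, species, "B", corrected=True)},
                         min_common_species=10).get("A", "B")
        perm = rng.permutation(12)
        pv = [species[i] for i in perm]
        permuted = gm_scores([("A", "B")],
                             {"A": _dm(va[np.ix_(perm, perm)], pv, "A", corrected=True),
                              "B": _dm(vb[np.ix_(perm, perm)], pv, "B", corrected=True)},
                             min_common_species=10).get("A", "B")
        assert base == pytest.approx(permuted)


class TestTreeSignalRemoval:
    """Correction removes the shared speciation signal; shared residuals survive."""

    N_SPECIES = 15
    N_SEEDS = 20
    NOISE_SD = 0.05
    RESIDUAL_SD = 0.5

    def _world(self, seed):
        _, species, raw = simulate_species_tree(self.N_SPECIES, seed)
        tree = raw / raw.max()
        rng = np.random.default_rng(seed)

        def sym_noise(sd):
            upper = np.triu(rng.standard_normal((self.N_SPECIES, self.N_SPECIES)) * sd, k=1)
            return upper + upper.T

        dg = _dm(tree, species, label="GENOME")
        shared_residual = sym_noise(self.RESIDUAL_SD)
        matrices = {}
        for name in ("L1", "L2"):  # linked pair: shared residual
            matrices[name] = _dm(tree + shared_residual + sym_noise(self.NOISE_SD),
                                 species, name, corrected=True)
        for name in ("U1", "U2", "U3", "U4"):  # unlinked: tree + private noise
            matrices[name] = _dm(tree + sym_noise(self.NOISE_SD), species, name,
                                 corrected=True)
        return dg, matrices

    def _pcc(self, a: DistanceMatrix, b: DistanceMatrix) -> float:
        return stats.pearsonr(upper_triangle(a.values), upper_triangle(b.values)).statistic

    def test_corrected_kills_unlinked_but_keeps_linked(self):
        unlinked_pccs, linked_pccs, raw_minus_corrected = [], [], []
        for seed in range(1, self.N_SEEDS + 1):
            dg, matrices = self._world(seed)
            rescale = compute_rescale_factor(dg, matrices)
            corrected = {name: correct_distance_matrix(m, dg, rescale)
                         for name, m in matrices.items()}
            unlinked_names = ["U1", "U2", "U3", "U4"]
            for i, a in enumerate(unlinked_names):
                for b in unlinked_names[i + 1:]:
                    raw = self._pcc(matrices[a], matrices[b])
                    cor = self._pcc(corrected[a], corrected[b])
                    unlinked_pccs.append(cor)
                    raw_minus_corrected.append(raw - cor)
            linked_pccs.append(self._pcc(corrected["L1"], corrected["L2"]))
        assert abs(float(np.mean(unlinked_pccs))) < 0.15
        assert float(np.mean(linked_pccs)) > 0.5
        # correction lowers unlinked similarity in >= 90% of simulated pairs
        assert np.mean(np.array(raw_minus_corrected) > 0) >= 0.9


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        dm = _dm(_random_symmetric(6, rng), label="pX")
        write_distance_matrix(dm, tmp_path / "m.tsv", header_comments=["seed=1"])
        back = read_distance_matrix(tmp_path / "m.tsv")
        assert back.label == "pX" and back.species_ids == dm.species_ids
        np.testing.assert_array_equal(back.values, dm.values)

    def test_asymmetry_rejected(self):
        values = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            _dm(values)

    def test_nonzero_diagonal_rejected(self):
        values = np.array([[0.1, 0.2], [0.2, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            _dm(values)

    def test_negative_raw_distances_rejected(self):
        values = np.array([[0, -0.2], [-0.2, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            _dm(values)
        _dm(values, corrected=True)  # allowed once corrected
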