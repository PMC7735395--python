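import numpy as np
import pytest

import admixscan as ax
from admixscan.genotype_io import MISSING

from _oracles import wc_theta_oracle


def _freq_table(freqs, sizes):
    return ax.AlleleFreqTable(
        populations=[f"pop{i}" for i in range(len(freqs))],
        freq=np.asarray(freqs, float),
        n_hap=np.asarray(sizes, float),
    )


class TestAlleleFreqs:
    def test_definition_and_missing_handling(self):
        m = ax.SnpMap(["s1", "s2"], [1, 1], [100, 200], ["A", "A"], ["G", "G"])
        d = np.array([[0, MISSING], [1, MISSING], [2, MISSING]], dtype=np.int8)
        G = ax.GenotypeMatrix(["a", "b", "c"], d, m)
        lab = ax.PopulationLabels({"a": "p", "b": "p", "c": "p"})
        t = ax.allele_freqs(G, lab)
        assert t.freq[0, 0] == pytest.approx(0.5)
        assert np.isnan(t.freq[0, 1])  # all-missing column flagged undefined
        assert t.n_hap[0, 1] == 0

    def test_hand_computed_two_population_fixture(self):
        m = ax.SnpMap(["s1", "s2"], [1, 1], [100, 200], ["A", "A"], ["G", "G"])
        d = np.array(
            [[0, 2], [1, 2], [2, 1], [0, 0], [0, 1], [MISSING, 2]], dtype=np.int8
        )
        G = ax.GenotypeMatrix(list("abcdef"), d, m)
        lab = ax.PopulationLabels(
            {"a": "x", "b": "x", "c": "x", "d": "y", "e": "y", "f": "y"}
        )
        t = ax.allele_freqs(G, lab)
        i, j = t.row("x"), t.row("y")
        assert t.freq[i, 0] == pytest.approx(3 / 6)   # dosages 0,1,2
        assert t.freq[i, 1] == pytest.approx(5 / 6)   # dosages 2,2,1
        assert t.freq[j, 0] == pytest.approx(0 / 4)   # dosages 0,0 (one missing)
        assert t.freq[j, 1] == pytest.approx(3 / 6)   # dosages 0,1,2
        assert t.n_hap[j, 0] == 4


class TestPairwiseFst:
    def test_identical_frequencies_give_nonpositive_theta(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.2, 0.8, 50)
        t = _freq_table([f, f], [np.full(50, 20), np.full(50, 20)])
        assert ax.pairwise_fst(t, "pop0", "pop1") <= 0

    def test_single_locus_toy_matches_oracle(self):
        t = _freq_table([[0.8], [0.2]], [[10], [10]])
        got = ax.pairwise_fst(t, "pop0", "pop1")
        want = wc_theta_oracle([0.8], [0.2], [10], [10])
        assert got == pytest.approx(want, abs=1e-12)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = int(rng.integers(1, 30))
            pA = rng.uniform(0, 1, L)
            pB = rng.uniform(0, 1, L)
            nA = rng.integers(2, 60, L).astype(float)
            nB = rng.integers(2, 60, L).astype(float)
            t = _freq_table([pA, pB], [nA, nB])
            try:
                want = wc_theta_oracle(pA, pB, nA, nB)
            except ValueError:
                with pytest.raises(ValueError):
                    ax.pairwise_fst(t, "pop0", "pop1")
                continue
            assert ax.pairwise_fst(t, "pop0", "pop1") == pytest.approx(
                want, abs=1e-10
            )

    def test_balding_nichols_recovery(self):
        specs = [
            ax.PopulationSpec("A", 50, admixture=[1.0, 0.0]),
            ax.PopulationSpec("B", 50, admixture=[0.0, 1.0]),
        ]
        cfg = ax.SimulationConfig(
            component_names=["a", "b"], drift=[0.05, 0.05], populations=specs,
            n_snps=5000, n_chromosomes=2, mode="independent", seed=9,
        )
        d = ax.simulate_dataset(cfg)
        t = ax.allele_freqs(d.genotypes, d.labels)
        theta = ax.pairwise_fst(t, "A", "B")
        assert 0.04 <= theta <= 0.06

    def test_monotone_in_drift(self):
        thetas = []
        for i, F in enumerate((0.01, 0.05, 0.1)):
            vals = []
            for rep in range(5):
                specs = [
                    ax.PopulationSpec("A", 40, admixture=[1.0, 0.0]),
                    ax.PopulationSpec("B", 40, admixture=[0.0, 1.0]),
                ]
                cfg = ax.SimulationConfig(
                    component_names=["a", "b"], drift=[F, F],
                    populations=specs, n_snps=2000, n_chromosomes=2,
                    mode="independent", seed=100 * i + rep,
                )
                d = ax.simulate_dataset(cfg)
                t = ax.allele_freqs(d.genotypes, d.labels)
                vals.append(ax.pairwise_fst(t, "A", "B"))
            thetas.append(np.mean(vals))
        assert thetas[0] < thetas[1] < thetas[2]

    def test_no_usable_loci_is_error(self):
        t = _freq_table([[np.nan], [0.5]], [[0], [10]])
        with pytest.raises(ValueError, match="usable"):
            ax.pairwise_fst(t, "pop0", "pop1")


class TestFstMatrix:
    def test_identical_populations_give_zero_matrix(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.2, 0.8, 100)
        t = _freq_table([f, f, f], [np.full(100, 30)] * 3)
        D = ax.fst_matrix(t)
        assert np.all(D.values == 0)

    def test_ordering_follows_simulated_divergence(self):
        specs = [
            ax.PopulationSpec("near1", 30, admixture=[1, 0, 0]),
            ax.PopulationSpec("near2", 30, admixture=[0, 1, 0]),
            ax.PopulationSpec("far", 30, admixture=[0, 0, 1]),
        ]
        cfg = ax.SimulationConfig(
            component_names=["a", "b", "c"], drift=[0.02, 0.02, 0.2],
            populations=specs, n_snps=3000, n_chromosomes=2,
            mode="independent", seed=5,
        )
        d = ax.simulate_dataset(cfg)
        t = ax.allele_freqs(d.genotypes, d.labels)
        D = ax.fst_matrix(t)
        assert D.get("near1", "near2") < D.get("near1", "far")
        assert D.get("near1", "near2") < D.get("near2", "far")

    def test_symmetry_contract_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            ax.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestFrequencyDistances:
    def test_identical_vectors_are_zero(self):
        f = np.array([0.2, 0.5, 0.9])
        assert ax.cavalli_chord(f, f) == pytest.approx(0.0, abs=1e-12)
        assert ax.nei_da(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_limits(self):
        assert ax.cavalli_chord([1.0], [0.0]) == pytest.approx(
            (2 / np.pi) * np.sqrt(2), abs=1e-12
        )
        assert ax.nei_da([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_two_locus_toy_matches_hand_evaluation(self):
        pA = np.array([0.7, 0.1])
        pB = np.array([0.4, 0.3])
        cos1 = np.sqrt(0.7 * 0.4) + np.sqrt(0.3 * 0.6)
        cos2 = np.sqrt(0.1 * 0.3) + np.sqrt(0.9 * 0.7)
        want_chord = np.mean(
            [(2 / np.pi) * np.sqrt(2 * (1 - cos1)),
             (2 / np.pi) * np.sqrt(2 * (1 - cos2))]
        )
        assert ax.cavalli_chord(pA, pB) == pytest.approx(want_chord, abs=1e-12)
        want_da = 1 - np.mean([cos1, cos2])
        assert ax.nei_da(pA, pB) == pytest.approx(want_da, abs=1e-12)


class TestOrientationInvariance:
    def test_all_distances_invariant_under_allele_relabeling(
        self, two_pop_dataset
    ):
        d = two_pop_dataset
        G = d.genotypes
        flipped = ax.GenotypeMatrix(
            G.individual_ids,
            np.where(G.dosage == MISSING, MISSING, 2 - G.dosage),
            G.snp_map,
        )
        t1 = ax.allele_freqs(G, d.labels)
        t2 = ax.allele_freqs(flipped, d.labels)
        assert ax.pairwise_fst(t1, "P1", "P2") == pytest.approx(
            ax.pairwise_fst(t2, "P1", "P2"), abs=1e-12
        )
        i, j = t1.row("P1"), t1.row("P2")
        assert ax.cavalli_chord(t1.freq[i], t1.freq[j]) == pytest.approx(
            ax.cavalli_chord(t2.freq[i], t2.freq[j]), abs=1e-12
        )
        assert ax.nei_da(t1.freq[i], t1.freq[j]) == pytest.approx(
            ax.nei_da(t2.freq[i], t2.freq[j]), abs=1e-12
        )


class TestDistanceMatrixIO:
    def test_phylip_round_trip(self, rng, tmp_path):
        vals = rng.uniform(0.1, 1.0, size=(4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        D = ax.DistanceMatrix(["w", "x", "y", "z"], vals)
        D.write_phylip(tmp_path / "d.phy")
        D2 = ax.DistanceMatrix.read_phylip(tmp_path / "d.phy")
        assert D2.labels == D.labels
        assert np.allclose(D2.values, D.values, atol=1e-6)

    def test_tsv_round_trip(self, rng, tmp_path):
        vals = rng.uniform(0.1, 1.0, size=(3, 3))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        D = ax.DistanceMatrix(["a", "b", "c"], vals)
        D.write_tsv(tmp_path / "d.tsv")
        D2 = ax.DistanceMatrix.read_tsv(tmp_path / "d.tsv")
        assert D2.labels == D.labels
        assert np.allclose(D2.values, D.values, atol=1e-9)
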