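import numpy as np
import pytest

import admixscan as ax


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def small_map():
    """Ten SNPs on two chromosomes with simple coordinates."""
    return ax.SnpMap(
        snp_id=[f"rs{i}" for i in range(10)],
        chrom=[1] * 6 + [2] * 4,
        pos=[100, 200, 350, 500, 800, 1000, 50, 150, 300, 700],
        allele_a=["A"] * 10,
        allele_b=["G"] * 10,
    )


@pytest.fixture
def two_pop_dataset():
    """Two drifted populations plus an admixed one, independent SNPs."""
    specs = [
        ax.PopulationSpec("P1", 25, admixture=[1.0, 0.0]),
        ax.PopulationSpec("P2", 25, admixture=[0.0, 1.0]),
        ax.PopulationSpec("MIX", 20, admixture=[0.6, 0.4]),
    ]
    cfg = ax.SimulationConfig(
        component_names=["c1", "c2"],
        drift=[0.08, 0.08],
        populations=specs,
        n_snps=800,
        n_chromosomes=4,
        mode="independent",
        seed=42,
    )
    return ax.simulate_dataset(cfg)


def write_ped_map(tmp_path, rows, snps):
    """Write a PED/MAP pair from explicit allele-pair strings.

    ``rows``: list of (iid, [allele-pair strings like "A G"]);
    ``snps``: list of (chrom, snp_id, pos).
    """
    map_path = tmp_path / "toy.map"
    ped_path = tmp_path / "toy.ped"
    with open(map_path, "w") as fh:
        for c, sid, p in snps:
            fh.write(f"{c}\t{sid}\t0\t{p}\n")
    with open(ped_path, "w") as fh:
        for iid, genos in rows:
            fh.write(" ".join([iid, iid, "0", "0", "0", "-9"] + genos) + "\n")
    return ped_path, map_path
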