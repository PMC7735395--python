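"""Synthetic admixed-population generator with recorded truth.

Populations are mixtures of ``K`` ancestral components.  Component allele
frequencies drift away from a shared ancestral frequency under the
Balding–Nichols model: ``p_k ~ Beta(p0 (1-F_k)/F_k, (1-p0)(1-F_k)/F_k)``,
so that ``E[p_k] = p0`` and ``Var[p_k] = F_k p0 (1-p0)``.  Each chromosome
copy of an individual draws its ancestry from the individual's admixture
vector ``q_i`` either per SNP (independent-SNP mode, suited to Fst and
admixture-recovery experiments) or per contiguous genomic block
(block-LD mode, which produces the shared multi-SNP haplotypes that the
sliding-window sharing analysis needs).

In block-LD mode each (component, block) pair carries a small pool of
founder haplotypes drawn from the component's allele frequencies; a
chromosome with ancestry ``z`` in a block copies one founder from
component ``z``'s pool.  Haplotype diversity within a window is then
bounded by the founder-pool size, mimicking the limited haplotype
diversity of real populations, while between-population sharing arises
exactly where populations mix the same components.

Two longer correlation scales make the block structure realistic:
ancestry switches only at tract boundaries (``ancestry_tract_bp``,
default 5 Mb — the tract scale of recent admixture), and the founder
index persists across blocks for ``founder_tract_bp`` (default 500 kb,
the persistence scale of shared haplotypes).  Without them, windows that
straddle a block boundary would combine independent founder choices and
show an artificial excess of population-private haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .genotype_io import GenotypeMatrix, HaplotypeSet, PopulationLabels, SnpMap

# approximate human autosome lengths (Mb), used to apportion markers
_AUTOSOME_MB = np.array(
    [247, 243, 199, 191, 181, 171, 159, 146, 141, 135,
     134, 132, 114, 106, 100, 89, 79, 76, 63, 62, 47, 49],
    dtype=float,
)

_FREQ_CLIP = 1e-4


@dataclass
class PopulationSpec:
    """One simulated population: fixed admixture vector or Dirichlet draw."""

    name: str
    n_individuals: int
    admixture: np.ndarray | None = None       # fixed q vector, sums to 1
    dirichlet: np.ndarray | None = None       # concentration, per-individual q

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError(f"population {self.name!r} has size 0")
        if (self.admixture is None) == (self.dirichlet is None):
            raise ValueError(
                f"population {self.name!r}: give exactly one of admixture/dirichlet"
            )
        if self.admixture is not None:
            self.admixture = np.asarray(self.admixture, dtype=float)
            s = self.admixture.sum()
            if not np.isclose(s, 1.0, atol=1e-6):
                raise ValueError(f"admixture vector of {self.name!r} sums to {s}")
            self.admixture = self.admixture / s
        if self.dirichlet is not None:
            self.dirichlet = np.asarray(self.dirichlet, dtype=float)


@dataclass
class SimulationConfig:
    component_names: list
    drift: np.ndarray                       # F per component, in (0, 1)
    populations: list                       # PopulationSpec
    n_snps: int
    n_chromosomes: int = 22
    mean_spacing_bp: float = 50_000.0
    spacing_log_sd: float = 1.4             # lognormal spread; clustered-array-like
    ancestral_freq_range: tuple = (0.05, 0.95)
    mode: str = "block"                     # "block" or "independent"
    block_length_bp: int = 100_000
    founders_per_block: int = 6
    founder_tract_bp: int = 500_000         # founder-index persistence scale
    ancestry_tract_bp: int = 5_000_000      # ancestry-switch scale
    seed: int = 0

    def __post_init__(self) -> None:
        self.drift = np.asarray(self.drift, dtype=float)
        if len(self.drift) != len(self.component_names):
            raise ValueError("drift must have one F per component")
        if np.any(self.drift <= 0) or np.any(self.drift >= 1):
            raise ValueError("drift parameters must lie in (0, 1)")
        if self.mean_spacing_bp <= 0:
            raise ValueError("mean spacing must be positive")
        if self.mode not in ("block", "independent"):
            raise ValueError("mode must be 'block' or 'independent'")
        for spec in self.populations:
            q = spec.admixture if spec.admixture is not None else spec.dirichlet
            if len(q) != self.n_components:
                raise ValueError(
                    f"population {spec.name!r}: vector length {len(q)} != K={self.n_components}"
                )

    @property
    def n_components(self) -> int:
        return len(self.component_names)


@dataclass
class TruthSet:
    """Ground truth recorded alongside a simulated dataset."""

    q: np.ndarray          # (N, K) per-individual admixture used
    p: np.ndarray          # (K, L) component allele frequencies
    snp_map: SnpMap
    ancestry: np.ndarray   # (2N, n_blocks) component of each chromosome block
    block_of_snp: np.ndarray  # (L,) block index per SNP

    def to_frame(self, individual_ids, component_names) -> "object":
        import pandas as pd

        return pd.DataFrame(self.q, index=individual_ids, columns=component_names)


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeSet
    labels: PopulationLabels
    truth: TruthSet


def simulate_snp_map(config: SimulationConfig, rng: np.random.Generator) -> SnpMap:
    """Marker map with lognormal inter-SNP spacings across autosomes.

    SNP counts per chromosome are proportional to human autosome lengths.
    The lognormal spread (default sigma = 1.4 on the log scale) emulates
    the clustered marker geometry of gene-centric genotyping arrays.
    """
    weights = _AUTOSOME_MB[: config.n_chromosomes]
    counts = np.floor(config.n_snps * weights / weights.sum()).astype(int)
    counts[: config.n_snps - counts.sum()] += 1
    mu = np.log(config.mean_spacing_bp) - config.spacing_log_sd**2 / 2
    chroms, poss = [], []
    for c, n in enumerate(counts, start=1):
        if n == 0:
            continue
        gaps = np.maximum(
            1, np.round(rng.lognormal(mu, config.spacing_log_sd, size=n)).astype(np.int64)
        )
        pos = np.cumsum(gaps)
        chroms.append(np.full(n, c, dtype=np.int64))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    snp_id = np.asarray([f"snp{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    m = SnpMap(
        snp_id, chrom, pos,
        np.full(len(snp_id), "A", dtype=object),
        np.full(len(snp_id), "G", dtype=object),
    )
    m.validate(autosomes_only=False)
    return m


def simulate_ancestral_freqs(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Component allele frequencies under Balding–Nichols drift.

    Returns a (K, L) matrix; frequencies are clipped away from 0 and 1.
    """
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_snps)
    P = np.empty((config.n_components, config.n_snps))
    for k, f in enumerate(config.drift):
        ratio = (1.0 - f) / f
        P[k] = rng.beta(p0 * ratio, (1.0 - p0) * ratio)
    return np.clip(P, _FREQ_CLIP, 1.0 - _FREQ_CLIP)


def _block_index(snp_map: SnpMap, block_length: int) -> tuple:
    """Global block index per SNP plus (chrom, start_bp) of each block.

    Blocks tile each chromosome from coordinate 0; np.unique sorts by
    (chrom, block) which matches map order.
    """
    key = np.stack([snp_map.chrom, snp_map.pos // block_length], axis=1)
    uniq, idx = np.unique(key, axis=0, return_inverse=True)
    starts = uniq[:, 1] * block_length
    return idx.astype(np.int64).ravel(), uniq[:, 0], starts


def _draw_q(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.admixture is not None:
        return np.tile(spec.admixture, (spec.n_individuals, 1))
    return rng.dirichlet(spec.dirichlet, size=spec.n_individuals)


def simulate_founder_pool(
    P: np.ndarray, n_founders: int, rng: np.random.Generator
) -> np.ndarray:
    """Founder haplotypes per component: (K, n_founders, L) 0/1 array.

    The pool is a property of the ancestral components, shared by every
    population that mixes them — drawing it once per dataset is what
    makes between-population haplotype sharing possible.
    """
    K, L = P.shape
    return (rng.random((K, n_founders, L)) < P[:, None, :]).astype(np.uint8)


def simulate_population(
    P: np.ndarray,
    spec: PopulationSpec,
    snp_map: SnpMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    founder_pool: np.ndarray | None = None,
) -> SimulatedDataset:
    """Simulate one population given component frequencies ``P`` (K x L).

    In block-LD mode ``founder_pool`` should be the dataset-wide pool from
    :func:`simulate_founder_pool`; if omitted, a private pool is drawn
    (adequate only for single-population use).
    """
    K, L = P.shape
    if L != len(snp_map):
        raise ValueError("P must be defined for every SNP in the map")
    q = _draw_q(spec, rng)
    n2 = 2 * spec.n_individuals
    chunk = 64
    cumq = np.cumsum(q, axis=1)
    cumq[:, -1] = 1.0  # guard against float round-off in the top bin

    def _draw_ancestry(n_units: int) -> np.ndarray:
        z = np.empty((n2, n_units), dtype=np.int8)
        for start in range(0, n2, chunk):
            stop = min(n2, start + chunk)
            u = rng.random((stop - start, n_units))
            cq = cumq[np.arange(start, stop) // 2]  # (chunk, K)
            z[start:stop] = (u[:, :, None] > cq[:, None, :]).sum(axis=2)
        return z

    alleles = np.empty((n2, L), dtype=np.uint8)
    if config.mode == "independent":
        block_of_snp = np.arange(L, dtype=np.int64)
        ancestry = _draw_ancestry(L)
        for start in range(0, n2, chunk):
            stop = min(n2, start + chunk)
            z = ancestry[start:stop]
            pz = P[z, np.arange(L)[None, :]]
            alleles[start:stop] = (rng.random(z.shape) < pz).astype(np.uint8)
    else:
        block_of_snp, block_chrom, block_start = _block_index(
            snp_map, config.block_length_bp
        )
        n_blocks = block_start.shape[0]
        # ancestry constant within multi-Mb tracts; founder index constant
        # within sub-Mb founder tracts (both tile from coordinate 0)
        _, tract_of_block = np.unique(
            np.stack([block_chrom, block_start // config.ancestry_tract_bp], 1),
            axis=0, return_inverse=True,
        )
        _, ftract_of_block = np.unique(
            np.stack([block_chrom, block_start // config.founder_tract_bp], 1),
            axis=0, return_inverse=True,
        )
        tract_of_block = tract_of_block.ravel()
        ftract_of_block = ftract_of_block.ravel()
        z_tract = _draw_ancestry(int(tract_of_block.max()) + 1)
        f_tract = rng.integers(
            0, config.founders_per_block,
            size=(n2, int(ftract_of_block.max()) + 1), dtype=np.int8,
        )
        ancestry = z_tract[:, tract_of_block]
        founder = f_tract[:, ftract_of_block]
        if founder_pool is None:
            founder_pool = simulate_founder_pool(
                P, config.founders_per_block, rng
            )
        boundaries = np.flatnonzero(np.diff(block_of_snp)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [L]])
        for s, e in zip(starts, stops):
            b = block_of_snp[s]
            alleles[:, s:e] = founder_pool[ancestry[:, b], founder[:, b], s:e]

    ids = [f"{spec.name}_{i:04d}" for i in range(spec.n_individuals)]
    hap = HaplotypeSet(ids, alleles, snp_map)
    geno = hap.to_genotypes()
    truth = TruthSet(q=q, p=P, snp_map=snp_map, ancestry=ancestry,
                     block_of_snp=block_of_snp)
    labels = PopulationLabels({iid: spec.name for iid in ids})
    return SimulatedDataset(geno, hap, labels, truth)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate all configured populations on one shared map and P matrix.

    A fixed config (including its seed) reproduces byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    snp_map = simulate_snp_map(config, rng)
    P = simulate_ancestral_freqs(config, rng)
    pool = (
        simulate_founder_pool(P, config.founders_per_block, rng)
        if config.mode == "block"
        else None
    )
    parts = [
        simulate_population(P, spec, snp_map, config, rng, founder_pool=pool)
        for spec in config.populations
    ]
    ids = [iid for part in parts for iid in part.genotypes.individual_ids]
    alleles = np.concatenate([part.haplotypes.alleles for part in parts], axis=0)
    hap = HaplotypeSet(ids, alleles, snp_map)
    geno = hap.to_genotypes()
    truth = TruthSet(
        q=np.concatenate([part.truth.q for part in parts], axis=0),
        p=P,
        snp_map=snp_map,
        ancestry=np.concatenate([part.truth.ancestry for part in parts], axis=0),
        block_of_snp=parts[0].truth.block_of_snp,
    )
    pops: dict = {}
    for part in parts:
        pops.update(part.labels.population)
    return SimulatedDataset(geno, hap, PopulationLabels(pops), truth)


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

def load_scenario(source) -> SimulationConfig:
    """Load a SimulationConfig from a YAML scenario file.

    ``source`` is a path, or the name of a scenario shipped with the
    package (e.g. ``"table2"``).
    """
    path = Path(source)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("admixscan") / "scenarios" / f"{source}.yaml"
        text = ref.read_text()
    raw = yaml.safe_load(text)
    return scenario_from_dict(raw)


def scenario_from_dict(raw: dict) -> SimulationConfig:
    comps = raw["components"]
    names = [c["name"] for c in comps]
    drift = [float(c["drift"]) for c in comps]
    pops = []
    for p in raw["populations"]:
        q = p.get("admixture")
        if q is not None:
            q = np.asarray(q, dtype=float)
            q = q / q.sum()
        d = p.get("dirichlet")
        pops.append(
            PopulationSpec(
                name=p["name"], n_individuals=int(p["n"]),
                admixture=q, dirichlet=None if d is None else np.asarray(d, float),
            )
        )
    kwargs = {}
    for key in (
        "n_snps", "n_chromosomes", "mean_spacing_bp", "spacing_log_sd",
        "mode", "block_length_bp", "founders_per_block", "founder_tract_bp",
        "ancestry_tract_bp", "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "ancestral_freq_range" in raw:
        kwargs["ancestral_freq_range"] = tuple(raw["ancestral_freq_range"])
    return SimulationConfig(
        component_names=names, drift=np.asarray(drift), populations=pops, **kwargs
    )
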