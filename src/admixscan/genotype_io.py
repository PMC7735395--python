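"""Genotype/haplotype containers and PLINK-dialect text I/O.

The pipeline works on three in-memory containers: a :class:`SnpMap` of
marker coordinates, a :class:`GenotypeMatrix` of minor-allele dosages
(0/1/2, ``-1`` for missing) and a :class:`HaplotypeSet` of phased 0/1
chromosomes.  Genotypes are read from whitespace-delimited PED/MAP files;
phased haplotypes come either from a transposed text format (one
chromosome per row) or from a VCF with ``|``-separated GT fields.

Dosage orientation: dosages count copies of ``allele_b``, defined as the
lexicographically later of the two observed alleles.  All downstream
statistics (Fst, chord/DA distances, admixture likelihood) are invariant
under flipping this orientation, which the test suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

AUTOSOMES = frozenset(range(1, 23))


class FormatError(ValueError):
    """Raised when an input file violates the expected text dialect."""


@dataclass
class SnpMap:
    """Marker coordinates for a set of biallelic SNPs.

    Positions are 1-based base pairs (PLINK convention) and must be
    strictly increasing within each chromosome.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)

    def __len__(self) -> int:
        return self.snp_id.shape[0]

    def validate(self, autosomes_only: bool = False) -> None:
        if len(set(self.snp_id)) != len(self):
            raise FormatError("duplicate SNP ids in map")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        if autosomes_only and not set(np.unique(self.chrom)) <= AUTOSOMES:
            raise FormatError("non-autosomal chromosome present")

    def subset(self, index: np.ndarray) -> "SnpMap":
        return SnpMap(
            self.snp_id[index],
            self.chrom[index],
            self.pos[index],
            self.allele_a[index],
            self.allele_b[index],
        )

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix (count of ``allele_b``)."""

    individual_ids: list
    dosage: np.ndarray  # int8, MISSING = -1
    snp_map: SnpMap

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D")
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_map)):
            raise ValueError(
                "dosage shape does not match individuals x SNPs: "
                f"{self.dosage.shape} vs ({len(self.individual_ids)}, {len(self.snp_map)})"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def call_rates(self) -> np.ndarray:
        """Per-individual fraction of non-missing genotypes."""
        return (self.dosage != MISSING).mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        ids = [self.individual_ids[i] for i in np.flatnonzero(index)] \
            if np.asarray(index).dtype == bool else [self.individual_ids[i] for i in index]
        return GenotypeMatrix(ids, self.dosage[index], self.snp_map)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids), self.dosage[:, index], self.snp_map.subset(index)
        )


@dataclass
class HaplotypeSet:
    """2N phased chromosomes x SNPs, allele codes 0/1, no missing data.

    Chromosomes ``2i`` and ``2i + 1`` belong to individual ``i``.
    """

    individual_ids: list
    alleles: np.ndarray  # uint8 (2N, L)
    snp_map: SnpMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape != (2 * len(self.individual_ids), len(self.snp_map)):
            raise ValueError("alleles must be (2N, L) matching ids and map")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("phased alleles must be 0/1 with no missing entries")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    def chromosome_ids(self) -> list:
        return [f"{iid}_{h}" for iid in self.individual_ids for h in (0, 1)]

    def individual_of_chromosome(self, c: int) -> str:
        return self.individual_ids[c // 2]

    def to_genotypes(self) -> GenotypeMatrix:
        dos = (self.alleles[0::2].astype(np.int8) + self.alleles[1::2])
        return GenotypeMatrix(list(self.individual_ids), dos, self.snp_map)


@dataclass
class GroupScheme:
    """Named mapping of group id -> set of population ids (disjoint, non-empty)."""

    name: str
    groups: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        groups = {g: frozenset(p) for g, p in self.groups.items()}
        seen: set = set()
        for g, pops in groups.items():
            if not pops:
                raise ValueError(f"group {g!r} in scheme {self.name!r} is empty")
            overlap = seen & pops
            if overlap:
                raise ValueError(
                    f"populations {sorted(overlap)} appear in more than one group"
                )
            seen |= pops
        self.groups = groups

    def group_ids(self) -> list:
        return list(self.groups)


@dataclass
class PopulationLabels:
    """Individual id -> population id, with optional group assignment."""

    population: Mapping[str, str]
    scheme: GroupScheme | None = None

    def population_of(self, individual: str) -> str:
        return self.population[individual]

    def populations(self) -> list:
        seen: dict = {}
        for p in self.population.values():
            seen.setdefault(p, None)
        return list(seen)

    def group_of(self, individual: str) -> str | None:
        if self.scheme is None:
            return None
        pop = self.population[individual]
        for g, pops in self.scheme.groups.items():
            if pop in pops:
                return g
        return None

    def indices_by_population(self, individual_ids: Sequence[str]) -> dict:
        out: dict = {}
        for i, iid in enumerate(individual_ids):
            if iid not in self.population:
                raise KeyError(f"individual {iid!r} has no population label")
            out.setdefault(self.population[iid], []).append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}

    def indices_by_group(
        self, individual_ids: Sequence[str], scheme: GroupScheme | None = None
    ) -> dict:
        scheme = scheme or self.scheme
        if scheme is None:
            raise ValueError("no group scheme attached or supplied")
        pop_to_group = {
            p: g for g, pops in scheme.groups.items() for p in pops
        }
        out: dict = {g: [] for g in scheme.groups}
        for i, iid in enumerate(individual_ids):
            g = pop_to_group.get(self.population[iid])
            if g is not None:
                out[g].append(i)
        return {g: np.asarray(ix, dtype=np.intp) for g, ix in out.items()}


# ---------------------------------------------------------------------------
# PED/MAP reading and writing
# ---------------------------------------------------------------------------

def read_map(map_path) -> tuple:
    """Read a PLINK MAP file; returns (chrom, snp_id, pos) arrays.

    Accepts the 4-column dialect (chrom, id, cM, pos) and the 3-column
    variant without the genetic-map column.
    """
    chroms, ids, poss = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                c, sid, _, p = fields
            elif len(fields) == 3:
                c, sid, p = fields
            else:
                raise FormatError(f"{map_path}:{lineno}: expected 3 or 4 columns")
            chroms.append(_parse_chrom(c))
            ids.append(sid)
            poss.append(int(p))
    return np.asarray(chroms), np.asarray(ids, dtype=object), np.asarray(poss)


def _parse_chrom(token: str) -> int:
    token = token.removeprefix("chr")
    special = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}
    if token in special:
        return special[token]
    return int(token)


def read_allele_reference(path) -> dict:
    """Read a reference-allele TSV: snp_id, allele_a, allele_b per line."""
    out = {}
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if fields:
                out[fields[0]] = (fields[1], fields[2])
    return out


def read_genotypes(ped_path, map_path, ref_alleles=None) -> GenotypeMatrix:
    """Read PED/MAP text into a GenotypeMatrix with an attached SnpMap.

    Dosage is the count of ``allele_b`` — the lexicographically later of
    the two alleles seen at the marker, unless ``ref_alleles`` (a path to
    a reference-allele TSV or a mapping snp_id -> (allele_a, allele_b))
    fixes the orientation; a reference also makes markers where only one
    allele is observed unambiguous.  ``0`` allele codes mark missing
    genotypes.  More than two distinct alleles at a marker is an error.
    """
    chrom, snp_id, pos = read_map(map_path)
    if ref_alleles is not None and not isinstance(ref_alleles, Mapping):
        ref_alleles = read_allele_reference(ref_alleles)
    n_snps = len(snp_id)
    ids: list = []
    rows: list = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2 x {n_snps} markers), found {len(fields)}"
                )
            ids.append(fields[1])
            rows.append(fields[6:])
    if not ids:
        raise FormatError(f"{ped_path}: no individuals")
    allele_pairs = np.asarray(rows, dtype=object).reshape(len(ids), n_snps, 2)

    allele_a = np.empty(n_snps, dtype=object)
    allele_b = np.empty(n_snps, dtype=object)
    dosage = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = allele_pairs[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise FormatError(
                f"marker {snp_id[j]} has more than two alleles: {observed}"
            )
        if ref_alleles is not None and snp_id[j] in ref_alleles:
            allele_a[j], allele_b[j] = ref_alleles[snp_id[j]]
            unknown = set(observed) - {allele_a[j], allele_b[j]}
            if unknown:
                raise FormatError(
                    f"marker {snp_id[j]}: alleles {sorted(unknown)} not in "
                    "the supplied reference"
                )
        elif len(observed) == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        elif len(observed) == 1:
            allele_a[j], allele_b[j] = "0", observed[0]
        else:
            allele_a[j], allele_b[j] = observed
        nonmiss = (col[:, 0] != "0") & (col[:, 1] != "0")
        count_b = (col[:, 0] == allele_b[j]).astype(np.int8) + (
            col[:, 1] == allele_b[j]
        )
        dosage[nonmiss, j] = count_b[nonmiss]

    snp_map = SnpMap(snp_id, chrom, pos, allele_a, allele_b)
    snp_map.validate()
    return GenotypeMatrix(ids, dosage, snp_map)


def write_genotypes(G: GenotypeMatrix, ped_path, map_path, ref_path=None) -> None:
    """Write PED/MAP text (PLINK dialect) from a GenotypeMatrix.

    With ``ref_path`` an allele-reference TSV is written alongside;
    re-reading with that reference reproduces the dosage matrix exactly
    even at markers where only one allele is observed (the PED codes
    alone cannot disambiguate those).
    """
    m = G.snp_map
    with open(map_path, "w") as fh:
        for j in range(len(m)):
            fh.write(f"{m.chrom[j]}\t{m.snp_id[j]}\t0\t{m.pos[j]}\n")
    # fall back to synthetic allele codes where the map has none
    a = np.where(m.allele_a == "0", "A", m.allele_a)
    b = np.where(m.allele_b == "0", "B", m.allele_b)
    if ref_path is not None:
        with open(ref_path, "w") as fh:
            for j in range(len(m)):
                fh.write(f"{m.snp_id[j]}\t{a[j]}\t{b[j]}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(G.individual_ids):
            parts = [iid, iid, "0", "0", "0", "-9"]
            d = G.dosage[i]
            for j in range(len(m)):
                if d[j] == MISSING:
                    parts.append("0 0")
                elif d[j] == 0:
                    parts.append(f"{a[j]} {a[j]}")
                elif d[j] == 1:
                    parts.append(f"{a[j]} {b[j]}")
                else:
                    parts.append(f"{b[j]} {b[j]}")
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# Phased haplotypes
# ---------------------------------------------------------------------------

def read_haplotypes(hap_path, map_path) -> HaplotypeSet:
    """Read transposed haplotype text: one chromosome per row.

    Row format: ``individual_id hap_index allele allele ...`` where
    hap_index is 0 or 1 and alleles are 0/1 codes (count of allele_b).
    """
    chrom, snp_id, pos = read_map(map_path)
    ids: list = []
    rows: list = []
    with open(hap_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2 + len(snp_id):
                raise FormatError(
                    f"{hap_path}:{lineno}: expected {2 + len(snp_id)} fields"
                )
            iid, h = fields[0], int(fields[1])
            if h == 0:
                ids.append(iid)
            elif iid != ids[-1]:
                raise FormatError(
                    f"{hap_path}:{lineno}: second haplotype of {iid!r} does "
                    "not follow its first"
                )
            rows.append([int(x) for x in fields[2:]])
    alleles = np.asarray(rows, dtype=np.uint8)
    snp_map = SnpMap(
        snp_id, chrom, pos,
        np.full(len(snp_id), "A", dtype=object),
        np.full(len(snp_id), "B", dtype=object),
    )
    return HaplotypeSet(ids, alleles, snp_map)


def write_haplotypes(H: HaplotypeSet, hap_path) -> None:
    with open(hap_path, "w") as fh:
        for c in range(H.n_chromosomes):
            iid = H.individual_of_chromosome(c)
            alleles = " ".join(map(str, H.alleles[c]))
            fh.write(f"{iid} {c % 2} {alleles}\n")


def read_phased_vcf(vcf_path) -> HaplotypeSet:
    """Read a VCF with fully phased ``|``-separated GT into a HaplotypeSet.

    Only biallelic SNPs are accepted; any unphased or missing genotype is
    an error because the haplotype-sharing stages require complete phase.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    ids = list(vcf.samples)
    chroms, snp_ids, poss, a_ref, a_alt = [], [], [], [], []
    cols: list = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"{var.ID or var.POS}: not biallelic")
        gts = np.asarray(var.genotype.array())
        if gts.shape[1] != 3 or not np.all(gts[:, 2] == 1):
            raise FormatError(f"{var.ID or var.POS}: unphased genotype present")
        if np.any(gts[:, :2] < 0):
            raise FormatError(f"{var.ID or var.POS}: missing genotype present")
        chroms.append(_parse_chrom(var.CHROM))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        poss.append(var.POS)
        a_ref.append(var.REF)
        a_alt.append(var.ALT[0])
        cols.append(gts[:, :2].reshape(-1))
    alleles = np.asarray(cols, dtype=np.uint8).T
    # dosage orientation: allele_b is the lexicographically later allele
    a_ref = np.asarray(a_ref, dtype=object)
    a_alt = np.asarray(a_alt, dtype=object)
    flip = a_ref > a_alt
    alleles[:, flip] = 1 - alleles[:, flip]
    allele_a = np.where(flip, a_alt, a_ref)
    allele_b = np.where(flip, a_ref, a_alt)
    snp_map = SnpMap(snp_ids, chroms, poss, allele_a, allele_b)
    snp_map.validate()
    return HaplotypeSet(ids, alleles, snp_map)


def read_labels(path, scheme: GroupScheme | None = None) -> PopulationLabels:
    """Read a 2/3-column TSV: individual, population[, group].

    If a third column is present a GroupScheme named after the file is
    built from it (unless an explicit scheme is passed).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 columns")
    pops = dict(zip(df[0], df[1]))
    if scheme is None and df.shape[1] >= 3:
        groups: dict = {}
        for pop, grp in zip(df[1], df[2]):
            if isinstance(grp, str) and grp:
                groups.setdefault(grp, set()).add(pop)
        if groups:
            scheme = GroupScheme(Path(path).stem, groups)
    return PopulationLabels(pops, scheme)


# ---------------------------------------------------------------------------
# QC filtering and BMD thinning
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_individuals_in: int
    n_individuals_removed: int
    n_snps_in: int
    n_snps_removed_nonautosomal: int
    n_snps_removed_keep: int
    n_snps_removed_callrate: int

    @property
    def n_snps_removed(self) -> int:
        return (
            self.n_snps_removed_nonautosomal
            + self.n_snps_removed_keep
            + self.n_snps_removed_callrate
        )

    @property
    def n_snps_retained(self) -> int:
        return self.n_snps_in - self.n_snps_removed

    @property
    def n_individuals_retained(self) -> int:
        return self.n_individuals_in - self.n_individuals_removed


def qc_filter(
    G: GenotypeMatrix,
    min_call_rate: float = 0.9,
    autosomes_only: bool = True,
    keep_snps: Iterable | None = None,
    min_snp_call_rate: float | None = None,
) -> tuple:
    """Sample call-rate filter followed by marker filters.

    Individuals with call rate strictly below ``min_call_rate`` are
    removed first; then non-autosomal markers, markers outside
    ``keep_snps`` and (optionally, off by default) markers below a
    per-SNP call rate computed on the retained individuals.

    Returns ``(filtered GenotypeMatrix, QCReport)``.
    """
    if not 0 <= min_call_rate <= 1:
        raise ValueError("min_call_rate must lie in [0, 1]")
    keep_ind = G.call_rates() >= min_call_rate
    if not keep_ind.any():
        raise ValueError("call-rate filter removed every individual")
    G2 = G.subset_individuals(keep_ind) if not keep_ind.all() else G

    m = G2.snp_map
    keep = np.ones(len(m), dtype=bool)
    n_auto = 0
    if autosomes_only:
        auto = np.isin(m.chrom, list(AUTOSOMES))
        n_auto = int((~auto & keep).sum())
        keep &= auto
    n_keepset = 0
    if keep_snps is not None:
        in_set = np.isin(m.snp_id, np.asarray(list(keep_snps), dtype=object))
        n_keepset = int((~in_set & keep).sum())
        keep &= in_set
    n_cr = 0
    if min_snp_call_rate is not None:
        ok = G2.snp_call_rates() >= min_snp_call_rate
        n_cr = int((~ok & keep).sum())
        keep &= ok
    G3 = G2.subset_snps(keep) if not keep.all() else G2
    report = QCReport(
        n_individuals_in=G.n_individuals,
        n_individuals_removed=int((~keep_ind).sum()),
        n_snps_in=G.n_snps,
        n_snps_removed_nonautosomal=n_auto,
        n_snps_removed_keep=n_keepset,
        n_snps_removed_callrate=n_cr,
    )
    return G3, report


@dataclass
class ThinResult:
    subsets: list          # list of object arrays of snp ids
    mean_spacing: list     # achieved mean spacing (bp) per subset


def thin_by_bmd(snp_map: SnpMap, target_spacing: int, n_subsets: int = 1) -> ThinResult:
    """Greedy between-marker-distance thinning into ``n_subsets`` SNP subsets.

    Subset ``k`` (0-based) starts at the ``k``-th SNP of each chromosome
    and then repeatedly takes the first SNP at least ``target_spacing``
    bp downstream of the last selected one.  Used to build weak-LD
    sub-panels for the admixture grid (the study's ~550 kb spacing gives
    panels of a few thousand markers).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    subsets: list = [[] for _ in range(n_subsets)]
    gaps: list = [[] for _ in range(n_subsets)]
    for c in snp_map.chromosomes():
        idx = np.flatnonzero(snp_map.chrom == c)
        pos = snp_map.pos[idx]
        for k in range(n_subsets):
            if k >= len(idx):
                warnings.warn(
                    f"chromosome {c} has fewer than {k + 1} SNPs; subset {k} "
                    "gets no contribution from it"
                )
                continue
            sel = [k]
            last = pos[k]
            j = np.searchsorted(pos, last + target_spacing)
            while j < len(idx):
                sel.append(j)
                last = pos[j]
                j = np.searchsorted(pos, last + target_spacing)
            subsets[k].extend(snp_map.snp_id[idx[sel]])
            if len(sel) > 1:
                gaps[k].extend(np.diff(pos[sel]).tolist())
    return ThinResult(
        subsets=[np.asarray(s, dtype=object) for s in subsets],
        mean_spacing=[float(np.mean(g)) if g else float("nan") for g in gaps],
    )
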