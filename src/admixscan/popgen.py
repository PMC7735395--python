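"""Allele frequencies, Weir–Cockerham Fst and allele-frequency distances.

Pairwise Fst is the two-population Weir–Cockerham theta computed from
per-population allele frequencies and haploid sample sizes, combined
across loci as a ratio of sums (sum of between-population variance
components over sum of total variance components).  Per locus, with
haploid sizes ``n_i``, sample frequencies ``p_i`` and ``r = 2``
populations::

    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
    MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
    a   = (MSP - MSG) / n_c          # between-population component
    b   = MSG                        # within-population component
    theta = sum_l a_l / sum_l (a_l + b_l)

with ``p_bar`` the size-weighted mean frequency and ``n_c`` the usual
variance-effective sample size.  Negative theta is preserved internally;
reported distance matrices floor it at zero because the MDS and tree
stages require nonnegative distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationLabels


@dataclass
class AlleleFreqTable:
    """Per-population allele_b frequencies and haploid sample sizes."""

    populations: list
    freq: np.ndarray    # (n_pops, L), NaN where undefined
    n_hap: np.ndarray   # (n_pops, L) haploid counts of non-missing alleles

    def row(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over unique labels, zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=0, rtol=0, equal_nan=True):
            raise ValueError("matrix must be exactly symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.values
        # tolerate asymmetry from decimal truncation in the text form
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls([str(c) for c in df.columns], values)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab[:10].ljust(10) + "  ")
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                fields = fh.readline().split()
                labels.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(labels, np.asarray(rows))


def allele_freqs(G: GenotypeMatrix, labels: PopulationLabels) -> AlleleFreqTable:
    """Missing-aware per-population allele_b frequencies.

    Frequency is (sum of dosages) / (2 x non-missing individuals); a
    population/SNP cell with no called genotypes is NaN with size 0 and
    is skipped by every downstream statistic.
    """
    by_pop = labels.indices_by_population(G.individual_ids)
    pops = list(by_pop)
    L = G.n_snps
    freq = np.full((len(pops), L), np.nan)
    n_hap = np.zeros((len(pops), L))
    for r, pop in enumerate(pops):
        d = G.dosage[by_pop[pop]]
        called = d != MISSING
        n = 2.0 * called.sum(axis=0)
        s = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[r] = np.where(n > 0, s / n, np.nan)
        n_hap[r] = n
    return AlleleFreqTable(pops, freq, n_hap)


def _theta_components(pA, pB, nA, nB):
    """Per-locus Weir–Cockerham a (between) and a+b (total) components."""
    nbar = (nA + nB) / 2.0
    nc = 2.0 * nA * nB / (nA + nB)
    pbar = (nA * pA + nB * pB) / (nA + nB)
    msp = nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2  # r - 1 = 1
    msg = (nA * pA * (1 - pA) + nB * pB * (1 - pB)) / (nA + nB - 2.0)
    a = (msp - msg) / nc
    return a, a + msg


def pairwise_fst(freqs: AlleleFreqTable, popA: str, popB: str) -> float:
    """Two-population Weir–Cockerham theta, ratio-of-sums over loci.

    Loci are skipped when either population has fewer than two sampled
    alleles, when a frequency is undefined, or when the locus is
    monomorphic across both populations (zero numerator and denominator).
    The result may be slightly negative and is not clamped here.
    """
    ia, ib = freqs.row(popA), freqs.row(popB)
    pA, pB = freqs.freq[ia], freqs.freq[ib]
    nA, nB = freqs.n_hap[ia], freqs.n_hap[ib]
    usable = (nA >= 2) & (nB >= 2) & np.isfinite(pA) & np.isfinite(pB)
    a, t = _theta_components(pA[usable], pB[usable], nA[usable], nB[usable])
    informative = t != 0
    if not informative.any():
        raise ValueError(f"no usable loci between {popA!r} and {popB!r}")
    return float(a[informative].sum() / t[informative].sum())


def fst_matrix(freqs: AlleleFreqTable, populations=None) -> DistanceMatrix:
    """All-pairs theta matrix; negative estimates floored at zero."""
    pops = list(populations) if populations is not None else list(freqs.populations)
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = max(0.0, pairwise_fst(freqs, pops[i], pops[j]))
    return DistanceMatrix(pops, out)


def _defined_pair(pA, pB):
    ok = np.isfinite(pA) & np.isfinite(pB)
    if not ok.any():
        raise ValueError("no shared defined loci")
    return pA[ok], pB[ok]


def cavalli_chord(freqsA: np.ndarray, freqsB: np.ndarray) -> float:
    """Cavalli-Sforza chord distance between two frequency vectors.

    Per biallelic locus: cos(theta) = sqrt(pA pB) + sqrt((1-pA)(1-pB));
    locus distance = (2/pi) sqrt(2 (1 - cos theta)); averaged over loci.
    """
    pA, pB = _defined_pair(np.asarray(freqsA, float), np.asarray(freqsB, float))
    cos_t = np.sqrt(pA * pB) + np.sqrt((1 - pA) * (1 - pB))
    d = (2.0 / np.pi) * np.sqrt(np.maximum(0.0, 2.0 * (1.0 - cos_t)))
    return float(d.mean())


def nei_da(freqsA: np.ndarray, freqsB: np.ndarray) -> float:
    """Nei's DA distance: 1 - mean over loci of sum_u sqrt(x_u y_u)."""
    pA, pB = _defined_pair(np.asarray(freqsA, float), np.asarray(freqsB, float))
    shared = np.sqrt(pA * pB) + np.sqrt((1 - pA) * (1 - pB))
    return float(1.0 - shared.mean())


def cluster_distance_matrix(
    P: np.ndarray, labels, method: str = "nei_da"
) -> DistanceMatrix:
    """Distance matrix between rows of a cluster allele-frequency matrix."""
    fn = {"nei_da": nei_da, "cavalli_chord": cavalli_chord}[method]
    labels = list(labels)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = max(0.0, fn(P[i], P[j]))
    return DistanceMatrix(labels, out)
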