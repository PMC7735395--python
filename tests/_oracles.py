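"""Independent reference implementations used to cross-check the package.

Everything here is written as directly as possible from first principles
(explicit loops, dict/set algebra, exhaustive enumeration) and must stay
independent of the vectorized implementations it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def wc_theta_oracle(pA, pB, nA, nB) -> float:
    """Two-population Weir–Cockerham theta from allele frequencies.

    Loop-based evaluation of the 1984 variance-components estimator for
    haploid allele counts (r = 2), combining loci as ratio of sums.
    """
    r = 2
    num = 0.0
    den = 0.0
    for p1, p2, n1, n2 in zip(pA, pB, nA, nB):
        if n1 < 2 or n2 < 2 or math.isnan(p1) or math.isnan(p2):
            continue
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * inner
        if a == 0 and b == 0:
            continue  # monomorphic across both samples
        num += a
        den += a + b
    if den == 0:
        raise ValueError("no informative loci")
    return num / den


def ssc_exhaustive(Q1: np.ndarray, Q2: np.ndarray) -> float:
    """Symmetric similarity coefficient by brute-force permutation search."""
    n, k = Q1.shape
    best = -np.inf
    for perm in itertools.permutations(range(k)):
        d = np.linalg.norm(Q1 - Q2[:, list(perm)])
        best = max(best, 1.0 - d / np.sqrt(2.0 * n))
    return best


def hsa_enumerate(alleles, window_snp_indices, group_chromosomes, min_count):
    """Four-category sharing percentages by direct set algebra.

    ``alleles``: (n_chrom, L) 0/1 array; ``window_snp_indices``: list of
    SNP-index lists; ``group_chromosomes``: ordered dict group -> list of
    chromosome row indices (first three groups form the framework).
    Returns {focal: [pct_private, pct_with_B, pct_with_C, pct_all]} with
    percentages averaged over windows that have surviving focal strings.
    """
    groups = list(group_chromosomes)
    core = groups[:3]
    out = {}
    for focal in core:
        b, c = [g for g in core if g != focal]
        per_window = []
        for snps in window_snp_indices:
            surviving = {}
            for g in groups:
                strings = [
                    tuple(alleles[ch][s] for s in snps)
                    for ch in group_chromosomes[g]
                ]
                surviving[g] = {
                    s for s in set(strings) if strings.count(s) >= min_count
                }
            sa = surviving[focal]
            if not sa:
                continue
            cats = [0, 0, 0, 0]
            for s in sa:
                in_b, in_c = s in surviving[b], s in surviving[c]
                if in_b and in_c:
                    cats[3] += 1
                elif in_b:
                    cats[1] += 1
                elif in_c:
                    cats[2] += 1
                else:
                    cats[0] += 1
            per_window.append([100.0 * x / len(sa) for x in cats])
        out[focal] = (
            [float(np.mean([w[i] for w in per_window])) for i in range(4)]
            if per_window
            else [float("nan")] * 4
        )
    return out


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with positive lengths, as leaf distances.

    Built by random agglomeration; leaf-to-leaf distances computed by
    path enumeration on the adjacency structure.  Returns
    ``(labels, D, bipartitions)`` where bipartitions is the set of
    non-trivial splits, each written as the frozenset of leaf labels on
    the side NOT containing ``labels[0]``.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    adj: dict = {lab: {} for lab in labels}
    active = list(labels)
    counter = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        new = f"I{counter}"
        counter += 1
        la = float(rng.uniform(0.1, 2.0))
        lb = float(rng.uniform(0.1, 2.0))
        adj[new] = {a: la, b: lb}
        adj[a][new] = la
        adj[b][new] = lb
        active = [x for x in active if x not in (a, b)] + [new]
    a, b = active
    ln = float(rng.uniform(0.1, 2.0))
    adj[a][b] = ln
    adj[b][a] = ln

    def path_length(start, goal):
        stack = [(start, None, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node == goal:
                return acc
            for nxt, w in adj[node].items():
                if nxt != prev:
                    stack.append((nxt, node, acc + w))
        raise RuntimeError("unreachable")

    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = path_length(labels[i], labels[j])

    def leaves_beyond(node, prev):
        if node.startswith("T"):
            return {node}
        out: set = set()
        for nxt in adj[node]:
            if nxt != prev:
                out |= leaves_beyond(nxt, node)
        return out

    bips = set()
    for u in adj:
        for v in adj[u]:
            side = frozenset(leaves_beyond(v, u))
            if labels[0] in side:
                side = frozenset(set(labels) - side)
            if 1 < len(side) < n_leaves - 1:
                bips.add(side)
    return labels, D, bips
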