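"""Sliding-window haplotype-sharing analysis (HSA).

In a three-population framework (A, B, C) the distinct window haplotypes
of a focal group A fall into four categories: private to A (``H_AP``),
shared with B only (``H_AB``), shared with C only (``H_AC``) and shared
with all three groups (``H_ABC``).  Percentages are computed over
distinct haplotype strings, ignoring their frequencies.

Sample-size bias is removed by non-replacement sampling (NRS): an equal
number of chromosomes is drawn from every group (default twice the
smallest group's individual count), the per-window percentages are
averaged over windows within each draw and then over replicate draws.
Within each drawn group sample, haplotype strings observed fewer than
``min_count`` times (default 2) are discarded before classification.

A fourth (outgroup) taxon never alters the focal categories; its sharing
with each category is recorded, and the category pseudo-populations
(chromosomes carrying private-A / private-B / private-C / fully shared /
outgroup haplotypes) feed the haplotype-sharing distance matrix used for
the HSA phylogenies, where every window is treated as one multi-allelic
locus and pairwise Weir–Cockerham theta is combined across windows as a
ratio of sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GroupScheme, HaplotypeSet, PopulationLabels, SnpMap
from .popgen import DistanceMatrix, _theta_components


@dataclass
class Window:
    chrom: int
    start: int   # half-open [start, end), 1-based coordinates
    end: int
    snp_index: np.ndarray


@dataclass
class WindowSpec:
    size_bp: int
    step_bp: int
    windows: list

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(snp_map: SnpMap, size_bp: int) -> WindowSpec:
    """Half-overlapping windows of ``size_bp`` (step = half the size).

    Per chromosome, candidate windows start at multiples of the step and
    only complete windows lying within the marker span are kept; windows
    containing no SNP are dropped.  If the chromosome span is shorter
    than one window, a single window covering the whole span is emitted.
    """
    if size_bp <= 0:
        raise ValueError("window size must be positive")
    step = size_bp // 2
    windows: list = []
    for c in snp_map.chromosomes():
        idx = np.flatnonzero(snp_map.chrom == c)
        pos = snp_map.pos[idx]
        first, last = int(pos[0]), int(pos[-1])
        c0 = max(0, (first - size_bp) // step + 1)
        added = False
        k = c0
        while k * step + size_bp <= last + 1:
            start = k * step
            lo = np.searchsorted(pos, start)
            hi = np.searchsorted(pos, start + size_bp)
            if hi > lo:
                windows.append(
                    Window(int(c), start, start + size_bp, idx[lo:hi])
                )
                added = True
            k += 1
        if not added:
            start = (first // step) * step
            windows.append(Window(int(c), start, start + size_bp, idx))
    return WindowSpec(size_bp=size_bp, step_bp=step, windows=windows)


@dataclass
class NRSConfig:
    """Non-replacement-sampling settings for the sharing analyses.

    ``chromosomes_per_group`` is the equal draw size per group (default
    ``None``: the smallest group's chromosome count, i.e. twice its
    individual count); the string ``"all"`` disables subsampling entirely
    (every chromosome of every group is used, deterministically).
    """

    chromosomes_per_group: int | None | str = None
    replicates: int = 100
    min_count: int = 2
    seed: int = 0


@dataclass
class HSPartition:
    """Four-category sharing percentages for one focal group."""

    focal: str
    others: list
    window_size: int
    categories: list                 # e.g. ["MY_private", "MY-CN", "MY-IN", "MY-CN-IN"]
    replicate_pct: np.ndarray        # (replicates, 4), each row sums to 100
    outgroup_share: np.ndarray | None  # (replicates, 4) fraction also in outgroup
    n_windows_used: np.ndarray       # windows with surviving focal haplotypes
    window_detail: list | None = None  # per replicate: (n_windows, 4) counts

    @property
    def mean_pct(self) -> np.ndarray:
        return self.replicate_pct.mean(axis=0)

    @property
    def sd_pct(self) -> np.ndarray:
        if self.replicate_pct.shape[0] < 2:
            return np.zeros(4)
        return self.replicate_pct.std(axis=0, ddof=1)


@dataclass
class _WindowCodes:
    """Distinct-haplotype integer codes per window, shared by all analyses."""

    codes: np.ndarray          # (n_chrom, n_windows) global haplotype ids
    window_of_id: np.ndarray   # (n_ids,) window index of each global id
    n_ids: int
    n_windows: int


def _encode_windows(H: HaplotypeSet, spec: WindowSpec) -> _WindowCodes:
    n_chrom = H.n_chromosomes
    codes = np.empty((n_chrom, len(spec)), dtype=np.int64)
    window_of_id: list = []
    offset = 0
    for w, win in enumerate(spec.windows):
        n_snps = len(win.snp_index)
        if n_snps <= 63:
            # exact bit-packing: each window haplotype becomes one integer
            packed = H.alleles[:, win.snp_index].astype(np.int64) @ (
                np.int64(1) << np.arange(n_snps, dtype=np.int64)
            )
            uniq, inverse = np.unique(packed, return_inverse=True)
        else:
            sub = np.ascontiguousarray(H.alleles[:, win.snp_index])
            uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
        codes[:, w] = offset + inverse.ravel()
        window_of_id.append(np.full(uniq.shape[0], w, dtype=np.int64))
        offset += uniq.shape[0]
    return _WindowCodes(
        codes=codes,
        window_of_id=np.concatenate(window_of_id),
        n_ids=offset,
        n_windows=len(spec),
    )


def _group_chromosomes(
    H: HaplotypeSet, labels: PopulationLabels, scheme: GroupScheme
) -> dict:
    by_group = labels.indices_by_group(H.individual_ids, scheme)
    out = {}
    for g, ind_ix in by_group.items():
        if len(ind_ix) == 0:
            raise ValueError(f"group {g!r} has no individuals")
        out[g] = np.concatenate([2 * ind_ix, 2 * ind_ix + 1])
    return out


def _resolve_draw(nrs: NRSConfig, chrom_groups: dict) -> int | None:
    if nrs.chromosomes_per_group == "all":
        return None
    if nrs.chromosomes_per_group is not None:
        draw = int(nrs.chromosomes_per_group)
    else:
        draw = min(len(v) for v in chrom_groups.values())
    for g, chroms in chrom_groups.items():
        if draw > len(chroms):
            raise ValueError(
                f"group {g!r} has only {len(chroms)} chromosomes, "
                f"cannot draw {draw}"
            )
    return draw


def _draw_groups(rng, chrom_groups: dict, draw: int | None, order) -> dict:
    if draw is None:
        return {g: chrom_groups[g] for g in order}
    return {
        g: rng.choice(chrom_groups[g], size=draw, replace=False) for g in order
    }


def _survivors(enc: _WindowCodes, drawn: np.ndarray, min_count: int) -> np.ndarray:
    counts = np.bincount(enc.codes[drawn].ravel(), minlength=enc.n_ids)
    return counts >= min_count


def classify_shared(
    H: HaplotypeSet,
    labels: PopulationLabels,
    scheme: GroupScheme,
    windows: WindowSpec,
    nrs: NRSConfig | None = None,
    encoding: _WindowCodes | None = None,
    keep_window_detail: bool = False,
) -> dict:
    """Four-category haplotype-sharing partition for each non-outgroup group.

    ``scheme`` must contain three groups (A, B, C) in comparison order,
    optionally followed by a fourth group treated as outgroup: it never
    changes the categories of the first three but its sharing with each
    category is recorded.  ``keep_window_detail`` retains per-window
    category counts for every replicate (memory proportional to
    replicates x windows).  Returns ``{focal group: HSPartition}``.
    """
    nrs = nrs or NRSConfig()
    group_ids = scheme.group_ids()
    if len(group_ids) not in (3, 4):
        raise ValueError("scheme must define 3 groups (plus optional outgroup)")
    core = group_ids[:3]
    outgroup = group_ids[3] if len(group_ids) == 4 else None
    chrom_groups = _group_chromosomes(H, labels, scheme)
    draw = _resolve_draw(nrs, chrom_groups)
    enc = encoding if encoding is not None else _encode_windows(H, windows)
    rng = np.random.default_rng(nrs.seed)

    reps_pct = {g: np.zeros((nrs.replicates, 4)) for g in core}
    reps_out = {g: np.zeros((nrs.replicates, 4)) for g in core} if outgroup else None
    reps_nw = {g: np.zeros(nrs.replicates, dtype=np.int64) for g in core}
    detail = {g: [] for g in core} if keep_window_detail else None

    for r in range(nrs.replicates):
        drawn = _draw_groups(rng, chrom_groups, draw, group_ids)
        survive = {g: _survivors(enc, drawn[g], nrs.min_count) for g in group_ids}
        for focal in core:
            b, c = [g for g in core if g != focal]
            s = survive[focal]
            in_b, in_c = survive[b], survive[c]
            cats = [
                s & ~in_b & ~in_c,       # private
                s & in_b & ~in_c,        # shared with B only
                s & ~in_b & in_c,        # shared with C only
                s & in_b & in_c,         # shared with all
            ]
            tot_w = np.bincount(enc.window_of_id[s], minlength=enc.n_windows)
            used = tot_w > 0
            reps_nw[focal][r] = int(used.sum())
            pct = np.zeros(4)
            cat_counts = np.zeros((enc.n_windows, 4), dtype=np.int64)
            for ci, mask in enumerate(cats):
                cnt_w = np.bincount(enc.window_of_id[mask], minlength=enc.n_windows)
                cat_counts[:, ci] = cnt_w
                pct[ci] = float(
                    (100.0 * cnt_w[used] / tot_w[used]).mean()
                ) if used.any() else np.nan
            reps_pct[focal][r] = pct
            if keep_window_detail:
                detail[focal].append(cat_counts)
            if outgroup:
                so = survive[outgroup]
                for ci, mask in enumerate(cats):
                    n_cat = mask.sum()
                    reps_out[focal][r, ci] = (
                        float((mask & so).sum() / n_cat) if n_cat else np.nan
                    )

    out: dict = {}
    for focal in core:
        b, c = [g for g in core if g != focal]
        out[focal] = HSPartition(
            focal=focal,
            others=[b, c],
            window_size=windows.size_bp,
            categories=[
                f"{focal}_private", f"{focal}-{b}", f"{focal}-{c}",
                f"{focal}-{b}-{c}",
            ],
            replicate_pct=reps_pct[focal],
            outgroup_share=reps_out[focal] if outgroup else None,
            n_windows_used=reps_nw[focal],
            window_detail=detail[focal] if keep_window_detail else None,
        )
    return out


def hs_summary(partitions: dict) -> pd.DataFrame:
    """Mean +/- sd of category percentages per focal group and window size."""
    rows = []
    for focal, part in partitions.items():
        for ci, cat in enumerate(part.categories):
            rows.append(
                {
                    "focal": focal,
                    "window_kb": part.window_size // 1000,
                    "category": cat,
                    "mean_pct": part.mean_pct[ci],
                    "sd_pct": part.sd_pct[ci],
                }
            )
        rows.append(
            {
                "focal": focal,
                "window_kb": part.window_size // 1000,
                "category": f"{focal}_found_in_either",
                "mean_pct": 100.0 - part.mean_pct[0],
                "sd_pct": part.sd_pct[0],
            }
        )
    return pd.DataFrame(rows)


def hs_distance_matrix(
    H: HaplotypeSet,
    labels: PopulationLabels,
    scheme: GroupScheme,
    windows: WindowSpec,
    nrs: NRSConfig | None = None,
    encoding: _WindowCodes | None = None,
    taxa: str = "categories",
) -> DistanceMatrix:
    """Weir–Cockerham distances from window haplotypes treated as alleles.

    With ``taxa="categories"`` (default) the taxa are haplotype-category
    pseudo-populations: chromosomes carrying haplotypes private to each
    of the three core groups, chromosomes carrying fully shared
    haplotypes, and (if a fourth group is present) outgroup chromosomes.
    With ``taxa="groups"`` the taxa are simply the drawn groups
    themselves, each represented by its surviving haplotype counts.  The
    exact construction behind a haplotype-sharing distance is a modelling
    choice; both readings are provided.

    Each window is one multi-allelic locus whose alleles are the
    surviving distinct haplotypes; pairwise theta is combined across
    windows as a ratio of sums and averaged over NRS replicates.
    Negative estimates report 0.
    """
    if taxa not in ("categories", "groups"):
        raise ValueError("taxa must be 'categories' or 'groups'")
    nrs = nrs or NRSConfig()
    group_ids = scheme.group_ids()
    if len(group_ids) < 3:
        raise ValueError("need at least 3 groups (plus optional outgroup)")
    core = group_ids[:3]
    outgroup = group_ids[3] if len(group_ids) >= 4 else None
    chrom_groups = _group_chromosomes(H, labels, scheme)
    draw = _resolve_draw(nrs, chrom_groups)
    enc = encoding if encoding is not None else _encode_windows(H, windows)
    rng = np.random.default_rng(nrs.seed)

    a_name, b_name, c_name = core
    if taxa == "categories":
        taxon_labels = [a_name, b_name, c_name, "shared"]
        if outgroup:
            taxon_labels.append(outgroup)
    else:
        taxon_labels = list(group_ids)

    n_taxa = len(taxon_labels)
    theta_sum = np.zeros((n_taxa, n_taxa))
    theta_n = np.zeros((n_taxa, n_taxa))
    wid = enc.window_of_id
    for r in range(nrs.replicates):
        drawn = _draw_groups(rng, chrom_groups, draw, group_ids)
        counts = {
            g: np.bincount(enc.codes[drawn[g]].ravel(), minlength=enc.n_ids)
            for g in group_ids
        }
        survive = {g: counts[g] >= nrs.min_count for g in group_ids}
        if taxa == "categories":
            sA, sB, sC = (survive[g] for g in core)
            members = [
                sA & ~sB & ~sC,
                sB & ~sA & ~sC,
                sC & ~sA & ~sB,
                sA & sB & sC,
            ]
            taxon_counts = [
                np.where(members[0], counts[a_name], 0),
                np.where(members[1], counts[b_name], 0),
                np.where(members[2], counts[c_name], 0),
                np.where(
                    members[3],
                    counts[a_name] + counts[b_name] + counts[c_name], 0,
                ),
            ]
            if outgroup:
                taxon_counts.append(
                    np.where(survive[outgroup], counts[outgroup], 0)
                )
        else:
            taxon_counts = [
                np.where(survive[g], counts[g], 0) for g in group_ids
            ]

        sizes = [
            np.bincount(wid, weights=tc, minlength=enc.n_windows)
            for tc in taxon_counts
        ]
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                ni = sizes[i][wid]
                nj = sizes[j][wid]
                ok = (ni >= 2) & (nj >= 2)
                if not ok.any():
                    continue
                pi = taxon_counts[i][ok] / ni[ok]
                pj = taxon_counts[j][ok] / nj[ok]
                a, t = _theta_components(pi, pj, ni[ok], nj[ok])
                if t.sum() != 0:
                    theta_sum[i, j] += a.sum() / t.sum()
                    theta_n[i, j] += 1

    values = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            if theta_n[i, j] == 0:
                values[i, j] = values[j, i] = np.nan
            else:
                theta = theta_sum[i, j] / theta_n[i, j]
                values[i, j] = values[j, i] = max(0.0, theta)
    keep = [i for i in range(n_taxa) if not np.isnan(values[i]).all()]
    if len(keep) < n_taxa:
        dropped = [taxon_labels[i] for i in range(n_taxa) if i not in keep]
        warnings.warn(f"dropping empty pseudo-population taxa: {dropped}")
        values = values[np.ix_(keep, keep)]
        taxon_labels = [taxon_labels[i] for i in keep]
    values = np.nan_to_num(values, nan=0.0)
    return DistanceMatrix(taxon_labels, values)
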