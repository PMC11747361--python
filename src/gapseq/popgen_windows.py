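"""Windowed population-genomic scan: SNP filtering, Tajima's D,
Weir-Cockerham F_ST, and permutation-based outlier regions.

The scan reproduces the analysis style used to compare two outbreeding
cultivars genotyped as diploid biallelic SNPs: sites are hard-filtered
(per-genotype depth, site quality, minor-allele frequency, call rate),
statistics are computed in non-overlapping windows tiling each sequence,
and two permutation nulls flag outliers:

* high F_ST — sample-to-population labels are permuted and each window's
  F_ST recomputed; a window is flagged when its observed value is in the
  extreme upper tail;
* low Tajima's D — sites are resampled without replacement into
  pseudo-windows with matched SNP counts (label permutation is undefined
  for a single-population statistic).

The regions of interest are the flagged high-F_ST windows that also show
significantly low D within a population: differentiated between groups and
unusually uniform within one.

F_ST follows Weir & Cockerham's variance-components estimator theta-hat
(per-site components a, b, c; window estimate = sum(a)/sum(a+b+c)).
Tajima's D uses the standard constants, computed from the mean observed
haplotype count of the window (missing genotypes reduce per-site counts).
P-values use the add-one estimator, so they are never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpFilterParams",
    "ScanParams",
    "GenotypeMatrix",
    "WindowStat",
    "OutlierScan",
    "filter_snps",
    "tajima_d",
    "wc_fst",
    "window_scan",
    "permutation_outliers",
    "stats_frame",
]


@dataclass(frozen=True)
class SnpFilterParams:
    min_dp: int = 5
    min_q: float = 200.0
    maf: float = 0.05
    max_maf: float = 0.95
    max_missing: float = 0.8  # minimum call-rate fraction
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.max_missing <= 1):
            raise ValueError("max_missing (call-rate floor) must be in (0, 1]")
        if not (0 <= self.maf <= self.max_maf <= 1):
            raise ValueError("need 0 <= maf <= max_maf <= 1")


@dataclass(frozen=True)
class ScanParams:
    window: int = 100_000
    n_perm: int = 10_000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes: one row per site, one column per sample.

    ``gt`` holds alt-allele copy counts (0/1/2) with -1 for missing.
    """

    chrom: np.ndarray  # (S,) str
    pos: np.ndarray  # (S,) int, 0-based
    gt: np.ndarray  # (S, N) int8
    samples: list[str]
    pops: np.ndarray | None = None  # (N,) population label per sample
    seq_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pop_names(self) -> list[str]:
        if self.pops is None:
            return []
        return sorted(set(self.pops.tolist()))

    def pop_columns(self, pop: str) -> np.ndarray:
        if self.pops is None:
            raise ValueError("no population labels attached")
        return np.flatnonzero(self.pops == pop)


@dataclass
class WindowStat:
    seq_id: str
    start: int
    end: int
    n_snps: int
    tajima_d: dict[str, float | None]
    fst: float | None
    p_fst_high: float | None = None
    p_d_low: dict[str, float | None] = field(default_factory=dict)


@dataclass
class OutlierScan:
    stats: list[WindowStat]
    high_fst: list[int]  # window indices with p_fst_high < alpha
    low_d: dict[str, list[int]]  # per population: high-FST windows also low in D


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>population`` map."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


def filter_snps(
    vcf_path: str | Path,
    params: SnpFilterParams = SnpFilterParams(),
    popmap: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Load a VCF and apply the hard filters, returning a genotype matrix.

    Per-genotype depths below ``min_dp`` are set missing first; a site is
    kept iff it is a biallelic SNP with ``QUAL >= min_q``, call rate
    ``>= max_missing``, and post-mask alt-allele frequency within
    ``[maf, max_maf]``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    for var in vcf:
        if params.biallelic_only and not (
            var.is_snp and len(var.ALT) == 1 and len(var.REF) == 1
        ):
            continue
        if var.QUAL is None or var.QUAL < params.min_q:
            continue
        try:
            g = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 alt copies, 3 unknown
        except Exception as exc:
            raise ValueError(f"malformed genotypes at {var.CHROM}:{var.POS}: {exc}") from exc
        g = np.where(g == 3, -1, g).astype(np.int8)
        depths = var.format("DP")
        if depths is not None:
            g = np.where(depths.ravel() < params.min_dp, np.int8(-1), g)
        called = g >= 0
        n_called = int(called.sum())
        if n_called / len(samples) < params.max_missing or n_called == 0:
            continue
        af = float(g[called].sum()) / (2 * n_called)
        if not (params.maf <= af <= params.max_maf):
            continue
        rows.append(g)
        chroms.append(var.CHROM)
        positions.append(var.POS - 1)  # VCF is 1-based

    seq_lengths = {}
    try:
        seq_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        pass

    if rows:
        order = np.lexsort((np.asarray(positions), np.asarray(chroms)))
        gt = np.vstack(rows)[order]
        chrom_arr = np.asarray(chroms)[order]
        pos_arr = np.asarray(positions)[order]
    else:
        gt = np.zeros((0, len(samples)), dtype=np.int8)
        chrom_arr = np.asarray([], dtype=object)
        pos_arr = np.asarray([], dtype=int)

    pops = None
    if popmap is not None:
        missing = [s for s in samples if s not in popmap]
        if missing:
            raise KeyError(f"samples missing from population map: {missing[:5]}")
        pops = np.asarray([popmap[s] for s in samples])
    return GenotypeMatrix(chrom_arr, pos_arr, gt, samples, pops, seq_lengths)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _site_summaries(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (pi, segregating flag, haplotype count, usable flag)."""
    called = gt >= 0
    n = 2 * called.sum(axis=1)
    c = np.where(called, gt, 0).sum(axis=1)
    usable = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(usable, c * (n - c) / (n * (n - 1) / 2.0), 0.0)
    seg = usable & (c > 0) & (c < n)
    return pi, seg.astype(float), np.where(usable, n, 0), usable.astype(float)


def tajima_d(gt: np.ndarray, per_site: bool = False) -> float | None:
    """Tajima's D from a (sites x samples) diploid genotype block.

    Allele counts are used directly (phase not required). Missing when
    there are no segregating sites or the variance term is non-positive.
    With ``per_site`` set, Watterson's theta sums per-site ``1/a1(n_i)``
    instead of using the window-mean haplotype count.
    """
    gt = np.atleast_2d(np.asarray(gt))
    pi_site, seg, n_site, usable = _site_summaries(gt)
    S = int(seg.sum())
    if S == 0:
        return None
    n_mean = n_site.sum() / usable.sum()
    n = int(round(n_mean))
    if n < 2:
        return None
    a1, e1, e2 = _tajima_constants(n)
    if per_site:
        ns = n_site[seg > 0].astype(int)
        theta_w = sum(1.0 / _tajima_constants(int(ni))[0] for ni in ns if ni >= 2)
    else:
        theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float((pi_site.sum() - theta_w) / math.sqrt(var))


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def _fst_components_masked(
    gt: np.ndarray, member1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site W&C components for 2 populations, vectorised over label sets.

    ``member1`` is an (N, P) 0/1 matrix of pop-1 membership (P label
    assignments evaluated at once; pop 2 is the complement). Returns per-
    site arrays ``a`` and ``a+b+c`` of shape (S, P); sites lacking two
    called diploids in either population contribute zero.
    """
    gt = np.asarray(gt)
    called = (gt >= 0).astype(np.float64)
    altc = np.where(gt >= 0, gt, 0).astype(np.float64)
    het = (gt == 1).astype(np.float64)
    member1 = np.asarray(member1, dtype=np.float64)
    if member1.ndim == 1:
        member1 = member1[:, None]

    n1 = called @ member1  # called diploids in pop 1, (S, P)
    s1 = altc @ member1
    h1 = het @ member1
    nT = called.sum(axis=1, keepdims=True)
    sT = altc.sum(axis=1, keepdims=True)
    hT = het.sum(axis=1, keepdims=True)
    n2, s2_, h2 = nT - n1, sT - s1, hT - h1

    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = s1 / (2 * n1)
        p2 = s2_ / (2 * n2)
        hf1 = h1 / n1
        hf2 = h2 / n2
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * hf1 + n2 * hf2) / (2.0 * nbar)
        inner = pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        d = a + b + c
    a = np.where(ok, a, 0.0)
    d = np.where(ok, d, 0.0)
    return a, d


def wc_fst(gt: np.ndarray, labels: Sequence[str]) -> float | None:
    """Weir & Cockerham theta-hat for one window (ratio of sums over sites).

    Requires exactly two populations; sites need two called diploids per
    population to contribute. Missing when the denominator is zero.
    """
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError(f"wc_fst compares exactly 2 populations, got {len(names)}")
    member1 = (labels == names[0]).astype(float)
    a, d = _fst_components_masked(np.atleast_2d(gt), member1)
    num, den = float(a.sum()), float(d.sum())
    if den == 0.0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# windowing and permutation nulls
# ---------------------------------------------------------------------------


def _windows(matrix: GenotypeMatrix, window: int) -> list[tuple[str, int, int, int, int]]:
    """Tile every sequence as (seq_id, start, end, site_lo, site_hi)."""
    out: list[tuple[str, int, int, int, int]] = []
    seq_ids = sorted(set(matrix.seq_lengths) | set(np.unique(matrix.chrom).tolist()))
    for seq_id in seq_ids:
        in_seq = np.flatnonzero(matrix.chrom == seq_id)
        pos = matrix.pos[in_seq]
        length = matrix.seq_lengths.get(seq_id, int(pos.max()) + 1 if len(pos) else window)
        base = int(in_seq[0]) if len(in_seq) else matrix.n_sites
        for start in range(0, length, window):
            end = min(start + window, length)
            lo = base + int(np.searchsorted(pos, start, side="left"))
            hi = base + int(np.searchsorted(pos, end, side="left"))
            out.append((seq_id, start, end, lo, hi))
    return out


def window_scan(matrix: GenotypeMatrix, params: ScanParams = ScanParams()) -> list[WindowStat]:
    """Per-window SNP count, Tajima's D per population, and F_ST.

    Windows tile each sequence as [0, w), [w, 2w), ... including the
    trailing partial window; empty windows carry missing statistics.
    """
    pops = matrix.pop_names()
    pop_cols = {p: matrix.pop_columns(p) for p in pops}
    two_pops = len(pops) == 2
    stats: list[WindowStat] = []
    for seq_id, start, end, lo, hi in _windows(matrix, params.window):
        block = matrix.gt[lo:hi]
        n_snps = hi - lo
        d_vals: dict[str, float | None] = {}
        if pops:
            for p in pops:
                d_vals[p] = tajima_d(block[:, pop_cols[p]]) if n_snps else None
        else:
            d_vals["all"] = tajima_d(block) if n_snps else None
        fst = None
        if two_pops and n_snps:
            fst = wc_fst(block, matrix.pops)
        stats.append(WindowStat(seq_id, start, end, n_snps, d_vals, fst))
    return stats


def _reduceat_windows(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(arr, starts, axis=0)


def permutation_outliers(
    stats: list[WindowStat],
    matrix: GenotypeMatrix,
    params: ScanParams = ScanParams(),
) -> OutlierScan:
    """Attach permutation p-values to windows and flag outlier regions.

    ``p_fst_high`` comes from permuting sample-to-population labels;
    ``p_d_low`` (per population) from resampling sites without replacement
    into pseudo-windows of matched SNP count. Both use the add-one
    estimator ``(1 + #extreme) / (n_perm + 1)``. Flagged regions are the
    high-F_ST windows; within them, per-population low-D windows give the
    intersection. Undefined permuted statistics count toward the tail
    (conservative).
    """
    rng = np.random.default_rng(params.seed)
    pops = matrix.pop_names()
    if len(pops) != 2:
        raise ValueError("permutation_outliers requires exactly 2 populations")
    P = params.n_perm

    nonempty = [i for i, w in enumerate(stats) if w.n_snps > 0]
    if not nonempty:
        return OutlierScan(stats, [], {p: [] for p in pops})
    win_sizes = np.asarray([stats[i].n_snps for i in nonempty])
    site_order = np.concatenate(
        [np.arange(*_stat_slice(stats, matrix, i)) for i in nonempty]
    )
    gt = matrix.gt[site_order]
    starts = np.concatenate([[0], np.cumsum(win_sizes)[:-1]])

    # --- F_ST null: label permutations ------------------------------------
    member_true = (matrix.pops == pops[0]).astype(float)
    members = np.empty((len(matrix.samples), P + 1))
    members[:, 0] = member_true
    for j in range(1, P + 1):
        members[:, j] = rng.permutation(member_true)
    a, d = _fst_components_masked(gt, members)
    a_sum = _reduceat_windows(a, starts)
    d_sum = _reduceat_windows(d, starts)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst_all = a_sum / d_sum  # (W, P+1), nan where denominator 0
    fst_obs, fst_perm = fst_all[:, 0], fst_all[:, 1:]

    # --- Tajima's D null: site resampling into matched pseudo-windows ------
    d_obs: dict[str, np.ndarray] = {}
    d_perm: dict[str, np.ndarray] = {}
    for p in pops:
        cols = matrix.pop_columns(p)
        pi_s, seg_s, n_s, use_s = _site_summaries(gt[:, cols])
        site_stack = np.stack([pi_s, seg_s, n_s.astype(float), use_s], axis=1)
        d_obs[p] = _d_from_sums(_reduceat_windows(site_stack, starts))
        perms = np.empty((len(nonempty), P))
        for j in range(P):
            shuffled = site_stack[rng.permutation(len(site_stack))]
            perms[:, j] = _d_from_sums(_reduceat_windows(shuffled, starts))
        d_perm[p] = perms

    # --- p-values and flags -------------------------------------------------
    high_fst: list[int] = []
    low_d: dict[str, list[int]] = {p: [] for p in pops}
    for row, i in enumerate(nonempty):
        w = stats[i]
        if not np.isnan(fst_obs[row]):
            extreme = np.isnan(fst_perm[row]) | (fst_perm[row] >= fst_obs[row])
            w.p_fst_high = float((1 + extreme.sum()) / (P + 1))
        for p in pops:
            if not np.isnan(d_obs[p][row]):
                extreme = np.isnan(d_perm[p][row]) | (d_perm[p][row] <= d_obs[p][row])
                w.p_d_low[p] = float((1 + extreme.sum()) / (P + 1))
        if w.p_fst_high is not None and w.p_fst_high < params.alpha:
            high_fst.append(i)
            for p in pops:
                pd_ = w.p_d_low.get(p)
                if pd_ is not None and pd_ < params.alpha:
                    low_d[p].append(i)
    return OutlierScan(stats, high_fst, low_d)


def _stat_slice(stats: list[WindowStat], matrix: GenotypeMatrix, i: int) -> tuple[int, int]:
    w = stats[i]
    in_seq = np.flatnonzero(matrix.chrom == w.seq_id)
    pos = matrix.pos[in_seq]
    base = int(in_seq[0])
    lo = base + int(np.searchsorted(pos, w.start, side="left"))
    hi = base + int(np.searchsorted(pos, w.end, side="left"))
    return lo, hi


_HARMONIC_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _harmonics(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    cached = _HARMONIC_CACHE.get(n_max)
    if cached is None:
        inv = np.concatenate([[0.0], 1.0 / np.arange(1, n_max + 1)])
        a1 = np.cumsum(inv)  # a1[n] = sum_{i<=n} 1/i; a1 of sample size n is a1[n-1]
        a2 = np.cumsum(inv**2)
        cached = (a1, a2)
        _HARMONIC_CACHE[n_max] = cached
    return cached


def _d_from_sums(sums: np.ndarray) -> np.ndarray:
    """Vectorised Tajima's D from per-window sums of (pi, seg, n, used)."""
    pi, S, n_tot, used = sums[:, 0], sums[:, 1], sums[:, 2], sums[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(used > 0, np.rint(n_tot / np.maximum(used, 1)), 0).astype(int)
    n = np.maximum(n, 0)
    a1_tab, a2_tab = _harmonics(int(n.max()) + 1 if len(n) else 2)
    nn = np.maximum(n, 2)
    a1 = a1_tab[nn - 1]
    a2 = a2_tab[nn - 1]
    b1 = (nn + 1) / (3.0 * (nn - 1))
    b2 = 2.0 * (nn**2 + nn + 3) / (9.0 * nn * (nn - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nn + 2) / (a1 * nn) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (pi - S / a1) / np.sqrt(var)
    d = np.where((S > 0) & (var > 0) & (n >= 2), d, np.nan)
    return d


def stats_frame(stats: list[WindowStat]) -> pd.DataFrame:
    """Flatten window statistics into a tidy table (one row per window)."""
    rows = []
    for w in stats:
        row: dict[str, object] = {
            "seq_id": w.seq_id,
            "start": w.start,
            "end": w.end,
            "n_snps": w.n_snps,
            "fst": w.fst,
            "p_fst_high": w.p_fst_high,
        }
        for p, v in w.tajima_d.items():
            row[f"tajima_d_{p}"] = v
        for p, v in w.p_d_low.items():
            row[f"p_d_low_{p}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
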