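"""Independent brute-force oracles and small simulation helpers for tests.

The oracles transcribe the published formulas directly and share no code
with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

from gapseq.io_formats import PafRecord
from gapseq.simdata import Fragmentation


def tajima_d_oracle(gt: np.ndarray) -> float | None:
    """Tajima (1989) D, computed naively from per-site allele counts."""
    gt = np.atleast_2d(np.asarray(gt))
    pi = 0.0
    S = 0
    ns = []
    for row in gt:
        called = row[row >= 0]
        n = 2 * len(called)
        if n < 2:
            continue
        ns.append(n)
        c = int(called.sum())
        pi += c * (n - c) / (n * (n - 1) / 2)
        if 0 < c < n:
            S += 1
    if S == 0 or not ns:
        return None
    n = int(round(sum(ns) / len(ns)))
    if n < 2:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi - S / a1) / math.sqrt(var)


def wc_fst_oracle(gt: np.ndarray, labels) -> float | None:
    """Weir & Cockerham (1984) theta-hat, per-site a/b/c summed naively."""
    gt = np.atleast_2d(np.asarray(gt))
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    assert len(names) == 2
    num = den = 0.0
    for row in gt:
        groups = []
        for name in names:
            g = row[labels == name]
            g = g[g >= 0]
            groups.append(g)
        if any(len(g) < 2 for g in groups):
            continue
        r = 2
        n = [len(g) for g in groups]
        p = [g.sum() / (2 * len(g)) for g in groups]
        h = [np.mean(g == 1) for g in groups]
        nbar = sum(n) / r
        nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    if den == 0.0:
        return None
    return num / den


def nx_oracle(lengths) -> tuple[int, int]:
    """Brute-force N50/L50: sort descending, walk the cumulative sum."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    cum = 0
    for rank, ln in enumerate(lengths, 1):
        cum += ln
        if cum * 2 >= total:
            return ln, rank
    raise AssertionError


def random_genotypes(rng: np.random.Generator, n_sites: int, n_samples: int,
                     missing_rate: float = 0.1) -> np.ndarray:
    p = rng.uniform(0.05, 0.95, size=n_sites)
    gt = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    gt[rng.random(gt.shape) < missing_rate] = -1
    return gt


def paf_reads_to_contigs(reads, frag: Fragmentation) -> list[PafRecord]:
    """Exact read-to-contig alignments from simulated read origins.

    Read ids carry ``read|chrom|start|end|strand``; every overlap with a
    fragment becomes one perfect PAF block with coordinates mapped into
    read and contig local space.
    """
    by_chrom: dict[str, list] = {}
    for fr in frag.fragments:
        by_chrom.setdefault(fr.chrom, []).append(fr)
    out = []
    for read in reads:
        _, chrom, start, end, strand = read.id.split("|")
        start, end = int(start), int(end)
        qlen = end - start
        for fr in by_chrom.get(chrom, ()):
            s, e = max(start, fr.start), min(end, fr.end)
            if s >= e:
                continue
            if strand == "+":
                qs, qe = s - start, e - start
            else:
                qs, qe = end - e, end - s
            if fr.orientation == "+":
                ts, te = s - fr.start, e - fr.start
            else:
                ts, te = fr.end - e, fr.end - s
            aln_strand = "+" if strand == fr.orientation else "-"
            out.append(
                PafRecord(read.id, qlen, qs, qe, aln_strand, fr.contig_id,
                          fr.end - fr.start, ts, te, e - s, e - s, 60)
            )
    return out


def joins_from_layouts(layouts) -> set[frozenset]:
    """The set of end-joins implied by a list of layouts."""
    made = set()
    for layout in layouts:
        for (c1, o1, _), (c2, o2, _) in zip(layout.parts, layout.parts[1:]):
            e1 = (c1, "tail" if o1 == "+" else "head")
            e2 = (c2, "head" if o2 == "+" else "tail")
            made.add(frozenset([e1, e2]))
    return made
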