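"""Seeded synthetic-data generators: truth-known inputs for every stage.

Every generator is a pure function of its parameters and seed. The models
are deliberately simple — uniform-random DNA, substitution-only read
errors with constant per-read quality, a Poisson toy model for k-mer
spectra, and Balding-Nichols allele frequencies parameterised directly by
F_ST — so that each pipeline stage can be tested against exact truth
without downloads or external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .asm_stats import DEFAULT_TELOMERE_MOTIF, KmerHistogram
from .io_formats import Interval, PafRecord, QualRead, revcomp
from .popgen_windows import GenotypeMatrix

__all__ = [
    "SimGenomeTruth",
    "Fragmentation",
    "SimPopTruth",
    "simulate_genome",
    "fragment_genome",
    "simulate_long_reads",
    "simulate_kmer_histogram",
    "simulate_two_pop_genotypes",
    "paf_from_fragmentations",
    "write_vcf",
    "write_popmap",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


@dataclass
class FragmentRecord:
    contig_id: str
    chrom: str
    start: int  # genome coordinates of the fragment (forward strand)
    end: int
    orientation: str  # orientation of the emitted contig relative to genome


@dataclass
class SimGenomeTruth:
    sequences: dict[str, str]
    telomeres: list[Interval]
    repeats: list[Interval]
    telomere_motif: str = DEFAULT_TELOMERE_MOTIF


@dataclass
class Fragmentation:
    """A contig set carved from a simulated genome, with truth adjacencies.

    ``adjacencies`` lists ``((contig_id, side), (contig_id, side), gap)``
    for each withheld gap, in terms of the emitted (possibly flipped)
    contig orientations.
    """

    contigs: dict[str, str]
    fragments: list[FragmentRecord]
    adjacencies: list[tuple[tuple[str, str], tuple[str, str], int]]


@dataclass
class SimPopTruth:
    matrix: GenotypeMatrix
    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    fst_target: float
    outlier_windows: list[int]
    window: int
    ref: np.ndarray = field(default_factory=lambda: np.asarray([]))
    alt: np.ndarray = field(default_factory=lambda: np.asarray([]))


def simulate_genome(
    n_chrom: int = 1,
    chrom_len: int = 1_000_000,
    telomere_motif: str = DEFAULT_TELOMERE_MOTIF,
    repeat_density: float = 0.0,
    seed: int = 0,
    telomere_copies: int = 40,
) -> SimGenomeTruth:
    """Random chromosomes with telomere arrays at both ends and optional
    interspersed copies of a fixed 500-bp repeat cassette.

    ``repeat_density`` is cassettes per Mb; cassette placements are
    recorded as repeat intervals. Deterministic given the seed.
    """
    if chrom_len < 50_000:
        raise ValueError("chrom_len must be >= 50 kb")
    rng = np.random.default_rng(seed)
    cassette = _random_dna(rng, 500)
    head = telomere_motif * telomere_copies
    tail = revcomp(telomere_motif) * telomere_copies
    sequences: dict[str, str] = {}
    telomeres: list[Interval] = []
    repeats: list[Interval] = []
    for ci in range(1, n_chrom + 1):
        name = f"chr{ci}"
        seq = list(_random_dna(rng, chrom_len))
        seq[: len(head)] = head
        seq[chrom_len - len(tail) :] = tail
        n_cassettes = int(round(repeat_density * chrom_len / 1e6))
        lo, hi = len(head) + 1_000, chrom_len - len(tail) - 1_000 - len(cassette)
        for start in sorted(rng.integers(lo, hi, size=n_cassettes).tolist()):
            seq[start : start + len(cassette)] = cassette
            repeats.append(Interval(name, start, start + len(cassette), "cassette"))
        sequences[name] = "".join(seq)
        telomeres.append(Interval(name, 0, len(head), "telomere_head"))
        telomeres.append(Interval(name, chrom_len - len(tail), chrom_len, "telomere_tail"))
    return SimGenomeTruth(sequences, telomeres, repeats, telomere_motif)


def fragment_genome(
    truth: SimGenomeTruth,
    n_contigs: int,
    min_gap: int = 100,
    max_gap: int = 1_000,
    seed: int = 0,
    min_contig: int = 10_000,
    flip_prob: float = 0.5,
    tag: str = "c",
) -> Fragmentation:
    """Carve each chromosome into contigs separated by withheld gaps.

    Gap sizes are uniform in ``[min_gap, max_gap]``; contig lengths are a
    random split with a ``min_contig`` floor; each contig is independently
    reverse-complemented with probability ``flip_prob`` (truth records the
    orientation). Concatenating fragments and gap sequence in truth order
    reproduces the chromosome exactly.
    """
    if n_contigs < 2:
        raise ValueError("need >= 2 contigs per chromosome")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    fragments: list[FragmentRecord] = []
    adjacencies: list[tuple[tuple[str, str], tuple[str, str], int]] = []
    for chrom in sorted(truth.sequences):
        seq = truth.sequences[chrom]
        L = len(seq)
        gaps = rng.integers(min_gap, max_gap + 1, size=n_contigs - 1)
        spare = L - int(gaps.sum()) - n_contigs * min_contig
        if spare < 0:
            raise ValueError("gaps exceed chromosome length")
        weights = rng.random(n_contigs)
        extra = np.floor(spare * weights / weights.sum()).astype(int)
        lengths = min_contig + extra
        lengths[-1] += L - int(gaps.sum()) - int(lengths.sum())  # absorb rounding
        pos = 0
        prev: tuple[str, str] | None = None
        prev_gap = 0
        for i in range(n_contigs):
            cid = f"{chrom}_{tag}{i + 1:02d}"
            start, end = pos, pos + int(lengths[i])
            flipped = bool(rng.random() < flip_prob)
            orient = "-" if flipped else "+"
            frag = seq[start:end]
            contigs[cid] = revcomp(frag) if flipped else frag
            fragments.append(FragmentRecord(cid, chrom, start, end, orient))
            this_head = ("head" if orient == "+" else "tail")
            if prev is not None:
                adjacencies.append((prev, (cid, this_head), prev_gap))
            prev = (cid, "tail" if orient == "+" else "head")
            pos = end
            if i < n_contigs - 1:
                prev_gap = int(gaps[i])
                pos += prev_gap
    return Fragmentation(contigs, fragments, adjacencies)


def fragment_genome_at(
    truth: SimGenomeTruth,
    cuts: dict[str, Sequence[int]],
    gap: int = 200,
    seed: int = 0,
    flip_prob: float = 0.0,
    tag: str = "c",
) -> Fragmentation:
    """Carve chromosomes at explicit cut positions (deterministic geometry).

    A cut at ``c`` withholds the gap ``[c - gap, c)``: the left contig ends
    at ``c - gap`` and the right contig starts at ``c``. Useful for
    constructing fragmentations whose junctions interleave with another
    fragmentation's.
    """
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    fragments: list[FragmentRecord] = []
    adjacencies: list[tuple[tuple[str, str], tuple[str, str], int]] = []
    for chrom in sorted(truth.sequences):
        seq = truth.sequences[chrom]
        bounds = sorted(cuts.get(chrom, ()))
        if any(c - gap <= 0 or c >= len(seq) for c in bounds):
            raise ValueError("cut points (minus gap) must fall inside the chromosome")
        starts = [0] + list(bounds)
        ends = [c - gap for c in bounds] + [len(seq)]
        prev: tuple[str, str] | None = None
        for i, (start, end) in enumerate(zip(starts, ends)):
            cid = f"{chrom}_{tag}{i + 1:02d}"
            flipped = bool(rng.random() < flip_prob)
            orient = "-" if flipped else "+"
            frag = seq[start:end]
            contigs[cid] = revcomp(frag) if flipped else frag
            fragments.append(FragmentRecord(cid, chrom, start, end, orient))
            if prev is not None:
                adjacencies.append((prev, (cid, "head" if orient == "+" else "tail"), gap))
            prev = (cid, "tail" if orient == "+" else "head")
    return Fragmentation(contigs, fragments, adjacencies)


def simulate_long_reads(
    truth: SimGenomeTruth,
    n_reads: int,
    mean_len: float = 12_000,
    len_sd: float = 2_000,
    error_rate: float = 0.01,
    seed: int = 0,
) -> list[QualRead]:
    """Sample reads from the full genome (so some span withheld gaps).

    Lengths are normal-truncated, substitutions occur at ``error_rate``,
    the quality string is constant at the Phred equivalent of the error
    rate, and the strand is random. Read ids record the origin as
    ``read<i>|chrom|start|end|strand`` for truth evaluation.
    """
    if mean_len <= 0:
        raise ValueError("mean_len must be positive")
    if not (0 <= error_rate < 0.2):
        raise ValueError("error_rate must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    chroms = sorted(truth.sequences)
    lens = np.array([len(truth.sequences[c]) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    qv = 60 if error_rate == 0 else int(round(-10 * math.log10(error_rate)))
    reads: list[QualRead] = []
    for i in range(n_reads):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        L = len(truth.sequences[chrom])
        rlen = int(np.clip(rng.normal(mean_len, len_sd), 500, L))
        start = int(rng.integers(0, L - rlen + 1))
        frag = truth.sequences[chrom][start : start + rlen]
        if error_rate > 0:
            arr = np.frombuffer(frag.encode(), dtype="S1").copy()
            hits = np.flatnonzero(rng.random(rlen) < error_rate)
            for j in hits:
                choices = [b for b in b"ACGT" if bytes([b]) != arr[j]]
                arr[j] = bytes([choices[rng.integers(0, 3)]])
            frag = arr.tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        rid = f"read{i:06d}|{chrom}|{start}|{start + rlen}|{strand}"
        reads.append(QualRead(rid, frag, (qv,) * rlen))
    return reads


def simulate_kmer_histogram(
    genome_size: int,
    coverage: float,
    error_rate: float = 0.0,
    k: int = 21,
    seed: int = 0,
    het_fraction: float = 0.0,
) -> KmerHistogram:
    """Toy k-mer spectrum: per-k-mer depth ~ Poisson(c * (1-e)^k).

    A ``het_fraction`` of genomic k-mers is split over two haplotypes and
    drawn at half depth (producing the heterozygous peak); erroneous
    k-mers (k per substitution, assumed unique) are added at multiplicity
    1. This emulates the shape a k-mer counter would report without
    counting any actual reads.
    """
    rng = np.random.default_rng(seed)
    lam = coverage * (1.0 - error_rate) ** k
    n_het = int(round(het_fraction * genome_size))
    n_hom = genome_size - n_het
    depths = rng.poisson(lam, size=n_hom)
    if n_het:
        depths = np.concatenate([depths, rng.poisson(lam / 2.0, size=2 * n_het)])
    counts = np.bincount(depths)
    n_error_kmers = rng.poisson(genome_size * coverage * error_rate * k)
    if len(counts) < 2:
        counts = np.pad(counts, (0, 2 - len(counts)))
    counts[1] += n_error_kmers
    pairs = tuple((m, int(c)) for m, c in enumerate(counts) if m >= 1 and c > 0)
    return KmerHistogram(pairs, k=k)


def simulate_two_pop_genotypes(
    n_sites: int = 2_000,
    n_per_pop: int = 50,
    fst_target: float = 0.1,
    outlier_windows: Sequence[int] = (),
    window: int = 100_000,
    chrom_len: int | None = None,
    seed: int = 0,
    pop_labels: tuple[str, str] = ("pop1", "pop2"),
) -> SimPopTruth:
    """Balding-Nichols two-population diploid genotypes on one chromosome.

    Ancestral frequencies are Uniform(0.05, 0.95); population frequencies
    follow Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target F_ST (F = 0:
    both populations share p exactly). ``outlier_windows`` (window
    indices) are planted as fixed differences. Genotypes are
    Binomial(2, p_pop); sites sit at uniform unique positions.
    """
    if not (0 <= fst_target < 1):
        raise ValueError("fst_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if chrom_len is None:
        chrom_len = 50 * window
    # unique sorted positions
    pool = np.unique(rng.integers(0, chrom_len, size=int(n_sites * 1.3) + 16))
    while len(pool) < n_sites:
        pool = np.unique(
            np.concatenate([pool, rng.integers(0, chrom_len, size=n_sites)])
        )
    pos = np.sort(rng.choice(pool, size=n_sites, replace=False))

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    if fst_target == 0:
        p1, p2 = p_anc.copy(), p_anc.copy()
    else:
        f = fst_target
        a_shape = p_anc * (1 - f) / f
        b_shape = (1 - p_anc) * (1 - f) / f
        p1 = rng.beta(a_shape, b_shape)
        p2 = rng.beta(a_shape, b_shape)

    outlier_windows = sorted(outlier_windows)
    win_idx = pos // window
    planted = np.isin(win_idx, outlier_windows)
    p1[planted] = 1.0
    p2[planted] = 0.0

    g1 = rng.binomial(2, p1[:, None], size=(n_sites, n_per_pop))
    g2 = rng.binomial(2, p2[:, None], size=(n_sites, n_per_pop))
    gt = np.concatenate([g1, g2], axis=1).astype(np.int8)

    samples = [f"{pop_labels[0]}_{i:03d}" for i in range(n_per_pop)] + [
        f"{pop_labels[1]}_{i:03d}" for i in range(n_per_pop)
    ]
    pops = np.asarray([pop_labels[0]] * n_per_pop + [pop_labels[1]] * n_per_pop)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    matrix = GenotypeMatrix(
        chrom=np.asarray(["chr1"] * n_sites),
        pos=pos,
        gt=gt,
        samples=samples,
        pops=pops,
        seq_lengths={"chr1": chrom_len},
    )
    return SimPopTruth(
        matrix,
        p_anc,
        {pop_labels[0]: p1, pop_labels[1]: p2},
        fst_target,
        list(outlier_windows),
        window,
        ref=bases[ref_idx].astype("U1"),
        alt=bases[alt_idx].astype("U1"),
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(truth: SimPopTruth, path, qual: float = 999.0, depth: int = 30) -> None:
    """Write the simulated genotypes as VCF v4.2 (GT:DP), passing the
    default hard filters by construction."""
    m = truth.matrix
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for seq_id, length in m.seq_lengths.items():
            fh.write(f"##contig=<ID={seq_id},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        for i in range(m.n_sites):
            cells = [f"{_GT_STRINGS[int(g)]}:{depth}" for g in m.gt[i]]
            fh.write(
                f"{m.chrom[i]}\t{m.pos[i] + 1}\t.\t{truth.ref[i]}\t{truth.alt[i]}\t"
                f"{qual:g}\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def write_popmap(truth: SimPopTruth, path) -> None:
    m = truth.matrix
    with open(path, "w") as fh:
        for sample, pop in zip(m.samples, m.pops):
            fh.write(f"{sample}\t{pop}\n")


def paf_from_fragmentations(
    frag_query: Fragmentation, frag_target: Fragmentation
) -> list[PafRecord]:
    """Exact alignments between two fragmentations of the same genome.

    Every genomic overlap between a query fragment and a target fragment
    becomes one perfect PAF block with coordinates mapped into the emitted
    (possibly flipped) contig orientations. Stands in for a whole-genome
    aligner on synthetic data.
    """
    out: list[PafRecord] = []
    by_chrom: dict[str, list[FragmentRecord]] = {}
    for fr in frag_target.fragments:
        by_chrom.setdefault(fr.chrom, []).append(fr)
    for q in frag_query.fragments:
        qlen = q.end - q.start
        for t in by_chrom.get(q.chrom, ()):
            s, e = max(q.start, t.start), min(q.end, t.end)
            if s >= e:
                continue
            tlen = t.end - t.start
            if q.orientation == "+":
                qs, qe = s - q.start, e - q.start
            else:
                qs, qe = q.end - e, q.end - s
            if t.orientation == "+":
                ts, te = s - t.start, e - t.start
            else:
                ts, te = t.end - e, t.end - s
            strand = "+" if q.orientation == t.orientation else "-"
            out.append(
                PafRecord(
                    q.contig_id, qlen, qs, qe, strand,
                    t.contig_id, tlen, ts, te, e - s, e - s, 60,
                )
            )
    return out
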