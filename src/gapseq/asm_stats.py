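"""Assembly QC: contiguity statistics, k-mer genome-size estimation,
coverage fold, and telomere end scanning.

The genome-size estimator follows the usual k-mer-spectrum recipe: discard
the error region left of the first local minimum, find coverage peaks in the
lightly smoothed spectrum, and divide the retained k-mer mass by the
homozygous-peak multiplicity. Two detected peaks flag a heterozygous
spectrum; the highest-multiplicity peak is taken as the homozygous one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

from .io_formats import SeqRecord, revcomp

__all__ = [
    "NxStats",
    "KmerHistogram",
    "TelomereHit",
    "nx_stats",
    "coverage_fold",
    "estimate_genome_size",
    "telomere_scan",
    "DEFAULT_TELOMERE_MOTIF",
]

#: Canonical plant telomere repeat.
DEFAULT_TELOMERE_MOTIF = "TTTAGGG"


@dataclass(frozen=True)
class NxStats:
    total_length: int
    n_sequences: int
    n50: int
    l50: int
    gap_bases: int


@dataclass(frozen=True)
class KmerHistogram:
    """A k-mer multiplicity spectrum: (multiplicity, distinct k-mer count)."""

    pairs: tuple[tuple[int, int], ...]
    k: int = 21

    def __post_init__(self) -> None:
        mults = [m for m, _ in self.pairs]
        if any(m < 1 for m in mults):
            raise ValueError("multiplicities must be >= 1")
        if any(b <= a for a, b in zip(mults, mults[1:])):
            raise ValueError("multiplicities must be strictly increasing")
        if any(c < 0 for _, c in self.pairs):
            raise ValueError("counts must be >= 0")

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts on the contiguous multiplicity grid 1..max."""
        max_m = self.pairs[-1][0]
        counts = np.zeros(max_m, dtype=float)
        for m, c in self.pairs:
            counts[m - 1] = c
        return np.arange(1, max_m + 1), counts


@dataclass(frozen=True)
class TelomereHit:
    seq_id: str
    side: Literal["head", "tail"]
    motif: str
    copy_count: int
    density: float


def _sequences_as_dict(sequences: Iterable[SeqRecord] | dict[str, str]) -> dict[str, str]:
    if isinstance(sequences, dict):
        return sequences
    return {rec.id: rec.sequence for rec in sequences}


def nx_stats(sequences: Iterable[SeqRecord] | dict[str, str]) -> NxStats:
    """Contiguity statistics (N50 = length where the cumulative descending
    sum first reaches half the total; L50 = its rank)."""
    seqs = _sequences_as_dict(sequences)
    if not seqs:
        raise ValueError("nx_stats requires at least one sequence")
    lengths = sorted((len(s) for s in seqs.values()), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    for rank, length in enumerate(lengths, 1):
        cum += length
        if cum >= half:
            n50, l50 = length, rank
            break
    gap_bases = sum(s.count("N") for s in seqs.values())
    return NxStats(total, len(lengths), n50, l50, gap_bases)


def coverage_fold(total_bases: float, genome_size: float) -> float:
    """Sequencing depth: total read bases over genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return total_bases / genome_size


def estimate_genome_size(
    hist: KmerHistogram, error_cutoff: int | Literal["auto"] = "auto"
) -> tuple[float, list[int]]:
    """Estimate genome size from a k-mer spectrum.

    Returns ``(size_bp, peak_multiplicities)``. The error cutoff is the
    first local minimum of the smoothed counts scanning up from
    multiplicity 1 (unless given); peaks are local maxima above the cutoff
    after a 3-bin moving average; size is the k-mer mass above the cutoff
    divided by the highest-multiplicity (homozygous) peak.
    """
    mults, counts = hist.dense()
    if len(counts) >= 3:
        smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    else:
        smoothed = counts.astype(float)

    if error_cutoff == "auto":
        cutoff = 0
        for i in range(1, len(smoothed) - 1):
            if smoothed[i - 1] > smoothed[i] <= smoothed[i + 1]:
                cutoff = int(mults[i])
                break
    else:
        cutoff = int(error_cutoff)

    above = mults > cutoff
    peak_idx, _ = find_peaks(smoothed)
    peaks = sorted(int(mults[i]) for i in peak_idx if above[i])
    if not peaks:
        # single-spike or boundary-peak spectra are invisible to find_peaks
        if above.any() and counts[above].max() > 0:
            sub = np.where(above)[0]
            peaks = [int(mults[sub[np.argmax(counts[sub])]])]
        else:
            raise ValueError("no usable peak above the error cutoff")

    homozygous_peak = peaks[-1]
    mass = float(np.sum(mults[above] * counts[above]))
    return mass / homozygous_peak, peaks


def _nonoverlapping_count(window: str, motif: str) -> int:
    return window.count(motif)


def telomere_scan(
    sequences: Iterable[SeqRecord] | dict[str, str],
    motif: str = DEFAULT_TELOMERE_MOTIF,
    window: int = 3000,
    min_copies: int = 10,
) -> list[TelomereHit]:
    """Scan both terminal windows of every sequence for telomere repeats.

    Both the motif and its reverse complement are counted (non-overlapping)
    in each terminal window; the larger count is reported per side. A
    sequence shorter than the window is scanned whole.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if window < len(motif):
        raise ValueError("window must be at least the motif length")
    rc = revcomp(motif)
    hits: list[TelomereHit] = []
    for seq_id, seq in sorted(_sequences_as_dict(sequences).items()):
        w = min(window, len(seq))
        for side, sub in (("head", seq[:w]), ("tail", seq[-w:])):
            copies = max(_nonoverlapping_count(sub, motif), _nonoverlapping_count(sub, rc))
            if copies >= min_copies:
                hits.append(
                    TelomereHit(seq_id, side, motif, copies, copies * len(motif) / w)
                )
    return hits
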