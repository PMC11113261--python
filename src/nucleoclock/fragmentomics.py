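"""Fragment-size distributions and multi-nucleosome proportions.

The size distribution of cfDNA fragments is dominated by the chromatosome
footprint (~167 bp) with secondary di- and tri-nucleosome peaks near
``NRL + 167`` and ``2*NRL + 167``; the relative mass in those windows is an
age-informative feature.  Distributions are histograms at 1-bp resolution
over an inclusive integer size range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_fragments import FragmentSet

__all__ = [
    "SizeDistribution",
    "size_distribution",
    "group_average_distribution",
    "multinucleosome_proportions",
    "DEFAULT_WINDOWS",
]

#: Default (mono, di, tri) fragment-size windows in bp, inclusive.
DEFAULT_WINDOWS = ((120, 200), (275, 420), (440, 600))


@dataclass(frozen=True)
class SizeDistribution:
    """Histogram of fragment sizes on integer bp bins [size_min, size_max]."""

    size_min: int
    size_max: int
    counts: np.ndarray  # int64, length size_max - size_min + 1

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.size_max - self.size_min + 1,):
            raise ValueError("counts length must match size range")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_total == 0

    @property
    def freq(self) -> np.ndarray:
        """Counts normalised to sum 1 (all-NaN for an empty distribution)."""
        n = self.n_total
        if n == 0:
            return np.full_like(self.counts, np.nan, dtype=float)
        return self.counts / n

    def freq_at(self, size: int) -> float:
        if not (self.size_min <= size <= self.size_max):
            raise KeyError(f"size {size} outside [{self.size_min}, {self.size_max}]")
        return float(self.freq[size - self.size_min])


def size_distribution(
    fs: FragmentSet, size_min: int = 100, size_max: int = 600
) -> SizeDistribution:
    """Histogram of a sample's fragment sizes over [size_min, size_max].

    Fragments outside the range are excluded; an empty input yields an
    all-zero histogram flagged by ``is_empty`` (with a warning).
    """
    if size_max <= size_min:
        raise ValueError("size_max must exceed size_min")
    sizes = fs.sizes()
    sizes = sizes[(sizes >= size_min) & (sizes <= size_max)]
    n_bins = size_max - size_min + 1
    counts = np.bincount(sizes - size_min, minlength=n_bins).astype(np.int64)
    if counts.sum() == 0:
        warnings.warn(f"{fs.sample_id}: no fragments in [{size_min}, {size_max}]")
    return SizeDistribution(size_min, size_max, counts)


def group_average_distribution(dists: list[SizeDistribution]) -> SizeDistribution:
    """Unweighted mean of per-sample frequency vectors, renormalised.

    All inputs must share the same bin grid and be non-empty.  The result is
    returned as a SizeDistribution whose ``freq`` equals the renormalised
    mean; its counts are scaled to a fixed resolution so exact frequencies
    are preserved via the attached ``mean_freq`` array.
    """
    if not dists:
        raise ValueError("need at least one distribution")
    first = dists[0]
    for d in dists[1:]:
        if (d.size_min, d.size_max) != (first.size_min, first.size_max):
            raise ValueError("mismatched bin edges across distributions")
    freqs = []
    for d in dists:
        if d.is_empty:
            raise ValueError("cannot average an empty distribution")
        freqs.append(d.freq)
    mean = np.mean(freqs, axis=0)
    mean = mean / mean.sum()
    return AveragedDistribution(first.size_min, first.size_max, mean)


class AveragedDistribution(SizeDistribution):
    """Group-average distribution carrying real-valued frequencies."""

    def __init__(self, size_min: int, size_max: int, mean_freq: np.ndarray) -> None:
        counts = np.zeros(size_max - size_min + 1, dtype=np.int64)
        super().__init__(size_min, size_max, counts)
        object.__setattr__(self, "mean_freq", np.asarray(mean_freq, dtype=float))

    @property
    def is_empty(self) -> bool:
        return False

    @property
    def freq(self) -> np.ndarray:
        return self.mean_freq  # type: ignore[attr-defined]


def multinucleosome_proportions(
    dist: SizeDistribution,
    windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS,
) -> tuple[float, ...]:
    """Frequency mass inside each (inclusive) size window.

    With the default windows the three values are the mono-, di- and
    tri-nucleosome fragment proportions.  Windows must be pairwise disjoint.
    """
    ordered = sorted(windows)
    for (lo1, hi1), (lo2, _hi2) in zip(ordered, ordered[1:]):
        if lo2 <= hi1:
            raise ValueError(f"overlapping windows: ({lo1},{hi1}) and ({lo2},{_hi2})")
    if dist.is_empty:
        raise ValueError("empty distribution has no defined proportions")
    freq = dist.freq
    out = []
    for lo, hi in windows:
        lo_i = max(lo, dist.size_min) - dist.size_min
        hi_i = min(hi, dist.size_max) - dist.size_min
        out.append(float(freq[lo_i : hi_i + 1].sum()) if hi_i >= lo_i else 0.0)
    return tuple(out)
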