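"""Phasograms and nucleosome repeat length (NRL) estimation.

The phasogram is the histogram of pairwise genomic distances between cfDNA
fragment centres on the same chromosome.  Because fragment centres track
nucleosome dyads, the phasogram oscillates with the nucleosome spacing: peaks
sit near integer multiples of the NRL.  The NRL is estimated as the slope of
an ordinary least-squares fit of peak position against peak order, which is
robust to a constant offset (the intercept absorbs any linker/footprint
shift) and to occasional missing harmonics.

Pipeline: ``compute_phasogram`` (exact pair counts via a sorted sliding
window) -> ``smooth_phasogram`` (Savitzky-Golay on the normalised signal) ->
``detect_peaks`` (prominence-based maxima, orders assigned from a coarse
spectral period estimate) -> ``estimate_nrl`` (OLS slope with diagnostics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io_fragments import FragmentSet, SampleMeta

__all__ = [
    "Phasogram",
    "Peak",
    "PeakSet",
    "NRLEstimate",
    "compute_phasogram",
    "smooth_phasogram",
    "detect_peaks",
    "estimate_nrl",
    "nrl_from_fragments",
    "nrl_cohort_table",
    "nrl_age_stats",
]

# Defaults for the NRL procedure.  The fit region starts at 120 bp to exclude
# the zero-lag/self-overlap shoulder; peak orders are capped at 10; the
# mono-nucleosome size window selects fragments whose centres sit on dyads.
D_MAX_DEFAULT = 2000
D_MIN_FIT_DEFAULT = 120
SG_WINDOW_DEFAULT = 51
SG_POLYORDER_DEFAULT = 3
MAX_PEAK_ORDER = 10
NRL_SIZE_WINDOW = (120, 200)
PERIOD_SEARCH = (120.0, 260.0)


@dataclass
class Phasogram:
    """Distance histogram between fragment centres at 1-bp resolution.

    ``counts[d]`` is the number of ordered same-chromosome centre pairs
    (i < j) at distance d, for d = 0..d_max, pooled over chromosomes.
    """

    counts: np.ndarray  # int64, length d_max + 1
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ValueError("counts must be a 1-D array over d = 0..d_max")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def distances(self) -> np.ndarray:
        return np.arange(len(self.counts))

    @property
    def norm(self) -> np.ndarray:
        n = self.n_pairs
        if n == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"distance": self.distances, "count": self.counts, "norm": self.norm}
        )
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df


@dataclass(frozen=True)
class Peak:
    order: int       # harmonic index k (position ~ k * NRL)
    position: float  # bp, sub-bin refined
    prominence: float


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    period_estimate: float  # coarse spectral period used for order assignment

    def __post_init__(self) -> None:
        orders = [p.order for p in self.peaks]
        positions = [p.position for p in self.peaks]
        if sorted(orders) != orders or len(set(orders)) != len(orders):
            raise ValueError("peak orders must be strictly increasing")
        if sorted(positions) != positions:
            raise ValueError("peak positions must increase with order")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def orders(self) -> np.ndarray:
        return np.array([p.order for p in self.peaks])

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])


@dataclass(frozen=True)
class NRLEstimate:
    """NRL as the OLS slope of peak position vs peak order."""

    nrl: float
    intercept: float
    r_squared: float
    slope_se: float
    n_peaks_used: int
    reliable: bool = True

    def flag_reason(self) -> str | None:
        if self.reliable:
            return None
        reasons = []
        if not (120.0 <= self.nrl <= 260.0):
            reasons.append("slope outside 120-260 bp")
        if self.r_squared < 0.95:
            reasons.append("R^2 < 0.95")
        if self.slope_se > 2.0:
            reasons.append("slope SE > 2 bp")
        return "; ".join(reasons) or "unreliable"


def compute_phasogram(fs: FragmentSet, d_max: int = D_MAX_DEFAULT) -> Phasogram:
    """Exact pairwise-distance histogram via a sorted sliding window.

    For each chromosome the centres are already sorted; distances are
    accumulated by comparing each centre with its k-th successor for
    k = 1, 2, ... until every such gap exceeds ``d_max``.  This touches only
    pairs within the window and never forms the all-pairs matrix.
    """
    if d_max < 500:
        raise ValueError("d_max must be >= 500")
    counts = np.zeros(d_max + 1, dtype=np.int64)
    n_centres = 0
    for chrom in fs.chromosomes:
        c = fs.centres(chrom)
        n_centres += len(c)
        k = 1
        while k < len(c):
            d = c[k:] - c[:-k]
            within = d[d <= d_max]
            if len(within) == 0:
                break
            counts += np.bincount(within, minlength=d_max + 1)
            k += 1
    if n_centres < 2:
        warnings.warn(f"{fs.sample_id}: fewer than 2 fragments; phasogram is empty")
    return Phasogram(counts)


def smooth_phasogram(
    p: Phasogram,
    window: int = SG_WINDOW_DEFAULT,
    polyorder: int = SG_POLYORDER_DEFAULT,
) -> Phasogram:
    """Savitzky-Golay smoothing of the normalised phasogram.

    Returns a new Phasogram with ``smoothed`` filled; raw counts untouched.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > len(p.counts):
        raise ValueError("window larger than signal length")
    smoothed = signal.savgol_filter(p.norm, window_length=window, polyorder=polyorder)
    return Phasogram(p.counts.copy(), smoothed=smoothed)


def _dominant_period(
    s: np.ndarray, d: np.ndarray, lo: float = PERIOD_SEARCH[0], hi: float = PERIOD_SEARCH[1]
) -> float:
    """Coarse period of the dominant oscillation, by scanning a DFT-style
    amplitude over candidate periods in [lo, hi] bp."""
    x = s - s.mean()
    periods = np.arange(lo, hi + 0.25, 0.25)
    phases = 2j * np.pi * d[None, :] / periods[:, None]
    power = np.abs((x[None, :] * np.exp(phases)).sum(axis=1))
    return float(periods[int(np.argmax(power))])


def _refine_peak(s: np.ndarray, i: int) -> float:
    """Sub-bin peak position by parabolic interpolation around index i."""
    if i <= 0 or i >= len(s) - 1:
        return float(i)
    y0, y1, y2 = s[i - 1], s[i], s[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a strict local max in the quadratic sense
        return float(i)
    delta = 0.5 * (y0 - y2) / denom
    return float(i + np.clip(delta, -0.5, 0.5))


def detect_peaks(
    p: Phasogram,
    d_min_fit: int = D_MIN_FIT_DEFAULT,
    min_prominence: float | None = None,
    max_order: int = MAX_PEAK_ORDER,
) -> PeakSet:
    """Find phasogram peaks and assign harmonic orders.

    Local maxima of the smoothed signal at d >= d_min_fit with prominence
    >= ``min_prominence`` (default: 5% of the signal range in the fit region)
    are candidate peaks.  A coarse period is estimated from the dominant
    spectral component on 120-260 bp, and each peak gets order
    k = round(position / period).  Peaks falling more than a quarter period
    from an integer multiple (e.g. half-period sub-harmonics produced by
    di-nucleosome fragment centres) are discarded; when two peaks map to the
    same order the more prominent wins.  Gaps in k are allowed.

    Raises
    ------
    ValueError
        If fewer than 3 usable peaks remain ("insufficient peaks for NRL").
    """
    if p.smoothed is None:
        raise ValueError("smoothed signal required; call smooth_phasogram first")
    if not (0 <= d_min_fit < p.d_max):
        raise ValueError("d_min_fit must lie inside [0, d_max)")
    s = p.smoothed[d_min_fit:]
    d = np.arange(d_min_fit, p.d_max + 1)

    if min_prominence is None:
        span = float(s.max() - s.min())
        min_prominence = max(0.05 * span, 1e-15)
    idx, props = signal.find_peaks(s, prominence=min_prominence)
    if len(idx) == 0:
        raise ValueError("insufficient peaks for NRL (no peaks found)")

    period = _dominant_period(s, d)
    best: dict[int, Peak] = {}
    for i, prom in zip(idx, props["prominences"]):
        pos = _refine_peak(s, int(i)) + d_min_fit
        ratio = pos / period
        k = int(np.floor(ratio + 0.5))
        if k < 1 or k > max_order:
            continue
        if abs(ratio - k) > 0.25:
            continue  # off-lattice peak (e.g. half-period sub-harmonic)
        if k not in best or prom > best[k].prominence:
            best[k] = Peak(order=k, position=pos, prominence=float(prom))
    peaks = tuple(sorted(best.values(), key=lambda pk: pk.order))
    if len(peaks) < 3:
        raise ValueError(
            f"insufficient peaks for NRL ({len(peaks)} usable, need >= 3)"
        )
    return PeakSet(peaks=peaks, period_estimate=period)


def estimate_nrl(peaks: PeakSet) -> NRLEstimate:
    """OLS fit of peak position on peak order; the slope is the NRL."""
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks")
    fit = stats.linregress(peaks.orders, peaks.positions)
    nrl = float(fit.slope)
    r2 = float(fit.rvalue**2)
    se = float(fit.stderr)
    reliable = (120.0 <= nrl <= 260.0) and r2 >= 0.95 and se <= 2.0
    return NRLEstimate(
        nrl=nrl,
        intercept=float(fit.intercept),
        r_squared=r2,
        slope_se=se,
        n_peaks_used=len(peaks),
        reliable=reliable,
    )


def nrl_from_fragments(
    fs: FragmentSet,
    d_max: int = D_MAX_DEFAULT,
    d_min_fit: int = D_MIN_FIT_DEFAULT,
    window: int = SG_WINDOW_DEFAULT,
    polyorder: int = SG_POLYORDER_DEFAULT,
    min_prominence: float | None = None,
    size_window: tuple[int, int] | None = NRL_SIZE_WINDOW,
) -> NRLEstimate:
    """Full NRL procedure for one sample.

    By default fragments are first restricted to the mono-nucleosome size
    window (120-200 bp) so that centres track single dyads; pass
    ``size_window=None`` to use all fragments.
    """
    if size_window is not None:
        fs = fs.filter_size(*size_window)
    p = compute_phasogram(fs, d_max=d_max)
    p = smooth_phasogram(p, window=window, polyorder=polyorder)
    peaks = detect_peaks(p, d_min_fit=d_min_fit, min_prominence=min_prominence)
    return estimate_nrl(peaks)


def nrl_cohort_table(
    samples: list[tuple[FragmentSet, SampleMeta]],
    **nrl_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample NRL table plus per-group summary statistics.

    Per-sample failures (too few peaks, etc.) become flagged rows, never
    pipeline aborts.  Returns ``(per_sample, per_group)`` DataFrames; groups
    come from ``SampleMeta.group_label`` (ungrouped samples are pooled under
    "all").
    """
    rows = []
    for fs, meta in samples:
        row: dict = {
            "sample_id": meta.sample_id,
            "age": meta.age,
            "group": meta.group_label or "all",
        }
        try:
            est = nrl_from_fragments(fs, **nrl_kwargs)
            row.update(
                nrl=est.nrl,
                slope_se=est.slope_se,
                r_squared=est.r_squared,
                n_peaks=est.n_peaks_used,
                flag="" if est.reliable else (est.flag_reason() or "unreliable"),
            )
        except ValueError as exc:
            row.update(
                nrl=np.nan, slope_se=np.nan, r_squared=np.nan, n_peaks=0,
                flag=f"failed: {exc}",
            )
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    ok = per_sample[per_sample["nrl"].notna()]
    per_group = (
        ok.groupby("group")["nrl"]
        .agg(mean="mean", median="median", var="var", n="count")
        .reset_index()
    )
    return per_sample, per_group


def nrl_age_stats(
    nrls: np.ndarray,
    ages: np.ndarray,
    pairing: np.ndarray | None = None,
) -> dict:
    """Pearson correlation of NRL with age, plus an optional paired t-test.

    ``pairing``, when given, is a label vector with exactly two levels and
    equal group sizes; samples are matched by order of appearance within each
    level and compared with a paired-sample t-test (two-sided).
    """
    nrls = np.asarray(nrls, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if nrls.shape != ages.shape or nrls.ndim != 1:
        raise ValueError("nrls and ages must be equal-length 1-D vectors")
    if len(nrls) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(nrls) == 0 or np.std(ages) == 0:
        raise ValueError("zero variance in NRL or age vector")
    r, p = stats.pearsonr(nrls, ages)
    out = {"pearson_r": float(r), "p_value": float(p)}
    if pairing is not None:
        pairing = np.asarray(pairing)
        levels = pd.unique(pairing)
        if len(levels) != 2:
            raise ValueError("pairing must have exactly two levels")
        a = nrls[pairing == levels[0]]
        b = nrls[pairing == levels[1]]
        if len(a) != len(b):
            raise ValueError("paired groups must have equal sizes")
        if np.allclose(a, b):
            t, tp = 0.0, 1.0
        else:
            t, tp = stats.ttest_rel(a, b)
        out["paired_t"] = float(t)
        out["paired_p"] = float(tp)
    return out
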