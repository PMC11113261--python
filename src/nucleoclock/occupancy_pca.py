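"""Binned cfDNA occupancy, differential-bin discovery, and PCA stratification.

Occupancy is the number of fragments overlapping each fixed-width genomic bin
(default 100 bp, grid anchored at coordinate 0), scaled within each sample to
fragments-per-million so samples of different sequencing depth are
comparable.  Bins whose occupancy differs between two age groups (per-bin
Welch t-test, Benjamini-Hochberg FDR) define a region set; the normalised
occupancy over those regions feeds a PCA fitted on discovery samples only,
onto which held-out samples are projected with the discovery
standardisation — the held-out samples never influence the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io_fragments import FragmentSet

__all__ = [
    "OccupancyTrack",
    "RegionSet",
    "PCAStratification",
    "bin_occupancy",
    "differential_bins",
    "region_matrix",
    "fit_pca",
    "project_samples",
]


@dataclass
class OccupancyTrack:
    """Per-bin fragment overlap counts for one sample, FPM-scaled.

    ``raw[chrom]`` holds integer overlap counts (a fragment overlapping m
    bins increments each of the m bins by 1); ``values[chrom]`` holds the
    counts scaled by 1e6 / n_fragments of the sample.
    """

    sample_id: str
    bin_size: int
    n_fragments: int
    raw: dict[str, np.ndarray]

    @property
    def values(self) -> dict[str, np.ndarray]:
        scale = 1e6 / self.n_fragments if self.n_fragments > 0 else 0.0
        return {c: v * scale for c, v in self.raw.items()}

    def grid_signature(self) -> tuple:
        return (self.bin_size, tuple(sorted((c, len(v)) for c, v in self.raw.items())))


@dataclass
class RegionSet:
    """Differential 100-bp-aligned bins with test statistics.

    ``table`` columns: chrom, start, end, statistic, p_adj, direction.
    ``method`` records how the bins were selected ("welch", "wilcoxon" or the
    small-sample fallback "fold_change").
    """

    table: pd.DataFrame
    bin_size: int
    method: str = "welch"

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "statistic", "p_adj", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"RegionSet table missing columns: {missing}")
        if len(self.table):
            if np.any(self.table["start"] % self.bin_size != 0):
                raise ValueError("region starts must be bin-aligned")
            padj = self.table["p_adj"].dropna()
            if len(padj) and (padj.min() < 0 or padj.max() > 1):
                raise ValueError("p_adj must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def bin_index(self) -> list[tuple[str, int]]:
        return [
            (row.chrom, int(row.start) // self.bin_size)
            for row in self.table.itertuples(index=False)
        ]

    def to_bed(self, path: str | Path) -> None:
        """BED6: name = statistic, score = -log10 p_adj (capped at 1000)."""
        with open(path, "w") as fh:
            for row in self.table.itertuples(index=False):
                score = (
                    min(1000.0, -np.log10(max(row.p_adj, 1e-300)))
                    if np.isfinite(row.p_adj)
                    else 0.0
                )
                fh.write(
                    f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                    f"{row.statistic:.4g}\t{score:.3f}\t{row.direction}\n"
                )


def bin_occupancy(
    fs: FragmentSet, bin_size: int = 100, genome_length: int | None = None
) -> OccupancyTrack:
    """Count fragments overlapping each bin; scale to fragments-per-million.

    A fragment [start, end) overlaps bins floor(start/bin) .. floor((end-1)/bin)
    inclusive and increments each by 1.  ``genome_length`` fixes the number of
    bins per chromosome (shared grid across a cohort); by default the grid
    extends to the last fragment end.
    """
    if bin_size < 10:
        raise ValueError("bin_size must be >= 10")
    raw: dict[str, np.ndarray] = {}
    for chrom in fs.chromosomes:
        starts, ends = fs.intervals(chrom)
        first = starts // bin_size
        last = (ends - 1) // bin_size
        n_bins = int(
            np.ceil(genome_length / bin_size)
            if genome_length is not None
            else last.max() + 1
        )
        # interval increments via a difference array
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        np.add.at(diff, np.clip(first, 0, n_bins), 1)
        np.add.at(diff, np.clip(last + 1, 0, n_bins), -1)
        raw[chrom] = np.cumsum(diff[:-1])
    return OccupancyTrack(
        sample_id=fs.sample_id,
        bin_size=bin_size,
        n_fragments=fs.n_fragments,
        raw=raw,
    )


def _stack_group(tracks: list[OccupancyTrack]) -> dict[str, np.ndarray]:
    """chrom -> (n_samples, n_bins) matrix of FPM values."""
    out: dict[str, list[np.ndarray]] = {}
    for t in tracks:
        for chrom, v in t.values.items():
            out.setdefault(chrom, []).append(v)
    return {c: np.vstack(vs) for c, vs in out.items()}


def differential_bins(
    group_a: list[OccupancyTrack],
    group_b: list[OccupancyTrack],
    alpha: float = 0.05,
    direction: str = "B>A",
    method: str = "welch",
    fc_threshold: float = 1.5,
) -> RegionSet:
    """Bins with significantly different occupancy between two groups.

    Per-bin two-sample test on FPM occupancy (Welch t by default; Wilcoxon
    rank-sum available for >= 4 samples per group), Benjamini-Hochberg FDR at
    ``alpha``; bins with zero occupancy in every sample are excluded before
    testing.  ``direction`` keeps "B>A", "A>B" or "both".  With fewer than
    2 samples in either group the test is impossible and the function falls
    back to fold-change ranking (mean B / mean A >= ``fc_threshold``),
    flagged via ``RegionSet.method == "fold_change"``.
    """
    if direction not in {"B>A", "A>B", "both"}:
        raise ValueError("direction must be 'B>A', 'A>B' or 'both'")
    tracks = group_a + group_b
    sig = tracks[0].grid_signature()
    if any(t.grid_signature() != sig for t in tracks[1:]):
        raise ValueError("mismatched bin grids across samples")
    bin_size = tracks[0].bin_size

    a = _stack_group(group_a)
    b = _stack_group(group_b)
    rows = []
    fallback = min(len(group_a), len(group_b)) < 2
    for chrom in sorted(a):
        mat_a, mat_b = a[chrom], b[chrom]
        nonzero = (mat_a.sum(axis=0) + mat_b.sum(axis=0)) > 0
        idx = np.flatnonzero(nonzero)
        if len(idx) == 0:
            continue
        mean_a = mat_a[:, idx].mean(axis=0)
        mean_b = mat_b[:, idx].mean(axis=0)
        delta = mean_b - mean_a
        if fallback:
            # moderated ratio: a pseudocount tied to the typical occupancy
            # keeps near-empty bins from producing explosive fold changes
            pseudo = 0.05 * float(np.mean((mean_a + mean_b) / 2)) + 1e-12
            fc = (mean_b + pseudo) / (mean_a + pseudo)
            stat = np.log2(fc)
            pvals = np.full(len(idx), np.nan)
            keep = (
                (fc >= fc_threshold)
                if direction == "B>A"
                else (fc <= 1 / fc_threshold)
                if direction == "A>B"
                else (fc >= fc_threshold) | (fc <= 1 / fc_threshold)
            )
            padj = pvals
        else:
            if method == "welch":
                stat, pvals = stats.ttest_ind(
                    mat_b[:, idx], mat_a[:, idx], axis=0, equal_var=False
                )
            elif method == "wilcoxon":
                if min(len(group_a), len(group_b)) < 4:
                    raise ValueError("wilcoxon needs >= 4 samples per group")
                stat, pvals = stats.ranksums(mat_b[:, idx], mat_a[:, idx], axis=0)
            else:
                raise ValueError(f"unknown method {method!r}")
            pvals = np.where(np.isnan(pvals), 1.0, pvals)
            _, padj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
            keep = padj < alpha
            if direction == "B>A":
                keep &= delta > 0
            elif direction == "A>B":
                keep &= delta < 0
        for j in np.flatnonzero(keep):
            i = int(idx[j])
            rows.append(
                {
                    "chrom": chrom,
                    "start": i * bin_size,
                    "end": (i + 1) * bin_size,
                    "statistic": float(np.atleast_1d(stat)[j]),
                    "p_adj": float(np.atleast_1d(padj)[j]),
                    "direction": "up" if delta[j] > 0 else "down",
                }
            )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "statistic", "p_adj", "direction"]
    )
    return RegionSet(
        table=table, bin_size=bin_size, method="fold_change" if fallback else method
    )


def region_matrix(tracks: list[OccupancyTrack], regions: RegionSet) -> np.ndarray:
    """(n_samples, n_regions) FPM occupancy matrix restricted to the regions."""
    out = np.zeros((len(tracks), len(regions)))
    index = regions.bin_index()
    for si, t in enumerate(tracks):
        values = t.values
        for ri, (chrom, b) in enumerate(index):
            if chrom not in values or b >= len(values[chrom]):
                raise ValueError(
                    f"sample {t.sample_id}: missing region {chrom}:{b * regions.bin_size}"
                )
            out[si, ri] = values[chrom][b]
    return out


@dataclass
class PCAStratification:
    """PCA over differential-region occupancy, fitted on discovery samples.

    Standardisation (per-region mean/SD over the discovery samples) and
    loadings are frozen at fit time; projection of new samples reuses them.
    """

    region_means: np.ndarray
    region_sds: np.ndarray
    components: np.ndarray              # (n_components, n_regions_kept)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray                  # discovery scores (n_samples, n_components)
    sample_ids: list[str]
    kept_regions: np.ndarray            # indices into the original RegionSet

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_means": self.region_means.tolist(),
            "region_sds": self.region_sds.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "scores": self.scores.tolist(),
            "sample_ids": self.sample_ids,
            "kept_regions": self.kept_regions.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAStratification":
        d = json.loads(Path(path).read_text())
        return cls(
            region_means=np.array(d["region_means"]),
            region_sds=np.array(d["region_sds"]),
            components=np.array(d["components"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            scores=np.array(d["scores"]),
            sample_ids=list(d["sample_ids"]),
            kept_regions=np.array(d["kept_regions"], dtype=int),
        )


def fit_pca(
    matrix: np.ndarray, sample_ids: list[str] | None = None
) -> PCAStratification:
    """Standardise regions across discovery samples and eigendecompose.

    Each region is centred and scaled to unit SD across the discovery
    samples; regions constant across all samples are dropped with a warning.
    All principal components are retained, so the explained-variance ratios
    sum to 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 discovery samples and >= 2 regions")
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(X.shape[0])]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant region(s) before PCA")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant regions")
    Z = (X[:, keep] - means[keep]) / sds[keep]
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(Z)
    return PCAStratification(
        region_means=means[keep],
        region_sds=sds[keep],
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        sample_ids=list(sample_ids),
        kept_regions=np.flatnonzero(keep),
    )


def project_samples(model: PCAStratification, matrix: np.ndarray) -> np.ndarray:
    """Project new samples (rows over the *original* region set) onto the PCA.

    Standardisation uses the stored discovery means/SDs; the model is never
    refitted.  Returns (n_samples, n_components) scores.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n_regions_total = int(model.kept_regions.max()) + 1 if len(model.kept_regions) else 0
    if X.shape[1] == len(model.kept_regions):
        Xk = X
    elif X.shape[1] >= n_regions_total:
        Xk = X[:, model.kept_regions]
    else:
        raise ValueError(
            f"sample has {X.shape[1]} regions; model needs the "
            f"{len(model.kept_regions)} retained regions (from {n_regions_total})"
        )
    Z = (Xk - model.region_means) / model.region_sds
    return Z @ model.components.T
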