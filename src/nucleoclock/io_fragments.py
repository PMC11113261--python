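"""Reading and writing cell-free DNA fragment data.

cfDNA fragments arrive as BED intervals (0-based, half-open) produced by an
upstream alignment pipeline.  This module parses them into :class:`FragmentSet`
objects that hold, per chromosome, fragment start/end arrays sorted by fragment
centre.  The centre of a fragment is taken as a proxy for the position of the
nucleosome dyad that protected it from nuclease digestion; every downstream
stage (size distributions, phasograms, occupancy tracks) works off these
centres and sizes.

Coordinate conventions: BED half-open ``[start, end)``; fragment size is
``end - start``; the centre is ``floor((start + end) / 2)`` so ties break
downward deterministically.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "FragmentSet",
    "SampleMeta",
    "read_fragments",
    "write_fragments",
    "read_sample_meta",
    "write_sample_meta",
    "fragment_centres",
]

#: Default fragment-size window in bp: keeps mono- through tri-nucleosome
#: fragments (chromatosome ~167 bp up to tri-nucleosome ~520 bp).
DEFAULT_SIZE_MIN = 100
DEFAULT_SIZE_MAX = 600


@dataclass(frozen=True)
class Fragment:
    """A single cfDNA fragment in BED coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: got [{self.start}, {self.end})"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2


class FragmentSet:
    """A sample's cfDNA fragments, grouped by chromosome, sorted by centre.

    Parameters
    ----------
    sample_id
        Identifier for the sample the fragments belong to.
    chroms
        Mapping ``chrom -> (starts, ends)`` of equal-length integer arrays.
        Arrays are copied and re-sorted by fragment centre on construction.
    n_dropped
        Count of fragments removed by the size filter at read time (metadata
        only; not part of equality).
    """

    def __init__(
        self,
        sample_id: str,
        chroms: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
        n_dropped: int = 0,
    ) -> None:
        self.sample_id = sample_id
        self.n_dropped = int(n_dropped)
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends) in (chroms or {}).items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.shape != ends.shape:
                raise ValueError(f"{chrom}: starts/ends length mismatch")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: fragments with end <= start")
            centre = (starts + ends) // 2
            order = np.lexsort((starts, centre))
            self._chroms[chrom] = (starts[order], ends[order])

    # -- container protocol -------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    @property
    def n_fragments(self) -> int:
        return sum(len(s) for s, _ in self._chroms.values())

    def __len__(self) -> int:
        return self.n_fragments

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        if set(self._chroms) != set(other._chroms):
            return False
        return all(
            np.array_equal(self._chroms[c][0], other._chroms[c][0])
            and np.array_equal(self._chroms[c][1], other._chroms[c][1])
            for c in self._chroms
        )

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for ``chrom``, sorted by centre; empty arrays if absent."""
        if chrom not in self._chroms:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._chroms[chrom]

    def centres(self, chrom: str) -> np.ndarray:
        starts, ends = self.intervals(chrom)
        return (starts + ends) // 2

    def sizes(self, chrom: str | None = None) -> np.ndarray:
        """Fragment sizes for one chromosome, or pooled over all of them."""
        if chrom is not None:
            starts, ends = self.intervals(chrom)
            return ends - starts
        if not self._chroms:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([e - s for s, e in self._chroms.values()])

    def iter_fragments(self) -> Iterator[Fragment]:
        for chrom in self.chromosomes:
            starts, ends = self._chroms[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield Fragment(chrom, s, e)

    def filter_size(self, size_min: int, size_max: int) -> "FragmentSet":
        """New FragmentSet keeping fragments with size in [size_min, size_max]."""
        if size_max <= size_min:
            raise ValueError("size_max must exceed size_min")
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        dropped = 0
        for chrom, (starts, ends) in self._chroms.items():
            size = ends - starts
            keep = (size >= size_min) & (size <= size_max)
            dropped += int((~keep).sum())
            if keep.any():
                out[chrom] = (starts[keep], ends[keep])
        return FragmentSet(self.sample_id, out, n_dropped=self.n_dropped + dropped)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: identifier, chronological age, optional group."""

    sample_id: str
    age: float
    group_label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"{self.sample_id}: age must be finite and >= 0")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fragments(
    path: str | Path,
    size_min: int = DEFAULT_SIZE_MIN,
    size_max: int = DEFAULT_SIZE_MAX,
    sample_id: str | None = None,
) -> FragmentSet:
    """Read a BED file of cfDNA fragments into a :class:`FragmentSet`.

    Only the first three columns (chrom, start, end) are used; extra columns
    (e.g. a fragment-size column) are ignored.  Fragments whose size falls
    outside ``[size_min, size_max]`` are dropped and counted in
    ``FragmentSet.n_dropped``.  gzip-compressed input (``.gz``) is accepted.

    Raises
    ------
    ValueError
        On a malformed line (fewer than 3 columns, non-integer coordinates,
        or ``end <= start``), naming the 1-based line number.
    """
    if size_min < 1:
        raise ValueError("size_min must be >= 1")
    if size_max <= size_min:
        raise ValueError("size_max must exceed size_min")
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".bed")

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {parts[1]!r}, {parts[2]!r}"
                ) from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)

    if not chroms:
        warnings.warn(f"{path}: no fragments found; returning empty FragmentSet")
        return FragmentSet(sample_id, {})

    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    n_before = len(df)
    size = df["end"] - df["start"]
    df = df[(size >= size_min) & (size <= size_max)]
    grouped = {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    return FragmentSet(sample_id, grouped, n_dropped=n_before - len(df))


def write_fragments(fs: FragmentSet, path: str | Path) -> None:
    """Write a FragmentSet as 4-column BED: chrom, start, end, size."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for chrom in fs.chromosomes:
            starts, ends = fs.intervals(chrom)
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{chrom}\t{s}\t{e}\t{e - s}\n")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV with header ``sample_id<TAB>age[<TAB>group]``.

    Raises on duplicate sample ids and on rows with missing/unparseable ages,
    listing the offending rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "age"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        return []
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample_id values: {dup}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = df.index[ages.isna()].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
        raise ValueError(f"{path}: missing or non-numeric age on line(s) {rows}")
    has_group = "group" in df.columns
    return [
        SampleMeta(
            sample_id=row.sample_id,
            age=float(age),
            group_label=(str(row.group) if has_group and pd.notna(row.group) else None),
        )
        for row, age in zip(df.itertuples(index=False), ages)
    ]


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [(m.sample_id, m.age, m.group_label) for m in metas]
    df = pd.DataFrame(rows, columns=["sample_id", "age", "group"])
    if df["group"].isna().all():
        df = df.drop(columns="group")
    df.to_csv(path, sep="\t", index=False)


def fragment_centres(fs: FragmentSet, chrom: str) -> np.ndarray:
    """Sorted fragment centres for one chromosome ([] if chrom absent)."""
    return fs.centres(chrom)
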