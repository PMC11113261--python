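"""Synthetic cfDNA cohort generator with age-linked nucleosome spacing.

The generator emulates the age signals the downstream pipeline is built to
detect:

* **NRL drift** — each subject's nucleosome spacing is
  ``NRL = beta0 + beta1 * age + Normal(0, sigma_subject)``.
* **Fragment-mixture drift** — emitted fragments are mono-, di- or
  tri-nucleosomal with age-dependent weights; the di- and tri-nucleosome
  shares decline linearly with age (weights renormalised), so older subjects
  carry proportionally fewer long fragments.
* **Differential occupancy** — an optional set of 100-bp bins whose fragment
  sampling rate is multiplied by a factor growing linearly with age, giving
  the differential-occupancy module a known planted effect.

Dyad placement follows the statistical-positioning picture of chromatin:
nucleosome arrays are phased from fixed boundary elements.  Barrier
positions on the single synthetic chromosome (``chrS``) are drawn once per
cohort and shared by every subject; within each array dyads sit at
``barrier + j * NRL + Normal(0, dyad_jitter_sd)``.  Sharing the barriers
makes binned occupancy comparable across subjects (as it is in real
cohorts, where nucleosome positioning is largely conserved) while each
subject's own NRL still sets the within-array spacing that phasograms
measure.  Setting ``barrier_spacing_range=None`` collapses the genome to a
single phased lattice starting at coordinate 0 — convenient for exact
deterministic checks.

A mono-nucleosome fragment is centred on one dyad with length
``Normal(mu_mono, sd_len)``; a di-(tri-)nucleosome fragment spans two
(three) adjacent dyads of the same array, its length being the dyad span
plus the same protected-length noise, so its expected length is
``NRL + mu_mono`` (``2*NRL + mu_mono``).

Randomness is fully reproducible: each subject draws from its own stream
derived from ``(seed, subject index)``, so cohorts are order-independent
and any subject can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_fragments import FragmentSet, SampleMeta, write_fragments, write_sample_meta

__all__ = ["MixtureLink", "CohortSpec", "generate_subject", "generate_cohort", "write_cohort"]

_BARRIER_STREAM = 0x5EED  # spawn key of the cohort-level barrier stream


@dataclass(frozen=True)
class MixtureLink:
    """Mono/di/tri-nucleosome fragment weights as a linear function of age.

    Raw weights at a given age are ``(w_mono0, w_di0 + d_di*age,
    w_tri0 + d_tri*age)``, renormalised to sum to 1.  Negative slopes for the
    di/tri terms make long fragments rarer in older subjects.
    """

    w_mono0: float = 0.55
    w_di0: float = 0.30
    w_tri0: float = 0.15
    d_di: float = -0.0015   # per year
    d_tri: float = -0.0010  # per year

    def weights(self, age: float) -> np.ndarray:
        raw = np.array(
            [self.w_mono0, self.w_di0 + self.d_di * age, self.w_tri0 + self.d_tri * age]
        )
        if np.any(raw < 0):
            raise ValueError(f"negative mixture weight at age {age}: {raw}")
        total = raw.sum()
        if total <= 0:
            raise ValueError(f"degenerate mixture weights at age {age}")
        return raw / total


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cfDNA cohort.

    Attributes
    ----------
    n_subjects : subjects in the cohort; ages drawn uniformly on ``age_range``.
    genome_length : length of the single synthetic chromosome (bp).
    nrl_beta0, nrl_beta1, nrl_sigma_subject :
        subject NRL = beta0 + beta1*age + Normal(0, sigma_subject), in bp
        (beta1 in bp/year).
    dyad_jitter_sd : total per-dyad positional jitter around the array
        lattice (bp, marginal SD).
    jitter_shared_frac : fraction of the jitter *variance* that is shared
        across subjects (sequence-encoded positioning preference at each
        array slot); the rest is subject-specific.  0 makes every subject
        re-roll all positions independently.
    frag_mu_mono, frag_sd_len : protected-length distribution (bp).
    mixture : age-linked mono/di/tri weights.
    n_fragments_per_subject : exact number of fragments emitted per subject.
    barrier_spacing_range : (lo, hi) bp for the uniform spacing of the
        cohort-shared array barriers; ``None`` places one lattice at 0.
    differential_bins : optional array of bin indices (``diff_bin_size`` bp)
        in which fragment sampling is boosted by
        ``1 + (diff_max_factor-1) * (age-lo)/(hi-lo)``; a fragment counts as
        "in" a bin when it overlaps it, so binned occupancy scales by the
        full factor.
    """

    n_subjects: int = 12
    age_range: tuple[float, float] = (25.0, 100.0)
    genome_length: int = 20_000_000
    nrl_beta0: float = 185.0
    nrl_beta1: float = 0.02
    nrl_sigma_subject: float = 0.5
    dyad_jitter_sd: float = 20.0
    jitter_shared_frac: float = 0.75
    frag_mu_mono: float = 167.0
    frag_sd_len: float = 15.0
    mixture: MixtureLink = field(default_factory=MixtureLink)
    n_fragments_per_subject: int = 200_000
    barrier_spacing_range: tuple[float, float] | None = (2500.0, 5000.0)
    differential_bins: np.ndarray | None = None
    diff_bin_size: int = 100
    diff_max_factor: float = 2.0
    seed: int = 0
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (hi > lo >= 0):
            raise ValueError("age_range must satisfy 0 <= lo < hi")
        nrl_hi = self.nrl_beta0 + self.nrl_beta1 * hi
        nrl_lo = self.nrl_beta0 + self.nrl_beta1 * lo
        for v in (nrl_lo, nrl_hi):
            if not (140.0 <= v <= 260.0):
                raise ValueError(f"mean NRL {v:.1f} bp outside [140, 260]")
        if self.genome_length < 100 * nrl_hi:
            raise ValueError("genome_length must be >= 100 * NRL")
        if self.barrier_spacing_range is not None:
            blo, bhi = self.barrier_spacing_range
            if not (bhi >= blo > 0):
                raise ValueError("barrier_spacing_range must satisfy 0 < lo <= hi")
        # Mixture must stay a probability vector across the whole age range.
        self.mixture.weights(lo)
        self.mixture.weights(hi)
        if self.n_fragments_per_subject < 1:
            raise ValueError("n_fragments_per_subject must be positive")
        if self.diff_max_factor < 1:
            raise ValueError("diff_max_factor must be >= 1")
        if not (0.0 <= self.jitter_shared_frac <= 1.0):
            raise ValueError("jitter_shared_frac must lie in [0, 1]")

    def true_nrl(self, age: float, rng: np.random.Generator) -> float:
        return self.nrl_beta0 + self.nrl_beta1 * age + rng.normal(0.0, self.nrl_sigma_subject)

    def diff_factor(self, age: float) -> float:
        lo, hi = self.age_range
        frac = np.clip((age - lo) / (hi - lo), 0.0, 1.0)
        return 1.0 + (self.diff_max_factor - 1.0) * float(frac)

    def barrier_positions(self) -> np.ndarray:
        """Cohort-shared array start positions, derived from the cohort seed."""
        if self.barrier_spacing_range is None:
            return np.array([0.0])
        lo, hi = self.barrier_spacing_range
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_BARRIER_STREAM,))
        )
        n_max = int(self.genome_length / lo) + 2
        gaps = rng.uniform(lo, hi, size=n_max)
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        return pos[pos < self.genome_length]

    def shared_jitter_units(self, n_arrays: int, max_slots: int) -> np.ndarray:
        """Cohort-shared standard-normal jitter units per (array, dyad slot).

        The same draw is reused by every subject for the dyad sitting at a
        given slot of a given array, emulating sequence-encoded positioning
        preferences that all individuals share.
        """
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_BARRIER_STREAM, 1))
        )
        return rng.standard_normal((n_arrays, max_slots))


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _dyad_array(
    spec: CohortSpec, true_nrl: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """All dyad positions plus the id of the barrier array each belongs to."""
    barriers = spec.barrier_positions()
    ends = np.append(barriers[1:], float(spec.genome_length))
    counts = np.maximum(((ends - barriers) // true_nrl).astype(np.int64), 0)
    total = int(counts.sum())
    if total < 4:
        raise ValueError("genome too short for dyad array")
    array_id = np.repeat(np.arange(len(barriers)), counts)
    # j-th dyad within its array: global index minus the array's first index
    first_of_array = np.repeat(np.cumsum(counts) - counts, counts)
    j = np.arange(total) - first_of_array
    dyads = np.repeat(barriers, counts) + j * true_nrl
    if spec.dyad_jitter_sd > 0:
        shared_sd = spec.dyad_jitter_sd * np.sqrt(spec.jitter_shared_frac)
        subject_sd = spec.dyad_jitter_sd * np.sqrt(1.0 - spec.jitter_shared_frac)
        if shared_sd > 0:
            units = spec.shared_jitter_units(len(barriers), int(counts.max()))
            dyads = dyads + shared_sd * units[array_id, j]
        if subject_sd > 0:
            dyads = dyads + rng.normal(0.0, subject_sd, total)
    dyads = np.clip(dyads, 0, spec.genome_length - 1)
    return dyads, array_id


def generate_subject(
    spec: CohortSpec,
    age: float,
    rng: np.random.Generator,
    sample_id: str = "subject",
    true_nrl: float | None = None,
) -> tuple[FragmentSet, float]:
    """Emit one subject's FragmentSet plus the subject's true NRL.

    Exactly ``spec.n_fragments_per_subject`` fragments are produced.  Di- and
    tri-nucleosome fragments span adjacent dyads of a single array, never a
    barrier.  When differential bins are planted, candidate fragments are
    thinned by rejection so that fragments overlapping a planted bin are
    retained at ``diff_factor(age)`` times the baseline rate.
    """
    if true_nrl is None:
        true_nrl = spec.true_nrl(age, rng)
    if true_nrl <= 0:
        raise ValueError("true NRL must be positive")

    dyads, array_id = _dyad_array(spec, true_nrl, rng)
    n_dyads = len(dyads)

    weights = spec.mixture.weights(age)
    factor = spec.diff_factor(age) if spec.differential_bins is not None else 1.0
    diff_csum = None
    if spec.differential_bins is not None and factor > 1.0:
        n_bins = -(-spec.genome_length // spec.diff_bin_size)
        mask = np.zeros(n_bins, dtype=np.int64)
        mask[np.asarray(spec.differential_bins, dtype=np.int64)] = 1
        diff_csum = np.concatenate([[0], np.cumsum(mask)])

    # valid span starts per fragment type: a k-nucleosome span must stay
    # within one barrier array
    valid_first = {
        1: np.arange(n_dyads),
        2: np.flatnonzero(array_id[:-1] == array_id[1:]),
        3: np.flatnonzero(array_id[:-2] == array_id[2:]),
    }
    for k in (2, 3):
        if weights[k - 1] > 0 and len(valid_first[k]) == 0:
            raise ValueError(f"no array long enough for {k}-nucleosome fragments")

    n_target = spec.n_fragments_per_subject
    out_starts: list[np.ndarray] = []
    out_ends: list[np.ndarray] = []
    n_have = 0
    while n_have < n_target:
        batch = max(1024, int((n_target - n_have) * 1.2 * max(factor, 1.0)))
        n_nuc = rng.choice(np.array([1, 2, 3]), size=batch, p=weights)
        first = np.empty(batch, dtype=np.int64)
        for k in (1, 2, 3):
            sel = n_nuc == k
            if sel.any():
                pool = valid_first[k]
                first[sel] = pool[rng.integers(0, len(pool), int(sel.sum()))]
        last = first + n_nuc - 1
        span_lo = dyads[first]
        span_hi = dyads[last]
        length = (span_hi - span_lo) + rng.normal(
            spec.frag_mu_mono, spec.frag_sd_len, batch
        )
        length = np.maximum(np.rint(length).astype(np.int64), 1)
        centre = np.rint((span_lo + span_hi) / 2.0).astype(np.int64)
        starts = centre - length // 2
        ends = starts + length
        # clip to genome bounds, keeping end > start
        starts = np.clip(starts, 0, spec.genome_length - 1)
        ends = np.clip(ends, starts + 1, spec.genome_length)

        if diff_csum is not None:
            b_first = starts // spec.diff_bin_size
            b_last = (ends - 1) // spec.diff_bin_size
            overlaps = (diff_csum[b_last + 1] - diff_csum[b_first]) > 0
            w = np.where(overlaps, factor, 1.0)
            keep = rng.random(len(starts)) < w / factor
            starts, ends = starts[keep], ends[keep]

        out_starts.append(starts)
        out_ends.append(ends)
        n_have += len(starts)

    starts = np.concatenate(out_starts)[:n_target]
    ends = np.concatenate(out_ends)[:n_target]
    fs = FragmentSet(sample_id, {spec.chrom_name: (starts, ends)})
    return fs, float(true_nrl)


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[FragmentSet, SampleMeta, float]]:
    """Generate the full cohort: (FragmentSet, SampleMeta, true NRL) per subject.

    Each subject's age, NRL and fragments come from a dedicated RNG stream
    derived from ``(spec.seed, subject index)``; barrier positions come from
    a separate cohort-level stream, so results do not depend on generation
    order.
    """
    lo, hi = spec.age_range
    out = []
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, i)
        age = float(rng.uniform(lo, hi))
        sample_id = f"S{i:03d}"
        fs, true_nrl = generate_subject(spec, age, rng, sample_id=sample_id)
        out.append((fs, SampleMeta(sample_id=sample_id, age=age), true_nrl))
    return out


def write_cohort(
    cohort: list[tuple[FragmentSet, SampleMeta, float]],
    out_dir: str | Path,
    spec: CohortSpec | None = None,
) -> None:
    """Write per-subject BED files, a metadata TSV and a JSON truth file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metas = []
    truth = {}
    for fs, meta, true_nrl in cohort:
        write_fragments(fs, out_dir / f"{meta.sample_id}.bed")
        metas.append(meta)
        truth[meta.sample_id] = {"age": meta.age, "true_nrl": true_nrl}
    write_sample_meta(metas, out_dir / "metadata.tsv")
    payload: dict = {"subjects": truth}
    if spec is not None:
        echo = asdict(spec)
        if echo.get("differential_bins") is not None:
            echo["differential_bins"] = np.asarray(echo["differential_bins"]).tolist()
        payload["spec"] = echo
    (out_dir / "truth.json").write_text(json.dumps(payload, indent=2))
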