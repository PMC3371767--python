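"""Synthetic ChIP + control read generator.

Emulates sonication-and-sequencing around point-source binding events in a
short hypothetical region: each peak is a fixed interval whose endpoints
represent the extreme borders of sonicated fragments; every fragment is a
random sub-interval of its peak, its left endpoint sequenced as a sense
(5') read and its right endpoint as an antisense (3') read. Uniform noise
reads are added independently per strand. The default preset is the
demonstration scenario: a 2000 bp region, two ChIP peaks (20 bp intervals)
of which one coincides with the single control peak (25 bp interval, i.e.
more fragment-length variation in the control), 40 ChIP and 25 control
peak fragments, and 20 noise reads per strand per track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_bed import AlignedRead

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class PeakSpec:
    """A peak as a fragment-placement interval: centre and interval length."""

    centre: int
    interval_length: int

    @property
    def start(self) -> int:
        return self.centre - self.interval_length // 2

    @property
    def end(self) -> int:
        return self.start + self.interval_length

    def overlaps(self, other: "PeakSpec") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; a fixed seed gives byte-identical output."""

    region_length: int = 2000
    chrom: str = "chrS"
    peaks_chip: tuple[PeakSpec, ...] = (PeakSpec(600, 20), PeakSpec(1400, 20))
    peaks_control: tuple[PeakSpec, ...] = (PeakSpec(600, 25),)
    reads_chip: int = 40
    reads_control: int = 25
    noise_per_strand: int = 20
    read_length: int = 30
    single_ended: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for peak in self.peaks_chip + self.peaks_control:
            if not (0 <= peak.start and peak.end <= self.region_length):
                raise ValueError(
                    f"peak interval {peak.start}-{peak.end} outside region "
                    f"[0, {self.region_length})"
                )
            if peak.interval_length < 2:
                raise ValueError("peak interval_length must be >= 2")
        if min(self.reads_chip, self.reads_control, self.noise_per_strand) < 0:
            raise ValueError("read counts must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def paper_preset(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default demonstration scenario with a chosen seed."""
    return replace(SyntheticConfig(seed=seed), **overrides)


@dataclass
class SyntheticDataset:
    """Generated reads plus the ground truth used to score results."""

    config: SyntheticConfig
    chip_reads: list[AlignedRead]
    control_reads: list[AlignedRead]
    truth: list[tuple[str, int, int, str]]  # (chrom, start, end, unique|shared)

    def write_bed(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write chip.bed, control.bed and truth.bed; returns the paths."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "chip": Path(f"{prefix}.chip.bed"),
            "control": Path(f"{prefix}.control.bed"),
            "truth": Path(f"{prefix}.truth.bed"),
        }
        for key, reads in (("chip", self.chip_reads), ("control", self.control_reads)):
            with open(paths[key], "w", newline="\n") as fh:
                for i, read in enumerate(reads):
                    fh.write(
                        f"{read.chrom}\t{read.start}\t{read.end}\t"
                        f"{key}_{i}\t0\t{read.strand}\n"
                    )
        with open(paths["truth"], "w", newline="\n") as fh:
            for chrom, start, end, label in self.truth:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t+\n")
        return paths


def _split_reads(total: int, n_peaks: int) -> list[int]:
    """Split ``total`` fragments equally among peaks, remainder to the first."""
    if n_peaks == 0:
        return []
    base, rem = divmod(total, n_peaks)
    return [base + (rem if i == 0 else 0) for i in range(n_peaks)]


def _draw_fragment(rng: np.random.Generator, peak: PeakSpec) -> tuple[int, int]:
    """Both endpoints uniform in the peak interval, ordered, distinct."""
    for _ in range(_MAX_REDRAWS):
        a, b = rng.integers(peak.start, peak.end, size=2)
        if a != b:
            return (int(min(a, b)), int(max(a, b)))
    raise RuntimeError(
        f"could not draw a valid fragment in peak {peak.start}-{peak.end}"
    )


def _fragment_reads(
    chrom: str, left: int, right: int, read_length: int
) -> tuple[AlignedRead, AlignedRead]:
    """Sense read at the fragment's left endpoint, antisense at its right.

    The antisense read is anchored so that its extracted start position
    (``end - 1``) is exactly the right endpoint; a left edge that would go
    negative is clipped at 0, which leaves the start position unchanged.
    """
    sense = AlignedRead(chrom, left, left + read_length, "+")
    anti = AlignedRead(chrom, max(0, right - read_length + 1), right + 1, "-")
    return sense, anti


def _peak_track_reads(
    rng: np.random.Generator,
    chrom: str,
    peaks: Sequence[PeakSpec],
    n_fragments: int,
    read_length: int,
    single_ended: bool,
) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    for peak, count in zip(peaks, _split_reads(n_fragments, len(peaks))):
        for _ in range(count):
            left, right = _draw_fragment(rng, peak)
            sense, anti = _fragment_reads(chrom, left, right, read_length)
            if single_ended:
                reads.append(sense if rng.integers(2) == 0 else anti)
            else:
                reads.extend((sense, anti))
    return reads


def _noise_reads(
    rng: np.random.Generator,
    chrom: str,
    region_length: int,
    n_per_strand: int,
    read_length: int,
) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    for strand in "+-":
        starts = rng.integers(0, region_length, size=n_per_strand)
        for pos in starts:
            pos = int(pos)
            if strand == "+":
                reads.append(AlignedRead(chrom, pos, pos + read_length, "+"))
            else:
                reads.append(
                    AlignedRead(chrom, max(0, pos - read_length + 1), pos + 1, "-")
                )
    return reads


def generate_synthetic_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the ChIP and control read sets plus truth annotations.

    Peak fragments are emitted as sense/antisense pairs (one fragment =
    two reads) unless ``config.single_ended``, in which case each fragment
    emits one read on a fair-coin strand. Noise reads are uniform over the
    region, independently per strand and track. Truth records each ChIP
    peak interval as ``shared`` (overlapping a control peak) or ``unique``.
    """
    rng = np.random.default_rng(config.seed)
    chip = _peak_track_reads(
        rng, config.chrom, config.peaks_chip, config.reads_chip,
        config.read_length, config.single_ended,
    )
    chip += _noise_reads(
        rng, config.chrom, config.region_length,
        config.noise_per_strand, config.read_length,
    )
    control = _peak_track_reads(
        rng, config.chrom, config.peaks_control, config.reads_control,
        config.read_length, config.single_ended,
    )
    control += _noise_reads(
        rng, config.chrom, config.region_length,
        config.noise_per_strand, config.read_length,
    )
    truth = []
    for peak in config.peaks_chip:
        label = (
            "shared"
            if any(peak.overlaps(cp) for cp in config.peaks_control)
            else "unique"
        )
        truth.append((config.chrom, peak.start, peak.end, label))
    for peak in config.peaks_control:
        if not any(peak.overlaps(cp) for cp in config.peaks_chip):
            truth.append((config.chrom, peak.start, peak.end, "control_only"))
    return SyntheticDataset(config, chip, control, truth)


def generate_fixed_length_fragments(
    n_fragments: int,
    fragment_length: int,
    region_length: int,
    seed: int = 0,
    chrom: str = "chrS",
    read_length: int = 30,
) -> list[AlignedRead]:
    """Paired reads from ``n_fragments`` fragments of one exact length.

    Each fragment's left endpoint is uniform over the region; its
    sense/antisense read pair is then ``fragment_length`` apart in the
    inclusive sense-start-to-antisense-start distance. Used to exercise
    fragment-size estimation against a known truth; keep the region large
    relative to ``n_fragments * fragment_length`` so fragments rarely
    interleave.
    """
    if fragment_length < 2:
        raise ValueError("fragment_length must be >= 2")
    if region_length < fragment_length:
        raise ValueError("region_length must be >= fragment_length")
    rng = np.random.default_rng(seed)
    lefts = rng.integers(0, region_length - fragment_length + 1, size=n_fragments)
    reads: list[AlignedRead] = []
    for left in lefts:
        left = int(left)
        right = left + fragment_length - 1
        reads.extend(_fragment_reads(chrom, left, right, read_length))
    return reads


def homogeneous_config(
    region_length: int = 1_000_000,
    n_loci: int = 100,
    fragments_per_peak: int = 20,
    noise_rate_per_strand: float = 0.01,
    seed: int = 0,
) -> SyntheticConfig:
    """A homogeneous many-peak genome built from the preset's local recipe.

    ``n_loci`` identically distributed peak loci are spaced evenly across
    the region, alternating control-shared and ChIP-unique; noise is
    uniform at ``noise_rate_per_strand`` reads per bp per strand (the
    preset's 20/2000 rate by default). Used for section-size robustness
    checks, where the per-bp output should not depend on how the genome is
    cut into sections.
    """
    spacing = region_length // (n_loci + 1)
    chip_peaks = []
    control_peaks = []
    for i in range(n_loci):
        centre = spacing * (i + 1)
        chip_peaks.append(PeakSpec(centre, 20))
        if i % 2 == 0:
            control_peaks.append(PeakSpec(centre, 25))
    n_shared = len(control_peaks)
    return SyntheticConfig(
        region_length=region_length,
        peaks_chip=tuple(chip_peaks),
        peaks_control=tuple(control_peaks),
        reads_chip=fragments_per_peak * n_loci,
        reads_control=fragments_per_peak * n_shared,
        noise_per_strand=int(round(noise_rate_per_strand * region_length)),
        seed=seed,
    )
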