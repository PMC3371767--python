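"""Boxcar smoothing, regular resampling, and per-bp signal rebuild.

Each per-bp start-count track is reduced to window means of width
``2*half_width + 1`` bp reported at centres spaced ``step`` bp apart
(defaults +/-5 bp every 5 bp, an overlapping design: the 11 bp windows of
adjacent centres share 6 bp). The window means at the centres are the
observation vectors fed to the regression; afterwards a per-bp signal is
rebuilt from the per-centre residuals by nearest-centre or linear fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_bed import StartCountTrack

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 5
DEFAULT_STEP = 5


@dataclass
class SmoothedTrack:
    """Window-mean counts sampled at regularly spaced centres.

    ``values[j]`` is the mean of the ``2*half_width + 1`` per-bp counts in
    the window centred at ``centres[j]``; centres are absolute 0-based
    coordinates, ``step`` bp apart.
    """

    chrom: str
    centres: np.ndarray
    values: np.ndarray
    half_width: int
    step: int

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.centres.shape != self.values.shape:
            raise ValueError("centres and values must have equal length")
        if len(self.centres) > 1:
            diffs = np.diff(self.centres)
            if not np.all(diffs == self.step):
                raise ValueError("centres must be spaced exactly step bp apart")

    def __len__(self) -> int:
        return int(self.centres.shape[0])


def smooth_and_sample(
    track: StartCountTrack,
    strand: str,
    half_width: int = DEFAULT_HALF_WIDTH,
    step: int = DEFAULT_STEP,
) -> SmoothedTrack:
    """Window-average one strand of a start-count track and resample it.

    Centres start at ``origin + half_width`` and advance by ``step`` while
    the full window fits inside the track; windows that would hang over
    either end are dropped rather than shrunk, so every value is the mean
    of exactly ``2*half_width + 1`` counts. A track shorter than one window
    yields an empty SmoothedTrack.
    """
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    counts = np.asarray(track.counts(strand), dtype=float)
    window = 2 * half_width + 1
    if counts.shape[0] < window:
        logger.info(
            "track %s:%d (+%d bp) shorter than one %d bp window; empty result",
            track.chrom, track.origin, counts.shape[0], window,
        )
        return SmoothedTrack(
            track.chrom, np.empty(0, dtype=np.int64), np.empty(0), half_width, step
        )
    # mean over every fully contained window, then take every step-th one
    means = np.convolve(counts, np.full(window, 1.0 / window), mode="valid")
    sampled = means[::step]
    centres = track.origin + half_width + step * np.arange(sampled.shape[0])
    return SmoothedTrack(track.chrom, centres, sampled, half_width, step)


def rebuild_per_bp(
    centres: np.ndarray,
    values: np.ndarray,
    fill_mode: str,
    region_start: int,
    region_length: int,
) -> np.ndarray:
    """Rebuild a per-bp signal over ``[region_start, region_start+region_length)``
    from per-centre values.

    ``fill_mode='step'``: each position takes its nearest centre's value,
    exact midpoints going to the left centre. ``fill_mode='linear'``:
    positions between adjacent centres are linearly interpolated. In both
    modes positions outside the centre span take the terminal centre's
    value, and the centre coordinates themselves reproduce their values
    exactly.
    """
    centres = np.asarray(centres, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if centres.shape[0] == 0:
        raise ValueError("rebuild_per_bp requires at least one centre")
    if fill_mode not in ("step", "linear"):
        raise ValueError(f"fill_mode must be 'step' or 'linear', got {fill_mode!r}")
    positions = region_start + np.arange(region_length)
    if fill_mode == "linear":
        return np.interp(positions, centres, values)
    # step: nearest centre, ties to the left
    right = np.searchsorted(centres, positions, side="left")
    right = np.clip(right, 1, len(centres) - 1) if len(centres) > 1 else np.zeros_like(right)
    left = right - 1 if len(centres) > 1 else right
    if len(centres) == 1:
        return np.full(region_length, values[0])
    dist_left = positions - centres[left]
    dist_right = centres[right] - positions
    take_left = dist_left <= dist_right
    idx = np.where(take_left, left, right)
    return values[idx]
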