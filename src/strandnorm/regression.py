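"""Per-section ordinary least squares of ChIP on control observations.

The observed ChIP start signal is modelled as a linear combination of the
true antibody-driven signal and nuisance components (sequencing background,
non-specific antibody binding) that the control measurements — Input
chromatin and/or IgG — also capture. Because the true signal is assumed
uncorrelated with the nuisance components, regressing the smoothed ChIP
observations on the smoothed controls *without an intercept* and keeping
the residuals yields a scaled estimate of the true signal at every
observation centre. Sequencing-depth differences between tracks are
absorbed into the regression coefficients, so no prior depth scaling is
needed or wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_bed import StartCountTrack
from .smoothing import (
    DEFAULT_HALF_WIDTH,
    DEFAULT_STEP,
    SmoothedTrack,
    smooth_and_sample,
)

logger = logging.getLogger(__name__)


@dataclass
class SectionFit:
    """Result of one per-section, per-strand regression.

    coefficients
        One unconstrained OLS coefficient per control (minimum-norm when
        the design is rank-deficient). If an intercept was requested it is
        stored separately in ``intercept``.
    residuals
        Observed minus fitted values at each centre — the scaled estimate
        of the antibody-driven signal. Negative residuals are retained
        here; they are only suppressed at BED export.
    n_hat
        Fitted values (the estimated nuisance signal).
    rank
        Numerical rank of the design matrix.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    n_hat: np.ndarray
    n_centres: int
    rank: int
    intercept: Optional[float] = None
    degenerate: bool = False

    @property
    def n_controls(self) -> int:
        return int(self.coefficients.shape[0])


def fit_section(
    chip: np.ndarray,
    controls: Sequence[np.ndarray],
    intercept: bool = False,
) -> SectionFit:
    """Fit ChIP observations on 1..K control observations by no-intercept OLS.

    Minimizes ``sum_i (chip_i - sum_k u_k * control_k,i)**2``. Solved with
    a rank-revealing least-squares routine; a rank-deficient design (e.g.
    an all-zero or collinear control) yields the minimum-norm solution and
    the reported rank, never an error.

    Raises if the section has too few observations (``n <= K``) or any
    input is non-finite.
    """
    chip = np.asarray(chip, dtype=float)
    cols = [np.asarray(c, dtype=float) for c in controls]
    if not cols:
        raise ValueError("at least one control vector is required")
    n = chip.shape[0]
    for c in cols:
        if c.shape[0] != n:
            raise ValueError("chip and control vectors must have equal length")
    n_params = len(cols) + (1 if intercept else 0)
    if n <= n_params:
        raise ValueError(
            f"section has too few observations: n={n} with {n_params} parameters"
        )
    design = np.column_stack(cols + ([np.ones(n)] if intercept else []))
    if not (np.all(np.isfinite(chip)) and np.all(np.isfinite(design))):
        raise ValueError("non-finite values in regression input")

    coef, _, rank, _ = np.linalg.lstsq(design, chip)
    n_hat = design @ coef
    residuals = chip - n_hat
    if np.any(coef[: len(cols)] < 0):
        logger.info(
            "negative control coefficient(s): %s",
            np.array2string(coef[: len(cols)], precision=4),
        )
    return SectionFit(
        coefficients=coef[: len(cols)],
        residuals=residuals,
        n_hat=n_hat,
        n_centres=n,
        rank=int(rank),
        intercept=float(coef[-1]) if intercept else None,
    )


def normalize_section(
    chip_track: StartCountTrack,
    control_tracks: Sequence[StartCountTrack],
    strand: str,
    half_width: int = DEFAULT_HALF_WIDTH,
    step: int = DEFAULT_STEP,
    intercept: bool = False,
) -> tuple[SmoothedTrack, SectionFit]:
    """Smooth, sample and regress one section for one strand.

    All tracks are smoothed and sampled identically (same centres), then
    the ChIP observations are fitted on the controls. Returns the ChIP
    SmoothedTrack (whose centres align the residuals to the genome) and
    the SectionFit. A section whose smoothed ChIP observations are all
    zero short-circuits to all-zero residuals without fitting.
    """
    if not control_tracks:
        raise ValueError("at least one control track is required")
    for trk in control_tracks:
        if trk.chrom != chip_track.chrom or trk.origin != chip_track.origin or (
            trk.length != chip_track.length
        ):
            raise ValueError("all tracks must cover the same section")

    smoothed_chip = smooth_and_sample(chip_track, strand, half_width, step)
    smoothed_controls = [
        smooth_and_sample(trk, strand, half_width, step) for trk in control_tracks
    ]
    n = len(smoothed_chip)
    if n == 0 or not np.any(smoothed_chip.values):
        logger.info(
            "section %s:%d strand %s: ChIP observations all zero; skipping fit",
            chip_track.chrom, chip_track.origin, strand,
        )
        zeros = np.zeros(n)
        fit = SectionFit(
            coefficients=np.zeros(len(control_tracks)),
            residuals=zeros,
            n_hat=zeros.copy(),
            n_centres=n,
            rank=0,
            degenerate=True,
        )
        return smoothed_chip, fit
    fit = fit_section(
        smoothed_chip.values,
        [s.values for s in smoothed_controls],
        intercept=intercept,
    )
    return smoothed_chip, fit
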