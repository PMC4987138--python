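"""Compact quantification formulas for imaging and electrophysiology traces.

Covers the standard readouts used alongside the behavioral assay: fractional
fluorescence change (dF/F) for calcium-indicator ROI traces, the
background-subtracted cyan:yellow emission ratio for ratiometric chloride
(FRET) imaging with an optional scalar bleed-through correction, binned
peristimulus time histograms of spike times, and the reversal potential of
glycine-evoked currents as the x-intercept of a linear current-voltage fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


class DegenerateBaselineError(ValueError):
    """Baseline fluorescence F0 is not positive."""


class NoReversalError(ValueError):
    """The fitted I-V line has zero slope: no x-intercept."""


@dataclass
class RoiTrace:
    """ROI mean-intensity time series with a matched background series."""

    intensity: np.ndarray
    background: np.ndarray
    rate: float = 1.0   # acquisition rate, Hz

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.background = np.broadcast_to(
            np.asarray(self.background, dtype=float), self.intensity.shape).copy()
        if self.intensity.shape != self.background.shape:
            raise ValueError("intensity and background must have equal length")
        if np.any(self.intensity < 0) or np.any(self.background < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def corrected(self) -> np.ndarray:
        return self.intensity - self.background


@dataclass
class IVPoints:
    """Paired command potentials (mV) and peak currents (pA)."""

    potentials: np.ndarray
    currents: np.ndarray

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape:
            raise ValueError("potentials and currents must be paired")
        if np.unique(self.potentials).size < 2:
            raise ValueError("need at least 2 distinct command potentials")


#: the standard voltage-step protocol: -80 to +10 mV in +10 mV increments
DEFAULT_IV_GRID = np.arange(-80.0, 10.0 + 1e-9, 10.0)


def dff(trace: RoiTrace, f0_window: int = 20) -> np.ndarray:
    """Fractional fluorescence change (F(t) - F0) / F0.

    F(t) is the background-subtracted ROI intensity; F0 is the mean of F over
    the initial ``f0_window`` frames (before stimulation begins).
    """
    f = trace.corrected
    if len(f) <= f0_window:
        raise ValueError(f"trace length {len(f)} must exceed f0_window={f0_window}")
    f0 = float(f[:f0_window].mean())
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline F0={f0:g} is not positive")
    return (f - f0) / f0


def ratio_cfp_yfp(cfp: RoiTrace, yfp: RoiTrace,
                  bleed_fraction: float = 0.0) -> np.ndarray:
    """Background-subtracted cyan:yellow intensity ratio.

    The yellow channel is corrected for donor bleed-through by subtracting
    ``bleed_fraction`` of the background-subtracted cyan signal (a single
    scalar correction). Samples where the corrected yellow signal is not
    positive are masked to NaN with a warning.
    """
    c = cfp.corrected
    y = yfp.corrected - bleed_fraction * c
    if c.shape != y.shape:
        raise ValueError("CFP and YFP traces must be aligned")
    bad = y <= 0
    if bad.any():
        log.warning("masked %d samples with nonpositive corrected YFP", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, c / np.where(bad, np.nan, y))
    return out


def psth(spike_times: np.ndarray, stimulus_onsets: np.ndarray,
         window: float, bin_width: float = 0.1
         ) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram in Hz.

    Spikes are aligned to each stimulus onset and counted in bins covering
    [0, window); counts convert to a rate by dividing by
    (bin_width * number of onsets). Returns (bin left edges, rates).
    """
    if bin_width <= 0 or window <= 0:
        raise ValueError("window and bin_width must be positive")
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one stimulus onset")
    spikes = np.asarray(spike_times, dtype=float)
    edges = np.arange(0.0, window + bin_width * 0.5, bin_width)
    if edges[-1] > window + 1e-12:
        edges = edges[:-1]
    counts = np.zeros(len(edges) - 1)
    for on in onsets:
        rel = spikes - on
        rel = rel[(rel >= 0) & (rel < edges[-1])]
        counts += np.histogram(rel, bins=edges)[0]
    rates = counts / (bin_width * onsets.size)
    return edges[:-1], rates


@dataclass
class ReversalFit:
    reversal_mv: float
    slope: float
    intercept: float
    residual_rms: float
    curvature_warning: bool


def egly_xintercept(points: IVPoints) -> ReversalFit:
    """Reversal potential as the x-intercept of a least-squares I-V line.

    Fits I = slope * V + intercept by ordinary least squares and returns
    -intercept/slope with residual diagnostics. A warning flag is set when a
    quadratic term reduces the residual sum of squares by more than half
    (the I-V relation may be rectifying rather than linear).
    """
    v, i = points.potentials, points.currents
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < 1e-12:
        raise NoReversalError("fitted I-V line has zero slope")
    resid1 = i - (slope * v + intercept)
    rss1 = float(resid1 @ resid1)
    curvature = False
    if np.unique(v).size >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            q = np.polyfit(v, i, 2)
        resid2 = i - np.polyval(q, v)
        rss2 = float(resid2 @ resid2)
        if rss1 > 0 and rss2 < 0.5 * rss1:
            curvature = True
            log.warning("quadratic I-V fit halves the residual: possible rectification")
    return ReversalFit(reversal_mv=float(-intercept / slope), slope=float(slope),
                       intercept=float(intercept),
                       residual_rms=float(np.sqrt(rss1 / len(v))),
                       curvature_warning=curvature)
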