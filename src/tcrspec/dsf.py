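"""Differential scanning fluorimetry (DSF) melting-temperature estimation.

A thermal melt monitored by an environment-sensitive dye (SYPRO-orange
convention: fluorescence rises on unfolding) is reduced to a melting
temperature by the derivative-maximum rule: T_m is the temperature at the
global maximum of the first derivative of the (optionally smoothed) melt
curve, searched over an interior window that excludes the curve ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, NoTransitionError

__all__ = ["MeltCurve", "TmResult", "estimate_tm"]


@dataclass
class MeltCurve:
    """Fluorescence vs temperature, strictly increasing temperature axis."""

    temperatures: np.ndarray  # degrees C
    fluorescence: np.ndarray  # arbitrary units
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise InvalidParameterError("temperature/fluorescence length mismatch")
        if self.temperatures.size < 10:
            raise InvalidParameterError("melt curve needs >= 10 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise InvalidParameterError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TmResult:
    tm: float  # degrees C
    derivative_peak_height: float  # AU per degree C
    flags: tuple[str, ...] = field(default_factory=tuple)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    if window % 2 == 0:
        raise InvalidParameterError("smooth_window must be odd")
    pad = window // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")


def estimate_tm(
    curve: MeltCurve,
    smooth_window: int = 5,
    edge_exclude: int = 2,
    inverted: bool = False,
) -> TmResult:
    """T_m as the temperature of the first-derivative maximum.

    Parameters
    ----------
    smooth_window : int
        Width (points, odd) of the centered moving average applied before
        differentiation; 1 disables smoothing.
    edge_exclude : int
        Points excluded at each end of the derivative when searching for the
        maximum, guarding against edge artefacts.
    inverted : bool
        Set True for dyes whose signal decreases on unfolding; the signal is
        negated before analysis.

    Raises
    ------
    NoTransitionError
        If the curve has no dynamic range or the derivative shows no peak
        above its own background (e.g. a strictly linear signal).
    """
    y = -curve.fluorescence if inverted else curve.fluorescence
    t = curve.temperatures
    if np.ptp(y) <= 0:
        raise NoTransitionError("flat melt curve: no dynamic range")

    ys = _moving_average(y, smooth_window)
    deriv = np.gradient(ys, t)

    lo = edge_exclude
    hi = deriv.size - edge_exclude
    if hi - lo < 3:
        raise InvalidParameterError("curve too short for the interior window")
    interior = deriv[lo:hi]

    peak_idx = int(np.argmax(interior))  # first (lowest-T) max on ties
    peak = float(interior[peak_idx])
    background = float(np.median(interior))
    spread = peak - float(np.min(interior))
    # the peak must rise above the typical derivative level by a meaningful
    # fraction of the derivative range; rules out linear signals and falling
    # sigmoids analyzed without inversion
    if peak <= 0 or spread <= 0 or (peak - background) <= 0.05 * spread:
        raise NoTransitionError(
            "no unfolding transition: derivative has no peak above background"
        )

    flags: list[str] = []
    if peak_idx in (0, interior.size - 1):
        flags.append("edge-peak")
    if (peak - background) < 3.0 * _mad(interior):
        flags.append("low-amplitude")

    return TmResult(
        tm=float(t[lo + peak_idx]),
        derivative_peak_height=peak,
        flags=tuple(flags),
    )


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))
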