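"""Adjacent-averaging smoothing, applied before differentiation.

The noise-removal step of the pipeline is an unweighted moving average with
a centered window (the "adjacent averaging" of common lab plotting
software), default 50 points.  A symmetric centered window needs an odd
length, so an even request w is realized as the centered window of w+1
points; the substitution is logged.  Near the edges the window shrinks
symmetrically to the largest centered window that fits, which avoids the
phase lag of a trailing window and so does not bias lift-off or collapse
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import SmoothingConfigError
from .io import CompressionIsotherm

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50


@dataclass(frozen=True)
class SmoothingConfig:
    """window: points; apply_to: which signals are smoothed."""

    window: int = DEFAULT_WINDOW
    apply_to: Literal["pressure", "potential", "both"] = "both"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise SmoothingConfigError("window must be >= 1")
        if self.apply_to not in ("pressure", "potential", "both"):
            raise SmoothingConfigError(f"bad apply_to {self.apply_to!r}")


def effective_window(window: int) -> int:
    """Odd window actually used for a requested size."""
    if window % 2 == 0:
        return window + 1
    return window


def adjacent_average(signal, window: int) -> np.ndarray:
    """Centered moving average with symmetric edge shrink.

    Each output point is the unweighted mean of the input points inside a
    centered window of the requested size (rounded up to odd); at the
    edges the window shrinks symmetrically so the output has the same
    length as the input.  Constants and the interior of linear ramps pass
    through unchanged.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if window < 1:
        raise SmoothingConfigError("window must be >= 1")
    if window > n:
        raise SmoothingConfigError(f"window {window} exceeds signal length {n}")
    w = effective_window(window)
    if w != window:
        logger.debug("even window %d realized as centered window %d", window, w)
    if w == 1:
        return x.copy()
    half = w // 2
    # cumulative sum with a leading zero: sum(x[a:b]) == c[b] - c[a]
    c = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo = idx - k
    hi = idx + k + 1
    out = (c[hi] - c[lo]) / (hi - lo)
    return out


def prepare_for_derivative(
    iso: CompressionIsotherm, cfg: SmoothingConfig = SmoothingConfig()
) -> CompressionIsotherm:
    """Return a copy of the isotherm with the configured signals smoothed.

    The area grid is untouched.  The smoothing configuration is appended to
    the metadata processing log for provenance; smoothing an already
    smoothed isotherm is permitted but shows up twice in that log.
    """
    pressure = iso.pressure
    potential = iso.potential
    if cfg.apply_to in ("pressure", "both"):
        pressure = adjacent_average(iso.pressure, cfg.window)
    if cfg.apply_to in ("potential", "both") and iso.potential is not None:
        potential = adjacent_average(iso.potential, cfg.window)
    stamp = f"adjacent_average(window={cfg.window}, apply_to={cfg.apply_to})"
    prior = iso.metadata.processing
    if any(s.startswith("adjacent_average") for s in prior):
        logger.warning("smoothing applied to an already-smoothed isotherm")
    meta = iso.metadata
    import dataclasses

    meta = dataclasses.replace(meta, processing=prior + (stamp,))
    return CompressionIsotherm(
        area=iso.area.copy(),
        pressure=pressure,
        potential=potential,
        metadata=meta,
    )
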