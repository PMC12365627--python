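"""Binary spectral barcodes from the Savitzky-Golay second derivative.

A spectrum is smoothed and twice differentiated by a Savitzky-Golay filter
(window 21 points, polynomial order 2 by default); positions where the
absolute second derivative exceeds 40 % of its maximum are assigned bit 1,
the rest bit 0.  Because the second derivative is linear and the threshold
is relative, the barcode is invariant to positive scaling and to affine
transforms of the spectrum (hence unchanged by SNV normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import EvspecError, WavenumberAxis
from .synthetic import PeakSpec


@dataclass(frozen=True)
class BarcodeConfig:
    window: int = 21
    polyorder: int = 2
    deriv: int = 2
    threshold: float = 0.40
    mode: str = "full"  # "full" | "peaks" (threshold only at local extrema)

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise EvspecError("window must be odd and >= 3")
        if not self.polyorder < self.window:
            raise EvspecError("polyorder must be < window")
        if self.polyorder < self.deriv:
            raise EvspecError("polyorder must be >= derivative order")
        if not 0 < self.threshold < 1:
            raise EvspecError("threshold must be in (0, 1)")


@dataclass
class Barcode:
    axis: WavenumberAxis
    bits: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.size != len(self.axis):
            raise EvspecError("bit vector length must equal axis length")
        if not np.isin(self.bits, (0, 1)).all():
            raise EvspecError("bits must be 0 or 1")

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


def sg_second_derivative(
    y: np.ndarray,
    config: BarcodeConfig | None = None,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay second derivative (polynomial-extrapolated edges)."""
    cfg = config or BarcodeConfig()
    y = np.asarray(y, dtype=float)
    if y.size <= cfg.window:
        raise EvspecError(f"spectrum length {y.size} must exceed window {cfg.window}")
    return savgol_filter(y, cfg.window, cfg.polyorder, deriv=cfg.deriv,
                         delta=delta, mode="interp")


def make_barcode(
    derivative: np.ndarray,
    axis: WavenumberAxis,
    config: BarcodeConfig | None = None,
    source_id: str = "",
) -> Barcode:
    """Threshold |second derivative| at threshold x max to binary bits.

    In "peaks" mode only local extrema of |d| can fire, giving the sparse
    tick-mark style barcode; "full" mode (default) thresholds every point.
    """
    cfg = config or BarcodeConfig()
    d = np.asarray(derivative, dtype=float)
    if not np.all(np.isfinite(d)):
        raise EvspecError("derivative contains non-finite values")
    m = np.abs(d).max()
    if m == 0:
        raise EvspecError("degenerate input: all-zero derivative")
    bits = (np.abs(d) > cfg.threshold * m).astype(int)
    if cfg.mode == "peaks":
        from scipy.signal import argrelextrema
        ext = np.zeros_like(bits)
        idx = argrelextrema(np.abs(d), np.greater_equal, order=1)[0]
        ext[idx] = 1
        bits = bits * ext
    return Barcode(axis, bits, source_id)


def spectrum_barcode(
    y: np.ndarray,
    axis: WavenumberAxis,
    config: BarcodeConfig | None = None,
    source_id: str = "",
) -> Barcode:
    """Convenience: derivative + thresholding in one call."""
    cfg = config or BarcodeConfig()
    d = sg_second_derivative(y, cfg, delta=axis.step)
    return make_barcode(d, axis, cfg, source_id)


def barcode_overlay_table(barcode: Barcode, peak_table: list[PeakSpec]) -> list[dict]:
    """Annotate the barcode bit at each reference band center."""
    records = []
    for p in peak_table:
        i = barcode.axis.index_of(p.center)
        records.append({
            "center": p.center,
            "assignment": p.assignment,
            "bit": int(barcode.bits[i]),
        })
    return records
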