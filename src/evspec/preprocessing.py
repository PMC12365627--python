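"""Spectral cleanup: despiking, baseline subtraction, averaging, SNV.

The stages run in a fixed order — cosmic-ray despiking first (spikes would
corrupt both the baseline fit and any averaging), then iterative polynomial
baseline subtraction, then optional replicate averaging, then standard
normal variate (SNV) normalization, which removes per-spectrum
multiplicative scatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .core import EvspecError, LabeledDataset, RamanSpectrum


@dataclass(frozen=True)
class PreprocessConfig:
    despike_window: int = 7
    despike_z: float = 8.0
    baseline_order: int = 5
    baseline_iters: int = 30
    replicate_group: int = 1

    def __post_init__(self) -> None:
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise EvspecError("despike window must be odd and >= 3")
        if self.baseline_order < 1:
            raise EvspecError("baseline order must be >= 1")
        if self.replicate_group < 1:
            raise EvspecError("replicate group must be >= 1")


def despike(y: np.ndarray, window: int = 7, z: float = 8.0) -> np.ndarray:
    """Replace cosmic-ray spikes by the running median.

    A point is a spike when its residual from the running median exceeds
    ``z`` times a robust scale (1.4826 x MAD of the residuals, floored at
    1 % of the spectrum's peak-to-peak range so that noiseless band
    curvature never fires the test).  All other points are returned
    unchanged bit-for-bit.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise EvspecError("despike window must be odd")
    if window >= y.size:
        raise EvspecError(f"despike window {window} must be smaller than spectrum ({y.size})")
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    ptp = float(np.max(y) - np.min(y))
    scale = max(1.4826 * float(mad), 0.01 * ptp, 1e-300)
    out = y.copy()
    spikes = np.abs(resid) > z * scale
    out[spikes] = med[spikes]
    return out


def baseline_subtract(
    y: np.ndarray,
    x: np.ndarray | None = None,
    order: int = 5,
    iters: int = 30,
) -> np.ndarray:
    """Iterative peak-clipping polynomial baseline subtraction.

    A degree-``order`` polynomial is fit to the spectrum; wherever the fit
    exceeds the working signal the working signal is kept (clipping the
    peaks out of the fit), and the fit is repeated.  Returns the spectrum
    minus the converged baseline estimate.
    """
    y = np.asarray(y, dtype=float)
    if order >= y.size:
        raise EvspecError("baseline order must be smaller than the number of points")
    if x is None:
        x = np.arange(y.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if x.size != y.size:
            raise EvspecError("x and y lengths differ")
        if np.ptp(x) == 0:
            raise EvspecError("degenerate axis: zero span")

    work = y.copy()
    fit = work
    for _ in range(max(1, iters)):
        poly = np.polynomial.Polynomial.fit(x, work, order)
        fit = poly(x)
        work = np.minimum(work, fit)
    return y - fit


def average_replicates(Y: np.ndarray, g: int) -> np.ndarray:
    """Mean over consecutive groups of ``g`` rows (map-position replicates).

    Averaging g replicates shrinks iid noise SD by 1/sqrt(g).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if g < 1:
        raise EvspecError("group size must be >= 1")
    if Y.shape[0] % g != 0:
        raise EvspecError(f"number of spectra ({Y.shape[0]}) is not a multiple of group size {g}")
    return Y.reshape(Y.shape[0] // g, g, Y.shape[1]).mean(axis=1)


def snv(y: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale to unit (n-1) variance.

    Invariant to affine transforms a*y + b (a > 0), which is what removes
    multiplicative scatter between spectra.
    """
    y = np.asarray(y, dtype=float)
    sd = np.std(y, ddof=1)
    if sd == 0:
        raise EvspecError("degenerate input: constant spectrum has zero SD")
    return (y - np.mean(y)) / sd


def preprocess_dataset(
    dataset: LabeledDataset,
    config: PreprocessConfig | None = None,
) -> LabeledDataset:
    """Run despike -> baseline -> (replicate averaging) -> SNV on a dataset."""
    cfg = config or PreprocessConfig()
    x = dataset.axis.values

    def clean(v: np.ndarray) -> np.ndarray:
        v = despike(v, cfg.despike_window, cfg.despike_z)
        v = baseline_subtract(v, x, cfg.baseline_order, cfg.baseline_iters)
        return v

    ds = dataset.map_intensities(clean)
    if cfg.replicate_group > 1:
        Y = average_replicates(ds.X, cfg.replicate_group)
        keep = ds.spectra[:: cfg.replicate_group]
        spectra = [
            RamanSpectrum(ds.axis, snv(row), s.fraction, s.state, s.sample_id)
            for row, s in zip(Y, keep)
        ]
        return LabeledDataset(spectra, class_names=list(ds.class_names), label_by=ds.label_by)
    return ds.map_intensities(snv)
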