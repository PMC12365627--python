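"""Core containers for Raman spectra and labeled spectral datasets.

The pipeline's atom is a :class:`RamanSpectrum`: one shared wavenumber axis
(the 700-1700 cm^-1 biological fingerprint region by default) plus an
intensity vector and fraction/state metadata.  A :class:`LabeledDataset`
stacks spectra that share a single axis and is the substrate for supervised
training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberAxis", "RamanSpectrum", "LabeledDataset", "EvspecError"]


class EvspecError(ValueError):
    """Labeled input/validation error raised across the package."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform wavenumber grid in cm^-1, inclusive of both endpoints.

    The default covers the biological fingerprint region 700-1700 cm^-1 at
    1 cm^-1 spacing (1001 points).
    """

    start: float = 700.0
    stop: float = 1700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise EvspecError(f"axis start ({self.start}) must be < stop ({self.stop})")
        if self.step <= 0:
            raise EvspecError(f"axis step must be positive, got {self.step}")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        if not self.contains(wavenumber):
            raise EvspecError(f"wavenumber {wavenumber} outside axis [{self.start}, {self.stop}]")
        return int(round((wavenumber - self.start) / self.step))

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavenumberAxis":
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise EvspecError("axis needs at least two points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise EvspecError("wavenumber axis must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise EvspecError("wavenumber axis must be uniformly spaced")
        return cls(float(values[0]), float(values[-1]), float(steps[0]))


@dataclass
class RamanSpectrum:
    axis: WavenumberAxis
    intensities: np.ndarray
    fraction: str = ""
    state: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size != len(self.axis):
            raise EvspecError(
                f"intensity vector length {self.intensities.size} does not match axis "
                f"length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise EvspecError("spectrum contains non-finite intensities")

    @property
    def label(self) -> str:
        """Combined class label used for supervised training."""
        parts = [p for p in (self.fraction, self.state) if p]
        return "/".join(parts)

    def with_intensities(self, values: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.axis, values, self.fraction, self.state, self.sample_id)


@dataclass
class LabeledDataset:
    """Spectra on one shared axis with an ordered class vocabulary."""

    spectra: list[RamanSpectrum]
    class_names: list[str] = field(default_factory=list)
    label_by: str = "label"  # "label" | "fraction" | "state"

    def __post_init__(self) -> None:
        if not self.spectra:
            raise EvspecError("dataset must contain at least one spectrum")
        axis0 = self.spectra[0].axis
        for i, s in enumerate(self.spectra):
            if s.axis != axis0:
                raise EvspecError(f"spectrum {i} is on a different wavenumber axis")
        if not self.class_names:
            seen: dict[str, None] = {}
            for s in self.spectra:
                seen.setdefault(self._label_of(s))
            self.class_names = list(seen)
        for i, s in enumerate(self.spectra):
            if self._label_of(s) not in self.class_names:
                raise EvspecError(f"spectrum {i} label {self._label_of(s)!r} not in class_names")

    def _label_of(self, s: RamanSpectrum) -> str:
        if self.label_by == "fraction":
            return s.fraction
        if self.label_by == "state":
            return s.state
        return s.label

    @property
    def axis(self) -> WavenumberAxis:
        return self.spectra[0].axis

    @property
    def labels(self) -> list[str]:
        return [self._label_of(s) for s in self.spectra]

    @property
    def X(self) -> np.ndarray:
        """Spectrum matrix, one row per spectrum."""
        return np.vstack([s.intensities for s in self.spectra])

    @property
    def y(self) -> np.ndarray:
        """Integer class index per spectrum, following class_names order."""
        idx = {c: k for k, c in enumerate(self.class_names)}
        return np.array([idx[lab] for lab in self.labels], dtype=int)

    def __len__(self) -> int:
        return len(self.spectra)

    def map_intensities(self, fn) -> "LabeledDataset":
        """Apply ``fn(vector) -> vector`` to every spectrum, keeping labels."""
        return LabeledDataset(
            [s.with_intensities(fn(s.intensities)) for s in self.spectra],
            class_names=list(self.class_names),
            label_by=self.label_by,
        )
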