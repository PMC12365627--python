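"""Size-exclusion membrane cascade model.

Particles flow top-down through a stack of membranes with strictly
decreasing pore sizes (default 5000, 500, 200, 100, 40 nm).  A particle is
trapped in the well above the FIRST membrane whose pore size it cannot pass
(diameter >= pore); anything smaller than every pore reaches the eluate.
The 40 nm membrane at the bottom traps sub-EV protein contaminants.

The separation-efficiency statistic is reported in two readings:
``routing_accuracy`` — the fraction of particles collected in their
size-expected well — and ``well_purity`` — per-well purity (fraction of
a well's content that belongs there) averaged over occupied wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EvspecError

DEFAULT_PORES = (5000.0, 500.0, 200.0, 100.0, 40.0)


@dataclass(frozen=True)
class ChipConfig:
    """Membrane pore sizes in nm, ordered top (largest) to bottom."""

    pore_sizes: tuple[float, ...] = DEFAULT_PORES

    def __post_init__(self) -> None:
        if len(self.pore_sizes) < 1:
            raise EvspecError("chip needs at least one membrane")
        if any(p <= 0 for p in self.pore_sizes):
            raise EvspecError("pore sizes must be positive")
        if len(self.pore_sizes) > 1 and np.any(np.diff(self.pore_sizes) >= 0):
            raise EvspecError("pore sizes must be strictly decreasing top to bottom")


@dataclass
class WellContents:
    """Per-membrane particle collections plus the final eluate.

    ``wells`` maps pore size (nm) to a list of (diameter, source label)
    tuples; every input particle appears in exactly one well or the eluate.
    """

    wells: dict[float, list[tuple[float, str]]]
    eluate: list[tuple[float, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.wells.values()) + len(self.eluate)

    def counts(self) -> dict[float, int]:
        c = {pore: len(v) for pore, v in self.wells.items()}
        c[0.0] = len(self.eluate)
        return c


@dataclass
class EfficiencyReport:
    well_purity: float
    routing_accuracy: float
    per_well_counts: dict[float, int]


def route_particles(
    diameters,
    chip: ChipConfig | None = None,
    labels=None,
    misroute_prob: float = 0.0,
    seed: int = 0,
) -> WellContents:
    """Deterministically route particles through the membrane cascade.

    Each particle lands in the well of the first membrane (top-down) with
    diameter >= pore size, otherwise in the eluate.  ``misroute_prob``
    (default 0) optionally sends a particle one level deeper with that
    probability per membrane, for leakage sensitivity studies.
    """
    chip = chip or ChipConfig()
    diameters = np.asarray(diameters, dtype=float)
    if diameters.ndim != 1:
        raise EvspecError("diameters must be a 1-D sequence")
    if np.any(diameters <= 0):
        raise EvspecError("all diameters must be positive")
    if labels is None:
        labels = [""] * diameters.size
    if len(labels) != diameters.size:
        raise EvspecError("labels length must match diameters")

    rng = np.random.default_rng(seed)
    wells: dict[float, list[tuple[float, str]]] = {p: [] for p in chip.pore_sizes}
    eluate: list[tuple[float, str]] = []
    for d, lab in zip(diameters, labels):
        placed = False
        for pore in chip.pore_sizes:
            if d >= pore:
                if misroute_prob > 0 and rng.random() < misroute_prob:
                    continue  # leaks through this membrane
                wells[pore].append((float(d), lab))
                placed = True
                break
        if not placed:
            eluate.append((float(d), lab))
    return WellContents(wells, eluate)


def separation_efficiency(contents: WellContents, expected_map: dict[str, float]) -> EfficiencyReport:
    """Score routing against each source label's expected well.

    ``expected_map`` maps source label -> expected pore size (0 for eluate).
    routing_accuracy is the global fraction of particles found in their
    expected well; well_purity is the mean, over occupied wells, of the
    fraction of each well's content whose expected well is that well.
    """
    all_bins: list[tuple[float, list[tuple[float, str]]]] = list(contents.wells.items())
    all_bins.append((0.0, contents.eluate))

    n_total = 0
    n_correct = 0
    purities = []
    for pore, particles in all_bins:
        for _, lab in particles:
            if lab not in expected_map:
                raise EvspecError(f"label {lab!r} missing from expected_map")
        n_total += len(particles)
        hits = sum(1 for _, lab in particles if expected_map[lab] == pore)
        n_correct += hits
        if particles:
            purities.append(hits / len(particles))
    if n_total == 0:
        raise EvspecError("no particles to score")
    return EfficiencyReport(
        well_purity=float(np.mean(purities)),
        routing_accuracy=n_correct / n_total,
        per_well_counts=contents.counts(),
    )


def well_size_summary(contents: WellContents) -> dict[float, dict[str, float | int | bool]]:
    """Arithmetic mean/SD/count per well (eluate keyed as 0.0).

    Empty wells are reported with count 0 and ``undefined_moments`` True.
    """
    out: dict[float, dict[str, float | int | bool]] = {}
    bins: list[tuple[float, list[tuple[float, str]]]] = list(contents.wells.items())
    bins.append((0.0, contents.eluate))
    for pore, particles in bins:
        d = np.array([p for p, _ in particles], dtype=float)
        if d.size == 0:
            out[pore] = {"count": 0, "mean": float("nan"), "sd": float("nan"),
                         "undefined_moments": True}
        else:
            sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
            out[pore] = {"count": int(d.size), "mean": float(np.mean(d)), "sd": sd,
                         "undefined_moments": False}
    return out
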