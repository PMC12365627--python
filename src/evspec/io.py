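"""File formats: CSV spectrum matrices, manifests, diameters, YAML config.

The spectrum matrix dialect stores the wavenumber axis once as the header
row; each subsequent row is one spectrum.  Labels travel in a sidecar
manifest CSV (sample_id, fraction, state).  A directory of two-column
wavenumber/intensity text files plus a manifest is accepted as an
equivalent input form.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EvspecError, LabeledDataset, RamanSpectrum, WavenumberAxis


def write_spectra(dataset: LabeledDataset, matrix_path, manifest_path=None) -> None:
    """Write the CSV matrix (header = wavenumbers) and optional manifest."""
    wn = dataset.axis.values
    df = pd.DataFrame(dataset.X, columns=[f"{v:g}" for v in wn])
    df.to_csv(matrix_path, index=False)
    if manifest_path is not None:
        man = pd.DataFrame(
            [(s.sample_id, s.fraction, s.state) for s in dataset.spectra],
            columns=["sample_id", "fraction", "state"],
        )
        man.to_csv(manifest_path, index=False)


def read_spectra(matrix_path, manifest_path=None, label_by: str = "label") -> LabeledDataset:
    """Read a spectrum-matrix CSV (row 0 = wavenumbers) plus manifest."""
    path = Path(matrix_path)
    if path.is_dir():
        return _read_spectra_dir(path, manifest_path, label_by)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise EvspecError(f"malformed spectrum matrix {path}: {exc}") from exc
    try:
        wn = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise EvspecError(f"{path}: header row must be numeric wavenumbers") from exc
    axis = WavenumberAxis.from_values(wn)
    X = df.to_numpy(dtype=float)
    for i in range(X.shape[0]):
        if not np.all(np.isfinite(X[i])):
            raise EvspecError(f"{path}: row {i} contains missing or non-finite values")

    meta = _read_manifest(manifest_path, X.shape[0]) if manifest_path else None
    spectra = []
    for i in range(X.shape[0]):
        frac, state, sid = meta[i] if meta else ("", "", f"s{i:04d}")
        spectra.append(RamanSpectrum(axis, X[i], fraction=frac, state=state, sample_id=sid))
    return LabeledDataset(spectra, label_by=label_by)


def _read_manifest(manifest_path, n: int) -> list[tuple[str, str, str]]:
    man = pd.read_csv(manifest_path).fillna("")
    for col in ("sample_id", "fraction", "state"):
        if col not in man.columns:
            raise EvspecError(f"manifest missing column {col!r}")
    if len(man) != n:
        raise EvspecError(f"manifest has {len(man)} rows but matrix has {n} spectra")
    return [(str(r.fraction), str(r.state), str(r.sample_id)) for r in man.itertuples()]


def _read_spectra_dir(path: Path, manifest_path, label_by: str) -> LabeledDataset:
    """Directory of two-column (wavenumber, intensity) text files + manifest."""
    if manifest_path is None:
        manifest_path = path / "manifest.csv"
    man = pd.read_csv(manifest_path).fillna("")
    spectra = []
    axis = None
    for r in man.itertuples():
        arr = np.loadtxt(path / f"{r.sample_id}.txt")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise EvspecError(f"{r.sample_id}: expected two-column wavenumber/intensity text")
        a = WavenumberAxis.from_values(arr[:, 0])
        axis = axis or a
        spectra.append(RamanSpectrum(a, arr[:, 1], fraction=str(r.fraction),
                                     state=str(r.state), sample_id=str(r.sample_id)))
    if not spectra:
        raise EvspecError("empty manifest")
    return LabeledDataset(spectra, label_by=label_by)


def write_diameters(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_diameters(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("label", "diameter_nm"):
        if col not in df.columns:
            raise EvspecError(f"diameters CSV missing column {col!r}")
    return df


# --- run configuration -------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "out_dir": "evspec_out",
    "generator": {
        "n_per_class": 100,
        "fractions": ["raw", "large", "mid", "small"],
        "states": ["healthy", "cvd"],
        "noise": {
            "additive_sd": 0.02,
            "scatter_sigma": 0.10,
            "baseline_coeffs_sd": [0.1, 1e-4, 1e-7],
            "cosmic_rate": 0.2,
            "cosmic_amp_range": [5.0, 20.0],
        },
    },
    "chip": {"pore_sizes": [5000, 500, 200, 100, 40], "beads_per_size": 1000},
    "preprocess": {
        "despike_window": 7,
        "despike_z": 8.0,
        "baseline_order": 5,
        "baseline_iters": 30,
        "replicate_group": 1,
    },
    "som": {"rows": 10, "cols": 10, "epochs": 4, "eta0": 0.1},
    "barcode": {"window": 21, "polyorder": 2, "threshold": 0.40},
    "evaluation": {"bands": [752, 851, 960, 1003, 1144, 1341, 1440, 1553, 1656]},
}


def _check_keys(cfg: dict, ref: dict, prefix: str = "") -> None:
    for key, val in cfg.items():
        if key not in ref:
            raise EvspecError(f"unknown config key {prefix + str(key)!r}")
        if isinstance(val, dict) and isinstance(ref[key], dict):
            _check_keys(val, ref[key], prefix + f"{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load the YAML run config, validated against the known schema."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise EvspecError("config root must be a mapping")
    _check_keys(user, DEFAULT_CONFIG)
    return _merge(DEFAULT_CONFIG, user)


def config_hash(cfg: dict) -> str:
    """Stable hash of the effective configuration."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
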