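"""Reference study protocols at desk scale.

These functions reproduce, on synthetic data with the generator's default
effect structure, the headline experiments of the study design: 4-class EV
subgroup classification from healthy spectra, healthy-vs-CVD classification
per fraction with ROC analysis, and the ideal-cascade bead-panel separation
efficiency.  Problem sizes (200 spectra per class for the subgroup
experiment, 100 + 100 per disease comparison, 1000 beads per nominal size)
keep every experiment within seconds on one CPU while leaving enough
held-out samples (40 per run) for stable accuracy estimates.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, filtration, preprocessing, som, synthetic
from .core import LabeledDataset

N_PER_FRACTION = 200  # healthy spectra per fraction, 4-class experiment
N_PER_STATE = 100  # spectra per state, disease experiments
BEADS_PER_SIZE = 1000


def fraction_classification(seed: int = 42, n_per_fraction: int = N_PER_FRACTION) -> dict:
    """4-class (raw / large / mid / small) hold-out accuracy of the SOM."""
    design = {(f, "healthy"): n_per_fraction for f in synthetic.FRACTIONS}
    ds = synthetic.generate_dataset(design, seed=seed, label_by="fraction")
    clean = preprocessing.preprocess_dataset(ds)
    res = som.train_test_evaluate(clean, som.SOMParams(seed=seed), som.SplitSpec(seed=seed))
    return {"accuracy": res["accuracy"], "n_test": len(res["test_idx"]), "result": res}


def disease_classification(fraction: str, seed: int = 42, n_per_state: int = N_PER_STATE) -> dict:
    """Healthy-vs-CVD hold-out accuracy and ROC AUC for one EV fraction."""
    ds = synthetic.generate_dataset(
        {(fraction, "healthy"): n_per_state, (fraction, "cvd"): n_per_state},
        seed=seed,
        label_by="state",
    )
    clean = preprocessing.preprocess_dataset(ds)
    res = som.train_test_evaluate(clean, som.SOMParams(seed=seed), som.SplitSpec(seed=seed))
    cvd_col = res["model"].class_names.index("cvd")
    roc = evaluation.roc_curve(res["test_scores"][:, cvd_col], res["test_labels"],
                               positive="cvd")
    return {
        "accuracy": res["accuracy"],
        "auc": roc.auc,
        "auc_ci95": roc.ci95,
        "n_test": len(res["test_idx"]),
        "result": res,
    }


def bead_panel_efficiency(seed: int = 42, beads_per_size: int = BEADS_PER_SIZE) -> dict:
    """Ideal-cascade separation efficiency of the seven-size bead panel."""
    beads = synthetic.generate_bead_panel(beads_per_size, seed=seed)
    contents = filtration.route_particles(
        beads["diameter_nm"].to_numpy(), labels=list(beads["label"])
    )
    expected = dict(beads.drop_duplicates("label")[["label", "expected_well"]].values)
    rep = filtration.separation_efficiency(contents, expected)
    return {
        "routing_accuracy": rep.routing_accuracy,
        "well_purity": rep.well_purity,
        "n": len(beads),
    }


def somdi_band_recovery(seed: int = 42, n_per_state: int = N_PER_STATE,
                        bands=(851, 960, 1003, 1657), top_n: int = 6,
                        tol: float = 8.0) -> dict:
    """Check that the headline CVD bands rank among the top SOMDI peaks."""
    res = disease_classification("small", seed=seed, n_per_state=n_per_state)
    sd = som.somdi(res["result"]["model"])
    top = [w for w, _ in sd.peaks["cvd"][:top_n]]
    recovered = {b: any(abs(w - b) <= tol for w in top) for b in bands}
    return {"top_peaks": top, "recovered": recovered,
            "all_recovered": all(recovered.values())}
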