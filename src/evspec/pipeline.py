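"""End-to-end pipeline: simulate -> filter -> preprocess -> classify -> report.

Mirrors the workflow of the integrated chip: particle populations are
routed through the membrane cascade, spectra of the collected fractions
are cleaned and normalized, the supervised SOM is trained and evaluated,
SOMDI discriminant spectra and class-mean barcodes are extracted, and
diagnostic metrics (accuracy, per-class confusion, ROC/AUC, band-level
rank tests) are written as a JSON report bundle with a config hash for
reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import evaluation, filtration, io, preprocessing, som, synthetic
from .barcoding import BarcodeConfig, barcode_overlay_table, spectrum_barcode
from .core import LabeledDataset

log = logging.getLogger("evspec")


def _stage(name: str, seed: int, t0: float, **info) -> None:
    log.info("stage=%s seed=%d elapsed=%.2fs %s", name, seed, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Run the full synthetic study described by ``cfg``; return the report."""
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": io.config_hash(cfg), "seed": seed}
    t0 = time.time()

    # -- particle simulation and cascade routing ------------------------
    gcfg, ccfg = cfg["generator"], cfg["chip"]
    chip = filtration.ChipConfig(tuple(float(p) for p in ccfg["pore_sizes"]))
    beads = synthetic.generate_bead_panel(int(ccfg["beads_per_size"]), seed=seed)
    contents = filtration.route_particles(
        beads["diameter_nm"].to_numpy(), chip, labels=list(beads["label"])
    )
    expected = dict(beads.drop_duplicates("label")[["label", "expected_well"]].values)
    eff = filtration.separation_efficiency(contents, expected)
    report["filtration"] = {
        "routing_accuracy": eff.routing_accuracy,
        "well_purity": eff.well_purity,
        "per_well_counts": {str(k): v for k, v in eff.per_well_counts.items()},
        "well_summary": {str(k): v for k, v in filtration.well_size_summary(contents).items()},
    }
    io.write_diameters(beads, out / "beads.csv")
    _stage("filter", seed, t0, beads=len(beads))

    # -- spectral simulation --------------------------------------------
    ncfg = gcfg["noise"]
    noise = synthetic.NoiseConfig(
        additive_sd=float(ncfg["additive_sd"]),
        scatter_sigma=float(ncfg["scatter_sigma"]),
        baseline_coeffs_sd=tuple(float(v) for v in ncfg["baseline_coeffs_sd"]),
        cosmic_rate=float(ncfg["cosmic_rate"]),
        cosmic_amp_range=tuple(float(v) for v in ncfg["cosmic_amp_range"]),
    )
    n = int(gcfg["n_per_class"])
    design = {
        (f, s): n for f in gcfg["fractions"] for s in gcfg["states"]
    }
    dataset = synthetic.generate_dataset(design, noise, seed=seed)
    io.write_spectra(dataset, out / "raw_spectra.csv", out / "manifest.csv")
    _stage("simulate", seed, t0, spectra=len(dataset))

    # -- preprocessing ---------------------------------------------------
    pcfg = cfg["preprocess"]
    prep = preprocessing.PreprocessConfig(
        despike_window=int(pcfg["despike_window"]),
        despike_z=float(pcfg["despike_z"]),
        baseline_order=int(pcfg["baseline_order"]),
        baseline_iters=int(pcfg["baseline_iters"]),
        replicate_group=int(pcfg["replicate_group"]),
    )
    clean = preprocessing.preprocess_dataset(dataset, prep)
    io.write_spectra(clean, out / "clean_spectra.csv")
    _stage("preprocess", seed, t0)

    # -- SKiNET training and evaluation ---------------------------------
    scfg = cfg["som"]
    params = som.SOMParams(rows=int(scfg["rows"]), cols=int(scfg["cols"]),
                           epochs=int(scfg["epochs"]), eta0=float(scfg["eta0"]),
                           seed=seed)
    split = som.SplitSpec(seed=seed)

    # 4-class EV-subgroup model on healthy spectra
    healthy = LabeledDataset(
        [s for s in clean.spectra if s.state == "healthy"], label_by="fraction"
    )
    frac_eval = som.train_test_evaluate(healthy, params, split)
    report["fraction_classification"] = {
        "accuracy": frac_eval["accuracy"],
        "confusion": frac_eval["confusion"],
    }
    frac_eval["model"].to_json(out / "som_fractions.json")
    _stage("train-fractions", seed, t0, accuracy=f"{frac_eval['accuracy']:.3f}")

    # healthy-vs-CVD model per fraction, with ROC
    report["disease_classification"] = {}
    for fraction in gcfg["fractions"]:
        sub = LabeledDataset(
            [s for s in clean.spectra if s.fraction == fraction],
            class_names=["healthy", "cvd"], label_by="state",
        )
        res = som.train_test_evaluate(sub, params, split)
        cvd_col = res["model"].class_names.index("cvd")
        roc = evaluation.roc_curve(res["test_scores"][:, cvd_col],
                                   res["test_labels"], positive="cvd")
        report["disease_classification"][fraction] = {
            "accuracy": res["accuracy"],
            "confusion": res["confusion"],
            "metrics_cvd": evaluation.confusion_metrics(
                evaluation.ConfusionMatrix(**res["confusion"]["cvd"])
            ),
            "auc": roc.auc,
            "auc_ci95": list(roc.ci95),
        }
        _stage("train-disease", seed, t0, fraction=fraction,
               accuracy=f"{res['accuracy']:.3f}", auc=f"{roc.auc:.3f}")

    # -- SOMDI and barcodes ---------------------------------------------
    small = LabeledDataset(
        [s for s in clean.spectra if s.fraction == "small"],
        class_names=["healthy", "cvd"], label_by="state",
    )
    small_eval = som.train_test_evaluate(small, params, split)
    sd = som.somdi(small_eval["model"])
    report["somdi_cvd_peaks"] = sd.peaks.get("cvd", [])

    bcfg = cfg["barcode"]
    bconf = BarcodeConfig(window=int(bcfg["window"]), polyorder=int(bcfg["polyorder"]),
                          threshold=float(bcfg["threshold"]))
    report["barcodes"] = {}
    for fraction in gcfg["fractions"]:
        rows = [s.intensities for s in clean.spectra
                if s.fraction == fraction and s.state == "healthy"]
        mean_spec = np.mean(rows, axis=0)
        bc = spectrum_barcode(mean_spec, clean.axis, bconf, source_id=fraction)
        table = barcode_overlay_table(bc, synthetic.build_peak_table(fraction, "healthy"))
        report["barcodes"][fraction] = {
            "hex": bc.to_hex(),
            "bands": {str(r["center"]): r["bit"] for r in table},
        }
    _stage("somdi-barcode", seed, t0)

    # -- band-level statistics ------------------------------------------
    bands = cfg["evaluation"]["bands"]
    band_rows = evaluation.band_intensity_report(small, bands)
    report["band_report_small"] = [
        {k: (asdict(v) if isinstance(v, evaluation.BoxStats) else v) for k, v in r.items()}
        for r in band_rows
    ]
    _stage("evaluate", seed, t0)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    manifest = {
        "config_hash": report["config_hash"],
        "seed": seed,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
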