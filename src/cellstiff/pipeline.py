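"""End-to-end orchestration: generate -> preprocess -> split -> train ->
evaluate -> calibrate -> predict -> explain, from one config.

Every stochastic stage derives its seed from the run seed, so a run
directory is fully reproducible from config + seed alone; a checksum
manifest of all outputs is written per run.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, gradcam, stiffness
from .models import ClassifierSpec, build_classifier, train_model
from .preprocessing import images_to_tensor, split_dataset
from .synthetic import (PhantomParams, generate_phantom_dataset,
                        generate_phantom_spectrum)


@dataclass
class RunConfig:
    seed: int = 0
    n_soft: int = 1000
    n_stiff: int = 1000
    n_wt: int = 400  # intermediate-stiffness phantoms for calibration
    s_soft: tuple = (0.0, 0.2)
    s_stiff: tuple = (0.8, 1.0)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    split_ratios: tuple = (0.6, 0.2, 0.2)
    epochs: int = 6
    batch_size: int = 32
    calibration_fraction: float = 0.5  # share of wt cells used to calibrate
    n_heatmaps: int = 6
    out_dir: str = "runs/run0"

    def validate(self) -> None:
        if self.n_soft + self.n_stiff < 10:
            raise ValueError("dataset too small to split and train")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if min(self.split_ratios) <= 0 or \
                abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must be positive and sum to 1")
        if self.epochs < 1:
            raise ValueError("need at least one epoch")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=str))


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the run report dict.

    Writes to the run directory: config.json, metrics.json,
    calibration.json, predictions.csv, training_record.csv, Grad-CAM
    heatmap PNGs, and checksums.txt. Partial outputs are retained on
    stage failure.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(0, 2 ** 31 - 1))
             for k in ("data", "wt", "split", "model", "train")}
    report: dict = {"seed": config.seed}
    t_start = time.time()

    stage = "generate"
    try:
        images = generate_phantom_dataset(
            config.n_soft, config.n_stiff, config.s_soft, config.s_stiff,
            seed=seeds["data"], params=config.phantom)
        wt_images = generate_phantom_spectrum(
            config.n_wt, seed=seeds["wt"], params=config.phantom)

        stage = "preprocess"
        x = images_to_tensor(images)
        y = np.array([1 if im.label == "stiff" else 0 for im in images])
        x_wt = images_to_tensor(wt_images)
        e_wt = np.array([im.modulus_pa for im in wt_images])

        stage = "split"
        split = split_dataset(list(range(len(images))),
                              ratios=config.split_ratios, labels=y,
                              seed=seeds["split"])
        tr, va, te = (np.array(s, dtype=int) for s in split)

        stage = "train"
        model = build_classifier(ClassifierSpec(seed=seeds["model"]))
        model, record = train_model(
            model, x[tr], y[tr], x[va], y[va], epochs=config.epochs,
            batch_size=config.batch_size, seed=seeds["train"])
        _write_record(record, out / "training_record.csv")

        stage = "evaluate"
        p_test = model.predict_proba(x[te])[:, 1]
        metrics = evaluation.classification_metrics(y[te], p_test)
        (out / "metrics.json").write_text(
            json.dumps(metrics.to_dict(), indent=2))
        report["metrics"] = metrics.to_dict()

        stage = "calibrate"
        p_wt = stiffness.stiffness_range(model.predict_proba(x_wt))
        n_cal = int(round(config.calibration_fraction * len(wt_images)))
        cal = stiffness.fit_one_phase_decay(e_wt[:n_cal], p_wt[:n_cal])
        cal.to_json(out / "calibration.json")
        report["calibration"] = asdict(cal)

        stage = "predict"
        pred = stiffness.range_to_modulus(p_wt[n_cal:], cal)
        apes = stiffness.absolute_percentage_error(e_wt[n_cal:], pred)
        with open(out / "predictions.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "p", "pred_pa", "true_pa", "ape_percent"])
            for k in range(len(pred)):
                w.writerow([wt_images[n_cal + k].source_id,
                            f"{p_wt[n_cal + k]:.6f}", f"{pred[k]:.2f}",
                            f"{e_wt[n_cal + k]:.2f}", f"{apes[k]:.2f}"])
        from scipy.stats import spearmanr
        report["mean_ape_percent"] = float(np.mean(apes))
        report["spearman_p_vs_E"] = float(
            spearmanr(p_wt, e_wt).statistic)

        stage = "explain"
        import imageio.v3 as iio
        for k in range(min(config.n_heatmaps, len(te))):
            sal = gradcam.gradcam_classification(model, x[te[k]])
            rendered = gradcam.overlay_heatmap(
                sal, (255 * (x[te[k], :, :, 0] / 2 + 0.5)).astype(np.uint8))
            iio.imwrite(out / f"gradcam_{k}_{images[te[k]].label}.png",
                        rendered)
    except Exception as err:  # annotate with the failing stage
        raise StageError(stage, err) from err

    report["runtime_s"] = time.time() - t_start
    _write_checksums(out)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _write_record(record, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "val_loss", "train_accuracy",
                    "val_accuracy"])
        for i in range(record.epochs):
            w.writerow([i + 1, record.train_loss[i],
                        record.val_loss[i] if record.val_loss else "",
                        record.train_accuracy[i],
                        record.val_accuracy[i] if record.val_accuracy else ""])


def _write_checksums(out: Path) -> None:
    lines = []
    for f in sorted(out.iterdir()):
        if f.name == "checksums.txt" or f.is_dir():
            continue
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        lines.append(f"{digest}  {f.name}")
    (out / "checksums.txt").write_text("\n".join(lines) + "\n")
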