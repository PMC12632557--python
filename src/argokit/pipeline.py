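"""End-to-end workflow stages: simulate -> quantify -> turnover analysis.

Each stage is a plain function over files and frames; the command-line
interface in :mod:`argokit.cli` is a thin wrapper. Every run emits a config
snapshot and a manifest so a result can be reproduced from its output
directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import quant, turnover
from .config import config_to_dict, save_config
from .decay import extra_ss_f_test, fit_one_phase, fit_two_phase, rout_outliers
from .discrimination import predict_model1, predict_model2
from .stack import ImageStack
from .synthetic import (
    SyntheticConfig,
    normalized_background,
    render_image_stack,
    simulate_ratio_cohort,
    simulate_truth_puncta,
)

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_quantify", "run_turnover"]

#: Per-neuron-class defaults mirroring the study's per-dataset choices.
CLASS_DEFAULTS = {
    "DA9": {"min_area_um2": 0.1, "rout_q": 0.05},
    "NSM": {"min_area_um2": 0.1, "rout_q": 0.01},
    "VD": {"min_area_um2": 0.2, "rout_q": 0.03},
    "DD": {"min_area_um2": 0.2, "rout_q": 0.03},
}


def run_simulate(
    config: SyntheticConfig,
    out_dir: str | Path,
    seed: int | None = None,
    render: bool = True,
    render_shape: tuple[int, int, int] = (10, 32, 448),
) -> dict:
    """Generate a cohort table (CSV) and optionally rendered stacks.

    The punctum table is produced by the analytic ratio model; stacks are
    rendered per animal from per-animal truth draws of the same generative
    model, each with a ground-truth JSON sidecar. Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    table = simulate_ratio_cohort(config, seed=seed)
    csv_path = out_dir / "cohort.csv"
    table.to_csv(csv_path, index=False, float_format="%.8g")
    manifest = {
        "seed": seed,
        "cohort_csv": csv_path.name,
        "n_records": int(table["animal_id"].nunique()),
        "stacks": [],
        "complete": False,
    }
    save_config(config, out_dir / "config_snapshot.yaml")
    if render:
        rng = np.random.default_rng(seed + 1)
        des, pre = config.design, config.preset
        # keep puncta inside the field of view
        fov_x = (render_shape[2] - 1) * config.pixel_size_um
        pre_r = pre if pre.axon_length_um <= fov_x else _shrunk(pre, fov_x * 0.95)
        treatments = ["pulsed"] + (["control"] if des.include_controls else [])
        idx = 0
        for age in des.chase_times:
            for treatment in treatments:
                for _ in range(des.n_animals_per_timepoint):
                    idx += 1
                    animal = f"{pre.neuron_class}_{treatment}_{age:g}_{idx:04d}"
                    pulse = None if treatment == "control" else des.pulse_age
                    puncta = simulate_truth_puncta(
                        pre_r,
                        age,
                        config.kinetics,
                        config.optics,
                        seed=rng,
                        pulse_age=pulse,
                        acidic_kappa=config.noise.acidic_kappa,
                    )
                    grel = 1.0 if pulse is None else pre.growth_rel(age, pulse)
                    stack = render_image_stack(
                        puncta,
                        config.optics,
                        config.noise,
                        config.pixel_size_um,
                        config.z_step_um,
                        render_shape,
                        rng=rng,
                        growth_rel=grel,
                    )
                    stack.metadata.update(
                        {
                            "animal_id": animal,
                            "neuron_class": pre.neuron_class,
                            "age_days": age,
                            "treatment": treatment,
                            "pulse_age": pulse,
                        }
                    )
                    path = out_dir / f"{animal}.ome.tif"
                    stack.save(path)
                    manifest["stacks"].append(path.name)
    manifest["complete"] = True
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _shrunk(preset, axon_length):
    from dataclasses import replace

    return replace(preset, axon_length_um=axon_length)


def run_quantify(
    image_paths: list[str | Path],
    out_csv: str | Path,
    min_area_um2: float | None = None,
    region_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify stacks into the shared punctum-table schema.

    Animal metadata is taken from each stack's sidecar when present,
    otherwise from the file stem. Invalid files are skipped and reported in
    the QC log; the run continues.
    """
    frames = []
    qc_log = []
    for path in image_paths:
        path = Path(path)
        try:
            stack = ImageStack.load(path)
        except Exception as exc:
            qc_log.append({"file": path.name, "error": str(exc)})
            logger.error("skipping %s: %s", path, exc)
            continue
        meta = stack.metadata
        neuron_class = meta.get("neuron_class", "DA9")
        area = (
            min_area_um2
            if min_area_um2 is not None
            else CLASS_DEFAULTS.get(neuron_class, CLASS_DEFAULTS["DA9"])["min_area_um2"]
        )
        try:
            puncta, qc = quant.quantify_stack(stack, area, region_bounds)
        except ValueError as exc:
            if "no threshold" not in str(exc):
                raise
            # featureless (constant) image: nothing to segment
            puncta, qc = [], {"threshold": None, "n_components": 0, "n_puncta": 0}
        qc["file"] = path.name
        if not puncta:
            qc["note"] = "no puncta"
        qc_log.append(qc)
        frames.append(
            quant.measurements_to_frame(
                puncta,
                animal_id=meta.get("animal_id", path.stem.replace(".ome", "")),
                neuron_class=neuron_class,
                age_days=meta.get("age_days", float("nan")),
                treatment=meta.get("treatment", "control"),
                pulse_age=meta.get("pulse_age"),
            )
        )
    frames = [f for f in frames if len(f)]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["animal_id", "ratio"])
    )
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_csv, index=False, float_format="%.8g")
    return table, qc_log


def run_turnover(
    cohort: pd.DataFrame | str | Path,
    plateau: float | str = "auto",
    rout_q: float | None = None,
    fit_two: bool = True,
    predictions: dict | None = None,
    out_json: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> dict:
    """Normalize, fit decay models, compare them, and report.

    ``plateau``: a number fixes the plateau on the normalized scale;
    ``"auto"`` derives it from the cohort's recorded background metadata if
    present, else leaves the plateau free. ``rout_q``: outlier rate; None
    uses the neuron-class default. Positional-bin half-lives are reported
    when positions are available.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    required = {"animal_id", "age_days", "treatment", "ratio", "neuron_class"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if not (cohort["treatment"] == "pulsed").any():
        raise ValueError("nothing to fit: cohort has no pulsed records")
    neurons = turnover.summarize_neurons(cohort)
    neurons = turnover.normalize_to_control(neurons)
    pulsed = neurons[neurons["treatment"] == "pulsed"]
    pulse_age = float(pulsed["pulse_age"].dropna().iloc[0])
    t = (pulsed["age_days"] - pulse_age).to_numpy(dtype=float)
    y = pulsed["normalized_ratio"].to_numpy(dtype=float)
    b = None if plateau == "auto" else float(plateau)
    neuron_class = str(cohort["neuron_class"].iloc[0])
    q = rout_q if rout_q is not None else CLASS_DEFAULTS.get(
        neuron_class, CLASS_DEFAULTS["DA9"]
    )["rout_q"]
    mask, fit1 = rout_outliers(t, y, "one_phase", Q=q, plateau=b)
    report = {
        "neuron_class": neuron_class,
        "pulse_age": pulse_age,
        "n_animals": int(len(pulsed)),
        "plateau": b,
        "one_phase": fit1.report(),
    }
    if fit_two and t.size >= (6 if b is None else 5):
        fit2 = fit_two_phase(t[mask], y[mask], b)
        F, p = extra_ss_f_test(fit1, fit2)
        report["two_phase"] = fit2.report()
        report["extra_ss_f_test"] = {"F": F, "p": p, "favors_two_phase": p < 0.05}
    if "position_norm" in cohort.columns:
        report["half_life_by_position"] = _positional_half_lives(cohort, neurons, b)
    if predictions:
        chase = sorted(pulsed["age_days"].unique().tolist())
        if "two_phase" in report:
            report["model1_prediction"] = predict_model1(
                fit2, pulse_age, chase
            ).report()
        if "shutoff_age" in (predictions or {}):
            report["model2_prediction"] = predict_model2(
                predictions.get("k", fit1.params["k"]),
                predictions["shutoff_age"],
                pulse_age,
                chase,
                plateau=b or 0.0,
            ).report()
    if plot_path is not None:
        _plot_decay(t, y, mask, fit1, plot_path)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=1, default=_jsonify))
    return report


def _positional_half_lives(cohort, neurons, plateau):
    """One-phase half-life per proximal/middle/distal positional bin."""
    labels, _ = turnover.bin_by_position(cohort)
    out = {}
    ctrl_mean = neurons[neurons["treatment"] == "control"].groupby("age_days")[
        "mean_ratio"
    ].mean()
    for bin_name in ("proximal", "middle", "distal"):
        sub = cohort[(labels == bin_name) & (cohort["treatment"] == "pulsed")]
        if sub.empty:
            continue
        per_animal = sub.groupby(["animal_id", "age_days", "pulse_age"])["ratio"].mean().reset_index()
        norm = per_animal["ratio"] / per_animal["age_days"].map(ctrl_mean)
        tt = (per_animal["age_days"] - per_animal["pulse_age"]).to_numpy(dtype=float)
        if len(per_animal) < 4 or np.ptp(tt) == 0:
            continue
        fit = fit_one_phase(tt, norm.to_numpy(dtype=float), plateau)
        h = fit.half_lives["half_life"]
        out[bin_name] = {"half_life": h.value, "ci95": list(h.ci95), "n": len(per_animal)}
    return out


def _plot_decay(t, y, mask, fit, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t[mask], y[mask], "o", ms=4, color="tab:blue", label="animals")
    if not mask.all():
        ax.plot(t[~mask], y[~mask], "o", ms=4, color="black", label="outliers")
    tt = np.linspace(0, max(t.max(), 1e-6), 100)
    ax.plot(tt, fit.predict(tt), "-", color="tab:red", label="one-phase fit")
    ax.axhline(fit.plateau_value, ls="--", color="gray", lw=1, label="background")
    ax.set_xlabel("days after pulse")
    ax.set_ylabel("normalized GFP/RFP")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
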