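"""Discriminating two-pool identity from age-dependent turnover shutoff.

Biphasic loss of old protein from a synapse admits two explanations:

* **Model 1 (pool identity)** — each punctum holds two chronically distinct
  pools, one turning over fast and one essentially inert. The predicted
  normalized ratio depends only on the chase duration, never on the age at
  which the pulse was given.
* **Model 2 (shutoff)** — all protein initially turns over at one rate, but
  the turnover machinery stops working at a fixed age. Pulses given after
  the shutoff age predict no decay at all, and the final plateau depends on
  how much chase time elapsed before the shutoff.

The two models therefore separate cleanly in a pulse-at-different-ages
design: evaluate both predictions at a common imaging age and compare with
the measured groups. Median-based censoring removes animals whose
recombination failed (pulsed animals retaining a control-like high ratio)
or recombined spontaneously (controls with a pulsed-like low ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decay import DecayFit

__all__ = [
    "ModelPrediction",
    "predict_model1",
    "predict_model2",
    "model2_shutoff_time",
    "censor_a7_groups",
]


@dataclass
class ModelPrediction:
    """Per-timepoint normalized-ratio predictions from one kinetic model."""

    model: str  # "pool_identity" | "shutoff"
    pulse_age: float
    chase_times: tuple[float, ...]
    predicted: tuple[float, ...]
    parameters: dict

    def report(self) -> dict:
        return {
            "model": self.model,
            "pulse_age": self.pulse_age,
            "chase_times": list(self.chase_times),
            "predicted": list(self.predicted),
            "parameters": self.parameters,
        }


def _check_chase(pulse_age: float, chase_times: Sequence[float]) -> None:
    bad = [c for c in chase_times if c < pulse_age]
    if bad:
        raise ValueError(f"chase times {bad} precede the pulse at {pulse_age}")


def predict_model1(
    two_phase_fit: DecayFit | dict,
    pulse_age: float,
    chase_times: Sequence[float],
) -> ModelPrediction:
    """Model 1 prediction from two-phase best-fit parameters.

    r(dt) = plateau + (1 - plateau)[f e^(-k_fast dt) + (1-f) e^(-k_slow dt)]
    with dt = chase - pulse_age. By construction the prediction at a given
    dt is identical for any pulse age — the model's defining property.
    """
    _check_chase(pulse_age, chase_times)
    if isinstance(two_phase_fit, DecayFit):
        if two_phase_fit.model != "two_phase":
            raise ValueError("predict_model1 needs a two-phase fit")
        p = dict(two_phase_fit.params)
        p["plateau"] = two_phase_fit.plateau_value
    else:
        p = dict(two_phase_fit)
    b, f, kf, ks = p["plateau"], p["f_fast"], p["k_fast"], p["k_slow"]
    preds = []
    for c in chase_times:
        dt = c - pulse_age
        preds.append(b + (1.0 - b) * (f * math.exp(-kf * dt) + (1 - f) * math.exp(-ks * dt)))
    return ModelPrediction(
        model="pool_identity",
        pulse_age=pulse_age,
        chase_times=tuple(chase_times),
        predicted=tuple(preds),
        parameters={"plateau": b, "f_fast": f, "k_fast": kf, "k_slow": ks},
    )


def model2_shutoff_time(k: float, f_remaining: float) -> float:
    """Chase time at which a one-phase decay leaves ``f_remaining`` of the pool.

    dt = -ln(f_remaining) / k. Under the shutoff model this is the delay
    between the pulse and the shutoff event implied by an observed terminal
    plateau of ``f_remaining``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not 0.0 < f_remaining <= 1.0:
        raise ValueError("f_remaining must lie in (0, 1]")
    return -math.log(f_remaining) / k


def predict_model2(
    k: float,
    shutoff_age: float,
    pulse_age: float,
    chase_times: Sequence[float],
    plateau: float = 0.0,
) -> ModelPrediction:
    """Model 2 prediction: one-phase decay frozen at ``shutoff_age``.

    Effective decay time per chase point is
    max(0, min(chase, shutoff_age) - pulse_age); the curve is flat after the
    shutoff, and a pulse given at or after the shutoff age predicts no
    turnover at all (r = 1 throughout).
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    _check_chase(pulse_age, chase_times)
    preds = []
    for c in chase_times:
        t_eff = max(0.0, min(c, shutoff_age) - pulse_age)
        preds.append(plateau + (1.0 - plateau) * math.exp(-k * t_eff))
    return ModelPrediction(
        model="shutoff",
        pulse_age=pulse_age,
        chase_times=tuple(chase_times),
        predicted=tuple(preds),
        parameters={"k": k, "shutoff_age": shutoff_age, "plateau": plateau},
    )


def censor_a7_groups(
    groups: dict[str, Sequence[float]],
    control_key: str = "control",
    reference_pulsed_key: str = "pulse_A4",
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Median-based censoring of per-animal mean ratios at the final age.

    Control animals with ratios strictly below the median of the
    late-pulse reference group (``reference_pulsed_key``) are removed as
    probable spontaneous recombination; animals of every pulsed group with
    ratios strictly above the control median are removed as probable
    recombination failures. Values exactly equal to the reference median
    are retained. Returns (censored groups, removal counts per group).
    """
    if control_key not in groups:
        raise ValueError(f"missing reference group {control_key!r}")
    if reference_pulsed_key not in groups:
        raise ValueError(f"missing reference group {reference_pulsed_key!r}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    ref_pulse_median = float(np.median(arrays[reference_pulsed_key]))
    control_median = float(np.median(arrays[control_key]))
    out: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for k, v in arrays.items():
        if k == control_key:
            keep = v >= ref_pulse_median
        else:
            keep = v <= control_median
        out[k] = v[keep]
        counts[k] = int(v.size - keep.sum())
    return out, counts
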