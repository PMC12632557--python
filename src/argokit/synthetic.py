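"""Synthetic pulse-chase cohorts with known ground-truth turnover kinetics.

A genetically encoded pulse-chase tags a protein of interest with a tandem
RFP::GFP pair; an inducible recombination pulse removes the GFP coding
sequence, so protein made after the pulse carries RFP only. The per-punctum
GFP/RFP ratio then reads out the fraction of protein that predates the pulse
("old" protein). This module generates punctum-level cohort tables and
renderable two-channel z-stacks from an explicit generative model, so the
whole downstream pipeline (segmentation, summaries, decay fits, model
discrimination) can be validated against known truth.

Generative model for one punctum imaged at age ``T`` after a pulse at age
``T0`` (chase time ``dt = T - T0``):

* old-protein fraction ``O(dt)`` follows the configured kinetics
  (one-phase exponential, two-pool two-phase, or age-dependent shutoff);
* a fraction ``a`` of punctum protein sits in acidic compartments where GFP
  retains only ``q`` of its brightness (pH quenching), so the effective
  GFP yield per old molecule is ``gamma * (1 - a * (1 - q))`` with ``gamma``
  the GFP:RFP brightness ratio per molecule;
* observed ratio ``r = gamma * O_app * (1 - a(1-q)) + af_ratio`` where
  ``af_ratio`` is the autofluorescence background on the ratio scale and
  ``O_app = O / g_rel`` folds in synapse growth between pulse and imaging
  (new protein dilutes the old pool); controls have ``O = 1``;
* lognormal multiplicative scatter applies per animal and per punctum.

Ages follow the convention A0 = final larval stage / day 0 of adulthood;
ages are float days of adulthood (larval stages map to negative offsets,
see :data:`LARVAL_AGES`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "KineticsModel",
    "OpticsModel",
    "NeuronPreset",
    "CohortDesign",
    "NoiseModel",
    "SyntheticConfig",
    "TruthPunctum",
    "simulate_ratio_cohort",
    "simulate_truth_puncta",
    "render_image_stack",
    "default_config",
    "LARVAL_AGES",
    "COHORT_COLUMNS",
]

#: Larval stages encoded as negative days of adulthood (A0 = L4 = 0.0).
LARVAL_AGES = {"L2": -1.5, "L3": -1.0, "L4": 0.0}

#: Schema of the punctum-level cohort table shared with the quantification
#: pipeline (quantified images produce the observable subset of columns).
COHORT_COLUMNS = [
    "animal_id",
    "neuron_class",
    "age_days",
    "treatment",
    "pulse_age",
    "punctum_index",
    "area_um2",
    "position_norm",
    "mean_rfp",
    "mean_gfp",
    "ratio",
    "true_old_fraction",
    "apparent_old_fraction",
    "true_acidic_fraction",
]


def _cv_to_sigma(cv: float) -> float:
    """Lognormal shape parameter giving coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factors with mean exactly 1."""
    if cv <= 0:
        return np.ones(size)
    s = _cv_to_sigma(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


class PiecewiseLinear:
    """Monotone-in-x piecewise-linear function of age, clamped outside knots."""

    def __init__(self, knots: dict[float, float]):
        if not knots:
            raise ValueError("need at least one knot")
        items = sorted(knots.items())
        self.x = np.array([k for k, _ in items], dtype=float)
        self.y = np.array([v for _, v in items], dtype=float)

    def __call__(self, age: float) -> float:
        return float(np.interp(age, self.x, self.y))

    def to_dict(self) -> dict[float, float]:
        return {float(a): float(b) for a, b in zip(self.x, self.y)}


@dataclass
class KineticsModel:
    """Ground-truth turnover kinetics of the old-protein pool.

    model_kind
        ``one_phase``: O(dt) = exp(-k dt).
        ``two_phase``: O(dt) = f_fast exp(-k_fast dt) + (1-f_fast) exp(-k_slow dt)
        (two chronically distinct pools).
        ``shutoff``: one-phase decay at rate ``k`` that stops at
        ``shutoff_age`` (age-dependent loss of turnover capacity).
    Rates are per day; ``shutoff_age`` is in days of adulthood.
    """

    model_kind: Literal["one_phase", "two_phase", "shutoff"] = "one_phase"
    k: float = 0.231
    f_fast: float = 0.39
    k_fast: float = 0.7535
    k_slow: float = 0.0
    shutoff_age: float = math.inf

    def __post_init__(self) -> None:
        if self.k < 0 or self.k_fast < 0 or self.k_slow < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.f_fast <= 1.0:
            raise ValueError("f_fast must lie in [0, 1]")
        if self.model_kind == "two_phase" and self.k_fast < self.k_slow:
            raise ValueError("two_phase requires k_fast >= k_slow")

    def old_fraction(self, chase_age: float, pulse_age: float) -> float:
        """Fraction of pulse-labelled protein remaining at ``chase_age``."""
        dt = chase_age - pulse_age
        if dt < 0:
            raise ValueError(
                f"chase age {chase_age} precedes pulse age {pulse_age}"
            )
        if self.model_kind == "one_phase":
            return math.exp(-self.k * dt)
        if self.model_kind == "two_phase":
            return self.f_fast * math.exp(-self.k_fast * dt) + (
                1.0 - self.f_fast
            ) * math.exp(-self.k_slow * dt)
        # shutoff: decay only while chase_age < shutoff_age
        t_eff = max(0.0, min(chase_age, self.shutoff_age) - pulse_age)
        return math.exp(-self.k * t_eff)


@dataclass
class OpticsModel:
    """Brightness, pH-quenching, and background parameters.

    ``yield_ratio`` (gamma) is the GFP:RFP brightness per molecule (>1: GFP
    has the higher quantum yield). ``quench`` is the residual GFP brightness
    in acidic compartments. ``acidic_fraction`` maps age -> fraction of
    punctum protein in acidic compartments (the route to lysosomal
    degradation); it is a calibration curve, not a measured value.
    ``af_gfp``/``af_rfp`` are per-channel autofluorescence levels used when
    rendering images; ``af_ratio`` is the equivalent additive background on
    the GFP/RFP ratio scale used by the table-level simulator.
    """

    yield_ratio: float = 2.6
    quench: float = 0.2
    acidic_fraction: PiecewiseLinear = field(
        default_factory=lambda: PiecewiseLinear({0.0: 0.05, 2.0: 0.35})
    )
    af_gfp: float = 30.0
    af_rfp: float = 12.0
    af_ratio: float = 0.15

    def __post_init__(self) -> None:
        if self.yield_ratio <= 0:
            raise ValueError("yield_ratio must be > 0")
        if not 0.0 <= self.quench <= 1.0:
            raise ValueError("quench must lie in [0, 1]")
        if self.af_gfp < 0 or self.af_rfp < 0 or self.af_ratio < 0:
            raise ValueError("autofluorescence levels must be >= 0")

    def gfp_yield(self, acidic: float | np.ndarray) -> float | np.ndarray:
        """Effective GFP brightness factor 1 - a(1-q) for acidic fraction a."""
        return 1.0 - np.asarray(acidic) * (1.0 - self.quench)


@dataclass
class NeuronPreset:
    """Anatomy and expression of one neuron class' presynaptic region.

    ``growth`` scales punctum size (total protein per punctum) with age;
    ``count_growth`` scales punctum number. Both plateau once early-adult
    synapse growth completes (DA9 presynapses grow >100% from A0 to A2,
    then are stable).
    """

    neuron_class: Literal["DA9", "NSM", "VD", "DD"] = "DA9"
    n_puncta: int = 15
    punctum_amount_mu: float = 800.0  # lognormal scale (median), a.u.
    punctum_amount_sigma: float = 0.5  # lognormal shape of total protein
    punctum_radius_um: float = 0.35
    axon_length_um: float = 40.0
    growth: PiecewiseLinear = field(
        default_factory=lambda: PiecewiseLinear({0.0: 1.0, 2.0: 2.2})
    )
    count_growth: PiecewiseLinear = field(
        default_factory=lambda: PiecewiseLinear({0.0: 1.0, 2.0: 1.4})
    )

    def __post_init__(self) -> None:
        if self.n_puncta < 1:
            raise ValueError("n_puncta must be >= 1")
        if np.any(np.diff(self.growth.y) < 0):
            raise ValueError("growth must be monotone non-decreasing")

    def n_puncta_at(self, age: float) -> int:
        return max(1, round(self.n_puncta * self.count_growth(age)))

    def growth_rel(self, age: float, pulse_age: float) -> float:
        """Synapse-size scaling between pulse and imaging (>= 1)."""
        return self.growth(age) / self.growth(pulse_age)


@dataclass
class CohortDesign:
    """Pulse-chase experimental design.

    ``chase_times`` are imaging ages (days of adulthood), not offsets;
    every pulsed timepoint gets an age-matched non-pulsed control cohort
    when ``include_controls``. ``pulse_delay_h`` models the lag between the
    nominal pulse and its biochemical completion and shifts the effective
    chase time. ``recomb_efficiency`` is the per-animal probability that the
    pulse actually excised the GFP tag (failures behave like controls).
    """

    pulse_age: float = 2.0
    chase_times: Sequence[float] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    n_animals_per_timepoint: int = 15
    include_controls: bool = True
    pulse_delay_h: float = 4.0
    recomb_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if any(t < self.pulse_age for t in self.chase_times):
            bad = [t for t in self.chase_times if t < self.pulse_age]
            raise ValueError(
                f"chase times {bad} precede the pulse at age {self.pulse_age}"
            )
        if not 0.0 <= self.recomb_efficiency <= 1.0:
            raise ValueError("recomb_efficiency must lie in [0, 1]")

    @property
    def pulse_delay_days(self) -> float:
        return self.pulse_delay_h / 24.0


@dataclass
class NoiseModel:
    """Biological and measurement scatter.

    ``animal_cv``: lognormal CV of per-animal mean ratios (animal-to-animal
    biology plus mounting/optics). ``punctum_cv``: lognormal CV of individual
    punctum ratios around the animal mean. ``brightness_cv``: per-animal
    absolute-brightness scatter; it cancels in the ratio but not in raw
    channel intensities. ``acidic_kappa``: Beta concentration of per-punctum
    acidic fractions (None = no punctum-level acidification scatter).
    ``read_sigma``/``photon_gain``: Gaussian read noise and Poisson photon
    scaling for rendered images.
    """

    animal_cv: float = 0.15
    punctum_cv: float = 0.2
    brightness_cv: float = 0.4
    acidic_kappa: float | None = 30.0
    read_sigma: float = 2.0
    photon_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("animal_cv", "punctum_cv", "brightness_cv", "read_sigma", "photon_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        """All scatter disabled — deterministic observables."""
        return cls(
            animal_cv=0.0,
            punctum_cv=0.0,
            brightness_cv=0.0,
            acidic_kappa=None,
            read_sigma=0.0,
            photon_gain=0.0,
        )


@dataclass
class SyntheticConfig:
    """Full generative model: kinetics, optics, anatomy, design, noise."""

    kinetics: KineticsModel = field(default_factory=KineticsModel)
    optics: OpticsModel = field(default_factory=OpticsModel)
    preset: NeuronPreset = field(default_factory=NeuronPreset)
    design: CohortDesign = field(default_factory=CohortDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    pixel_size_um: float = 0.108
    z_step_um: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def default_config(**kwargs) -> SyntheticConfig:
    """The shipped default calibration (DA9-like cohort at A2)."""
    return SyntheticConfig(**kwargs)


@dataclass
class TruthPunctum:
    """Ground truth for one rendered punctum."""

    index: int
    position_um: float
    amount: float
    acidic_fraction: float
    old_fraction: float
    radius_um: float

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "position_um": self.position_um,
            "amount": self.amount,
            "acidic_fraction": self.acidic_fraction,
            "old_fraction": self.old_fraction,
            "radius_um": self.radius_um,
        }


def _draw_acidic(
    rng: np.random.Generator, mean_a: float, kappa: float | None, n: int
) -> np.ndarray:
    """Per-punctum acidic fractions: Beta(mean*k, (1-mean)*k), or constant."""
    if kappa is None or mean_a <= 0.0 or mean_a >= 1.0:
        return np.full(n, mean_a)
    return rng.beta(mean_a * kappa, (1.0 - mean_a) * kappa, size=n)


def _place_separated(
    rng: np.random.Generator, n: int, length: float, min_sep: float
) -> np.ndarray:
    """Approximately uniform positions with a guaranteed minimum spacing.

    En-passant boutons are discrete varicosities: one punctum per jittered
    grid slot keeps adjacent spots at least ``min_sep`` apart while staying
    close to uniform along the axon. Falls back to plain uniform placement
    when the axon cannot accommodate ``n`` spots at that spacing.
    """
    if n == 1:
        return rng.uniform(0.0, length, size=1)
    slot = length / n
    if min_sep >= slot:  # infeasible spacing: plain uniform
        return np.sort(rng.uniform(0.0, length, size=n))
    jitter = (slot - min_sep) / 2.0
    centers = (np.arange(n) + 0.5) * slot
    pos = centers + rng.uniform(-jitter, jitter, size=n)
    return np.sort(pos)


def simulate_truth_puncta(
    preset: NeuronPreset,
    age: float,
    kinetics: KineticsModel,
    optics: OpticsModel,
    seed: int | np.random.Generator,
    pulse_age: float | None = None,
    acidic_kappa: float | None = 30.0,
    amount_scale: float = 1.0,
    min_separation_um: float | None = None,
) -> list[TruthPunctum]:
    """Draw ground-truth puncta along a straight axon.

    Positions are uniform on ``[0, axon_length_um]`` and returned sorted
    proximal-to-distal; ``min_separation_um`` (default 4x the punctum
    radius) keeps adjacent spots resolvable as separate particles — en
    passant boutons are discrete varicosities, not a continuum. Amounts are
    lognormal with the preset's shape, scaled by the age-dependent growth
    factor; ``pulse_age=None`` means a control animal (``old_fraction = 1``).
    """
    if preset.axon_length_um <= 0:
        raise ValueError("axon_length_um must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = preset.n_puncta_at(age)
    if min_separation_um is None:
        min_separation_um = max(2.0, 4.0 * preset.punctum_radius_um)
    positions = _place_separated(rng, n, preset.axon_length_um, min_separation_um)
    amounts = (
        preset.punctum_amount_mu
        * amount_scale
        * preset.growth(age)
        * rng.lognormal(0.0, preset.punctum_amount_sigma, size=n)
    )
    acidic = _draw_acidic(rng, optics.acidic_fraction(age), acidic_kappa, n)
    old = 1.0 if pulse_age is None else kinetics.old_fraction(age, pulse_age)
    return [
        TruthPunctum(
            index=i,
            position_um=float(positions[i]),
            amount=float(amounts[i]),
            acidic_fraction=float(acidic[i]),
            old_fraction=float(old),
            radius_um=preset.punctum_radius_um,
        )
        for i in range(n)
    ]


def simulate_ratio_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate a full pulse-chase cohort at the punctum-table level.

    Returns one row per punctum with observable columns (``mean_rfp``,
    ``mean_gfp``, ``ratio``, ``position_norm``, ``area_um2``) alongside
    ground truth (``true_old_fraction``, ``apparent_old_fraction``,
    ``true_acidic_fraction``). Animals are unique per (timepoint x
    treatment): each cohort is imaged once, as in the source designs.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    kin, opt, pre, des, noise = (
        config.kinetics,
        config.optics,
        config.preset,
        config.design,
        config.noise,
    )
    delay = des.pulse_delay_days
    rows: list[dict] = []
    animal_counter = 0
    treatments = ["pulsed"] + (["control"] if des.include_controls else [])
    for age in des.chase_times:
        for treatment in treatments:
            for _ in range(des.n_animals_per_timepoint):
                animal_counter += 1
                animal_id = f"{pre.neuron_class}_{treatment}_{age:g}_{animal_counter:04d}"
                if treatment == "pulsed":
                    # pulse completes `delay` after the nominal pulse age
                    eff_pulse = des.pulse_age + delay
                    if des.recomb_efficiency < 1.0 and rng.random() > des.recomb_efficiency:
                        old = 1.0  # recombination failure: GFP never excised
                    else:
                        old = kin.old_fraction(max(age, eff_pulse), eff_pulse)
                    grel = pre.growth_rel(age, des.pulse_age)
                    pulse_age: float | None = des.pulse_age
                else:
                    old, grel, pulse_age = 1.0, 1.0, None
                old_app = old / grel
                n = pre.n_puncta_at(age)
                positions = np.sort(rng.uniform(0.0, 1.0, size=n))
                amounts = pre.punctum_amount_mu * pre.growth(age) * rng.lognormal(
                    0.0, pre.punctum_amount_sigma, size=n
                )
                acidic = _draw_acidic(
                    rng, opt.acidic_fraction(age), noise.acidic_kappa, n
                )
                brightness = _lognormal_unit_mean(rng, noise.brightness_cv, ())
                animal_factor = _lognormal_unit_mean(rng, noise.animal_cv, ())
                punctum_factors = _lognormal_unit_mean(rng, noise.punctum_cv, n)
                signal = opt.yield_ratio * opt.gfp_yield(acidic) * old_app
                ratios = (signal + opt.af_ratio) * animal_factor * punctum_factors
                mean_rfp = brightness * amounts
                mean_gfp = ratios * mean_rfp
                area = math.pi * pre.punctum_radius_um**2 * pre.growth(age) ** (2 / 3)
                for i in range(n):
                    rows.append(
                        {
                            "animal_id": animal_id,
                            "neuron_class": pre.neuron_class,
                            "age_days": age,
                            "treatment": treatment,
                            "pulse_age": pulse_age,
                            "punctum_index": i,
                            "area_um2": area,
                            "position_norm": float(positions[i]),
                            "mean_rfp": float(mean_rfp[i]),
                            "mean_gfp": float(mean_gfp[i]),
                            "ratio": float(ratios[i]),
                            "true_old_fraction": old,
                            "apparent_old_fraction": old_app,
                            "true_acidic_fraction": float(acidic[i]),
                        }
                    )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def normalized_background(config: SyntheticConfig) -> float:
    """Autofluorescence plateau on the normalized-ratio scale.

    This is the value the decay fits constrain the plateau to: the
    background ratio divided by the control-cohort mean ratio (the same
    denominator used to normalize the pulsed data). Computed analytically
    from the configured optics at the design's pulse age.
    """
    opt = config.optics
    a = opt.acidic_fraction(config.design.pulse_age)
    control_mean = opt.yield_ratio * float(opt.gfp_yield(a)) + opt.af_ratio
    return opt.af_ratio / control_mean


def render_image_stack(
    truth_puncta: Sequence[TruthPunctum],
    optics: OpticsModel,
    noise: NoiseModel,
    pixel_size_um: float = 0.108,
    z_step_um: float = 0.4,
    shape: tuple[int, int, int] = (10, 32, 448),
    rng: int | np.random.Generator = 0,
    growth_rel: float = 1.0,
) -> ImageStack:
    """Render puncta as isotropic 3-D Gaussian spots in a two-channel stack.

    Per punctum, the RFP spot amplitude is the total protein amount (scaled
    by ``growth_rel`` relative growth since the pulse) and the GFP amplitude
    is ``gamma * amount * O * (1 - a(1-q))``; each channel gains its additive
    autofluorescence background, then Poisson photon noise (if
    ``photon_gain > 0``) and Gaussian read noise (clipped at zero).
    Amplitudes are spot peak heights above background.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nz, ny, nx = shape
    y_center_um = (ny - 1) / 2.0 * pixel_size_um
    z_center_um = (nz - 1) / 2.0 * z_step_um
    zz = np.arange(nz)[:, None, None] * z_step_um
    yy = np.arange(ny)[None, :, None] * pixel_size_um
    xx = np.arange(nx)[None, None, :] * pixel_size_um
    rfp = np.full(shape, optics.af_rfp, dtype=float)
    gfp = np.full(shape, optics.af_gfp, dtype=float)
    x_max = (nx - 1) * pixel_size_um
    for p in truth_puncta:
        if not 0.0 <= p.position_um <= x_max:
            raise ValueError(
                f"punctum {p.index} at x={p.position_um:.2f} um is outside "
                f"the field of view (0..{x_max:.2f} um)"
            )
        sig = p.radius_um
        spot = np.exp(
            -(
                (xx - p.position_um) ** 2
                + (yy - y_center_um) ** 2
                + (zz - z_center_um) ** 2
            )
            / (2.0 * sig * sig)
        )
        amp_rfp = p.amount * growth_rel
        amp_gfp = (
            optics.yield_ratio
            * p.amount
            * p.old_fraction
            * float(optics.gfp_yield(p.acidic_fraction))
        )
        rfp += amp_rfp * spot
        gfp += amp_gfp * spot
    data = np.stack([rfp, gfp])
    if noise.photon_gain > 0:
        data = rng.poisson(data * noise.photon_gain) / noise.photon_gain
    if noise.read_sigma > 0:
        data = data + rng.normal(0.0, noise.read_sigma, size=data.shape)
    data = np.clip(data, 0.0, None)
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        metadata={"truth_puncta": [p.to_dict() for p in truth_puncta]},
    )
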