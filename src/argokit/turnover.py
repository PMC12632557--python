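"""Per-neuron summaries, control normalization, positional binning, and
recombination scoring for punctum-level cohort tables.

The unit of replication throughout is the animal (one neuron per animal):
each turnover datapoint is the mean GFP/RFP ratio over all presynaptic
puncta of one neuron, normalized by the mean ratio of an age-matched
non-pulsed control cohort. Ratio dispersion is summarized on the lognormal
scale, CV = sqrt(exp(sigma^2) - 1) with sigma^2 the sample variance of
log-ratios.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "lognormal_cv",
    "neuron_summary",
    "summarize_neurons",
    "normalize_to_control",
    "bin_by_position",
    "interneuronal_cv",
    "classify_recombination",
]

#: Positional bins along the presynaptic region (proximal fraction bounds).
POSITION_BINS = {"proximal": (0.0, 0.3), "middle": (0.3, 0.7), "distal": (0.7, 1.0)}


def lognormal_cv(values) -> float:
    """Coefficient of variation on the lognormal scale.

    CV = sqrt(exp(s^2) - 1) where s^2 is the sample (n-1) variance of the
    natural-log values. Scale-invariant: CV(c*x) == CV(x) for c > 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("lognormal_cv requires at least 2 values")
    if np.any(x <= 0):
        raise ValueError("lognormal_cv requires strictly positive values")
    s2 = np.log(x).var(ddof=1)
    return math.sqrt(math.expm1(s2))


def neuron_summary(punctum_ratios) -> tuple[float, float | None]:
    """(mean ratio, intraneuronal CV) over one neuron's punctum ratios.

    The mean is the arithmetic mean; the CV is lognormal-scale and is None
    (undefined, not zero) when only one punctum was measured.
    """
    x = np.asarray(punctum_ratios, dtype=float)
    if x.size < 1:
        raise ValueError("neuron_summary requires at least 1 punctum")
    mean = float(x.mean())
    cv = lognormal_cv(x) if x.size >= 2 else None
    return mean, cv


def summarize_neurons(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a punctum table to one row per animal/neuron."""
    rows = []
    group_cols = ["animal_id", "neuron_class", "age_days", "treatment", "pulse_age"]
    for keys, grp in table.groupby(group_cols, dropna=False, sort=False):
        mean, cv = neuron_summary(grp["ratio"].to_numpy())
        rec = dict(zip(group_cols, keys))
        rec["n_puncta"] = len(grp)
        rec["mean_ratio"] = mean
        rec["intraneuronal_cv"] = cv
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["pulse_age"] = out["pulse_age"].astype(float)
    return out


def normalize_to_control(neurons: pd.DataFrame) -> pd.DataFrame:
    """Divide pulsed per-neuron mean ratios by the age-matched control mean.

    Input is a per-neuron summary (from :func:`summarize_neurons`). Every
    pulsed (neuron_class, age_days) group must have a control group with the
    same keys. Control records also gain a ``normalized_ratio`` column
    (their own group mean as denominator, so the control group mean is 1).
    """
    out = neurons.copy()
    ctrl = neurons[neurons["treatment"] == "control"]
    denom = ctrl.groupby(["neuron_class", "age_days"])["mean_ratio"].mean()
    normalized = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        key = (row["neuron_class"], row["age_days"])
        if key not in denom.index:
            raise ValueError(
                f"no age-matched control cohort for neuron_class={key[0]}, "
                f"age_days={key[1]}"
            )
        normalized[i] = row["mean_ratio"] / denom.loc[key]
    out["normalized_ratio"] = normalized
    return out


def bin_by_position(puncta: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Assign puncta to proximal/middle/distal 30/40/30 positional bins.

    Bins are half-open at the upper edge except distal, which includes 1:
    proximal [0, 0.3), middle [0.3, 0.7), distal [0.7, 1]. Returns the
    per-punctum assignment and the per-bin mean ratios.
    """
    pos = puncta["position_norm"]
    labels = pd.Series(
        np.where(pos < 0.3, "proximal", np.where(pos < 0.7, "middle", "distal")),
        index=puncta.index,
        name="position_bin",
    )
    means = puncta["ratio"].groupby(labels).mean().reindex(
        ["proximal", "middle", "distal"]
    )
    return labels, means


def interneuronal_cv(neurons: pd.DataFrame) -> pd.DataFrame:
    """Lognormal CV of per-neuron mean ratios within each
    (neuron_class, age_days, treatment) cell — one value per cell, for
    qualitative comparison across conditions."""
    rows = []
    for keys, grp in neurons.groupby(["neuron_class", "age_days", "treatment"]):
        if len(grp) < 2:
            continue
        rows.append(
            dict(
                zip(["neuron_class", "age_days", "treatment"], keys),
                n=len(grp),
                cv=lognormal_cv(grp["mean_ratio"].to_numpy()),
            )
        )
    return pd.DataFrame(rows)


def _intermeans_split(values: np.ndarray) -> float:
    """2-class intermeans fixed point on raw values: t = (mu_lo + mu_hi)/2."""
    t = values.mean()
    for _ in range(200):
        lo, hi = values[values <= t], values[values > t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return float(t)


def classify_recombination(
    per_animal_mean_ratios, margin: float = 0.10
) -> tuple[list[str], float]:
    """Score animals as recombined / not_recombined from a bimodal ratio set.

    After the GFP-excision pulse, recombined animals have a low GFP/RFP
    ratio and failures keep the high steady-state ratio; the distribution is
    expected to be bimodal. The split threshold is the 2-class intermeans
    point of the log ratios; animals within ``margin`` (relative, on the
    ratio scale) of the threshold are left unscored, mirroring manual
    scoring where intermediate animals are skipped. If the two classes are
    not separated (gap between class means below the pooled within-class
    spread), all animals get the majority-side label with a warning.

    Returns (labels, threshold_ratio).
    """
    r = np.asarray(per_animal_mean_ratios, dtype=float)
    if r.size < 4:
        raise ValueError("classify_recombination requires at least 4 animals")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    logs = np.log(r)
    t_log = _intermeans_split(logs)
    thr = math.exp(t_log)
    lo, hi = logs[logs <= t_log], logs[logs > t_log]
    separated = lo.size > 0 and hi.size > 0
    if separated:
        # a unimodal (log)normal sample split at its intermeans point gives a
        # gap of ~1.6 sigma against a within-class spread sum of ~1.2 sigma;
        # require twice the spread so single modes are not split
        spread = 0.0
        if lo.size > 1:
            spread += lo.std(ddof=1)
        if hi.size > 1:
            spread += hi.std(ddof=1)
        separated = (hi.mean() - lo.mean()) > 2.0 * spread
    if not separated:
        logger.warning(
            "ratio distribution not bimodal; labelling all animals one class"
        )
        # single mode: decide by absolute level (steady-state tandem-tag
        # ratios sit well above 1; excised-GFP ratios well below)
        label = "not_recombined" if logs.mean() > 0.0 else "recombined"
        return [label] * r.size, thr
    labels = []
    for ri in r:
        if abs(ri - thr) <= margin * thr:
            labels.append("unscored")
        elif ri <= thr:
            labels.append("recombined")
        else:
            labels.append("not_recombined")
    return labels, thr
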