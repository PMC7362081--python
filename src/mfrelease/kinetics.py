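"""Classical dissolution-kinetics models, linearized fitting and stage-wise
model-adequacy reporting.

Implements the five standard release laws used throughout dissolution
testing, each fitted by ordinary least squares on its linearized form:

* zero order:        Q_t = k0 * t                      -> (t, Q)
* first order:       log10 Q_t = k * t / 2.303         -> (t, log10 Q)
* Higuchi:           Q_t = kH * sqrt(t)                -> (sqrt t, Q)
* Korsmeyer-Peppas:  M_t/M_inf = K * t**n              -> (log10 t, log10 M)
* Hixson-Crowell:    W0^(1/3) - Wt^(1/3) = k_hc * t    -> (t, 1-(1-Q)^(1/3))

where Q (and M_t/M_inf) is the cumulative released fraction of total load
(W0 = 1).  The first-order form follows the log-of-released-amount
convention; the textbook log-of-remaining variant is available via
``first_order_remaining=True``.  Fits include a free intercept so
stage-local segments that start from nonzero release remain fittable; the
reported model constant is the slope of the linearized fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ReleaseProfile, average_replicates, isotonic_cleanup

__all__ = [
    "MODEL_NAMES",
    "KineticFit",
    "linearize",
    "fit_kinetic_model",
    "predict_kinetic",
    "stagewise_model_report",
    "ReleaseProfile",
    "average_replicates",
    "isotonic_cleanup",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "zero_order",
    "first_order",
    "higuchi",
    "korsmeyer_peppas",
    "hixson_crowell",
)

# Korsmeyer-Peppas is conventionally valid only up to 60% release.
KP_DEFAULT_MAX_FRACTION = 0.6

_SLOPE_NAME = {
    "zero_order": "k0",
    "first_order": "k",
    "higuchi": "kH",
    "hixson_crowell": "k_hc",
}


@dataclass(frozen=True)
class KineticFit:
    """Fitted constants and goodness of fit for one model on one segment."""

    model_name: str
    params: dict
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        if not all(np.isfinite(v) for v in self.params.values()):
            raise ValueError("params must be finite")


def linearize(
    model_name: str,
    times,
    fractions,
    *,
    kp_max_fraction: float | None = KP_DEFAULT_MAX_FRACTION,
    first_order_remaining: bool = False,
):
    """Transform (t, Q) to the model's linear coordinates.

    Points where the transform is undefined (log of a nonpositive release,
    cube root of a negative remaining amount, t = 0 on a log-time axis) are
    dropped with a logged count.  Returns (x, y).

    Raises
    ------
    ValueError
        If the model is unknown or fewer than 3 usable points remain.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    t = np.asarray(times, dtype=float)
    q = np.asarray(fractions, dtype=float)
    if t.shape != q.shape:
        raise ValueError("times and fractions must align")

    if model_name == "zero_order":
        keep = np.ones_like(t, dtype=bool)
    elif model_name == "first_order":
        keep = (q < 1.0) if first_order_remaining else (q > 0.0)
    elif model_name == "higuchi":
        keep = t >= 0.0
    elif model_name == "korsmeyer_peppas":
        keep = (t > 0.0) & (q > 0.0)
        if kp_max_fraction is not None:
            keep &= q <= kp_max_fraction
    else:  # hixson_crowell
        keep = q <= 1.0

    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d unusable point(s)", model_name, n_dropped)
    t, q = t[keep], q[keep]
    if t.size < 3:
        raise ValueError(
            f"{model_name}: only {t.size} usable points after filtering "
            "(need >= 3)"
        )

    if model_name == "zero_order":
        return t, q
    if model_name == "first_order":
        y = np.log10(1.0 - q) if first_order_remaining else np.log10(q)
        return t, y
    if model_name == "higuchi":
        return np.sqrt(t), q
    if model_name == "korsmeyer_peppas":
        return np.log10(t), np.log10(q)
    # Hixson-Crowell with W0 = 1, Wt = 1 - Q
    return t, 1.0 - np.cbrt(1.0 - q)


def fit_kinetic_model(
    times,
    fractions,
    model_name: str,
    **linearize_opts,
) -> KineticFit:
    """Ordinary least squares on the linearized coordinates.

    The slope maps back to the model constant (Korsmeyer-Peppas: n = slope
    and K = 10**intercept); r_squared is the coefficient of determination of
    the linear fit.
    """
    x, y = linearize(model_name, times, fractions, **linearize_opts)
    if np.ptp(x) == 0:
        raise ValueError(f"{model_name}: degenerate x (zero variance)")
    res = stats.linregress(x, y)
    if model_name == "korsmeyer_peppas":
        params = {"K": 10.0**res.intercept, "n": res.slope}
    else:
        params = {_SLOPE_NAME[model_name]: res.slope, "intercept": res.intercept}
    r2 = res.rvalue**2
    return KineticFit(
        model_name=model_name,
        params=params,
        r_squared=float(r2),
        n_points=int(x.size),
    )


def predict_kinetic(fit: KineticFit, times, *, first_order_remaining: bool = False):
    """Forward-evaluate a fitted model at the given times.

    Inverse of the linearization, so fit-then-predict is the identity on
    noise-free model-generated data.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    p = fit.params
    name = fit.model_name
    if name == "zero_order":
        return p["intercept"] + p["k0"] * t
    if name == "first_order":
        lin = p["intercept"] + p["k"] * t
        if first_order_remaining:
            return 1.0 - 10.0**lin
        return 10.0**lin
    if name == "higuchi":
        return p["intercept"] + p["kH"] * np.sqrt(t)
    if name == "korsmeyer_peppas":
        if np.any(t == 0):
            raise ValueError("Korsmeyer-Peppas requires t > 0")
        return p["K"] * t ** p["n"]
    # hixson_crowell: y = 1 - (1-Q)^(1/3) = intercept + k t
    y = p["intercept"] + p["k_hc"] * t
    return 1.0 - (1.0 - y) ** 3


def stagewise_model_report(
    profiles: ReleaseProfile | list[ReleaseProfile],
    partition,
    *,
    adequacy_threshold: float = 0.90,
    stage_local: bool = True,
    **linearize_opts,
) -> pd.DataFrame:
    """Fit all five models on each stage and flag adequacy.

    Each stage is fitted in stage-local coordinates (time measured from the
    stage boundary, release measured as the increment over the last
    observation of the previous stage) so that every stage is analysed as
    its own incremental dissolution experiment; ``stage_local=False`` fits
    raw coordinates instead.  A stage x model cell whose fit is impossible
    (too few usable points, degenerate x) is marked not evaluable and the
    run continues.

    Returns a tidy DataFrame with one row per (stage, model).
    """
    from .pipeline import segment_stages, StagePartition  # avoid cycle

    if isinstance(profiles, ReleaseProfile):
        profile = profiles
    else:
        profile = average_replicates(profiles)
    if not isinstance(partition, StagePartition):
        partition = StagePartition(*partition)

    segments = segment_stages(profile, partition)
    rows = []
    for seg in segments:
        t_origin = seg.t_origin if stage_local else 0.0
        f_offset = seg.offset if stage_local else 0.0
        for model in MODEL_NAMES:
            row = {
                "formulation": profile.formulation_code,
                "stage": seg.stage_id,
                "model": model,
                "n_points": 0,
                "r_squared": np.nan,
                "adequate": False,
                "evaluable": False,
                "params": "",
            }
            if seg.times.size >= 3:
                try:
                    fit = fit_kinetic_model(
                        seg.times - t_origin,
                        seg.fractions - f_offset,
                        model,
                        **linearize_opts,
                    )
                except ValueError as exc:
                    logger.warning(
                        "stage %d %s not evaluable: %s", seg.stage_id, model, exc
                    )
                else:
                    row.update(
                        n_points=fit.n_points,
                        r_squared=fit.r_squared,
                        adequate=bool(fit.r_squared >= adequacy_threshold),
                        evaluable=True,
                        params=";".join(
                            f"{k}={v:.6g}" for k, v in fit.params.items()
                        ),
                    )
            rows.append(row)
    return pd.DataFrame(rows)
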