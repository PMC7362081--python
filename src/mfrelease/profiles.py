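"""Release-profile container shared by the kinetics, pipeline and synthetic
modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

__all__ = ["ReleaseProfile", "average_replicates", "isotonic_cleanup"]

# Cumulative fractions may slightly exceed 1 through measurement noise.
_MAX_FRACTION = 1.05


@dataclass
class ReleaseProfile:
    """One replicate's cumulative-release time series for one formulation.

    times are in hours, strictly increasing and nonnegative;
    cumulative_fraction is the fraction of the total payload released
    (0 to 1.05, the headroom absorbing measurement noise).
    """

    formulation_code: str
    replicate_id: str
    times: np.ndarray
    cumulative_fraction: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_fraction = np.asarray(self.cumulative_fraction, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if self.times.shape != self.cumulative_fraction.shape:
            raise ValueError("times and cumulative_fraction must align")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cumulative_fraction < 0) or np.any(
            self.cumulative_fraction > _MAX_FRACTION
        ):
            raise ValueError(
                f"cumulative_fraction must lie in [0, {_MAX_FRACTION}]"
            )

    @property
    def n_points(self) -> int:
        return int(self.times.size)


def average_replicates(profiles: list[ReleaseProfile]) -> ReleaseProfile:
    """Replicate-averaged profile (the curve used for fitting).

    All replicates must share the same formulation code and sampling times.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.formulation_code != first.formulation_code:
            raise ValueError("cannot average across formulations")
        if not np.allclose(p.times, first.times):
            raise ValueError("replicates must share sampling times")
    frac = np.mean([p.cumulative_fraction for p in profiles], axis=0)
    return ReleaseProfile(
        formulation_code=first.formulation_code,
        replicate_id="mean",
        times=first.times.copy(),
        cumulative_fraction=frac,
    )


def isotonic_cleanup(profile: ReleaseProfile) -> ReleaseProfile:
    """Pool-adjacent-violators projection onto nondecreasing curves.

    Optional cleanup for noisy profiles whose measured cumulative fraction
    dips; applied only on request, never silently.
    """
    iso = isotonic_regression(profile.cumulative_fraction, increasing=True)
    return ReleaseProfile(
        formulation_code=profile.formulation_code,
        replicate_id=profile.replicate_id,
        times=profile.times.copy(),
        cumulative_fraction=np.minimum(iso.x, _MAX_FRACTION),
    )
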