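"""Synthetic release experiments with the statistical structure of the in
vitro urea-release protocol.

The generator emulates a dissolution study of chitosan/salicylaldehyde
xerogel formulations loaded with urea: each specimen (weighed to contain 50
mg of urea) sits in 10 mL of water; at each sampling time 1 mL of supernatant
is withdrawn for quantification and replaced with 1 mL of fresh water;
sampling is hourly over the first day and daily thereafter through day 35;
experiments run in duplicate.  The underlying true release curve advances in
three stages -- a burst to 46% within 5 h, a slower diffusive stage to 75%
over the following 11 days, and a slow erosion-driven tail to near-complete
release by day 35 -- and the measured concentrations carry multiplicative
noise standing in for NMR quantification error.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .profiles import ReleaseProfile

__all__ = [
    "Formulation",
    "GeneratorConfig",
    "SamplingResult",
    "formulation_percent",
    "table1_fixtures",
    "true_release_curve",
    "formulation_modifiers",
    "sampling_schedule",
    "simulate_sampling",
    "generate_panel",
]


# ---------------------------------------------------------------------------
# Formulations
# ---------------------------------------------------------------------------


def formulation_percent(urea_mg: float, matrix_mg: float) -> int:
    """Urea content of a formulation as the printed integer percent.

    Nearest-integer rounding of 100*urea/(matrix+urea), except that the exact
    ratio 2/3 (urea mass double the matrix mass) is printed as 66, i.e.
    truncated rather than rounded -- the convention of the source composition
    table.
    """
    if urea_mg < 0 or matrix_mg < 0:
        raise ValueError("masses must be >= 0")
    if matrix_mg == 0:
        raise ValueError("matrix mass must be > 0")
    ratio = urea_mg / (matrix_mg + urea_mg)
    if abs(ratio - 2.0 / 3.0) < 1e-12:
        return 66
    return int(np.floor(100.0 * ratio + 0.5))


@dataclass(frozen=True)
class Formulation:
    """One row of the formulation composition table.

    ``code`` encodes the NH2/CHO molar ratio of the matrix (1.5 or 2) and the
    urea-to-matrix mass ratio x in Ux (0, 0.5, 1 or 2).
    """

    code: str
    nh2_cho_ratio: float
    chitosan_mg: float
    sa_mg: float
    urea_mg: float

    def __post_init__(self):
        if self.nh2_cho_ratio not in (1.5, 2.0):
            raise ValueError(f"nh2_cho_ratio must be 1.5 or 2.0, got {self.nh2_cho_ratio}")
        for name in ("chitosan_mg", "sa_mg", "urea_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def matrix_mg(self) -> float:
        return self.chitosan_mg + self.sa_mg

    @property
    def formulation_mg(self) -> float:
        return self.matrix_mg + self.urea_mg

    @property
    def urea_percent(self) -> int:
        if self.urea_mg == 0:
            return 0
        return formulation_percent(self.urea_mg, self.matrix_mg)


def table1_fixtures() -> list[Formulation]:
    """The eight formulations of the composition table.

    Four per crosslinking ratio: the blank matrix (U0) plus urea at half,
    equal and double the matrix mass (U0.5, U1, U2).
    """
    rows = [
        ("1.5-U0", 1.5, 100.0, 41.0, 0.0),
        ("1.5-U0.5", 1.5, 100.0, 41.0, 70.5),
        ("1.5-U1", 1.5, 100.0, 41.0, 141.0),
        ("1.5-U2", 1.5, 100.0, 41.0, 282.0),
        ("2-U0", 2.0, 100.0, 31.0, 0.0),
        ("2-U0.5", 2.0, 100.0, 31.0, 65.0),
        ("2-U1", 2.0, 100.0, 31.0, 131.0),
        ("2-U2", 2.0, 100.0, 31.0, 262.0),
    ]
    return [Formulation(*r) for r in rows]


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated release experiment.

    Stage milestones pin the true curve to the observed narrative: 46%
    released at the end of the 5 h burst, 75% at the end of the 11-day
    diffusive stage (t = 269 h), 99% at day 35 (t = 840 h).  Stage shapes are
    first-order (burst), square-root-of-time (diffusive) and first-order
    (erosion tail); ``k1`` and ``k3`` are the stage-1 and stage-3 rate
    constants in 1/h.  Noise is multiplicative Gaussian on measured
    concentrations with relative standard deviation ``noise_rel``.
    """

    t1: float = 5.0
    f1: float = 0.46
    t2: float = 269.0
    f2: float = 0.75
    t_final: float = 840.0
    f_final: float = 0.99
    k1: float = 0.1
    k3: float = 0.0065
    noise_rel: float = 0.03
    n_replicates: int = 2
    medium_ml: float = 10.0
    sample_ml: float = 1.0
    urea_load_mg: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.t1 < self.t2 < self.t_final):
            raise ValueError("stage boundaries must satisfy 0 < t1 < t2 < t_final")
        if not (0 < self.f1 < self.f2 < self.f_final <= 1):
            raise ValueError("milestones must satisfy 0 < F1 < F2 < F_final <= 1")
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError("rate constants must be > 0")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_ml <= 0 or self.medium_ml <= self.sample_ml:
            raise ValueError("need 0 < sample_ml < medium_ml")
        if self.urea_load_mg <= 0:
            raise ValueError("urea_load_mg must be > 0")


# ---------------------------------------------------------------------------
# True release curve
# ---------------------------------------------------------------------------


def true_release_curve(cfg: GeneratorConfig, t, speed: float = 1.0):
    """Noise-free cumulative released fraction at time(s) t (hours).

    Piecewise three-stage curve, continuous and nondecreasing, hitting the
    configured milestones exactly:

    * stage 1 (0..t1):  F1 * (1 - exp(-k1 t)) / (1 - exp(-k1 t1))
    * stage 2 (t1..t2): F1 + (F2-F1) * sqrt(t-t1) / sqrt(t2-t1)
    * stage 3 (t2..tf): F2 + (Ff-F2) * (1-exp(-k3 (t-t2)))/(1-exp(-k3 (tf-t2)))

    ``speed`` (from :func:`formulation_modifiers`) multiplies the stage-1
    rate constant and the stage-2 time scale; because stage 2 is normalized
    to its milestones the time-scale factor cancels there, so formulations
    differ in within-stage shape while all hit the same milestones.
    Times beyond t_final are clamped to F_final with a warning.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if np.any(t > cfg.t_final):
        warnings.warn(
            "times beyond t_final clamped to F_final", stacklevel=2
        )
    k1 = cfg.k1 * speed
    f = np.empty_like(t)

    s1 = t <= cfg.t1
    f[s1] = cfg.f1 * -np.expm1(-k1 * t[s1]) / -np.expm1(-k1 * cfg.t1)

    s2 = (t > cfg.t1) & (t <= cfg.t2)
    # speed scales the stage-2 time coordinate; it cancels in the normalized
    # sqrt form but is kept explicit for nonunit exponents.
    f[s2] = cfg.f1 + (cfg.f2 - cfg.f1) * np.sqrt(
        speed * (t[s2] - cfg.t1)
    ) / np.sqrt(speed * (cfg.t2 - cfg.t1))

    s3 = t > cfg.t2
    tc = np.minimum(t[s3], cfg.t_final)
    f[s3] = cfg.f2 + (cfg.f_final - cfg.f2) * -np.expm1(
        -cfg.k3 * (tc - cfg.t2)
    ) / -np.expm1(-cfg.k3 * (cfg.t_final - cfg.t2))
    return float(f[0]) if scalar else f


def formulation_modifiers(f: Formulation) -> float | None:
    """Release speed multiplier encoding the observed formulation ordering.

    Higher crosslinking (NH2/CHO = 1.5) releases slightly faster (factor
    1.1), and formulations with larger urea crystals (66% load) release
    faster while dilute ones (33%) release slower.  Returns ``None`` for
    blank matrices (nothing to release).
    """
    if f.urea_mg == 0:
        return None
    a = 1.1 if f.nh2_cho_ratio == 1.5 else 1.0
    b = {66: 1.15, 50: 1.0, 33: 0.9}[f.urea_percent]
    return a * b


# ---------------------------------------------------------------------------
# Sampling protocol
# ---------------------------------------------------------------------------


def sampling_schedule() -> np.ndarray:
    """Sampling times in hours: hourly through hour 24, then daily to day 35.

    58 points: 1..24 then 48, 72, ..., 840.
    """
    hourly = np.arange(1.0, 25.0)
    daily = np.arange(48.0, 841.0, 24.0)
    return np.concatenate([hourly, daily])


@dataclass(frozen=True)
class SamplingResult:
    """Raw measured concentrations (mg/mL) per replicate per sampling time."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_replicates, n_times)
    formulation_code: str


def simulate_sampling(
    cfg: GeneratorConfig,
    formulation: Formulation | None = None,
    seed: int = 0,
    times=None,
) -> SamplingResult:
    """Simulate the withdrawal/replacement protocol on the true curve.

    Mass balance per replicate: between samplings the matrix feeds the
    medium with the increment of the true cumulative release curve; at each
    sampling time the concentration of the 10 mL medium is measured (with
    multiplicative noise), then 1 mL is withdrawn -- removing 1/10 of the
    dissolved mass -- and replaced with fresh water.  The dilution makes raw
    concentrations systematically understate cumulative release; the mass-
    balance correction (``pipeline.correct_sampling``) inverts it exactly.

    All randomness flows from ``seed`` (one child stream per replicate);
    identical seeds give bit-identical output.
    """
    if formulation is not None and formulation.urea_mg == 0:
        raise ValueError("blank matrix has no payload to release")
    speed = 1.0 if formulation is None else formulation_modifiers(formulation)
    code = "reference" if formulation is None else formulation.code
    if times is None:
        times = sampling_schedule()
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("times must be nonnegative and strictly increasing")

    frac = np.asarray(true_release_curve(cfg, times, speed=speed))
    increments = np.diff(np.concatenate([[0.0], frac])) * cfg.urea_load_mg

    streams = np.random.SeedSequence(seed).spawn(cfg.n_replicates)
    keep = 1.0 - cfg.sample_ml / cfg.medium_ml
    concs = np.empty((cfg.n_replicates, times.size))
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        eps = rng.normal(0.0, cfg.noise_rel, size=times.size) if cfg.noise_rel > 0 else np.zeros(times.size)
        dissolved = 0.0
        for i in range(times.size):
            dissolved += increments[i]
            concs[r, i] = dissolved / cfg.medium_ml * (1.0 + eps[i])
            dissolved *= keep  # 1 mL withdrawn, replaced with water
    return SamplingResult(times=times, concentrations=concs, formulation_code=code)


# ---------------------------------------------------------------------------
# Full panel
# ---------------------------------------------------------------------------


def generate_panel(cfg: GeneratorConfig, seed: int | None = None):
    """Generate the full synthetic study: all urea-bearing formulations.

    Returns (profiles, manifest): one :class:`ReleaseProfile` per replicate
    of each of the six urea-bearing formulations (blanks carry no payload and
    are skipped), and a manifest dict recording the generator truth --
    config, per-formulation speed factors and sub-seeds -- for parameter-
    recovery testing.  Deterministic for a fixed seed.
    """
    from .pipeline import correct_sampling  # local import avoids a cycle

    if seed is None:
        seed = cfg.seed
    forms = [f for f in table1_fixtures() if f.urea_mg > 0]
    root = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(forms))]

    profiles: list[ReleaseProfile] = []
    manifest = {
        "config": asdict(cfg),
        "seed": int(seed),
        "formulations": {},
    }
    for f, sub in zip(forms, sub_seeds):
        sim = simulate_sampling(cfg, formulation=f, seed=sub)
        for r in range(cfg.n_replicates):
            mass = correct_sampling(
                sim.concentrations[r],
                medium_ml=cfg.medium_ml,
                sample_ml=cfg.sample_ml,
            )
            frac = np.minimum(mass / cfg.urea_load_mg, 1.05)
            profiles.append(
                ReleaseProfile(
                    formulation_code=f.code,
                    replicate_id=f"R{r + 1}",
                    times=sim.times.copy(),
                    cumulative_fraction=frac,
                )
            )
        manifest["formulations"][f.code] = {
            "speed_factor": formulation_modifiers(f),
            "sub_seed": sub,
            "urea_percent": f.urea_percent,
        }
    return profiles, manifest
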