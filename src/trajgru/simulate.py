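"""Synthetic aMCI-like longitudinal cohort generator.

The generative model is a linear mixed model per feature:

    y[i, f, t] = baseline[i, f] + slope[group(i), f] * t
                 + loading[f] * severity[i] + noise[i, f, t]

with ``baseline ~ N(mean[group, f], sd[group, f])``, a subject-level latent
severity ``severity ~ N(0, 1)`` inducing cross-feature correlation, and
i.i.d. Gaussian observation noise. The amyloid-positive group declines
strictly faster on every marker; CDR-SB is the one score whose slope is
positive (higher = worse). APOE carrier status, Centiloid, gender and
education are baseline draws duplicated across visits; age increments with
the visit offset.

Missingness is MCAR intermittent masking plus monotone dropout, applied to
the MRI and cognitive features only (baseline-measured features — APOE,
Centiloid, demographics — are known at every visit by duplication). The
baseline visit is never masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .cohort import LongitudinalCohort, build_delta
from .schema import FeatureSchema, default_schema

GROUPS = ("abeta_neg", "abeta_pos")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``features`` maps feature name -> dict with per-group ``mean``/``sd``/
    ``slope`` plus scalar ``loading`` and ``noise_sd``. Defaults are loaded
    from the versioned ``configs/simulation_defaults.yaml``.
    """

    n_subjects: int | None = None  # per group
    n_visits: int | None = None
    p_miss: float | None = None
    p_drop: float | None = None
    apoe_rate: dict = field(default_factory=dict)
    female_rate: dict = field(default_factory=dict)
    age: dict = field(default_factory=dict)
    education: dict = field(default_factory=dict)
    centiloid: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        defaults = _load_defaults()
        for key in ("n_subjects", "n_visits", "p_miss", "p_drop"):
            if getattr(self, key) is None:
                setattr(self, key, defaults[key])
        for key in (
            "apoe_rate",
            "female_rate",
            "age",
            "education",
            "centiloid",
            "features",
        ):
            if not getattr(self, key):
                setattr(self, key, defaults[key])
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects per group")
        if self.n_visits < 2:
            raise ConfigError("need at least 2 visits")
        for p in (self.p_miss, self.p_drop):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("missingness rates must lie in [0, 1]")
        for fcfg in self.features.values():
            if any(s <= 0 for s in fcfg["sd"].values()) or fcfg["noise_sd"] < 0:
                raise ConfigError("feature sds must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("version", None)
        raw.update(overrides)
        return cls(**raw)


def _load_defaults() -> dict:
    ref = resources.files("trajgru.configs").joinpath("simulation_defaults.yaml")
    raw = yaml.safe_load(ref.read_text())
    raw.pop("version", None)
    return raw


@dataclass
class GroundTruthCohort:
    """Complete (pre-masking) trajectories plus the observed cohort."""

    complete_values: np.ndarray  # (N, B, T), no missingness
    severity: np.ndarray  # (N,), latent subject severity
    slopes: np.ndarray  # (N, B), generating slope per subject/feature
    observed: LongitudinalCohort  # after masking

    def validate(self) -> None:
        obs = self.observed
        ok = obs.mask == 1
        if not np.allclose(obs.values[ok], self.complete_values[ok]):
            raise ValueError("observed values disagree with complete values")


def simulate(config: SimulationConfig, schema: FeatureSchema | None = None) -> GroundTruthCohort:
    """Draw a two-group cohort; deterministic under a fixed config seed."""
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed)
    n_per, t = config.n_subjects, config.n_visits
    n = 2 * n_per
    b = schema.n_features
    times = np.arange(t, dtype=float)

    labels = np.repeat([0, 1], n_per)
    severity = rng.standard_normal(n)
    values = np.zeros((n, b, t))
    slopes = np.zeros((n, b))

    for gi, gname in enumerate(GROUPS):
        rows = np.where(labels == gi)[0]
        for fname, fcfg in config.features.items():
            fi = schema.index(fname)
            base = rng.normal(fcfg["mean"][gname], fcfg["sd"][gname], size=len(rows))
            slope = fcfg["slope"][gname]
            noise = (
                rng.standard_normal((len(rows), t)) * fcfg["noise_sd"]
                if fcfg["noise_sd"] > 0
                else np.zeros((len(rows), t))
            )
            traj = (
                base[:, None]
                + slope * times[None, :]
                + fcfg["loading"] * severity[rows, None]
                + noise
            )
            values[rows, fi, :] = traj
            slopes[rows, fi] = slope

        # baseline-measured, duplicated features
        apoe = (rng.random(len(rows)) < config.apoe_rate[gname]).astype(float)
        values[rows, schema.index("apoe_e4"), :] = apoe[:, None]
        cl = rng.normal(
            config.centiloid["mean"][gname],
            config.centiloid["sd"][gname],
            size=len(rows),
        )
        values[rows, schema.index("centiloid"), :] = cl[:, None]
        age0 = np.clip(
            rng.normal(config.age["mean"][gname], config.age["sd"], size=len(rows)),
            55.0,
            92.0,
        )
        values[rows, schema.index("age"), :] = age0[:, None] + times[None, :]
        edu = np.clip(
            rng.normal(
                config.education["mean"][gname],
                config.education["sd"],
                size=len(rows),
            ),
            0.0,
            22.0,
        )
        values[rows, schema.index("education"), :] = edu[:, None]
        female = (rng.random(len(rows)) < config.female_rate[gname]).astype(float)
        values[rows, schema.index("gender"), :] = female[:, None]

    subject_ids = np.array([f"S{i:04d}" for i in range(n)])
    observed = apply_missingness(
        values,
        labels,
        schema,
        times,
        subject_ids,
        p_miss=config.p_miss,
        p_drop=config.p_drop,
        seed=_derive_seed(config.seed, "missingness"),
    )
    truth = GroundTruthCohort(
        complete_values=values, severity=severity, slopes=slopes, observed=observed
    )
    truth.validate()
    return truth


def apply_missingness(
    complete_values: np.ndarray,
    labels: np.ndarray,
    schema: FeatureSchema,
    visit_times: np.ndarray,
    subject_ids: np.ndarray,
    p_miss: float,
    p_drop: float,
    seed: int,
) -> LongitudinalCohort:
    """Mask MRI/cognitive cells: i.i.d. intermittent at ``p_miss`` plus
    monotone dropout with per-visit hazard ``p_drop``. Baseline never masked.
    """
    if not (0.0 <= p_miss <= 1.0 and 0.0 <= p_drop <= 1.0):
        raise ConfigError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n, b, t = complete_values.shape
    mask = np.ones((n, b, t))
    maskable = schema.indices_for("mri", "cognitive")

    # monotone dropout: geometric first-drop visit with hazard p_drop
    dropped = np.full(n, t)  # first unobserved visit; t = never drops
    if p_drop > 0:
        draws = rng.random((n, t - 1)) < p_drop
        for i in range(n):
            hit = np.nonzero(draws[i])[0]
            if hit.size:
                dropped[i] = hit[0] + 1
    # intermittent missingness, non-baseline visits only
    inter = rng.random((n, len(maskable), t - 1)) < p_miss

    for i in range(n):
        for k, fi in enumerate(maskable):
            mask[i, fi, 1:][inter[i, k]] = 0.0
            mask[i, fi, dropped[i]:] = 0.0

    values = complete_values.copy()
    values[mask == 0] = np.nan
    delta = build_delta(mask, visit_times)
    cohort = LongitudinalCohort(
        values=values,
        mask=mask,
        delta=delta,
        labels=np.asarray(labels, dtype=int),
        schema=schema,
        visit_times=np.asarray(visit_times, dtype=float),
        subject_ids=np.asarray(subject_ids),
    )
    cohort.validate()
    return cohort


def benchmark_config(seed: int) -> SimulationConfig:
    """The standard synthetic benchmark: 200 subjects/group, 4 annual visits,
    20% intermittent missingness, no dropout."""
    return SimulationConfig(n_subjects=200, n_visits=4, p_miss=0.2, p_drop=0.0, seed=seed)


def _derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    import zlib

    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)
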