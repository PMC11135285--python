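"""Feature schema for the longitudinal aMCI cohort.

The cohort couples three kinds of per-visit measurements:

* six MRI markers — mean cortical thickness of the cingulate, frontal,
  parietal, temporal and occipital regions (mm) and hippocampal volume
  normalized by intracranial volume;
* nine neuropsychological scores (DSF, K-BNT, RCFT-Copy, SVLT-Delayed,
  RCFT-Delayed, COWAT, Stroop color reading, K-MMSE, CDR-SB);
* APOE e4 carrier status and the global amyloid Centiloid value;

plus baseline demographics (age, education years, gender) that are carried
forward across visits, age being incremented by the visit offset.

The MRI + cognitive + APOE + Centiloid block (size B') is what the attention
fusion operates on; demographics bypass the attention and are concatenated
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

VALID_ROLES = frozenset(
    {
        "mri",
        "cognitive",
        "apoe",
        "centiloid",
        "demographic_age",
        "demographic_edu",
        "demographic_gender",
    }
)

DEMOGRAPHIC_ROLES = ("demographic_age", "demographic_edu", "demographic_gender")


class SchemaError(ValueError):
    """Raised when a feature schema or a file violating it is encountered."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with their roles and units.

    Invariants: exactly 6 ``mri`` and 9 ``cognitive`` features, unique names,
    every feature assigned exactly one known role.
    """

    names: tuple[str, ...]
    roles: tuple[str, ...]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != len(self.roles):
            raise SchemaError("names and roles must have equal length")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names must be unique")
        unknown = set(self.roles) - VALID_ROLES
        if unknown:
            raise SchemaError(f"unknown roles: {sorted(unknown)}")
        if self.role_count("mri") != 6:
            raise SchemaError("schema must contain exactly 6 mri features")
        if self.role_count("cognitive") != 9:
            raise SchemaError("schema must contain exactly 9 cognitive features")

    # -- lookups --------------------------------------------------------------

    def role_count(self, role: str) -> int:
        return sum(r == role for r in self.roles)

    def names_for(self, *roles: str) -> list[str]:
        return [n for n, r in zip(self.names, self.roles) if r in roles]

    def indices_for(self, *roles: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r in roles]

    @property
    def mri_names(self) -> list[str]:
        return self.names_for("mri")

    @property
    def cognitive_names(self) -> list[str]:
        return self.names_for("cognitive")

    @property
    def core_names(self) -> list[str]:
        """Features entering the attention fusion (B' block)."""
        return self.names_for("mri", "cognitive", "apoe", "centiloid")

    @property
    def demographic_names(self) -> list[str]:
        return self.names_for(*DEMOGRAPHIC_ROLES)

    @property
    def core_indices(self) -> list[int]:
        return self.indices_for("mri", "cognitive", "apoe", "centiloid")

    @property
    def demographic_indices(self) -> list[int]:
        return self.indices_for(*DEMOGRAPHIC_ROLES)

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def n_core(self) -> int:
        return len(self.core_indices)

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": n, "role": r, "unit": self.units.get(n, "")}
                for n, r in zip(self.names, self.roles)
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        feats = d["features"]
        return cls(
            names=tuple(f["name"] for f in feats),
            roles=tuple(f["role"] for f in feats),
            units={f["name"]: f.get("unit", "") for f in feats},
        )

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_DEFAULT_FEATURES = [
    ("ct_cingulate", "mri", "mm"),
    ("ct_frontal", "mri", "mm"),
    ("ct_parietal", "mri", "mm"),
    ("ct_temporal", "mri", "mm"),
    ("ct_occipital", "mri", "mm"),
    ("hippocampus_icv", "mri", "ratio"),
    ("dsf", "cognitive", "score"),
    ("kbnt", "cognitive", "score"),
    ("rcft_copy", "cognitive", "score"),
    ("svlt_delayed", "cognitive", "score"),
    ("rcft_delayed", "cognitive", "score"),
    ("cowat", "cognitive", "score"),
    ("stroop_color", "cognitive", "score"),
    ("kmmse", "cognitive", "score"),
    ("cdr_sb", "cognitive", "score"),
    ("apoe_e4", "apoe", "carrier"),
    ("centiloid", "centiloid", "CL"),
    ("age", "demographic_age", "years"),
    ("education", "demographic_edu", "years"),
    ("gender", "demographic_gender", "female=1"),
]


def default_schema() -> FeatureSchema:
    """The 20-column default schema (B' = 17 core + 3 demographics)."""
    return FeatureSchema(
        names=tuple(n for n, _, _ in _DEFAULT_FEATURES),
        roles=tuple(r for _, r, _ in _DEFAULT_FEATURES),
        units={n: u for n, _, u in _DEFAULT_FEATURES},
    )
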