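"""Canonical feature schema for the balance/vestibular diagnostic battery.

The cohort matrix is a wide patient-by-feature table: 53 numeric variables
grouped into 8 test blocks (posturography, visual acuity, video head impulse,
myogenic potentials, verticality perception, caloric irrigation, fundus
photography, plus epidemiological covariates).  Block membership drives the
leave-one-test-out importance analysis, so the schema is an explicit, ordered
object rather than an implicit column convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered block structure of the diagnostic feature matrix.

    ``blocks`` maps each test block to its ordered variable names; variable
    names must be unique across blocks so that columns can be addressed by
    name anywhere in the pipeline.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        names = self.variable_names
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique across blocks")

    @property
    def block_names(self) -> list[str]:
        return [name for name, _ in self.blocks]

    @property
    def variable_names(self) -> list[str]:
        return [v for _, names in self.blocks for v in names]

    @property
    def total_variables(self) -> int:
        return len(self.variable_names)

    def block_sizes(self) -> dict[str, int]:
        return {name: len(names) for name, names in self.blocks}

    def block_of(self, variable: str) -> str:
        for name, names in self.blocks:
            if variable in names:
                return name
        raise KeyError(f"unknown variable {variable!r}")

    def columns_of(self, block: str) -> list[int]:
        """Column indices (into the full variable order) of one block."""
        offset = 0
        for name, names in self.blocks:
            if name == block:
                return list(range(offset, offset + len(names)))
            offset += len(names)
        raise KeyError(f"unknown block {block!r}")

    def drop_block(self, block: str) -> "FeatureSchema":
        if block not in self.block_names:
            raise KeyError(f"unknown block {block!r}")
        return FeatureSchema(tuple((n, v) for n, v in self.blocks if n != block))

    def drop_variable(self, variable: str) -> "FeatureSchema":
        self.block_of(variable)  # raises on unknown
        return FeatureSchema(
            tuple(
                (n, tuple(v for v in names if v != variable))
                for n, names in self.blocks
            )
        )


#: Default 8-block / 53-variable battery.  Variable names are schematic
#: stand-ins with field-standard terminology (the study's exact parameter
#: list is not public); block sizes are fixed: SOT 5, DVA 8, V-HIT 9,
#: VEMPs 3, SVV 11, Caloric 11, Fundus 3, General 3.
_DEFAULT_BLOCKS: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "SOT",
        ("sot_cs", "sot_som", "sot_vis", "sot_vest", "sot_pref"),
    ),
    (
        "DVA",
        (
            "dva_static",
            "dva_dynamic",
            "dva_loss",
            "dva_velocity",
            "dva_retest_static",
            "dva_retest_dynamic",
            "dva_head_yaw",
            "dva_head_pitch",
        ),
    ),
    (
        "V-HIT",
        (
            "vhit_gain_lat_l",
            "vhit_gain_lat_r",
            "vhit_gain_ant_l",
            "vhit_gain_ant_r",
            "vhit_gain_post_l",
            "vhit_gain_post_r",
            "vhit_saccades_l",
            "vhit_saccades_r",
            "vhit_asymmetry",
        ),
    ),
    (
        "VEMPs",
        ("cvemp_asymmetry", "ovemp_asymmetry", "vemp_latency"),
    ),
    (
        "SVV",
        (
            "svv_static_mean",
            "svv_static_sd",
            "svv_dyn_cw_mean",
            "svv_dyn_cw_sd",
            "svv_dyn_ccw_mean",
            "svv_dyn_ccw_sd",
            "svv_offset",
            "svv_tilt_l",
            "svv_tilt_r",
            "svv_error_abs",
            "svv_range",
        ),
    ),
    (
        "Caloric",
        (
            "caloric_mspv_30",
            "caloric_mspv_44",
            "caloric_mspv_sum",
            "caloric_index_30",
            "caloric_index_44",
            "caloric_difference",
            "caloric_dominancy",
            "caloric_asymmetry",
            "caloric_fixation_index",
            "caloric_latency",
            "caloric_duration",
        ),
    ),
    (
        "Fundus",
        ("fundus_torsion_l", "fundus_torsion_r", "fundus_asymmetry"),
    ),
    (
        "General",
        ("sex", "age", "days_since_injury"),
    ),
)


def default_schema() -> FeatureSchema:
    """The canonical 8-block, 53-variable battery schema."""
    return FeatureSchema(_DEFAULT_BLOCKS)


#: 12-item modified concussion symptom inventory (binary absent/present).
DEFAULT_SYMPTOMS: tuple[str, ...] = (
    "headache",
    "dizziness",
    "neck_pain",
    "difficulty_concentrating",
    "blurred_vision",
    "sensitivity_to_light",
    "balance_problems",
    "feeling_confused",
    "coordination_problems",
    "nausea",
    "difficulty_remembering",
    "feeling_slowed_down",
)


@dataclass
class SymptomTable:
    """Binary symptom inventory; never fed to the clustering stages.

    ``presence`` is a float matrix with entries 0.0 (absent), 1.0 (present)
    or NaN (no response), one row per patient.
    """

    symptoms: list[str] = field(default_factory=lambda: list(DEFAULT_SYMPTOMS))
    presence: "object" = None  # (n_patients, n_symptoms) float array

    def __post_init__(self) -> None:
        import numpy as np

        if self.presence is not None:
            self.presence = np.asarray(self.presence, dtype=float)
            if self.presence.ndim != 2 or self.presence.shape[1] != len(self.symptoms):
                raise ValueError("presence must be (n_patients, n_symptoms)")
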