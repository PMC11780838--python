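"""Muscle rosters and nominal module-composition templates.

Two muscle sets are analyzed per leg: the full 43-muscle roster of the
lower-limb musculoskeletal model (all leg muscles; torso muscles excluded)
and an 8-muscle subset matching the muscles typically recorded with surface
EMG in gait studies (TA, SOL, medial gastrocnemius, vastus medialis, rectus
femoris, medial and lateral hamstrings, gluteus medius).

The module templates encode the canonical composition of the walking motor
modules: a stance extensor module (glutei, knee extensors, with hip
adductor/abductor representation), a plantarflexor module active in late
stance, a hip-flexor module active from late stance into swing, and an
ankle-dorsiflexor module active in late swing into early stance.  The
hip-flexor module has no dominant muscle within the 8-muscle subset, so the
subset carries only three modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Module role names, in canonical order (full set). The subset lacks the
# hip-flexor module because no hip flexor is among its eight muscles.
MODULE_ROLES_FULL: tuple[str, ...] = (
    "stance_extensor",
    "plantarflexor",
    "hip_flexor",
    "dorsiflexor",
)
MODULE_ROLES_SUBSET: tuple[str, ...] = (
    "stance_extensor",
    "plantarflexor",
    "dorsiflexor",
)

SUBSET_8_NAMES: tuple[str, ...] = (
    "TA",    # tibialis anterior
    "SOL",   # soleus
    "GM",    # medial gastrocnemius
    "VM",    # vastus medialis
    "RF",    # rectus femoris
    "MH",    # medial hamstrings (semimembranosus/semitendinosus)
    "LH",    # lateral hamstrings (biceps femoris)
    "GMED",  # gluteus medius
)

FULL_43_NAMES: tuple[str, ...] = (
    "PIRI", "PSOAS", "SART", "TFL", "IL",
    "ADDB", "ADDL", "ADDMI", "ADDMD", "ADDMM", "ADDMP",
    "GMAX1", "GMAX2", "GMAX3",
    "GMED1", "GMED2", "GMED3",
    "GMIN1", "GMIN2", "GMIN3",
    "SM", "ST", "BFLH", "BFSH", "GRAC",
    "VM", "VI", "VL", "RF",
    "EXDL", "EXHL",
    "PERB", "PERL", "PERT",
    "TA", "FDB", "FDL", "FHL", "TP",
    "GM", "GL", "SOL", "POP",
)

#: Weight assigned to muscles with no nominal role in a module.
BASELINE_WEIGHT: float = 0.05

# Per-module nominal weights. Muscles not listed receive BASELINE_WEIGHT.
_FULL_TEMPLATE: dict[str, dict[str, float]] = {
    "stance_extensor": {
        # glutei
        "GMAX1": 1.0, "GMAX2": 0.95, "GMAX3": 0.9,
        "GMED1": 0.9, "GMED2": 0.85, "GMED3": 0.8,
        "GMIN1": 0.6, "GMIN2": 0.6, "GMIN3": 0.55,
        # knee extensors
        "VM": 0.9, "VI": 0.85, "VL": 0.9, "RF": 0.5,
        # hamstrings (early-stance support)
        "SM": 0.45, "ST": 0.4, "BFLH": 0.45,
        # hip adductors / abductor musculature
        "ADDB": 0.35, "ADDL": 0.35, "ADDMI": 0.3, "ADDMD": 0.3,
        "ADDMM": 0.3, "ADDMP": 0.3, "TFL": 0.45, "GRAC": 0.25,
        "PIRI": 0.3, "SART": 0.25,
    },
    "plantarflexor": {
        "GM": 1.0, "GL": 0.95, "SOL": 1.0,
        "FHL": 0.5, "FDL": 0.45, "FDB": 0.3, "TP": 0.5,
        "PERB": 0.35, "PERL": 0.4, "POP": 0.25,
        # secondary iliacus/psoas representation
        "IL": 0.3, "PSOAS": 0.3,
    },
    "hip_flexor": {
        "IL": 1.0, "PSOAS": 0.95, "SART": 0.6, "TFL": 0.5,
        "RF": 0.45, "GRAC": 0.4,
        # secondary hamstring and dorsiflexor activity
        "SM": 0.35, "ST": 0.35, "BFLH": 0.3, "BFSH": 0.4,
        "TA": 0.3, "EXDL": 0.25,
    },
    "dorsiflexor": {
        "TA": 1.0, "EXDL": 0.9, "EXHL": 0.85, "PERT": 0.6,
    },
}

_SUBSET_TEMPLATE: dict[str, dict[str, float]] = {
    "stance_extensor": {
        "GMED": 1.0, "VM": 0.95, "RF": 0.55, "MH": 0.7, "LH": 0.7,
    },
    "plantarflexor": {
        "SOL": 1.0, "GM": 0.95,
    },
    "dorsiflexor": {
        "TA": 1.0, "RF": 0.15,
    },
}


@dataclass(frozen=True)
class MuscleSetDefinition:
    """An ordered muscle roster plus nominal per-module weights.

    ``module_template_map`` maps module role -> {muscle name -> nominal
    weight}; muscles absent from a module's map receive a small uniform
    baseline weight so every muscle carries some activity.
    """

    name: str
    names: tuple[str, ...]
    module_roles: tuple[str, ...]
    module_template_map: dict[str, dict[str, float]] = field(repr=False)

    @property
    def n_muscles(self) -> int:
        return len(self.names)

    def index_of(self, muscle: str) -> int:
        try:
            return self.names.index(muscle)
        except ValueError:
            raise KeyError(f"unknown muscle label {muscle!r} in set {self.name!r}")


FULL_43 = MuscleSetDefinition(
    name="full_43",
    names=FULL_43_NAMES,
    module_roles=MODULE_ROLES_FULL,
    module_template_map=_FULL_TEMPLATE,
)

SUBSET_8 = MuscleSetDefinition(
    name="subset_8",
    names=SUBSET_8_NAMES,
    module_roles=MODULE_ROLES_SUBSET,
    module_template_map=_SUBSET_TEMPLATE,
)

MUSCLE_SET_BY_NAME: dict[str, MuscleSetDefinition] = {
    "full_43": FULL_43,
    "subset_8": SUBSET_8,
}


def get_muscle_set(name: str) -> MuscleSetDefinition:
    """Look up a muscle set by name ("full_43" or "subset_8")."""
    try:
        return MUSCLE_SET_BY_NAME[name]
    except KeyError:
        raise ValueError(
            f"unknown muscle set {name!r}; expected one of {sorted(MUSCLE_SET_BY_NAME)}"
        )
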