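"""Species physiology: organ tables and reference individuals.

The package ships reference organ tables for the rat (0.23 kg, 40 weeks) and
the European adult human (60 kg, 163 cm, 30 years). Organ volumes carry the
tissue-composition fractions used by the tissue-partitioning model and the
vascular/interstitial volume split used by the whole-body ODE system.

Body-weight scaling is isometric: scaling an individual's body weight by a
factor f scales every organ volume, blood volume, cardiac output and GFR by
f and leaves composition fractions untouched. Within the narrow population
ranges used here (±20%) this is the simplest defensible choice.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

from .errors import RangeError, UnsupportedOperationError, ValidationError

log = logging.getLogger(__name__)

SPECIES = ("rat", "human")

#: plausible body-weight bounds per species (kg); outside → warning, kept
PLAUSIBLE_BW = {"rat": (0.1, 0.6), "human": (30.0, 200.0)}


@dataclass
class OrganSpec:
    """One organ row: volume, perfusion and tissue composition.

    Composition fields are per-mL-of-tissue fractions: extracellular water
    ``f_ew``, intracellular water ``f_iw``, neutral lipid ``f_nl``, neutral
    phospholipid ``f_np``; ``albumin_ratio`` is the tissue:plasma albumin
    concentration ratio used by the acid/neutral partition model.
    """

    name: str
    volume: float               # mL
    blood_flow: float           # L/h (absolute; lung carries total CO)
    vascular_fraction: float
    interstitial_fraction: float
    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    albumin_ratio: float
    intracellular_ph: float = 7.0
    portal: bool = False        # drains to the liver (splanchnic)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise RangeError(f"organ {self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise RangeError(f"organ {self.name}: blood_flow must be >= 0")
        for f in ("vascular_fraction", "interstitial_fraction",
                  "f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise RangeError(f"organ {self.name}: {f}={v} outside [0, 1]")

    @property
    def cellular_fraction(self) -> float:
        return 1.0 - self.vascular_fraction - self.interstitial_fraction


@dataclass
class Individual:
    """A parameterized organism: species, anthropometry and organ table."""

    species: str
    body_weight: float          # kg
    age: float                  # years
    gfr: float                  # mL/min
    hematocrit: float
    cardiac_output: float       # L/h (systemic)
    organs: list[OrganSpec]
    arterial_blood_volume: float    # mL
    venous_blood_volume: float      # mL
    height: float | None = None     # cm, human only
    plasma_ph: float = 7.4
    body_density: float = 1.05      # g/mL

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.gfr < 0:
            raise RangeError("gfr must be >= 0")
        body_volume_ml = self.body_weight * 1000.0 / self.body_density
        total = self.total_organ_volume + self.arterial_blood_volume \
            + self.venous_blood_volume
        if total >= body_volume_ml:
            raise ValidationError(
                f"organ volumes ({total:.0f} mL) exceed body volume "
                f"({body_volume_ml:.0f} mL)"
            )

    @property
    def total_organ_volume(self) -> float:
        return sum(o.volume for o in self.organs)

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ named {name!r}")

    def scaled(self, body_weight: float) -> "Individual":
        """Return a copy isometrically rescaled to ``body_weight``."""
        f = body_weight / self.body_weight
        organs = [
            dataclasses.replace(o, volume=o.volume * f, blood_flow=o.blood_flow * f)
            for o in self.organs
        ]
        return dataclasses.replace(
            self,
            body_weight=body_weight,
            organs=organs,
            cardiac_output=self.cardiac_output * f,
            gfr=self.gfr * f,
            arterial_blood_volume=self.arterial_blood_volume * f,
            venous_blood_volume=self.venous_blood_volume * f,
        )


def _load_table(species: str) -> dict:
    ref = resources.files("homopbk.data").joinpath(f"organs_{species}.json")
    return json.loads(ref.read_text())


def build_individual(species: str, overrides: dict | None = None) -> Individual:
    """Build a reference individual with optional overrides.

    Reference values: rat — 0.23 kg, 40 weeks; human — 60 kg, 163 cm,
    30 years. ``overrides`` may set ``body_weight`` (organ volumes, flows,
    cardiac output and GFR rescale isometrically), ``age``, ``height``,
    ``gfr``, ``hematocrit`` or ``cardiac_output``. Implausible overrides are
    kept but logged as warnings; unknown keys raise.
    """
    if species not in SPECIES:
        raise ValidationError(f"unknown species {species!r}; supported: {SPECIES}")
    overrides = dict(overrides or {})
    known = {"body_weight", "age", "height", "gfr", "hematocrit", "cardiac_output"}
    unknown = set(overrides) - known
    if unknown:
        raise ValidationError(f"unknown override keys {sorted(unknown)}")

    table = _load_table(species)
    co = table["cardiac_output_l_per_h"]
    organs = [
        OrganSpec(
            name=row["name"],
            volume=row["volume_ml"],
            blood_flow=row["flow_fraction"] * co,
            vascular_fraction=row["vascular_fraction"],
            interstitial_fraction=row["interstitial_fraction"],
            f_ew=row["f_ew"], f_iw=row["f_iw"],
            f_nl=row["f_nl"], f_np=row["f_np"],
            albumin_ratio=row["albumin_ratio"],
            intracellular_ph=row["intracellular_ph"],
            portal=row["portal"],
        )
        for row in table["organs"]
    ]

    if species == "rat":
        kidney_g = table["gfr_ml_min_per_100g_kidney"]  # per 100 g kidney
        kidney_mass_g = next(o for o in organs if o.name == "kidney").volume  # density ~1
        gfr = kidney_g * kidney_mass_g / 100.0
        height = None
    else:
        gfr = table["gfr_ml_min"]
        height = table["reference_height_cm"]

    ind = Individual(
        species=species,
        body_weight=table["reference_body_weight_kg"],
        age=table["reference_age_years"],
        gfr=gfr,
        hematocrit=table["hematocrit"],
        cardiac_output=co,
        organs=organs,
        arterial_blood_volume=table["arterial_blood_volume_ml"],
        venous_blood_volume=table["venous_blood_volume_ml"],
        height=height,
        body_density=table["body_density_g_per_ml"],
    )

    if "body_weight" in overrides:
        bw = overrides.pop("body_weight")
        lo, hi = PLAUSIBLE_BW[species]
        if not (lo <= bw <= hi):
            log.warning(
                "body_weight override %.3g kg outside plausible %s range "
                "[%.3g, %.3g]; kept", bw, species, lo, hi,
            )
        ind = ind.scaled(bw)
    for key, value in overrides.items():
        ind = dataclasses.replace(ind, **{key: value})
    return ind


def bmi(individual: Individual) -> float:
    """Body-mass index, kg/m². Requires height (human)."""
    if individual.height is None:
        raise UnsupportedOperationError(
            f"BMI undefined for a {individual.species} individual without height"
        )
    h_m = individual.height / 100.0
    return individual.body_weight / (h_m * h_m)
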