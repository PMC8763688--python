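"""Substance parameter sets: physicochemical and binding properties.

The central type is :class:`SubstanceProperties`, covering the inputs a
whole-body kinetic model needs for a small lipophilic molecule: octanol:water
lipophilicity, acid/base ionization, plasma protein binding, partitioning
into blood cells and the membrane permeabilities that control exchange
between vascular, interstitial and intracellular spaces.

Two parameter files for the UV filter homosalate ship with the package:

* ``homosalate`` — literature physicochemical values with the initial
  in vitro plasma binding (Fu 2%).
* ``homosalate_optimized`` — the same physicochemistry with the
  binding/permeability set identified against the legacy rat IV study
  (Fu 1.4%, cellular permeability 4.83 cm/min, endothelial permeability
  1.9 cm/min, blood-cell:plasma coefficient 21.28).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import RangeError, ValidationError

IONIZATION_CLASSES = ("acid", "base", "neutral")


@dataclass(frozen=True)
class SubstanceProperties:
    """Physicochemical and binding parameters of a substance.

    Permeabilities are entered in cm/min (the convention of the source
    assays); the model layer converts internally.
    """

    name: str
    molecular_weight: float          # g/mol
    log_p: float                     # octanol:water, log10
    pka: float
    ionization_class: str            # acid | base | neutral
    fraction_unbound: float          # Fu, fraction of plasma concentration
    blood_cell_plasma_partition: float   # K_bc:pl, unitless
    endothelial_permeability: float      # cm/min, plasma <-> interstitial
    cellular_permeability: float         # cm/min, interstitial <-> intracellular
    plasma_to_blood_cell_permeability: float  # cm/min
    blood_cell_to_plasma_permeability: float  # cm/min
    water_solubility: float | None = None     # mg/L
    melting_point: float | None = None        # degC

    def __post_init__(self) -> None:
        if self.ionization_class not in IONIZATION_CLASSES:
            raise ValidationError(
                f"ionization_class must be one of {IONIZATION_CLASSES}, "
                f"got {self.ionization_class!r}"
            )
        if not (0.0 < self.fraction_unbound <= 1.0):
            raise RangeError(
                f"fraction_unbound must be in (0, 1], got {self.fraction_unbound}"
            )
        if self.molecular_weight <= 0:
            raise RangeError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if self.blood_cell_plasma_partition <= 0:
            raise RangeError(
                "blood_cell_plasma_partition must be > 0, "
                f"got {self.blood_cell_plasma_partition}"
            )
        for field in (
            "endothelial_permeability",
            "cellular_permeability",
            "plasma_to_blood_cell_permeability",
            "blood_cell_to_plasma_permeability",
        ):
            value = getattr(self, field)
            if value < 0:
                raise RangeError(f"{field} must be >= 0, got {value}")

    def replace(self, **changes) -> "SubstanceProperties":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}


_FIELD_NAMES = {f.name for f in dataclasses.fields(SubstanceProperties)}
_MANDATORY = _FIELD_NAMES - {"water_solubility", "melting_point"}


def _from_mapping(data: dict, source: str) -> SubstanceProperties:
    if not isinstance(data, dict):
        raise ValidationError(f"{source}: expected a mapping at top level")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValidationError(
            f"{source}: unknown keys {sorted(unknown)}; "
            f"allowed keys are {sorted(_FIELD_NAMES)}"
        )
    missing = _MANDATORY - set(data)
    if missing:
        raise ValidationError(f"{source}: missing mandatory fields {sorted(missing)}")
    return SubstanceProperties(**data)


def load_substance(path: str | Path) -> SubstanceProperties:
    """Load and validate a substance parameter file (JSON or YAML)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return _from_mapping(data, str(path))


def save_substance(substance: SubstanceProperties, path: str | Path) -> None:
    """Write a substance parameter file; format chosen by extension."""
    path = Path(path)
    data = substance.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def packaged_substance(name: str = "homosalate_optimized") -> SubstanceProperties:
    """Load a substance parameter set shipped with the package.

    ``homosalate`` is the literature/initial set (Fu 2%);
    ``homosalate_optimized`` carries the rat-IV-identified binding and
    permeability values.
    """
    ref = resources.files("homopbk.data").joinpath(f"{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValidationError(f"no packaged substance named {name!r}") from None
    return _from_mapping(json.loads(text), f"packaged:{name}")
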