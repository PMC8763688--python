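"""Tissue distribution: partition coefficients and charge-corrected permeability.

Tissue:plasma-water partitioning follows the steady-state mechanistic model
for weak acids and neutral compounds (the 2006 Rodgers–Rowland formulation):
the unbound partition coefficient Kpu combines

* dissolution in extracellular and intracellular tissue water (the
  intracellular term carries the Henderson–Hasselbalch ionization ratio
  between intracellular and plasma pH),
* partitioning into neutral lipid and neutral phospholipid, scaled by the
  octanol:water partition coefficient P = 10**logP, with the conventional
  (0.3·P + 0.7) phospholipid affinity,
* binding to extravascular albumin, estimated from plasma binding in excess
  of the plasma lipid contribution and the tissue:plasma albumin ratio.

For very lipophilic compounds the plasma lipid term can already account for
all measured plasma binding; the albumin bracket is then clamped at zero
(standard practice for this model class).

Membrane permeability is charge-corrected by the neutral fraction: charged
species are assumed not to permeate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .physiology import Individual, OrganSpec
from .substance import SubstanceProperties
from .units import PLASMA_WATER_FRACTION

#: neutral lipid / neutral phospholipid volume fractions of plasma
F_NL_PLASMA = 0.0023
F_NP_PLASMA = 0.0013

METHOD_TAG = "rodgers-rowland-2006-acid-neutral"


def neutral_fraction(pka: float, ph: float, ionization_class: str) -> float:
    """Henderson–Hasselbalch fraction of the neutral species.

    Acids: 1 / (1 + 10**(pH − pKa)); bases: 1 / (1 + 10**(pKa − pH));
    neutral compounds: 1.
    """
    if ionization_class == "neutral":
        return 1.0
    if ionization_class == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if ionization_class == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    raise ValidationError(f"unknown ionization_class {ionization_class!r}")


def _ionization_ratio(pka: float, ph: float, ionization_class: str) -> float:
    """X = 1 + [ionized]/[neutral] at the given pH (1 for neutrals)."""
    if ionization_class == "neutral":
        return 1.0
    if ionization_class == "acid":
        return 1.0 + 10.0 ** (ph - pka)
    if ionization_class == "base":
        return 1.0 + 10.0 ** (pka - ph)
    raise ValidationError(f"unknown ionization_class {ionization_class!r}")


def compute_kpu(
    substance: SubstanceProperties,
    organ: OrganSpec,
    plasma_ph: float = 7.4,
) -> float:
    """Unbound tissue:plasma-water partition coefficient for one organ."""
    for f in ("f_ew", "f_iw", "f_nl", "f_np", "albumin_ratio"):
        if getattr(organ, f, None) is None:
            raise ValidationError(f"organ {organ.name}: missing composition field {f}")
    p = 10.0 ** substance.log_p
    x = _ionization_ratio(substance.pka, organ.intracellular_ph,
                          substance.ionization_class)
    y = _ionization_ratio(substance.pka, plasma_ph, substance.ionization_class)
    lipid = (p * organ.f_nl + (0.3 * p + 0.7) * organ.f_np) / y
    plasma_lipid = p * F_NL_PLASMA + (0.3 * p + 0.7) * F_NP_PLASMA
    albumin_bracket = max(0.0, 1.0 / substance.fraction_unbound - 1.0 - plasma_lipid)
    kpu = (organ.f_ew + (x / y) * organ.f_iw + lipid
           + albumin_bracket * organ.albumin_ratio)
    return kpu


@dataclass
class PartitionSet:
    """Per-organ partition coefficients with provenance tag.

    ``kpu`` maps organ name → unbound tissue:plasma-water coefficient;
    ``kp`` maps organ name → total tissue:plasma ratio,
    Kp = Kpu · Fu / plasma-water-fraction.
    """

    kpu: dict[str, float]
    kp: dict[str, float]
    fraction_unbound: float
    method: str = METHOD_TAG

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.kpu.items() if v <= 0}
        if bad:
            raise ValidationError(f"non-positive Kpu for organs {sorted(bad)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"method": self.method, "fraction_unbound": self.fraction_unbound,
             "kpu": self.kpu, "kp": self.kp}, indent=2))


def build_partition_set(
    substance: SubstanceProperties,
    individual: Individual,
    plasma_ph: float | None = None,
) -> PartitionSet:
    """Compute the full partition set for an individual's organ table."""
    ph = individual.plasma_ph if plasma_ph is None else plasma_ph
    kpu = {o.name: compute_kpu(substance, o, ph) for o in individual.organs}
    fu = substance.fraction_unbound
    kp = {k: v * fu / PLASMA_WATER_FRACTION for k, v in kpu.items()}
    return PartitionSet(kpu=kpu, kp=kp, fraction_unbound=fu)


def effective_permeability(
    p_neutral: float, substance: SubstanceProperties, ph: float
) -> float:
    """Charge-corrected permeability: neutral fraction × neutral permeability."""
    if p_neutral < 0:
        raise ValidationError("p_neutral must be >= 0")
    return neutral_fraction(substance.pka, ph, substance.ionization_class) * p_neutral
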