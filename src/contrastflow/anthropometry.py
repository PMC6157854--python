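"""Patient representation and blood-volume / body-size computations.

Total blood volume (BV, litres) is estimated from sex, height and weight with
the classical Nadler regression formulas.  BV is the "patient factor" that the
dosing model scales contrast flow by: a larger circulating volume dilutes the
injected iodine more, so a larger patient needs a higher flow rate to reach the
same intravascular attenuation.

Heights are metres throughout.  The Nadler coefficients (0.3669 / 0.3561 on
the cubed height term) are the metre-based ones; feeding centimetres into them
produces blood volumes three orders of magnitude too large.  The CLI accepts
centimetre input for operator convenience and normalises it on entry.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ValidationError

__all__ = [
    "Sex",
    "Patient",
    "BloodVolume",
    "nadler_formula",
    "nadler_blood_volume",
    "bmi",
    "normalize_height",
    "read_patients_csv",
    "write_patients_csv",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        """Accept ``M``/``F``, ``male``/``female`` (any case) or a Sex member."""
        if isinstance(value, Sex):
            return value
        token = str(value).strip().lower()
        if token in ("m", "male", "man", "men"):
            return cls.MALE
        if token in ("f", "female", "woman", "women"):
            return cls.FEMALE
        raise ValidationError(f"sex: cannot interpret {value!r} (expected M/F)")


# Plausibility windows used to reject data-entry errors before dosing.
HEIGHT_RANGE_M = (0.5, 2.5)
WEIGHT_RANGE_KG = (20.0, 250.0)
HEART_RATE_RANGE_BPM = (30.0, 220.0)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo < value < hi):
        raise ValidationError(f"{name}: {value} outside plausible range ({lo}, {hi})")


@dataclass(frozen=True)
class Patient:
    """An adult patient referred for contrast-enhanced coronary CT.

    Parameters
    ----------
    sex : Sex
        Biological sex; selects the Nadler formula variant.
    height : float
        Standing height in metres.
    weight : float
        Body weight in kilograms.
    heart_rate : float, optional
        Resting heart rate in beats per minute.  Needed to pick the scan
        mode; may be omitted when the mode is chosen explicitly.
    pacemaker : bool
        Pacemaker carriers are scanned at a fixed 120 kV to avoid lead
        artefacts, bypassing automated voltage selection.
    """

    sex: Sex
    height: float
    weight: float
    heart_rate: float | None = None
    pacemaker: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        _check_range("height", self.height, *HEIGHT_RANGE_M)
        _check_range("weight", self.weight, *WEIGHT_RANGE_KG)
        if self.heart_rate is not None:
            _check_range("heart_rate", self.heart_rate, *HEART_RATE_RANGE_BPM)


@dataclass(frozen=True)
class BloodVolume:
    """Estimated total blood volume in litres, tagged with its formula."""

    value: float
    formula_id: str = field(default="nadler_male")

    def __post_init__(self) -> None:
        if not (0.0 < self.value < 12.0):
            raise ValidationError(
                f"blood volume: {self.value} L outside plausible range (0, 12)"
            )


# (a, b, c) in BV = a*h^3 + b*w + c, h in metres, w in kilograms.
NADLER_COEFFICIENTS: dict[Sex, tuple[float, float, float]] = {
    Sex.MALE: (0.3669, 0.03219, 0.6041),
    Sex.FEMALE: (0.3561, 0.03308, 0.1833),
}


def nadler_formula(sex: Sex, height_m: float, weight_kg: float) -> float:
    """Raw Nadler regression, litres; no range validation.

    BV = 0.3669·h³ + 0.03219·w + 0.6041 (men)
    BV = 0.3561·h³ + 0.03308·w + 0.1833 (women)
    """
    a, b, c = NADLER_COEFFICIENTS[Sex.parse(sex)]
    return a * height_m**3 + b * weight_kg + c


def nadler_blood_volume(patient: Patient) -> BloodVolume:
    """Sex-matched Nadler blood volume of a validated patient."""
    value = nadler_formula(patient.sex, patient.height, patient.weight)
    formula_id = "nadler_male" if patient.sex is Sex.MALE else "nadler_female"
    return BloodVolume(value=value, formula_id=formula_id)


def bmi(patient: Patient) -> float:
    """Body-mass index, kg/m²."""
    return patient.weight / patient.height**2


def normalize_height(value: float) -> float:
    """Interpret heights > 3 as centimetres and convert to metres."""
    return value / 100.0 if value > 3.0 else value


_CSV_COLUMNS = ["id", "sex", "height_m", "weight_kg", "heart_rate_bpm", "pacemaker"]


def read_patients_csv(path: str | Path) -> list[tuple[str, Patient]]:
    """Read ``id,sex,height_m,weight_kg,heart_rate_bpm,pacemaker`` records.

    The header is required; sex is ``M``/``F``; an empty heart-rate field is
    allowed.  Returns ``(id, Patient)`` pairs in file order.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS[:4]) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"patient CSV missing columns: {sorted(missing)}")
        records: list[tuple[str, Patient]] = []
        for row in reader:
            hr_raw = (row.get("heart_rate_bpm") or "").strip()
            pm_raw = (row.get("pacemaker") or "").strip().lower()
            patient = Patient(
                sex=Sex.parse(row["sex"]),
                height=normalize_height(float(row["height_m"])),
                weight=float(row["weight_kg"]),
                heart_rate=float(hr_raw) if hr_raw else None,
                pacemaker=pm_raw in ("1", "true", "yes"),
            )
            records.append((row["id"], patient))
    return records


def write_patients_csv(path: str | Path, records: Iterable[tuple[str, Patient]]) -> None:
    """Inverse of :func:`read_patients_csv`."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for pid, p in records:
            writer.writerow(
                [
                    pid,
                    "M" if p.sex is Sex.MALE else "F",
                    f"{p.height:.3f}",
                    f"{p.weight:.1f}",
                    "" if p.heart_rate is None else f"{p.heart_rate:.1f}",
                    int(p.pacemaker),
                ]
            )
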