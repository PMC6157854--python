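"""First-pass pharmacokinetic attenuation model and the personalised flow rule.

The injected contrast bolus is modelled as a single well-mixed compartment:
iodine enters at rate F·Ic (flow × agent concentration) and is washed out by
cardiac output CO from a mixing volume V, giving the blood concentration

    c(t) = (F·Ic / CO) · (1 − exp(−CO·t / V))        [mgI/mL]

Intravascular attenuation is proportional to concentration (HU = k·c) and
inversely proportional to tube voltage, and the estimated blood volume BV
enters as the dilution ("patient") factor:

    HU(kVp) = k · F · Ic / (kVp · BV)

The model is anchored to a reference patient (male, 1.80 m, 80 kg, scanned at
120 kV with a 7.0 mL/s flow producing 350 HU).  Solving the anchor for k and
for the flow rule's proportionality constant yields the personalised flow

    F = c_cal · BV · kVp,   c_cal = F_ref / (BV_ref · kV_ref) ≈ 0.010966

so that every patient, at their selected voltage, is predicted to reach the
same 350 HU target (a safety margin above the 300 HU diagnostic threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .anthropometry import BloodVolume, Patient, Sex, nadler_blood_volume
from .errors import CalibrationError, ValidationError

__all__ = [
    "PKParameters",
    "CalibrationAnchor",
    "FlowCalibration",
    "REFERENCE_ANCHOR",
    "DEFAULT_CARDIAC_OUTPUT",
    "DEFAULT_MIXING_VOLUME",
    "PRINTED_FLOW_CONSTANT",
    "VALID_KV",
    "concentration_at_time",
    "predicted_attenuation",
    "calibrate",
    "flow_rate",
    "default_calibration",
    "printed_flow_calibration",
]

logger = logging.getLogger(__name__)

#: Nominal haemodynamic defaults for exercising the concentration curve.
#: They do not enter the flow rule, which is anchored independently.
DEFAULT_CARDIAC_OUTPUT = 90.0  # mL/s
DEFAULT_MIXING_VOLUME = 100.0  # mL

#: Tube voltages selectable on the scanner (automated selection steps).
VALID_KV = (70.0, 80.0, 90.0, 100.0, 110.0, 120.0)

#: Literal constant of the nominal worksheet formulation of the flow rule.
#: Dimensionally inconsistent with the reference anchor (gives 0.13 mL/s for
#: the reference patient instead of 7.0); retained for auditing only.
PRINTED_FLOW_CONSTANT = 2.0e-4


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name}: must be strictly positive, got {value}")


@dataclass(frozen=True)
class PKParameters:
    """Parameters of the concentration/attenuation model.

    flow F (mL/s), iodine_concentration Ic (mgI/mL), cardiac_output CO (mL/s),
    mixing_volume V (mL) and the calibrated attenuation constant k (HU per
    calibrated concentration term; ``None`` until calibrated).
    """

    flow: float
    iodine_concentration: float
    cardiac_output: float = DEFAULT_CARDIAC_OUTPUT
    mixing_volume: float = DEFAULT_MIXING_VOLUME
    attenuation_constant: float | None = None

    def __post_init__(self) -> None:
        _require_positive("flow", self.flow)
        _require_positive("iodine_concentration", self.iodine_concentration)
        _require_positive("cardiac_output", self.cardiac_output)
        _require_positive("mixing_volume", self.mixing_volume)
        if self.attenuation_constant is not None:
            _require_positive("attenuation_constant", self.attenuation_constant)


@dataclass(frozen=True)
class CalibrationAnchor:
    """The reference patient that pins down the model constants."""

    height: float = 1.80  # m
    weight: float = 80.0  # kg
    sex: Sex = Sex.MALE
    kv: float = 120.0
    flow: float = 7.0  # mL/s
    target_hu: float = 350.0
    idr: float = 2.1  # gI/s


REFERENCE_ANCHOR = CalibrationAnchor()


@dataclass(frozen=True)
class FlowCalibration:
    """Proportionality constant of F = c_cal · BV · kVp (mL·s⁻¹ per L·kV)."""

    constant: float
    source: str = "reference_anchor"

    def __post_init__(self) -> None:
        _require_positive("flow calibration constant", self.constant)


def concentration_at_time(t: float, p: PKParameters) -> float:
    """Blood iodine concentration (mgI/mL) at time t seconds after injection start.

    Monotone non-decreasing in t, bounded above by the plateau F·Ic/CO.
    """
    if t < 0:
        raise ValidationError(f"t: injection time must be non-negative, got {t}")
    plateau = p.flow * p.iodine_concentration / p.cardiac_output
    return plateau * (1.0 - math.exp(-p.cardiac_output * t / p.mixing_volume))


def predicted_attenuation(
    flow: float, kv: float, bv: BloodVolume | float, p: PKParameters
) -> float:
    """Predicted intravascular attenuation (HU) of a first-pass scan.

    HU = k · F · Ic / (kVp · BV); linear in flow, inverse in voltage and in
    blood volume.  Requires a calibrated attenuation constant.
    """
    if p.attenuation_constant is None:
        raise CalibrationError(
            "calibration required: attenuation constant k is not set "
            "(run calibrate() against a reference anchor first)"
        )
    bv_l = bv.value if isinstance(bv, BloodVolume) else float(bv)
    _require_positive("blood volume", bv_l)
    _require_positive("kv", kv)
    return p.attenuation_constant * flow * p.iodine_concentration / (kv * bv_l)


def calibrate(
    anchor: CalibrationAnchor, iodine_concentration: float
) -> tuple[float, FlowCalibration]:
    """Solve the anchor for the attenuation constant k and the flow constant.

    Returns ``(k, FlowCalibration)`` such that the anchor patient, at the
    anchor voltage and flow, is predicted to reach exactly ``target_hu``, and
    ``flow_rate`` reproduces the anchor flow.

    Raises
    ------
    CalibrationError
        If the anchor's stated iodine delivery rate disagrees with
        flow × Ic / 1000, or the target attenuation is non-positive.
    """
    _require_positive("iodine_concentration", iodine_concentration)
    if anchor.target_hu <= 0:
        raise CalibrationError(
            f"degenerate anchor: target attenuation must be positive, got {anchor.target_hu}"
        )
    implied_idr = anchor.flow * iodine_concentration / 1000.0
    if abs(implied_idr - anchor.idr) > 1e-6:
        raise CalibrationError(
            "inconsistent anchor: stated IDR "
            f"{anchor.idr} gI/s != flow × Ic/1000 = {implied_idr} gI/s"
        )
    patient = Patient(sex=anchor.sex, height=anchor.height, weight=anchor.weight)
    bv = nadler_blood_volume(patient)
    c_cal = anchor.flow / (bv.value * anchor.kv)
    k = anchor.target_hu * anchor.kv * bv.value / (anchor.flow * iodine_concentration)
    return k, FlowCalibration(constant=c_cal, source="reference_anchor")


def flow_rate(
    bv: BloodVolume | float,
    kv: float,
    cal: FlowCalibration,
    *,
    allow_any_kv: bool = False,
    round_to: float | None = 0.1,
) -> float:
    """Personalised contrast flow rate F = c_cal · BV · kVp, in mL/s.

    Rounded to injector granularity (0.1 mL/s) by default; pass
    ``round_to=None`` for the exact value.  ``kv`` must be one of the
    scanner's selectable steps unless ``allow_any_kv`` is set.
    """
    bv_l = bv.value if isinstance(bv, BloodVolume) else float(bv)
    _require_positive("blood volume", bv_l)
    if not allow_any_kv and float(kv) not in VALID_KV:
        raise ValidationError(
            f"kv: {kv} not a selectable tube voltage {VALID_KV}; "
            "pass allow_any_kv=True to override"
        )
    f = cal.constant * bv_l * kv
    if round_to is not None:
        f = round(f / round_to) * round_to
    return f


def default_calibration(iodine_concentration: float = 300.0) -> tuple[float, FlowCalibration]:
    """Calibrate against the built-in reference anchor (300 mgI/mL agent)."""
    return calibrate(REFERENCE_ANCHOR, iodine_concentration)


def printed_flow_calibration() -> FlowCalibration:
    """The literal 0.0002 constant of the nominal worksheet formulation.

    Emits a warning: it is dimensionally inconsistent with the reference
    anchor and produces clinically implausible flows; use only for audits.
    """
    logger.warning(
        "Using the literal flow constant 0.0002: it does not reproduce the "
        "reference anchor (gives %.3f mL/s instead of 7.0) and is provided "
        "for auditability only.",
        PRINTED_FLOW_CONSTANT * 5.319 * 120,
    )
    return FlowCalibration(constant=PRINTED_FLOW_CONSTANT, source="printed")
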