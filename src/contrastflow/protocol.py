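"""Injection-protocol generation: patient + scan mode + kV → complete protocol.

Re-implements the locked dosing worksheet used at the scanner console: the
personalised flow rate is multiplied by the (mode-determined) scan time to give
the main bolus volume, and a short fixed-duration pre-injection gives the test
bolus used for scan-delay timing.  Iodine delivery rate (IDR, gI/s) and total
iodine load (TIL, gI) are bookkeeping derived from the flow and main bolus;
TIL deliberately excludes the test bolus.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import pandas as pd

from .anthropometry import Patient, Sex, nadler_blood_volume
from .errors import OutOfScopeError, ValidationError
from .pk import FlowCalibration, flow_rate

__all__ = [
    "ScanMode",
    "ScanProtocol",
    "ContrastAgent",
    "IOPROMIDE_300",
    "InjectionProtocol",
    "DEFAULT_SCAN_TIMES",
    "DEFAULT_TEST_BOLUS_DURATION",
    "DEFAULT_MAX_FLOW",
    "assign_scan_mode",
    "generate_protocol",
    "protocol_record",
    "protocol_table",
]

logger = logging.getLogger(__name__)


class ScanMode(str, enum.Enum):
    HIGH_PITCH = "high_pitch"
    ADAPTIVE_SEQUENCE = "adaptive_sequence"


#: Acquisition durations of the two prospectively ECG-triggered modes.
DEFAULT_SCAN_TIMES: dict[ScanMode, float] = {
    ScanMode.HIGH_PITCH: 8.0,
    ScanMode.ADAPTIVE_SEQUENCE: 10.0,
}

#: Test-bolus duration in seconds (test volume = flow × this duration).
DEFAULT_TEST_BOLUS_DURATION = 2.1

#: Flow above which an 18–22 G cannula becomes a safety concern.
DEFAULT_MAX_FLOW = 7.5


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition mode, tube voltage and scan time."""

    mode: ScanMode
    kv: float
    scan_time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ScanMode(self.mode))
        if self.scan_time is None:
            object.__setattr__(self, "scan_time", DEFAULT_SCAN_TIMES[self.mode])
        if not self.scan_time > 0:
            raise ValidationError(f"scan_time: must be positive, got {self.scan_time}")


@dataclass(frozen=True)
class ContrastAgent:
    """An iodinated contrast agent; concentration in mgI/mL."""

    name: str
    iodine_concentration: float

    def __post_init__(self) -> None:
        if not (100.0 < self.iodine_concentration <= 450.0):
            raise ValidationError(
                f"iodine_concentration: {self.iodine_concentration} mgI/mL "
                "outside (100, 450]"
            )


IOPROMIDE_300 = ContrastAgent(name="iopromide", iodine_concentration=300.0)


@dataclass(frozen=True)
class InjectionProtocol:
    """A complete personalised injection prescription.

    Volumes in mL (rounded to 0.1, injector granularity), flow in mL/s,
    times in s, IDR in gI/s, TIL in gI (main bolus only).  ``warnings``
    carries non-fatal safety notes (e.g. flow above the cannula limit).
    """

    flow: float
    test_bolus: float
    main_bolus: float
    injection_time: float
    idr: float
    til: float
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("flow", "test_bolus", "main_bolus", "injection_time", "idr", "til"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name}: must be positive")
        if abs(self.main_bolus - self.flow * self.injection_time) > 0.1:
            raise ValidationError(
                "main_bolus inconsistent with flow × injection_time: "
                f"{self.main_bolus} vs {self.flow * self.injection_time}"
            )


def assign_scan_mode(heart_rate: float | None) -> ScanMode:
    """Heart-rate rule for the acquisition mode.

    ≤ 70 bpm → high pitch; 70–90 bpm → adaptive sequence.  Above 90 bpm the
    site used a retrospective helical protocol that this package does not
    model; a missing heart rate requires an explicit mode choice.
    """
    if heart_rate is None:
        raise ValidationError(
            "heart_rate missing: choose the scan mode explicitly "
            "(high_pitch or adaptive_sequence)"
        )
    if heart_rate > 90.0:
        raise OutOfScopeError(
            f"heart rate {heart_rate} bpm > 90: helical protocol, out of scope"
        )
    return ScanMode.HIGH_PITCH if heart_rate <= 70.0 else ScanMode.ADAPTIVE_SEQUENCE


def generate_protocol(
    patient: Patient,
    scan: ScanProtocol,
    agent: ContrastAgent,
    cal: FlowCalibration,
    *,
    test_bolus_duration: float = DEFAULT_TEST_BOLUS_DURATION,
    injection_time_buffer: float = 0.0,
    max_flow: float = DEFAULT_MAX_FLOW,
) -> InjectionProtocol:
    """Compute the full injection protocol for one patient and scan.

    Flow comes from the calibrated rule F = c_cal·BV·kV; the injection time
    equals the scan time (plus an optional site buffer); the main bolus is
    flow × injection time.  Volumes and flow are rounded to 0.1; IDR and TIL
    are kept at full precision (round only for display).
    """
    bv = nadler_blood_volume(patient)
    kv_override = patient.pacemaker  # fixed 120 kV path bypasses the whitelist
    flow = flow_rate(bv, scan.kv, cal, allow_any_kv=kv_override)
    injection_time = scan.scan_time + injection_time_buffer
    main_bolus = round(flow * injection_time, 1)
    test_bolus = round(flow * test_bolus_duration, 1)
    warnings: tuple[str, ...] = ()
    if flow > max_flow:
        warnings = (
            f"flow {flow:.1f} mL/s exceeds the {max_flow:.1f} mL/s cannula "
            "safety limit (18-22 G)",
        )
        logger.warning(warnings[0])
    return InjectionProtocol(
        flow=flow,
        test_bolus=test_bolus,
        main_bolus=main_bolus,
        injection_time=injection_time,
        idr=flow * agent.iodine_concentration / 1000.0,
        til=main_bolus * agent.iodine_concentration / 1000.0,
        warnings=warnings,
    )


def protocol_record(
    patient_id: str,
    patient: Patient,
    scan: ScanProtocol,
    protocol: InjectionProtocol,
) -> dict:
    """Flat record for tabular output; TIL/IDR rounded to reporting precision."""
    bv = nadler_blood_volume(patient)
    return {
        "id": patient_id,
        "sex": "M" if patient.sex is Sex.MALE else "F",
        "mode": scan.mode.value,
        "kv": scan.kv,
        "bv_l": round(bv.value, 3),
        "flow_ml_s": round(protocol.flow, 1),
        "test_bolus_ml": round(protocol.test_bolus, 1),
        "main_bolus_ml": round(protocol.main_bolus, 1),
        "injection_time_s": protocol.injection_time,
        "idr_gi_s": round(protocol.idr, 1),
        "til_g": round(protocol.til, 1),
    }


_TABLE_COLUMNS = [
    "flow_ml_s",
    "test_bolus_ml",
    "main_bolus_ml",
    "til_g",
    "idr_gi_s",
    "injection_time_s",
]


def protocol_table(
    patients: "list[Patient] | list[tuple[str, Patient]]",
    scans: "ScanProtocol | list[ScanProtocol]",
    agent: ContrastAgent,
    cal: FlowCalibration,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Group-wise protocol summary: mean and [min–max] by mode × kV × sex.

    ``scans`` may be a single protocol applied to every patient or a list
    paired element-wise with ``patients``.  Groups with no members simply do
    not appear.  Rows are ordered by (mode, kv, sex).
    """
    if not patients:
        raise ValidationError("patients: empty input")
    norm: list[tuple[str, Patient]] = [
        p if isinstance(p, tuple) else (str(i), p) for i, p in enumerate(patients)
    ]
    if isinstance(scans, ScanProtocol):
        scan_list = [scans] * len(norm)
    else:
        if len(scans) != len(norm):
            raise ValidationError(
                f"scans: expected 1 or {len(norm)} entries, got {len(scans)}"
            )
        scan_list = list(scans)
    rows = []
    for (pid, patient), scan in zip(norm, scan_list):
        proto = generate_protocol(patient, scan, agent, cal, **protocol_kwargs)
        rows.append(protocol_record(pid, patient, scan, proto))
    df = pd.DataFrame(rows)
    grouped = df.groupby(["mode", "kv", "sex"], sort=False)[_TABLE_COLUMNS]
    summary = grouped.agg(["mean", "min", "max"])
    summary.columns = [f"{col}_{stat}" for col, stat in summary.columns]
    summary = summary.reset_index()
    mode_order = {ScanMode.HIGH_PITCH.value: 0, ScanMode.ADAPTIVE_SEQUENCE.value: 1}
    summary = summary.sort_values(
        by=["mode", "kv", "sex"],
        key=lambda s: s.map(mode_order) if s.name == "mode" else s,
    ).reset_index(drop=True)
    return summary
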