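"""Objective image quality: attenuation, noise, CNR/SNR, per-segment bookkeeping.

Measurements follow the convention of intravascular region-of-interest (ROI)
analysis on coronary CTA: image noise is the standard deviation of the
intravascular attenuation; CNR = (vessel − epicardial fat) / fat SD;
SNR = vessel / vessel SD.  Diagnostic flags use an intravascular threshold of
300 HU (inclusive) and CNR > 10 (strict).

Coronary segments follow the 17-segment AHA model; the synthetic ROI
generator draws per-segment attenuation around the pharmacokinetic model's
predicted value and marks distal segments non-assessable with configurable
dropout probabilities.
"""

from __future__ import annotations

import warnings as _warnings
import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .anthropometry import BloodVolume
from .errors import ValidationError
from .pk import PKParameters, predicted_attenuation
from .protocol import InjectionProtocol

__all__ = [
    "VESSEL_BY_SEGMENT",
    "RoiMeasurement",
    "SegmentIQ",
    "IqThresholds",
    "RoiNoiseConfig",
    "DEFAULT_DROPOUT",
    "cnr",
    "snr",
    "classify",
    "simulate_roi_set",
    "cohort_iq_summary",
    "read_segments_csv",
]

#: AHA 17-segment → coronary vessel assignment (RI = ramus intermedius).
VESSEL_BY_SEGMENT: dict[int, str] = {
    1: "RCA", 2: "RCA", 3: "RCA", 4: "RCA",
    5: "LM",
    6: "LAD", 7: "LAD", 8: "LAD", 9: "LAD", 10: "LAD",
    11: "Cx", 12: "Cx", 13: "Cx", 14: "Cx", 15: "Cx",
    16: "RCA",
    17: "RI",
}

#: Per-segment non-assessability probabilities.  Distal/side-branch segments
#: carry the observed dropout rates; unlisted segments default to 1%.
DEFAULT_DROPOUT: dict[int, float] = {
    4: 0.061, 9: 0.105, 10: 0.079, 12: 0.132, 13: 0.044, 14: 0.132,
}
_BASELINE_DROPOUT = 0.01


@dataclass(frozen=True)
class RoiMeasurement:
    """One segment's ROI statistics, all in HU."""

    vessel_mean: float
    vessel_sd: float  # image noise
    fat_mean: float
    fat_sd: float

    def __post_init__(self) -> None:
        if not self.vessel_sd > 0:
            raise ValidationError(f"vessel_sd: must be positive, got {self.vessel_sd}")
        if not self.fat_sd > 0:
            raise ValidationError(f"fat_sd: must be positive, got {self.fat_sd}")


@dataclass(frozen=True)
class SegmentIQ:
    """Quality record of one AHA segment; cnr/snr present iff assessable."""

    segment_id: int
    vessel: str
    roi: RoiMeasurement | None = None
    cnr: float | None = None
    snr: float | None = None
    assessable: bool = False
    diagnostic_attenuation: bool = False
    diagnostic_cnr: bool = False
    likert: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.segment_id <= 17:
            raise ValidationError(f"segment_id: {self.segment_id} outside [1, 17]")
        if self.assessable and (self.cnr is None or self.snr is None):
            raise ValidationError("assessable segment must carry cnr and snr")
        if not self.assessable and (self.cnr is not None or self.snr is not None):
            raise ValidationError("non-assessable segment must not carry cnr/snr")


@dataclass(frozen=True)
class IqThresholds:
    """Diagnostic cut-offs: attenuation ≥ 300 HU, CNR > 10."""

    attenuation_min: float = 300.0
    cnr_min: float = 10.0

    def __post_init__(self) -> None:
        if self.attenuation_min <= 0 or self.cnr_min <= 0:
            raise ValidationError("thresholds must be positive")


def cnr(roi: RoiMeasurement) -> float:
    """Contrast-to-noise ratio: (vessel − fat) / fat SD."""
    return (roi.vessel_mean - roi.fat_mean) / roi.fat_sd


def snr(roi: RoiMeasurement) -> float:
    """Signal-to-noise ratio: vessel / vessel SD."""
    return roi.vessel_mean / roi.vessel_sd


def classify(seg: SegmentIQ, th: IqThresholds = IqThresholds()) -> SegmentIQ:
    """Pure, idempotent diagnostic flagging of one segment.

    Attenuation uses an inclusive boundary (300.0 HU is diagnostic); CNR uses
    a strict one (CNR = 10.0 is not).  Non-assessable segments get both flags
    cleared.
    """
    if not seg.assessable or seg.roi is None:
        return replace(seg, diagnostic_attenuation=False, diagnostic_cnr=False)
    return replace(
        seg,
        diagnostic_attenuation=seg.roi.vessel_mean >= th.attenuation_min,
        diagnostic_cnr=(seg.cnr if seg.cnr is not None else cnr(seg.roi)) > th.cnr_min,
    )


@dataclass(frozen=True)
class RoiNoiseConfig:
    """Generative priors for synthetic ROI statistics (all HU).

    ``attenuation_sd`` is the between-segment scatter around the predicted
    intravascular attenuation; ``noise_mean/sd`` parametrise the image noise
    (vessel SD); fat attenuation is drawn around −80 HU and the fat-ROI SD
    around 30 HU, giving CNR values in the mid-teens at ~350 HU vessels.
    """

    attenuation_sd: float = 43.0
    noise_mean: float = 42.0
    noise_sd: float = 6.0
    fat_mean: float = -80.0
    fat_spread: float = 15.0
    fat_noise_mean: float = 30.0
    fat_noise_sd: float = 5.0
    dropout: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    baseline_dropout: float = _BASELINE_DROPOUT

    def dropout_for(self, segment_id: int) -> float:
        return float(self.dropout.get(segment_id, self.baseline_dropout))


_MIN_SD = 1.0  # floor keeping simulated ROI SDs physically meaningful


def simulate_roi_set(
    protocol: InjectionProtocol,
    kv: float,
    bv: BloodVolume | float,
    p: PKParameters,
    noise: RoiNoiseConfig = RoiNoiseConfig(),
    seed: "int | np.random.Generator | None" = None,
    thresholds: IqThresholds = IqThresholds(),
) -> list[SegmentIQ]:
    """Synthetic per-segment ROI statistics for one scanned patient.

    Returns the 17 AHA segments in order.  Segment attenuation is drawn
    Normal(predicted HU, attenuation_sd); a dropped-out segment is returned
    non-assessable with no ROI.  Fully reproducible from ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    predicted = predicted_attenuation(protocol.flow, kv, bv, p)
    segments: list[SegmentIQ] = []
    for seg_id in range(1, 18):
        vessel = VESSEL_BY_SEGMENT[seg_id]
        if rng.random() < noise.dropout_for(seg_id):
            segments.append(SegmentIQ(segment_id=seg_id, vessel=vessel))
            continue
        roi = RoiMeasurement(
            vessel_mean=float(rng.normal(predicted, noise.attenuation_sd)),
            vessel_sd=float(max(rng.normal(noise.noise_mean, noise.noise_sd), _MIN_SD)),
            fat_mean=float(rng.normal(noise.fat_mean, noise.fat_spread)),
            fat_sd=float(max(rng.normal(noise.fat_noise_mean, noise.fat_noise_sd), _MIN_SD)),
        )
        seg = SegmentIQ(
            segment_id=seg_id,
            vessel=vessel,
            roi=roi,
            cnr=cnr(roi),
            snr=snr(roi),
            assessable=True,
        )
        segments.append(classify(seg, thresholds))
    return segments


def cohort_iq_summary(
    segments_by_patient: Mapping[str, Sequence[SegmentIQ]],
    thresholds: IqThresholds = IqThresholds(),
) -> dict:
    """Cohort-level aggregation of per-segment quality records.

    A patient's "overall" attenuation/CNR/SNR is the unweighted mean across
    their assessable segments; patients with none are excluded with a
    warning.  Returns patient- and segment-level diagnostic fractions.
    """
    if not segments_by_patient:
        raise ValidationError("segments_by_patient: empty input")
    per_patient: dict[str, dict] = {}
    n_segments = 0
    n_assessable = 0
    n_diag_hu = 0
    n_diag_cnr = 0
    for pid, segs in segments_by_patient.items():
        n_segments += len(segs)
        assessable = [s for s in segs if s.assessable and s.roi is not None]
        n_assessable += len(assessable)
        n_diag_hu += sum(s.diagnostic_attenuation for s in assessable)
        n_diag_cnr += sum(s.diagnostic_cnr for s in assessable)
        if not assessable:
            _warnings.warn(
                f"patient {pid}: no assessable segments, excluded from "
                "patient-level summary",
                stacklevel=2,
            )
            continue
        per_patient[pid] = {
            "overall_attenuation_hu": float(np.mean([s.roi.vessel_mean for s in assessable])),
            "overall_cnr": float(np.mean([s.cnr for s in assessable])),
            "overall_snr": float(np.mean([s.snr for s in assessable])),
            "n_assessable": len(assessable),
        }
    overall_hu = np.array([v["overall_attenuation_hu"] for v in per_patient.values()])
    return {
        "n_patients": len(per_patient),
        "n_segments": n_segments,
        "segment_assessable_fraction": n_assessable / n_segments if n_segments else 0.0,
        "segment_diagnostic_attenuation_fraction": (
            n_diag_hu / n_assessable if n_assessable else 0.0
        ),
        "segment_diagnostic_cnr_fraction": (
            n_diag_cnr / n_assessable if n_assessable else 0.0
        ),
        "patient_diagnostic_fraction": (
            float(np.mean(overall_hu >= thresholds.attenuation_min)) if overall_hu.size else 0.0
        ),
        "mean_overall_attenuation_hu": float(np.mean(overall_hu)) if overall_hu.size else None,
        "mean_overall_cnr": (
            float(np.mean([v["overall_cnr"] for v in per_patient.values()])) if per_patient else None
        ),
        "mean_overall_snr": (
            float(np.mean([v["overall_snr"] for v in per_patient.values()])) if per_patient else None
        ),
        "per_patient": per_patient,
    }


def read_segments_csv(
    path: str | Path, thresholds: IqThresholds = IqThresholds()
) -> dict[str, list[SegmentIQ]]:
    """Read ``patient_id,segment_id,vessel,vessel_mean_hu,vessel_sd_hu,
    fat_mean_hu,fat_sd_hu,likert`` records into classified segments.

    Empty ROI fields mark a segment non-assessable.  Likert grades, when
    present, are stored verbatim; they are never generated by this package.
    """
    out: dict[str, list[SegmentIQ]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pid = row["patient_id"]
            seg_id = int(row["segment_id"])
            vessel = row.get("vessel") or VESSEL_BY_SEGMENT[seg_id]
            likert_raw = (row.get("likert") or "").strip()
            likert = int(likert_raw) if likert_raw else None
            vm = (row.get("vessel_mean_hu") or "").strip()
            if not vm:
                seg = SegmentIQ(segment_id=seg_id, vessel=vessel, likert=likert)
            else:
                roi = RoiMeasurement(
                    vessel_mean=float(vm),
                    vessel_sd=float(row["vessel_sd_hu"]),
                    fat_mean=float(row["fat_mean_hu"]),
                    fat_sd=float(row["fat_sd_hu"]),
                )
                seg = classify(
                    SegmentIQ(
                        segment_id=seg_id,
                        vessel=vessel,
                        roi=roi,
                        cnr=cnr(roi),
                        snr=snr(roi),
                        assessable=True,
                        likert=likert,
                    ),
                    thresholds,
                )
            out.setdefault(pid, []).append(seg)
    return out
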