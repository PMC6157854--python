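"""YAML/JSON run configuration: calibration anchor, agent, dosing options.

Schema (all blocks optional; omitted fields take the built-in defaults)::

    anchor:
      height_m: 1.80
      weight_kg: 80.0
      sex: M
      kv: 120
      flow_ml_s: 7.0
      target_hu: 350
    agent:
      name: iopromide
      iodine_mg_ml: 300
    flow_constant: reference_anchor   # or: printed (literal 0.0002, audit only)
    test_bolus_duration_s: 2.1
    injection_time_buffer_s: 0.0
    max_flow_ml_s: 7.5
    cohort:                           # any CohortConfig field name
      n_male: 55
      n_female: 59
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .anthropometry import Sex, normalize_height
from .cohort import CohortConfig
from .errors import ValidationError
from .pk import (
    CalibrationAnchor,
    FlowCalibration,
    calibrate,
    printed_flow_calibration,
)
from .protocol import (
    DEFAULT_MAX_FLOW,
    DEFAULT_TEST_BOLUS_DURATION,
    IOPROMIDE_300,
    ContrastAgent,
)

__all__ = ["RunConfig", "load_config", "calibration_from_config"]


@dataclass(frozen=True)
class RunConfig:
    anchor: CalibrationAnchor = CalibrationAnchor()
    agent: ContrastAgent = IOPROMIDE_300
    flow_constant_source: str = "reference_anchor"
    test_bolus_duration: float = DEFAULT_TEST_BOLUS_DURATION
    injection_time_buffer: float = 0.0
    max_flow: float = DEFAULT_MAX_FLOW
    cohort: CohortConfig = CohortConfig()

    @property
    def protocol_kwargs(self) -> dict:
        return {
            "test_bolus_duration": self.test_bolus_duration,
            "injection_time_buffer": self.injection_time_buffer,
            "max_flow": self.max_flow,
        }


def _build_anchor(block: dict, iodine: float) -> CalibrationAnchor:
    kv = float(block.get("kv", 120.0))
    flow = float(block.get("flow_ml_s", 7.0))
    return CalibrationAnchor(
        height=normalize_height(float(block.get("height_m", 1.80))),
        weight=float(block.get("weight_kg", 80.0)),
        sex=Sex.parse(block.get("sex", "M")),
        kv=kv,
        flow=flow,
        target_hu=float(block.get("target_hu", 350.0)),
        idr=flow * iodine / 1000.0,
    )


def load_config(path: "str | Path | None" = None) -> RunConfig:
    """Load a run configuration; ``None`` returns the built-in defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: expected a mapping at top level")

    agent_block = raw.get("agent", {})
    agent = ContrastAgent(
        name=str(agent_block.get("name", IOPROMIDE_300.name)),
        iodine_concentration=float(
            agent_block.get("iodine_mg_ml", IOPROMIDE_300.iodine_concentration)
        ),
    )
    anchor = _build_anchor(raw.get("anchor", {}), agent.iodine_concentration)

    source = str(raw.get("flow_constant", "reference_anchor"))
    if source not in ("reference_anchor", "printed"):
        raise ValidationError(
            f"flow_constant: {source!r} not one of 'reference_anchor', 'printed'"
        )

    cohort = CohortConfig()
    cohort_block = raw.get("cohort", {})
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(cohort_block) - known
    if unknown:
        raise ValidationError(f"cohort config: unknown fields {sorted(unknown)}")
    if cohort_block:
        if "hr_bounds" in cohort_block:
            cohort_block = {**cohort_block, "hr_bounds": tuple(cohort_block["hr_bounds"])}
        cohort = replace(cohort, **cohort_block)

    return RunConfig(
        anchor=anchor,
        agent=agent,
        flow_constant_source=source,
        test_bolus_duration=float(
            raw.get("test_bolus_duration_s", DEFAULT_TEST_BOLUS_DURATION)
        ),
        injection_time_buffer=float(raw.get("injection_time_buffer_s", 0.0)),
        max_flow=float(raw.get("max_flow_ml_s", DEFAULT_MAX_FLOW)),
        cohort=cohort,
    )


def calibration_from_config(cfg: RunConfig) -> tuple[float, FlowCalibration]:
    """Attenuation constant k and flow calibration implied by a run config."""
    k, cal = calibrate(cfg.anchor, cfg.agent.iodine_concentration)
    if cfg.flow_constant_source == "printed":
        cal = printed_flow_calibration()
    return k, cal
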