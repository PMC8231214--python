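"""Micro-controller deployment accounting: cycles, latency, current, battery.

Models a duty-cycled Cortex-M4-class target (reference constants: 80 MHz
clock, ~9 CPU cycles per FP32 multiply-accumulate, 10.2 mA active draw,
1.6 uA in STOP2 sleep, one inference per 90 s window, one 2600 mAh lithium
cell). All currents in this module are microamps unless a field name says
otherwise; vendor "A" figures quoted for this class of part are
microamps — the battery arithmetic only closes with that reading.

Accelerometer sampling current is excluded by default (the feasibility
estimate concerns the classifier); pass ``sensor_ua`` to add a constant
sensor draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .architecture import (
    ArchitectureSpec,
    Precision,
    count_macc,
    count_params,
    format_compression,
    format_kb,
    memory_kb,
)

__all__ = [
    "EnergyModel",
    "DeploymentReport",
    "cpu_cycles",
    "inference_time_s",
    "average_current_uA",
    "battery_life_years",
    "deployment_report",
]


@dataclass(frozen=True)
class EnergyModel:
    """Electrical constants of the deployment target."""

    clock_hz: float = 80e6
    cycles_per_macc: float = 9.0
    active_current_mA: float = 10.2
    sleep_current_uA: float = 1.6
    window_period_s: float = 90.0
    battery_capacity_mAh: float = 2600.0
    hours_per_year: float = 8760.0

    def __post_init__(self):
        for name in (
            "clock_hz",
            "cycles_per_macc",
            "active_current_mA",
            "sleep_current_uA",
            "window_period_s",
            "battery_capacity_mAh",
            "hours_per_year",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def cpu_cycles(n_ops: int, model: EnergyModel) -> float:
    """CPU cycles for ``n_ops`` multiply-accumulates."""
    if n_ops < 0:
        raise ValueError("n_ops must be >= 0")
    return n_ops * model.cycles_per_macc


def inference_time_s(cycles: float, model: EnergyModel) -> float:
    """Wall time of one forward pass at the target clock."""
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    return cycles / model.clock_hz


def average_current_uA(active_s: float, model: EnergyModel, sensor_ua: float = 0.0) -> float:
    """Duty-cycle average current in microamps: active for ``active_s`` of
    each window period, asleep for the rest, plus an optional constant
    sensor draw."""
    if not 0.0 <= active_s <= model.window_period_s:
        raise ValueError(
            f"active time {active_s} s outside [0, {model.window_period_s}] s window"
        )
    active_ua = model.active_current_mA * 1000.0
    avg = (
        active_ua * active_s + model.sleep_current_uA * (model.window_period_s - active_s)
    ) / model.window_period_s
    return avg + sensor_ua


def battery_life_years(avg_current_uA: float, model: EnergyModel) -> float:
    """Operational lifetime on the configured cell at a constant average
    draw: capacity[mAh] * 1000 / current[uA] / hours-per-year."""
    if avg_current_uA <= 0:
        raise ValueError("average current must be strictly positive")
    return model.battery_capacity_mAh * 1000.0 / avg_current_uA / model.hours_per_year


@dataclass
class DeploymentReport:
    """Chained complexity and energy figures for one architecture."""

    n_params: int
    n_macc: int
    input_length: int
    memory_kb_fp32: float
    memory_kb_fp16: float
    fits_sram_fp32: bool
    fits_sram_fp16: bool
    sram_limit_kb: float
    cycles: float
    inference_s: float
    avg_current_uA: float
    battery_years: float
    compression: float | None = None

    def to_dict(self) -> dict:
        out = {
            "params": self.n_params,
            "operations_macc": self.n_macc,
            "input_length": self.input_length,
            "memory_kb": {
                "fp32": format_kb(self.memory_kb_fp32),
                "fp16": format_kb(self.memory_kb_fp16),
            },
            "fits_sram": {"fp32": self.fits_sram_fp32, "fp16": self.fits_sram_fp16},
            "sram_limit_kb": self.sram_limit_kb,
            "cpu_cycles": self.cycles,
            "inference_ms": round(self.inference_s * 1e3, 3),
            "avg_current_uA": round(self.avg_current_uA, 3),
            "battery_life_years": round(self.battery_years, 2),
        }
        if self.compression is not None:
            out["compression"] = format_compression(self.compression)
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = ["| quantity | value |", "| --- | --- |"]
        for key, value in d.items():
            lines.append(f"| {key} | {value} |")
        return "\n".join(lines)


def deployment_report(
    spec: ArchitectureSpec,
    input_length: int,
    model: EnergyModel | None = None,
    sram_limit_kb: float = 128.0,
    reference: ArchitectureSpec | None = None,
    sensor_ua: float = 0.0,
) -> DeploymentReport:
    """Full feasibility chain for a spec: parameters -> memory/SRAM fit,
    MACCs -> cycles -> latency -> duty-cycle current -> battery life."""
    model = model or EnergyModel()
    n_params = count_params(spec)
    n_macc = count_macc(spec, input_length)
    mem32 = memory_kb(n_params, Precision.FP32)
    mem16 = memory_kb(n_params, Precision.FP16)
    cycles = cpu_cycles(n_macc, model)
    t_inf = inference_time_s(cycles, model)
    avg = average_current_uA(min(t_inf, model.window_period_s), model, sensor_ua=sensor_ua)
    comp = None
    if reference is not None:
        comp = count_params(reference) / n_params
    return DeploymentReport(
        n_params=n_params,
        n_macc=n_macc,
        input_length=input_length,
        memory_kb_fp32=mem32,
        memory_kb_fp16=mem16,
        fits_sram_fp32=mem32 <= sram_limit_kb,
        fits_sram_fp16=mem16 <= sram_limit_kb,
        sram_limit_kb=sram_limit_kb,
        cycles=cycles,
        inference_s=t_inf,
        avg_current_uA=avg,
        battery_years=battery_life_years(avg, model),
        compression=comp,
    )
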