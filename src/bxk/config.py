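"""Model configuration: parameter groups, validation, TOML round-trip.

Every rate constant, volume and flow in the model lives here with a
documented default, so a run is fully reproducible from its effective
config plus a seed.  Unknown keys are rejected; invalid values raise
errors naming the offending key.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Group(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DoseConfig(_Group):
    """Blast dose drive: injury threshold and residual-damage map.

    The injury threshold is non-dimensional and proportional to a blast
    overpressure of 4 psi; below it residual damage is zero (full
    recovery), above it residual damage grows linearly with exceedance.
    """

    threshold: float = Field(4.0, gt=0, description="non-dimensional injury threshold (= psi)")
    lambda_gain: float = Field(0.25, ge=0, description="residual damage per psi above threshold")
    rise_tau_s: float = Field(
        0.0383, gt=0,
        description="first-order rise time constant of the blast pulse, seconds; "
        "default solves peak R_M at ~0.5 s for the default damage decay rate",
    )
    dose_scale: float = Field(1.0, gt=0, description="peak R_M amplitude per psi of overpressure")
    mode: Literal["daily_aggregate", "per_shot"] = "daily_aggregate"


class DamageConfig(_Group):
    """Rates of the mechanical-damage and biological-response ODEs."""

    alpha: float = Field(1.0, gt=0, description="damage decay coefficient (dimensionless)")
    t_d_h: float = Field(5.0, gt=0, description="characteristic impulse-recovery time, h")
    k_in: float = Field(1.0, gt=0, description="R_M -> R_B1 drive rate, 1/h")
    k_out1: float = Field(0.5, gt=0, description="R_B1 clearance / R_B2 drive rate, 1/h")
    k_out2: float = Field(0.1, gt=0, description="R_B2 clearance rate, 1/h")
    r_m0: float = Field(1.0, gt=0, description="basal mechanical repair")


class PBPKConfig(_Group):
    """Whole-body amyloid kinetics: synthesis, cleavage, transport, clearance.

    Volumes in mL, flows in mL/h, first-order rates in 1/h, for a 70-kg
    male.  ``k_app0`` is the baseline brain APP synthesis rate; with the
    default ``auto`` it is scaled so that baseline plasma Abeta42 equals
    ``baseline_plasma_pg_ml`` (normalized outputs are invariant to this).
    """

    # synthesis / amyloidogenic cleavage
    k_app0: float | Literal["auto"] = Field("auto", description="brain APP synthesis, pg/mL/h or 'auto'")
    x: float = Field(1.5, ge=0, description="blast amplification constant of APP synthesis")
    f_per: float = Field(0.10, ge=0, le=1, description="peripheral synthesis fraction of brain synthesis")
    modulate_peripheral: bool = Field(False, description="apply blast modulation to peripheral synthesis")
    k_bace1: float = Field(0.4, ge=0, description="APP -> sAPPbeta + C99 cleavage, 1/h")
    k_gs: float = Field(1.2, ge=0, description="C99 -> Abeta + AICD cleavage, 1/h")
    f_42: float = Field(0.10, ge=0, le=1, description="fraction of Abeta produced as Abeta42")
    rb_drive: Literal["rb1", "rb2", "sum"] = Field("rb1", description="which response phase modulates synthesis")
    # volumes (mL)
    v_isf: float = Field(250.0, gt=0)
    v_vas: float = Field(60.0, gt=0)
    v_pvs: float = Field(30.0, gt=0)
    v_pla: float = Field(3000.0, gt=0)
    v_per: float = Field(36000.0, gt=0)
    v_lym: float = Field(1000.0, gt=0)
    # flows (mL/h)
    q_br: float = Field(21000.0, ge=0, description="plasma flow, plasma <-> brain vascular")
    q_per: float = Field(160000.0, ge=0, description="plasma flow, plasma <-> peripheral tissue")
    l_br: float = Field(10.0, ge=0, description="brain lymphatic drainage")
    l_per: float = Field(120.0, ge=0, description="peripheral lymphatic drainage")
    f_bbb: float = Field(5.0, ge=0, description="bidirectional BBB fluid exchange")
    f_gly: float = Field(20.0, ge=0, description="glymphatic flux ISF -> perivascular -> lymph")
    # BBB transporters (1/h)
    k_rage: float = Field(0.05, ge=0, description="RAGE influx, vascular -> ISF")
    k_lrp1: float = Field(0.4, ge=0, description="LRP1 efflux, ISF -> vascular")
    k_pgp: float = Field(0.1, ge=0, description="P-gP efflux, ISF -> vascular")
    saturable_transport: bool = Field(False, description="Michaelis form for transporters")
    km_transport: float = Field(1000.0, gt=0, description="transporter K_m, pg/mL (saturable mode)")
    # degradation (1/h) per compartment
    k_deg_isf: float = Field(0.1, ge=0)
    k_deg_vas: float = Field(0.0, ge=0)
    k_deg_pvs: float = Field(0.0, ge=0)
    k_deg_pla: float = Field(0.35, ge=0)
    k_deg_per: float = Field(0.3, ge=0)
    k_deg_lym: float = Field(0.05, ge=0)
    # optional species
    include_ab40: bool = Field(False, description="track Abeta40 as a parallel species")
    include_byproducts: bool = Field(False, description="track inert sAPPbeta/AICD/sBACE1")
    k_byproduct_elim: float = Field(1.0, ge=0, description="first-order elimination of byproducts, 1/h")
    baseline_plasma_pg_ml: float = Field(20.0, gt=0, description="target baseline plasma Abeta42")


class CalibrationConfig(_Group):
    free: tuple[str, ...] = ("x",)
    lower: tuple[float, ...] = (0.0,)
    upper: tuple[float, ...] = (10.0,)
    objective: Literal["sse_normalized", "sse_log"] = "sse_normalized"
    multistart: int = Field(3, ge=1)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _bounds_ok(self) -> "CalibrationConfig":
        if not (len(self.free) == len(self.lower) == len(self.upper)):
            raise ValueError("calibration.free/lower/upper must have equal length")
        for name, lo, hi in zip(self.free, self.lower, self.upper):
            if not (lo < hi):
                raise ValueError(f"calibration bounds for {name!r}: lower must be < upper")
        return self


class SimulationConfig(_Group):
    rtol: float = Field(1e-8, gt=0, description="relative tolerance of the adaptive integrator")
    atol: float = Field(1e-10, gt=0, description="absolute tolerance")
    grid_dt_h: float = Field(0.1, gt=0, description="dense output grid spacing, h")
    training_start_hour: float = Field(9.0, ge=0, lt=24, description="clock hour training begins each day")
    day_length_h: float = Field(24.0, gt=0)
    margin_h: float = Field(6.0, ge=0, description="simulated time past the last sample")
    pulse_window_s: float = Field(2.0, gt=0, description="locally refined window after each blast event")


class ModelConfig(_Group):
    """Full effective configuration of the blast-dose BxK model."""

    schema_version: int = 1
    dose: DoseConfig = Field(default_factory=DoseConfig)
    damage: DamageConfig = Field(default_factory=DamageConfig)
    pbpk: PBPKConfig = Field(default_factory=PBPKConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    def to_toml(self) -> str:
        return _dump_toml(self.model_dump())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml())


class ConfigError(ValueError):
    """Invalid or inconsistent model configuration."""


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a TOML config file; an absent path or empty file yields all defaults."""
    if path is None:
        return ModelConfig()
    raw = Path(path).read_text()
    try:
        data = tomllib.loads(raw)
    except tomllib.TOMLDecodeError as exc:  # pragma: no cover - message passthrough
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return ModelConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def _fmt(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {value!r}")


def _dump_toml(data: dict) -> str:
    # flat two-level structure (sections of scalars/arrays) is all we need
    lines: list[str] = []
    for key, value in data.items():
        if not isinstance(value, dict):
            lines.append(f"{key} = {_fmt(value)}")
    for section, group in data.items():
        if isinstance(group, dict):
            lines.append("")
            lines.append(f"[{section}]")
            for key, value in group.items():
                lines.append(f"{key} = {_fmt(value)}")
    return "\n".join(lines) + "\n"
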