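"""Temperature-controlled RF generator emulation.

The generator drives the cast with a sinusoidal amplitude limited to the
50-80 V window, holds the catheter sensor at the 80 degC set-point with a
clamped integrating proportional update (V0 += Kp*(setpoint - sensor)), and
terminates a run when either the preset time is reached or the impedance
rises over the 250 Ohm cut-off — the signature of the desiccation-driven
conductivity collapse around the cast.  Efficacy follows the clinical
convention: a run is effective when the sensor (cast-volume mean) reaches
60 degC or higher at any point.

Setting v_min = v_max and kp = 0 degenerates the controller into a fixed-
amplitude open-loop drive, which the geometry sweeps use to isolate
geometric effects from control compensation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioheat import BioheatSolver, read_sensor
from .electrostatics import SourceMode, solve_potential
from .errors import ConfigurationError
from .geometry import VoxelDomain
from .materials import Label, MaterialTable, SigmaModel, sigma_of_temperature

__all__ = ["Termination", "AblationProtocol", "AblationResult",
           "run_ablation", "classify_effective"]


class Termination(enum.Enum):
    TIME_REACHED = "time_reached"
    IMPEDANCE_CUTOFF = "impedance_cutoff"


@dataclass
class AblationProtocol:
    """Generator settings and run limits (defaults follow the clinical mode)."""

    setpoint: float = 80.0            # degC
    v_min: float = 50.0               # V
    v_max: float = 80.0               # V
    control_interval: float = 1.0     # s
    max_duration: float = 300.0       # s (300 / 600 / 900 typical)
    impedance_cutoff: float = 250.0   # Ohm
    efficacy_threshold: float = 60.0  # degC
    sigma_model: SigmaModel = SigmaModel.CONSTANT
    kp: float = 0.5                   # V per degC of sensor error
    deadband: float = 0.0             # degC; no update inside the band
    scheme: str = "explicit"          # bioheat scheme: 'explicit' | 'implicit'
    dt: float | None = None           # implicit step; None -> control_interval

    def __post_init__(self) -> None:
        self.sigma_model = SigmaModel(self.sigma_model)
        if self.v_min > self.v_max:
            raise ConfigurationError("v_min must not exceed v_max")
        if min(self.control_interval, self.max_duration) <= 0:
            raise ConfigurationError("durations must be positive")
        if self.impedance_cutoff <= 0:
            raise ConfigurationError("impedance cutoff must be positive")


@dataclass
class AblationResult:
    """Recorded ablation run: time series, peak-temperature map, outcome."""

    series: pd.DataFrame              # t, sensor_T, tip_T, V0, P, Z
    termination: Termination
    Tmax_map: np.ndarray
    effective: bool
    final_T: np.ndarray = field(repr=False, default=None)

    @property
    def peak_sensor_T(self) -> float:
        return float(self.series["sensor_T"].max())


def classify_effective(result: AblationResult, protocol: AblationProtocol) -> bool:
    """Effective ablation: peak sensor temperature >= the 60 degC threshold."""
    if len(result.series) == 0:
        raise ConfigurationError("empty ablation series")
    return bool(result.series["sensor_T"].max() >= protocol.efficacy_threshold)


def run_ablation(domain: VoxelDomain, table: MaterialTable,
                 protocol: AblationProtocol) -> AblationResult:
    """Run one complete temperature-controlled ablation.

    Alternates electrostatic (re-)solves with bioheat stepping at the control
    interval.  With constant conductivity the field is solved once at unit
    amplitude and rescaled by V0^2, which is exact for the linear problem;
    with the roll-off model the conductivity grid is rebuilt from the current
    temperature and the potential re-solved (warm-started) every interval.
    Deterministic for fixed inputs.  The impedance cut-off requires an actual
    rise above the starting impedance, so a barely conducting domain runs to
    its time limit instead of tripping on its (large, constant) impedance.
    """
    source_label = domain.source_label()
    mode = (SourceMode.EQUIPOTENTIAL_ELECTRODE if source_label is Label.ELECTRODE
            else SourceMode.POINT_FED_FLUID)

    solver = BioheatSolver(domain, table, scheme=protocol.scheme,
                           dt=(protocol.dt if protocol.scheme == "implicit"
                               and protocol.dt else
                               (protocol.control_interval
                                if protocol.scheme == "implicit" else None)))
    state = solver.make_state()

    sigma0 = table.sigma_grid(domain.labels)
    unit = solve_potential(domain, table, 1.0, source_mode=mode)
    Z0 = unit.Z
    phi_prev = unit.phi

    V0 = protocol.v_min
    rows = []
    sensor, tip = read_sensor(state, domain)
    rows.append((0.0, sensor, tip, V0, unit.P * V0**2, unit.Z))

    termination = Termination.TIME_REACHED
    t, eps = 0.0, 1e-9
    while t < protocol.max_duration - eps:
        if protocol.sigma_model is not SigmaModel.CONSTANT:
            sigma = sigma_of_temperature(sigma0, state.T, protocol.sigma_model)
            # the metal cast stays a Dirichlet equipotential; only tissue rolls off
            unit = solve_potential(domain, table, 1.0, source_mode=mode,
                                   sigma_grid=sigma, x0=phi_prev)
            phi_prev = unit.phi
        U = unit.U * V0**2
        P = unit.P * V0**2
        Z = unit.Z

        dt = min(protocol.control_interval, protocol.max_duration - t)
        solver.advance(state, U, dt)
        t = state.t
        sensor, tip = read_sensor(state, domain)
        rows.append((t, sensor, tip, V0, P, Z))

        if Z > protocol.impedance_cutoff and Z > Z0 * 1.05:
            termination = Termination.IMPEDANCE_CUTOFF
            break

        err = protocol.setpoint - sensor
        if abs(err) > protocol.deadband:
            V0 = float(np.clip(V0 + protocol.kp * err,
                               protocol.v_min, protocol.v_max))

    series = pd.DataFrame(rows, columns=["t", "sensor_T", "tip_T", "V0", "P", "Z"])
    result = AblationResult(series=series, termination=termination,
                            Tmax_map=state.Tmax, effective=False,
                            final_T=state.T)
    result.effective = classify_effective(result, protocol)
    return result
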