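"""CO2 evolution rate (CER) and cumulative CER from respirometry traces.

A trace carries effluent CO2 volume fraction and volumetric flow sampled at
strictly increasing times.  The instantaneous evolution rate, normalised by
the dry matter in the reactor, is

    CER(t) = flow(t) [L/min] * 60 * (co2(t) - baseline(t))
             * (44.01 / Vm) * 1000 / dry_mass        [mg CO2 / g / h]

with Vm the molar volume of the sensor gas (default 24.0 L/mol, ambient
conditions) and 44.01 g/mol the molar mass of CO2.  cCER is the trapezoidal
time integral of CER, in mg CO2 per g dry matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MOLAR_MASS_CO2 = 44.01  # g/mol
DEFAULT_MOLAR_VOLUME = 24.0  # L/mol, ambient sensor conditions


@dataclass
class RespTrace:
    """One reactor's respirometry time series.

    time in hours (strictly increasing), co2_fraction as a volume fraction in
    [0, 1], flow in L/min, dry_mass in grams.  An optional baseline column
    holds the inlet CO2 fraction to subtract (default zero).
    """

    time: np.ndarray
    co2_fraction: np.ndarray
    flow: np.ndarray
    dry_mass: float
    molar_volume: float = DEFAULT_MOLAR_VOLUME
    baseline: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.co2_fraction = np.asarray(self.co2_fraction, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("a trace needs at least two time points")
        if self.co2_fraction.size != n or self.flow.size != n:
            raise ValueError("time, co2_fraction and flow must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.dry_mass <= 0:
            raise ValueError("dry_mass must be positive")
        if self.molar_volume <= 0:
            raise ValueError("molar_volume must be positive")
        if np.any(self.flow < 0):
            raise ValueError("negative flow")
        if np.any((self.co2_fraction < 0) | (self.co2_fraction > 1)):
            raise ValueError("co2_fraction outside [0, 1]")
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)
            if self.baseline.size != n:
                raise ValueError("baseline length mismatch")


def compute_cer(trace: RespTrace) -> np.ndarray:
    """Instantaneous CO2 evolution rate in mg CO2 per g dry matter per hour."""
    co2 = trace.co2_fraction
    if trace.baseline is not None:
        co2 = np.clip(co2 - trace.baseline, 0.0, None)
    mg_per_l = MOLAR_MASS_CO2 / trace.molar_volume * 1000.0  # mg CO2 per L of CO2
    return trace.flow * 60.0 * co2 * mg_per_l / trace.dry_mass


def integrate_ccer(cer: np.ndarray, time: np.ndarray) -> float:
    """Cumulative CER: trapezoidal integral of CER over the time span (mg/g)."""
    cer = np.asarray(cer, dtype=float)
    time = np.asarray(time, dtype=float)
    if cer.size != time.size:
        raise ValueError("cer and time must have equal length")
    if cer.size < 2:
        import warnings
        warnings.warn("single-point trace integrates to 0", stacklevel=2)
        return 0.0
    return float(np.trapezoid(cer, time))


def ccer_series(trace: RespTrace) -> np.ndarray:
    """Running cumulative CER at each time point (monotone when CER >= 0)."""
    cer = compute_cer(trace)
    dt = np.diff(trace.time)
    seg = 0.5 * (cer[1:] + cer[:-1]) * dt
    return np.concatenate([[0.0], np.cumsum(seg)])


def read_trace(path: str | Path) -> RespTrace:
    """Read a trace TSV (columns time, co2_fraction, flow, optional baseline).

    The dry mass and molar volume ride in '#'-prefixed header lines of the
    form ``# dry_mass_g = 10.0``.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("#").partition("=")
                meta[key.strip()] = float(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "dry_mass_g" not in meta:
        raise ValueError(f"{path}: missing '# dry_mass_g = ...' header")
    return RespTrace(
        time=df["time"].to_numpy(),
        co2_fraction=df["co2_fraction"].to_numpy(),
        flow=df["flow"].to_numpy(),
        dry_mass=meta["dry_mass_g"],
        molar_volume=meta.get("molar_volume_l_per_mol", DEFAULT_MOLAR_VOLUME),
        baseline=df["baseline"].to_numpy() if "baseline" in df.columns else None,
    )


def write_trace(trace: RespTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dry_mass_g = {trace.dry_mass!r}\n")
        fh.write(f"# molar_volume_l_per_mol = {trace.molar_volume!r}\n")
        cols = {"time": trace.time, "co2_fraction": trace.co2_fraction, "flow": trace.flow}
        if trace.baseline is not None:
            cols["baseline"] = trace.baseline
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def cer_report(trace: RespTrace) -> pd.DataFrame:
    """Tabular CER / running cCER report for one trace."""
    return pd.DataFrame({
        "time": trace.time,
        "cer_mg_per_g_h": compute_cer(trace),
        "ccer_mg_per_g": ccer_series(trace),
    })


__all__ = [
    "RespTrace", "compute_cer", "integrate_ccer", "ccer_series",
    "read_trace", "write_trace", "cer_report",
    "MOLAR_MASS_CO2", "DEFAULT_MOLAR_VOLUME",
]
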