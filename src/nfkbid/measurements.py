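"""From trajectories to (noisy, normalized) measurement sets.

Measurements mimic what a wet-lab experiment would deliver: per-series time
courses in arbitrary units. Two conventions follow from that premise.

*Normalization.* Each series x is first shifted, x′ = x + ρ·max(x) with
ρ = 0.03, so that values below ~3% of the series maximum — which in a real
experiment are indistinguishable from background — cannot dominate the log
residuals. Each shifted series is then divided by its geometric mean, which
removes the arbitrary unit. A normalized series of n points therefore carries
n − 1 independent numbers.

*Noise.* Measurement error is multiplicative: each raw value is replaced by a
lognormal draw whose median is the true value and whose geometric standard
deviation is σ_data (σ_data = 1 means no noise). Noise is applied to raw
values, before the ρ-shift and geometric scaling, as an experimenter's raw
readouts would be; the ρ-shift then uses the noisy series' own maximum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import simulate
from .parameters import ParameterSet
from .protocols import MeasurementSchedule, Protocol

__all__ = [
    "RHO",
    "TimeSeries",
    "MeasurementSet",
    "NoiseModel",
    "extract_observables",
    "simulate_measurements",
    "normalize_series",
    "normalize",
    "add_lognormal_noise",
    "read_csv",
    "write_csv",
]

#: Background shift as a fraction of each series' maximum.
RHO = 0.03


@dataclass(frozen=True)
class TimeSeries:
    """One observable's time course for one genotype in one protocol."""

    protocol: str
    genotype: str
    observable: str
    times: np.ndarray  # minutes
    values: np.ndarray  # arbitrary units, >= 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if np.any(v < 0):
            raise ValueError("measurement values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protocol, self.genotype, self.observable)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MeasurementSet:
    """A collection of series, raw or normalized."""

    series: tuple[TimeSeries, ...]
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "series", tuple(self.series))
        keys = [s.key for s in self.series]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (protocol, genotype, observable) series")

    @property
    def N(self) -> int:
        """Total number of measurements."""
        return sum(len(s) for s in self.series)

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def dim(self) -> int:
        """Independent data points after per-series geometric scaling."""
        return self.N - self.n_series

    def values_vector(self) -> np.ndarray:
        """All values concatenated in series order."""
        return np.concatenate([s.values for s in self.series]) if self.series \
            else np.empty(0)

    def index(self) -> list[tuple[str, str, str, float]]:
        """(protocol, genotype, observable, time_min) per concatenated value."""
        return [(s.protocol, s.genotype, s.observable, float(t))
                for s in self.series for t in s.times]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    Each value v is replaced by a draw from Lognormal(μ, σ²) with median
    exp(μ) = v and σ = ln(sigma_data); sigma_data is the geometric standard
    deviation of the error and sigma_data = 1 disables the noise.
    """

    sigma_data: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma_data < 1.0:
            raise ValueError(
                f"sigma_data is a geometric SD and must be >= 1, "
                f"got {self.sigma_data}"
            )


def extract_observables(
    trajectory: pd.DataFrame,
    schedule: MeasurementSchedule,
    genotype: str,
    protocol_name: str = "",
) -> list[TimeSeries]:
    """Sample one genotype's scheduled observables from a trajectory table.

    IKKa, NFkBn, A20 and IkBat are read directly; total IκBα is the derived
    column IkBa_total = IκBα + 1 − NFκBn. Values at scheduled times are
    linearly interpolated from the trajectory grid, so the trajectory should
    contain the scheduled times (or a dense grid around them).
    """
    t_grid = trajectory["time_min"].to_numpy()
    out = []
    for gt, obs in schedule.series_keys():
        if gt != genotype:
            continue
        times = np.asarray(schedule.entries[(gt, obs)])
        if times.min() < t_grid.min() - 1e-9 or times.max() > t_grid.max() + 1e-9:
            raise ValueError(
                f"scheduled times for ({gt}, {obs}) outside trajectory span"
            )
        vals = np.interp(times, t_grid, trajectory[obs].to_numpy())
        out.append(TimeSeries(protocol_name, gt, obs, times, vals))
    return out


def simulate_measurements(
    params: ParameterSet,
    protocol: Protocol,
    genotypes: Sequence[str] | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> MeasurementSet:
    """Simulate a protocol and extract its raw (noise-free) measurements."""
    from . import model as _m

    genotypes = tuple(genotypes) if genotypes is not None \
        else protocol.schedule.genotypes()
    kw = {}
    if rtol is not None:
        kw["rtol"] = rtol
    if atol is not None:
        kw["atol"] = atol
    series: list[TimeSeries] = []
    for gt in genotypes:
        times = sorted({
            t for (g, _), tt in protocol.schedule.entries.items()
            if g == gt for t in tt
        })
        if not times:
            continue
        traj = _m.simulate(params, protocol.stimulus, genotype=gt,
                           t_eval_min=np.asarray(times), **kw)
        series.extend(extract_observables(traj, protocol.schedule, gt,
                                          protocol.name))
    return MeasurementSet(tuple(series), normalized=False)


def normalize_series(series: TimeSeries, rho: float = RHO) -> TimeSeries:
    """ρ-shift then divide by the geometric mean; output geo-mean is 1."""
    x = series.values
    m = x.max(initial=0.0)
    if m <= 0:
        raise ValueError(
            f"series {series.key} is identically zero; cannot normalize"
        )
    shifted = x + rho * m
    y = shifted / np.exp(np.mean(np.log(shifted)))
    return replace(series, values=y)


def normalize(mset: MeasurementSet, rho: float = RHO) -> MeasurementSet:
    """Normalize every series of a raw measurement set."""
    if mset.normalized:
        raise ValueError("measurement set is already normalized")
    return MeasurementSet(
        tuple(normalize_series(s, rho) for s in mset.series), normalized=True
    )


def add_lognormal_noise(mset: MeasurementSet, noise: NoiseModel) -> MeasurementSet:
    """Perturb each raw value by an independent lognormal error.

    Deterministic under a fixed ``noise.seed``; ``sigma_data = 1`` returns the
    input values unchanged.
    """
    if mset.normalized:
        raise ValueError("noise is applied to raw values, before normalization")
    sigma_ln = np.log(noise.sigma_data)
    rng = np.random.default_rng(noise.seed)
    out = []
    for s in mset.series:
        z = rng.standard_normal(len(s))
        out.append(replace(s, values=s.values * np.exp(sigma_ln * z)))
    return MeasurementSet(tuple(out), normalized=False)


# ----------------------------------------------------------------------
# long-format CSV I/O: protocol, genotype, observable, time_min, value
# ----------------------------------------------------------------------

def write_csv(mset: MeasurementSet, path: str | Path) -> None:
    rows = [
        {"protocol": s.protocol, "genotype": s.genotype,
         "observable": s.observable, "time_min": t, "value": v}
        for s in mset.series for t, v in zip(s.times, s.values)
    ]
    buf = io.StringIO()
    buf.write(f"# normalized: {str(mset.normalized).lower()}\n")
    pd.DataFrame(rows).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_csv(path: str | Path) -> MeasurementSet:
    path = Path(path)
    normalized = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            normalized = "true" in first.lower()
    df = pd.read_csv(path, comment="#")
    required = {"protocol", "genotype", "observable", "time_min", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    series = []
    for (prot, gt, obs), grp in df.groupby(
            ["protocol", "genotype", "observable"], sort=False, dropna=False):
        grp = grp.sort_values("time_min")
        series.append(TimeSeries(
            "" if pd.isna(prot) else str(prot), str(gt), str(obs),
            grp["time_min"].to_numpy(), grp["value"].to_numpy(),
        ))
    return MeasurementSet(tuple(series), normalized=normalized)
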