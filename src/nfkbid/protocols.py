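"""TNF stimulation protocols and measurement schedules.

A protocol couples a piecewise-constant TNF stimulus (ON/OFF segments, in
minutes) with a measurement schedule: for each genotype (wild type or A20
knock-out) and each observable, the list of times at which that observable is
read. The five observables are IKKa, nuclear NF-κB, total IκBα protein
(IkBa_total = free IκBα + NF-κB-bound complexes), A20 and IκBα mRNA; A20 is
never scheduled for the knock-out, where the protein is absent.

Because every measured series is later normalized by its geometric mean, a
series of n points carries only n − 1 independent numbers. The count of
independent data points, ``dim = N − n_series``, is the quantity all
identifiability measures are scaled by.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "OBSERVABLES",
    "GENOTYPES",
    "StimulusProfile",
    "MeasurementSchedule",
    "Protocol",
    "make_on_off",
    "make_tonic",
    "make_pulsatile",
    "load_protocol",
    "save_protocol",
    "get_protocol",
    "count_independent_points",
]

OBSERVABLES = ("IKKa", "NFkBn", "IkBa_total", "A20", "IkBat")
GENOTYPES = ("WT", "A20KO")


@dataclass(frozen=True)
class StimulusProfile:
    """Ordered, contiguous TNF segments ``(start_min, end_min, T_R)``."""

    segments: tuple[tuple[float, float, int], ...]

    def __post_init__(self):
        segs = tuple((float(a), float(b), int(tr)) for a, b, tr in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("stimulus must contain at least one segment")
        prev_end = segs[0][0]
        for a, b, tr in segs:
            if b <= a:
                raise ValueError(f"segment [{a}, {b}] has non-positive length")
            if abs(a - prev_end) > 1e-9:
                raise ValueError(
                    f"segments must be contiguous; gap/overlap at t={a} min"
                )
            if tr not in (0, 1):
                raise ValueError(f"T_R must be 0 or 1, got {tr}")
            prev_end = b
        if segs[0][0] != 0.0:
            raise ValueError("stimulus must start at t = 0 min")

    @property
    def horizon_min(self) -> float:
        return self.segments[-1][1]

    def tnf_at(self, t_min: float) -> int:
        """T_R at a time (right-open segments; the last endpoint included)."""
        for a, b, tr in self.segments:
            if a <= t_min < b:
                return tr
        if abs(t_min - self.horizon_min) < 1e-9:
            return self.segments[-1][2]
        raise ValueError(f"t={t_min} min outside stimulus span")


@dataclass(frozen=True)
class MeasurementSchedule:
    """Per-genotype, per-observable measurement times (minutes)."""

    entries: Mapping[tuple[str, str], tuple[float, ...]]

    def __post_init__(self):
        norm = {}
        for (gt, obs), times in dict(self.entries).items():
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r}")
            if obs not in OBSERVABLES:
                raise ValueError(f"unknown observable {obs!r}")
            if gt == "A20KO" and obs == "A20":
                raise ValueError("A20 cannot be measured in A20KO cells")
            tt = tuple(float(t) for t in times)
            if any(b <= a for a, b in zip(tt, tt[1:])):
                raise ValueError(
                    f"times for ({gt}, {obs}) must be strictly increasing"
                )
            if tt and tt[0] < 0:
                raise ValueError("measurement times must be non-negative")
            if tt:
                norm[(gt, obs)] = tt
        object.__setattr__(self, "entries", norm)

    @property
    def n_measurements(self) -> int:
        return sum(len(t) for t in self.entries.values())

    @property
    def n_series(self) -> int:
        return len(self.entries)

    def genotypes(self) -> tuple[str, ...]:
        return tuple(g for g in GENOTYPES
                     if any(gt == g for gt, _ in self.entries))

    def series_keys(self) -> list[tuple[str, str]]:
        """(genotype, observable) pairs in canonical order."""
        return [(g, o) for g in GENOTYPES for o in OBSERVABLES
                if (g, o) in self.entries]

    def latest_time(self) -> float:
        return max((t[-1] for t in self.entries.values()), default=0.0)


@dataclass(frozen=True)
class Protocol:
    """A named stimulus plus its measurement schedule."""

    name: str
    stimulus: StimulusProfile
    schedule: MeasurementSchedule = field(
        default_factory=lambda: MeasurementSchedule({})
    )

    def __post_init__(self):
        if self.schedule.latest_time() > self.stimulus.horizon_min + 1e-9:
            raise ValueError(
                "measurement times extend beyond the stimulus horizon"
            )

    @property
    def n_measurements(self) -> int:
        """Total measurement count N."""
        return self.schedule.n_measurements

    @property
    def n_series(self) -> int:
        return self.schedule.n_series

    @property
    def dim(self) -> int:
        """Independent data points: N − n_series (one lost per normalized series)."""
        return self.n_measurements - self.n_series


#: Measurement times (minutes) of the on–off protocol, per observable.
_ON_OFF_TIMES = {
    "IKKa": (0.0, 5.0, 30.0),
    "NFkBn": (0.0, 5.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0),
    "IkBa_total": (0.0, 5.0, 30.0, 60.0, 120.0, 180.0, 300.0, 720.0),
    "A20": (0.0, 30.0, 60.0, 300.0),
    "IkBat": (0.0, 30.0, 60.0, 300.0),
}


def make_on_off() -> Protocol:
    """The on–off protocol: TNF ON 0–120 min, OFF 120–720 min.

    All five observables are measured in wild type and all but A20 in the
    A20 knock-out, 50 measurements in total across 9 series (41 independent
    data points). Sampling is densest where each variable changes fastest.
    """
    entries = {}
    for obs, times in _ON_OFF_TIMES.items():
        entries[("WT", obs)] = times
        if obs != "A20":
            entries[("A20KO", obs)] = times
    return Protocol(
        name="on_off",
        stimulus=StimulusProfile(((0.0, 120.0, 1), (120.0, 720.0, 0))),
        schedule=MeasurementSchedule(entries),
    )


def make_tonic(horizon_min: float = 720.0, onset_min: float = 0.0,
               name: str = "tonic") -> Protocol:
    """Continuous TNF from ``onset_min`` to the horizon (schedule empty)."""
    if horizon_min <= onset_min or horizon_min <= 0:
        raise ValueError("horizon must exceed the onset time")
    if onset_min < 0:
        raise ValueError("onset must be non-negative")
    segs = []
    if onset_min > 0:
        segs.append((0.0, onset_min, 0))
    segs.append((onset_min, horizon_min, 1))
    return Protocol(name=name, stimulus=StimulusProfile(tuple(segs)))


def make_pulsatile(pulse_min: float, gap_min: float, n_pulses: int,
                   name: str | None = None) -> Protocol:
    """Square-wave TNF: ``n_pulses`` ON pulses separated by OFF gaps.

    ``make_pulsatile(5, 200, 3)`` gives ON segments [0, 5], [205, 210] and
    [410, 415] min; ``make_pulsatile(45, 45, k)`` is a period-90-min square
    wave. The horizon ends with the last pulse; schedules are empty.
    """
    if pulse_min <= 0 or gap_min <= 0 or n_pulses < 1:
        raise ValueError("pulse length, gap and pulse count must be positive")
    segs = []
    t = 0.0
    for i in range(int(n_pulses)):
        segs.append((t, t + pulse_min, 1))
        t += pulse_min
        if i < n_pulses - 1:
            segs.append((t, t + gap_min, 0))
            t += gap_min
    if name is None:
        name = f"pulses_{pulse_min:g}x{n_pulses}_gap{gap_min:g}"
    return Protocol(name=name, stimulus=StimulusProfile(tuple(segs)))


def count_independent_points(protocols: Iterable[Protocol]) -> int:
    """Total dim = ΣN − Σn_series over the given protocols.

    Geometric-mean normalization removes one degree of freedom per series,
    so dim — not the raw measurement count — is the dimension of the data
    that constrains parameters.
    """
    protocols = list(protocols)
    if not protocols or any(p.n_measurements == 0 for p in protocols):
        raise ValueError("every protocol must have a non-empty schedule")
    return sum(p.dim for p in protocols)


# ----------------------------------------------------------------------
# serialization: {name, segments: [[start, end, TR], ...],
#                 schedule: {WT: {IKKa: [...], ...}, A20KO: {...}}}
# ----------------------------------------------------------------------

def _to_mapping(protocol: Protocol) -> dict:
    sched: dict[str, dict[str, list[float]]] = {}
    for (gt, obs), times in protocol.schedule.entries.items():
        sched.setdefault(gt, {})[obs] = list(times)
    return {
        "name": protocol.name,
        "segments": [list(s) for s in protocol.stimulus.segments],
        "schedule": sched,
    }


def _from_mapping(data: Mapping) -> Protocol:
    for key in ("name", "segments"):
        if key not in data:
            raise ValueError(f"protocol config missing field {key!r}")
    try:
        stimulus = StimulusProfile(tuple(tuple(s) for s in data["segments"]))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid 'segments': {exc}") from exc
    entries = {}
    for gt, per_obs in (data.get("schedule") or {}).items():
        for obs, times in per_obs.items():
            entries[(gt, obs)] = tuple(times)
    try:
        schedule = MeasurementSchedule(entries)
        return Protocol(str(data["name"]), stimulus, schedule)
    except ValueError as exc:
        raise ValueError(f"invalid 'schedule': {exc}") from exc


def save_protocol(protocol: Protocol, path: str | Path) -> None:
    """Write a protocol to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = _to_mapping(protocol)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_protocol(path: str | Path) -> Protocol:
    """Read and validate a protocol from a YAML/JSON config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: protocol config must be a mapping")
    return _from_mapping(data)


#: A skeleton config for transcribing externally documented protocols
#: (e.g. the published pulsatile schedules): fill in segments and per-
#: genotype measurement times, then ``load_protocol`` validates it.
PROTOCOL_TEMPLATE = """\
# Protocol config template.
# segments: contiguous [start_min, end_min, T_R] triples covering [0, horizon]
# schedule: per-genotype measurement times in minutes per observable
#   (observables: IKKa, NFkBn, IkBa_total, A20, IkBat; no A20 under A20KO)
name: my_protocol
segments:
  - [0, 120, 1]
  - [120, 720, 0]
schedule:
  WT:
    IKKa: [0, 5, 30]
    NFkBn: [0, 5, 30, 60, 90, 120, 150, 180]
    IkBa_total: [0, 5, 30, 60, 120, 180, 300, 720]
    A20: [0, 30, 60, 300]
    IkBat: [0, 30, 60, 300]
  A20KO:
    IKKa: [0, 5, 30]
    NFkBn: [0, 5, 30, 60, 90, 120, 150, 180]
    IkBa_total: [0, 5, 30, 60, 120, 180, 300, 720]
    IkBat: [0, 30, 60, 300]
"""


def write_protocol_template(path: str | Path) -> None:
    """Write a commented YAML skeleton for user-defined protocols."""
    Path(path).write_text(PROTOCOL_TEMPLATE)


_BUILTINS = {
    "on_off": make_on_off,
    "tonic": make_tonic,
}


def get_protocol(name: str) -> Protocol:
    """Built-in protocol by name, or load from a config file path."""
    if name in _BUILTINS:
        return _BUILTINS[name]()
    p = Path(name)
    if p.exists():
        return load_protocol(p)
    raise KeyError(
        f"unknown protocol {name!r}; built-ins: {sorted(_BUILTINS)} "
        "(or pass a YAML/JSON config path)"
    )
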