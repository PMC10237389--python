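"""Rate-constant sets of the reduced NF-κB pathway model.

The model is non-dimensional: protein and mRNA levels are fractions of their
conserved totals (total NF-κB = 1) or of reference steady-state levels, so all
13 parameters are first-order rate constants in s⁻¹ except the two
Michaelis-type constants ``delta`` and ``epsilon``, which are dimensionless.

Two named presets ship with the package:

``pre-fitted``
    The parameter values obtained directly from the reduction of the
    15-variable mechanistic model, before any refitting.
``fitted``
    The values after refitting the reduced model to trajectories of the
    full model (the nominal set used throughout the analyses here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = ["ParameterSet", "PARAM_NAMES", "PRE_FITTED", "FITTED", "get_preset"]

#: Canonical parameter order used for vectors/matrices throughout the package.
PARAM_NAMES = (
    "k_deg", "k1", "k2", "k3", "a2", "a3",
    "delta", "epsilon", "c_deg", "c4a", "c5a", "c3a", "i1a",
)


@dataclass(frozen=True)
class ParameterSet:
    """The 13 rate constants of the reduced NF-κB model.

    Attributes
    ----------
    k_deg : float
        Synthesis and degradation of IKKn; degradation of IKKa (s⁻¹).
    k1 : float
        TNF-driven activation of IKKn to IKKa (s⁻¹).
    k2 : float
        A20-promoted inactivation of IKKa (s⁻¹).
    k3 : float
        Spontaneous inactivation of IKKa (s⁻¹).
    a2 : float
        IKKa-induced degradation of free IκBα (s⁻¹).
    a3 : float
        IKKa association with (IκBα|NF-κB) complexes leading to IκBα
        degradation and NF-κB release (s⁻¹).
    delta, epsilon : float
        Dimensionless Michaelis-type constants of the reduced nuclear
        import/export terms; both must be strictly positive.
    c_deg : float
        Synthesis and degradation of A20 (s⁻¹).
    c4a : float
        IκBα translation (s⁻¹).
    c5a : float
        Spontaneous IκBα degradation (s⁻¹).
    c3a : float
        IκBα transcription and IκBα mRNA degradation (s⁻¹).
    i1a : float
        IκBα nuclear import leading to NF-κB removal from the nucleus (s⁻¹).
    """

    k_deg: float
    k1: float
    k2: float
    k3: float
    a2: float
    a3: float
    delta: float
    epsilon: float
    c_deg: float
    c4a: float
    c5a: float
    c3a: float
    i1a: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.delta <= 0 or self.epsilon <= 0:
            raise ValueError("delta and epsilon must be strictly positive")

    # -- container-ish helpers -------------------------------------------
    def __iter__(self) -> Iterator[float]:
        return (getattr(self, n) for n in PARAM_NAMES)

    def __getitem__(self, name: str) -> float:
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_array(self):
        import numpy as np

        return np.array(list(self), dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def with_updates(self, **overrides: float) -> "ParameterSet":
        """Return a copy with some parameters replaced (e.g. ``k2=0``)."""
        return replace(self, **overrides)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        extra = set(d) - set(PARAM_NAMES)
        if extra:
            raise ValueError(f"unknown parameters: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_array(cls, arr) -> "ParameterSet":
        if len(arr) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(arr)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        """Read a parameter set from a flat JSON or YAML mapping."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


#: Parameters obtained from the model reduction, before refitting.
PRE_FITTED = ParameterSet(
    k_deg=0.000125,
    k1=0.0025,
    k2=0.0625,
    k3=0.0015,
    a2=0.04,
    a3=0.2,
    delta=0.0833,
    epsilon=0.0167,
    c_deg=0.000171,
    c4a=0.0031,
    c5a=0.0001,
    c3a=0.0004,
    i1a=0.001,
)

#: Parameters of the reduced model refitted to the full 15-variable model
#: (the nominal set).
FITTED = ParameterSet(
    k_deg=0.000107,
    k1=0.00195,
    k2=0.0357,
    k3=0.00145,
    a2=0.0763,
    a3=0.0946,
    delta=0.108,
    epsilon=0.0428,
    c_deg=0.000106,
    c4a=0.00313,
    c5a=0.0000578,
    c3a=0.000372,
    i1a=0.000595,
)

_PRESETS = {"pre-fitted": PRE_FITTED, "prefitted": PRE_FITTED, "fitted": FITTED}


def get_preset(name: str) -> ParameterSet:
    """Return a named preset (``"pre-fitted"`` or ``"fitted"``)."""
    try:
        return _PRESETS[name.lower().replace("_", "-")]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: 'pre-fitted', 'fitted'"
        ) from None
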