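"""Species climate-response parameter sets.

A :class:`SpeciesParameters` bundles the thresholds and rates that shape a
species' weekly growth and stress response: four temperature thresholds
(limiting low, lower optimal, upper optimal, limiting high), four soil
moisture thresholds on the same trapezoidal pattern, and one
threshold/rate pair per stress (cold, heat, wet, dry).

All stress rates are stored as non-negative magnitudes; the direction of
accumulation is fixed by the stress kind (cold and dry accumulate below
their threshold, heat and wet above). Parameter files are flat YAML
mappings with lower-cased mnemonic keys.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = [
    "SpeciesParameters",
    "ParameterError",
    "load_parameters",
    "save_parameters",
    "date_palm_defaults",
]


class ParameterError(ValueError):
    """Invalid or incomplete species parameter set."""


@dataclass(frozen=True)
class SpeciesParameters:
    """Thresholds and stress rates defining a species' climate response.

    Temperature thresholds (``dv0..dv3``) are in deg C; soil-moisture
    thresholds (``sm0..sm3``, ``smws``, ``smds``) are fractions of soil
    storage capacity; stress rates are magnitudes per week. A rate of 0
    disables the corresponding stress.
    """

    dv0: float
    dv1: float
    dv2: float
    dv3: float
    sm0: float
    sm1: float
    sm2: float
    sm3: float
    ttcs: float
    thcs_rate: float
    tths: float
    thhs_rate: float
    smws: float
    hws_rate: float
    smds: float = 0.0
    hds_rate: float = 0.0
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ParameterError` on any violated invariant."""
        for lo, hi in [("dv0", "dv1"), ("dv1", "dv2"), ("dv2", "dv3"),
                       ("sm0", "sm1"), ("sm1", "sm2"), ("sm2", "sm3")]:
            if getattr(self, lo) > getattr(self, hi):
                raise ParameterError(
                    f"threshold ordering violated: {lo} <= {hi} "
                    f"({getattr(self, lo)} > {getattr(self, hi)})"
                )
        for key in ("thcs_rate", "thhs_rate", "hws_rate", "hds_rate"):
            if getattr(self, key) < 0:
                raise ParameterError(
                    f"stress rates are magnitudes and must be >= 0; {key} is "
                    f"{getattr(self, key)}"
                )

    def to_dict(self) -> dict:
        return asdict(self)


_REQUIRED_KEYS = tuple(
    f.name for f in fields(SpeciesParameters) if f.name != "name"
)


def load_parameters(path: str | Path) -> SpeciesParameters:
    """Read a species parameter file (flat YAML mapping).

    Missing required keys raise an "incomplete parameter set" error naming
    the key; unknown keys warn and are ignored; ordering violations raise
    :class:`ParameterError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {path} is not a mapping")
    return _from_mapping(raw, source=str(path))


def _from_mapping(raw: dict, source: str = "<mapping>") -> SpeciesParameters:
    known = {f.name for f in fields(SpeciesParameters)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(
            f"ignoring unknown parameter keys in {source}: {sorted(unknown)}",
            stacklevel=3,
        )
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ParameterError(
            f"incomplete parameter set in {source}: missing {missing}"
        )
    kwargs = {k: raw[k] for k in raw if k in known}
    return SpeciesParameters(**kwargs)


def save_parameters(p: SpeciesParameters, path: str | Path) -> None:
    """Write a parameter set as a flat YAML mapping (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


def date_palm_defaults() -> SpeciesParameters:
    """Date-palm parameter set shipped with the package.

    Dry stress is disabled (``hds_rate = 0``): with the limiting-low soil
    moisture already at the permanent wilting point (0.007), an extra dry
    stress adds nothing for this drought-tolerant crop.
    """
    ref = importlib.resources.files("ecoclim").joinpath("data/date_palm.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _from_mapping(raw, source="packaged date_palm.yaml")
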