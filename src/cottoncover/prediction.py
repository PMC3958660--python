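"""Applying exponential calibration models to canopy cover.

Ships ready-to-use parameter sets for cotton — pooled, per cultivar
(XLZ43, XLZ48) and per nitrogen rate (N0 through N4, i.e. 0 to
480 kg N hm^-2) — covering aboveground total N content (g m^-2), leaf
area index (m^2 m^-2) and aboveground biomass (g m^-2). The calibrations
hold from emergence to full bloom; past that, canopy cover saturates and
stops tracking growth, so predictions at high cover carry a warning.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .calibration import ExpModel

__all__ = [
    "SaturationWarning",
    "BundledParameterSet",
    "bundled_parameters",
    "predict",
    "SATURATION_COVER",
]

#: Cover above which the exponential calibrations extrapolate unreliably:
#: a closed canopy stops gaining cover while the plant keeps growing.
SATURATION_COVER = 0.95


class SaturationWarning(UserWarning):
    """Canopy cover near saturation; prediction may underestimate growth."""


class _ChecksumError(RuntimeError):
    pass


@dataclass(frozen=True)
class BundledParameterSet:
    """The shipped calibration models, keyed by (property, grouping)."""

    entries: Mapping[tuple[str, str], ExpModel]
    metadata: Mapping[str, object]

    def get(self, property: str, grouping: str = "pooled") -> ExpModel:
        key = (property, grouping)
        if key not in self.entries:
            available = sorted(f"{p}:{g}" for p, g in self.entries)
            raise KeyError(
                f"no bundled model for property={property!r}, "
                f"grouping={grouping!r}; available: {', '.join(available)}"
            )
        return self.entries[key]

    def groupings(self) -> list[str]:
        return sorted({g for _, g in self.entries})


_cached_set: BundledParameterSet | None = None


def _load_bundled() -> BundledParameterSet:
    global _cached_set
    if _cached_set is not None:
        return _cached_set
    text = (
        importlib.resources.files("cottoncover")
        .joinpath("data/bundled_models.json")
        .read_text()
    )
    doc = json.loads(text)
    canonical = json.dumps(doc["entries"], sort_keys=True, separators=(",", ":"))
    digest = hashlib.sha256(canonical.encode()).hexdigest()
    if digest != doc["sha256"]:
        raise _ChecksumError(
            "bundled_models.json failed its integrity check; the shipped "
            "parameter table must not be edited in place"
        )
    entries = {
        (e["property"], e["grouping"]): ExpModel(
            k=e["k"], b=e["b"], property=e["property"], group=e["grouping"]
        )
        for e in doc["entries"]
    }
    meta = {k: v for k, v in doc.items() if k != "entries"}
    _cached_set = BundledParameterSet(entries=entries, metadata=meta)
    return _cached_set


def bundled_parameters(property: str, grouping: str = "pooled") -> ExpModel:
    """Look up a shipped calibration model.

    Parameters
    ----------
    property : {"total_N", "LAI", "biomass"}
    grouping : str
        "pooled" (default), "cultivar:XLZ43", "cultivar:XLZ48", or
        "nrate:N0" ... "nrate:N4".
    """
    return _load_bundled().get(property, grouping)


def predict(
    model: ExpModel, cc: Union[float, Sequence[float]]
) -> Union[float, np.ndarray]:
    """Predict a crop property from canopy cover: y = k * e^(b * CC).

    Accepts a scalar or array of cover values in [0, 1]; values above
    0.95 trigger a :class:`SaturationWarning` (a closed canopy no longer
    tracks growth). Returns the prediction in the model's units.
    """
    arr = np.asarray(cc, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)):
        bad = arr[(arr < 0) | (arr > 1)].flat[0]
        raise ValueError(f"canopy cover must be in [0, 1], got {bad}")
    if np.any(arr > SATURATION_COVER):
        warnings.warn(
            f"canopy cover above {SATURATION_COVER}: the canopy is near "
            "saturation and cover no longer reflects growth; the prediction "
            "may underestimate the true value",
            SaturationWarning,
            stacklevel=2,
        )
    y = model.k * np.exp(model.b * arr)
    if np.isscalar(cc) or arr.ndim == 0:
        return float(y)
    return y
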