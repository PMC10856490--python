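"""Pelvimetry measures from labeled landmarks.

Measures are declarative: a versioned YAML/JSON config maps each measure
to landmark endpoints (13 Euclidean lengths in mm, 2 angles in degrees).
The packaged default config defines the 15 standard obstetric measures —
inlet conjugates and diameters, mid-pelvis and outlet diameters, and the
subpubic and pectineal angles.  Angles are computed in 3D, not projected
to a plane.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landmarks import CANONICAL_LANDMARKS, LandmarkSet

__all__ = [
    "MeasureDefinition",
    "load_measure_config",
    "default_measure_definitions",
    "resolve_endpoint",
    "compute_measure",
    "compute_all",
    "measures_to_csv",
]


@dataclasses.dataclass
class MeasureDefinition:
    """One pelvimetry measure.

    ``kind`` is ``distance`` (two endpoint specs) or ``angle`` (either an
    apex with two rays, or two ordered point pairs defining lines).  An
    endpoint spec is ``{"landmark": name, "side": side}`` or
    ``{"midpoint": [spec, spec]}``.
    """

    name: str
    kind: str
    endpoints: list | None = None  # distance
    apex: dict | None = None  # angle, apex/rays form
    rays: list | None = None
    lines: list | None = None  # angle, two-lines form

    def __post_init__(self):
        if self.kind not in ("distance", "angle"):
            raise ValueError(f"unknown measure kind {self.kind!r} in {self.name!r}")
        if self.kind == "distance":
            if not self.endpoints or len(self.endpoints) != 2:
                raise ValueError(f"distance measure {self.name!r} needs 2 endpoints")
        else:
            has_rays = self.apex is not None and self.rays is not None and len(self.rays) == 2
            has_lines = self.lines is not None and len(self.lines or []) == 2
            if not (has_rays or has_lines):
                raise ValueError(
                    f"angle measure {self.name!r} needs an apex with 2 rays or 2 lines"
                )
        for spec in self._all_specs():
            _validate_spec(spec, self.name)

    def _all_specs(self) -> list[dict]:
        if self.kind == "distance":
            return list(self.endpoints)
        if self.lines is not None:
            return [s for line in self.lines for s in line]
        return [self.apex, *self.rays]

    @property
    def units(self) -> str:
        return "mm" if self.kind == "distance" else "degrees"


def _validate_spec(spec: dict, measure: str) -> None:
    if "midpoint" in spec:
        pair = spec["midpoint"]
        if len(pair) != 2:
            raise ValueError(f"midpoint spec in measure {measure!r} needs 2 entries")
        for sub in pair:
            _validate_spec(sub, measure)
        return
    name = spec.get("landmark")
    if name not in CANONICAL_LANDMARKS:
        raise ValueError(f"unknown landmark {name!r} in measure {measure!r}")
    side = spec.get("side", "midline")
    bilateral = CANONICAL_LANDMARKS[name]
    if bilateral and side not in ("left", "right"):
        raise ValueError(
            f"bilateral landmark {name!r} in measure {measure!r} needs side left/right"
        )
    if not bilateral and side != "midline":
        raise ValueError(f"midline landmark {name!r} in measure {measure!r} has no sides")


def load_measure_config(path: str | Path) -> list[MeasureDefinition]:
    """Load and validate measure definitions from a YAML or JSON config."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = (doc or {}).get("measures", [])
    if not raw:
        warnings.warn("measure config defines no measures", stacklevel=2)
        return []
    defs = [MeasureDefinition(**entry) for entry in raw]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate measure names in config")
    return defs


def default_measure_definitions() -> list[MeasureDefinition]:
    """The packaged 15-measure default configuration."""
    ref = resources.files("pelvimetry3d").joinpath("data/measures_default.yaml")
    with resources.as_file(ref) as path:
        return load_measure_config(path)


def resolve_endpoint(ls: LandmarkSet, spec: dict) -> np.ndarray:
    """Resolve an endpoint spec to a 3D point (landmark or midpoint).

    Raises
    ------
    KeyError
        A referenced landmark is missing from the set.
    """
    if "midpoint" in spec:
        a, b = (resolve_endpoint(ls, s) for s in spec["midpoint"])
        return 0.5 * (a + b)
    name = spec["landmark"]
    side = spec.get("side", "midline")
    if (name, side) not in ls:
        raise KeyError(f"missing landmark ({name}, {side})")
    return ls.position(name, side)


def compute_measure(ls: LandmarkSet, d: MeasureDefinition) -> float:
    """Evaluate one measure: Euclidean length (mm) or 3D angle (degrees)."""
    if d.kind == "distance":
        p, q = (resolve_endpoint(ls, s) for s in d.endpoints)
        return float(np.linalg.norm(p - q))
    if d.lines is not None:
        (a0, a1), (b0, b1) = (
            [resolve_endpoint(ls, s) for s in line] for line in d.lines
        )
        u, v = a1 - a0, b1 - b0
    else:
        apex = resolve_endpoint(ls, d.apex)
        u, v = (resolve_endpoint(ls, s) - apex for s in d.rays)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError(f"degenerate angle in measure {d.name!r}: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compute_all(ls: LandmarkSet, defs: list[MeasureDefinition] | None = None) -> pd.DataFrame:
    """Evaluate all measures; per-measure failures are recorded, not raised.

    Returns a DataFrame with one row per definition: columns ``measure``,
    ``kind``, ``value`` (NaN when not computable), ``units``, ``reason``
    plus subject/segmentation/rater provenance.
    """
    defs = defs if defs is not None else default_measure_definitions()
    rows = []
    for d in defs:
        value, reason = np.nan, ""
        try:
            value = compute_measure(ls, d)
        except (KeyError, ValueError) as exc:
            reason = str(exc).strip('"')
        rows.append(
            {
                "subject": ls.subject_id,
                "segmentation": ls.segmentation_id,
                "rater": ls.rater_id,
                "measure": d.name,
                "kind": d.kind,
                "value": value,
                "units": d.units,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def measures_to_csv(tables: list[pd.DataFrame], path: str | Path) -> pd.DataFrame:
    """Concatenate per-labeling measure tables into one long-format CSV."""
    df = pd.concat(tables, ignore_index=True)
    df.to_csv(path, index=False)
    return df
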