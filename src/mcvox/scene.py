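"""Simulation-scene dialect: JSON document model, validation and parsing.

The input document follows the JSON layout established by voxel Monte
Carlo tools in tissue optics, with five top-level sections — ``Session`` (run control), ``Forward`` (time gating), ``Optode``
(source and detectors), ``Domain`` (grid, media, boundary conditions and an
optional voxel volume) and ``Shapes`` (CSG primitives).  Exactly one of
``Domain.Volume`` / ``Shapes`` defines the medium.

Validation is schema-driven: the pydantic models below are the single
source of truth, and the JSON Schema asset shipped under
``mcvox/data/input.schema.json`` is generated from them
(:func:`input_json_schema`).  ``validate_config`` returns a list of
violations (JSON path + rule) instead of raising, so a CLI can print all
problems at once.

Coordinate convention: continuous positions are in grid units, 0-based,
with voxel ``(i, j, k)`` spanning the half-open box
``[i, i+1) x [j, j+1) x [k, k+1)``.  Optical coefficients are entered per
millimetre and scaled by ``LengthUnit`` (mm per grid unit) internally.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Literal, Optional

import numpy as np
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from . import jdata

logger = logging.getLogger(__name__)

SOURCE_TYPES = (
    "pencil",
    "isotropic",
    "cone",
    "planar",
    "disk",
    "gaussian",
    "fourier",
    "line",
    "slit",
    "pattern",
    "pattern3d",
)
BC_TYPES = ("absorb", "fresnel", "mirror", "cyclic")

Vec3 = tuple[float, float, float]


# ---------------------------------------------------------------------------
# pydantic document models (raw JSON dialect)
# ---------------------------------------------------------------------------

class _Doc(BaseModel):
    model_config = ConfigDict(extra="allow", populate_by_name=True)


class SessionDoc(_Doc):
    id: str = Field(default="mcvox", alias="ID")
    photons: int = Field(default=100000, ge=1, alias="Photons")
    rng_seed: int = Field(default=1, ge=0, alias="RNGSeed")
    do_mismatch: bool = Field(default=False, alias="DoMismatch")
    do_normalize: bool = Field(default=True, alias="DoNormalize")
    out_dtype: Literal["single", "double"] = Field(default="single", alias="OutputType")


class ForwardDoc(_Doc):
    t0: float = Field(default=0.0, ge=0.0, alias="T0")
    t1: float = Field(alias="T1")
    dt: float = Field(gt=0.0, alias="Dt")

    @model_validator(mode="after")
    def _check_gates(self):
        if not self.t1 > self.t0:
            raise ValueError("T1 must exceed T0")
        gates = (self.t1 - self.t0) / self.dt
        if gates < 1 - 1e-9 or abs(gates - round(gates)) > 1e-6 * max(gates, 1.0):
            raise ValueError("(T1 - T0) must be a positive integer multiple of Dt")
        return self


class MediumDoc(_Doc):
    mua: float = Field(ge=0.0)
    mus: float = Field(ge=0.0)
    g: float = Field(ge=-1.0, le=1.0)
    n: float = Field(ge=1.0)


class SourceDoc(_Doc):
    type: Literal[SOURCE_TYPES] = Field(alias="Type")
    pos: Vec3 = Field(alias="Pos")
    dir: Vec3 = Field(default=(0.0, 0.0, 1.0), alias="Dir")
    param1: tuple[float, float, float, float] = Field(
        default=(0.0, 0.0, 0.0, 0.0), alias="Param1"
    )
    param2: tuple[float, float, float, float] = Field(
        default=(0.0, 0.0, 0.0, 0.0), alias="Param2"
    )
    focus: Optional[float] = Field(default=None, alias="Focus")
    phase: float = Field(default=0.0, alias="Phase")
    pattern: Optional[dict] = Field(default=None, alias="Pattern")

    @model_validator(mode="after")
    def _check_dir(self):
        if sum(c * c for c in self.dir) <= 0.0:
            raise ValueError("Dir must be a nonzero vector")
        if self.type in ("pattern", "pattern3d") and self.pattern is None:
            raise ValueError(f"source type {self.type!r} requires a Pattern array")
        return self


class DetectorDoc(_Doc):
    pos: Vec3 = Field(alias="Pos")
    radius: float = Field(gt=0.0, alias="R")


class OptodeDoc(_Doc):
    source: SourceDoc = Field(alias="Source")
    detectors: list[DetectorDoc] = Field(default_factory=list, alias="Detector")


class BoundaryDoc(_Doc):
    x0: Literal[BC_TYPES] = "absorb"
    x1: Literal[BC_TYPES] = "absorb"
    y0: Literal[BC_TYPES] = "absorb"
    y1: Literal[BC_TYPES] = "absorb"
    z0: Literal[BC_TYPES] = "absorb"
    z1: Literal[BC_TYPES] = "absorb"


class DomainDoc(_Doc):
    dim: tuple[int, int, int] = Field(alias="Dim")
    length_unit: float = Field(default=1.0, gt=0.0, alias="LengthUnit")
    media: list[MediumDoc] = Field(alias="Media", min_length=1)
    media_format: Literal["labels", "muamus_float"] = Field(
        default="labels", alias="MediaFormat"
    )
    boundary: BoundaryDoc = Field(default_factory=BoundaryDoc, alias="Boundary")
    volume: Optional[dict] = Field(default=None, alias="Volume")

    @model_validator(mode="after")
    def _check_dim(self):
        if any(d < 1 for d in self.dim):
            raise ValueError("Dim components must be >= 1")
        return self


class InputDoc(_Doc):
    """Top-level simulation input document."""

    session: SessionDoc = Field(default_factory=SessionDoc, alias="Session")
    forward: ForwardDoc = Field(alias="Forward")
    optode: OptodeDoc = Field(alias="Optode")
    domain: DomainDoc = Field(alias="Domain")
    shapes: Optional[list[dict]] = Field(default=None, alias="Shapes")

    @model_validator(mode="after")
    def _check_medium_def(self):
        has_vol = self.domain.volume is not None
        has_shapes = self.shapes is not None and len(self.shapes) > 0
        if has_vol == has_shapes:
            raise ValueError(
                "exactly one of Domain.Volume and Shapes must define the medium"
            )
        return self


# ---------------------------------------------------------------------------
# parsed configuration (plain dataclasses, numpy-backed)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SessionCfg:
    id: str
    photons: int
    rng_seed: int
    do_mismatch: bool
    do_normalize: bool
    out_dtype: str


@dataclasses.dataclass
class ForwardCfg:
    t0: float
    t1: float
    dt: float

    @property
    def gates(self) -> int:
        return max(1, int(round((self.t1 - self.t0) / self.dt)))


@dataclasses.dataclass
class MediumOptics:
    """Optical properties of one tissue label: μa, μs in mm⁻¹, anisotropy g, index n."""

    mua: float
    mus: float
    g: float
    n: float


@dataclasses.dataclass
class SourceCfg:
    type: str
    pos: np.ndarray
    dir: np.ndarray          # unit vector
    param1: np.ndarray       # 4-vector, type-specific geometry
    param2: np.ndarray
    focus: Optional[float]   # None => collimated
    phase: float
    pattern: Optional[np.ndarray]


@dataclasses.dataclass
class DetectorCfg:
    pos: np.ndarray
    radius: float


@dataclasses.dataclass
class DomainCfg:
    dim: tuple[int, int, int]
    length_unit: float
    media: list[MediumOptics]
    media_format: str
    boundary: tuple[str, str, str, str, str, str]  # x0,x1,y0,y1,z0,z1
    volume: Optional[np.ndarray]    # label array (x,y,z) or float (x,y,z,2)


@dataclasses.dataclass
class SimConfig:
    session: SessionCfg
    forward: ForwardCfg
    source: SourceCfg
    detectors: list[DetectorCfg]
    domain: DomainCfg
    shapes: Optional[list[dict]]


@dataclasses.dataclass
class Violation:
    path: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.rule}"


class ConfigError(ValueError):
    """Raised by parse_config for documents that fail validation."""


_KNOWN_TOP = {"Session", "Forward", "Optode", "Domain", "Shapes"}


def validate_config(doc: dict) -> list[Violation]:
    """Validate a raw JSON document against the scene dialect.

    Returns an empty list iff *doc* conforms; otherwise one
    :class:`Violation` per problem, each carrying a JSON path and the rule
    that failed.  Unknown keys are tolerated (forward compatibility) but
    logged at warning level.
    """
    for key in doc:
        if key not in _KNOWN_TOP:
            logger.warning("ignoring unknown top-level key %r", key)
    try:
        InputDoc.model_validate(doc)
    except ValidationError as exc:
        out = []
        for err in exc.errors():
            path = "/" + "/".join(str(p) for p in err["loc"])
            out.append(Violation(path=path, rule=err["msg"]))
        return out
    return []


def _decode_volume(dom: DomainDoc) -> Optional[np.ndarray]:
    if dom.volume is None:
        return None
    vol = jdata.decode_ndarray(dom.volume)
    dim = tuple(dom.dim)
    if dom.media_format == "labels":
        if vol.shape != dim:
            raise ConfigError(
                f"volume shape {vol.shape} does not match Domain.Dim {dim}"
            )
        vol = vol.astype(np.int32)
        labels = np.unique(vol)
        if labels.size and labels.max() >= len(dom.media):
            raise ConfigError(
                f"label {int(labels.max())} has no Media entry "
                f"({len(dom.media)} media defined)"
            )
        if labels.size and labels.min() < 0:
            raise ConfigError("negative labels are not permitted")
        return vol
    # continuous per-voxel (mua, mus) pairs, global g and n from Media[1]
    if vol.shape != dim + (2,):
        raise ConfigError(
            f"muamus_float volume must have shape {dim + (2,)}, got {vol.shape}"
        )
    return vol.astype(np.float32)


def parse_config(doc: dict) -> SimConfig:
    """Parse a validated document into a fully-defaulted :class:`SimConfig`.

    Applies documented defaults (absorbing boundary on all faces,
    ``LengthUnit`` 1 mm, refractive mismatch off, "single" output type),
    normalizes the source direction, and decodes any JData-annotated
    volume or source pattern.
    """
    violations = validate_config(doc)
    if violations:
        raise ConfigError(
            "invalid configuration: " + "; ".join(str(v) for v in violations)
        )
    model = InputDoc.model_validate(doc)

    s = model.session
    session = SessionCfg(
        id=s.id,
        photons=s.photons,
        rng_seed=s.rng_seed,
        do_mismatch=s.do_mismatch,
        do_normalize=s.do_normalize,
        out_dtype=s.out_dtype,
    )
    f = model.forward
    forward = ForwardCfg(t0=f.t0, t1=f.t1, dt=f.dt)

    sd = model.optode.source
    direction = np.asarray(sd.dir, dtype=np.float64)
    direction = direction / math.sqrt(float(direction @ direction))
    pattern = None
    if sd.pattern is not None:
        pattern = jdata.decode_ndarray(sd.pattern).astype(np.float64)
        if np.any(pattern < 0):
            raise ConfigError("source pattern values must be >= 0")
    source = SourceCfg(
        type=sd.type,
        pos=np.asarray(sd.pos, dtype=np.float64),
        dir=direction,
        param1=np.asarray(sd.param1, dtype=np.float64),
        param2=np.asarray(sd.param2, dtype=np.float64),
        focus=sd.focus,
        phase=sd.phase,
        pattern=pattern,
    )
    detectors = [
        DetectorCfg(pos=np.asarray(d.pos, dtype=np.float64), radius=d.radius)
        for d in model.optode.detectors
    ]

    dom = model.domain
    media = [MediumDoc_to_optics(m) for m in dom.media]
    volume = _decode_volume(dom)
    b = dom.boundary
    domain = DomainCfg(
        dim=tuple(int(d) for d in dom.dim),
        length_unit=dom.length_unit,
        media=media,
        media_format=dom.media_format,
        boundary=(b.x0, b.x1, b.y0, b.y1, b.z0, b.z1),
        volume=volume,
    )
    return SimConfig(
        session=session,
        forward=forward,
        source=source,
        detectors=detectors,
        domain=domain,
        shapes=model.shapes,
    )


def MediumDoc_to_optics(m: MediumDoc) -> MediumOptics:
    return MediumOptics(mua=m.mua, mus=m.mus, g=m.g, n=m.n)


def serialize_config(cfg: SimConfig) -> dict:
    """Rebuild a JSON document from a parsed config (round-trip support)."""
    doc: dict = {
        "Session": {
            "ID": cfg.session.id,
            "Photons": cfg.session.photons,
            "RNGSeed": cfg.session.rng_seed,
            "DoMismatch": cfg.session.do_mismatch,
            "DoNormalize": cfg.session.do_normalize,
            "OutputType": cfg.session.out_dtype,
        },
        "Forward": {"T0": cfg.forward.t0, "T1": cfg.forward.t1, "Dt": cfg.forward.dt},
        "Optode": {
            "Source": {
                "Type": cfg.source.type,
                "Pos": list(cfg.source.pos),
                "Dir": list(cfg.source.dir),
                "Param1": list(cfg.source.param1),
                "Param2": list(cfg.source.param2),
                "Phase": cfg.source.phase,
            },
            "Detector": [
                {"Pos": list(d.pos), "R": d.radius} for d in cfg.detectors
            ],
        },
        "Domain": {
            "Dim": list(cfg.domain.dim),
            "LengthUnit": cfg.domain.length_unit,
            "Media": [dataclasses.asdict(m) for m in cfg.domain.media],
            "MediaFormat": cfg.domain.media_format,
            "Boundary": dict(
                zip(("x0", "x1", "y0", "y1", "z0", "z1"), cfg.domain.boundary)
            ),
        },
    }
    if cfg.source.focus is not None:
        doc["Optode"]["Source"]["Focus"] = cfg.source.focus
    if cfg.source.pattern is not None:
        doc["Optode"]["Source"]["Pattern"] = jdata.encode_ndarray(
            cfg.source.pattern.astype(np.float64)
        )
    if cfg.shapes is not None:
        doc["Shapes"] = cfg.shapes
    elif cfg.domain.volume is not None:
        vol = cfg.domain.volume
        if cfg.domain.media_format == "labels":
            enc = vol.astype(np.uint8) if vol.max(initial=0) < 256 else vol.astype(np.int32)
        else:
            enc = vol.astype(np.float32)
        doc["Domain"]["Volume"] = jdata.encode_ndarray(enc)
    return doc


def input_json_schema() -> dict:
    """JSON Schema for the input dialect, generated from the document models."""
    return InputDoc.model_json_schema(by_alias=True)
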