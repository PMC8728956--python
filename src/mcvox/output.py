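"""Fluence normalization, result merging and JSON/JData output files.

Raw kernel output is deposited energy per (voxel, time gate) — weight
units, since every photon launches with weight ≈ 1.  Normalization turns
it into a fluence *rate* per unit delivered source energy:

    phi(v, k) = E_dep(v, k) / (mua(v) · V_voxel · dt · W_launched)   [mm^-2 s^-1]

For voxels with mua = 0 the kernel already accumulated the pathlength
estimator Σ w·l instead, and normalization divides by (V_voxel · dt ·
W_launched) only — the two estimators agree in expectation.

Two files are written per run, both plain JSON readable by any strict
parser: a JNIfTI-style volume file (``<base>.jnii``: header object plus a
zlib-compressed JData 4D array) and a detected-photon table
(``<base>_detp.json``) whose columns are detector id, per-medium partial
pathlengths (mm), per-medium scattering counts, exit position and
direction (grid units), momentum transfer Σ(1−cosθ), initial weight and
the photon's RNG stream index (replay seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import jdata

__all__ = [
    "SimResult",
    "normalize_fluence",
    "merge_results",
    "write_outputs",
    "read_fluence",
    "read_detected",
    "detected_columns",
]


@dataclasses.dataclass
class SimResult:
    """Raw or normalized outcome of one (possibly merged) run."""

    config: "object"                 # parsed SimConfig
    volume: np.ndarray               # label or property volume actually used
    raw: np.ndarray                  # (nx,ny,nz,G) deposited energy
    detected: np.ndarray             # detected-photon rows
    accounting: dict                 # exact weight ledger
    fluence: Optional[np.ndarray] = None   # normalized rate, same shape as raw
    seed: int = 0
    worker_photons: Optional[list] = None

    @property
    def normalized(self) -> bool:
        return self.fluence is not None

    def cw_fluence(self) -> np.ndarray:
        """Time-integrated (CW) fluence per unit source energy, mm^-2."""
        if not self.normalized:
            raise ValueError("normalize the result first")
        return self.fluence.sum(axis=3) * self.config.forward.dt


def _voxel_mua_mm(config, volume) -> np.ndarray:
    dom = config.domain
    if dom.media_format == "muamus_float":
        return np.asarray(volume[..., 0], dtype=np.float64)
    mua = np.array([m.mua for m in dom.media], dtype=np.float64)
    return mua[np.asarray(volume, dtype=np.int64)]


def normalize_fluence(result: SimResult) -> SimResult:
    """Return a copy of *result* carrying the normalized fluence rate."""
    if result.normalized:
        raise ValueError("result is already normalized")
    config = result.config
    launched = result.accounting["launched"]
    if launched <= 0:
        raise ValueError("cannot normalize a zero-weight run")
    lu = config.domain.length_unit
    vvox = lu ** 3
    dt = config.forward.dt
    mua = _voxel_mua_mm(config, result.volume)
    scale = np.where(mua > 0, mua, 1.0 / lu)  # mua=0 voxels hold sum(w*l_grid)
    fl = result.raw / (scale[..., None] * vvox * dt * launched)
    return dataclasses.replace(result, fluence=fl)


def _same_config(a, b) -> bool:
    from .scene import serialize_config

    da, db = serialize_config(a), serialize_config(b)
    for d in (da, db):
        d["Session"].pop("Photons", None)
        d["Session"].pop("RNGSeed", None)
    return da == db


def merge_results(parts: list[SimResult]) -> SimResult:
    """Combine raw worker results: energies add, detected tables concatenate,
    launched-weight totals add.  Normalize only after merging."""
    if not parts:
        raise ValueError("nothing to merge")
    first = parts[0]
    for p in parts[1:]:
        if p.normalized or first.normalized:
            raise ValueError("merge raw results, then normalize")
        if p.raw.shape != first.raw.shape or not _same_config(p.config, first.config):
            raise ValueError("cannot merge results from different configurations")
    raw = np.zeros_like(first.raw)
    acct = {k: 0.0 for k in first.accounting}
    tables = []
    worker_photons = []
    for p in parts:
        raw += p.raw
        for k, v in p.accounting.items():
            acct[k] += v
        tables.append(p.detected)
        worker_photons.extend(p.worker_photons or [])
    detected = (
        np.concatenate(tables, axis=0) if tables else np.zeros((0, 0))
    )
    return SimResult(
        config=first.config,
        volume=first.volume,
        raw=raw,
        detected=detected,
        accounting=acct,
        seed=first.seed,
        worker_photons=worker_photons or None,
    )


def detected_columns(config) -> list[str]:
    nmedia = (
        1
        if config.domain.media_format == "muamus_float"
        else max(1, len(config.domain.media) - 1)
    )
    cols = ["detector_id"]
    cols += [f"ppath_medium{m + 1}_mm" for m in range(nmedia)]
    cols += [f"nscat_medium{m + 1}" for m in range(nmedia)]
    cols += ["exit_x", "exit_y", "exit_z", "exit_dx", "exit_dy", "exit_dz"]
    cols += ["momentum_transfer", "initial_weight", "photon_index"]
    return cols


_OUT_DTYPE = {"single": np.float32, "double": np.float64}


def write_outputs(result: SimResult, basename: str | Path) -> list[Path]:
    """Write ``<base>.jnii`` and ``<base>_detp.json``; returns the paths."""
    if not result.normalized and result.config.session.do_normalize:
        raise ValueError("normalize the result before writing")
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    config = result.config
    data = result.fluence if result.normalized else result.raw
    out = np.ascontiguousarray(data, dtype=_OUT_DTYPE[config.session.out_dtype])
    header = {
        "Dim": list(config.domain.dim) + [config.forward.gates],
        "LengthUnit": config.domain.length_unit,
        "T0": config.forward.t0,
        "T1": config.forward.t1,
        "Dt": config.forward.dt,
        "Normalized": result.normalized,
        "SessionID": config.session.id,
        "Seed": result.seed,
        "PathlengthUnit": "mm",
    }
    vol_path = base.with_suffix(".jnii")
    vol_doc = {
        "NIFTIHeader": header,
        "NIFTIData": jdata.encode_ndarray(out, compress=True),
    }
    vol_path.write_text(json.dumps(vol_doc, sort_keys=True))

    det_path = base.parent / (base.name + "_detp.json")
    det = np.ascontiguousarray(result.detected, dtype=np.float64)
    if det.size == 0:
        det = det.reshape(0, len(detected_columns(config)))
    det_doc = {
        "Info": {
            "Columns": detected_columns(config),
            "DetectedPhotons": int(det.shape[0]),
            "LengthUnit": config.domain.length_unit,
            "Accounting": {k: float(v) for k, v in result.accounting.items()},
        },
        "Detected": jdata.encode_ndarray(det, compress=True),
    }
    det_path.write_text(json.dumps(det_doc, sort_keys=True))
    return [vol_path, det_path]


def read_fluence(path: str | Path) -> tuple[np.ndarray, dict]:
    doc = json.loads(Path(path).read_text())
    return jdata.decode_ndarray(doc["NIFTIData"]), doc["NIFTIHeader"]


def read_detected(path: str | Path) -> tuple[np.ndarray, dict]:
    doc = json.loads(Path(path).read_text())
    return jdata.decode_ndarray(doc["Detected"]), doc["Info"]
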