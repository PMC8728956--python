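"""JData-style annotated N-D arrays in plain JSON.

Typed N-D arrays are carried inside ordinary JSON objects using annotation
keys: ``_ArrayType_`` (element type), ``_ArraySize_`` (dimension extents,
declared in row-major / C order) and either ``_ArrayData_`` (nested JSON
lists) or a compressed form ``_ArrayZipType_``/``_ArrayZipSize_``/
``_ArrayZipData_`` where the raw little-endian element bytes are
zlib-deflated and Base64-encoded.  ``decode_ndarray(encode_ndarray(a))``
reproduces ``a`` bit-exactly for every supported dtype.

The 3D volume convention is axis order (x, y, z): index ``(i, j, k)`` of the
decoded array addresses voxel ``x=i, y=j, z=k``.
"""

from __future__ import annotations

import base64
import binascii
import zlib

import numpy as np

__all__ = [
    "encode_ndarray",
    "decode_ndarray",
    "is_ndarray_annotation",
    "JDataError",
    "UnsupportedTypeError",
    "CorruptPayloadError",
    "UnsupportedCodecError",
]

# JData type name <-> numpy dtype (little-endian enforced on the wire)
_TYPE_TO_DTYPE = {
    "uint8": np.dtype("<u1"),
    "int8": np.dtype("<i1"),
    "uint16": np.dtype("<u2"),
    "int16": np.dtype("<i2"),
    "uint32": np.dtype("<u4"),
    "int32": np.dtype("<i4"),
    "single": np.dtype("<f4"),
    "double": np.dtype("<f8"),
}
_DTYPE_TO_TYPE = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int8): "int8",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int16): "int16",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.int32): "int32",
    np.dtype(np.float32): "single",
    np.dtype(np.float64): "double",
}


class JDataError(ValueError):
    """Base error for annotated-array encode/decode failures."""


class UnsupportedTypeError(JDataError):
    """Element type outside the supported set."""


class CorruptPayloadError(JDataError):
    """Payload byte count disagrees with the declared shape/type."""


class UnsupportedCodecError(JDataError):
    """``_ArrayZipType_`` names a compressor other than zlib."""


def _jdata_type(arr: np.ndarray) -> str:
    key = arr.dtype.newbyteorder("=")
    try:
        return _DTYPE_TO_TYPE[np.dtype(key)]
    except KeyError:
        raise UnsupportedTypeError(
            f"unsupported element type {arr.dtype!r}; supported: "
            + ", ".join(_TYPE_TO_DTYPE)
        ) from None


def encode_ndarray(array: np.ndarray, compress: bool = True) -> dict:
    """Encode a typed N-D array as a JSON-serializable annotation object.

    Parameters
    ----------
    array
        Array with at least one dimension and a supported element type
        (u)int8/16/32, float32 ("single") or float64 ("double").
    compress
        If true, emit the zlib+Base64 ``_ArrayZipData_`` form; otherwise
        emit nested lists under ``_ArrayData_``.
    """
    arr = np.asarray(array)
    if arr.ndim < 1:
        arr = arr.reshape(1)
    tname = _jdata_type(arr)
    if np.issubdtype(arr.dtype, np.floating) is False and not np.issubdtype(
        arr.dtype, np.integer
    ):
        raise UnsupportedTypeError(f"unsupported element type {arr.dtype!r}")
    obj: dict = {
        "_ArrayType_": tname,
        "_ArraySize_": [int(s) for s in arr.shape],
    }
    le = np.ascontiguousarray(arr, dtype=_TYPE_TO_DTYPE[tname])
    if compress:
        raw = le.tobytes(order="C")
        obj["_ArrayZipType_"] = "zlib"
        obj["_ArrayZipSize_"] = [int(s) for s in arr.shape]
        obj["_ArrayZipData_"] = base64.b64encode(zlib.compress(raw)).decode("ascii")
    else:
        obj["_ArrayData_"] = le.tolist()
    return obj


def is_ndarray_annotation(obj) -> bool:
    """True if *obj* looks like an annotated-array JSON object."""
    return (
        isinstance(obj, dict)
        and "_ArrayType_" in obj
        and "_ArraySize_" in obj
        and ("_ArrayData_" in obj or "_ArrayZipData_" in obj)
    )


def decode_ndarray(obj: dict) -> np.ndarray:
    """Decode an annotation object back into a typed N-D array.

    Raises
    ------
    CorruptPayloadError
        If the payload byte count does not equal
        ``prod(_ArraySize_) * element_width``.
    UnsupportedCodecError
        If ``_ArrayZipType_`` is not ``"zlib"``.
    JDataError
        For malformed Base64 or missing keys.
    """
    if not isinstance(obj, dict):
        raise JDataError("annotated array must be a JSON object")
    try:
        tname = obj["_ArrayType_"]
        shape = tuple(int(s) for s in obj["_ArraySize_"])
    except KeyError as exc:
        raise JDataError(f"missing annotation key {exc}") from None
    if tname not in _TYPE_TO_DTYPE:
        raise UnsupportedTypeError(f"unsupported _ArrayType_ {tname!r}")
    dtype = _TYPE_TO_DTYPE[tname]
    nelem = int(np.prod(shape)) if shape else 0
    if "_ArrayZipData_" in obj:
        codec = obj.get("_ArrayZipType_", "zlib")
        if codec != "zlib":
            raise UnsupportedCodecError(f"unsupported _ArrayZipType_ {codec!r}")
        try:
            comp = base64.b64decode(obj["_ArrayZipData_"], validate=True)
        except (binascii.Error, ValueError) as exc:
            raise JDataError(f"malformed Base64 payload: {exc}") from None
        try:
            raw = zlib.decompress(comp)
        except zlib.error as exc:
            raise CorruptPayloadError(f"zlib inflate failed: {exc}") from None
        if len(raw) != nelem * dtype.itemsize:
            raise CorruptPayloadError(
                f"payload is {len(raw)} bytes but shape {shape} of {tname} "
                f"needs {nelem * dtype.itemsize}"
            )
        return np.frombuffer(raw, dtype=dtype).reshape(shape).copy()
    if "_ArrayData_" not in obj:
        raise JDataError("annotated array carries neither _ArrayData_ nor _ArrayZipData_")
    arr = np.asarray(obj["_ArrayData_"])
    if arr.size != nelem:
        raise CorruptPayloadError(
            f"_ArrayData_ holds {arr.size} elements but _ArraySize_ {shape} "
            f"declares {nelem}"
        )
    return arr.reshape(shape).astype(dtype)
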