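"""Annotated N-D array codec: round trips, wire format, failure modes."""

import base64
import json
import zlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mcvox import jdata

DTYPES = ["uint8", "int8", "uint16", "int16", "uint32", "int32", "float32", "float64"]


def _random_array(rng, dtype, shape):
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        return rng.integers(info.min, info.max, size=shape, endpoint=True).astype(dtype)
    return rng.standard_normal(shape).astype(dtype)


@pytest.mark.parametrize("dtype", DTYPES)
@pytest.mark.parametrize("compress", [True, False])
def test_round_trip_bit_exact(dtype, compress):
    rng = np.random.default_rng(42)
    for shape in [(3,), (2, 5), (4, 3, 2), (1, 3)]:
        arr = _random_array(rng, dtype, shape)
        obj = jdata.encode_ndarray(arr, compress=compress)
        # must survive a strict JSON writer/parser unchanged
        obj = json.loads(json.dumps(obj))
        back = jdata.decode_ndarray(obj)
        assert back.dtype == arr.dtype
        assert back.shape == arr.shape
        assert np.array_equal(back, arr, equal_nan=True)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    arr=st.sampled_from(DTYPES).flatmap(
        lambda dt: hnp.arrays(
            dtype=dt,
            shape=hnp.array_shapes(min_dims=1, max_dims=4, max_side=6),
            elements={"allow_nan": False} if dt.startswith("float") else None,
        )
    ),
    compress=st.booleans(),
)
def test_round_trip_property(arr, compress):
    back = jdata.decode_ndarray(jdata.encode_ndarray(arr, compress=compress))
    assert back.dtype == arr.dtype and back.shape == arr.shape
    assert np.array_equal(back, arr)


def test_compressed_and_plain_encodings_agree():
    arr = np.arange(24, dtype=np.float32).reshape(2, 3, 4)
    a = jdata.decode_ndarray(jdata.encode_ndarray(arr, compress=True))
    b = jdata.decode_ndarray(jdata.encode_ndarray(arr, compress=False))
    assert np.array_equal(a, b)


def test_annotation_keys_and_size():
    obj = jdata.encode_ndarray(np.array([[1.0, 2.0, 3.0]]), compress=False)
    assert obj["_ArrayType_"] == "double"
    assert obj["_ArraySize_"] == [1, 3]
    assert obj["_ArrayData_"] == [[1.0, 2.0, 3.0]]


def test_zero_array_compresses_to_zero_bytes():
    obj = jdata.encode_ndarray(np.zeros((2, 2), dtype=np.uint8), compress=True)
    raw = zlib.decompress(base64.b64decode(obj["_ArrayZipData_"]))
    assert raw == b"\x00" * 4


def test_hand_built_object_with_independent_zlib_tool():
    # payload produced here with the stdlib, decoded by the package
    payload = base64.b64encode(zlib.compress(bytes([1, 2, 3]))).decode()
    obj = {
        "_ArrayType_": "uint8",
        "_ArraySize_": [3, 1],
        "_ArrayZipType_": "zlib",
        "_ArrayZipSize_": [3, 1],
        "_ArrayZipData_": payload,
    }
    arr = jdata.decode_ndarray(obj)
    assert arr.shape == (3, 1)
    assert arr.ravel().tolist() == [1, 2, 3]


def test_payload_byte_count_mismatch_raises():
    payload = base64.b64encode(zlib.compress(b"\x01" * 5)).decode()
    obj = {
        "_ArrayType_": "uint8",
        "_ArraySize_": [2, 2],
        "_ArrayZipType_": "zlib",
        "_ArrayZipData_": payload,
    }
    with pytest.raises(jdata.CorruptPayloadError):
        jdata.decode_ndarray(obj)


def test_plain_element_count_mismatch_raises():
    obj = {"_ArrayType_": "uint8", "_ArraySize_": [2, 2], "_ArrayData_": [1, 2, 3]}
    with pytest.raises(jdata.CorruptPayloadError):
        jdata.decode_ndarray(obj)


def test_unknown_codec_rejected():
    obj = {
        "_ArrayType_": "uint8",
        "_ArraySize_": [1],
        "_ArrayZipType_": "lzma",
        "_ArrayZipData_": "AA==",
    }
    with pytest.raises(jdata.UnsupportedCodecError):
        jdata.decode_ndarray(obj)


def test_malformed_base64_rejected():
    obj = {
        "_ArrayType_": "uint8",
        "_ArraySize_": [1],
        "_ArrayZipType_": "zlib",
        "_ArrayZipData_": "not base64 !!",
    }
    with pytest.raises(jdata.JDataError):
        jdata.decode_ndarray(obj)


def test_unsupported_dtype_rejected():
    with pytest.raises(jdata.UnsupportedTypeError):
        jdata.encode_ndarray(np.zeros(3, dtype=np.float16))


def test_decoded_volume_axis_order():
    # (x, y, z) convention: element (i, j, k) addresses voxel x=i, y=j, z=k
    arr = np.arange(2 * 3 * 4, dtype=np.uint8).reshape(2, 3, 4)
    back = jdata.decode_ndarray(jdata.encode_ndarray(arr))
    assert back[1, 2, 3] == arr[1, 2, 3]
    assert back.shape == (2, 3, 4)
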