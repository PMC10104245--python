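"""Binary container for keys and ciphertexts.

Layout: 4 magic bytes ``CGHE``, format version (u16 LE), 16-char parameter
digest, a 4-byte ASCII type tag, then a type-specific payload. All residue
arrays are little-endian 64-bit words; the round trip is bit-exact, which is
also what makes seeded key/ciphertext generation byte-reproducible.
"""

from __future__ import annotations

import io
import json
import struct

import numpy as np

from .ckks import Ciphertext, KeyBundle, KeySwitchKey
from .errors import DigestMismatchError, ParameterError
from .packing import BsgsPlan

MAGIC = b"CGHE"
VERSION = 1

TAG_SECRET = b"SECK"
TAG_PUBLIC = b"PUBK"
TAG_RELIN = b"RELK"
TAG_GALOIS = b"GALK"
TAG_CIPHERTEXT = b"CTXT"
TAG_CT_BUNDLE = b"CTBL"


def _write_array(buf: io.BytesIO, arr: np.ndarray) -> None:
    a = np.ascontiguousarray(arr, dtype="<u8")
    buf.write(struct.pack("<BI", a.shape[0], a.shape[1]))
    buf.write(a.tobytes())


def _read_array(buf: io.BytesIO) -> np.ndarray:
    rows, cols = struct.unpack("<BI", buf.read(5))
    data = buf.read(rows * cols * 8)
    return np.frombuffer(data, dtype="<u8").reshape(rows, cols).astype(np.uint64)


def _header(tag: bytes, digest: str) -> bytes:
    return MAGIC + struct.pack("<H", VERSION) + digest.encode() + tag


def _check_header(buf: io.BytesIO, expect_tag: bytes, digest: str | None) -> str:
    if buf.read(4) != MAGIC:
        raise ParameterError("not a ciphergeno container")
    (ver,) = struct.unpack("<H", buf.read(2))
    if ver != VERSION:
        raise ParameterError(f"unsupported container version {ver}")
    found = buf.read(16).decode()
    tag = buf.read(4)
    if tag != expect_tag:
        raise ParameterError(f"expected {expect_tag!r} container, found {tag!r}")
    if digest is not None and found != digest:
        raise DigestMismatchError(
            f"artifact digest {found} does not match parameters {digest}")
    return found


# -- ciphertexts -------------------------------------------------------------
def ciphertext_bytes(ct: Ciphertext, digest: str) -> bytes:
    buf = io.BytesIO()
    buf.write(_header(TAG_CIPHERTEXT, digest))
    buf.write(struct.pack("<Bd", ct.level, ct.scale))
    _write_array(buf, ct.c0)
    _write_array(buf, ct.c1)
    return buf.getvalue()


def ciphertext_from_bytes(data: bytes, digest: str | None = None) -> Ciphertext:
    buf = io.BytesIO(data)
    _check_header(buf, TAG_CIPHERTEXT, digest)
    level, scale = struct.unpack("<Bd", buf.read(9))
    return Ciphertext(_read_array(buf), _read_array(buf), level, scale)


def ct_bundle_bytes(cts: list[Ciphertext], digest: str,
                    meta: dict | None = None) -> bytes:
    """A list of ciphertexts plus a JSON metadata blob (e.g. the BSGS plan)."""
    buf = io.BytesIO()
    buf.write(_header(TAG_CT_BUNDLE, digest))
    blob = json.dumps(meta or {}, sort_keys=True).encode()
    buf.write(struct.pack("<I", len(blob)))
    buf.write(blob)
    buf.write(struct.pack("<I", len(cts)))
    for ct in cts:
        buf.write(struct.pack("<Bd", ct.level, ct.scale))
        _write_array(buf, ct.c0)
        _write_array(buf, ct.c1)
    return buf.getvalue()


def ct_bundle_from_bytes(data: bytes,
                         digest: str | None = None) -> tuple[list[Ciphertext], dict]:
    buf = io.BytesIO(data)
    _check_header(buf, TAG_CT_BUNDLE, digest)
    (blen,) = struct.unpack("<I", buf.read(4))
    meta = json.loads(buf.read(blen).decode())
    (count,) = struct.unpack("<I", buf.read(4))
    cts = []
    for _ in range(count):
        level, scale = struct.unpack("<Bd", buf.read(9))
        cts.append(Ciphertext(_read_array(buf), _read_array(buf), level, scale))
    return cts, meta


def plan_from_meta(meta: dict) -> BsgsPlan:
    return BsgsPlan(meta["l"], meta["n_sub"], meta["g"], meta["b"],
                    meta["gamma"], meta["s"], meta["complex_packed"],
                    meta["m_rows"], meta["n_cols"])


# -- keys --------------------------------------------------------------------
def _write_ksk(buf: io.BytesIO, ksk: KeySwitchKey) -> None:
    buf.write(struct.pack("<B", len(ksk.alpha)))
    for a, b in zip(ksk.alpha, ksk.beta):
        _write_array(buf, a)
        _write_array(buf, b)


def _read_ksk(buf: io.BytesIO) -> KeySwitchKey:
    (ndig,) = struct.unpack("<B", buf.read(1))
    alpha, beta = [], []
    for _ in range(ndig):
        alpha.append(_read_array(buf))
        beta.append(_read_array(buf))
    return KeySwitchKey(alpha, beta)


def secret_key_bytes(bundle: KeyBundle) -> bytes:
    buf = io.BytesIO()
    buf.write(_header(TAG_SECRET, bundle.digest))
    _write_array(buf, bundle.secret)
    return buf.getvalue()


def public_key_bytes(bundle: KeyBundle) -> bytes:
    buf = io.BytesIO()
    buf.write(_header(TAG_PUBLIC, bundle.digest))
    _write_array(buf, bundle.public_a)
    _write_array(buf, bundle.public_b)
    return buf.getvalue()


def relin_key_bytes(bundle: KeyBundle) -> bytes:
    buf = io.BytesIO()
    buf.write(_header(TAG_RELIN, bundle.digest))
    _write_ksk(buf, bundle.relin)
    return buf.getvalue()


def galois_keys_bytes(bundle: KeyBundle) -> bytes:
    buf = io.BytesIO()
    buf.write(_header(TAG_GALOIS, bundle.digest))
    buf.write(struct.pack("<I", len(bundle.galois)))
    for step in sorted(bundle.galois):
        buf.write(struct.pack("<I", step))
        _write_ksk(buf, bundle.galois[step])
    return buf.getvalue()


def load_secret_key(data: bytes, digest: str | None = None) -> np.ndarray:
    buf = io.BytesIO(data)
    _check_header(buf, TAG_SECRET, digest)
    return _read_array(buf)


def load_public_key(data: bytes,
                    digest: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    buf = io.BytesIO(data)
    _check_header(buf, TAG_PUBLIC, digest)
    return _read_array(buf), _read_array(buf)


def load_relin_key(data: bytes, digest: str | None = None) -> KeySwitchKey:
    buf = io.BytesIO(data)
    _check_header(buf, TAG_RELIN, digest)
    return _read_ksk(buf)


def load_galois_keys(data: bytes,
                     digest: str | None = None) -> dict[int, KeySwitchKey]:
    buf = io.BytesIO(data)
    _check_header(buf, TAG_GALOIS, digest)
    (count,) = struct.unpack("<I", buf.read(4))
    out = {}
    for _ in range(count):
        (step,) = struct.unpack("<I", buf.read(4))
        out[step] = _read_ksk(buf)
    return out
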