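"""Minimal DICOM (explicit VR little endian) encoder/decoder.

Supports exactly what the RT Plan / RT Dose round-trip needs: flat data
elements with the common VRs, nested sequences written with undefined
lengths, and a standard Part-10 file header.  Not a general DICOM
implementation — unknown transfer syntaxes are rejected up front.
"""

from __future__ import annotations

import hashlib
import struct
from typing import Any

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
UID_ROOT = "1.2.826.0.1.3680043.10.1474"  # org-root style prefix for generated UIDs

# VRs that use the 4-byte length form (2 reserved bytes after the VR code)
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT",
               "PN", "SH", "ST", "TM", "UI", "UT"}


class DicomError(ValueError):
    pass


class Element:
    __slots__ = ("tag", "vr", "value")

    def __init__(self, tag: tuple[int, int], vr: str, value: Any):
        self.tag = tag
        self.vr = vr
        self.value = value

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Element({self.tag[0]:04X},{self.tag[1]:04X} {self.vr} {self.value!r})"


class Dataset(dict):
    """Tag -> Element mapping with convenience accessors."""

    def add(self, group: int, elem: int, vr: str, value: Any) -> None:
        self[(group, elem)] = Element((group, elem), vr, value)

    def get_value(self, tag: tuple[int, int], default=None):
        el = self.get(tag)
        return default if el is None else el.value

    def require(self, tag: tuple[int, int], what: str):
        el = self.get(tag)
        if el is None:
            raise DicomError(f"missing required element {what} "
                             f"({tag[0]:04X},{tag[1]:04X})")
        return el.value


def deterministic_uid(*parts) -> str:
    """A valid UID derived from a hash of the given parts (reproducible)."""
    h = hashlib.sha256("/".join(str(p) for p in parts).encode()).hexdigest()
    return f"{UID_ROOT}.{int(h[:24], 16) % 10**24}"


# ---------------------------------------------------------------------------
# encoding

def _encode_string(vr: str, value) -> bytes:
    if isinstance(value, (list, tuple)):
        text = "\\".join(str(v) for v in value)
    else:
        text = str(value)
    raw = text.encode("ascii")
    if len(raw) % 2:
        raw += b"\x00" if vr == "UI" else b" "
    return raw


def _encode_value(el: Element) -> bytes:
    vr, value = el.vr, el.value
    if vr in _STRING_VRS:
        return _encode_string(vr, value)
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    if vr == "FL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}f", *[float(v) for v in vals])
    if vr == "FD":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}d", *[float(v) for v in vals])
    if vr in ("OB", "OW"):
        raw = bytes(value)
        if len(raw) % 2:
            raw += b"\x00"
        return raw
    raise DicomError(f"unsupported VR for encoding: {vr}")


def _write_element(buf: bytearray, el: Element) -> None:
    group, elem = el.tag
    if el.vr == "SQ":
        buf += struct.pack("<HH", group, elem)
        buf += b"SQ\x00\x00" + struct.pack("<I", 0xFFFFFFFF)
        for item in el.value:
            buf += struct.pack("<HHI", 0xFFFE, 0xE000, 0xFFFFFFFF)
            _write_dataset(buf, item)
            buf += struct.pack("<HHI", 0xFFFE, 0xE00D, 0)
        buf += struct.pack("<HHI", 0xFFFE, 0xE0DD, 0)
        return
    raw = _encode_value(el)
    buf += struct.pack("<HH", group, elem)
    if el.vr in _LONG_VRS:
        buf += el.vr.encode() + b"\x00\x00" + struct.pack("<I", len(raw))
    else:
        if len(raw) > 0xFFFF:
            raise DicomError(f"value too long for short VR {el.vr}")
        buf += el.vr.encode() + struct.pack("<H", len(raw))
    buf += raw


def _write_dataset(buf: bytearray, ds: Dataset) -> None:
    for tag in sorted(ds):
        _write_element(buf, ds[tag])


def write_file(path, ds: Dataset, sop_class_uid: str, sop_instance_uid: str) -> None:
    """Write a Part-10 file (preamble + file meta + explicit-LE dataset)."""
    meta = Dataset()
    meta.add(0x0002, 0x0001, "OB", b"\x00\x01")
    meta.add(0x0002, 0x0002, "UI", sop_class_uid)
    meta.add(0x0002, 0x0003, "UI", sop_instance_uid)
    meta.add(0x0002, 0x0010, "UI", EXPLICIT_VR_LE)
    meta.add(0x0002, 0x0012, "UI", UID_ROOT + ".1")
    meta_buf = bytearray()
    _write_dataset(meta_buf, meta)
    head = bytearray()
    group_len = Element((0x0002, 0x0000), "UL", len(meta_buf))
    _write_element(head, group_len)
    body = bytearray()
    _write_dataset(body, ds)
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(head)
        fh.write(meta_buf)
        fh.write(body)


# ---------------------------------------------------------------------------
# decoding

def _decode_value(vr: str, raw: bytes):
    if vr in _STRING_VRS:
        text = raw.decode("ascii").rstrip("\x00 ")
        if "\\" in text:
            return text.split("\\")
        return text
    if vr == "US":
        vals = list(struct.unpack(f"<{len(raw)//2}H", raw))
    elif vr == "UL":
        vals = list(struct.unpack(f"<{len(raw)//4}I", raw))
    elif vr == "FL":
        vals = list(struct.unpack(f"<{len(raw)//4}f", raw))
    elif vr == "FD":
        vals = list(struct.unpack(f"<{len(raw)//8}d", raw))
    elif vr in ("OB", "OW", "UN"):
        return raw
    else:
        raise DicomError(f"unsupported VR for decoding: {vr}")
    return vals[0] if len(vals) == 1 else vals


class _Reader:
    def __init__(self, data: bytes, pos: int = 0):
        self.data = data
        self.pos = pos

    def u16(self):
        (v,) = struct.unpack_from("<H", self.data, self.pos)
        self.pos += 2
        return v

    def u32(self):
        (v,) = struct.unpack_from("<I", self.data, self.pos)
        self.pos += 4
        return v

    def take(self, n):
        raw = self.data[self.pos:self.pos + n]
        self.pos += n
        return raw

    def at_end(self):
        return self.pos >= len(self.data)


def _read_dataset(rd: _Reader, stop_at_item_delim: bool = False) -> Dataset:
    ds = Dataset()
    while not rd.at_end():
        group = rd.u16()
        elem = rd.u16()
        if group == 0xFFFE:
            length = rd.u32()
            if elem == 0xE00D and stop_at_item_delim:
                return ds
            raise DicomError(f"unexpected delimiter ({group:04X},{elem:04X})")
        vr = rd.take(2).decode("ascii")
        if vr in _LONG_VRS:
            rd.take(2)
            length = rd.u32()
        else:
            length = rd.u16()
        if vr == "SQ":
            items = []
            if length == 0xFFFFFFFF:
                while True:
                    g, e = rd.u16(), rd.u16()
                    ln = rd.u32()
                    if (g, e) == (0xFFFE, 0xE0DD):
                        break
                    if (g, e) != (0xFFFE, 0xE000):
                        raise DicomError("malformed sequence item")
                    if ln == 0xFFFFFFFF:
                        items.append(_read_dataset(rd, stop_at_item_delim=True))
                    else:
                        items.append(_read_dataset(_Reader(rd.take(ln))))
            else:
                sub = _Reader(rd.take(length))
                while not sub.at_end():
                    g, e = sub.u16(), sub.u16()
                    ln = sub.u32()
                    if (g, e) != (0xFFFE, 0xE000):
                        raise DicomError("malformed sequence item")
                    items.append(_read_dataset(_Reader(sub.take(ln))))
            ds[(group, elem)] = Element((group, elem), "SQ", items)
            continue
        raw = rd.take(length)
        ds[(group, elem)] = Element((group, elem), vr, _decode_value(vr, raw))
    return ds


def read_file(path) -> Dataset:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[128:132] != b"DICM":
        raise DicomError(f"{path}: missing DICM magic")
    rd = _Reader(data, 132)
    # file meta group (always explicit LE)
    group = struct.unpack_from("<H", data, rd.pos)[0]
    meta = Dataset()
    while not rd.at_end():
        group = struct.unpack_from("<H", data, rd.pos)[0]
        if group != 0x0002:
            break
        g, e = rd.u16(), rd.u16()
        vr = rd.take(2).decode("ascii")
        if vr in _LONG_VRS:
            rd.take(2)
            length = rd.u32()
        else:
            length = rd.u16()
        raw = rd.take(length)
        meta[(g, e)] = Element((g, e), vr, _decode_value(vr, raw))
    ts = meta.get_value((0x0002, 0x0010))
    if ts != EXPLICIT_VR_LE:
        raise DicomError(f"unsupported transfer syntax: {ts}")
    return _read_dataset(rd)
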