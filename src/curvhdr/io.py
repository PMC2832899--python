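"""File I/O: event tables (CSV/TSV and list-mode FCS), gate JSON, membership CSV.

The FCS support is a minimal, self-contained codec for FCS 2.0/3.0/3.1
list-mode files: integer (8/16/32/64-bit), float and double data types,
both byte orders, channel names from ``$PnN`` with ``$PnS`` fallback.  The
writer emits FCS 3.0 float32 list-mode files and exists mainly so round
trips can be exercised without vendor files; reading arbitrary vendor
extensions is best-effort.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .errors import FormatError, ValidationError
from .preprocess import EventTable

__all__ = [
    "read_events",
    "write_events_csv",
    "read_fcs",
    "write_fcs",
    "write_gate",
    "read_gate",
    "write_membership_csv",
]


def read_events(
    path: str | Path, format: str | None = None, channels: list[str] | None = None
) -> EventTable:
    """Load an event table from FCS or delimited text (original units)."""
    path = Path(path)
    fmt = format or {".fcs": "fcs", ".tsv": "tsv", ".txt": "tsv"}.get(
        path.suffix.lower(), "csv"
    )
    if fmt == "fcs":
        table = read_fcs(path)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
        table = EventTable(
            df.to_numpy(dtype=float), tuple(str(c) for c in df.columns), "original"
        )
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    if channels:
        table = table.select(list(channels))
    return table


def write_events_csv(path: str | Path, table: EventTable) -> None:
    pd.DataFrame(table.values, columns=list(table.channel_names)).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FormatError(f"empty TEXT segment at offset {offset}")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.strip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    return {
        parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)
    }


def read_fcs(path: str | Path) -> EventTable:
    """Read a list-mode FCS 2.0/3.0/3.1 file."""
    raw = Path(path).read_bytes()
    version = raw[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS"):
        raise FormatError(f"not an FCS file (bad magic {version!r} at offset 0)")
    if version[3:] not in ("2.0", "3.0", "3.1"):
        raise FormatError(f"unsupported FCS version {version!r}")

    def header_int(lo: int, hi: int) -> int:
        s = raw[lo:hi].decode("latin-1").strip()
        try:
            return int(s) if s else 0
        except ValueError as exc:
            raise FormatError(f"bad header offset field at byte {lo}") from exc

    text_beg, text_end = header_int(10, 18), header_int(18, 26)
    data_beg, data_end = header_int(26, 34), header_int(34, 42)
    kw = _parse_text_segment(raw[text_beg : text_end + 1], text_beg)
    if data_beg == 0:
        data_beg = int(kw.get("$BEGINDATA", 0))
    if data_end == 0:
        data_end = int(kw.get("$ENDDATA", 0))
    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"only list mode is supported, got $MODE={kw.get('$MODE')}")
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].upper()
    except KeyError as exc:
        raise FormatError(f"missing required keyword {exc} in TEXT segment") from exc
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        bits = {int(kw.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise FormatError("integer FCS data requires uniform $PnB of 8/16/32/64")
        nbytes = int(kw["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    data = raw[data_beg : data_beg + expected]
    if len(data) < expected:
        raise FormatError(
            f"DATA segment truncated at offset {data_beg}: "
            f"need {expected} bytes, have {len(data)}"
        )
    values = np.frombuffer(data, dtype=dtype).reshape(n_tot, n_par).astype(float)
    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        names.append(name)
    # de-duplicate (vendor files occasionally repeat short names)
    seen: dict[str, int] = {}
    unique = []
    for name in names:
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        unique.append(name)
    return EventTable(values, tuple(unique), "original")


def write_fcs(path: str | Path, table: EventTable) -> None:
    """Write a minimal FCS 3.0 list-mode file (float32, little-endian)."""
    n, d = table.n, table.d
    data = np.ascontiguousarray(table.values, dtype="<f4").tobytes()
    delim = "/"
    pairs = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(d),
        "$TOT": str(n),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(table.channel_names, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(np.ceil(max(1.0, table.values[:, i - 1].max()))))

    header_len = 58
    # offsets depend on the TEXT length which depends on the offsets: iterate
    beg_data, end_data = 0, 0
    for _ in range(4):
        kv = dict(pairs)
        kv["$BEGINDATA"] = str(beg_data)
        kv["$ENDDATA"] = str(end_data)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
        new_beg = header_len + len(text)
        new_end = new_beg + len(data) - 1
        if (new_beg, new_end) == (beg_data, end_data):
            break
        beg_data, end_data = new_beg, new_end
    text_beg = header_len
    text_end = text_beg + len(text) - 1
    header = (
        b"FCS3.0    "
        + f"{text_beg:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{beg_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + b"       0"
        + b"       0"
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text.encode("latin-1") + data)


# ---------------------------------------------------------------------------
# gates and membership
# ---------------------------------------------------------------------------

def write_gate(path: str | Path, region: geometry.GateRegion) -> None:
    Path(path).write_text(json.dumps(geometry.region_to_dict(region)))


def read_gate(path: str | Path) -> geometry.GateRegion:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"gate file is not valid JSON: {exc}") from exc
    return geometry.region_from_dict(data)


def write_membership_csv(path: str | Path, membership: np.ndarray) -> None:
    pd.DataFrame(
        {"event_index": np.arange(len(membership)), "member": membership.astype(int)}
    ).to_csv(path, index=False)
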