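"""Minimal FCS 3.0/3.1 reader and writer.

Supports list-mode ($MODE L) files with float ($DATATYPE F/D) or integer
($DATATYPE I, 16/32 bit) data, which covers files exported by acquisition
software for downstream analysis. Values are honoured as stored; the only
transform applied is the standard $PnE antilog rule when a parameter declares
a non-identity log amplifier (value = 10^(f1·x/$PnR) · f2).

Keyword-value escaping by delimiter doubling is not implemented; keys and
values containing the delimiter are rejected on write.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .events import ChannelMap, DEFAULT_CHANNEL_MAP, EventTable, SampleMeta

_DELIM = "/"


def _text_segment(keywords: Mapping[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        key, value = str(key), str(value)
        if _DELIM in key or _DELIM in value:
            raise FormatError(f"delimiter {_DELIM!r} inside keyword {key!r}")
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(table: EventTable, path: str | Path, columns: list[str] | None = None) -> None:
    """Write the numeric *columns* of *table* (default: all numeric) as FCS 3.0.

    Data are stored as little-endian float32; per-parameter $PnN carries the
    column name, so a round-trip read restores values to float32 precision.
    """
    df = table.data
    if columns is None:
        columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    if not columns:
        raise FormatError("no numeric columns to write")
    data = df[columns].to_numpy(dtype=np.float32)
    n_events, n_par = data.shape

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 8,  # placeholder, patched below
        "$ENDDATA": "0" * 8,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        rng = float(np.nanmax(data[:, i - 1])) if n_events else 1.0
        keywords[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    header_len = 58
    text = _text_segment(keywords)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    # patch the data offsets with fixed-width values so lengths stay stable
    keywords["$BEGINDATA"] = f"{data_begin:08d}"
    keywords["$ENDDATA"] = f"{data_end:08d}"
    text = _text_segment(keywords)

    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.astype("<f4").tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)[1:]
    if len(parts) < 2:
        raise FormatError("unparseable TEXT segment")
    kv: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        if key:
            kv[key.strip().upper()] = value
    return kv


def read_fcs(
    path: str | Path,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
    meta: SampleMeta | None = None,
) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Parameter names are resolved against *channel_map* using $PnN first and
    $PnS as fallback; intensities come out on the linear scale. Raises
    :class:`FormatError` on malformed headers and :class:`SchemaError` when
    no parameter maps to the autofluorescence role.
    """
    blob = Path(path).read_bytes()
    if len(blob) < 58 or not blob[:6].startswith(b"FCS3"):
        raise FormatError("not an FCS 3.x file (bad header)")

    def _offset(lo: int, hi: int) -> int:
        chunk = blob[lo:hi].decode("ascii", errors="replace").strip()
        try:
            return int(chunk) if chunk else 0
        except ValueError as exc:
            raise FormatError(f"bad header offset {chunk!r}") from exc

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    if text_begin <= 0 or text_end <= text_begin:
        raise FormatError("invalid TEXT segment offsets")
    kv = _parse_text(blob[text_begin : text_end + 1])

    try:
        n_events = int(kv["$TOT"])
        n_par = int(kv["$PAR"])
        datatype = kv["$DATATYPE"].upper()
        byteord = kv.get("$BYTEORD", "1,2,3,4")
    except KeyError as exc:
        raise FormatError(f"missing required keyword {exc}") from exc
    if kv.get("$MODE", "L").upper() != "L":
        raise FormatError("only list-mode ($MODE L) files are supported")

    data_begin = _offset(26, 34) or int(kv.get("$BEGINDATA", 0))
    data_end = _offset(34, 42) or int(kv.get("$ENDDATA", 0))
    if data_begin <= 0:
        data_begin = int(kv.get("$BEGINDATA", 0))
        data_end = int(kv.get("$ENDDATA", 0))
    if data_begin <= 0 or data_end < data_begin:
        raise FormatError("invalid DATA segment offsets")

    endian = "<" if byteord.startswith("1") else ">"
    bits = [int(kv.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        fmts = {32: "f4", 64: "f8"}
    elif datatype == "D":
        fmts = {64: "f8"}
    elif datatype == "I":
        fmts = {16: "u2", 32: "u4"}
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")
    try:
        dtypes = [np.dtype(endian + fmts[b]) for b in bits]
    except KeyError as exc:
        raise FormatError(f"unsupported $PnB {exc} for $DATATYPE {datatype}") from exc

    raw = blob[data_begin : data_end + 1]
    row_bytes = sum(dt.itemsize for dt in dtypes)
    if len(raw) < row_bytes * n_events:
        raise FormatError("DATA segment shorter than $TOT×$PAR")
    if len(set(dtypes)) == 1:
        arr = np.frombuffer(raw[: row_bytes * n_events], dtype=dtypes[0]).reshape(
            n_events, n_par
        ).astype(float)
    else:  # mixed widths: struct-unpack row by row (rare, small files)
        fmt = endian + "".join(
            {"u2": "H", "u4": "I", "f4": "f", "f8": "d"}[fmts[b]] for b in bits
        )
        arr = np.array(
            [struct.unpack_from(fmt, raw, i * row_bytes) for i in range(n_events)],
            dtype=float,
        )

    names = []
    for i in range(1, n_par + 1):
        names.append(kv.get(f"$P{i}N", kv.get(f"$P{i}S", f"P{i}")))
        # standard antilog rule for log-amplified parameters
        pne = kv.get(f"$P{i}E", "0,0").split(",")
        f1 = float(pne[0]) if pne[0] else 0.0
        f2 = float(pne[1]) if len(pne) > 1 and pne[1] else 0.0
        if f1 != 0.0:
            rng = float(kv.get(f"$P{i}R", "1024"))
            arr[:, i - 1] = 10.0 ** (f1 * arr[:, i - 1] / rng) * (f2 if f2 > 0 else 1.0)

    df = pd.DataFrame(arr, columns=names)
    rename = channel_map.resolve(names)
    # fall back to $PnS short names for unresolved roles
    if "af" not in rename.values():
        short = {
            names[i - 1]: kv.get(f"$P{i}S", "") for i in range(1, n_par + 1)
        }
        for col, s in short.items():
            if s:
                r = channel_map.resolve([s])
                if r.get(s) and r[s] not in rename.values():
                    rename[col] = r[s]
    df = df.rename(columns=rename)
    from .events import _ALIAS_PATTERNS, _normalize  # feature-name aliases

    df = df.rename(
        columns={c: _ALIAS_PATTERNS[_normalize(c)] for c in df.columns if _normalize(c) in _ALIAS_PATTERNS}
    )
    if "af" not in df.columns:
        raise SchemaError("no FCS parameter maps to the autofluorescence role")
    return EventTable(df, meta=meta)
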