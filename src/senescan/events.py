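"""Per-event tables: reading, writing and merging cytometry feature exports.

The in-memory container is a thin wrapper around a :class:`pandas.DataFrame`
with canonical column names. Morphology features are stored in instrument
units (areas in µm², lengths in µm); channel intensities are stored linear
under role names (``af``, ``dapi``, ``annexin``, ``dox``, ``bf``) — log or
other display transforms are an analysis-stage concern, never applied at I/O
time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MergeError, ParseError, SchemaError

#: canonical morphology feature columns (units: µm² for area, µm for lengths)
FEATURE_COLUMNS = (
    "area",
    "aspect_ratio",
    "circularity",
    "shape_ratio",
    "width",
    "height",
    "diameter",
)

#: channel roles stored under these column names (linear intensities, a.u.)
ROLE_COLUMNS = ("af", "dapi", "annexin", "dox", "bf")

#: columns that may carry signed values (scores appended downstream)
SIGNED_COLUMNS = ("si", "mlsc", "mlsc2")

_ALIAS_PATTERNS = {
    "area": "area",
    "aspectratio": "aspect_ratio",
    "aspectratiointensity": "aspect_ratio",
    "circularity": "circularity",
    "shaperatio": "shape_ratio",
    "width": "width",
    "height": "height",
    "diameter": "diameter",
    "eventid": "event_id",
    "objectnumber": "event_id",
    "sampleid": "sample_id",
    "condition": "condition",
}


def _normalize(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


@dataclass(frozen=True)
class ChannelMap:
    """Maps detection roles to instrument channel names.

    Defaults follow the FlowSight layout used throughout: brightfield Ch01,
    autofluorescence Ch02 (480–560 nm), doxorubicin Ch04, DAPI Ch07
    (435–505 nm), Annexin-APC Ch11 (640–745 nm). The autofluorescence role is
    mandatory for every table.
    """

    autofluorescence: str = "Ch02"
    brightfield: str = "Ch01"
    dox: str = "Ch04"
    dapi: str = "Ch07"
    annexin: str = "Ch11"

    #: role -> canonical column name
    ROLE_NAMES = {
        "autofluorescence": "af",
        "brightfield": "bf",
        "dox": "dox",
        "dapi": "dapi",
        "annexin": "annexin",
    }

    def resolve(self, columns: Sequence[str]) -> dict[str, str]:
        """Return mapping ``source column -> role column`` for *columns*.

        A column matches a role if its name equals the mapped channel name
        (case-insensitively), contains it as a token (``Intensity_MC_Ch02``),
        or already equals the role column name itself.
        """
        out: dict[str, str] = {}
        norm_cols = {c: _normalize(c) for c in columns}
        for role, channel in (
            ("autofluorescence", self.autofluorescence),
            ("brightfield", self.brightfield),
            ("dox", self.dox),
            ("dapi", self.dapi),
            ("annexin", self.annexin),
        ):
            target = self.ROLE_NAMES[role]
            chan_norm = _normalize(channel)
            for col, ncol in norm_cols.items():
                if col in out:
                    continue
                if ncol == _normalize(target) or ncol == chan_norm or (
                    chan_norm and chan_norm in ncol
                ):
                    out[col] = target
                    break
        return out


DEFAULT_CHANNEL_MAP = ChannelMap()


@dataclass
class SampleMeta:
    """Free-form acquisition metadata attached to one sample."""

    sample_id: str
    condition: str = "unknown"  # proliferating | senescent | unknown
    model: str = ""  # cell model, e.g. "HUVEC"
    note: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SampleMeta":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class EventTable:
    """Per-event feature matrix plus optional sample metadata.

    ``data`` always carries ``event_id`` (unique within ``sample_id``) and
    ``sample_id``. Ground-truth columns from the synthetic generator
    (``true_phenotype``, ``true_structure``, ``true_af``) and gate labels are
    plain extra columns.
    """

    data: pd.DataFrame
    meta: SampleMeta | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.data
        if "event_id" not in df.columns:
            df = df.assign(event_id=np.arange(len(df)))
        if "sample_id" not in df.columns:
            sid = self.meta.sample_id if self.meta else "S0"
            df = df.assign(sample_id=sid)
        self.data = df.reset_index(drop=True)
        self.validate()

    # -- container sugar ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def feature_columns(self) -> list[str]:
        known = set(FEATURE_COLUMNS) | set(ROLE_COLUMNS)
        return [c for c in self.data.columns if c in known]

    def validate(self) -> None:
        df = self.data
        if "af" not in df.columns:
            raise SchemaError("mandatory autofluorescence column 'af' is missing")
        dup = df.duplicated(subset=["sample_id", "event_id"])
        if dup.any():
            raise SchemaError(
                f"event_id not unique within sample_id (first duplicate row {int(np.argmax(dup.values))})"
            )
        for col in self.feature_columns():
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise SchemaError(f"column '{col}' contains non-finite values")
            if col not in SIGNED_COLUMNS and np.any(vals < 0):
                raise SchemaError(f"column '{col}' contains negative values")

    def with_columns(self, **cols) -> "EventTable":
        return EventTable(self.data.assign(**cols), meta=self.meta)


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    for col in columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {raw.loc[row]!r} in column '{col}' at row {row}"
            )
        df[col] = num.astype(float)
    return df


def read_feature_table(
    path: str | Path,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
    meta: SampleMeta | None = None,
) -> EventTable:
    """Read a delimited per-event export (IDEAS-style CSV/TSV).

    Feature columns are resolved via case/punctuation-insensitive aliases
    (``Aspect Ratio`` -> ``aspect_ratio``); channel intensity columns are
    resolved through *channel_map*. Unknown columns are preserved untouched.
    Raises :class:`SchemaError` if no column maps to the autofluorescence
    role, and :class:`ParseError` (with row index) on non-numeric cells.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    rename: dict[str, str] = {}
    for col in df.columns:
        alias = _ALIAS_PATTERNS.get(_normalize(col))
        if alias:
            rename[col] = alias
    rename.update(channel_map.resolve([c for c in df.columns if c not in rename]))
    df = df.rename(columns=rename)
    # drop duplicate targets keeping the first occurrence
    df = df.loc[:, ~df.columns.duplicated()]
    if "af" not in df.columns:
        raise SchemaError(
            "no column resolves to the mandatory autofluorescence role "
            f"(looked for '{channel_map.autofluorescence}')"
        )
    numeric = [c for c in df.columns if c in set(FEATURE_COLUMNS) | set(ROLE_COLUMNS)]
    df = _coerce_numeric(df, numeric)
    return EventTable(df, meta=meta)


def write_feature_table(table: EventTable, path: str | Path) -> None:
    """Write *table* as comma-separated UTF-8 with canonical column names.

    The canonical names round-trip through :func:`read_feature_table`
    unchanged (the reader recognises role names directly).
    """
    table.data.to_csv(Path(path), index=False)
    if table.meta is not None:
        table.meta.to_json(Path(path).with_suffix(".meta.json"))


def merge_tables(
    tables: Sequence[EventTable], keep_provenance: bool = True
) -> EventTable:
    """Concatenate samples into one merged table.

    All inputs must share the same feature/channel column set (the analysis
    works on merged files of whole populations); ``event_id`` is re-keyed to
    stay unique across the merge while ``sample_id`` retains provenance.
    """
    if not tables:
        raise MergeError("nothing to merge")
    ref_cols = set(tables[0].feature_columns())
    for t in tables[1:]:
        cols = set(t.feature_columns())
        if cols != ref_cols:
            diff = sorted(cols.symmetric_difference(ref_cols))
            raise MergeError(f"feature column sets differ: {diff}")
    frames = []
    for t in tables:
        df = t.data.copy()
        if keep_provenance and t.meta is not None:
            if "condition" not in df.columns:
                df["condition"] = t.meta.condition
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    merged["event_id"] = np.arange(len(merged))
    return EventTable(merged)
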