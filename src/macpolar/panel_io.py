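"""Readers and writers for the tabular formats the pipeline exchanges.

Everything is plain delimited text (tab-separated by default, comma via
``sep=","``) so the core pipeline has no binary-format dependency.  FCS 3.x
reading is available when ``fcsparser`` or ``flowio`` is installed; the
delimited path never requires it.

The shared in-memory containers live here too: :class:`MarkerPanel` (which
markers feed which composite score), :class:`MFIMatrix` (samples x markers
median fluorescence intensities with per-sample metadata) and the event-level
:class:`~macpolar.gating.EventTable` re-exported from :mod:`macpolar.gating`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .gating import EventTable

ROLES = ("M1", "M2", "stemness", "immunomodulation")

#: Marker panel used throughout: five M1 and two M2 surface markers.
DEFAULT_PANEL_ENTRIES = (
    ("CD86", "M1"),
    ("CD80", "M1"),
    ("MHC II", "M1"),
    ("CD274", "M1"),
    ("CD11c", "M1"),
    ("CD163", "M2"),
    ("CD206", "M2"),
)

#: Name variants folded together when matching marker names.
DEFAULT_ALIASES: Mapping[str, str] = {
    "mhc-ii": "mhc ii",
    "mhcii": "mhc ii",
    "hla-dr": "mhc ii",
    "pd-l1": "cd274",
    "mhc-i": "mhc i",
    "mhci": "mhc i",
}


def _canon(name: str, aliases: Mapping[str, str] | None = None) -> str:
    key = " ".join(name.strip().lower().split())
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({_canon(k): _canon(v) for k, v in aliases.items()})
    return table.get(key, key)


@dataclass(frozen=True)
class PanelEntry:
    marker: str
    role: str
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown marker role {self.role!r} for {self.marker!r}; "
                f"allowed: {', '.join(ROLES)}"
            )


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of markers, each with a functional role.

    Marker names are matched case-insensitively with whitespace collapsed,
    and common synonyms (``MHC-II`` vs ``MHC II``) folded via an alias map.
    """

    entries: tuple[PanelEntry, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            c = _canon(e.marker, self.aliases)
            if c in seen:
                raise ValidationError(f"duplicate marker in panel: {e.marker!r}")
            seen.add(c)

    def markers(self, role: str | None = None) -> tuple[str, ...]:
        if role is not None and role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        return tuple(e.marker for e in self.entries if role is None or e.role == role)

    @property
    def m1_markers(self) -> tuple[str, ...]:
        return self.markers("M1")

    @property
    def m2_markers(self) -> tuple[str, ...]:
        return self.markers("M2")

    def require_polarization_markers(self) -> None:
        if not self.m1_markers or not self.m2_markers:
            raise ValidationError(
                "polarization scoring needs at least one M1 and one M2 marker; "
                f"panel has {len(self.m1_markers)} M1 and {len(self.m2_markers)} M2"
            )

    def resolve(self, names: Iterable[str], role: str) -> list[str]:
        """Map this panel's ``role`` markers onto column names in ``names``.

        Raises :class:`ValidationError` listing every marker that has no
        (alias-folded, case-insensitive) match.
        """
        lookup = {_canon(n, self.aliases): n for n in names}
        found, missing = [], []
        for m in self.markers(role):
            c = _canon(m, self.aliases)
            if c in lookup:
                found.append(lookup[c])
            else:
                missing.append(m)
        if missing:
            raise ValidationError(
                f"{role} markers missing from data: {', '.join(missing)}; "
                f"available: {', '.join(names)}"
            )
        return found


def default_panel() -> MarkerPanel:
    return MarkerPanel(tuple(PanelEntry(m, r) for m, r in DEFAULT_PANEL_ENTRIES))


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str = ""
    group: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"replicate must be >= 1, got {self.replicate} for {self.sample_id!r}"
            )


# metadata columns recognised in an MFI table, besides the sample_id column
META_COLUMNS = ("condition", "group", "replicate")


@dataclass
class MFIMatrix:
    """Samples x markers median fluorescence intensities (a.u., > 0)."""

    values: pd.DataFrame  # index: sample_id, columns: markers
    meta: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate marker columns")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("MFI matrix contains non-finite values")
        if (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                f"non-positive MFI at sample {idx[r]!r}, marker "
                f"{self.values.columns[c]!r}: {arr[r, c]}"
            )
        if not self.meta:
            self.meta = [SampleMeta(str(s)) for s in idx]
        if [m.sample_id for m in self.meta] != [str(s) for s in idx]:
            raise ValidationError("metadata not aligned with sample order")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def features(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def meta_for(self, sample_id: str) -> SampleMeta:
        for m in self.meta:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# event tables


def read_event_table(path: str | Path, dialect: str = "delimited", *,
                     sample_id: str | None = None, sep: str = "\t") -> EventTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "fcs":
        return _read_fcs(path, sample_id)
    if dialect != "delimited":
        raise ValidationError(f"unknown dialect {dialect!r}; use 'delimited' or 'fcs'")
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: zero events")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = int(np.argmax(bad.isna().to_numpy()))
            raise FormatError(
                f"{path}: non-numeric value in channel {col!r} at data row {row}"
            )
        df[col] = bad.astype(float)
    return EventTable(sample_id or path.stem, df)


def _read_fcs(path: Path, sample_id: str | None) -> EventTable:
    # Optional dependency: delimited export is the always-available path.
    try:
        import fcsparser
    except ImportError:
        try:
            import flowio
        except ImportError as exc:
            raise FormatError(
                "FCS reading needs the optional 'fcsparser' (or 'flowio') package; "
                "export the events as a delimited table instead"
            ) from exc
        fd = flowio.FlowData(str(path))
        data = np.reshape(fd.events, (-1, fd.channel_count))
        names = [fd.channels[str(i + 1)].get("PnN", f"ch{i + 1}")
                 for i in range(fd.channel_count)]
        return EventTable(sample_id or path.stem, pd.DataFrame(data, columns=names))
    _, data = fcsparser.parse(str(path))
    return EventTable(sample_id or path.stem, pd.DataFrame(data))


def write_event_table(table: EventTable, path: str | Path, *, sep: str = "\t") -> None:
    table.events.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# marker panel config


def read_panel(path: str | Path, *, sep: str = "\t") -> MarkerPanel:
    """Read a declarative panel table with columns marker, role[, channel]."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "marker" not in cols or "role" not in cols:
        raise FormatError(f"{path}: panel config needs 'marker' and 'role' columns")
    entries = []
    for _, row in df.iterrows():
        channel = None
        if "channel" in cols and pd.notna(row[cols["channel"]]):
            channel = str(row[cols["channel"]])
        entries.append(PanelEntry(str(row[cols["marker"]]).strip(),
                                  str(row[cols["role"]]).strip(), channel))
    panel = MarkerPanel(tuple(entries))
    panel.require_polarization_markers()
    return panel


def write_panel(panel: MarkerPanel, path: str | Path, *, sep: str = "\t") -> None:
    rows = [{"marker": e.marker, "role": e.role, "channel": e.channel or ""}
            for e in panel.entries]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# MFI matrices


def read_mfi_matrix(path: str | Path, *, sep: str = "\t") -> MFIMatrix:
    """Read a wide MFI table: first column sample_id, optional metadata
    columns (condition, group, replicate), remaining columns markers."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected sample_id column plus marker columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample_id(s): {dups}")
    meta_cols = [c for c in df.columns if c.lower() in META_COLUMNS]
    meta = []
    for sid in df.index:
        kw = {}
        for c in meta_cols:
            v = df.loc[sid, c]
            if c.lower() == "replicate":
                kw["replicate"] = int(v)
            elif pd.notna(v):
                kw[c.lower()] = str(v)
        meta.append(SampleMeta(str(sid), **kw))
    values = df.drop(columns=meta_cols).astype(float)
    return MFIMatrix(values, meta)


def write_mfi_matrix(matrix: MFIMatrix, path: str | Path, *, sep: str = "\t") -> None:
    df = matrix.values.copy()
    has_meta = any(m.condition or m.group or m.replicate != 1 for m in matrix.meta)
    if has_meta:
        df.insert(0, "replicate", [m.replicate for m in matrix.meta])
        df.insert(0, "group", [m.group for m in matrix.meta])
        df.insert(0, "condition", [m.condition for m in matrix.meta])
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def write_json_report(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
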