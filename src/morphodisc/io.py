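"""Reading and writing landmark configurations, metadata and measurement protocols.

All formats are plain text. Landmark indices are **0-based** everywhere — in
protocol files, in APIs and in error messages. Published measurement tables
are typically 1-based; convert on import.

Supported formats
-----------------
* TPS (3D only): ``LM3=<p>`` records, one ``x y z`` line per landmark,
  ``ID=<specimen>`` after the block. ``SCALE=`` lines are ignored with a
  warning; 2D ``LM=`` records are rejected.
* Long-form CSV with columns ``specimen,landmark,x,y,z``.
* Protocol CSV with columns ``label,a,b`` and optional ``mirror_a,mirror_b``.
* Metadata CSV with columns ``specimen,group`` (group ``unknown`` flags
  unidentified specimens).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN_GROUP = "unknown"

__all__ = [
    "LandmarkDataset",
    "Measurement",
    "MeasurementProtocol",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
    "write_metadata",
    "read_protocol",
    "write_protocol",
    "protocol_overlap",
    "UNKNOWN_GROUP",
]


class LandmarkFormatError(ValueError):
    """Raised when a landmark, metadata or protocol file is malformed."""


@dataclass
class LandmarkDataset:
    """3D landmark configurations for a sample of specimens.

    Parameters
    ----------
    coords
        Array of shape ``(n_specimens, n_landmarks, 3)``. Units are arbitrary
        but must be uniform across specimens; every size quantity downstream
        inherits them.
    specimen_ids
        Unique specimen identifiers, one per configuration.
    groups
        Per-specimen group label, or ``"unknown"`` for unidentified specimens.
    landmark_names
        Optional landmark names (defaults to ``L000 ...``).
    landmark_roles
        Optional per-landmark role, each one of ``fixed``/``curve``/``surface``.
    """

    coords: np.ndarray
    specimen_ids: list[str]
    groups: list[str] | None = None
    landmark_names: list[str] | None = None
    landmark_roles: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise LandmarkFormatError(
                f"coords must have shape (n, p, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            bad = np.argwhere(~np.isfinite(self.coords))[0]
            raise LandmarkFormatError(
                f"non-finite coordinate for specimen index {bad[0]}, landmark {bad[1]}"
            )
        self.specimen_ids = [str(s) for s in self.specimen_ids]
        if len(self.specimen_ids) != self.n_specimens:
            raise LandmarkFormatError("one specimen id required per configuration")
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            dupes = {s for s in self.specimen_ids if self.specimen_ids.count(s) > 1}
            raise LandmarkFormatError(f"duplicate specimen ids: {sorted(dupes)}")
        if self.groups is None:
            self.groups = [UNKNOWN_GROUP] * self.n_specimens
        self.groups = [str(g) for g in self.groups]
        if len(self.groups) != self.n_specimens:
            raise LandmarkFormatError("one group label required per specimen")
        if self.landmark_names is None:
            self.landmark_names = [f"L{j:03d}" for j in range(self.n_landmarks)]
        if len(self.landmark_names) != self.n_landmarks:
            raise LandmarkFormatError("one landmark name required per landmark")
        if self.landmark_roles is not None:
            allowed = {"fixed", "curve", "surface"}
            bad_roles = set(self.landmark_roles) - allowed
            if bad_roles:
                raise LandmarkFormatError(f"invalid landmark roles: {sorted(bad_roles)}")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def known_group_labels(self) -> list[str]:
        """Distinct non-``unknown`` group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups:
            if g != UNKNOWN_GROUP:
                seen.setdefault(g)
        return list(seen)

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "LandmarkDataset":
        mask = np.asarray(mask, dtype=bool)
        return LandmarkDataset(
            coords=self.coords[mask],
            specimen_ids=[s for s, m in zip(self.specimen_ids, mask) if m],
            groups=[g for g, m in zip(self.groups, mask) if m],
            landmark_names=list(self.landmark_names),
            landmark_roles=None if self.landmark_roles is None else list(self.landmark_roles),
        )

    def split_unknowns(self) -> tuple["LandmarkDataset", "LandmarkDataset | None"]:
        """Split into (identified, unidentified); second item None if no unknowns."""
        mask = np.array([g != UNKNOWN_GROUP for g in self.groups])
        if mask.all():
            return self, None
        return self.subset(mask), self.subset(~mask)


@dataclass(frozen=True)
class Measurement:
    """One linear measurement: a landmark index pair, optionally mirrored.

    ``mirror`` holds the contralateral index pair; when present the reported
    distance is the mean of the left and right point-to-point distances.
    """

    label: str
    a: int
    b: int
    mirror: tuple[int, int] | None = None


@dataclass
class MeasurementProtocol:
    """Ordered, uniquely-labelled list of linear measurements."""

    name: str
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [m.label for m in self.measurements]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise LandmarkFormatError(
                f"protocol {self.name!r}: duplicate measurement labels {dupes}"
            )
        for m in self.measurements:
            if m.a == m.b:
                raise LandmarkFormatError(
                    f"protocol {self.name!r}, measurement {m.label!r}: identical endpoints"
                )
            if m.mirror is not None and m.mirror[0] == m.mirror[1]:
                raise LandmarkFormatError(
                    f"protocol {self.name!r}, measurement {m.label!r}: identical mirror endpoints"
                )

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.measurements]

    def validate_for(self, n_landmarks: int) -> None:
        """Raise if any endpoint index is out of range for a p-landmark dataset."""
        for m in self.measurements:
            idx = (m.a, m.b) + (m.mirror or ())
            for i in idx:
                if not 0 <= i < n_landmarks:
                    raise LandmarkFormatError(
                        f"protocol {self.name!r}, measurement {m.label!r}: "
                        f"landmark index {i} out of range [0, {n_landmarks})"
                    )


# ---------------------------------------------------------------------------
# landmark I/O


def read_landmarks(path: str | Path, format: str = "table") -> LandmarkDataset:
    """Read a :class:`LandmarkDataset` from ``path``.

    ``format`` is ``"tps"`` or ``"table"`` (long-form CSV). Group labels are
    not carried by either format; attach them with :func:`read_metadata`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tps":
        return _read_tps(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown landmark format {format!r} (expected 'tps' or 'table')")


def _read_tps(path: Path) -> LandmarkDataset:
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] = []
    expected: int | None = None

    def close_block(lineno: int) -> None:
        nonlocal current, expected
        if expected is None:
            return
        if len(current) != expected:
            raise LandmarkFormatError(
                f"{path}:{lineno}: specimen block declares LM3={expected} "
                f"but has {len(current)} coordinate lines"
            )
        blocks.append(np.array(current, dtype=float))
        current, expected = [], None

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                close_block(lineno)
                if len(blocks) != len(ids):
                    # previous block had no ID line
                    ids.append(f"spec{len(ids)}")
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("LM="):
                raise LandmarkFormatError(
                    f"{path}:{lineno}: 2D TPS (LM=) not supported; this reader is 3D-only"
                )
            elif upper.startswith("ID="):
                ids.append(line.split("=", 1)[1].strip())
            elif upper.startswith("SCALE="):
                warnings.warn(f"{path}:{lineno}: SCALE= line ignored", stacklevel=3)
            elif upper.startswith("IMAGE=") or upper.startswith("COMMENT="):
                continue
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                    )
                try:
                    current.append([float(v) for v in parts])
                except ValueError as exc:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: non-numeric coordinate: {line!r}"
                    ) from exc
    close_block(lineno)
    if len(blocks) > len(ids):
        ids.append(f"spec{len(ids)}")
    if not blocks:
        raise LandmarkFormatError(f"{path}: no LM3 records found")
    counts = {b.shape[0] for b in blocks}
    if len(counts) > 1:
        offender = ids[[b.shape[0] for b in blocks].index(max(counts))]
        raise LandmarkFormatError(
            f"{path}: ragged landmark counts {sorted(counts)} (e.g. specimen {offender!r})"
        )
    return LandmarkDataset(coords=np.stack(blocks), specimen_ids=ids)


def _read_table(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str})
    required = {"specimen", "landmark", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {sorted(missing)}")
    for axis in ("x", "y", "z"):
        if not np.issubdtype(df[axis].dtype, np.number):
            bad = df[pd.to_numeric(df[axis], errors="coerce").isna()].index[0]
            raise LandmarkFormatError(
                f"{path}: non-numeric {axis!r} value on data row {bad + 1}"
            )
    counts = df.groupby("specimen", sort=False).size()
    if counts.nunique() > 1:
        offender = counts.idxmax()
        raise LandmarkFormatError(
            f"{path}: ragged landmark counts per specimen "
            f"(e.g. specimen {offender!r} has {counts.max()}, others {counts.min()})"
        )
    specimens = list(dict.fromkeys(df["specimen"]))
    p = int(counts.iloc[0])
    coords = np.empty((len(specimens), p, 3))
    lm_names: list[str] | None = None
    for i, spec in enumerate(specimens):
        sub = df[df["specimen"] == spec].sort_values("landmark", kind="stable")
        coords[i] = sub[["x", "y", "z"]].to_numpy()
        if lm_names is None:
            lm_names = [str(v) for v in sub["landmark"]]
    return LandmarkDataset(coords=coords, specimen_ids=specimens, landmark_names=lm_names)


def write_landmarks(
    dataset: LandmarkDataset, path: str | Path, format: str = "table"
) -> None:
    """Write ``dataset`` to ``path`` with 12 significant digits (round-trip safe)."""
    path = Path(path)
    if format == "tps":
        with open(path, "w") as fh:
            for i, sid in enumerate(dataset.specimen_ids):
                fh.write(f"LM3={dataset.n_landmarks}\n")
                for row in dataset.coords[i]:
                    fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")
                fh.write(f"ID={sid}\n")
    elif format == "table":
        n, p = dataset.n_specimens, dataset.n_landmarks
        df = pd.DataFrame(
            {
                "specimen": np.repeat(dataset.specimen_ids, p),
                "landmark": np.tile(np.arange(p), n),
                "x": dataset.coords[:, :, 0].ravel(),
                "y": dataset.coords[:, :, 1].ravel(),
                "z": dataset.coords[:, :, 2].ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a ``specimen,group`` CSV into an id -> group mapping."""
    df = pd.read_csv(path, dtype=str)
    missing = {"specimen", "group"} - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["specimen"], df["group"]))


def write_metadata(dataset: LandmarkDataset, path: str | Path) -> None:
    pd.DataFrame({"specimen": dataset.specimen_ids, "group": dataset.groups}).to_csv(
        path, index=False
    )


def attach_groups(dataset: LandmarkDataset, groups: dict[str, str]) -> LandmarkDataset:
    """Return a copy of ``dataset`` with group labels taken from ``groups``.

    Specimens absent from the mapping are labelled ``unknown``.
    """
    labels = [groups.get(sid, UNKNOWN_GROUP) for sid in dataset.specimen_ids]
    return LandmarkDataset(
        coords=dataset.coords.copy(),
        specimen_ids=list(dataset.specimen_ids),
        groups=labels,
        landmark_names=list(dataset.landmark_names),
        landmark_roles=None if dataset.landmark_roles is None else list(dataset.landmark_roles),
    )


# ---------------------------------------------------------------------------
# protocol I/O


def read_protocol(path: str | Path, name: str | None = None) -> MeasurementProtocol:
    """Read a protocol CSV (``label,a,b[,mirror_a,mirror_b]``, 0-based indices)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"label", "a", "b"} - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {sorted(missing)}")
    has_mirror = {"mirror_a", "mirror_b"} <= set(df.columns)
    measurements = []
    for _, row in df.iterrows():
        mirror = None
        if has_mirror and not (pd.isna(row["mirror_a"]) or pd.isna(row["mirror_b"])):
            mirror = (int(row["mirror_a"]), int(row["mirror_b"]))
        measurements.append(
            Measurement(label=str(row["label"]), a=int(row["a"]), b=int(row["b"]), mirror=mirror)
        )
    return MeasurementProtocol(name=name or path.stem, measurements=measurements)


def write_protocol(protocol: MeasurementProtocol, path: str | Path) -> None:
    rows = []
    for m in protocol.measurements:
        rows.append(
            {
                "label": m.label,
                "a": m.a,
                "b": m.b,
                "mirror_a": m.mirror[0] if m.mirror else "",
                "mirror_b": m.mirror[1] if m.mirror else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_synonyms(path: str | Path) -> list[tuple[str, str]]:
    """Read a synonym CSV with columns ``label_a,label_b`` (one pair per row)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"label_a", "label_b"} - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {sorted(missing)}")
    return list(zip(df["label_a"], df["label_b"]))


def protocol_overlap(
    a: MeasurementProtocol,
    b: MeasurementProtocol,
    synonyms: Iterable[tuple[str, str]] | None = None,
) -> float:
    """Percentage of protocol ``b``'s measurements that protocol ``a`` covers.

    A measurement of ``b`` is covered when its label appears in ``a`` or a
    synonym pair ``(label_in_a, label_in_b)`` links it to a measurement of
    ``a``. Cross-protocol measurement identity is expert judgement, so it is
    supplied explicitly as a pair list rather than inferred from strings; the
    pairs may be many-to-many, which makes the coverage matrix genuinely
    asymmetric. Returns ``100 * covered / len(b)``.
    """
    if len(b) == 0:
        raise ValueError("overlap with an empty protocol is undefined")
    a_labels = set(a.labels)
    covered_b: set[str] = set(b.labels) & a_labels
    if synonyms is not None:
        b_labels = set(b.labels)
        for la, lb in synonyms:
            if la in a_labels and lb in b_labels:
                covered_b.add(lb)
            # pairs are direction-free: also accept (label_in_b, label_in_a)
            if lb in a_labels and la in b_labels:
                covered_b.add(la)
    return 100.0 * len(covered_b) / len(b)
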