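"""Reading, writing and relabeling plant point clouds.

Supported formats:

* plain text, one point per line ``x y z [label]`` (whitespace- or
  comma-separated), the layout used by daily-scan phenotyping datasets such
  as Pheno4D;
* PLY point clouds (ascii and binary little-endian on read, binary written),
  with labels as an integer ``label`` vertex property;
* HDF5 bundles produced by this package: one group per (plant, day) holding
  ``coords`` (N×3 float32) and optionally ``labels`` (N int8), plus the
  plant→train/test split table at the root.

Raw per-leaf instance labels follow the convention 0 = ground, 1 = stem,
≥2 = individual leaf instances; :func:`relabel_semantic` collapses every
leaf instance onto a single ``leaf`` class so the cloud carries the three
semantic classes ``ground`` / ``stem`` / ``leaf``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "SEMANTIC_CLASSES",
    "DEFAULT_LABEL_MAP",
    "LabeledPointCloud",
    "DatasetBundle",
    "FormatError",
    "read_points_txt",
    "write_points_txt",
    "relabel_semantic",
    "write_bundle_hdf",
    "read_bundle_hdf",
    "export_ply",
    "import_ply",
    "split_by_plant",
]

SEMANTIC_CLASSES = ["ground", "stem", "leaf"]

#: raw instance-label convention: ids ≥ the "leaf_from" threshold are leaf
#: instances; the two named ids map directly.  Override for datasets whose
#: numeric coding differs.
DEFAULT_LABEL_MAP = {"ground": 0, "stem": 1, "leaf_from": 2}


class FormatError(ValueError):
    """Malformed input file (bad line, missing PLY element, missing HDF key)."""


@dataclass
class LabeledPointCloud:
    """N×3 coordinates with optional per-point integer labels.

    ``class_names`` is ``["ground", "stem", "leaf"]`` for semantic clouds;
    raw instance-labeled clouds leave it empty.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)
    plant_id: str = ""
    day: int = 0
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N×3")
        if self.coords.shape[0] < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain NaN/Inf")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.coords.shape[0],):
                raise ValueError("labels length must match point count")
            if self.class_names and (
                self.labels.min() < 0
                or self.labels.max() >= len(self.class_names)
            ):
                raise ValueError("labels out of range for class_names")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass
class DatasetBundle:
    """An ordered collection of clouds plus the per-plant train/test split."""

    clouds: list[LabeledPointCloud]
    split: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        for c in self.clouds:
            if c.plant_id not in self.split:
                raise ValueError(f"plant id {c.plant_id!r} missing from split")
        for pid, part in self.split.items():
            if part not in ("train", "test"):
                raise ValueError(f"split[{pid!r}] must be 'train' or 'test'")

    def plant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clouds:
            seen.setdefault(c.plant_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.clouds)


# ---------------------------------------------------------------------------
# plain text
# ---------------------------------------------------------------------------

def read_points_txt(path, label_scheme: str = "raw") -> LabeledPointCloud:
    """Parse an ``x y z [label]`` text file.

    ``label_scheme`` is recorded provenance only ("raw" instance ids, or
    "leaf_tip" for maize files whose stem/leaf boundary was drawn at the
    leaf tip); labels are returned untouched either way.
    """
    if label_scheme not in ("raw", "leaf_tip"):
        raise ValueError("label_scheme must be 'raw' or 'leaf_tip'")
    coords: list[tuple[float, float, float]] = []
    labels: list[int] = []
    has_labels: bool | None = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected ≥3 fields")
            try:
                x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric coordinate"
                ) from None
            row_has_label = len(parts) >= 4
            if has_labels is None:
                has_labels = row_has_label
            elif has_labels != row_has_label:
                raise FormatError(
                    f"line {lineno}: inconsistent column count"
                )
            if row_has_label:
                try:
                    labels.append(int(float(parts[3])))
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-integer label"
                    ) from None
            coords.append((x, y, z))
    if not coords:
        raise FormatError("empty point file")
    return LabeledPointCloud(
        coords=np.asarray(coords, dtype=np.float64),
        labels=np.asarray(labels, dtype=np.int64) if has_labels else None,
        source=str(path),
    )


def write_points_txt(cloud: LabeledPointCloud, path) -> None:
    with open(path, "w") as fh:
        if cloud.labels is None:
            for p in cloud.coords:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        else:
            for p, l in zip(cloud.coords, cloud.labels):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(l)}\n")


# ---------------------------------------------------------------------------
# semantic relabeling
# ---------------------------------------------------------------------------

def relabel_semantic(
    cloud: LabeledPointCloud, label_map: dict | None = None
) -> LabeledPointCloud:
    """Collapse per-leaf instance ids onto one semantic ``leaf`` class.

    Idempotent on clouds that already carry the three semantic labels.
    """
    if cloud.labels is None:
        raise ValueError("cloud has no labels to relabel")
    lm = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    raw = cloud.labels
    if raw.min() < 0:
        raise ValueError("negative raw label")
    out = np.full(raw.shape, -1, dtype=np.int64)
    out[raw == lm["ground"]] = 0
    out[raw == lm["stem"]] = 1
    out[raw >= lm["leaf_from"]] = 2
    if (out < 0).any():
        bad = raw[out < 0][0]
        raise ValueError(f"raw label {bad} not covered by the label map")
    return replace(cloud, labels=out, class_names=list(SEMANTIC_CLASSES))


# ---------------------------------------------------------------------------
# HDF5 bundles
# ---------------------------------------------------------------------------

def write_bundle_hdf(bundle: DatasetBundle, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "ffnet3d-bundle-v1"
        f.attrs["provenance"] = bundle.provenance
        f.attrs["split"] = json.dumps(bundle.split)
        f.attrs["order"] = json.dumps(
            [[c.plant_id, c.day] for c in bundle.clouds]
        )
        for cloud in bundle.clouds:
            grp = f.create_group(f"{cloud.plant_id}/day{cloud.day:03d}")
            grp.create_dataset(
                "coords", data=cloud.coords.astype(np.float32)
            )
            if cloud.labels is not None:
                grp.create_dataset(
                    "labels", data=cloud.labels.astype(np.int8)
                )
            grp.attrs["class_names"] = json.dumps(cloud.class_names)
            grp.attrs["source"] = cloud.source


def read_bundle_hdf(path) -> DatasetBundle:
    with h5py.File(path, "r") as f:
        if "split" not in f.attrs:
            raise FormatError("missing root attribute 'split'")
        if "order" not in f.attrs:
            raise FormatError("missing root attribute 'order'")
        split = json.loads(f.attrs["split"])
        order = json.loads(f.attrs["order"])
        clouds = []
        for plant_id, day in order:
            key = f"{plant_id}/day{day:03d}"
            if key not in f:
                raise FormatError(f"missing group '{key}'")
            grp = f[key]
            if "coords" not in grp:
                raise FormatError(f"missing dataset '{key}/coords'")
            labels = (
                np.asarray(grp["labels"], dtype=np.int64)
                if "labels" in grp
                else None
            )
            clouds.append(
                LabeledPointCloud(
                    coords=np.asarray(grp["coords"], dtype=np.float64),
                    labels=labels,
                    class_names=json.loads(
                        grp.attrs.get("class_names", "[]")
                    ),
                    plant_id=str(plant_id),
                    day=int(day),
                    source=str(grp.attrs.get("source", "")),
                )
            )
        return DatasetBundle(
            clouds=clouds,
            split=split,
            provenance=str(f.attrs.get("provenance", "")),
        )


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------
# A small point-cloud-only PLY codec (vertex x/y/z float32, optional integer
# "label" property).  Ascii and binary_little_endian are accepted on read;
# binary_little_endian is written.

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def export_ply(cloud: LabeledPointCloud, path) -> None:
    n = cloud.n_points
    props = ["property float x", "property float y", "property float z"]
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if cloud.labels is not None:
        props.append("property int label")
        fields.append(("label", "<i4"))
    header = "\n".join(
        [
            "ply",
            "format binary_little_endian 1.0",
            f"element vertex {n}",
            *props,
            "end_header",
        ]
    ) + "\n"
    rec = np.empty(n, dtype=fields)
    rec["x"] = cloud.coords[:, 0].astype(np.float32)
    rec["y"] = cloud.coords[:, 1].astype(np.float32)
    rec["z"] = cloud.coords[:, 2].astype(np.float32)
    if cloud.labels is not None:
        rec["label"] = cloud.labels.astype(np.int32)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


def import_ply(path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError("not a PLY file")
        fmt = None
        n_vertex = None
        vertex_props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise FormatError("unterminated PLY header")
            tokens = line.decode("ascii", "replace").strip().split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise FormatError("list properties unsupported for vertices")
                if tokens[1] not in _PLY_TYPES:
                    raise FormatError(f"unknown PLY type {tokens[1]!r}")
                vertex_props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if n_vertex is None:
            raise FormatError("PLY file has no vertex element")
        names = [n for n, _ in vertex_props]
        for axis in "xyz":
            if axis not in names:
                raise FormatError(f"vertex element lacks property {axis!r}")
        if fmt == "ascii":
            rows = []
            while len(rows) < n_vertex:
                line = fh.readline()
                if not line:
                    raise FormatError("truncated PLY vertex data")
                vals = line.split()
                if not vals:
                    continue
                rows.append([float(v) for v in vals[: len(vertex_props)]])
            data = np.asarray(rows)
            cols = {n: data[:, i] for i, (n, _) in enumerate(vertex_props)}
        elif fmt == "binary_little_endian":
            dtype = np.dtype([(n, "<" + t) for n, t in vertex_props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) < dtype.itemsize * n_vertex:
                raise FormatError("truncated PLY vertex data")
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            cols = {n: rec[n] for n, _ in vertex_props}
        else:
            raise FormatError(f"unsupported PLY format {fmt!r}")
        coords = np.stack(
            [cols["x"], cols["y"], cols["z"]], axis=1
        ).astype(np.float64)
        labels = None
        if "label" in cols:
            labels = np.asarray(cols["label"], dtype=np.int64)
        return LabeledPointCloud(coords=coords, labels=labels, source=str(path))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_by_plant(
    bundle: DatasetBundle, train_ids: set[str]
) -> tuple[DatasetBundle, DatasetBundle]:
    """Partition a bundle by plant identity (never by individual cloud)."""
    present = set(bundle.plant_ids())
    unknown = set(train_ids) - present
    if unknown:
        raise ValueError(f"unknown plant ids in train_ids: {sorted(unknown)}")
    train_clouds = [c for c in bundle.clouds if c.plant_id in train_ids]
    test_clouds = [c for c in bundle.clouds if c.plant_id not in train_ids]
    train = DatasetBundle(
        clouds=train_clouds,
        split={pid: "train" for pid in present if pid in train_ids},
        provenance=bundle.provenance,
    )
    test = DatasetBundle(
        clouds=test_clouds,
        split={pid: "test" for pid in present if pid not in train_ids},
        provenance=bundle.provenance,
    )
    return train, test
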