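"""Reading and writing microscopy volumes, label volumes and track files.

Supported containers: OME-TIFF (T×Z×Y×X with physical calibration in the
OME metadata), HDF5 (dataset ``intensity`` with ``voxel_size_um`` /
``frame_interval_s`` attributes), and directories of per-frame 3D TIFFs.
Tracking results are exported in the Cell Tracking Challenge dialect
(per-frame 16-bit label TIFFs plus a ``res_track.txt`` of
``label begin end parent`` lines) and as a flat CSV lineage table.

Conventions: voxel indices are 0-based; centroids are physical µm
``(z, y, x)`` with the origin at the centre of voxel (0, 0, 0); frames are
0-based and CTC begin/end frames are inclusive.
"""

from __future__ import annotations

import os
import re
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .forest import LineageForest


class VolumeSeries:
    """A 4D (T, Z, Y, X) intensity series with physical calibration."""

    def __init__(
        self,
        frames: Sequence[np.ndarray] | np.ndarray | Callable[[int], np.ndarray],
        voxel_size_um: Sequence[float],
        frame_interval_s: float,
        n_frames: int | None = None,
        shape: tuple[int, int, int] | None = None,
        time_origin_hpf: float | None = None,
    ) -> None:
        self.voxel_size_um = tuple(float(v) for v in voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive values (z, y, x)")
        if frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        self.frame_interval_s = float(frame_interval_s)
        self.time_origin_hpf = time_origin_hpf

        if callable(frames):
            if n_frames is None or shape is None:
                raise ValueError("lazy series needs explicit n_frames and shape")
            self._loader = frames
            self._frames = None
            self.n_frames = int(n_frames)
            self.shape = tuple(shape)
        else:
            arrs = [np.asarray(f) for f in frames]
            if not arrs:
                raise ValueError("series must contain at least one frame")
            shp = arrs[0].shape
            for i, a in enumerate(arrs):
                if a.ndim != 3:
                    raise ValueError(f"frame {i} is not 3D")
                if a.shape != shp:
                    raise ValueError(
                        f"frame {i} shape {a.shape} differs from frame 0 shape {shp}"
                    )
                if np.issubdtype(a.dtype, np.floating) and np.any(a < 0):
                    raise ValueError(f"frame {i} contains negative intensities")
            self._frames = arrs
            self._loader = None
            self.n_frames = len(arrs)
            self.shape = shp

    def frame(self, t: int) -> np.ndarray:
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame {t} out of range [0, {self.n_frames})")
        if self._frames is not None:
            return self._frames[t]
        return self._loader(t)

    def __len__(self) -> int:
        return self.n_frames

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size_um))


class LabelSeries:
    """Per-frame integer instance-label volumes; label 0 is background."""

    def __init__(self, frames: Sequence[np.ndarray], voxel_size_um: Sequence[float]):
        self.frames = [np.ascontiguousarray(f, dtype=np.int32) for f in frames]
        self.voxel_size_um = tuple(float(v) for v in voxel_size_um)
        for i, f in enumerate(self.frames):
            if f.ndim != 3:
                raise ValueError(f"label frame {i} is not 3D")
            if f.min() < 0:
                raise ValueError(f"label frame {i} has negative labels")

    def __len__(self) -> int:
        return len(self.frames)

    def labels_in_frame(self, t: int) -> np.ndarray:
        u = np.unique(self.frames[t])
        return u[u > 0]

    def mask(self, t: int, label: int) -> np.ndarray:
        return self.frames[t] == label

    def voxel_count(self, t: int, label: int) -> int:
        return int(np.count_nonzero(self.frames[t] == label))

    def centroid_um(self, t: int, label: int) -> np.ndarray:
        idx = np.argwhere(self.frames[t] == label)
        if idx.size == 0:
            raise KeyError(f"label {label} absent from frame {t}")
        return idx.mean(axis=0) * np.asarray(self.voxel_size_um)

    def copy(self) -> "LabelSeries":
        return LabelSeries([f.copy() for f in self.frames], self.voxel_size_um)


# ---------------------------------------------------------------------------
# volume I/O


def write_volume_series(series: VolumeSeries, path: str) -> None:
    """Write a series as OME-TIFF (TZYX) or HDF5, by file extension."""
    data = np.stack([series.frame(t) for t in range(series.n_frames)])
    vz, vy, vx = series.voxel_size_um
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("intensity", data=data)
            ds.attrs["voxel_size_um"] = series.voxel_size_um
            ds.attrs["frame_interval_s"] = series.frame_interval_s
            if series.time_origin_hpf is not None:
                ds.attrs["time_origin_hpf"] = series.time_origin_hpf
    else:
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "TZYX",
                "PhysicalSizeZ": vz,
                "PhysicalSizeY": vy,
                "PhysicalSizeX": vx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
                "TimeIncrement": series.frame_interval_s,
                "TimeIncrementUnit": "s",
            },
        )


def _ome_calibration(xml: str):
    def grab(attr):
        m = re.search(rf'{attr}="([0-9.eE+-]+)"', xml)
        return float(m.group(1)) if m else None

    vz, vy, vx = grab("PhysicalSizeZ"), grab("PhysicalSizeY"), grab("PhysicalSizeX")
    dt = grab("TimeIncrement")
    return vz, vy, vx, dt


def read_volume_series(
    path: str,
    layout: str = "TZYX",
    voxel_size_um: Sequence[float] | None = None,
    frame_interval_s: float | None = None,
) -> VolumeSeries:
    """Read a 4D series from OME-TIFF, HDF5 or a per-frame TIFF directory.

    Calibration must be present in the file metadata or passed explicitly;
    a missing calibration is an error — isotropy is never assumed.
    """
    if layout not in ("TZYX", "ZYX-sequence"):
        raise ValueError(f"unknown layout {layout!r}")

    if layout == "ZYX-sequence":
        if not os.path.isdir(path):
            raise FileNotFoundError(path)
        files = sorted(
            os.path.join(path, f)
            for f in os.listdir(path)
            if f.lower().endswith((".tif", ".tiff"))
        )
        if not files:
            raise FileNotFoundError(f"no TIFF frames in {path}")
        frames = [tifffile.imread(f) for f in files]
        if voxel_size_um is None or frame_interval_s is None:
            raise ValueError(
                "ZYX-sequence layout carries no calibration; pass voxel_size_um "
                "and frame_interval_s explicitly"
            )
        return VolumeSeries(frames, voxel_size_um, frame_interval_s)

    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh["intensity"]
            data = ds[...]
            vs = ds.attrs.get("voxel_size_um")
            dt = ds.attrs.get("frame_interval_s")
            origin = ds.attrs.get("time_origin_hpf")
        voxel_size_um = voxel_size_um or (tuple(vs) if vs is not None else None)
        frame_interval_s = frame_interval_s or (float(dt) if dt is not None else None)
        if voxel_size_um is None or frame_interval_s is None:
            raise ValueError(f"{path} carries no calibration and none was supplied")
        return VolumeSeries(
            list(data),
            voxel_size_um,
            frame_interval_s,
            time_origin_hpf=float(origin) if origin is not None else None,
        )

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if tf.ome_metadata:
            vz, vy, vx, dt = _ome_calibration(tf.ome_metadata)
            if voxel_size_um is None and None not in (vz, vy, vx):
                voxel_size_um = (vz, vy, vx)
            if frame_interval_s is None and dt is not None:
                frame_interval_s = dt
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected 4D TZYX data, got shape {data.shape}")
    if voxel_size_um is None or frame_interval_s is None:
        raise ValueError(f"{path} carries no calibration and none was supplied")
    return VolumeSeries(list(data), voxel_size_um, frame_interval_s)


def write_label_series(labels: LabelSeries, out_dir: str, prefix: str = "mask") -> None:
    os.makedirs(out_dir, exist_ok=True)
    for t, frame in enumerate(labels.frames):
        if frame.max() > np.iinfo(np.uint16).max:
            raise ValueError(f"frame {t} labels exceed 16-bit range")
        tifffile.imwrite(
            os.path.join(out_dir, f"{prefix}{t:03d}.tif"),
            frame.astype(np.uint16),
            photometric="minisblack",
        )


def read_label_series(
    in_dir: str, voxel_size_um: Sequence[float], prefix: str = "mask"
) -> LabelSeries:
    files = sorted(
        f for f in os.listdir(in_dir) if f.startswith(prefix) and f.endswith(".tif")
    )
    if not files:
        raise FileNotFoundError(f"no {prefix}*.tif files in {in_dir}")
    return LabelSeries(
        [tifffile.imread(os.path.join(in_dir, f)) for f in files], voxel_size_um
    )


# ---------------------------------------------------------------------------
# CTC track-file dialect


def export_tracks_ctc(
    forest: LineageForest, labels: LabelSeries, out_dir: str
) -> dict[int, int]:
    """Write ``res_track.txt`` + per-frame 16-bit label TIFFs (CTC dialect).

    Each division-free segment of the forest becomes one track with label
    ``L`` and one line ``L B E P`` (begin/end frames inclusive; ``P`` the
    parent track's label, 0 for none).  Label images are re-labelled so
    voxel values equal track labels.  Returns the node -> track-label map.

    Interpolated (virtual) nodes have no voxels of their own; they are
    rendered as a small cube at the node centroid so every track is
    represented in every frame it spans.
    """
    forest.validate()
    os.makedirs(out_dir, exist_ok=True)
    segments = forest.tracks()
    # deterministic label order: by (start frame, start centroid)
    segments.sort(
        key=lambda seg: (forest.frame_of(seg[0]), tuple(forest.centroid_of(seg[0])))
    )
    track_of_node: dict[int, int] = {}
    for lbl, seg in enumerate(segments, start=1):
        for n in seg:
            track_of_node[n] = lbl

    out_frames = [np.zeros_like(f, dtype=np.uint16) for f in labels.frames]
    voxel = np.asarray(labels.voxel_size_um)
    used: list[set[int]] = [set() for _ in labels.frames]
    for n in forest.nodes():
        t = forest.frame_of(n)
        lbl = track_of_node[n]
        det = forest.graph.nodes[n].get("det")
        if det is not None and not forest.graph.nodes[n].get("interpolated", False):
            mask = labels.frames[t] == det[1]
            if not mask.any():
                raise ValueError(f"forest node {n} references missing label {det}")
        else:
            # virtual node: 2-voxel cube at the centroid
            c = np.round(forest.centroid_of(n) / voxel).astype(int)
            c = np.clip(c, 0, np.asarray(out_frames[t].shape) - 1)
            mask = np.zeros_like(out_frames[t], dtype=bool)
            sl = tuple(slice(max(0, ci), min(s, ci + 2)) for ci, s in zip(c, mask.shape))
            mask[sl] = True
        if lbl in used[t]:
            raise ValueError(f"track label {lbl} collides in frame {t}")
        if np.any(out_frames[t][mask] != 0):
            raise ValueError(f"label collision across tracks in frame {t}")
        out_frames[t][mask] = lbl
        used[t].add(lbl)

    lines = []
    for lbl, seg in enumerate(segments, start=1):
        b = forest.frame_of(seg[0])
        e = forest.frame_of(seg[-1])
        par = forest.parent(seg[0])
        p = track_of_node[par] if par is not None else 0
        lines.append(f"{lbl} {b} {e} {p}")
    with open(os.path.join(out_dir, "res_track.txt"), "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    for t, frame in enumerate(out_frames):
        tifffile.imwrite(
            os.path.join(out_dir, f"mask{t:03d}.tif"),
            frame,
            photometric="minisblack",
        )
    return track_of_node


def parse_tracks_ctc(in_dir: str, voxel_size_um: Sequence[float]) -> LineageForest:
    """Rebuild a LineageForest from a CTC-dialect result directory."""
    track_path = os.path.join(in_dir, "res_track.txt")
    if not os.path.exists(track_path):
        raise FileNotFoundError(track_path)
    rows = []
    with open(track_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                l, b, e, p = (int(x) for x in line.split())
                rows.append((l, b, e, p))
    files = sorted(f for f in os.listdir(in_dir) if re.fullmatch(r"mask\d+\.tif", f))
    frames = [tifffile.imread(os.path.join(in_dir, f)) for f in files]
    voxel = np.asarray(voxel_size_um, dtype=float)

    forest = LineageForest()
    last_node_of_track: dict[int, int] = {}
    first_node_of_track: dict[int, int] = {}
    for l, b, e, p in sorted(rows, key=lambda r: (r[1], r[0])):
        prev = None
        for t in range(b, e + 1):
            idx = np.argwhere(frames[t] == l)
            if idx.size == 0:
                raise ValueError(f"track {l} missing from frame {t}")
            centroid = idx.mean(axis=0) * voxel
            vol = idx.shape[0] * float(np.prod(voxel))
            n = forest.add_node(t, centroid, volume=vol, det=(t, l))
            if prev is not None:
                forest.add_edge(prev, n)
            else:
                first_node_of_track[l] = n
            prev = n
        last_node_of_track[l] = prev
    for l, b, e, p in rows:
        if p != 0:
            forest.add_edge(last_node_of_track[p], first_node_of_track[l])
    forest.validate()
    return forest


# ---------------------------------------------------------------------------
# flat lineage table (CSV)

_TABLE_COLS = ["id", "frame", "z", "y", "x", "parent_id", "track_id", "division_flag"]


def export_lineage_table(forest: LineageForest, path: str | None = None) -> pd.DataFrame:
    """One row per node: id, frame, z, y, x, parent_id, track_id, division_flag."""
    segments = forest.tracks()
    segments.sort(
        key=lambda seg: (forest.frame_of(seg[0]), tuple(forest.centroid_of(seg[0])))
        if seg
        else (0,)
    )
    track_of_node = {n: i + 1 for i, seg in enumerate(segments) for n in seg}
    recs = []
    for n in sorted(forest.nodes()):
        z, y, x = forest.centroid_of(n)
        par = forest.parent(n)
        recs.append(
            {
                "id": n,
                "frame": forest.frame_of(n),
                "z": z,
                "y": y,
                "x": x,
                "parent_id": -1 if par is None else par,
                "track_id": track_of_node[n],
                "division_flag": int(len(forest.children(n)) == 2),
            }
        )
    df = pd.DataFrame(recs, columns=_TABLE_COLS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def parse_lineage_table(path_or_df) -> LineageForest:
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    forest = LineageForest()
    for _, row in df.iterrows():
        forest.add_node(
            int(row["frame"]),
            (row["z"], row["y"], row["x"]),
            node_id=int(row["id"]),
        )
    for _, row in df.iterrows():
        if int(row["parent_id"]) >= 0:
            forest.add_edge(int(row["parent_id"]), int(row["id"]))
    forest.validate()
    return forest
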