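"""Readers and writers for the toolkit's JSON/CSV schemas.

Skeleton JSON schema::

    {"fps": float, "joint_names": [...], "edges": [[i, j], ...],
     "frames": [{"t": int, "xyz": [[x, y, z] x J], "conf": [c x J]}]}

All JSON output is canonicalized (sorted keys, compact separators,
shortest-round-trip floats) so identical data is byte-identical on disk.
Frame and joint indices are 0-based; intervals are half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from taijikit.layout import JOINT_NAMES_32, skeleton_edges
from taijikit.multiview import CameraModel, Observation2D
from taijikit.segmentation import Segment
from taijikit.skeleton import SkeletonSequence

__all__ = [
    "read_skeleton",
    "write_skeleton",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_cameras",
    "write_cameras",
    "read_observations",
    "write_observations",
    "read_segments",
    "write_segments",
    "canonical_json",
]


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _dump(obj, path: str | Path) -> None:
    Path(path).write_text(canonical_json(obj) + "\n")


def write_skeleton(seq: SkeletonSequence, path: str | Path) -> None:
    doc = {
        "fps": seq.fps,
        "joint_names": list(seq.joint_names),
        "edges": [list(e) for e in seq.edges],
        "frames": [
            {
                "t": t,
                "xyz": seq.positions[t].tolist(),
                "conf": seq.confidence[t].tolist(),
            }
            for t in range(seq.n_frames)
        ],
    }
    _dump(doc, path)


def _fail(field: str, record: int | None, msg: str) -> None:
    where = f" in frame record {record}" if record is not None else ""
    raise ValueError(f"skeleton schema violation at '{field}'{where}: {msg}")


def read_skeleton(path: str | Path) -> SkeletonSequence:
    doc = json.loads(Path(path).read_text())
    for key in ("fps", "joint_names", "edges", "frames"):
        if key not in doc:
            _fail(key, None, "missing")
    names = tuple(doc["joint_names"])
    J = len(names)
    positions, confidence = [], []
    for i, fr in enumerate(doc["frames"]):
        xyz = np.asarray(fr.get("xyz"), dtype=float)
        if xyz.shape != (J, 3):
            _fail("xyz", i, f"expected ({J}, 3), got {xyz.shape}")
        conf = np.asarray(fr.get("conf"), dtype=float)
        if conf.shape != (J,):
            _fail("conf", i, f"expected ({J},), got {conf.shape}")
        bad = np.where((conf < 0) | (conf > 1))[0]
        if bad.size:
            _fail("conf", i,
                  f"joint '{names[bad[0]]}' confidence {conf[bad[0]]} outside [0, 1]")
        positions.append(xyz)
        confidence.append(conf)
    return SkeletonSequence(
        positions=np.stack(positions),
        confidence=np.stack(confidence),
        fps=float(doc["fps"]),
        joint_names=names,
        edges=tuple(tuple(e) for e in doc["edges"]),
    )


def write_skeleton_csv(seq: SkeletonSequence, path: str | Path) -> None:
    rows = []
    for t in range(seq.n_frames):
        for j, name in enumerate(seq.joint_names):
            rows.append(
                {
                    "frame": t,
                    "joint": name,
                    "x": seq.positions[t, j, 0],
                    "y": seq.positions[t, j, 1],
                    "z": seq.positions[t, j, 2],
                    "conf": seq.confidence[t, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_skeleton_csv(
    path: str | Path,
    fps: float = 30.0,
    edges: tuple[tuple[int, int], ...] | None = None,
) -> SkeletonSequence:
    df = pd.read_csv(path)
    required = {"frame", "joint", "x", "y", "z", "conf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"skeleton CSV missing columns: {sorted(missing)}")
    names = tuple(dict.fromkeys(df["joint"]))
    T = int(df["frame"].max()) + 1
    J = len(names)
    pos = np.zeros((T, J, 3))
    conf = np.zeros((T, J))
    jidx = {n: j for j, n in enumerate(names)}
    pos[df["frame"], [jidx[n] for n in df["joint"]]] = df[["x", "y", "z"]].to_numpy()
    conf[df["frame"], [jidx[n] for n in df["joint"]]] = df["conf"].to_numpy()
    if edges is None:
        edges = (
            tuple(skeleton_edges()) if names == JOINT_NAMES_32 else ()
        )
    return SkeletonSequence(
        positions=pos, confidence=conf, fps=fps, joint_names=names, edges=edges
    )


def write_cameras(cameras: list[CameraModel], path: str | Path) -> None:
    _dump(
        {
            "cameras": [
                {"id": c.cam_id, "K": c.K.tolist(), "R": c.R.tolist(),
                 "C": c.C.tolist()}
                for c in cameras
            ]
        },
        path,
    )


def read_cameras(path: str | Path) -> list[CameraModel]:
    doc = json.loads(Path(path).read_text())
    return [
        CameraModel(
            K=np.asarray(c["K"]), R=np.asarray(c["R"]), C=np.asarray(c["C"]),
            cam_id=str(c["id"]),
        )
        for c in doc["cameras"]
    ]


def write_observations(
    frames_obs: list[dict[int, list[Observation2D]]], path: str | Path
) -> None:
    doc = {
        "frames": [
            {
                str(j): [
                    {"view": o.view_id, "pixel": o.pixel.tolist(),
                     "conf": o.weight}
                    for o in obs
                ]
                for j, obs in sorted(obs_t.items())
            }
            for obs_t in frames_obs
        ]
    }
    _dump(doc, path)


def read_observations(path: str | Path) -> list[dict[int, list[Observation2D]]]:
    doc = json.loads(Path(path).read_text())
    out = []
    for obs_t in doc["frames"]:
        out.append(
            {
                int(j): [
                    Observation2D(
                        view_id=o["view"], pixel=np.asarray(o["pixel"]),
                        weight=float(o["conf"]),
                    )
                    for o in obs
                ]
                for j, obs in obs_t.items()
            }
        )
    return out


def write_segments(segments: list[Segment], path: str | Path) -> None:
    _dump(
        [
            {
                "start": s.start,
                "end": s.end,
                "label": s.label,
                "dtw_distance": s.dtw_distance if np.isfinite(s.dtw_distance)
                else None,
                "valid": s.valid,
            }
            for s in segments
        ],
        path,
    )


def read_segments(path: str | Path) -> list[Segment]:
    doc = json.loads(Path(path).read_text())
    return [
        Segment(
            start=int(s["start"]),
            end=int(s["end"]),
            label=s["label"],
            dtw_distance=(
                float("inf") if s["dtw_distance"] is None
                else float(s["dtw_distance"])
            ),
            valid=bool(s["valid"]),
        )
        for s in doc
    ]
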