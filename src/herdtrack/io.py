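"""Readers and writers for MOTChallenge-style text files and the run config.

Detection files carry comma-separated rows ``frame, -1, x, y, w, h, conf,
-1, -1, -1`` with 1-based frame numbers (mapped to 0-based internally);
appearance features travel in a whitespace-separated sidecar file, one row
per detection in file order, which keeps the main file compatible with
standard MOT tooling.  Ground-truth files use ``frame, id, x, y, w, h,
conf, occlusion, truncation``.  Results files mirror the detection layout
with real track ids.  All writers emit deterministic, fixed-precision rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .association import AssociationParams
from .core import BoundingBox, Detection
from .metrics import FrameAnnotations, GtObject
from .motion import FlowParams
from .servo import ServoGains
from .simulator import ScenarioConfig
from .tracker import FrameResult, TrackerParams

__all__ = [
    "ParseError",
    "read_mot_detections",
    "write_mot_detections",
    "read_mot_ground_truth",
    "write_mot_ground_truth",
    "write_mot_results",
    "read_mot_results",
    "MetricsParams",
    "RunConfig",
    "load_config",
]


class ParseError(ValueError):
    """Malformed row in a MOT-format file, with its line number."""


def _rows(path: str | Path) -> list[tuple[int, list[str]]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append((lineno, [tok.strip() for tok in line.split(",")]))
    return out


def read_mot_detections(
    path: str | Path, features_path: str | Path | None = None
) -> list[list[Detection]]:
    """Parse a detection file (plus optional feature sidecar) per frame."""
    parsed: list[tuple[int, Detection]] = []
    features: list[np.ndarray] | None = None
    if features_path is not None:
        features = [
            np.asarray([float(x) for x in line.split()], dtype=float)
            for line in Path(features_path).read_text().splitlines()
            if line.strip()
        ]
    for k, (lineno, toks) in enumerate(_rows(path)):
        if len(toks) < 7:
            raise ParseError(f"{path}:{lineno}: expected >= 7 fields, got {len(toks)}")
        try:
            frame = int(float(toks[0]))
            x, y, w, h, conf = (float(t) for t in toks[2:7])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        feat = None
        if features is not None:
            if k >= len(features):
                raise ValueError(
                    f"feature sidecar has {len(features)} rows but "
                    f"{path} has more detections"
                )
            feat = features[k] / np.linalg.norm(features[k])
        parsed.append(
            (frame - 1, Detection(BoundingBox(x, y, w, h), min(max(conf, 0.0), 1.0), feat))
        )
    if features is not None and len(features) != len(parsed):
        raise ValueError(
            f"feature sidecar rows ({len(features)}) != detections ({len(parsed)})"
        )
    if not parsed:
        return []
    n_frames = max(f for f, _ in parsed) + 1
    out: list[list[Detection]] = [[] for _ in range(n_frames)]
    for f, det in parsed:
        if f < 0:
            raise ParseError(f"{path}: frame numbers must be >= 1")
        out[f].append(det)
    return out


def write_mot_detections(
    path: str | Path,
    detections_per_frame: list[list[Detection]],
    features_path: str | Path | None = None,
) -> None:
    lines = []
    feat_lines = []
    for f, dets in enumerate(detections_per_frame):
        for d in dets:
            b = d.box
            lines.append(
                f"{f + 1},-1,{b.x:.2f},{b.y:.2f},{b.width:.2f},{b.height:.2f},"
                f"{d.confidence:.4f},-1,-1,-1"
            )
            if features_path is not None:
                feat = d.feature if d.feature is not None else np.zeros(1)
                feat_lines.append(" ".join(f"{v:.6f}" for v in feat))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if features_path is not None:
        Path(features_path).write_text(
            "\n".join(feat_lines) + ("\n" if feat_lines else "")
        )


def read_mot_ground_truth(path: str | Path) -> list[FrameAnnotations]:
    by_frame: dict[int, list[GtObject]] = {}
    for lineno, toks in _rows(path):
        if len(toks) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 fields")
        try:
            frame = int(float(toks[0])) - 1
            gid = int(float(toks[1]))
            x, y, w, h = (float(t) for t in toks[2:6])
            occ = float(toks[7]) if len(toks) > 7 else 0.0
            trunc = float(toks[8]) if len(toks) > 8 else 0.0
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        by_frame.setdefault(frame, []).append(
            GtObject(gid, BoundingBox(x, y, w, h), occ, trunc)
        )
    if not by_frame:
        return []
    n_frames = max(by_frame) + 1
    return [FrameAnnotations(f, by_frame.get(f, [])) for f in range(n_frames)]


def write_mot_ground_truth(path: str | Path, gt: list[FrameAnnotations]) -> None:
    lines = []
    for frame in gt:
        for o in frame.objects:
            b = o.box
            lines.append(
                f"{frame.frame_index + 1},{o.gt_id},{b.x:.2f},{b.y:.2f},"
                f"{b.width:.2f},{b.height:.2f},1,"
                f"{o.occlusion_fraction:.3f},{o.truncation_fraction:.3f}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_mot_results(path: str | Path, results: list[FrameResult]) -> None:
    """Write tracker output; rows sorted by (frame, id), frames 1-based."""
    lines = []
    for res in sorted(results, key=lambda r: r.frame_index):
        for tid, box, conf in sorted(res.confirmed_tracks, key=lambda t: t[0]):
            if tid <= 0:
                raise ValueError("track ids must be positive")
            lines.append(
                f"{res.frame_index + 1},{tid},{box.x:.2f},{box.y:.2f},"
                f"{box.width:.2f},{box.height:.2f},{conf:.4f},-1,-1,-1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_mot_results(path: str | Path) -> dict[int, list[tuple[int, BoundingBox]]]:
    out: dict[int, list[tuple[int, BoundingBox]]] = {}
    for lineno, toks in _rows(path):
        if len(toks) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 fields")
        frame = int(float(toks[0])) - 1
        tid = int(float(toks[1]))
        x, y, w, h = (float(t) for t in toks[2:6])
        out.setdefault(frame, []).append((tid, BoundingBox(x, y, w, h)))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class MetricsParams:
    iou_threshold: float = 0.5
    threshold_grid: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(10))


@dataclass
class RunConfig:
    seed: int = 0
    tracker: TrackerParams = field(default_factory=TrackerParams)
    servo: ServoGains = field(default_factory=ServoGains)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    scenario: ScenarioConfig | None = None


def _coerce(value: Any, target_type: Any) -> Any:
    if isinstance(value, list) and not isinstance(target_type, dict):
        return tuple(value)
    return value


def _build(cls: type, data: dict, context: str) -> Any:
    """Instantiate a (possibly nested) dataclass strictly from a dict."""
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    valid = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = valid[key]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[key] = _build(f.type, value, f"{context}.{key}")
        elif isinstance(value, dict) and key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value, f"{context}.{key}")
        else:
            kwargs[key] = _coerce(value, f.type)
    return cls(**kwargs)


_NESTED = {
    "association": AssociationParams,
    "flow": FlowParams,
    "tracker": TrackerParams,
    "servo": ServoGains,
    "metrics": MetricsParams,
    "scenario": ScenarioConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {"seed", "tracker", "association", "flow", "servo", "metrics", "scenario"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")

    tracker_raw = dict(raw.get("tracker", {}))
    # association/flow may be given as top-level sections or nested
    if "association" in raw:
        tracker_raw.setdefault("association", raw["association"])
    if "flow" in raw:
        tracker_raw.setdefault("flow", raw["flow"])

    cfg = RunConfig(seed=int(raw.get("seed", 0)))
    cfg.tracker = _build(TrackerParams, tracker_raw, "tracker")
    if "servo" in raw:
        cfg.servo = _build(ServoGains, raw["servo"], "servo")
    if "metrics" in raw:
        cfg.metrics = _build(MetricsParams, raw["metrics"], "metrics")
    if "scenario" in raw:
        scen = dict(raw["scenario"])
        scen.setdefault("seed", cfg.seed)
        cfg.scenario = _build(ScenarioConfig, scen, "scenario")
    return cfg
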