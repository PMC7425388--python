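"""Areas of interest (AOIs) on noise-pareidolia stimuli.

Each stimulus carries pre-drawn AOIs: one ellipse around the embedded face
(label ``target``) on face images, and one or more polygons around salient
noise patches (label ``noise``). Point-in-AOI tests use the normalised
quadratic form for ellipses and shapely (ray casting) for polygons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from shapely.geometry import Point, Polygon

__all__ = ["AOI", "Stimulus", "StimulusSet", "assign_aoi", "read_aoi_json", "write_aoi_json"]

STIMULUS_SIZE_PX = 700  # stimuli subtend 700 x 700 px on screen


@dataclass(frozen=True)
class AOI:
    """A labelled region on a stimulus: ellipse or simple polygon (px units)."""

    label: str  # "target" | "noise"
    shape: str  # "ellipse" | "polygon"
    # ellipse: (cx, cy, semi_x, semi_y, rotation_deg); polygon: vertex list
    params: tuple = ()
    vertices: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.shape == "ellipse":
            cx, cy, a, b, _rot = self.params
            if a <= 0 or b <= 0:
                raise ValueError("ellipse semi-axes must be positive")
        elif self.shape == "polygon":
            if len(self.vertices) < 3:
                raise ValueError("polygon needs at least 3 vertices")
            if not Polygon(self.vertices).is_valid:
                raise ValueError("polygon must be simple (non-self-intersecting)")
        else:
            raise ValueError(f"unknown AOI shape {self.shape!r}")

    def contains(self, x: float, y: float) -> bool:
        if self.shape == "ellipse":
            cx, cy, a, b, rot = self.params
            th = math.radians(rot)
            dx, dy = x - cx, y - cy
            u = dx * math.cos(th) + dy * math.sin(th)
            v = -dx * math.sin(th) + dy * math.cos(th)
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return Polygon(self.vertices).covers(Point(x, y))

    def to_shapely(self) -> Polygon:
        """Polygonal approximation (ellipses discretised to 64 vertices)."""
        if self.shape == "polygon":
            return Polygon(self.vertices)
        cx, cy, a, b, rot = self.params
        th = math.radians(rot)
        pts = []
        for k in range(64):
            ang = 2 * math.pi * k / 64
            u, v = a * math.cos(ang), b * math.sin(ang)
            pts.append((cx + u * math.cos(th) - v * math.sin(th),
                        cy + u * math.sin(th) + v * math.cos(th)))
        return Polygon(pts)


@dataclass
class Stimulus:
    stimulus_id: str
    face_present: bool
    aois: list[AOI] = field(default_factory=list)

    @property
    def target_aoi(self) -> AOI | None:
        for a in self.aois:
            if a.label == "target":
                return a
        return None


@dataclass
class StimulusSet:
    stimuli: list[Stimulus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def get(self, stimulus_id: str) -> Stimulus:
        for s in self.stimuli:
            if s.stimulus_id == stimulus_id:
                return s
        raise KeyError(stimulus_id)

    @property
    def n_face_images(self) -> int:
        return sum(s.face_present for s in self.stimuli)


def assign_aoi(x: float, y: float, aois: list[AOI]) -> int | None:
    """Index of the AOI containing (x, y), or None.

    AOIs within a stimulus are non-overlapping by construction; if a point
    nevertheless falls in several (hand-edited definitions), the
    first-listed AOI wins.
    """
    for i, a in enumerate(aois):
        if a.contains(x, y):
            return i
    return None


def _aoi_to_dict(a: AOI) -> dict:
    if a.shape == "ellipse":
        return {"label": a.label, "shape": "ellipse", "params": list(a.params)}
    return {"label": a.label, "shape": "polygon", "vertices": [list(v) for v in a.vertices]}


def _aoi_from_dict(d: dict) -> AOI:
    if d["shape"] == "ellipse":
        return AOI(label=d["label"], shape="ellipse", params=tuple(d["params"]))
    return AOI(label=d["label"], shape="polygon",
               vertices=tuple(tuple(v) for v in d["vertices"]))


def write_aoi_json(stimulus_set: StimulusSet, path) -> None:
    payload = [
        {
            "stimulus_id": s.stimulus_id,
            "face_present": s.face_present,
            "aois": [_aoi_to_dict(a) for a in s.aois],
        }
        for s in stimulus_set
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_aoi_json(path) -> StimulusSet:
    with open(path) as fh:
        payload = json.load(fh)
    return StimulusSet(
        [
            Stimulus(d["stimulus_id"], bool(d["face_present"]),
                     [_aoi_from_dict(a) for a in d["aois"]])
            for d in payload
        ]
    )
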