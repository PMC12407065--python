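"""Reading and writing segmented skeletal models.

A *skeleton* is a set of per-segment triangulated meshes (or bare vertex
clouds) plus a manifest that names the taxon, classifies each segment,
and fixes the body coordinate frame.  The frame convention used
throughout the package is:

* origin at the mid-acetabular point,
* ``+x`` anterior,
* ``+z`` dorsal,
* ``y`` mediolateral (right-handed, so ``+y`` is the animal's left).

Whole-body centre of mass is therefore reported directly as displacement
from the acetabula; the glenoid landmark gives the glenoacetabular (GA)
distance used for COM normalisation downstream.

Meshes need not be watertight or manifold: only the vertex cloud is used
by the hulling stage, which tolerates the messy geometry typical of
fossil scan data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
import yaml

__all__ = [
    "SegmentClass",
    "SegmentMesh",
    "SkeletonManifest",
    "SkeletonError",
    "load_skeleton",
    "write_skeleton",
    "glenoacetabular_distances",
    "SEGMENT_CLASS_NAMES",
    "AXIAL_CLASSES",
    "LIMB_CLASSES",
    "DvDegenerateWarning",
]

AXIAL_CLASSES = frozenset({"head", "neck", "torso", "tail", "ornament", "osteoderm", "sail"})
LIMB_CLASSES = frozenset(
    {"brachium", "antebrachium", "manus", "thigh", "shank", "metatarsus", "pes"}
)
SEGMENT_CLASS_NAMES = AXIAL_CLASSES | LIMB_CLASSES

_UNIT_TO_M = {"m": 1.0, "dm": 0.1, "cm": 0.01, "mm": 0.001}

#: dorsoventral GA distances below this (in metres, post unit-normalisation)
#: are flagged degenerate for downstream normalisation
DV_EPSILON = 1e-6


class SkeletonError(ValueError):
    """Raised on invalid manifests or degenerate segment geometry."""


class DvDegenerateWarning(UserWarning):
    """Glenoid lies (nearly) at acetabular height: DV GA distance unusable."""


@dataclass(frozen=True)
class SegmentClass:
    """A body-segment category.

    Parameters
    ----------
    name
        One of :data:`SEGMENT_CLASS_NAMES` (``head``, ``neck``, ``torso``,
        ``tail``, the limb segments, or ``ornament``/``osteoderm``/``sail``).
    subdivision_index
        1-based ordinal when a class is split into serial sub-segments
        (long necks and tails typically are); ``None`` for unsplit classes.
    """

    name: str
    subdivision_index: int | None = None

    def __post_init__(self) -> None:
        if self.name not in SEGMENT_CLASS_NAMES:
            raise SkeletonError(
                f"unknown segment class {self.name!r}; expected one of "
                f"{sorted(SEGMENT_CLASS_NAMES)}"
            )
        if self.subdivision_index is not None and self.subdivision_index < 1:
            raise SkeletonError("subdivision_index must be >= 1")

    @property
    def is_limb(self) -> bool:
        return self.name in LIMB_CLASSES

    @property
    def label(self) -> str:
        if self.subdivision_index is None:
            return self.name
        return f"{self.name}_{self.subdivision_index}"


@dataclass
class SegmentMesh:
    """Vertex cloud (plus optional faces) for one body segment, in metres."""

    segment_class: SegmentClass
    side: str  # left | right | midline
    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray | None = None
    is_ornament: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.side not in ("left", "right", "midline"):
            raise SkeletonError(f"segment side must be left/right/midline, got {self.side!r}")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SkeletonError(f"segment {self.label}: vertices must be (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise SkeletonError(f"segment {self.label}: non-finite vertex coordinates")
        if len(self.vertices) < 4:
            raise SkeletonError(
                f"segment {self.label}: needs >= 4 vertices, got {len(self.vertices)}"
            )
        if _coplanar(self.vertices):
            raise SkeletonError(f"segment {self.label}: vertices are coplanar/degenerate")

    @property
    def label(self) -> str:
        base = self.segment_class.label
        return base if self.side == "midline" else f"{base}_{self.side}"


def _coplanar(vertices: np.ndarray, tol: float = 1e-12) -> bool:
    centred = vertices - vertices.mean(axis=0)
    scale = np.abs(centred).max()
    if scale == 0.0:
        return True
    s = np.linalg.svd(centred / scale, compute_uv=False)
    return bool(s[-1] < tol * max(1.0, s[0]))


@dataclass
class SkeletonManifest:
    """A loaded skeleton: segments, landmarks, and posture metadata.

    Landmarks are in the body frame (origin = mid-acetabular point), so
    ``acetabulum`` is exactly the zero vector after loading.
    """

    taxon: str
    segments: list[SegmentMesh]
    acetabulum: np.ndarray
    glenoid: np.ndarray
    joint_pivots: dict[str, np.ndarray] = field(default_factory=dict)
    posture_flag: str = "biped"  # biped | quadruped
    tail_in_torso: bool = False
    posture_notes: str = ""

    def __post_init__(self) -> None:
        self.acetabulum = np.asarray(self.acetabulum, dtype=float)
        self.glenoid = np.asarray(self.glenoid, dtype=float)
        if self.posture_flag not in ("biped", "quadruped"):
            raise SkeletonError(f"posture_flag must be biped/quadruped, got {self.posture_flag!r}")
        if not (np.all(np.isfinite(self.acetabulum)) and np.all(np.isfinite(self.glenoid))):
            raise SkeletonError("acetabulum/glenoid landmarks must be finite")
        if np.allclose(self.acetabulum, self.glenoid):
            raise SkeletonError("glenoid coincides with acetabulum")
        self._validate_subdivisions()

    def _validate_subdivisions(self) -> None:
        # sub-segment indices within one (class, side) must be unique and
        # contiguous from 1
        groups: dict[tuple[str, str], list[int]] = {}
        for seg in self.segments:
            idx = seg.segment_class.subdivision_index
            if idx is not None:
                groups.setdefault((seg.segment_class.name, seg.side), []).append(idx)
        for (name, side), idxs in groups.items():
            if sorted(idxs) != list(range(1, len(idxs) + 1)):
                raise SkeletonError(
                    f"{name} ({side}) sub-segment indices {sorted(idxs)} are not "
                    "contiguous from 1"
                )

    def segment_labels(self) -> list[str]:
        return [seg.label for seg in self.segments]


def glenoacetabular_distances(manifest: SkeletonManifest) -> tuple[float, float]:
    """Anteroposterior and dorsoventral glenoacetabular distances (m).

    Measured in the reference pose as absolute axis-wise displacements of
    the glenoid from the acetabulum.  A dorsoventral distance below
    :data:`DV_EPSILON` triggers :class:`DvDegenerateWarning`, signalling
    downstream code to omit DV-GA-normalised quantities for this taxon.
    """
    ap = abs(float(manifest.glenoid[0]) - float(manifest.acetabulum[0]))
    dv = abs(float(manifest.glenoid[2]) - float(manifest.acetabulum[2]))
    if dv < DV_EPSILON:
        warnings.warn(
            f"{manifest.taxon}: dorsoventral glenoacetabular distance ~0; "
            "DV-normalised COM will be flagged missing",
            DvDegenerateWarning,
            stacklevel=2,
        )
    return ap, dv


# ---------------------------------------------------------------------------
# manifest file handling


def _frame_matrix(anterior: str, dorsal: str) -> np.ndarray:
    """Rotation mapping a source frame (given by its anterior and dorsal
    axes, e.g. ``"+y"``, ``"+z"``) onto the body frame (+x anterior,
    +z dorsal, y completing a right-handed triad)."""
    ax = {"x": 0, "y": 1, "z": 2}

    def vec(spec: str) -> np.ndarray:
        sign = -1.0 if spec.startswith("-") else 1.0
        v = np.zeros(3)
        v[ax[spec.lstrip("+-")]] = sign
        return v

    a, d = vec(anterior), vec(dorsal)
    if abs(float(a @ d)) > 1e-9:
        raise SkeletonError(f"frame axes {anterior!r}/{dorsal!r} are not orthogonal")
    m = np.cross(d, a)  # mediolateral completing right-handed frame
    rot = np.vstack([a, m, d])  # rows: where source x', y', z' land
    if not math.isclose(float(np.linalg.det(rot)), 1.0, abs_tol=1e-9):
        raise SkeletonError("frame specification is not a proper rotation")
    return rot


def load_skeleton(manifest_path: str | Path) -> SkeletonManifest:
    """Load a skeleton manifest (YAML/JSON) and its referenced meshes.

    The manifest declares units and (optionally) its own axis convention;
    vertices and landmarks are rescaled to metres and rigidly transformed
    into the body frame with the origin at the mid-acetabular point.

    Raises
    ------
    SkeletonError
        On a missing mesh file, a degenerate segment (<4 vertices or
        coplanar), or missing/coincident landmarks.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        raw = yaml.safe_load(fh)

    for key in ("taxon", "acetabulum", "glenoid", "segments"):
        if key not in raw:
            raise SkeletonError(f"manifest missing required field {key!r}")

    unit = raw.get("units", "m")
    if unit not in _UNIT_TO_M:
        raise SkeletonError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_M)}")
    scale = _UNIT_TO_M[unit]

    frame = raw.get("frame", {})
    rot = _frame_matrix(frame.get("anterior", "+x"), frame.get("dorsal", "+z"))

    acetabulum = rot @ (np.asarray(raw["acetabulum"], dtype=float) * scale)
    glenoid = rot @ (np.asarray(raw["glenoid"], dtype=float) * scale)

    def to_body(points: np.ndarray) -> np.ndarray:
        return (points * scale) @ rot.T - acetabulum

    segments: list[SegmentMesh] = []
    for entry in raw["segments"]:
        cls = SegmentClass(entry["class"], entry.get("subdivision"))
        mesh_file = manifest_path.parent / entry["mesh"]
        if not mesh_file.exists():
            raise SkeletonError(f"segment {cls.label}: mesh file not found: {mesh_file}")
        loaded = trimesh.load(mesh_file, process=False)
        vertices = np.asarray(loaded.vertices, dtype=float)
        raw_faces = getattr(loaded, "faces", None)
        faces = np.asarray(raw_faces) if raw_faces is not None and len(raw_faces) else None
        segments.append(
            SegmentMesh(
                segment_class=cls,
                side=entry.get("side", "midline"),
                vertices=to_body(vertices),
                faces=faces,
                is_ornament=cls.name in ("ornament", "osteoderm", "sail"),
            )
        )

    pivots = {
        name: rot @ (np.asarray(p, dtype=float) * scale) - acetabulum
        for name, p in raw.get("joint_pivots", {}).items()
    }

    return SkeletonManifest(
        taxon=raw["taxon"],
        segments=segments,
        acetabulum=acetabulum - acetabulum,  # origin by construction
        glenoid=glenoid - acetabulum,
        joint_pivots=pivots,
        posture_flag=raw.get("posture", "biped"),
        tail_in_torso=bool(raw.get("tail_in_torso", False)),
        posture_notes=str(raw.get("posture_notes", "")),
    )


def write_skeleton(manifest: SkeletonManifest, out_dir: str | Path) -> Path:
    """Write meshes (OBJ) and a manifest YAML; returns the manifest path.

    The written set round-trips through :func:`load_skeleton` to within
    float round-off (coordinates are already in the body frame and metres,
    so the manifest declares units ``m`` and the default axis convention).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for seg in manifest.segments:
        fname = f"{seg.label}.obj"
        faces = seg.faces
        if faces is None:
            # export as a point-only OBJ (vertices, no faces)
            lines = [f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in seg.vertices]
            (out_dir / fname).write_text("\n".join(lines) + "\n")
        else:
            trimesh.Trimesh(vertices=seg.vertices, faces=faces, process=False).export(
                out_dir / fname
            )
        entry = {"class": seg.segment_class.name, "side": seg.side, "mesh": fname}
        if seg.segment_class.subdivision_index is not None:
            entry["subdivision"] = seg.segment_class.subdivision_index
        entries.append(entry)
    doc = {
        "taxon": manifest.taxon,
        "units": "m",
        "acetabulum": [float(x) for x in manifest.acetabulum],
        "glenoid": [float(x) for x in manifest.glenoid],
        "posture": manifest.posture_flag,
        "tail_in_torso": manifest.tail_in_torso,
        "posture_notes": manifest.posture_notes,
        "joint_pivots": {k: [float(x) for x in v] for k, v in manifest.joint_pivots.items()},
        "segments": entries,
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def translate_manifest(manifest: SkeletonManifest, offset: np.ndarray) -> SkeletonManifest:
    """Rigidly translate a whole skeleton (used for frame-invariance checks)."""
    offset = np.asarray(offset, dtype=float)
    segs = [replace(s, vertices=s.vertices + offset) for s in manifest.segments]
    return SkeletonManifest(
        taxon=manifest.taxon,
        segments=segs,
        acetabulum=manifest.acetabulum + offset,
        glenoid=manifest.glenoid + offset,
        joint_pivots={k: v + offset for k, v in manifest.joint_pivots.items()},
        posture_flag=manifest.posture_flag,
        tail_in_torso=manifest.tail_in_torso,
        posture_notes=manifest.posture_notes,
    )
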