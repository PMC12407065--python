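"""Rigid reposing of segment chains and its effect on whole-body COM.

Hulls are measured once, in the reference pose; posture sensitivity
(e.g. pitching a long neck 45 degrees above horizontal) is modelled by
rigidly rotating the affected segments' centres of mass about a joint
pivot.  Masses and volumes are untouched, so the only change is a
redistribution of where those masses sit.

Sign convention: with the default mediolateral rotation axis, a positive
angle pitches anterior structures dorsally (an anterior neck COM moves
up and back toward the pivot's vertical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mass_model import BodyMassProps, MassModelError, assemble_body
from .skeleton_io import DV_EPSILON, SkeletonManifest, glenoacetabular_distances

__all__ = ["ReposeSpec", "repose", "neck_pitch_report", "rotation_matrix"]

#: default rotation axis: negative mediolateral, so that a positive angle
#: is a dorsal pitch under the right-hand rule (+x anterior -> +z dorsal)
DEFAULT_AXIS = (0.0, -1.0, 0.0)


@dataclass
class ReposeSpec:
    """A rigid rotation applied to an ordered chain of segments.

    ``chain`` lists segment labels (e.g. neck sub-segments plus head);
    ``angle_deg`` is in degrees, positive = dorsal pitch about the
    default axis.
    """

    chain: list[str]
    pivot: np.ndarray
    angle_deg: float
    axis: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_AXIS))

    def __post_init__(self) -> None:
        self.pivot = np.asarray(self.pivot, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if not np.all(np.isfinite(self.pivot)):
            raise ValueError("repose pivot must be finite")
        norm = float(np.linalg.norm(self.axis))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"rotation axis must be unit norm, got |axis| = {norm}")
        if not self.chain:
            raise ValueError("repose chain is empty")


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis (right-hand rule)."""
    axis = np.asarray(axis, dtype=float)
    theta = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)


def repose(body: BodyMassProps, spec: ReposeSpec) -> BodyMassProps:
    """Rotate the chain segments' COMs about the pivot; reassemble the body.

    Masses and volumes are unchanged; the whole-body COM is recomputed
    from the displaced segment point masses.

    Raises
    ------
    MassModelError
        If a chain label names no segment of the body.
    """
    labels = {s.label for s in body.per_segment}
    unknown = [c for c in spec.chain if c not in labels]
    if unknown:
        raise MassModelError(f"repose chain names unknown segments: {unknown}")
    rot = rotation_matrix(spec.axis, spec.angle_deg)
    chain = set(spec.chain)
    new_segments = []
    for seg in body.per_segment:
        if seg.label in chain:
            new_com = rot @ (seg.com - spec.pivot) + spec.pivot
            new_segments.append(replace(seg, com=new_com))
        else:
            new_segments.append(seg)
    return assemble_body(
        new_segments,
        taxon=body.taxon,
        model_set_name=body.model_set_name,
        density_scheme=body.density_scheme,
    )


def neck_pitch_report(
    base: BodyMassProps,
    pitched: BodyMassProps,
    manifest: SkeletonManifest,
) -> pd.DataFrame:
    """COM shift between a base and a reposed body, in GA percentages.

    The anteroposterior shift is expressed as a percentage of the AP
    glenoacetabular distance, the dorsoventral shift as a percentage of
    the DV GA distance (NaN when the DV distance is degenerate).
    Negative AP = posterior shift; positive DV = dorsal shift.
    """
    if base.taxon != pitched.taxon:
        raise MassModelError(
            f"taxon mismatch: {base.taxon!r} vs {pitched.taxon!r}"
        )
    if base.model_set_name != pitched.model_set_name:
        raise MassModelError("model-set mismatch between base and reposed bodies")
    ap, dv = glenoacetabular_distances(manifest)
    dcom = pitched.com - base.com
    return pd.DataFrame(
        [
            {
                "taxon": base.taxon,
                "model_set": base.model_set_name,
                "delta_com_ap_pct_ga": 100.0 * float(dcom[0]) / ap,
                "delta_com_dv_pct_ga": (100.0 * float(dcom[2]) / dv)
                if dv >= DV_EPSILON
                else np.nan,
                "delta_com_x_m": float(dcom[0]),
                "delta_com_z_m": float(dcom[2]),
            }
        ]
    )
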