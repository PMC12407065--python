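"""Densities, segment masses, and whole-body mass properties.

Segment mass is density times expanded volume; whole-body centre of mass
is the mass-weighted mean of segment COMs:

    M = sum_i m_i,    COM = sum_i m_i x_i / M

with x_i the segment COM (hull centroid) expressed as displacement from
the mid-acetabular origin.  Whole-body mass bounds are formed by summing
the segment-wise lower (respectively upper) volumes simultaneously — a
conservative envelope that does not model per-segment independence.

Density schemes
---------------
``primary_heterogeneous`` assigns 1000 kg/m^3 to head, tail and limb
segments, 800 to the neck and 850 to the torso (air-sac/lung allowance),
2000 to ornaments and major osteoderms (compact bone) and 1000 to
separately hulled sails.  Sensitivity presets: homogeneous extremes 731
and 1169 kg/m^3 (plucked-bird whole-body extremes), a low-density
(500 kg/m^3) neck variant for highly pneumatised necks, an
ornament-light variant (ornament 1000), and a dense-sail variant
(sail 2000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expansion import ExpandedSegmentVolume
from .skeleton_io import LIMB_CLASSES, SkeletonManifest

__all__ = [
    "DensityScheme",
    "SegmentMassProps",
    "BodyMassProps",
    "MassModelError",
    "segment_mass",
    "assemble_body",
    "compute_body",
    "variant_exclude_osteoderms",
    "variant_redensify",
    "DENSITY_PRESETS",
    "body_table",
]


class MassModelError(ValueError):
    """Raised for missing densities or empty bodies."""


@dataclass(frozen=True)
class DensityScheme:
    """Mapping from segment class to tissue density (kg/m^3).

    ``homogeneous_value``, when set, overrides every class.
    """

    name: str
    class_density: dict[str, float] = field(default_factory=dict)
    homogeneous_value: float | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.class_density.values()):
            raise MassModelError(f"scheme {self.name}: densities must be > 0")
        if self.homogeneous_value is not None and self.homogeneous_value <= 0:
            raise MassModelError(f"scheme {self.name}: homogeneous density must be > 0")

    def density(self, segment_class: str) -> float:
        if self.homogeneous_value is not None:
            return self.homogeneous_value
        try:
            return self.class_density[segment_class]
        except KeyError:
            raise MassModelError(
                f"scheme {self.name!r} has no density for segment class {segment_class!r}"
            ) from None

    def with_density(self, segment_class: str, value: float, name: str) -> "DensityScheme":
        dens = dict(self.class_density)
        dens[segment_class] = value
        return DensityScheme(name=name, class_density=dens)


def _primary_density_map() -> dict[str, float]:
    dens = {"head": 1000.0, "neck": 800.0, "torso": 850.0, "tail": 1000.0}
    dens.update({cls: 1000.0 for cls in LIMB_CLASSES})
    dens.update({"ornament": 2000.0, "osteoderm": 2000.0, "sail": 1000.0})
    return dens


def _make_presets() -> dict[str, DensityScheme]:
    primary = DensityScheme("primary_heterogeneous", _primary_density_map())
    return {
        "primary_heterogeneous": primary,
        "homogeneous_min": DensityScheme("homogeneous_min", homogeneous_value=731.0),
        "homogeneous_max": DensityScheme("homogeneous_max", homogeneous_value=1169.0),
        "sauropod_low_neck": primary.with_density("neck", 500.0, "sauropod_low_neck"),
        "ornament_light": primary.with_density("ornament", 1000.0, "ornament_light"),
        "sail_light": primary,  # primary already carries sail 1000
        "sail_dense": primary.with_density("sail", 2000.0, "sail_dense"),
    }


DENSITY_PRESETS: dict[str, DensityScheme] = _make_presets()


@dataclass
class SegmentMassProps:
    """Mass (kg), COM (m, body frame) and bounds for one segment."""

    segment_class: str
    side: str
    label: str
    mass: float
    com: np.ndarray
    mass_lower: float
    mass_upper: float
    volume: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.mass_lower <= self.mass <= self.mass_upper):
            raise MassModelError(f"{self.label}: mass bounds must bracket the point mass")


@dataclass
class BodyMassProps:
    """Whole-body mass properties assembled from segment masses."""

    taxon: str
    model_set_name: str
    density_scheme: str
    total_mass: float
    total_mass_lower: float
    total_mass_upper: float
    com: np.ndarray
    per_segment: list[SegmentMassProps]
    segment_fraction: dict[str, float]
    mediolateral_flagged: bool = False

    def segment(self, label: str) -> SegmentMassProps:
        for seg in self.per_segment:
            if seg.label == label:
                return seg
        raise KeyError(label)


def segment_mass(
    vol: ExpandedSegmentVolume,
    centroid: np.ndarray | None,
    scheme: DensityScheme,
) -> SegmentMassProps:
    """Mass properties of one segment: ``m = rho(class) * V_point``.

    Bounds come from the lower/upper volumes at the same density; the
    segment COM is the hull centroid (``centroid=None`` uses the one
    stored on the expanded volume).
    """
    rho = scheme.density(vol.segment_class)
    com = np.asarray(centroid if centroid is not None else vol.centroid, dtype=float)
    return SegmentMassProps(
        segment_class=vol.segment_class,
        side=vol.side,
        label=vol.label,
        mass=rho * vol.point_volume,
        com=com,
        mass_lower=rho * vol.lower_volume,
        mass_upper=rho * vol.upper_volume,
        volume=vol.point_volume,
    )


def assemble_body(
    segments: list[SegmentMassProps],
    manifest: SkeletonManifest | None = None,
    *,
    taxon: str | None = None,
    model_set_name: str = "",
    density_scheme: str = "",
) -> BodyMassProps:
    """Total mass, whole-body COM and bounds from segment masses.

    Bounds are segment-wise extreme sums (all segments simultaneously at
    their lower, respectively upper, mass).  The mediolateral COM
    component is computed but flagged: for bilaterally modelled bodies it
    is expected to be at or negligibly displaced from the sagittal plane.
    """
    if not segments:
        raise MassModelError("cannot assemble a body from zero segments")
    masses = np.array([s.mass for s in segments])
    total = float(masses.sum())
    if total <= 0:
        raise MassModelError("zero total body mass")
    coms = np.vstack([s.com for s in segments])
    com = (masses[:, None] * coms).sum(axis=0) / total

    fractions: dict[str, float] = {}
    for s in segments:
        fractions[s.segment_class] = fractions.get(s.segment_class, 0.0) + s.mass
    fractions = {k: 100.0 * v / total for k, v in fractions.items()}

    ml_flag = abs(float(com[1])) > 1e-6 * max(1.0, float(np.abs(coms).max()))
    return BodyMassProps(
        taxon=taxon or (manifest.taxon if manifest is not None else ""),
        model_set_name=model_set_name,
        density_scheme=density_scheme,
        total_mass=total,
        total_mass_lower=float(sum(s.mass_lower for s in segments)),
        total_mass_upper=float(sum(s.mass_upper for s in segments)),
        com=com,
        per_segment=list(segments),
        segment_fraction=fractions,
        mediolateral_flagged=ml_flag,
    )


def compute_body(
    volumes: list[ExpandedSegmentVolume],
    scheme: DensityScheme,
    manifest: SkeletonManifest | None = None,
    *,
    taxon: str | None = None,
    model_set_name: str = "",
) -> BodyMassProps:
    """Convenience: segment masses plus assembly in one call."""
    segs = [segment_mass(v, None, scheme) for v in volumes]
    return assemble_body(
        segs,
        manifest,
        taxon=taxon,
        model_set_name=model_set_name,
        density_scheme=scheme.name,
    )


def variant_exclude_osteoderms(body: BodyMassProps) -> BodyMassProps:
    """Recompute totals and COM without osteoderm-class segments.

    A body with no osteoderms is returned unchanged (same totals; a new
    object is still constructed).
    """
    kept = [s for s in body.per_segment if s.segment_class != "osteoderm"]
    if not kept:
        raise MassModelError("body consists only of osteoderms")
    return assemble_body(
        kept,
        taxon=body.taxon,
        model_set_name=body.model_set_name,
        density_scheme=body.density_scheme + "+no_osteoderms",
    )


def variant_redensify(
    volumes: list[ExpandedSegmentVolume],
    scheme2: DensityScheme,
    manifest: SkeletonManifest | None = None,
    *,
    taxon: str | None = None,
    model_set_name: str = "",
) -> BodyMassProps:
    """Recompute masses under an alternative density scheme.

    Volumes are untouched; only densities change.  Pair the result with
    the base body via :func:`redensify_report` for delta tables.
    """
    return compute_body(
        volumes, scheme2, manifest, taxon=taxon, model_set_name=model_set_name
    )


def redensify_report(
    base: BodyMassProps,
    alt: BodyMassProps,
    ga_ap: float | None = None,
    ga_dv: float | None = None,
) -> pd.DataFrame:
    """One-row delta table: mass change (%) and COM shift.

    COM shifts are reported in metres and, when GA distances are given,
    as percentages of the anteroposterior (x) and dorsoventral (z)
    glenoacetabular distances.
    """
    if base.taxon != alt.taxon:
        raise MassModelError("redensify report requires the same taxon")
    dmass_pct = 100.0 * (alt.total_mass - base.total_mass) / base.total_mass
    dcom = alt.com - base.com
    row = {
        "taxon": base.taxon,
        "scheme_base": base.density_scheme,
        "scheme_alt": alt.density_scheme,
        "delta_mass_pct": dmass_pct,
        "delta_com_x_m": float(dcom[0]),
        "delta_com_z_m": float(dcom[2]),
    }
    if ga_ap:
        row["delta_com_ap_pct_ga"] = 100.0 * float(dcom[0]) / ga_ap
    if ga_dv:
        row["delta_com_dv_pct_ga"] = 100.0 * float(dcom[2]) / ga_dv
    return pd.DataFrame([row])


def body_table(bodies: list[BodyMassProps], ga: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Per-taxon summary CSV rows: totals, bounds, COM, segment fractions."""
    rows = []
    for b in bodies:
        row = {
            "taxon": b.taxon,
            "model_set": b.model_set_name,
            "density_scheme": b.density_scheme,
            "total_mass_kg": b.total_mass,
            "total_mass_lower_kg": b.total_mass_lower,
            "total_mass_upper_kg": b.total_mass_upper,
            "com_x_m": float(b.com[0]),
            "com_z_m": float(b.com[2]),
        }
        if ga and b.taxon in ga:
            ap, dv = ga[b.taxon]
            row["com_ap_ga"] = float(b.com[0]) / ap if ap else np.nan
            row["com_dv_ga"] = float(b.com[2]) / dv if dv else np.nan
        for cls, frac in sorted(b.segment_fraction.items()):
            row[f"frac_{cls}_pct"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
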