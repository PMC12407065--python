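"""Synthetic skeletons, trees and trait cohorts with known ground truth.

Real fossil mesh sets cannot be bundled, so every pipeline stage is
exercised against generated inputs whose correct answers are known
analytically:

* **Primitive segments.**  Boxes (hull volume and centroid exact),
  conical frusta emitted as two aligned regular m-gon rings (the hull is
  a polygonal frustum whose volume/centroid have exact closed forms that
  converge to the smooth frustum as m grows), and ellipsoids emitted as
  Fibonacci-sphere surface clouds (hull volume converges to the
  ellipsoid volume from below; stored truth carries a discretisation
  bound rather than an exact flag).
* **Body plans.**  A multi-segment dinosaurian stand-in (torso, neck and
  tail sub-segments, head, limbs on both sides) built from boxes, with
  acetabulum/glenoid landmarks, scalable to any body size.  Shapes are
  abstract volumetric stand-ins, not osteology.
* **Cohorts.**  A pure-birth tree, log10 body masses evolved by Brownian
  motion (rescaled to span a stated mass range), and a log10 segment
  dimension constructed as ``intercept + slope * log10(mass)`` plus an
  independent Brownian deviation on the same tree — the configuration
  assumed by the PGLS estimator, so parameter-recovery experiments are
  well-posed.  All truth (slope, intercept, sigma^2, per-taxon values)
  is recorded on the cohort object.

All randomness flows from a single integer seed through
``numpy.random.default_rng`` (PCG64) and, for tree shape, a seeded
``random.Random``; regeneration with the same seed is identical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .skeleton_io import SegmentClass, SegmentMesh, SkeletonManifest, write_skeleton
from .trees import PhyloTree

__all__ = [
    "PrimitiveSpec",
    "BodyPlanTemplate",
    "SyntheticCohort",
    "box_vertices",
    "frustum_vertices",
    "ellipsoid_vertices",
    "frustum_hull_volume",
    "frustum_hull_centroid_height",
    "default_body_plan",
    "generate_skeleton",
    "random_tree",
    "simulate_brownian",
    "generate_cohort",
]

#: default cohort design: 53 taxa spanning 0.2 kg to 60 t (log-uniform-ish),
#: mirroring a broad archosaur body-size survey
DEFAULT_N_TAXA = 53
DEFAULT_LOG_MASS_RANGE = (np.log10(0.2), np.log10(6.0e4))
#: torso length ~ 0.3 * M^(1/3) (m, kg): ~0.65 m for 10 kg, ~3 m for 1 t
DEFAULT_TRUE_SLOPE = 1.0 / 3.0
DEFAULT_TRUE_INTERCEPT = float(np.log10(0.3))
#: Brownian variance (dex^2 per unit tree depth) of the trait deviation:
#: ~0.05 dex scatter at the tips of a depth-1 tree (tight allometry)
DEFAULT_SIGMA2 = 0.0025

REFERENCE_DENSITY = 1000.0  # kg/m^3, homogeneous, for volume->mass truth


# ---------------------------------------------------------------------------
# primitive solids with analytic hulls


def box_vertices(center, size) -> np.ndarray:
    """Corner vertices of an axis-aligned box."""
    center = np.asarray(center, dtype=float)
    half = np.asarray(size, dtype=float) / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    return center + corners * half


def frustum_vertices(base_center, axis, r1, r2, h, n_sides: int = 64) -> np.ndarray:
    """Two aligned regular n-gon rings: the cloud of a conical frustum.

    ``axis`` is the unit direction from the base ring (radius ``r1``)
    toward the top ring (radius ``r2``, at distance ``h``).
    """
    base_center = np.asarray(base_center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = 2.0 * np.pi * np.arange(n_sides) / n_sides
    ring = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
    bottom = base_center + r1 * ring
    top = base_center + h * axis + r2 * ring
    return np.vstack([bottom, top])


def frustum_hull_volume(r1: float, r2: float, h: float, n_sides: int = 64) -> float:
    """Exact volume of the hull of two aligned regular n-gon rings.

    The cross-section at height z is a regular n-gon of linearly
    interpolated radius, so ``V = c * h * (r1^2 + r1 r2 + r2^2) / 3``
    with ``c = (n/2) sin(2 pi / n)``; as n grows c -> pi and the smooth
    frustum volume is recovered.
    """
    c = 0.5 * n_sides * np.sin(2.0 * np.pi / n_sides)
    return float(c * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0)


def frustum_hull_centroid_height(r1: float, r2: float, h: float) -> float:
    """Centroid height above the base (independent of n for aligned rings)."""
    num = r1 * r1 + 2.0 * r1 * r2 + 3.0 * r2 * r2
    den = 4.0 * (r1 * r1 + r1 * r2 + r2 * r2)
    return float(h * num / den)


def ellipsoid_vertices(center, radii, n_points: int = 256) -> np.ndarray:
    """Deterministic Fibonacci-lattice surface cloud of an ellipsoid."""
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    i = np.arange(n_points, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = 2.0 * np.pi * i / phi
    sphere = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return center + sphere * radii


@dataclass
class PrimitiveSpec:
    """One synthetic segment: a primitive solid with analytic truth."""

    segment_class: str
    side: str = "midline"
    subdivision: int | None = None
    shape: str = "box"  # box | frustum | ellipsoid
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    size: np.ndarray | None = None  # box
    axis: np.ndarray | None = None  # frustum
    r1: float = 1.0
    r2: float = 0.5
    h: float = 1.0
    n_sides: int = 64
    radii: np.ndarray | None = None  # ellipsoid
    n_points: int = 256

    def vertices(self) -> np.ndarray:
        if self.shape == "box":
            return box_vertices(self.center, self.size)
        if self.shape == "frustum":
            return frustum_vertices(self.center, self.axis, self.r1, self.r2, self.h, self.n_sides)
        if self.shape == "ellipsoid":
            return ellipsoid_vertices(self.center, self.radii, self.n_points)
        raise ValueError(f"unknown primitive shape {self.shape!r}")

    def truth(self) -> dict:
        """Hull volume/centroid truth; ``exact`` marks closed-form-exact hulls."""
        if self.shape == "box":
            size = np.asarray(self.size, dtype=float)
            return {
                "volume": float(np.prod(size)),
                "centroid": np.asarray(self.center, dtype=float),
                "exact": True,
                "rel_bound": 0.0,
            }
        if self.shape == "frustum":
            axis = np.asarray(self.axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            zbar = frustum_hull_centroid_height(self.r1, self.r2, self.h)
            return {
                "volume": frustum_hull_volume(self.r1, self.r2, self.h, self.n_sides),
                "centroid": np.asarray(self.center, dtype=float) + zbar * axis,
                "exact": True,
                "rel_bound": 0.0,
            }
        if self.shape == "ellipsoid":
            radii = np.asarray(self.radii, dtype=float)
            # inscribed-polytope deficit shrinks with the point count;
            # the stated bound is an empirical envelope, not a theorem
            bound = 12.0 * self.n_points ** (-2.0 / 3.0)
            return {
                "volume": float(4.0 / 3.0 * np.pi * np.prod(radii)),
                "centroid": np.asarray(self.center, dtype=float),
                "exact": False,
                "rel_bound": bound,
            }
        raise ValueError(f"unknown primitive shape {self.shape!r}")

    @property
    def label(self) -> str:
        cls = SegmentClass(self.segment_class, self.subdivision)
        return cls.label if self.side == "midline" else f"{cls.label}_{self.side}"


@dataclass
class BodyPlanTemplate:
    """Recipe for a synthetic multi-segment skeleton."""

    name: str
    segments: list[PrimitiveSpec]
    acetabulum: np.ndarray
    glenoid: np.ndarray
    posture_flag: str = "biped"
    tail_in_torso: bool = False
    joint_pivots: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def total_volume(self) -> float:
        return float(sum(s.truth()["volume"] for s in self.segments))


def default_body_plan(
    torso_length: float = 1.0,
    scale: float | None = None,
    quadruped: bool = False,
    name: str = "synthetic",
) -> BodyPlanTemplate:
    """A box-built dinosaurian stand-in, isometrically scalable.

    ``scale`` multiplies every dimension except the torso anteroposterior
    length, which is set directly by ``torso_length`` (so cohort
    generators can perturb one measured dimension independently of
    overall body size).  When ``scale`` is omitted it defaults to
    ``torso_length``, giving a fully isometric body.
    """
    s = torso_length if scale is None else scale
    L = torso_length
    segs: list[PrimitiveSpec] = [
        PrimitiveSpec("torso", center=np.array([0.45 * L, 0.0, 0.35 * s]),
                      size=np.array([L, 0.45 * s, 0.45 * s])),
        PrimitiveSpec("neck", subdivision=1,
                      center=np.array([0.45 * L + 0.55 * L + 0.15 * s, 0.0, 0.5 * s]),
                      size=np.array([0.3 * s, 0.18 * s, 0.18 * s])),
        PrimitiveSpec("neck", subdivision=2,
                      center=np.array([0.45 * L + 0.55 * L + 0.45 * s, 0.0, 0.55 * s]),
                      size=np.array([0.3 * s, 0.16 * s, 0.16 * s])),
        PrimitiveSpec("head",
                      center=np.array([0.45 * L + 0.55 * L + 0.72 * s, 0.0, 0.58 * s]),
                      size=np.array([0.24 * s, 0.14 * s, 0.15 * s])),
        PrimitiveSpec("tail", subdivision=1,
                      center=np.array([-0.35 * L + 0.1 * L, 0.0, 0.38 * s]),
                      size=np.array([0.5 * L, 0.2 * s, 0.2 * s])),
        PrimitiveSpec("tail", subdivision=2,
                      center=np.array([-0.35 * L - 0.4 * L, 0.0, 0.4 * s]),
                      size=np.array([0.5 * L, 0.12 * s, 0.12 * s])),
    ]
    for side, ysign in (("left", 1.0), ("right", -1.0)):
        y = ysign * 0.18 * s
        segs += [
            PrimitiveSpec("thigh", side=side, center=np.array([0.0, y, -0.15 * s]),
                          size=np.array([0.16 * s, 0.1 * s, 0.3 * s])),
            PrimitiveSpec("shank", side=side, center=np.array([0.0, y, -0.42 * s]),
                          size=np.array([0.12 * s, 0.08 * s, 0.26 * s])),
            PrimitiveSpec("metatarsus", side=side, center=np.array([0.0, y, -0.62 * s]),
                          size=np.array([0.07 * s, 0.06 * s, 0.16 * s])),
            PrimitiveSpec("pes", side=side, center=np.array([0.05 * s, y, -0.72 * s]),
                          size=np.array([0.2 * s, 0.08 * s, 0.05 * s])),
        ]
        if quadruped:
            xg = 0.85 * L
            segs += [
                PrimitiveSpec("brachium", side=side, center=np.array([xg, y, -0.05 * s]),
                              size=np.array([0.13 * s, 0.08 * s, 0.26 * s])),
                PrimitiveSpec("antebrachium", side=side, center=np.array([xg, y, -0.3 * s]),
                              size=np.array([0.1 * s, 0.07 * s, 0.22 * s])),
                PrimitiveSpec("manus", side=side, center=np.array([xg + 0.03 * s, y, -0.44 * s]),
                              size=np.array([0.12 * s, 0.07 * s, 0.05 * s])),
            ]
    glenoid = np.array([0.85 * L, 0.0, 0.3 * s])
    neck_base = np.array([L, 0.0, 0.45 * s])
    return BodyPlanTemplate(
        name=name,
        segments=segs,
        acetabulum=np.zeros(3),
        glenoid=glenoid,
        posture_flag="quadruped" if quadruped else "biped",
        joint_pivots={"neck": neck_base},
    )


def generate_skeleton(
    template: BodyPlanTemplate, out_dir: str | Path | None = None
) -> tuple[SkeletonManifest, pd.DataFrame]:
    """Materialise a body plan as a skeleton manifest plus a truth table.

    The truth table has one row per segment with the analytic hull
    volume and centroid (columns ``exact``/``rel_bound`` qualify curved
    primitives).  With ``out_dir`` the meshes and manifest are also
    written to disk in the formats :func:`hullmass.load_skeleton` reads.
    """
    if np.allclose(template.acetabulum, template.glenoid):
        raise ValueError("template landmarks coincide")
    meshes: list[SegmentMesh] = []
    rows = []
    for spec in template.segments:
        cls = SegmentClass(spec.segment_class, spec.subdivision)
        mesh = SegmentMesh(
            segment_class=cls,
            side=spec.side,
            vertices=spec.vertices(),
            is_ornament=spec.segment_class in ("ornament", "osteoderm", "sail"),
        )
        meshes.append(mesh)
        t = spec.truth()
        rows.append(
            {
                "segment": mesh.label,
                "segment_class": spec.segment_class,
                "side": spec.side,
                "volume": t["volume"],
                "centroid_x": t["centroid"][0],
                "centroid_y": t["centroid"][1],
                "centroid_z": t["centroid"][2],
                "exact": t["exact"],
                "rel_bound": t["rel_bound"],
            }
        )
    manifest = SkeletonManifest(
        taxon=template.name,
        segments=meshes,
        acetabulum=np.asarray(template.acetabulum, dtype=float),
        glenoid=np.asarray(template.glenoid, dtype=float),
        joint_pivots={k: np.asarray(v, dtype=float) for k, v in template.joint_pivots.items()},
        posture_flag=template.posture_flag,
        tail_in_torso=template.tail_in_torso,
    )
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_skeleton(manifest, out_dir)
        truth.to_csv(out_dir / "truth.csv", index=False)
    return manifest, truth


# ---------------------------------------------------------------------------
# trees and Brownian traits


def random_tree(n_taxa: int, seed: int, depth: float = 1.0) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_taxa`` extant tips, scaled so the
    root-to-tip depth equals ``depth`` (ultrametric)."""
    from dendropy.model import birthdeath

    rng = random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    # general sampling approach: a time slice with exactly n_taxa lineages,
    # so terminal branches are strictly positive (no tip-pair degeneracy)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        gsa_ntax=2 * n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    tree.seed_node.edge.length = 0.0
    max_depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * depth / max_depth
    return PhyloTree(tree)


def simulate_brownian(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Brownian-motion tip values: MVN(root_value, sigma2 * C).

    Values are returned in ``tree.taxa`` order.  ``sigma2`` is variance
    accumulated per unit branch length; zero gives all tips equal to the
    root value.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))
    n = tree.n_tips
    if sigma2 == 0:
        return np.full(n, float(root_value))
    C = tree.tip_covariance()
    jitter = 1e-12 * max(1.0, float(C.max()))
    L = np.linalg.cholesky(C + jitter * np.eye(n))
    return root_value + np.sqrt(sigma2) * (L @ rng.standard_normal(n))


@dataclass
class SyntheticCohort:
    """A simulated taxon sample with full generating truth.

    ``log_mass`` is the assigned log10 body mass (kg); ``log_trait`` the
    log10 torso length (m) constructed from the true allometry plus a
    Brownian deviation.  ``templates`` hold per-taxon body plans whose
    overall scale tracks assigned mass (so analytic body volume is a
    strictly monotone map of mass) and whose torso length realises the
    trait.
    """

    tree: PhyloTree
    taxa: list[str]
    log_mass: np.ndarray
    log_trait: np.ndarray
    true_slope: float
    true_intercept: float
    sigma2: float
    seed: int
    templates: dict[str, BodyPlanTemplate]

    def body_volume(self, taxon: str) -> float:
        return self.templates[taxon].total_volume()

    def mass_from_volume(self, taxon: str) -> float:
        return REFERENCE_DENSITY * self.body_volume(taxon)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "taxon": self.taxa,
                "log10_mass_kg": self.log_mass,
                "log10_torso_length_m": self.log_trait,
            }
        )
        if self.templates:
            out["body_volume_m3"] = [self.body_volume(t) for t in self.taxa]
        return out


def generate_cohort(
    n_taxa: int = DEFAULT_N_TAXA,
    true_slope: float = DEFAULT_TRUE_SLOPE,
    true_intercept: float = DEFAULT_TRUE_INTERCEPT,
    sigma2: float = DEFAULT_SIGMA2,
    seed: int = 0,
    log_mass_range: tuple[float, float] = DEFAULT_LOG_MASS_RANGE,
    with_templates: bool = True,
) -> SyntheticCohort:
    """Simulate a taxon cohort on a random tree with known allometry.

    log10 body mass evolves by Brownian motion and is affinely rescaled
    to span ``log_mass_range`` (an affine map of a Brownian sample is
    still Brownian, so the phylogenetic signal in the predictor is
    preserved).  The trait is ``intercept + slope * log_mass`` plus an
    independent Brownian deviation of variance ``sigma2`` per unit
    depth — exactly the residual structure PGLS assumes.
    """
    if n_taxa < 8:
        raise ValueError("cohorts need n_taxa >= 8")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    seed = int(seed)
    tree = random_tree(n_taxa, seed=seed)
    rng = np.random.default_rng(seed + 1)
    x_raw = simulate_brownian(tree, sigma2=1.0, root_value=0.0, seed=rng)
    lo, hi = log_mass_range
    span = x_raw.max() - x_raw.min()
    if span == 0:
        x = np.full(n_taxa, 0.5 * (lo + hi))
    else:
        x = lo + (x_raw - x_raw.min()) * (hi - lo) / span
    noise = simulate_brownian(tree, sigma2=sigma2, root_value=0.0, seed=rng)
    y = true_intercept + true_slope * x + noise

    templates: dict[str, BodyPlanTemplate] = {}
    if with_templates:
        # every plan dimension is linear in either the torso length L or the
        # body scale s, so total volume is cL*L*s^2 + c3*s^3; solving the
        # cubic for s makes analytic body volume exactly
        # mass / REFERENCE_DENSITY, i.e. volume is a strictly monotone map
        # of assigned mass
        v11 = default_body_plan(1.0, scale=1.0).total_volume()
        v21 = default_body_plan(2.0, scale=1.0).total_volume()
        cL = v21 - v11
        c3 = v11 - cL
        for taxon, lm, lt in zip(tree.taxa, x, y):
            L = 10.0 ** lt
            v_target = 10.0 ** lm / REFERENCE_DENSITY
            roots = np.roots([c3, cL * L, 0.0, -v_target])
            s = float(max(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0))
            templates[taxon] = default_body_plan(torso_length=L, scale=s, name=taxon)
    return SyntheticCohort(
        tree=tree,
        taxa=list(tree.taxa),
        log_mass=x,
        log_trait=y,
        true_slope=true_slope,
        true_intercept=true_intercept,
        sigma2=sigma2,
        seed=seed,
        templates=templates,
    )


def measure_torso_length(manifest: SkeletonManifest) -> float:
    """Anteroposterior extent of the torso hull (pipeline-side trait)."""
    from .hulling import compute_hull

    for seg in manifest.segments:
        if seg.segment_class.name == "torso":
            hull = compute_hull(seg)
            return float(hull.hull_vertices[:, 0].max() - hull.hull_vertices[:, 0].min())
    raise ValueError("manifest has no torso segment")
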