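"""Hull-to-soft-tissue volume expansion.

Minimal skeletal hulls systematically underestimate live body volume;
calibration against extant animals supplies per-segment correction
models.  Two functional forms are supported, both fitted on extant
sauropsids (crocodylian/lepidosaur "NAS" = non-avian sauropsid source,
or bird source):

* allometric: ``V_soft = 10**(a + b * log10(V_hull))`` (power law in
  volume, coefficients from log10-transformed fits),
* isometric: ``V_soft = k * V_hull`` (size-independent average factor).

A third, ``sellers21``, applies the classic whole-body +21% uniform
expansion to every non-exempt segment.

Each model carries a mean absolute percentage prediction error (mPPE)
which is propagated as symmetric multiplicative bounds
``point * (1 -/+ mPPE)``.  Two policy rules modify the raw prediction:

* floor rule — for segment classes whose hulls hug the skeleton tightly
  (by default neck and metatarsus) the hull volume is a hard minimum for
  the predicted soft-tissue volume;
* exemption — ornamental structures, major osteoderms and sails are
  never expanded (dermal envelopes wrap them tightly), so their
  soft-tissue volume equals the hull volume with zero mPPE.

The calibration coefficients themselves are inputs: this package ships
only a clearly labelled placeholder table (see
:func:`placeholder_factor_table`); real analyses must supply the
published extant-sauropsid coefficients via :func:`load_factor_table`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hulling import SegmentHull
from .skeleton_io import SkeletonManifest

__all__ = [
    "ScalingModel",
    "ExpansionPolicy",
    "ExpandedSegmentVolume",
    "ExpansionError",
    "expand_segment",
    "build_model_set",
    "load_factor_table",
    "placeholder_factor_table",
    "MODEL_SET_NAMES",
    "SELLERS_FACTOR",
]

#: uniform whole-hull expansion factor of the minimal-hull mass protocol
SELLERS_FACTOR = 1.21

MODEL_SET_NAMES = (
    "NAS_allometric",
    "NAS_isometric",
    "bird_allometric",
    "bird_isometric",
    "preferred_allometric",
    "preferred_isometric",
    "sellers21",
)

DEFAULT_FLOOR_CLASSES = frozenset({"neck", "metatarsus"})
DEFAULT_EXEMPT_CLASSES = frozenset({"ornament", "osteoderm", "sail"})


class ExpansionError(ValueError):
    """Raised for missing factors or pathological predictions."""


@dataclass(frozen=True)
class ScalingModel:
    """One segment-class expansion rule from one source/mode.

    ``a``/``b`` are the intercept and exponent of the log10-linear
    (power-law) form; ``k`` the multiplicative isometric factor; exactly
    one of the two parameter groups is populated.  ``mppe`` is the mean
    absolute percentage prediction error as a fraction (e.g. 0.52).
    """

    segment_class: str
    source: str  # NAS | bird
    mode: str  # allometric | isometric
    a: float | None = None
    b: float | None = None
    k: float | None = None
    mppe: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in ("NAS", "bird"):
            raise ExpansionError(f"source must be NAS or bird, got {self.source!r}")
        if self.mode == "allometric":
            if self.a is None or self.b is None or self.k is not None:
                raise ExpansionError("allometric model requires a and b (and no k)")
        elif self.mode == "isometric":
            if self.k is None or self.a is not None or self.b is not None:
                raise ExpansionError("isometric model requires k only")
            if self.k <= 0:
                raise ExpansionError("isometric factor k must be > 0")
        else:
            raise ExpansionError(f"mode must be allometric or isometric, got {self.mode!r}")
        if self.mppe < 0:
            raise ExpansionError("mppe must be >= 0")

    def predict(self, hull_volume: float) -> float:
        if hull_volume <= 0:
            raise ExpansionError("hull volume must be > 0")
        if self.mode == "allometric":
            return float(10.0 ** (self.a + self.b * np.log10(hull_volume)))
        return float(self.k * hull_volume)


@dataclass
class ExpansionPolicy:
    """Which model set to use and how the floor/exemption rules apply.

    ``per_segment_overrides`` maps ``(taxon, segment_class)`` to a
    ``(source, mode)`` pair, expressing taxon-by-taxon "preferred"
    model-set choices as data rather than code.
    """

    model_set_name: str = "NAS_isometric"
    per_segment_overrides: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    floor_classes: frozenset[str] = DEFAULT_FLOOR_CLASSES
    exempt_classes: frozenset[str] = DEFAULT_EXEMPT_CLASSES

    def __post_init__(self) -> None:
        if self.model_set_name not in MODEL_SET_NAMES:
            raise ExpansionError(
                f"unknown model set {self.model_set_name!r}; expected one of {MODEL_SET_NAMES}"
            )
        from .skeleton_io import SEGMENT_CLASS_NAMES

        for (taxon, cls), (source, mode) in self.per_segment_overrides.items():
            if cls not in SEGMENT_CLASS_NAMES:
                raise ExpansionError(f"override for unknown segment class {cls!r} ({taxon})")
            if source not in ("NAS", "bird") or mode not in ("allometric", "isometric"):
                raise ExpansionError(f"override ({taxon}, {cls}) has invalid source/mode")

    @property
    def base_source_mode(self) -> tuple[str | None, str | None]:
        """(source, mode) implied by the model-set name; (None, None) for sellers21.

        The "preferred" sets default to NAS factors of the stated mode,
        with overrides supplying the per-taxon deviations.
        """
        name = self.model_set_name
        if name == "sellers21":
            return None, None
        source, mode = name.split("_")
        if source == "preferred":
            source = "NAS"
        return source, mode


@dataclass
class ExpandedSegmentVolume:
    """Predicted soft-tissue volume for one segment, with mPPE bounds."""

    segment_class: str
    side: str
    label: str
    hull_volume: float
    point_volume: float
    lower_volume: float
    upper_volume: float
    floored: bool
    centroid: np.ndarray
    source: str | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lower_volume <= self.point_volume <= self.upper_volume):
            raise ExpansionError(
                f"{self.label}: volume bounds must satisfy 0 < lower <= point <= upper"
            )


def expand_segment(
    hull: SegmentHull,
    model: ScalingModel | None,
    policy: ExpansionPolicy,
) -> ExpandedSegmentVolume:
    """Expand one segment hull to a soft-tissue volume estimate.

    ``model`` may be ``None`` for exempt classes and for the ``sellers21``
    policy (which needs no per-segment model).  The floor rule is applied
    to the point estimate and to both bounds.
    """
    v = hull.hull_volume
    cls = hull.segment_class.name
    if cls in policy.exempt_classes:
        point, mppe, source, mode = v, 0.0, None, None
    elif policy.model_set_name == "sellers21":
        point, mppe, source, mode = SELLERS_FACTOR * v, 0.0, None, "sellers21"
    else:
        if model is None:
            raise ExpansionError(f"segment {hull.label}: no scaling model supplied")
        if model.segment_class != cls:
            raise ExpansionError(
                f"segment {hull.label}: model is for class {model.segment_class!r}"
            )
        point = model.predict(v)
        mppe, source, mode = model.mppe, model.source, model.mode
    if point <= 0 or not np.isfinite(point):
        raise ExpansionError(f"segment {hull.label}: non-positive predicted volume {point}")

    lower = point * (1.0 - mppe)
    upper = point * (1.0 + mppe)
    floored = False
    if cls in policy.floor_classes:
        if point < v:
            floored = True
        point = max(point, v)
        lower = max(lower, v)
        upper = max(upper, v)
    if lower <= 0:
        raise ExpansionError(f"segment {hull.label}: mppe {mppe} >= 1 gives non-positive bound")
    return ExpandedSegmentVolume(
        segment_class=cls,
        side=hull.side,
        label=hull.label,
        hull_volume=v,
        point_volume=point,
        lower_volume=lower,
        upper_volume=upper,
        floored=floored,
        centroid=hull.hull_centroid,
        source=source,
        mode=mode,
    )


def _index_factors(factor_table: list[ScalingModel]) -> dict[tuple[str, str, str], ScalingModel]:
    idx: dict[tuple[str, str, str], ScalingModel] = {}
    for m in factor_table:
        idx[(m.segment_class, m.source, m.mode)] = m
    return idx


def build_model_set(
    hulls: list[SegmentHull],
    policy: ExpansionPolicy,
    factor_table: list[ScalingModel] | None = None,
    manifest: SkeletonManifest | None = None,
    taxon: str | None = None,
) -> list[ExpandedSegmentVolume]:
    """Expand every hull under one model set.

    Rules applied on top of the per-segment expansion:

    * bird-source sets use NAS tail factors (extant bird torso hulls
      contain the reduced tail, so no bird tail calibration exists);
    * a manifest with ``tail_in_torso=True`` gets no separate tail
      expansion: tail segments keep their hull volume (treated as exempt);
    * ``per_segment_overrides`` swap (source, mode) for single
      (taxon, class) pairs, which is how "preferred" sets are expressed.
    """
    if taxon is None and manifest is not None:
        taxon = manifest.taxon
    tail_in_torso = bool(manifest.tail_in_torso) if manifest is not None else False
    base_source, base_mode = policy.base_source_mode
    idx = _index_factors(factor_table or [])

    out: list[ExpandedSegmentVolume] = []
    for hull in hulls:
        cls = hull.segment_class.name
        if cls in policy.exempt_classes or policy.model_set_name == "sellers21":
            out.append(expand_segment(hull, None, policy))
            continue
        if cls == "tail" and tail_in_torso:
            exempt_policy = ExpansionPolicy(
                model_set_name=policy.model_set_name,
                floor_classes=policy.floor_classes,
                exempt_classes=policy.exempt_classes | {"tail"},
            )
            out.append(expand_segment(hull, None, exempt_policy))
            continue
        source, mode = base_source, base_mode
        if taxon is not None and (taxon, cls) in policy.per_segment_overrides:
            source, mode = policy.per_segment_overrides[(taxon, cls)]
        if cls == "tail" and source == "bird":
            source = "NAS"
        model = idx.get((cls, source, mode))
        if model is None:
            raise ExpansionError(
                f"no scaling factor for segment class {cls!r} (source={source}, mode={mode})"
            )
        out.append(expand_segment(hull, model, policy))
    return out


# ---------------------------------------------------------------------------
# factor-table I/O

_FACTOR_COLUMNS = ["segment_class", "source", "mode", "a", "b", "k", "mppe"]


def load_factor_table(path: str | Path) -> list[ScalingModel]:
    """Read a scaling-factor table from CSV or JSON.

    CSV columns: ``segment_class, source, mode, a, b, k, mppe`` (blank
    cells for the parameters the mode does not use).  JSON: a list of
    objects with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        missing = set(_FACTOR_COLUMNS) - set(df.columns)
        if missing:
            raise ExpansionError(f"factor table missing columns {sorted(missing)}")
        rows = df.to_dict(orient="records")

    models = []
    for row in rows:
        kwargs = {
            "segment_class": row["segment_class"],
            "source": row["source"],
            "mode": row["mode"],
            "mppe": float(row.get("mppe", 0.0) or 0.0),
        }
        for key in ("a", "b", "k"):
            val = row.get(key)
            if val is not None and not (isinstance(val, float) and np.isnan(val)):
                kwargs[key] = float(val)
        models.append(ScalingModel(**kwargs))
    return models


def placeholder_factor_table() -> list[ScalingModel]:
    """PLACEHOLDER scaling factors for demonstration and testing only.

    These are NOT the published extant-sauropsid calibration
    coefficients (which must be obtained from the primary calibration
    study and supplied via :func:`load_factor_table`).  The placeholder
    values are merely plausible: modest super-unity isometric factors,
    allometric forms close to isometry, and mPPE magnitudes in the range
    reported for extant-calibrated hull expansions.
    """
    classes = [
        "head", "neck", "torso", "tail",
        "brachium", "antebrachium", "manus",
        "thigh", "shank", "metatarsus", "pes",
    ]
    iso_k = {"NAS": 1.6, "bird": 1.3}
    iso_mppe = {"NAS": 0.30, "bird": 0.25}
    allo_b = {"NAS": 1.02, "bird": 0.98}
    allo_mppe = {"NAS": 0.35, "bird": 0.30}
    models: list[ScalingModel] = []
    for cls in classes:
        for source in ("NAS", "bird"):
            models.append(
                ScalingModel(cls, source, "isometric", k=iso_k[source], mppe=iso_mppe[source])
            )
            models.append(
                ScalingModel(
                    cls,
                    source,
                    "allometric",
                    a=float(np.log10(iso_k[source])),
                    b=allo_b[source],
                    mppe=allo_mppe[source],
                )
            )
    return models
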