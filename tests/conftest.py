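import numpy as np
import pytest

from hullmass import (
    DENSITY_PRESETS,
    ExpansionPolicy,
    build_model_set,
    compute_body,
    hull_all,
    placeholder_factor_table,
)
from hullmass.expansion import ExpandedSegmentVolume
from hullmass.mass_model import SegmentMassProps, assemble_body
from hullmass.synthetic_data import default_body_plan, generate_skeleton


@pytest.fixture(scope="session")
def box_skeleton():
    """Default synthetic biped (all-box primitives) with analytic truth."""
    manifest, truth = generate_skeleton(default_body_plan(1.2))
    return manifest, truth


@pytest.fixture(scope="session")
def factor_table():
    return placeholder_factor_table()


@pytest.fixture(scope="session")
def box_body(box_skeleton, factor_table):
    """Whole-body mass properties of the default synthetic skeleton."""
    manifest, _ = box_skeleton
    policy = ExpansionPolicy(model_set_name="NAS_isometric")
    volumes = build_model_set(hull_all(manifest), policy, factor_table, manifest)
    body = compute_body(
        volumes,
        DENSITY_PRESETS["primary_heterogeneous"],
        manifest,
        model_set_name="NAS_isometric",
    )
    return manifest, volumes, body


def make_volume(cls="torso", point=1.0, lower=None, upper=None, hull=None,
                centroid=(0.0, 0.0, 0.0), side="midline", label=None):
    """Hand-built expanded segment volume for mass-model unit tests."""
    return ExpandedSegmentVolume(
        segment_class=cls,
        side=side,
        label=label or cls,
        hull_volume=hull if hull is not None else point,
        point_volume=point,
        lower_volume=lower if lower is not None else point,
        upper_volume=upper if upper is not None else point,
        floored=False,
        centroid=np.asarray(centroid, dtype=float),
    )


def make_point_mass(label, mass, com, cls="torso", side="midline"):
    return SegmentMassProps(
        segment_class=cls,
        side=side,
        label=label,
        mass=mass,
        com=np.asarray(com, dtype=float),
        mass_lower=mass,
        mass_upper=mass,
        volume=mass / 1000.0,
    )


def make_body(point_masses, taxon="test"):
    return assemble_body(point_masses, taxon=taxon)
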