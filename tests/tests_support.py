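"""Shared helpers for the test suite."""

from macn.synthetic_data import SceneSpec


def small_template() -> SceneSpec:
    """128x128 scene spec with down-scaled structures (fast test geometry)."""
    return SceneSpec(
        image_size=(128, 128),
        n_ducts=2,
        duct_inner_radius_range=(4.0, 8.0),
        duct_wall_thickness_range=(3.0, 5.0),
        n_arteries=1,
        artery_inner_radius_range=(8.0, 12.0),
        artery_wall_thickness_range=(5.0, 8.0),
    )
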