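import dataclasses

import pytest

from sinusvol.phantom import CavitySpec, PhantomSpec, VariationRanges, generate_phantom
from sinusvol.segmentation import segment_exam


def small_spec(**overrides) -> PhantomSpec:
    """A fast 40x128x128 phantom with both sinuses and the midline decoy.

    Cavities span slices 8..32 (z = 10 ± 6 mm at 0.5 mm spacing).
    """
    base = PhantomSpec(
        grid_shape=(40, 128, 128),
        spacing_mm=(0.5, 0.35, 0.35),
        right=CavitySpec(center_mm=(10.0, 22.225, 9.0), semi_axes_mm=(6.0, 8.0, 5.0)),
        left=CavitySpec(center_mm=(10.0, 22.225, 35.45), semi_axes_mm=(6.0, 8.0, 5.0)),
        rng_seed=7,
    )
    return dataclasses.replace(base, **overrides)


def small_ranges(**overrides) -> VariationRanges:
    """Anatomical variation scaled down to fit the small phantom grid."""
    base = VariationRanges(
        semi_axis_z_mm=(5.0, 6.0),
        semi_axis_y_mm=(7.0, 8.0),
        semi_axis_x_mm=(4.5, 5.0),
        center_jitter_mm=0.5,
        mucosa_thickness_mm=(0.5, 1.0),
        fluid_fill_fraction=(0.0, 0.2),
    )
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_segmentation(small_phantom):
    volume, _ = small_phantom
    return segment_exam(volume)
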