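import numpy as np
import pandas as pd
import pytest

from retphen import synthetic_data as sd


@pytest.fixture
def straight_vessel_spec():
    """Factory: horizontal vessel through the image center.

    The centerline sits on a half-integer row so a rectangular profile of
    even pixel width covers whole pixels exactly.
    """

    def make(
        width_um=30.0,
        scale=2.0,
        profile="rectangular",
        noise_sd=0.0,
        size=200,
        peak=80.0,
        seed=0,
        angle_deg=0.0,
        background=100.0,
        gradient=0.0,
    ):
        c = (size - 1) / 2.0
        a = np.deg2rad(angle_deg)
        d = np.array([np.cos(a), np.sin(a)])
        half = size * 0.4
        if angle_deg == 0.0:
            p0, p1 = np.array([c - half, c + 0.5]), np.array([c + half, c + 0.5])
        else:
            p0, p1 = np.array([c, c]) - half * d, np.array([c, c]) + half * d
        return sd.SyntheticVesselSpec(
            image_size=(size, size),
            pixel_scale_um_per_px=scale,
            vessels=[
                sd.SyntheticVessel(
                    points_px=np.array([p0, p1]),
                    true_width_um=width_um,
                    peak_brightness=peak,
                    profile_shape=profile,
                )
            ],
            background_level=background,
            background_gradient=gradient,
            noise_sd=noise_sd,
            reference_circle_diameter_um=size * 0.7 * scale,
            seed=seed,
        )

    return make


def write_synthetic_cohort(root, widen_genotype_b=1.0, n_per_group=2, seed0=100):
    """Synthetic 2-genotype vessel + OCT cohort; returns the manifest path."""
    rows = []
    k = 0
    phase_rng = np.random.default_rng(seed0)
    for genotype, factor in (("A", 1.0), ("B", widen_genotype_b)):
        for i in range(n_per_group):
            animal = f"{genotype}{i}"
            for retina in ("L", "R"):
                # random subpixel placement, as for real vessels
                yv = 80.0 + phase_rng.uniform(-0.5, 0.5)
                ya = 45.0 + phase_rng.uniform(-0.5, 0.5)
                spec = sd.SyntheticVesselSpec(
                    image_size=(160, 160),
                    pixel_scale_um_per_px=2.0,
                    vessels=[
                        sd.SyntheticVessel(
                            points_px=np.array([[15.0, yv], [144.0, yv]]),
                            true_width_um=20.0 * factor,
                            vessel_class="venule",
                        ),
                        sd.SyntheticVessel(
                            points_px=np.array([[15.0, ya], [144.0, ya]]),
                            true_width_um=14.0,
                            vessel_class="arteriole",
                        ),
                    ],
                    noise_sd=2.0,
                    reference_circle_diameter_um=220.0,
                    seed=seed0 + k,
                )
                k += 1
                d = root / "data" / f"{animal}_{retina}"
                path = sd.write_vessel_dataset(spec, d)
                rows.append(
                    dict(
                        animal_id=animal,
                        genotype=genotype,
                        age_group="P6",
                        modality="vessel",
                        path=str(path.relative_to(root)),
                        eye_or_retina=retina,
                    )
                )
            boundaries, _ = sd.generate_oct_boundaries(sd.random_oct_spec(seed0 + k))
            k += 1
            oct_path = root / "data" / f"{animal}_oct.json"
            sd.write_oct_json(boundaries, oct_path)
            rows.append(
                dict(
                    animal_id=animal,
                    genotype=genotype,
                    age_group="P6",
                    modality="oct",
                    path=str(oct_path.relative_to(root)),
                    eye_or_retina="OD",
                )
            )
    manifest = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


@pytest.fixture
def cohort_writer():
    return write_synthetic_cohort


@pytest.fixture
def erg_spec():
    """Factory for the synthetic flash-response spec."""

    def make(**overrides):
        return sd.SyntheticErgSpec(**overrides)

    return make
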