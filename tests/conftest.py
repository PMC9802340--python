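import numpy as np
import pytest

import biofilm_mech as bm


@pytest.fixture(scope="session")
def clean_colony():
    """Noiseless expanding colony: 0.3 mm/h (5 µm/min), 10-min frames."""
    scen = bm.ColonyScenario(initial_radius=300.0, radial_speed=5.0,
                             noise_sd=0.0, n_frames=5, seed=11)
    stack, truth = bm.generate_colony_stack(scen)
    return scen, stack, truth


@pytest.fixture(scope="session")
def noisy_colony():
    """Expanding colony with boundary roughness and 4%-of-contrast noise."""
    scen = bm.ColonyScenario(initial_radius=300.0, radial_speed=5.0,
                             boundary_roughness_amplitude=5.0,
                             boundary_roughness_wavenumber=8,
                             noise_sd=800.0, n_frames=5, seed=12)
    stack, truth = bm.generate_colony_stack(scen)
    return scen, stack, truth


@pytest.fixture(scope="session")
def static_bead_frame():
    """One noiseless bead frame on a 288×288 canvas, for shift oracles."""
    beads = bm.BeadScenario(seed=5, noise_sd=0.0, image_shape=(288, 288))
    stack, _ = bm.generate_bead_stack(beads, bm.DisplacementModel(), 2)
    return stack[0].astype(float)


@pytest.fixture(scope="session")
def drift_bead_stack():
    """3-frame bead stack advected by pure stage drift (1.5, −0.7) µm/frame."""
    model = bm.DisplacementModel(drift_per_frame=(1.5, -0.7))
    beads = bm.BeadScenario(seed=3)
    stack, truth = bm.generate_bead_stack(beads, model, 3)
    return stack, truth, model


@pytest.fixture(scope="session")
def contractile_bead_stack():
    """Bead stack with an accumulating contractile inward displacement."""
    model = bm.DisplacementModel(contractile_amplitude=0.8,
                                 contractile_center=(204.8, 204.8),
                                 contractile_length_scale=150.0)
    beads = bm.BeadScenario(seed=9)
    stack, truth = bm.generate_bead_stack(beads, model, 4)
    return stack, truth, model


def grid_displacement_field(model, spacing=5.0, extent=512.0, frame=1):
    """Sample a displacement model on a regular grid as a DisplacementField."""
    g = np.arange(spacing / 2, extent, spacing)
    X, Y = np.meshgrid(g, g)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    u = bm.evaluate_displacement_model(model, pts, frame).reshape(len(g), len(g), 2)
    return bm.DisplacementField(
        x=g, y=g, u=u[..., 0], v=u[..., 1],
        quality=np.full(X.shape, np.inf), mask=np.ones(X.shape, dtype=bool),
        frame=frame,
    )
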