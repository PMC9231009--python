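import numpy as np
import pytest

from toxmem import synthetic as syn


@pytest.fixture(scope="session")
def snx482():
    return syn.load_snx482_fixture()


@pytest.fixture(scope="session")
def flat_bilayer():
    """20-frame bilayer with zero head roughness (exactly planar leaflets)."""
    return syn.make_bilayer(
        syn.BilayerSpec(head_roughness_sigma=0.0, n_frames=20, frame_dt=1.0, seed=7)
    )


@pytest.fixture(scope="session")
def rough_bilayer():
    return syn.make_bilayer(
        syn.BilayerSpec(head_roughness_sigma=0.05, n_frames=60, frame_dt=1.0, seed=8)
    )


@pytest.fixture()
def patch_scenario(snx482):
    """Hydrophobic patch inserted at −0.3 nm, everything else at +0.5 nm."""
    depths = np.full(snx482.n_residues, 0.5)
    for r in snx482.hydrophobic_patch:
        depths[r - 1] = -0.3
    return syn.BindingScenario(target_depths=depths, onset_frame=5, depth_noise_sigma=0.0, seed=3)


@pytest.fixture()
def patch_trajectory(flat_bilayer, patch_scenario, snx482):
    return syn.make_binding_trajectory(flat_bilayer, patch_scenario, snx482)
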