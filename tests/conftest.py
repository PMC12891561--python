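import numpy as np
import pytest

from ctmorph import simgen


@pytest.fixture(scope="session")
def small_noisy_field():
    """A 12-nucleus noisy field with truth, shared across tests (read-only)."""
    cfg = simgen.SimulationConfig(
        field_shape=(24, 240, 240), voxel_size=(0.3, 0.15, 0.15),
        n_nuclei=12, nucleus_radius_um=1.5, channel_names=("dna", "chr2"),
        territory_volume_fraction=0.03, pairing_fraction=0.5,
        read_noise_sd=2.0, seed=7)
    field, truth_labels, truth = simgen.generate_field(cfg)
    return cfg, field, truth_labels, truth


@pytest.fixture()
def ball_mask():
    """Digital ball of radius 2 µm on a 0.1 µm isotropic grid."""
    vs = (0.1, 0.1, 0.1)
    mask = simgen.render_blob((3.0, 3.0, 3.0), (2.0, 2.0, 2.0), 0.0,
                              (61, 61, 61), vs, seed=0)
    return mask, vs


def match_nuclei_to_truth(records, truth_nuclei):
    """Greedy nearest-centroid matching; returns list of (record, truth row, µm error)."""
    out = []
    centers = truth_nuclei[["center_z_um", "center_y_um",
                            "center_x_um"]].to_numpy()
    for r in records:
        d = np.linalg.norm(centers - np.asarray(r.centroid_um), axis=1)
        i = int(np.argmin(d))
        out.append((r, truth_nuclei.iloc[i], float(d[i])))
    return out
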