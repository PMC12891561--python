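"""Canonical validation protocols: fixed study conditions for self-checks.

These configurations define the synthetic study conditions under which the
pipeline validates itself: field geometry, nucleus sizes, spot volume
fractions, optics and noise are fixed here once and reused by the test suite
and the reproduction script alike.  Nuclei are rendered at confocal-like
anisotropy (0.3 µm z step, 0.15 µm xy pixels); FISH spots carry 3% of the
nuclear volume split across homologs, so paired spots merge below the 0.8 µm
threshold while unpaired spots (≥1.2 µm apart) stay resolvable; photon noise
at 200 photons per unit intensity gives an SNR of ~14.
"""

from __future__ import annotations

from .simgen import SimulationConfig

#: Confocal-like anisotropic voxel, µm (z, y, x).
VOXEL_SIZE = (0.3, 0.15, 0.15)


def segmentation_recovery_config(seed: int = 0, n_nuclei: int = 50,
                                 pairing_fraction: float = 0.5) -> SimulationConfig:
    """A 50-nucleus non-touching field for segmentation recovery checks."""
    return SimulationConfig(
        field_shape=(24, 420, 420), voxel_size=VOXEL_SIZE,
        n_nuclei=n_nuclei, nucleus_radius_um=1.5,
        channel_names=("dna", "chr2"), territory_volume_fraction=0.03,
        pairing_fraction=pairing_fraction, read_noise_sd=2.0, seed=seed)


def pairing_recovery_config(pairing_fraction: float, seed: int,
                            n_nuclei: int = 300) -> SimulationConfig:
    """A 300-nucleus replicate field for pairing-fraction recovery checks."""
    return SimulationConfig(
        field_shape=(18, 660, 660), voxel_size=VOXEL_SIZE,
        n_nuclei=n_nuclei, nucleus_radius_um=1.4,
        channel_names=("dna", "chr2"), territory_volume_fraction=0.03,
        pairing_fraction=pairing_fraction, read_noise_sd=2.0, seed=seed)


def demo_pipeline_config(outdir, seed: int = 0, n_nuclei: int = 40,
                         n_replicates: int = 3):
    """A small but complete pipeline run (3 replicates) for demos and tests."""
    from .pipeline import PipelineConfig

    sim = SimulationConfig(
        field_shape=(20, 300, 300), voxel_size=VOXEL_SIZE,
        n_nuclei=n_nuclei, nucleus_radius_um=1.5,
        channel_names=("dna", "chr2"), territory_volume_fraction=0.03,
        pairing_fraction=0.8, read_noise_sd=2.0)
    return PipelineConfig(
        simulation=sim, n_replicates=n_replicates, output_dir=str(outdir),
        seed=seed, min_nuclei=90, min_replicates=3)
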