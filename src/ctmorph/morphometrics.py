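"""Per-object morphometrics: volume, sphericity, overlap, focus-aware intensity.

Volume is always the exact voxel count times the physical voxel volume.
Sphericity, pi^(1/3) (6 V)^(2/3) / A, is evaluated on a marching-cubes surface
mesh of the (lightly smoothed) mask with the physical voxel spacing passed to
the mesher, using the mesh-enclosed volume together with the mesh area.  Using
the mesh for both numerator and denominator keeps the statistic internally
consistent: a digital ball scores ~1 at any resolution, and the value is
insensitive to the sub-voxel shrink that smoothing introduces at small radii.
The voxel-count volume and the mesh volume agree to a few percent for objects
more than a few voxels across.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import marching_cubes, mesh_surface_area

from .core import CONNECTIVITY, LabelVolume, validate_voxel_size


@dataclass
class RegionMetrics:
    """Measurements for one connected voxel region."""

    volume_um3: float
    surface_area_um2: float
    sphericity: float
    centroid_um: tuple[float, float, float]
    mean_intensity: float | None = None
    normalized_volume: float | None = None
    nucleus_id: int | None = None
    channel: str | None = None
    component_id: int | None = None


@dataclass
class OverlapRecord:
    """Territory intermixing between two channels within one nucleus."""

    nucleus_id: int | None
    channel_a: str
    channel_b: str
    overlap_of_a_pct: float
    overlap_of_b_pct: float
    intersection_volume_um3: float
    defined: bool = True


def _mesh_measures(mask: np.ndarray, voxel_size, smoothing_sigma_vox=0.6):
    """(mesh area µm², mesh volume µm³) for a connected boolean mask.

    Small masks (where smoothing would erase the 0.5 level set) fall back to
    the unsmoothed mask; sub-voxel meshes are handled by the caller.
    """
    pad = max(2, int(np.ceil(2 * smoothing_sigma_vox)) + 1)
    vol = np.pad(mask, pad).astype(np.float32)
    if smoothing_sigma_vox > 0:
        sm = ndi.gaussian_filter(vol, smoothing_sigma_vox)
        if sm.max() > 0.5:
            vol = sm
    verts, faces, _, _ = marching_cubes(vol, level=0.5, spacing=voxel_size)
    area = float(mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_vol = float(abs(np.einsum(
        "ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))
    return area, mesh_vol


def measure_region(mask, voxel_size, intensity=None, *,
                   smoothing_sigma_vox=0.6) -> RegionMetrics:
    """Measure one connected voxel region.

    Raises on an empty or disconnected mask (the caller is expected to pass
    single connected components).
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    voxel_size = validate_voxel_size(voxel_size)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty region")
    if cc_label(mask, connectivity=CONNECTIVITY).max() > 1:
        raise ValueError("mask is disconnected; measure components separately")

    voxvol = float(np.prod(voxel_size))
    volume = count * voxvol
    idx = np.nonzero(mask)
    centroid = tuple(float(np.mean(ax)) * v for ax, v in zip(idx, voxel_size))

    # crop to the bounding box to keep meshing cheap
    sl = tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in idx)
    area, mesh_vol = _mesh_measures(mask[sl], voxel_size, smoothing_sigma_vox)
    if mesh_vol <= 0 or area <= 0:
        sphericity = float("nan")
    else:
        sphericity = float(
            np.pi ** (1 / 3) * (6.0 * mesh_vol) ** (2 / 3) / area)

    mean_int = None
    if intensity is not None:
        intensity = np.asarray(intensity)
        if intensity.shape != mask.shape:
            raise ValueError("intensity grid does not match mask")
        mean_int = float(intensity[mask].mean())
    return RegionMetrics(volume_um3=volume, surface_area_um2=area,
                         sphericity=sphericity, centroid_um=centroid,
                         mean_intensity=mean_int)


def normalized_volume(object_volume_um3: float,
                      nuclear_volume_um3: float) -> float:
    """Object volume as a fraction of its host nuclear volume.

    For paired-versus-unpaired comparisons the unpaired side should pass the
    *combined* volume of the two homolog signals before normalization.
    """
    if nuclear_volume_um3 <= 0:
        raise ValueError("nuclear volume must be positive")
    if object_volume_um3 < 0:
        raise ValueError("object volume must be nonnegative")
    ratio = object_volume_um3 / nuclear_volume_um3
    if ratio > 1:
        warnings.warn(
            f"normalized volume {ratio:.3f} > 1: object larger than nucleus "
            "(segmentation pathology?)", stacklevel=2)
    return ratio


def overlap_percent(mask_a, mask_b, voxel_size, *, nucleus_id=None,
                    channel_a="a", channel_b="b") -> OverlapRecord:
    """Voxelwise intermixing of two territory masks.

    ``overlap_of_a_pct`` is 100 × |A∩B| / |A| (and symmetrically for b), the
    intersection expressed as a percent of each territory's own volume.  When
    either channel has no voxels the record is returned with ``defined=False``
    and NaN percentages.
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a grid")
    voxel_size = validate_voxel_size(voxel_size)
    voxvol = float(np.prod(voxel_size))
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    ninter = int(np.count_nonzero(mask_a & mask_b))
    if na == 0 or nb == 0:
        return OverlapRecord(nucleus_id, channel_a, channel_b,
                             float("nan"), float("nan"),
                             ninter * voxvol, defined=False)
    return OverlapRecord(
        nucleus_id, channel_a, channel_b,
        100.0 * ninter / na, 100.0 * ninter / nb, ninter * voxvol)


def intensity_excluding_foci(channel, nucleus_mask, voxel_size, *, k_foci,
                             focus_min_volume_um3=0.0, threshold=None,
                             quantile=None):
    """Mean nuclear intensity with the ``k_foci`` brightest bodies removed.

    Detects bright connected components inside ``nucleus_mask`` (Otsu on the
    within-nucleus intensities by default; a fixed ``threshold`` or a
    ``quantile`` in (0, 1) may be supplied instead), keeps the ``k_foci``
    largest ones at least ``focus_min_volume_um3`` big, and returns
    ``(mean_outside_foci, [RegionMetrics for each focus])``.  Typical use:
    two histone-locus bodies per diploid nucleus, one per haploid nucleus.

    If fewer than ``k_foci`` qualifying components exist, those found are
    returned without error.
    """
    channel = np.asarray(channel)
    nucleus_mask = np.asarray(nucleus_mask, bool)
    if channel.shape != nucleus_mask.shape:
        raise ValueError("channel and nucleus mask must share a grid")
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    if k_foci < 0:
        raise ValueError("k_foci must be >= 0")
    voxel_size = validate_voxel_size(voxel_size)

    vals = channel[nucleus_mask]
    if k_foci == 0 or vals.max() <= vals.min():
        return float(vals.mean()), []

    if threshold is not None:
        thr = float(threshold)
    elif quantile is not None:
        thr = float(np.quantile(vals, quantile))
    else:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(vals))
    bright = nucleus_mask & (channel > thr)
    comp = cc_label(bright, connectivity=CONNECTIVITY)
    voxvol = float(np.prod(voxel_size))
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1]
    foci_metrics = []
    foci_mask = np.zeros(channel.shape, bool)
    for comp_id in order:
        if len(foci_metrics) >= k_foci or sizes[comp_id] == 0:
            break
        if sizes[comp_id] * voxvol < focus_min_volume_um3:
            continue
        m = comp == comp_id
        metrics = measure_region(m, voxel_size, intensity=channel)
        foci_metrics.append(metrics)
        foci_mask |= m
    outside = nucleus_mask & ~foci_mask
    mean_outside = float(channel[outside].mean()) if outside.any() else float("nan")
    return mean_outside, foci_metrics


def measure_labels(labels: LabelVolume, *, intensity=None, channel=None,
                   nuclear_volumes=None, nucleus_of=None,
                   smoothing_sigma_vox=0.6):
    """Measure every labelled component of a LabelVolume.

    ``nucleus_of`` maps component label -> nucleus id, and
    ``nuclear_volumes`` maps nucleus id -> µm³ for normalized volumes.
    Returns a list of RegionMetrics.
    """
    out = []
    objects = ndi.find_objects(labels.labels)
    for comp_id, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        m = np.zeros(labels.labels.shape, bool)
        m[sl] = labels.labels[sl] == comp_id
        metrics = measure_region(m, labels.voxel_size, intensity=intensity,
                                 smoothing_sigma_vox=smoothing_sigma_vox)
        metrics.component_id = comp_id
        metrics.channel = channel
        if nucleus_of is not None:
            metrics.nucleus_id = nucleus_of.get(comp_id)
            if nuclear_volumes is not None and metrics.nucleus_id in nuclear_volumes:
                metrics.normalized_volume = normalized_volume(
                    metrics.volume_um3, nuclear_volumes[metrics.nucleus_id])
        out.append(metrics)
    return out
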