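"""Reading and writing standard formats: OME-TIFF stacks, label TIFFs, CSV, YAML.

Voxel size precedence when reading: an explicit override always wins, then
OME metadata (PhysicalSize{Z,Y,X}); a stack with neither is an error — the
pipeline never silently assumes isotropy.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import ImageField, LabelVolume


def write_field(field: ImageField, path) -> None:
    """Write a multichannel field as OME-TIFF (CZYX) with voxel size metadata."""
    vz, vy, vx = field.voxel_size
    tifffile.imwrite(
        str(path), field.data.astype(np.float32), ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": vy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": vx, "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(field.channel_names)},
        })


def _ome_voxel_size(ome_xml: str):
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None
    try:
        vs = tuple(float(pixels.attrib[f"PhysicalSize{ax}"])
                   for ax in ("Z", "Y", "X"))
    except KeyError:
        vs = None
    names = [ch.attrib.get("Name") for ch in pixels.findall("ome:Channel", ns)]
    names = [n for n in names if n] or None
    return vs, names


def read_field(path, voxel_size=None, channel_names=None) -> ImageField:
    """Read a (OME-)TIFF stack into an ImageField.

    Accepts CZYX or ZYX (promoted to one channel) stacks.  ``voxel_size``
    overrides any metadata; without metadata it is required.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta_vs = meta_names = None
        if tf.ome_metadata:
            meta_vs, meta_names = _ome_voxel_size(tf.ome_metadata)
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected a 3D or 4D stack, got shape {data.shape}")
    vs = voxel_size if voxel_size is not None else meta_vs
    if vs is None:
        raise ValueError(
            f"{path}: no voxel size in metadata; pass voxel_size=(z, y, x) µm")
    names = channel_names if channel_names is not None else meta_names
    return ImageField(data, vs, tuple(names) if names else ())


def write_labels(labels: LabelVolume, path) -> None:
    """Write a label volume as a plain multi-page TIFF (int32)."""
    tifffile.imwrite(str(path), labels.labels.astype(np.int32))


def read_labels(path, voxel_size) -> LabelVolume:
    return LabelVolume(tifffile.imread(str(path)).astype(np.int32), voxel_size)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
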