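"""Image and annotation I/O.

The package exchanges images as OME-TIFF (one 8-bit plane per channel,
physical calibration in micrometres), regions as GeoJSON FeatureCollections
with coordinates in micrometres, and tables as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

DEFAULT_CHANNELS = ("DAPI", "INS", "CD68", "HLAII")


@dataclass
class ChannelStack:
    """A pixel-registered multi-channel 2-D image with physical calibration.

    Attributes
    ----------
    channels
        Mapping from channel name to a 2-D ``uint8`` array. All channels
        share one shape.
    pixel_size_um
        Side length of a pixel in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name, arr in self.channels.items():
            if arr.dtype != np.uint8:
                raise ValueError(f"channel {name!r} must be uint8, got {arr.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_ome_tiff(stack: ChannelStack, path) -> None:
    """Write a :class:`ChannelStack` as a calibrated OME-TIFF (axes CYX)."""
    data = np.stack([stack.channels[c] for c in stack.channel_names])
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        datetime=False,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": stack.channel_names},
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_ome_tiff(path) -> ChannelStack:
    """Read an OME-TIFF written by :func:`write_ome_tiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.ome_metadata
    import xml.etree.ElementTree as ET

    root = ET.fromstring(meta)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    px = float(pixels.get("PhysicalSizeX", "1.0"))
    names = [c.get("Name") or f"ch{i}" for i, c in enumerate(pixels.findall("ome:Channel", ns))]
    if data.ndim == 2:
        data = data[None]
    channels = {name: np.asarray(plane, dtype=np.uint8) for name, plane in zip(names, data)}
    return ChannelStack(channels=channels, pixel_size_um=px)


def geometry_to_feature(geom: BaseGeometry, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def write_geojson(features: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> list[tuple[BaseGeometry, dict]]:
    """Read a FeatureCollection, returning (geometry, properties) pairs.

    Coordinates are taken verbatim (the package convention is micrometres).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in doc["features"]:
        out.append((shape(feat["geometry"]), feat.get("properties") or {}))
    return out
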