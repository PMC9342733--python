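"""Single-band GeoTIFF I/O for WGS84 abiotic layers, built on tifffile.

Georeferencing uses the standard GeoTIFF tags: ModelPixelScale (33550),
ModelTiepoint (33922) anchored at the raster's upper-left corner, a minimal
GeoKeyDirectory (34735) declaring a geographic EPSG:4326 model, and the GDAL
nodata convention (ASCII tag 42113). Rasters without these tags, or declaring
any other CRS, are rejected rather than reprojected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import FormatError

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024     # 2 = geographic lat/lon
_KEY_RASTER_TYPE = 1025    # 1 = pixel-is-area
_KEY_GEOGRAPHIC_CRS = 2048  # 4326 = WGS84


@dataclass
class AbioticLayer:
    """A single abiotic variable on a regular WGS84 pixel grid (north-up).

    ``values[0, 0]`` is the north-west pixel. Pixel centres are offset half a
    pixel inward from the declared corner ``(lon_min, lat_max)``.
    """

    variable_id: str
    values: np.ndarray          # 2-D, row 0 = northernmost
    lon_min: float              # west edge of the west column
    lat_max: float              # north edge of the north row
    pixel_deg: float
    nodata: float | None = None
    crs_epsg: int = field(default=4326)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("layer values must be a 2-D single-band array")

    @property
    def lon_centres(self) -> np.ndarray:
        n = self.values.shape[1]
        return self.lon_min + (np.arange(n) + 0.5) * self.pixel_deg

    @property
    def lat_centres(self) -> np.ndarray:
        n = self.values.shape[0]
        return self.lat_max - (np.arange(n) + 0.5) * self.pixel_deg

    def sample(self, lon: float, lat: float) -> float:
        """Value of the pixel containing the point; NaN outside coverage or nodata."""
        j = int(np.floor((lon - self.lon_min) / self.pixel_deg))
        i = int(np.floor((self.lat_max - lat) / self.pixel_deg))
        if not (0 <= i < self.values.shape[0] and 0 <= j < self.values.shape[1]):
            return float("nan")
        v = float(self.values[i, j])
        if self.nodata is not None and v == self.nodata:
            return float("nan")
        return v


def write_geotiff(layer: AbioticLayer, path: str | Path) -> None:
    """Write a layer as a single-band float32 GeoTIFF with WGS84 geokeys."""
    geo_keys = [
        1, 1, 0, 3,  # version, revision, minor, number of keys
        _KEY_MODEL_TYPE, 0, 1, 2,
        _KEY_RASTER_TYPE, 0, 1, 1,
        _KEY_GEOGRAPHIC_CRS, 0, 1, layer.crs_epsg,
    ]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (layer.pixel_deg, layer.pixel_deg, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, layer.lon_min, layer.lat_max, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geo_keys), tuple(geo_keys)),
    ]
    if layer.nodata is not None:
        nd = repr(float(layer.nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    tifffile.imwrite(str(path), layer.values.astype(np.float32), extratags=extratags)


def read_geotiff(path: str | Path, variable_id: str | None = None) -> AbioticLayer:
    """Read a single-band WGS84 GeoTIFF into an :class:`AbioticLayer`.

    Raises
    ------
    FormatError
        If the file lacks georeferencing tags or declares a non-WGS84 CRS.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise FormatError(f"{path.name}: expected a single-band raster")
        tags = {t.code: t.value for t in page.tags.values()}

    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise FormatError(f"{path.name}: missing GeoTIFF georeferencing tags")
    scale = tags[_TAG_PIXEL_SCALE]
    tiepoint = tags[_TAG_TIEPOINT]
    if abs(scale[0] - scale[1]) > 1e-9:
        raise FormatError(f"{path.name}: non-square pixels are not supported")

    epsg = None
    if _TAG_GEO_KEYS in tags:
        keys = list(tags[_TAG_GEO_KEYS])
        for k in range(4, len(keys), 4):
            if keys[k] == _KEY_GEOGRAPHIC_CRS:
                epsg = keys[k + 3]
    if epsg is None:
        raise FormatError(f"{path.name}: no geographic CRS geokey found")
    if epsg != 4326:
        raise FormatError(f"{path.name}: CRS EPSG:{epsg} is not WGS84; reprojection is out of scope")

    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            nodata = None

    # Tiepoint maps raster (col, row) = (tiepoint[0], tiepoint[1]) to model
    # (lon, lat) = (tiepoint[3], tiepoint[4]); shift back to the (0, 0) corner.
    lon_min = tiepoint[3] - tiepoint[0] * scale[0]
    lat_max = tiepoint[4] + tiepoint[1] * scale[1]
    return AbioticLayer(
        variable_id=variable_id or path.stem,
        values=values,
        lon_min=lon_min,
        lat_max=lat_max,
        pixel_deg=float(scale[0]),
        nodata=nodata,
        crs_epsg=int(epsg),
    )
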