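"""Shared test helpers."""

import numpy as np

from aquaniche.raster import AbioticLayer


def make_layer(variable_id, fn, grid, pixel_arcmin=10, nodata=-9999.0):
    """Layer over the grid extent whose pixel values are fn(lon, lat)."""
    px = pixel_arcmin / 60.0
    ncols = int(round((grid.lon_max - grid.lon_min) / px))
    nrows = int(round((grid.lat_max - grid.lat_min) / px))
    lon = grid.lon_min + (np.arange(ncols) + 0.5) * px
    lat = grid.lat_max - (np.arange(nrows) + 0.5) * px
    lon_g, lat_g = np.meshgrid(lon, lat)
    return AbioticLayer(
        variable_id=variable_id,
        values=fn(lon_g, lat_g),
        lon_min=grid.lon_min,
        lat_max=grid.lat_max,
        pixel_deg=px,
        nodata=nodata,
    )
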