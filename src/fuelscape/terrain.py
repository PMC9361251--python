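"""Topographic metrics from a digital terrain model.

Slope/aspect use the Horn 3x3 finite-difference gradient; curvatures follow
the Zevenbergen-Thorne quadratic surface fit; the heat-load index is the
McCune-Keon formulation with aspect folded about the NE-SW (225 deg) axis;
TPI is center minus neighborhood mean and TRI the root-mean-square
deviation of neighbors from the center (Wilson).  Aspect is degrees
clockwise from north of the downslope direction; flat cells carry the
sentinel NaN aspect, which the derived transforms replace with neutral
values (TRASP 0.5, SCOSA/SSINA 0).

Edge cells are computed on an edge-replicated pad and flagged in the
``edge`` mask layer rather than dropped.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from .grids import GridSpec

FLAT_ASPECT = np.nan


def _horn_gradients(elev: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn-weighted dz/dx (east+) and dz/dy (north+) on an edge-padded grid."""
    z = np.pad(elev, 1, mode="edge")
    c = z[1:-1, 1:-1]  # noqa: F841  (kept for readability of the stencil)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell)  # row 0 is north
    return dzdx, dzdy


def slope_aspect(spec: GridSpec, elev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees clockwise from north, downslope).

    Flat cells (zero gradient) get slope 0 and NaN aspect.
    """
    elev = np.asarray(elev, float)
    if elev.shape[0] < 3 or elev.shape[1] < 3:
        raise ValueError("DTM must be at least 3x3")
    dzdx, dzdy = _horn_gradients(elev, spec.cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope vector is -grad; azimuth measured clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(slope == 0, FLAT_ASPECT, aspect)
    return slope, aspect


def curvatures(spec: GridSpec, elev: np.ndarray) -> dict[str, np.ndarray]:
    """Plan, profile, and total curvature from the 3x3 quadratic surface.

    Coefficient convention (cell size L, window z1..z9 row-major from NW):
    D = [(zW+zE)/2 - zC]/L^2, E = [(zN+zS)/2 - zC]/L^2,
    F = (-zNW + zNE + zSW - zSE)/(4 L^2), G = (-zW+zE)/(2L), H = (zN-zS)/(2L).
    plan = 2(DH^2 + EG^2 - FGH)/(G^2+H^2),
    profile = -2(DG^2 + EH^2 + FGH)/(G^2+H^2), total = -2(D + E).
    Cells with zero gradient have undefined plan/profile; they are set to 0.
    Units: 1/m (some GIS packages multiply by 100; we do not).
    """
    elev = np.asarray(elev, float)
    if elev.shape[0] < 3 or elev.shape[1] < 3:
        raise ValueError("DTM must be at least 3x3")
    L = spec.cell
    z = np.pad(elev, 1, mode="edge")
    zc = z[1:-1, 1:-1]
    zn, zs = z[:-2, 1:-1], z[2:, 1:-1]
    zw, ze = z[1:-1, :-2], z[1:-1, 2:]
    znw, zne = z[:-2, :-2], z[:-2, 2:]
    zsw, zse = z[2:, :-2], z[2:, 2:]
    D = ((zw + ze) / 2 - zc) / L**2
    E = ((zn + zs) / 2 - zc) / L**2
    F = (-znw + zne + zsw - zse) / (4 * L**2)
    G = (-zw + ze) / (2 * L)
    H = (zn - zs) / (2 * L)
    g2 = G**2 + H**2
    with np.errstate(divide="ignore", invalid="ignore"):
        plan = np.where(g2 > 0, 2 * (D * H**2 + E * G**2 - F * G * H) / g2, 0.0)
        profile = np.where(g2 > 0, -2 * (D * G**2 + E * H**2 + F * G * H) / g2, 0.0)
    total = -2 * (D + E)
    return {"CURV.plan": plan, "CURV.profile": profile, "CURV.total": total}


def fold_aspect_heatload(aspect_deg):
    """Fold aspect about the 225-deg (SW) axis: 225 -> 0, 45 -> 180."""
    return np.abs(180.0 - np.abs(np.asarray(aspect_deg, float) - 225.0))


def heat_load_index(slope_deg, aspect_deg, latitude_deg) -> np.ndarray:
    """McCune-Keon heat-load index (third published equation).

    HLI = 0.339 + 0.808 cos(lat) cos(slope) - 0.196 sin(lat) sin(slope)
          - 0.482 cos(folded aspect) sin(slope)

    with aspect folded about the NE-SW axis so that SW slopes are hottest.
    The value is the log of potential annual direct incident radiation and
    is used here, as in common practice, as a unitless relative index.
    Flat cells (NaN aspect) use the folded-aspect term at its neutral
    zero-slope limit, where it vanishes anyway.
    """
    if np.any(np.abs(latitude_deg) > 90):
        raise ValueError("latitude must be within [-90, 90] degrees")
    slope = np.radians(np.asarray(slope_deg, float))
    folded = np.radians(fold_aspect_heatload(aspect_deg))
    folded = np.where(np.isnan(folded), 0.0, folded)
    lat = np.radians(latitude_deg)
    return (
        0.339
        + 0.808 * np.cos(lat) * np.cos(slope)
        - 0.196 * np.sin(lat) * np.sin(slope)
        - 0.482 * np.cos(folded) * np.sin(slope)
    )


def tpi_tri(elev: np.ndarray, window: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Topographic position index and roughness index over an odd window.

    TPI = center - mean(neighbors); TRI = sqrt(mean((neighbor - center)^2)),
    both excluding the center cell, computed on an edge-replicated pad.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    elev = np.asarray(elev, float)
    k = window * window
    mean_all = uniform_filter(elev, size=window, mode="nearest")
    mean_sq = uniform_filter(elev**2, size=window, mode="nearest")
    nb_mean = (mean_all * k - elev) / (k - 1)
    nb_mean_sq = (mean_sq * k - elev**2) / (k - 1)
    tpi = elev - nb_mean
    # E[(z_i - c)^2] over neighbors = E[z_i^2] - 2c E[z_i] + c^2
    tri = np.sqrt(np.maximum(nb_mean_sq - 2 * elev * nb_mean + elev**2, 0.0))
    return tpi, tri


def aspect_transforms(slope_deg, aspect_deg) -> dict[str, np.ndarray]:
    """TRASP and the slope-aspect interactions SCOSA / SSINA.

    TRASP = (1 - cos(aspect - 30 deg))/2, in [0, 1] with 1 on hot SSW
    aspects; SCOSA = slope*cos(aspect), SSINA = slope*sin(aspect) with slope
    in degrees.  Flat cells (NaN aspect) get the neutral fills TRASP = 0.5,
    SCOSA = SSINA = 0.
    """
    slope = np.asarray(slope_deg, float)
    aspect = np.asarray(aspect_deg, float)
    flat = np.isnan(aspect)
    a = np.where(flat, 0.0, np.radians(aspect))
    trasp = (1.0 - np.cos(a - np.radians(30.0))) / 2.0
    scosa = slope * np.cos(a)
    ssina = slope * np.sin(a)
    trasp = np.where(flat, 0.5, trasp)
    scosa = np.where(flat, 0.0, scosa)
    ssina = np.where(flat, 0.0, ssina)
    return {"TRASP": trasp, "SCOSA": scosa, "SSINA": ssina}


def terrain_metrics(spec: GridSpec, elev: np.ndarray, latitude_deg: float = 36.0,
                    window: int = 3) -> dict[str, np.ndarray]:
    """All topographic metric layers: curvatures, DEM, HLI, SLOPE, SCOSA,
    SSINA, TPI, TRASP, TRI, plus an ``edge`` flag layer."""
    elev = np.asarray(elev, float)
    slope, aspect = slope_aspect(spec, elev)
    layers = dict(curvatures(spec, elev))
    layers["DEM"] = elev.copy()
    layers["HLI"] = heat_load_index(slope, aspect, latitude_deg)
    layers["SLOPE"] = slope
    layers.update(aspect_transforms(slope, aspect))
    tpi, tri = tpi_tri(elev, window=window)
    layers["TPI"] = tpi
    layers["TRI"] = tri
    edge = np.zeros(elev.shape)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = 1.0
    layers["edge"] = edge
    return layers


def extract_layers_at_points(spec: GridSpec, layers: dict, x, y) -> dict[str, np.ndarray]:
    """Nearest-cell values of each layer at point coordinates."""
    row, col = spec.index_of(x, y)
    if np.any((row < 0) | (row >= spec.nrows) | (col < 0) | (col >= spec.ncols)):
        bad = np.where((row < 0) | (row >= spec.nrows) | (col < 0) | (col >= spec.ncols))[0]
        raise ValueError(f"points outside grid at indices {bad.tolist()}")
    return {name: arr[row, col] for name, arr in layers.items()}
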