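"""Shrake-Rupley solvent-accessible surface area."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import ConfigError
from ..units import A_PER_NM
from ..structure_model.beads import Bead, coords_of, radii_of
from ..structure_model.nanocluster import fibonacci_sphere


def sasa(beads, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> np.ndarray:
    """Per-bead solvent-accessible surface area, in A^2.

    Test points are placed on each bead's probe-expanded sphere with a
    Fibonacci lattice; a point is accessible when it is not inside any
    neighbour's expanded sphere.  ``probe_radius`` is in Angstrom; bead
    coordinates and radii (nm) are converted internally.
    """
    if n_sphere_points < 10:
        raise ConfigError("n_sphere_points must be >= 10")
    if probe_radius < 0:
        raise ConfigError("probe_radius must be non-negative")
    if len(beads) and isinstance(beads[0], Bead):
        coords = coords_of(beads) * A_PER_NM
        radii = radii_of(beads) * A_PER_NM
    else:
        coords, radii = beads
        coords = np.asarray(coords, float)
        radii = np.asarray(radii, float)
    n = len(radii)
    expanded = radii + probe_radius
    unit = fibonacci_sphere(n_sphere_points)
    areas = np.zeros(n)
    d = cdist(coords, coords)
    for i in range(n):
        # only neighbours whose expanded spheres can bury points of i
        neigh = np.nonzero(
            (d[i] < expanded[i] + expanded) & (np.arange(n) != i))[0]
        pts = coords[i] + expanded[i] * unit
        if neigh.size:
            dist2 = cdist(pts, coords[neigh], metric="sqeuclidean")
            buried = np.any(dist2 < expanded[neigh] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas
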