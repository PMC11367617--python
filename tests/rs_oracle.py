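"""Brute-force Rayleigh-Sommerfeld diffraction integral.

Independent oracle for the angular-spectrum solver: the first
Rayleigh-Sommerfeld integral propagates a complex pressure plane exactly
(one-way) in homogeneous lossless water by direct summation over source
samples.  O(N_source * N_obs); use decimated observation grids.
"""

import numpy as np

C_WATER = 1500.0


def rayleigh_sommerfeld(source_plane: np.ndarray, spacing_mm: float,
                        frequency: float, obs_mm: np.ndarray,
                        c: float = C_WATER) -> np.ndarray:
    """Field at observation points (n, 3) mm, z > 0, from the z=0 plane.

    p(x) = -(1/2pi) sum p0 * (ik - 1/R) * (z/R) * e^{ikR}/R * dA
    """
    k = 2.0 * np.pi * frequency / c
    n0, n1 = source_plane.shape
    x = (np.arange(n0) - (n0 - 1) / 2.0) * spacing_mm * 1e-3
    y = (np.arange(n1) - (n1 - 1) / 2.0) * spacing_mm * 1e-3
    X, Y = np.meshgrid(x, y, indexing="ij")
    nz = source_plane != 0
    sx, sy, sp = X[nz], Y[nz], source_plane[nz]
    dA = (spacing_mm * 1e-3) ** 2
    obs = np.atleast_2d(obs_mm) * 1e-3
    out = np.empty(len(obs), complex)
    for i, (ox, oy, oz) in enumerate(obs):
        R = np.sqrt((ox - sx) ** 2 + (oy - sy) ** 2 + oz ** 2)
        out[i] = -np.sum(sp * (1j * k - 1.0 / R) * (oz / R)
                         * np.exp(1j * k * R) / R) * dA / (2.0 * np.pi)
    return out
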