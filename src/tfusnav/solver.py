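"""One-way hybrid angular-spectrum continuous-wave beam solver.

The complex pressure is marched plane by plane along the transducer axis
on a local grid aligned with the pose.  Each marching step is split into

1. an angular-spectrum diffraction step in a homogeneous background
   (water): multiply the 2-D spatial spectrum by ``exp(i k_z dz)`` with
   ``k_z = sqrt(k_ref^2 - k_x^2 - k_y^2)``; evanescent components decay
   exponentially instead of wrapping;
2. a heterogeneity phase/attenuation screen in real space:
   ``exp(i (k(r) - k_ref) dz) * exp(-alpha(r) dz)`` with
   ``k(r) = omega / c(r)``;
3. optionally, a plane-wave impedance transmission factor
   ``2 Z2 / (Z1 + Z2)`` wherever the acoustic impedance rho*c changes
   between consecutive planes.

A raised-cosine absorbing strip on the transverse edges suppresses
wrap-around from the periodic FFT.  The scheme is one-way: backscatter,
internal reverberation and standing waves are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as sp_fft

from .materials import HeadModel, WATER
from .scalp import TransducerPose
from .source import TransducerSpec, bowl_source_plane

__all__ = ["BeamGrid", "LocalFields", "BeamResult", "build_beam_grid",
           "resample_to_grid", "propagate", "intensity_from_pressure",
           "solve_beam"]

C_WATER = 1500.0  # m/s, background speed for the angular-spectrum step


@dataclass(frozen=True)
class BeamGrid:
    """Transducer-aligned local grid.

    Point (i, j, k) sits at ``origin + spacing * (i*u + j*v + k*w)`` in
    world mm; ``w`` is the beam axis, ``u``/``v`` span the transverse
    plane, right-handed.  Spacing is lambda/5 at the reference speed.
    """

    origin: np.ndarray  # (3,) world mm
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    spacing: float  # mm, isotropic
    shape: tuple[int, int, int]  # (nu, nv, nz)

    def world_coords(self) -> np.ndarray:
        """(nu, nv, nz, 3) world-mm coordinates of every grid point."""
        nu, nv, nz = self.shape
        i = np.arange(nu)[:, None, None, None]
        j = np.arange(nv)[None, :, None, None]
        k = np.arange(nz)[None, None, :, None]
        return (self.origin + self.spacing
                * (i * self.u + j * self.v + k * self.w))

    def world_to_local(self, xyz: np.ndarray) -> np.ndarray:
        """World mm -> fractional grid indices (i, j, k)."""
        d = np.atleast_2d(xyz) - self.origin
        R = np.stack([self.u, self.v, self.w], axis=1)
        return (d @ R) / self.spacing

    def transverse_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-centered transverse coordinates (mm) of the grid planes."""
        nu, nv, _ = self.shape
        x = (np.arange(nu) - (nu - 1) / 2.0) * self.spacing
        y = (np.arange(nv) - (nv - 1) / 2.0) * self.spacing
        return x[:, None], y[None, :]

    def z_mm(self) -> np.ndarray:
        return np.arange(self.shape[2]) * self.spacing


@dataclass
class LocalFields:
    """Acoustic properties resampled onto a BeamGrid (SI units; alpha in
    Np/m/MHz, scaled to the operating frequency inside the solver)."""

    rho: np.ndarray
    c: np.ndarray
    alpha: np.ndarray

    @classmethod
    def water(cls, shape: tuple[int, int, int]) -> "LocalFields":
        rho_w, c_w, _ = WATER
        return cls(rho=np.full(shape, rho_w, np.float32),
                   c=np.full(shape, c_w, np.float32),
                   alpha=np.zeros(shape, np.float32))


@dataclass
class BeamResult:
    """Continuous-wave solve on a local grid: complex pressure (optional)
    and time-averaged intensity ``|p|^2 / (2 rho c)`` in arbitrary units."""

    intensity: np.ndarray
    grid: BeamGrid
    pose: Optional[TransducerPose] = None
    pressure: Optional[np.ndarray] = None


def _transverse_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed (u, v) completing the axis w."""
    w = np.asarray(w, float)
    w = w / np.linalg.norm(w)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(w)))] = 1.0
    u = np.cross(e, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def build_beam_grid(
    pose: TransducerPose,
    spec: TransducerSpec,
    c_ref: float = C_WATER,
) -> BeamGrid:
    """Reduced computational domain for one pose: 1.3 d transverse,
    2 f axial, lambda/5 isotropic spacing, z = 0 at the exit plane."""
    h = spec.wavelength_mm(c_ref) / 5.0
    lt = 1.3 * spec.aperture_diameter
    lz = 2.0 * spec.focal_distance
    nu = int(round(lt / h)) + 1
    nz = int(round(lz / h)) + 1
    u, v = _transverse_basis(pose.axis)
    w = pose.axis
    origin = (pose.position - (nu - 1) / 2.0 * h * u
              - (nu - 1) / 2.0 * h * v)
    return BeamGrid(origin=origin, u=u, v=v, w=w, spacing=h,
                    shape=(nu, nu, nz))


def _trilinear_shared(volumes: list[np.ndarray], cvals: list[float],
                      coords: np.ndarray) -> list[np.ndarray]:
    """Trilinear interpolation of several volumes at the same coordinates.

    Corner indices and weights are computed once and shared.  Each volume
    is padded with two layers of its fill value so out-of-volume points
    blend toward, then reach, *cval* — matching constant-mode behavior.
    """
    shape = volumes[0].shape
    out_shape = coords.shape[1:]
    c = coords.reshape(3, -1).astype(np.float32) + 2.0  # into padded frame
    for ax in range(3):
        np.clip(c[ax], 1.0, shape[ax] + 2.0, out=c[ax])
    i0 = c.astype(np.int32)
    fr = c - i0.astype(np.float32)
    ny, nz = shape[1] + 4, shape[2] + 4
    flat0 = (i0[0] * ny + i0[1]) * nz + i0[2]
    offs = [np.int32((di * ny + dj) * nz + dk)
            for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]
    corner_idx = [flat0 if o == 0 else flat0 + o for o in offs]
    wx, wy, wz = fr
    weights = [((1 - wx) if di == 0 else wx)
               * ((1 - wy) if dj == 0 else wy)
               * ((1 - wz) if dk == 0 else wz)
               for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]
    results = []
    for vol, cval in zip(volumes, cvals):
        pv = np.pad(np.asarray(vol, np.float32), 2, constant_values=cval).ravel()
        acc = pv[corner_idx[0]] * weights[0]
        for idx, w in zip(corner_idx[1:], weights[1:]):
            acc += pv[idx] * w
        results.append(acc.reshape(out_shape))
    return results


def resample_to_grid(head_model: HeadModel, grid: BeamGrid) -> LocalFields:
    """Trilinear resampling of the head property volumes onto the local
    grid; points outside the head volume get water properties."""
    inv = np.linalg.inv(head_model.affine)
    # voxel = M @ (i,j,k) + b, composing grid->world->voxel
    R = np.stack([grid.u, grid.v, grid.w], axis=1) * grid.spacing
    M = inv[:3, :3] @ R
    b = inv[:3, :3] @ grid.origin + inv[:3, 3]
    nu, nv, nz = grid.shape
    i = np.arange(nu, dtype=np.float32)[:, None, None]
    j = np.arange(nv, dtype=np.float32)[None, :, None]
    k = np.arange(nz, dtype=np.float32)[None, None, :]
    coords = np.empty((3, nu, nv, nz), dtype=np.float32)
    for ax in range(3):
        coords[ax] = M[ax, 0] * i + M[ax, 1] * j + M[ax, 2] * k + b[ax]
    rho_w, c_w, alpha_w = WATER
    rho, c, alpha = _trilinear_shared(
        [head_model.rho, head_model.c, head_model.alpha],
        [rho_w, c_w, alpha_w], coords)
    return LocalFields(rho=rho, c=c, alpha=alpha)


def _edge_taper(nu: int, nv: int, width: int) -> np.ndarray | None:
    if width <= 0:
        return None
    def win(n: int) -> np.ndarray:
        w = np.ones(n)
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(width) + 0.5) / width))
        w[:width] = ramp
        w[-width:] = ramp[::-1]
        return w
    return (win(nu)[:, None] * win(nv)[None, :]).astype(np.float32)


def propagate(
    source_plane: np.ndarray,
    local_fields: LocalFields,
    grid: BeamGrid,
    frequency: float,
    *,
    c_ref: float = C_WATER,
    impedance_steps: bool = True,
    taper_width: int = 8,
    alpha_exponent: float = 1.0,
    keep_pressure: bool = True,
    pose: TransducerPose | None = None,
) -> BeamResult:
    """March the complex pressure from the z=0 source plane through the
    resampled medium.  Returns pressure (if kept) and intensity on the
    full grid.  The step size must satisfy dz <= lambda_ref / 2."""
    nu, nv, nz = grid.shape
    p0 = np.asarray(source_plane)
    if p0.shape != (nu, nv):
        raise ValueError(f"source plane shape {p0.shape} != transverse {nu, nv}")
    lam_mm = c_ref / frequency * 1e3
    if grid.spacing > lam_mm / 2.0 + 1e-12:
        raise ValueError(
            f"marching step {grid.spacing:g} mm exceeds lambda/2 = {lam_mm / 2:g} mm")
    for name in ("rho", "c", "alpha"):
        if not np.isfinite(getattr(local_fields, name)).all():
            raise ValueError(f"NaN/Inf in resampled field {name!r}")

    dz = grid.spacing * 1e-3  # m
    k_ref = 2.0 * np.pi * frequency / c_ref
    kx = 2.0 * np.pi * np.fft.fftfreq(nu, d=dz)
    ky = 2.0 * np.pi * np.fft.fftfreq(nv, d=dz)
    kz2 = k_ref ** 2 - kx[:, None] ** 2 - ky[None, :] ** 2
    H = np.where(kz2 >= 0,
                 np.exp(1j * np.sqrt(np.maximum(kz2, 0.0)) * dz),
                 np.exp(-np.sqrt(np.maximum(-kz2, 0.0)) * dz)).astype(np.complex64)

    f_mhz_pow = (frequency / 1e6) ** alpha_exponent
    omega = 2.0 * np.pi * frequency
    taper = _edge_taper(nu, nv, taper_width)

    pressure = np.empty((nu, nv, nz), dtype=np.complex64)
    p = p0.astype(np.complex64)
    pressure[:, :, 0] = p
    rho_f = np.asarray(local_fields.rho, np.float64)
    c_f = np.asarray(local_fields.c, np.float64)
    a_f = np.asarray(local_fields.alpha, np.float64)
    Z_prev = rho_f[:, :, 0] * c_f[:, :, 0]
    for iz in range(1, nz):
        p = sp_fft.ifft2(sp_fft.fft2(p) * H)
        c_loc = c_f[:, :, iz]
        a_loc = a_f[:, :, iz] * f_mhz_pow
        screen = np.exp((1j * (omega / c_loc - k_ref) - a_loc) * dz)
        p = p * screen.astype(np.complex64)
        if impedance_steps:
            Z = rho_f[:, :, iz] * c_loc
            if not np.array_equal(Z, Z_prev):
                p = p * (2.0 * Z / (Z + Z_prev)).astype(np.float32)
            Z_prev = Z
        if taper is not None:
            p = p * taper
        pressure[:, :, iz] = p

    intensity = intensity_from_pressure(pressure, local_fields)
    return BeamResult(intensity=intensity, grid=grid, pose=pose,
                      pressure=pressure if keep_pressure else None)


def intensity_from_pressure(pressure: np.ndarray,
                            local_fields: LocalFields) -> np.ndarray:
    """Time-averaged CW intensity ``I = |p|^2 / (2 rho c)`` elementwise."""
    if pressure.shape != local_fields.rho.shape:
        raise ValueError("pressure and property shapes differ")
    mag2 = (pressure.real.astype(np.float64) ** 2
            + pressure.imag.astype(np.float64) ** 2)
    I = mag2 / (2.0 * local_fields.rho * local_fields.c)
    return I.astype(np.float32)


def solve_beam(
    pose: TransducerPose,
    spec: TransducerSpec,
    head_model: HeadModel | None,
    *,
    c_ref: float = C_WATER,
    impedance_steps: bool = True,
    taper_width: int = 8,
    alpha_exponent: float = 1.0,
    keep_pressure: bool = False,
) -> BeamResult:
    """Convenience end-to-end solve for one pose: build the local grid,
    synthesize the bowl source, resample the head (or use pure water when
    *head_model* is None) and propagate."""
    grid = build_beam_grid(pose, spec, c_ref)
    x, y = grid.transverse_mm()
    src = bowl_source_plane(spec, x, y, c_ref)
    fields = (LocalFields.water(grid.shape) if head_model is None
              else resample_to_grid(head_model, grid))
    return propagate(src, fields, grid, spec.frequency, c_ref=c_ref,
                     impedance_steps=impedance_steps, taper_width=taper_width,
                     alpha_exponent=alpha_exponent,
                     keep_pressure=keep_pressure, pose=pose)
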