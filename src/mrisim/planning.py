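"""Geometric prescription of an acquisition and reslicing onto its grid.

A :class:`PlanGeometry` captures the clinical planning step: an orthonormal
frequency/phase/slice axis triad, in-plane FOV and matrix, slice thickness
and separation, stack centre and optional phase oversampling (the
no-phase-wrap mechanism).  :func:`reslice` resamples the anatomical model
onto that grid by trilinear interpolation, averaging sub-planes across the
slice thickness to approximate the slice profile.

Sampling convention: voxel-centre sampling with pixel (0, 0) at the
(-freq, -phase) corner; the world coordinate of pixel (i, j) in slice s is

    centre + ((i + 0.5)/N_f - 0.5) * fov_f * freq_axis
           + ((j + 0.5)/N_p - 0.5) * fov_p * phase_axis
           + (s - (n_slices - 1)/2) * slice_separation * slice_axis

with N_p and fov_p the oversampled phase matrix and FOV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .phantom import AnatomicalModel, ValidationError

__all__ = ["PlanGeometry", "ReslicedStack", "canonical_plan", "reslice"]

#: Number of equispaced sub-planes averaged across the slice thickness.
DEFAULT_N_SUB = 5


@dataclass
class PlanGeometry:
    """Full geometric prescription of one acquisition stack."""

    freq_axis: np.ndarray
    phase_axis: np.ndarray
    slice_axis: np.ndarray
    fov_freq: float
    fov_phase: float
    matrix_freq: int
    matrix_phase: int
    slice_thickness: float
    slice_separation: float
    n_slices: int
    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phase_oversampling: float = 1.0

    def __post_init__(self) -> None:
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.phase_axis = np.asarray(self.phase_axis, dtype=float)
        self.slice_axis = np.asarray(self.slice_axis, dtype=float)
        self.centre = np.asarray(self.centre, dtype=float)
        self.validate()

    def validate(self) -> None:
        axes = np.stack([self.freq_axis, self.phase_axis, self.slice_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValidationError("freq/phase/slice axes must form an orthonormal triad")
        if self.fov_freq <= 0 or self.fov_phase <= 0:
            raise ValidationError("FOV must be positive")
        if self.matrix_freq <= 0 or self.matrix_phase <= 0 or self.n_slices <= 0:
            raise ValidationError("matrix sizes and n_slices must be positive integers")
        if self.slice_thickness <= 0 or self.slice_separation <= 0:
            raise ValidationError("slice thickness and separation must be positive")
        if self.phase_oversampling < 1:
            raise ValidationError("phase_oversampling must be >= 1")

    @property
    def matrix_phase_eff(self) -> int:
        """Phase matrix including oversampling."""
        return int(round(self.matrix_phase * self.phase_oversampling))

    @property
    def fov_phase_eff(self) -> float:
        """Phase FOV including oversampling (pixel size is preserved)."""
        return self.fov_phase * self.matrix_phase_eff / self.matrix_phase

    def pixel_spacing(self) -> tuple[float, float]:
        return self.fov_freq / self.matrix_freq, self.fov_phase / self.matrix_phase

    def world_coordinates(self, slice_idx: int, slice_offset_mm: float = 0.0) -> np.ndarray:
        """World coordinates (N_f, N_p_eff, 3) of the pixel centres of one slice."""
        nf, np_eff = self.matrix_freq, self.matrix_phase_eff
        u = ((np.arange(nf) + 0.5) / nf - 0.5) * self.fov_freq
        v = ((np.arange(np_eff) + 0.5) / np_eff - 0.5) * self.fov_phase_eff
        s = (slice_idx - (self.n_slices - 1) / 2.0) * self.slice_separation + slice_offset_mm
        return (
            self.centre
            + u[:, None, None] * self.freq_axis
            + v[None, :, None] * self.phase_axis
            + s * self.slice_axis
        )

    def swapped_encoding(self) -> "PlanGeometry":
        """Same stack with frequency and phase assignments exchanged."""
        return PlanGeometry(
            freq_axis=self.phase_axis,
            phase_axis=self.freq_axis,
            slice_axis=self.slice_axis,
            fov_freq=self.fov_phase,
            fov_phase=self.fov_freq,
            matrix_freq=self.matrix_phase,
            matrix_phase=self.matrix_freq,
            slice_thickness=self.slice_thickness,
            slice_separation=self.slice_separation,
            n_slices=self.n_slices,
            centre=self.centre,
            phase_oversampling=self.phase_oversampling,
        )


@dataclass
class ReslicedStack:
    """Per-slice tissue-property maps on the planned (freq x phase) grid.

    Arrays have shape ``(n_slices, matrix_freq, matrix_phase_eff)``.
    """

    pd: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    delta_b0: np.ndarray
    geometry: PlanGeometry

    def __post_init__(self) -> None:
        expected = (
            self.geometry.n_slices,
            self.geometry.matrix_freq,
            self.geometry.matrix_phase_eff,
        )
        for name in ("pd", "t1", "t2", "delta_b0"):
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {expected}")


_CANONICAL_AXES: dict[str, tuple[int, int, int]] = {
    # (in-plane axis a, in-plane axis b, slice axis) as model-axis indices
    "axial": (0, 1, 2),
    "coronal": (0, 2, 1),
    "sagittal": (1, 2, 0),
}


def canonical_plan(
    kind: Literal["axial", "sagittal", "coronal"],
    model: AnatomicalModel,
    matrix: tuple[int, int],
    fov: tuple[float, float],
    thickness: float,
    separation: float | None = None,
    n_slices: int = 1,
    phase_oversampling: float = 1.0,
    swap_encoding: bool = False,
    centre: np.ndarray | None = None,
) -> PlanGeometry:
    """Orthogonal plan centred on the model.

    By default the frequency axis is assigned to the in-plane direction
    with the longer anatomical extent (the usual choice, since wrap-around
    only occurs along phase); ``swap_encoding`` overrides it.  ``matrix``
    and ``fov`` are given as (frequency, phase).
    """
    if kind not in _CANONICAL_AXES:
        raise ValidationError(f"unknown plan kind {kind!r}; expected one of {sorted(_CANONICAL_AXES)}")
    ia, ib, islc = _CANONICAL_AXES[kind]
    extent = model.extent_mm()
    # longer extent -> frequency
    if extent[ia] >= extent[ib]:
        ifreq, iphase = ia, ib
    else:
        ifreq, iphase = ib, ia
    if swap_encoding:
        ifreq, iphase = iphase, ifreq
    R = model.orientation
    plan = PlanGeometry(
        freq_axis=R[:, ifreq],
        phase_axis=R[:, iphase],
        slice_axis=R[:, islc] * float(np.sign(np.linalg.det(R) or 1.0)),
        fov_freq=float(fov[0]),
        fov_phase=float(fov[1]),
        matrix_freq=int(matrix[0]),
        matrix_phase=int(matrix[1]),
        slice_thickness=float(thickness),
        slice_separation=float(separation if separation is not None else thickness),
        n_slices=int(n_slices),
        centre=model.centre_world() if centre is None else np.asarray(centre, dtype=float),
        phase_oversampling=float(phase_oversampling),
    )
    # re-orthogonalize the triad in case slice axis sign flipped handedness
    if not np.allclose(np.cross(plan.freq_axis, plan.phase_axis) @ plan.slice_axis, 1.0, atol=1e-9):
        plan.slice_axis = -plan.slice_axis
    return plan


def _voxel_coords(world: np.ndarray, model: AnatomicalModel) -> np.ndarray:
    """World points (..., 3) -> fractional voxel indices as a (3, N) array."""
    rel = np.ascontiguousarray(world.reshape(-1, 3)) - model.origin
    vox = (rel @ model.orientation) / model.spacing  # R.T applied to row vectors
    return np.ascontiguousarray(vox.T)


def _sample_volume(
    volume: np.ndarray,
    world: np.ndarray,
    model: AnatomicalModel,
    cval: float,
    order: int = 1,
) -> np.ndarray:
    """Trilinear (or nearest) interpolation of ``volume`` at world points."""
    coords = _voxel_coords(world, model)
    out = ndimage.map_coordinates(
        volume, coords, order=order, mode="grid-constant", cval=cval, prefilter=False
    )
    return out.reshape(world.shape[:-1])


def reslice(
    model: AnatomicalModel,
    geom: PlanGeometry,
    n_sub: int = DEFAULT_N_SUB,
) -> ReslicedStack:
    """Resample the model onto the planned acquisition grid.

    Each output voxel is the average over ``n_sub`` equispaced sub-planes
    spanning the slice thickness (midpoint-centred) of the trilinear
    interpolation of the source volume.  Points outside the model map to 0
    for PD and ΔB0 and to a 1.0 ms sentinel for T1/T2 so downstream
    divisions stay finite (PD = 0 suppresses the signal there anyway).
    """
    if n_sub < 1:
        raise ValidationError("n_sub must be >= 1")
    geom.validate()
    nf, np_eff, ns = geom.matrix_freq, geom.matrix_phase_eff, geom.n_slices
    channels = {
        "pd": (model.pd, 0.0),
        "t1": (model.t1, 1.0),
        "t2": (model.t2, 1.0),
        "delta_b0": (model.delta_b0, 0.0),
    }
    offsets = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * geom.slice_thickness
    # one (ns, n_sub, nf, np_eff, 3) coordinate block -> a single interpolation
    # call per channel, then average over the sub-plane axis
    world = np.empty((ns, n_sub, nf, np_eff, 3))
    for s in range(ns):
        for m, off in enumerate(offsets):
            world[s, m] = geom.world_coordinates(s, slice_offset_mm=float(off))
    coords = _voxel_coords(world, model)
    out = {}
    for name, (vol, cval) in channels.items():
        if cval == 0.0 and not np.any(vol):
            out[name] = np.zeros((ns, nf, np_eff))  # exact: interpolation of 0 is 0
            continue
        sampled = ndimage.map_coordinates(
            vol, coords, order=1, mode="grid-constant", cval=cval, prefilter=False
        )
        out[name] = sampled.reshape(ns, n_sub, nf, np_eff).mean(axis=1)
    return ReslicedStack(geometry=geom, **out)
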