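"""Tissue-property anatomical models: generation, validation and NIfTI I/O.

The simulator's ground truth is a set of co-registered 3-D volumes holding
the tissue properties that determine MR contrast: proton density (PD,
dimensionless in [0, 1]), the longitudinal relaxation time T1 and the
transverse relaxation time T2 (both in milliseconds).  An optional ΔB0
volume (in parts per million of the main field) models main-field
inhomogeneity, and an optional integer label volume records which tissue
painted each voxel.

Models are normally produced by :func:`build_phantom` from a list of
geometric :class:`TissueSpec` primitives, and serialized as one NIfTI-1
file per property plus a JSON manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "AnatomicalModel",
    "TissueSpec",
    "ValidationError",
    "FormatError",
    "build_phantom",
    "make_b0_perturbation",
    "default_head_phantom",
    "read_model",
    "write_model",
]

#: T1/T2 sentinel (ms) written into voxels that no tissue covers.  Any
#: positive value works because PD = 0 suppresses the signal; 1.0 ms keeps
#: downstream divisions finite.
BACKGROUND_RELAXATION_MS = 1.0


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when an on-disk model is structurally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AnatomicalModel:
    """Co-registered PD / T1 / T2 (+ ΔB0, labels) volumes with spatial metadata.

    Parameters
    ----------
    pd, t1, t2
        3-D arrays on a common grid.  PD is dimensionless in [0, 1]; T1 and
        T2 are milliseconds and must satisfy ``0 < t2 <= t1`` wherever
        ``pd > 0``.
    delta_b0
        Main-field inhomogeneity in ppm; ``None`` means a homogeneous field
        (stored as all-zero).
    labels
        Optional integer tissue-class map (0 = background).
    spacing, origin, orientation
        Voxel size (mm), world position of voxel (0,0,0) (mm) and the
        orthonormal 3x3 direction matrix mapping voxel axes to world axes.
    """

    pd: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    delta_b0: np.ndarray | None = None
    labels: np.ndarray | None = None
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.pd = np.asarray(self.pd, dtype=np.float64)
        self.t1 = np.asarray(self.t1, dtype=np.float64)
        self.t2 = np.asarray(self.t2, dtype=np.float64)
        if self.delta_b0 is None:
            self.delta_b0 = np.zeros_like(self.pd)
        else:
            self.delta_b0 = np.asarray(self.delta_b0, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.orientation = np.asarray(self.orientation, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        shapes = {self.pd.shape, self.t1.shape, self.t2.shape, self.delta_b0.shape}
        if self.labels is not None:
            shapes.add(self.labels.shape)
        if len(shapes) != 1:
            raise FormatError(f"component volumes have mismatched grids: {sorted(shapes)}")
        if self.pd.ndim != 3:
            raise ValidationError("volumes must be 3-D")
        if np.any(self.pd < -1e-12) or np.any(self.pd > 1 + 1e-12):
            raise ValidationError("pd must lie in [0, 1]")
        tissue = self.pd > 0
        if np.any(self.t1[tissue] <= 0) or np.any(self.t2[tissue] <= 0):
            raise ValidationError("t1 and t2 must be positive wherever pd > 0")
        if np.any(self.t2[tissue] > self.t1[tissue] * (1 + 1e-12)):
            raise ValidationError("t2 must not exceed t1 wherever pd > 0")
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be positive")
        R = self.orientation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or abs(abs(np.linalg.det(R)) - 1) > 1e-9:
            raise ValidationError("orientation matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pd.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index → world-mm affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def centre_world(self) -> np.ndarray:
        """World coordinate of the geometric centre of the grid (mm)."""
        dims = np.asarray(self.shape, dtype=float)
        return self.origin + self.orientation @ (self.spacing * (dims - 1) / 2.0)

    def extent_mm(self) -> np.ndarray:
        """Physical extent of the grid along its three axes (mm)."""
        return np.asarray(self.shape, dtype=float) * self.spacing

    def with_orientation(self, rotation: np.ndarray) -> "AnatomicalModel":
        """Return a copy rigidly rotated in world space about the origin."""
        rotation = np.asarray(rotation, dtype=float)
        return replace(
            self,
            orientation=rotation @ self.orientation,
            origin=rotation @ self.origin,
        )


@dataclass(frozen=True)
class TissueSpec:
    """A homogeneous tissue painted as a geometric primitive.

    ``shape`` is one of
      - ``{"type": "ellipsoid", "center": [x,y,z], "semi_axes": [a,b,c], "rotation_deg": [rx,ry,rz]}``
      - ``{"type": "box", "center": [x,y,z], "half_size": [a,b,c], "rotation_deg": [...]}``
      - ``{"type": "slab", "center": [x,y,z], "normal": [nx,ny,nz], "thickness": t}``
    with all lengths in mm (world coordinates); rotation is optional
    extrinsic XYZ Euler angles in degrees.
    """

    name: str
    pd: float
    t1: float
    t2: float
    shape: dict

    def __post_init__(self) -> None:
        if not (0 <= self.pd <= 1):
            raise ValidationError(f"tissue {self.name!r}: pd must be in [0,1], got {self.pd}")
        if self.pd > 0 and not (0 < self.t2 <= self.t1):
            raise ValidationError(
                f"tissue {self.name!r}: need 0 < t2 <= t1, got t1={self.t1}, t2={self.t2}"
            )
        if self.shape.get("type") not in ("ellipsoid", "box", "slab"):
            raise ValidationError(f"tissue {self.name!r}: unknown shape type {self.shape.get('type')!r}")


def _rotation_matrix(rotation_deg: Sequence[float] | None) -> np.ndarray:
    if rotation_deg is None:
        return np.eye(3)
    rx, ry, rz = (math.radians(a) for a in rotation_deg)
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _shape_mask(shape: dict, world: np.ndarray) -> np.ndarray:
    """Boolean mask of world points (..., 3) inside the primitive."""
    kind = shape["type"]
    centre = np.asarray(shape["center"], dtype=float)
    rel = world - centre
    if kind == "slab":
        normal = np.asarray(shape["normal"], dtype=float)
        normal = normal / np.linalg.norm(normal)
        return np.abs(rel @ normal) <= shape["thickness"] / 2.0
    R = _rotation_matrix(shape.get("rotation_deg"))
    local = rel @ R  # == R.T applied to each row vector
    if kind == "ellipsoid":
        semi = np.asarray(shape["semi_axes"], dtype=float)
        return np.sum((local / semi) ** 2, axis=-1) <= 1.0
    if kind == "box":
        half = np.asarray(shape["half_size"], dtype=float)
        return np.all(np.abs(local) <= half, axis=-1)
    raise ValidationError(f"unknown shape type {kind!r}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def build_phantom(
    tissues: Sequence[TissueSpec],
    grid: Sequence[int],
    spacing: Sequence[float],
    seed: int = 0,
    origin: Sequence[float] | None = None,
    texture_jitter: float = 0.0,
) -> AnatomicalModel:
    """Paint a list of tissue primitives onto a regular grid.

    Later tissues overwrite earlier ones where shapes overlap; tissue ``i``
    (0-based) is recorded as label ``i + 1`` in the label volume, with 0 for
    uncovered background.  ``texture_jitter`` adds multiplicative PD texture
    of the given relative standard deviation (clipped back into [0, 1]);
    the seed is consumed only by this jitter, so the output is deterministic
    either way.
    """
    if not tissues:
        raise ValidationError("tissue list must be non-empty")
    grid = tuple(int(n) for n in grid)
    if len(grid) != 3 or any(n < 8 for n in grid):
        raise ValidationError("grid must be 3-D with at least 8 voxels per axis")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValidationError("spacing must be 3 positive lengths (mm)")
    if origin is None:
        # centre the grid on the world origin
        origin = -spacing * (np.asarray(grid, dtype=float) - 1) / 2.0
    origin = np.asarray(origin, dtype=float)

    idx = np.indices(grid, dtype=float)  # (3, nx, ny, nz)
    world = origin + np.moveaxis(idx, 0, -1) * spacing  # identity orientation

    pd = np.zeros(grid)
    t1 = np.full(grid, BACKGROUND_RELAXATION_MS)
    t2 = np.full(grid, BACKGROUND_RELAXATION_MS)
    labels = np.zeros(grid, dtype=np.int32)
    for i, tissue in enumerate(tissues):
        mask = _shape_mask(tissue.shape, world)
        pd[mask] = tissue.pd
        t1[mask] = tissue.t1 if tissue.pd > 0 else BACKGROUND_RELAXATION_MS
        t2[mask] = tissue.t2 if tissue.pd > 0 else BACKGROUND_RELAXATION_MS
        labels[mask] = i + 1

    if texture_jitter > 0:
        rng = np.random.default_rng(seed)
        pd = np.clip(pd * (1 + texture_jitter * rng.standard_normal(grid)), 0.0, 1.0)

    return AnatomicalModel(pd=pd, t1=t1, t2=t2, labels=labels, spacing=spacing, origin=origin)


def make_b0_perturbation(
    grid: Sequence[int],
    spacing: Sequence[float],
    amplitude_ppm: float,
    smoothness_mm: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Smooth synthetic ΔB0 field (ppm) with ``max |ΔB0| = amplitude_ppm``.

    White Gaussian noise is low-pass filtered with an isotropic Gaussian
    kernel of standard deviation ``smoothness_mm`` (the spatial correlation
    length) and rescaled so that the peak absolute value equals the
    requested amplitude; amplitude 0 returns an all-zero field.
    """
    if amplitude_ppm < 0:
        raise ValidationError("amplitude_ppm must be >= 0")
    grid = tuple(int(n) for n in grid)
    if amplitude_ppm == 0:
        return np.zeros(grid)
    spacing = np.asarray(spacing, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid)
    sigma_vox = smoothness_mm / spacing
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    peak = np.max(np.abs(fieldv))
    if peak == 0:  # pragma: no cover - degenerate filter output
        return np.zeros(grid)
    return fieldv * (amplitude_ppm / peak)


def default_head_phantom(
    n: int = 64,
    spacing_mm: float = 3.0,
    seed: int = 0,
    delta_b0_ppm: float = 0.0,
) -> AnatomicalModel:
    """Head-like nested-ellipsoid demonstration phantom.

    Literature-typical 1.5 T relaxation values: an outer "scalp" shell,
    white matter, grey-matter ribbon and central CSF ventricles.  Intended
    for demonstrations and tests, not anatomical realism.
    """
    half = n * spacing_mm / 2.0
    a = 0.85 * half
    tissues = [
        TissueSpec("scalp", 0.9, 500.0, 60.0,
                   {"type": "ellipsoid", "center": [0, 0, 0], "semi_axes": [a, 0.8 * a, 0.75 * a]}),
        TissueSpec("white_matter", 0.7, 600.0, 80.0,
                   {"type": "ellipsoid", "center": [0, 0, 0], "semi_axes": [0.85 * a, 0.68 * a, 0.63 * a]}),
        TissueSpec("grey_matter", 0.8, 900.0, 100.0,
                   {"type": "ellipsoid", "center": [0, 0, 0], "semi_axes": [0.55 * a, 0.45 * a, 0.4 * a]}),
        TissueSpec("csf", 1.0, 4000.0, 2000.0,
                   {"type": "ellipsoid", "center": [0, 0, 0], "semi_axes": [0.25 * a, 0.18 * a, 0.15 * a]}),
    ]
    model = build_phantom(tissues, (n, n, n), (spacing_mm,) * 3, seed=seed)
    if delta_b0_ppm > 0:
        model.delta_b0 = make_b0_perturbation(
            (n, n, n), (spacing_mm,) * 3, delta_b0_ppm, smoothness_mm=10 * spacing_mm, seed=seed + 1
        )
    return model


# ---------------------------------------------------------------------------
# Serialization (NIfTI-1 volumes + JSON manifest)
# ---------------------------------------------------------------------------

_COMPONENTS = ("pd", "t1", "t2", "delta_b0", "labels")


def write_model(model: AnatomicalModel, path: str | Path) -> Path:
    """Write one NIfTI-1 file per property plus a JSON manifest.

    ``path`` is the manifest path (``.json``); volumes are written next to
    it as ``<stem>_<component>.nii``.  Returns the manifest path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    manifest: dict[str, str | None] = {}
    affine = model.affine
    for comp in _COMPONENTS:
        vol = getattr(model, comp)
        if vol is None:
            manifest[comp] = None
            continue
        fname = f"{stem}_{comp}.nii"
        dtype = np.int16 if comp == "labels" else np.float64
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=dtype), affine), path.parent / fname)
        manifest[comp] = fname
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_model(path: str | Path) -> AnatomicalModel:
    """Read a model written by :func:`write_model`.

    A missing ΔB0 component yields an all-zero field; mismatched grid
    dimensions across components raise :class:`FormatError`.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    vols: dict[str, np.ndarray | None] = {}
    affine = None
    for comp in _COMPONENTS:
        fname = manifest.get(comp)
        if fname is None:
            vols[comp] = None
            continue
        img = nib.load(path.parent / fname)
        vols[comp] = np.asarray(img.dataobj)
        if affine is None:
            affine = img.affine
    if vols["pd"] is None or vols["t1"] is None or vols["t2"] is None:
        raise FormatError("manifest must reference pd, t1 and t2 volumes")
    assert affine is not None
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    orientation = linear / spacing
    return AnatomicalModel(
        pd=vols["pd"],
        t1=vols["t1"],
        t2=vols["t2"],
        delta_b0=vols["delta_b0"],
        labels=vols["labels"],
        spacing=spacing,
        origin=affine[:3, 3],
        orientation=orientation,
    )
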