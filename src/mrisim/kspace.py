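"""k-space formation, artifact injection and reconstruction.

The contrast image is carried to the spatial-frequency domain with a
DC-centred *unitary* 2-D discrete Fourier transform (``norm="ortho"``,
``fftshift`` bracketing), so Parseval's identity holds exactly and complex
Gaussian noise of a given per-component standard deviation in k-space
reappears with the same standard deviation in the image — which is what
makes the Rayleigh background-noise statement below exact.

Artifact operators act on :class:`KSpaceSlice` and are pure functions of
their inputs (and an explicit seed where randomness is involved).  The
pipeline applies them in a fixed order: echo-train (FSE) attenuation →
motion → spikes → thermal noise → half-Fourier / wrap handling at
reconstruction.

Axis convention: ``data[i, j]`` indexes (frequency row i, phase line j);
ghosting from inter-view motion and wrap-around both occur along j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .contrast import SequenceParams
from .phantom import ValidationError
from .planning import PlanGeometry, ReslicedStack

__all__ = [
    "KSpaceSlice",
    "ArtifactConfig",
    "MotionSpec",
    "HalfFourierSpec",
    "forward_kspace",
    "inverse_recon",
    "inverse_complex",
    "add_thermal_noise",
    "add_spike",
    "add_motion",
    "apply_etl_attenuation",
    "half_fourier_recon",
    "apply_wraparound",
    "dc_index",
    "derive_seed",
]

NORMALIZATION_TAG = "unitary-dc-centred"


@dataclass
class KSpaceSlice:
    """Complex (freq x phase) matrix for one slice, DC at the matrix centre."""

    data: np.ndarray
    geometry: PlanGeometry | None = None
    normalization: str = NORMALIZATION_TAG

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValidationError("k-space data must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("k-space data must be finite")

    def copy_with(self, data: np.ndarray) -> "KSpaceSlice":
        return KSpaceSlice(data=data, geometry=self.geometry, normalization=self.normalization)


@dataclass(frozen=True)
class MotionSpec:
    """Periodic rigid in-plane translation during phase encoding."""

    kind: Literal["none", "periodic"] = "none"
    amplitude_mm: float = 0.0
    period_lines: float = 16.0


@dataclass(frozen=True)
class HalfFourierSpec:
    """Partial-Fourier acquisition: fraction of phase lines kept (+ overscan)."""

    enabled: bool = False
    fraction: float = 0.6
    overscan_lines: int = 0


@dataclass(frozen=True)
class ArtifactConfig:
    """Per-entry artifact toggles consumed by the simulation pipeline."""

    thermal_sigma: float = 0.0
    spikes: Sequence[tuple[tuple[int, int], complex]] = ()
    motion: MotionSpec = MotionSpec()
    half_fourier: HalfFourierSpec = HalfFourierSpec()
    wraparound_on: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_sigma < 0:
            raise ValidationError("thermal_sigma must be >= 0")
        if self.half_fourier.enabled and not (0.5 < self.half_fourier.fraction <= 1):
            raise ValidationError("half-Fourier fraction must lie in (0.5, 1]")
        if self.motion.kind == "periodic" and self.motion.period_lines < 2:
            raise ValidationError("motion period must be >= 2 lines")


def dc_index(shape: tuple[int, int]) -> tuple[int, int]:
    """Matrix index of the DC sample under the DC-centred convention."""
    return shape[0] // 2, shape[1] // 2


def derive_seed(root_seed: int, label: str) -> int:
    """Deterministic per-artifact substream seed (< 2**31) from a root seed."""
    h = np.uint64(1469598103934665603)  # FNV-1a over the label, mixed with root
    for byte in label.encode():
        h = np.uint64((int(h) ^ byte) * 1099511628211 % (1 << 64))
    return int((int(h) ^ (root_seed * 2654435761)) % (1 << 31))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def forward_kspace(image: np.ndarray, geometry: PlanGeometry | None = None) -> KSpaceSlice:
    """Unitary 2-D DFT with the DC sample at the matrix centre."""
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image must be finite")
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))
    return KSpaceSlice(data=k, geometry=geometry)


def inverse_complex(k: KSpaceSlice) -> np.ndarray:
    """Complex image from the unitary inverse transform."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k.data), norm="ortho"))


def inverse_recon(k: KSpaceSlice, return_phase: bool = False):
    """Magnitude image (optionally also the phase image) of the inverse DFT."""
    img = inverse_complex(k)
    if return_phase:
        return np.abs(img), np.angle(img)
    return np.abs(img)


# ---------------------------------------------------------------------------
# Artifact operators
# ---------------------------------------------------------------------------

def add_thermal_noise(k: KSpaceSlice, sigma: float, seed: int) -> KSpaceSlice:
    """Add i.i.d. circular complex Gaussian noise (std ``sigma`` per component).

    Under the unitary convention the reconstructed background magnitude then
    follows a Rayleigh law with scale ``sigma``.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return k.copy_with(k.data)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, k.data.shape) + 1j * rng.normal(0.0, sigma, k.data.shape)
    return k.copy_with(k.data + noise)


def add_spike(k: KSpaceSlice, location: tuple[int, int], amplitude: complex) -> KSpaceSlice:
    """Add a point perturbation at matrix index ``location``.

    The reconstructed image gains a superposed plane-wave stripe whose cycle
    counts across the image equal the spike's (row, column) offset from DC.
    """
    i, j = location
    n0, n1 = k.data.shape
    if not (0 <= i < n0 and 0 <= j < n1):
        raise ValidationError(f"spike location {location} outside matrix {k.data.shape}")
    data = k.data.copy()
    data[i, j] += amplitude
    return k.copy_with(data)


def add_motion(
    k: KSpaceSlice,
    amplitude_mm: float,
    period_lines: float,
    geometry: PlanGeometry | None = None,
) -> KSpaceSlice:
    """Periodic rigid translation along frequency during phase encoding.

    Phase line j is acquired with the object displaced by
    ``d(j) = amplitude * sin(2*pi*j/period)`` mm along the frequency axis,
    i.e. multiplied by ``exp(-2*pi*i*k_f*d(j))`` (Fourier shift theorem).
    The modulation is periodic in j, so the image gains ghost replicas of
    the parent displaced along phase by multiples of N_phase/period pixels.
    """
    if period_lines < 2:
        raise ValidationError("period_lines must be >= 2")
    geometry = geometry or k.geometry
    if geometry is None:
        raise ValidationError("add_motion requires a geometry for the k_f axis scale")
    if amplitude_mm == 0:
        return k.copy_with(k.data)
    n_f, n_p = k.data.shape
    kf = (np.arange(n_f) - n_f // 2) / geometry.fov_freq  # cycles / mm
    d = amplitude_mm * np.sin(2 * np.pi * np.arange(n_p) / period_lines)  # mm
    phase = np.exp(-2j * np.pi * kf[:, None] * d[None, :])
    return k.copy_with(k.data * phase)


def _fse_line_times(n_p: int, seq: SequenceParams) -> np.ndarray:
    """Echo time (ms) at which each phase line is acquired.

    Lines are grouped into ``etl`` contiguous segments (linear view
    ordering); echo numbers are assigned by a cyclic shift so that the
    segment containing the k-space centre is read at the echo whose time is
    closest to the prescribed TE.  Line times are centred on TE:
    ``t(j) = TE + (echo(j) - echo_centre) * echo_spacing`` (clipped at 0),
    so ETL = 1 degenerates to a uniform scale exp(-TE/T2_eff).
    """
    etl = int(seq.etl)  # type: ignore[arg-type]
    esp = float(seq.echo_spacing)  # type: ignore[arg-type]
    seg = np.minimum((np.arange(n_p) * etl) // n_p, etl - 1)
    seg_c = seg[n_p // 2]
    e_c = int(np.clip(round(seq.te / esp), 1, etl))
    echo = ((seg - seg_c + (e_c - 1)) % etl) + 1
    return np.maximum(seq.te + (echo - e_c) * esp, 0.0)


def apply_etl_attenuation(
    k: KSpaceSlice,
    resliced_slice: dict | ReslicedStack,
    seq: SequenceParams,
    slice_idx: int = 0,
) -> KSpaceSlice:
    """T2 attenuation of a fast-spin-echo echo train as a per-line k-space filter.

    Each phase line is scaled by ``exp(-t(j)/T2_eff)`` where ``t(j)`` is the
    line's acquisition echo time (see :func:`_fse_line_times`) and T2_eff is
    the PD-weighted mean T2 of the slice (a per-slice scalar, keeping the
    attenuation a pure k-space filter).

    ``resliced_slice`` is either a ``{"pd": 2-D, "t2": 2-D}`` mapping or a
    :class:`ReslicedStack` with ``slice_idx`` selecting the slice.
    """
    if seq.family != "FSE":
        raise ValidationError("apply_etl_attenuation applies to FSE only")
    if isinstance(resliced_slice, ReslicedStack):
        pd = resliced_slice.pd[slice_idx]
        t2 = resliced_slice.t2[slice_idx]
    else:
        pd = np.asarray(resliced_slice["pd"])
        t2 = np.asarray(resliced_slice["t2"])
    w = np.sum(pd)
    t2_eff = float(np.sum(pd * t2) / w) if w > 0 else float(np.mean(t2))
    times = _fse_line_times(k.data.shape[1], seq)
    scale = np.exp(-times / t2_eff)
    return k.copy_with(k.data * scale[None, :])


# ---------------------------------------------------------------------------
# Reconstruction-time manipulations
# ---------------------------------------------------------------------------

def _hermitian_fill(data: np.ndarray, keep: int) -> np.ndarray:
    """Replace phase lines j >= keep with the Hermitian conjugate of their mirror."""
    n0, n1 = data.shape
    c0, c1 = n0 // 2, n1 // 2
    filled = data.copy()
    for j in range(keep, n1):
        jm = (2 * c1 - j) % n1
        im = (2 * c0 - np.arange(n0)) % n0
        filled[:, j] = np.conj(data[im, jm])
    return filled


def half_fourier_recon(k: KSpaceSlice, fraction: float, overscan: int = 0) -> np.ndarray:
    """Partial-Fourier magnitude reconstruction by conjugate-symmetry fill.

    The first ``max(ceil(fraction * N_p), N_p//2 + 1 + overscan)`` phase
    lines are treated as acquired; the missing high-j lines are synthesized
    by Hermitian conjugation about the DC sample, then the unitary inverse
    transform is applied.  Exact for zero-phase (real, non-negative) images;
    phase errors in the object degrade it — which is the pedagogical point.
    ``fraction = 1`` reproduces the full reconstruction bit-for-bit.
    """
    if not (0.5 < fraction <= 1):
        raise ValidationError("fraction must lie in (0.5, 1]")
    n1 = k.data.shape[1]
    keep = max(int(np.ceil(fraction * n1)), n1 // 2 + 1 + int(overscan))
    keep = min(keep, n1)
    if keep == n1:
        return inverse_recon(k)
    filled = _hermitian_fill(k.data, keep)
    return inverse_recon(k.copy_with(filled))


def apply_wraparound(image: np.ndarray, geometry: PlanGeometry, wraparound_on: bool = True) -> np.ndarray:
    """Map an image on the phase-oversampled grid to the nominal phase FOV.

    With wrap-around on, the oversampled extent is folded into the nominal
    FOV by periodic summation along phase (aliasing); with no-phase-wrap the
    oversampled reconstruction is centre-cropped instead.  A point at phase
    coordinate FOV/2 + d folds to -FOV/2 + d.
    """
    image = np.asarray(image)
    n_nom = geometry.matrix_phase
    n_over = geometry.matrix_phase_eff
    if image.shape[-1] != n_over:
        raise ValidationError(
            f"image phase size {image.shape[-1]} does not match oversampled matrix {n_over}"
        )
    c_over, c_nom = n_over // 2, n_nom // 2
    start = c_over - c_nom
    if not wraparound_on:
        return image[..., start : start + n_nom]
    out = np.zeros(image.shape[:-1] + (n_nom,), dtype=image.dtype)
    # fold: output bin q collects samples with (p - c_over) ≡ (q - c_nom) (mod n_nom)
    col_energy = np.sum(np.abs(image) ** 2, axis=tuple(range(image.ndim - 1)))
    if n_over > n_nom and col_energy[[0, -1]].mean() > 0.5 * col_energy.mean():
        # the outermost columns carry as much energy as typical interior ones:
        # the object reaches the oversampled edge and the fold is incomplete
        warnings.warn(
            "object extends to the edge of the oversampled FOV; fold may be partial",
            stacklevel=2,
        )
    for p in range(n_over):
        q = (p - c_over + c_nom) % n_nom
        out[..., q] += image[..., p]
    return out
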