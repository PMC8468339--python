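"""Steady-state signal models and contrast-image synthesis.

The simulator evaluates the canonical closed-form steady-state expressions
for the supported sequence families instead of integrating the Bloch
equations; this is the standard "textbook" contrast model and is what makes
interactive simulation times possible.

Signal expressions (PD = proton density, times in ms):

  spin echo (SE, also FSE in-plane contrast)
      S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)
  spoiled gradient echo (GRE), flip angle alpha
      S = PD * sin(a) * (1 - E1) / (1 - cos(a) E1) * exp(-TE/T2*),  E1 = exp(-TR/T1)
  inversion recovery spin echo (IR), magnitude reconstruction
      S = PD * |1 - 2 exp(-TI/T1) + exp(-TR/T1)| * exp(-TE/T2)

GRE uses T2* from the ΔB0 map: 1/T2* = 1/T2 + gamma' * B0 * |ΔB0_ppm| with
gamma' = 42.58 Hz per (T * ppm) expressed per millisecond; shimming resets
ΔB0 to zero.  Saturation bands multiply PD before the signal expression is
applied, as does the receive-coil sensitivity, so both act identically on
every family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .phantom import ValidationError
from .planning import ReslicedStack

__all__ = [
    "SequenceParams",
    "SaturationBand",
    "CoilProfile",
    "signal_se",
    "signal_gre_spoiled",
    "signal_ir",
    "t2star_map",
    "contrast_stack",
    "ernst_angle_deg",
]

#: ΔB0 dephasing rate constant: reduced gyromagnetic ratio 42.58 MHz/T
#: scaled to 1/ms per (tesla * ppm): 42.58e6 Hz/T * 1e-6 ppm / 1000 ms.
GAMMA_PRIME_PER_MS_T_PPM = 42.58e6 * 1e-6 / 1e3

Family = Literal["SE", "FSE", "GRE_SPOILED", "IR_SE"]


@dataclass
class SequenceParams:
    """Contrast-determining parameters of one pulse sequence."""

    family: Family
    te: float
    tr: float
    ti: float | None = None
    flip_deg: float | None = None
    etl: int | None = None
    echo_spacing: float | None = None
    shimming_on: bool = False
    field_strength_t: float = 1.5
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.family not in ("SE", "FSE", "GRE_SPOILED", "IR_SE"):
            raise ValidationError(f"unknown sequence family {self.family!r}")
        if self.te < 0:
            raise ValidationError("te must be >= 0")
        if self.tr <= self.te:
            raise ValidationError("tr must exceed te")
        if self.family == "IR_SE":
            if self.ti is None:
                raise ValidationError("IR_SE requires parameter 'ti'")
            if not (0 < self.ti < self.tr):
                raise ValidationError("ti must satisfy 0 < ti < tr")
        if self.family == "GRE_SPOILED":
            if self.flip_deg is None:
                raise ValidationError("GRE_SPOILED requires parameter 'flip_deg'")
            if not (0 < self.flip_deg <= 90):
                raise ValidationError("flip_deg must lie in (0, 90]")
        if self.family == "FSE":
            if self.etl is None:
                raise ValidationError("FSE requires parameter 'etl'")
            if self.etl < 1:
                raise ValidationError("etl must be >= 1")
            if self.echo_spacing is None:
                raise ValidationError("FSE requires parameter 'echo_spacing'")
            if self.echo_spacing <= 0:
                raise ValidationError("echo_spacing must be positive")


@dataclass(frozen=True)
class SaturationBand:
    """Slab whose PD is suppressed before acquisition (0 = full suppression)."""

    centre: Sequence[float]
    normal: Sequence[float]
    thickness: float
    suppression: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValidationError("saturation band thickness must be positive")
        if not (0 <= self.suppression <= 1):
            raise ValidationError("suppression must lie in [0, 1]")

    def factor(self, world: np.ndarray) -> np.ndarray:
        """Multiplicative PD factor at world points (..., 3)."""
        normal = np.asarray(self.normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        d = (world - np.asarray(self.centre, dtype=float)) @ normal
        inside = np.abs(d) <= self.thickness / 2.0
        return np.where(inside, self.suppression, 1.0)


@dataclass(frozen=True)
class CoilProfile:
    """Receive-coil sensitivity: homogeneous body coil or exponential surface coil.

    The surface coil decays as exp(-|distance to reference plane| / falloff),
    the plane passing through ``reference`` with unit normal ``normal``.
    """

    kind: Literal["homogeneous", "surface"] = "homogeneous"
    reference: Sequence[float] = (0.0, 0.0, 0.0)
    falloff_mm: float | None = None
    normal: Sequence[float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind == "surface" and (self.falloff_mm is None or self.falloff_mm <= 0):
            raise ValidationError("surface coil requires positive falloff_mm")

    def sensitivity(self, world: np.ndarray) -> np.ndarray:
        if self.kind == "homogeneous":
            return np.ones(world.shape[:-1])
        normal = np.asarray(self.normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        d = np.abs((world - np.asarray(self.reference, dtype=float)) @ normal)
        return np.exp(-d / self.falloff_mm)


# ---------------------------------------------------------------------------
# Signal expressions
# ---------------------------------------------------------------------------

def _check_relaxation(t1, t2) -> None:
    if np.any(np.asarray(t1) <= 0) or np.any(np.asarray(t2) <= 0):
        raise ValidationError("t1 and t2 must be positive")


def signal_se(pd, t1, t2, te: float, tr: float):
    """Spin-echo steady-state signal; 0 <= S <= PD."""
    _check_relaxation(t1, t2)
    if te < 0 or tr <= 0:
        raise ValidationError("need te >= 0 and tr > 0")
    return pd * (1.0 - np.exp(-tr / np.asarray(t1))) * np.exp(-te / np.asarray(t2))


def signal_gre_spoiled(pd, t1, t2star, te: float, tr: float, flip_deg: float):
    """Spoiled gradient-echo steady-state signal (Ernst formula)."""
    _check_relaxation(t1, t2star)
    if not (0 < flip_deg <= 90):
        raise ValidationError("flip_deg must lie in (0, 90]")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr / np.asarray(t1))
    return pd * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1) * np.exp(-te / np.asarray(t2star))


def signal_ir(pd, t1, t2, te: float, tr: float, ti: float):
    """Inversion-recovery spin-echo signal, magnitude reconstruction."""
    _check_relaxation(t1, t2)
    if ti >= tr:
        raise ValidationError("ti must be smaller than tr")
    t1 = np.asarray(t1)
    return pd * np.abs(1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)) * np.exp(-te / np.asarray(t2))


def ernst_angle_deg(t1: float, tr: float) -> float:
    """Flip angle maximizing the spoiled-GRE signal: arccos(exp(-TR/T1))."""
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def t2star_map(t2, delta_b0_ppm, field_strength_t: float = 1.5):
    """Effective transverse relaxation: 1/T2* = 1/T2 + gamma' * B0 * |ΔB0|.

    With a homogeneous field (ΔB0 = 0) this returns T2 exactly.
    """
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 <= 0):
        raise ValidationError("t2 must be positive")
    r2prime = GAMMA_PRIME_PER_MS_T_PPM * field_strength_t * np.abs(np.asarray(delta_b0_ppm, dtype=float))
    return 1.0 / (1.0 / t2 + r2prime)


# ---------------------------------------------------------------------------
# Stack-level contrast synthesis
# ---------------------------------------------------------------------------

def contrast_stack(
    resliced: ReslicedStack,
    seq: SequenceParams,
    bands: Sequence[SaturationBand] = (),
    coil: CoilProfile | None = None,
) -> np.ndarray:
    """Real-valued contrast images, shape (n_slices, N_f, N_p_eff).

    PD is first multiplied by every saturation band's suppression factor
    (where the voxel's world coordinate lies in the slab) and by the coil
    sensitivity; the family's signal expression is then applied voxel-wise.
    FSE uses the SE expression here — its echo-train attenuation is a
    k-space filter applied later in the pipeline.
    """
    seq.validate()
    geom = resliced.geometry
    pd = resliced.pd.copy()
    if bands or (coil is not None and coil.kind != "homogeneous"):
        for s in range(geom.n_slices):
            world = geom.world_coordinates(s)
            for band in bands:
                pd[s] *= band.factor(world)
            if coil is not None:
                pd[s] *= coil.sensitivity(world)

    # sentinel relaxation values keep the expressions finite where pd == 0
    t1 = np.where(resliced.t1 > 0, resliced.t1, 1.0)
    t2 = np.where(resliced.t2 > 0, resliced.t2, 1.0)
    db0 = np.zeros_like(resliced.delta_b0) if seq.shimming_on else resliced.delta_b0

    if seq.family in ("SE", "FSE"):
        return signal_se(pd, t1, t2, seq.te, seq.tr)
    if seq.family == "IR_SE":
        return signal_ir(pd, t1, t2, seq.te, seq.tr, seq.ti)  # type: ignore[arg-type]
    if seq.family == "GRE_SPOILED":
        t2star = t2star_map(t2, db0, seq.field_strength_t)
        return signal_gre_spoiled(pd, t1, t2star, seq.te, seq.tr, seq.flip_deg)  # type: ignore[arg-type]
    raise ValidationError(f"unknown family {seq.family!r}")  # pragma: no cover
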