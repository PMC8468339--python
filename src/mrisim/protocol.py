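"""Protocol documents, validation, and the end-to-end simulation pipeline.

A protocol is an ordered list of acquisition entries, each pairing a
geometric plan with sequence parameters, artifact toggles and optional
saturation bands, plus session-level metadata (patient position, coil).
Protocols are plain JSON documents validated with pydantic;
:func:`validate_protocol` returns an itemized error list (with JSON paths)
rather than raising, so a front-end can show every problem at once.

:func:`run_protocol` executes the single-pass pipeline per entry:

    reslice → contrast → forward DFT → ETL attenuation (FSE) → motion →
    spikes → thermal noise → half-Fourier / wrap handling → magnitude image

and is bit-reproducible from (model, protocol, seed): every stochastic
stage draws from a substream derived from the root seed and a stable label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional

import nibabel as nib
import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__ as _pkg_version
from . import kspace as ksp
from .contrast import CoilProfile, SaturationBand, SequenceParams, contrast_stack
from .phantom import AnatomicalModel, ValidationError
from .planning import PlanGeometry, canonical_plan, reslice

__all__ = [
    "Protocol",
    "ProtocolEntry",
    "SessionResult",
    "EntryResult",
    "validate_protocol",
    "run_protocol",
    "load_protocol",
    "write_session",
]

PATIENT_POSITIONS = (
    "head_first_supine",
    "head_first_prone",
    "feet_first_supine",
    "feet_first_prone",
)


# ---------------------------------------------------------------------------
# JSON schema (pydantic models)
# ---------------------------------------------------------------------------

class PlanDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["axial", "sagittal", "coronal"] = "axial"
    matrix: tuple[int, int] = (128, 128)
    fov_mm: tuple[float, float] = (240.0, 240.0)
    thickness_mm: float = Field(5.0, gt=0)
    separation_mm: Optional[float] = Field(None, gt=0)
    n_slices: int = Field(1, ge=1)
    phase_oversampling: float = Field(1.0, ge=1.0)
    swap_encoding: bool = False
    centre_mm: Optional[tuple[float, float, float]] = None


class SequenceDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    family: Literal["SE", "FSE", "GRE_SPOILED", "IR_SE"]
    te_ms: float = Field(ge=0)
    tr_ms: float = Field(gt=0)
    ti_ms: Optional[float] = Field(None, gt=0)
    flip_deg: Optional[float] = None
    etl: Optional[int] = Field(None, ge=1)
    echo_spacing_ms: Optional[float] = Field(None, gt=0)
    shimming_on: bool = False
    field_strength_t: float = Field(1.5, gt=0)

    @model_validator(mode="after")
    def _family_consistency(self) -> "SequenceDoc":
        if self.tr_ms <= self.te_ms:
            raise ValueError(f"tr_ms ({self.tr_ms}) must exceed te_ms ({self.te_ms})")
        if self.family == "IR_SE" and self.ti_ms is None:
            raise ValueError("family IR_SE requires ti_ms")
        if self.family == "IR_SE" and self.ti_ms is not None and self.ti_ms >= self.tr_ms:
            raise ValueError("ti_ms must be smaller than tr_ms")
        if self.family == "GRE_SPOILED":
            if self.flip_deg is None:
                raise ValueError("family GRE_SPOILED requires flip_deg")
            if not (0 < self.flip_deg <= 90):
                raise ValueError("flip_deg must lie in (0, 90]")
        if self.family == "FSE" and (self.etl is None or self.echo_spacing_ms is None):
            raise ValueError("family FSE requires etl and echo_spacing_ms")
        return self

    def to_params(self) -> SequenceParams:
        return SequenceParams(
            family=self.family,
            te=self.te_ms,
            tr=self.tr_ms,
            ti=self.ti_ms,
            flip_deg=self.flip_deg,
            etl=self.etl,
            echo_spacing=self.echo_spacing_ms,
            shimming_on=self.shimming_on,
            field_strength_t=self.field_strength_t,
        )


class MotionDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["none", "periodic"] = "none"
    amplitude_mm: float = Field(0.0, ge=0)
    period_lines: float = Field(16.0, ge=2)


class HalfFourierDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = False
    fraction: float = Field(0.6, gt=0.5, le=1.0)
    overscan_lines: int = Field(0, ge=0)


class SpikeDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    offset: tuple[int, int]  # (freq, phase) offset from the DC sample
    amplitude: float = 1.0
    phase_deg: float = 0.0


class ArtifactDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    thermal_sigma: float = Field(0.0, ge=0)
    spikes: list[SpikeDoc] = Field(default_factory=list)
    motion: MotionDoc = Field(default_factory=MotionDoc)
    half_fourier: HalfFourierDoc = Field(default_factory=HalfFourierDoc)
    wraparound_on: bool = False


class BandDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    centre_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness_mm: float = Field(gt=0)
    suppression: float = Field(0.0, ge=0, le=1)


class CoilDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["homogeneous", "surface"] = "homogeneous"
    reference_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    falloff_mm: Optional[float] = Field(None, gt=0)
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @model_validator(mode="after")
    def _surface_needs_falloff(self) -> "CoilDoc":
        if self.kind == "surface" and self.falloff_mm is None:
            raise ValueError("surface coil requires falloff_mm")
        return self

    def to_profile(self) -> CoilProfile:
        return CoilProfile(
            kind=self.kind, reference=self.reference_mm,
            falloff_mm=self.falloff_mm, normal=self.normal,
        )


class EntryDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    plan: PlanDoc = Field(default_factory=PlanDoc)
    sequence: SequenceDoc
    artifacts: ArtifactDoc = Field(default_factory=ArtifactDoc)
    sat_bands: list[BandDoc] = Field(default_factory=list)


class ProtocolDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "protocol"
    patient_position: Literal[PATIENT_POSITIONS] = "head_first_supine"  # type: ignore[valid-type]
    coil: CoilDoc = Field(default_factory=CoilDoc)
    entries: list[EntryDoc] = Field(min_length=1)

    @model_validator(mode="after")
    def _unique_entry_names(self) -> "ProtocolDoc":
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"entry names must be unique, got {names}")
        return self


# Resolved (runtime) protocol -----------------------------------------------

@dataclass
class ProtocolEntry:
    name: str
    plan: PlanDoc
    sequence: SequenceParams
    artifacts: ArtifactDoc
    sat_bands: list[SaturationBand]


@dataclass
class Protocol:
    name: str
    patient_position: str
    coil: CoilProfile
    entries: list[ProtocolEntry]
    document: dict = dc_field(default_factory=dict)


def validate_protocol(document: dict) -> tuple[Protocol | None, list[str]]:
    """Validate a protocol JSON document.

    Returns ``(protocol, [])`` on success or ``(None, errors)`` where each
    error cites the JSON path of the offending field.
    """
    try:
        doc = ProtocolDoc.model_validate(document)
    except Exception as exc:  # pydantic.ValidationError
        errors = []
        for err in getattr(exc, "errors", lambda: [{"loc": (), "msg": str(exc)}])():
            path = "$" + "".join(
                f"[{p}]" if isinstance(p, int) else f".{p}" for p in err["loc"]
            )
            errors.append(f"{path}: {err['msg']}")
        return None, errors
    entries = [
        ProtocolEntry(
            name=e.name,
            plan=e.plan,
            sequence=e.sequence.to_params(),
            artifacts=e.artifacts,
            sat_bands=[
                SaturationBand(
                    centre=b.centre_mm, normal=b.normal,
                    thickness=b.thickness_mm, suppression=b.suppression,
                )
                for b in e.sat_bands
            ],
        )
        for e in doc.entries
    ]
    return (
        Protocol(
            name=doc.name,
            patient_position=doc.patient_position,
            coil=doc.coil.to_profile(),
            entries=entries,
            document=doc.model_dump(mode="json"),
        ),
        [],
    )


def load_protocol(path: str | Path) -> Protocol:
    """Load and validate a protocol JSON file; raises on any error."""
    protocol, errors = validate_protocol(json.loads(Path(path).read_text()))
    if errors:
        raise ValidationError("invalid protocol:\n  " + "\n  ".join(errors))
    assert protocol is not None
    return protocol


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class EntryResult:
    name: str
    images: np.ndarray  # (n_slices, N_f, N_p) magnitude stack at nominal FOV
    geometry: PlanGeometry
    kspace: list[np.ndarray] | None = None  # optional per-slice |k| dumps


@dataclass
class SessionResult:
    entries: dict[str, EntryResult]
    provenance: dict


def _resolve_plan(entry: ProtocolEntry, model: AnatomicalModel) -> PlanGeometry:
    p = entry.plan
    return canonical_plan(
        p.kind,
        model,
        matrix=p.matrix,
        fov=p.fov_mm,
        thickness=p.thickness_mm,
        separation=p.separation_mm,
        n_slices=p.n_slices,
        phase_oversampling=p.phase_oversampling,
        swap_encoding=p.swap_encoding,
        centre=None if p.centre_mm is None else np.asarray(p.centre_mm),
    )


def _simulate_entry(
    entry: ProtocolEntry,
    model: AnatomicalModel,
    coil: CoilProfile,
    seed: int,
    dump_kspace: bool = False,
) -> EntryResult:
    geom = _resolve_plan(entry, model)
    stack = reslice(model, geom)
    contrast = contrast_stack(stack, entry.sequence, bands=entry.sat_bands, coil=coil)
    art = entry.artifacts
    images = []
    kdumps: list[np.ndarray] = []
    for s in range(geom.n_slices):
        k = ksp.forward_kspace(contrast[s], geometry=geom)
        if entry.sequence.family == "FSE":
            k = ksp.apply_etl_attenuation(k, stack, entry.sequence, slice_idx=s)
        if art.motion.kind == "periodic" and art.motion.amplitude_mm > 0:
            k = ksp.add_motion(k, art.motion.amplitude_mm, art.motion.period_lines, geom)
        dc = ksp.dc_index(k.data.shape)
        for spike in art.spikes:
            loc = (dc[0] + spike.offset[0], dc[1] + spike.offset[1])
            amp = spike.amplitude * np.exp(1j * np.deg2rad(spike.phase_deg))
            k = ksp.add_spike(k, loc, amp)
        if art.thermal_sigma > 0:
            sub = ksp.derive_seed(seed, f"{entry.name}/slice{s}/thermal")
            k = ksp.add_thermal_noise(k, art.thermal_sigma, sub)
        if dump_kspace:
            kdumps.append(np.abs(k.data))
        if art.half_fourier.enabled:
            img = ksp.half_fourier_recon(k, art.half_fourier.fraction, art.half_fourier.overscan_lines)
        else:
            img = ksp.inverse_recon(k)
        img = ksp.apply_wraparound(img, geom, wraparound_on=art.wraparound_on)
        images.append(img)
    return EntryResult(
        name=entry.name,
        images=np.stack(images),
        geometry=geom,
        kspace=kdumps if dump_kspace else None,
    )


def run_protocol(
    model: AnatomicalModel,
    protocol: Protocol,
    seed: int = 0,
    dump_kspace: bool = False,
) -> SessionResult:
    """Execute every protocol entry in order; bit-reproducible given the seed.

    Any stage's validation error is re-raised annotated with the entry name
    and stage, so a misconfigured entry is easy to locate.
    """
    model.validate()
    results: dict[str, EntryResult] = {}
    for entry in protocol.entries:
        try:
            results[entry.name] = _simulate_entry(entry, model, protocol.coil, seed, dump_kspace)
        except ValidationError as exc:
            raise ValidationError(f"entry {entry.name!r}: {exc}") from exc
    provenance = {
        "software": {"name": "mrisim", "version": _pkg_version},
        "protocol": protocol.document or {"name": protocol.name},
        "patient_position": protocol.patient_position,
        "seed": seed,
        "model_shape": list(model.shape),
        "model_spacing_mm": model.spacing.tolist(),
    }
    return SessionResult(entries=results, provenance=provenance)


def write_session(session: SessionResult, out_dir: str | Path) -> Path:
    """Write each entry's magnitude stack as NIfTI-1 plus a provenance sidecar.

    The NIfTI affine carries the plan's orientation, origin and pixel size,
    so viewers place the stack correctly in world space.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, res in session.entries.items():
        g = res.geometry
        df, dp = g.pixel_spacing()
        affine = np.eye(4)
        affine[:3, 0] = g.freq_axis * df
        affine[:3, 1] = g.phase_axis * dp
        affine[:3, 2] = g.slice_axis * g.slice_separation
        # world position of voxel (0, 0, 0): pixel centre of the first voxel
        affine[:3, 3] = g.world_coordinates(0)[0, 0] if g.matrix_phase_eff == g.matrix_phase else (
            g.centre
            + ((0.5 / g.matrix_freq) - 0.5) * g.fov_freq * g.freq_axis
            + ((0.5 / g.matrix_phase) - 0.5) * g.fov_phase * g.phase_axis
            - ((g.n_slices - 1) / 2.0) * g.slice_separation * g.slice_axis
        )
        vol = np.moveaxis(res.images, 0, -1)  # (freq, phase, slice)
        nib.save(nib.Nifti1Image(vol, affine), out_dir / f"{name}.nii")
        if res.kspace is not None:
            for s, kmag in enumerate(res.kspace):
                np.savetxt(out_dir / f"{name}_kspace_slice{s:02d}.txt", kmag)
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(session.provenance, indent=2))
    return prov_path
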