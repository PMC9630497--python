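"""Low-level biofluid data fusion: plasma + saliva spectral stitching.

Each patient's mean plasma spectrum and mean saliva spectrum are
concatenated (plasma first, saliva second) into one fused trace on an
arbitrary integer axis 1..2L. With the native 847-point fingerprint grid
per fluid the fused axis runs 1..1694. The physical wavenumber axis is
deliberately abandoned at this step; downstream peak reporting maps fused
indices back to each fluid's cm^-1 grid through ``segment_boundary``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .spectra import Cohort, Spectrum, SpectrumMeta

__all__ = ["FusionError", "fuse", "split_fused", "build_fused_cohort", "fused_index_to_shift"]


class FusionError(ValueError):
    """Plasma/saliva pair cannot be stitched."""


def fuse(plasma: Spectrum, saliva: Spectrum, renormalize: bool = False) -> Spectrum:
    """Concatenate a patient's mean plasma and saliva spectra.

    Returns a Spectrum with integer axis 1..2L, intensities
    ``concat(plasma, saliva)``, biofluid ``"fused"`` and axis unit
    ``"index"``. The stitch point L is recoverable as ``len(fused) // 2``
    and via :func:`split_fused`.

    ``renormalize=True`` rescales the fused trace to unit L2 norm. Off by
    default: the stitched values are the already-processed intensities,
    and because both halves are unit-norm the fused norm is exactly
    sqrt(2) for every patient, so re-normalization divides all fused
    spectra by one common constant and cannot change any scale-invariant
    downstream model.
    """
    if len(plasma) != len(saliva):
        raise FusionError(
            f"length mismatch: plasma {len(plasma)} vs saliva {len(saliva)} points"
        )
    if plasma.meta.patient_id != saliva.meta.patient_id:
        raise FusionError(
            f"pairing error: plasma patient {plasma.meta.patient_id!r} "
            f"vs saliva patient {saliva.meta.patient_id!r}"
        )
    if plasma.meta.biofluid != "plasma" or saliva.meta.biofluid != "saliva":
        raise FusionError("arguments must be (plasma, saliva) in that order")
    if plasma.meta.state != saliva.meta.state:
        raise FusionError("plasma and saliva must share the same state")
    L = len(plasma)
    intensities = np.concatenate([plasma.intensities, saliva.intensities])
    if renormalize:
        intensities = intensities / np.linalg.norm(intensities)
    axis = np.arange(1, 2 * L + 1, dtype=float)
    meta = SpectrumMeta(
        patient_id=plasma.meta.patient_id,
        biofluid="fused",
        state=plasma.meta.state,
        spot="mean",
        label=plasma.meta.label,
        stage=plasma.meta.stage,
        axis_unit="index",
        source=f"fused({plasma.meta.source}|{saliva.meta.source})",
    )
    return Spectrum(axis=axis, intensities=intensities, meta=meta)


def segment_boundary(fused: Spectrum) -> int:
    """Stitch point L of a fused trace (plasma occupies indices 1..L)."""
    if fused.meta.biofluid != "fused":
        raise FusionError("not a fused spectrum")
    if len(fused) % 2:
        raise FusionError("fused spectrum has odd length")
    return len(fused) // 2


def split_fused(
    fused: Spectrum, plasma_axis: np.ndarray, saliva_axis: np.ndarray
) -> tuple[Spectrum, Spectrum]:
    """Lossless inverse of :func:`fuse`, given the original fluid axes."""
    L = segment_boundary(fused)
    if len(plasma_axis) != L or len(saliva_axis) != L:
        raise FusionError("fluid axes do not match the segment boundary")
    pm = replace(fused.meta, biofluid="plasma", axis_unit="cm-1", source="")
    sm = replace(fused.meta, biofluid="saliva", axis_unit="cm-1", source="")
    plasma = Spectrum(np.asarray(plasma_axis, float), fused.intensities[:L], pm)
    saliva = Spectrum(np.asarray(saliva_axis, float), fused.intensities[L:], sm)
    return plasma, saliva


def fused_index_to_shift(
    index: float, boundary: int, plasma_axis: np.ndarray, saliva_axis: np.ndarray
) -> tuple[str, float]:
    """Map a fused 1-based index back to (biofluid, Raman shift cm^-1)."""
    i = int(round(index))
    if not 1 <= i <= 2 * boundary:
        raise FusionError(f"fused index {index} outside 1..{2 * boundary}")
    if i <= boundary:
        return "plasma", float(plasma_axis[i - 1])
    return "saliva", float(saliva_axis[i - boundary - 1])


def build_fused_cohort(
    c: Cohort, state: str = "dried", renormalize: bool = False
) -> Cohort:
    """Fuse every patient that has both per-patient mean fluids in ``state``.

    Patients missing either fluid are excluded and listed in the cohort
    provenance under ``fusion_excluded``.
    """
    plasma = {s.meta.patient_id: s for s in c.select(biofluid="plasma", state=state, spot="mean")}
    saliva = {s.meta.patient_id: s for s in c.select(biofluid="saliva", state=state, spot="mean")}
    both = sorted(set(plasma) & set(saliva))
    excluded = sorted((set(plasma) | set(saliva)) - set(both))
    if not both:
        raise FusionError(f"no patient has both fluids in state {state!r}")
    fused = [fuse(plasma[p], saliva[p], renormalize=renormalize) for p in both]
    patients = c.patients[c.patients["patient_id"].isin(both)].reset_index(drop=True)
    prov = dict(c.provenance)
    prov["fusion_excluded"] = excluded
    prov["fusion_state"] = state
    return Cohort(spectra=fused, patients=patients, provenance=prov)
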