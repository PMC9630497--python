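"""Core spectral data model and text-file I/O.

A :class:`Spectrum` is one measured or derived Raman trace: a strictly
increasing axis (Raman shift in cm^-1, or dimensionless integer indices for
fused traces), a same-length intensity vector, and provenance metadata.
A :class:`Cohort` is a keyed collection of spectra plus the patient table.

Spectra travel as plain two-column text files (axis, intensity), the format
typically exported from instrument software. Cohorts are described by a CSV
manifest mapping each file to (patient_id, biofluid, state, spot, label,
stage).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BIOFLUIDS",
    "STATES",
    "LABELS",
    "STAGES",
    "SpectrumMeta",
    "Spectrum",
    "Cohort",
    "SpectrumParseError",
    "CohortError",
    "read_spectrum_txt",
    "write_spectrum_txt",
    "load_cohort",
]

BIOFLUIDS = ("plasma", "saliva", "fused")
STATES = ("native", "dried")
LABELS = ("cancer", "control", "unknown")
STAGES = ("I", "II", "III", "IV", "none")


class SpectrumParseError(ValueError):
    """A spectrum text file could not be parsed."""


class CohortError(ValueError):
    """A cohort manifest or its files violate cohort invariants."""


@dataclass(frozen=True)
class SpectrumMeta:
    """Provenance metadata attached to every spectrum.

    ``spot`` is a 1-based acquisition-spot index, or the string ``"mean"``
    for a per-patient spot average. ``axis_unit`` distinguishes physical
    Raman-shift axes (``"cm-1"``) from the arbitrary integer index axis of
    fused traces (``"index"``).
    """

    patient_id: str = ""
    biofluid: str = "plasma"
    state: str = "dried"
    spot: int | str = 1
    label: str = "unknown"
    stage: str = "none"
    axis_unit: str = "cm-1"
    source: str = ""

    def __post_init__(self) -> None:
        if self.biofluid not in BIOFLUIDS:
            raise ValueError(f"biofluid must be one of {BIOFLUIDS}, got {self.biofluid!r}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if isinstance(self.spot, str):
            if self.spot != "mean":
                raise ValueError(f'spot must be an integer >= 1 or "mean", got {self.spot!r}')
        elif self.spot < 1:
            raise ValueError(f"spot index must be >= 1, got {self.spot}")

    @property
    def key(self) -> tuple[str, str, str, int | str]:
        return (self.patient_id, self.biofluid, self.state, self.spot)


@dataclass(frozen=True)
class Spectrum:
    """One Raman trace: strictly increasing axis + finite intensities."""

    axis: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", inten)
        if axis.ndim != 1 or inten.ndim != 1:
            raise ValueError("axis and intensities must be 1-D")
        if axis.size != inten.size:
            raise ValueError(f"axis length {axis.size} != intensities length {inten.size}")
        if axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(inten)):
            raise ValueError("axis and intensities must be finite")
        if not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.axis.size)

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def with_meta(self, **changes) -> "Spectrum":
        return replace(self, meta=replace(self.meta, **changes))

    def allclose(self, other: "Spectrum", rtol: float = 1e-9, atol: float = 0.0) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.axis, other.axis, rtol=rtol, atol=atol)
            and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol)
        )


@dataclass
class Cohort:
    """Keyed spectrum collection + patient table + ingestion provenance.

    Invariants enforced at construction: (patient_id, biofluid, state, spot)
    keys are unique; every spectrum's patient appears in the patient table;
    all spectra sharing a (biofluid, state) group sit on an identical axis,
    which is what later matrix assembly requires.
    """

    spectra: list[Spectrum]
    patients: pd.DataFrame  # columns: patient_id, label, stage
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"patient_id", "label", "stage"}
        missing = required - set(self.patients.columns)
        if missing:
            raise CohortError(f"patient table missing columns {sorted(missing)}")
        keys = [s.meta.key for s in self.spectra]
        if len(keys) != len(set(keys)):
            seen: set = set()
            dupes = sorted({k for k in keys if k in seen or seen.add(k)})  # type: ignore[func-returns-value]
            raise CohortError(f"duplicate spectrum keys: {dupes[:5]}")
        known = set(self.patients["patient_id"])
        orphans = sorted({s.meta.patient_id for s in self.spectra} - known)
        if orphans:
            raise CohortError(f"spectra reference unknown patients: {orphans[:5]}")
        self._check_axes()

    def _check_axes(self) -> None:
        ref_axes: dict[tuple[str, str], np.ndarray] = {}
        bad: list[str] = []
        for s in self.spectra:
            group = (s.meta.biofluid, s.meta.state)
            ref = ref_axes.setdefault(group, s.axis)
            if s.axis.shape != ref.shape or not np.array_equal(s.axis, ref):
                bad.append(s.meta.source or str(s.meta.key))
        if bad:
            raise CohortError(f"axis mismatch within biofluid+state group(s): {bad[:5]}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def select(self, **meta_filters) -> list[Spectrum]:
        """Spectra whose metadata match every given field value."""
        out = []
        for s in self.spectra:
            if all(getattr(s.meta, k) == v for k, v in meta_filters.items()):
                out.append(s)
        return out

    def label_of(self, patient_id: str) -> str:
        row = self.patients.loc[self.patients["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        return str(row["label"].iloc[0])

    def to_matrix(self, biofluid: str, state: str, spot: int | str = "mean"):
        """Assemble a (patients x wavelengths) matrix for one group.

        Returns ``(X, patient_ids, labels, axis)`` with rows sorted by
        patient_id for determinism.
        """
        group = sorted(
            self.select(biofluid=biofluid, state=state, spot=spot),
            key=lambda s: s.meta.patient_id,
        )
        if not group:
            raise CohortError(f"no spectra for ({biofluid}, {state}, spot={spot!r})")
        X = np.vstack([s.intensities for s in group])
        pids = [s.meta.patient_id for s in group]
        labels = [self.label_of(p) for p in pids]
        return X, pids, labels, group[0].axis


def _parse_rows(lines: Iterable[str], name: str) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{name}: line {lineno}: expected 2 columns, got {len(parts)}"
            )
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{name}: line {lineno}: non-numeric value") from exc
    if len(xs) < 2:
        raise SpectrumParseError(f"{name}: fewer than 2 data rows")
    return np.asarray(xs), np.asarray(ys)


def read_spectrum_txt(path: str | Path, meta: SpectrumMeta | None = None) -> Spectrum:
    """Read a two-column (axis, intensity) text spectrum.

    Accepts whitespace-, tab- or comma-delimited columns and '#' comment
    lines. Rows are re-sorted into ascending axis order with intensities
    kept paired.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        axis, inten = _parse_rows(fh, path.name)
    order = np.argsort(axis, kind="stable")
    axis, inten = axis[order], inten[order]
    meta = meta or SpectrumMeta()
    meta = replace(meta, source=str(path))
    return Spectrum(axis=axis, intensities=inten, meta=meta)


def write_spectrum_txt(s: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as tab-separated two-column text at full precision.

    Integer-index axes (fused traces) are written as integers; physical
    axes use repr-round-trip float formatting so that read -> write is
    byte-stable.
    """
    path = Path(path)
    buf = io.StringIO()
    integer_axis = s.meta.axis_unit == "index" or np.all(s.axis == np.round(s.axis))
    for x, y in zip(s.axis, s.intensities):
        xs = str(int(x)) if integer_axis else repr(float(x))
        buf.write(f"{xs}\t{float(y)!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


MANIFEST_COLUMNS = ("patient_id", "biofluid", "state", "spot", "label", "stage", "filename")


def load_cohort(manifest: str | Path, data_dir: str | Path | None = None) -> Cohort:
    """Load a cohort from a manifest CSV plus a directory of spectrum files.

    The manifest must have columns ``patient_id, biofluid, state, spot,
    label, stage, filename``. ``data_dir`` defaults to the manifest's
    directory. Duplicate keys, missing files and within-group axis
    mismatches all raise :class:`CohortError`.
    """
    manifest = Path(manifest)
    data_dir = Path(data_dir) if data_dir is not None else manifest.parent
    table = pd.read_csv(manifest, dtype={"patient_id": str, "stage": str})
    missing_cols = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing_cols:
        raise CohortError(f"manifest missing columns {sorted(missing_cols)}")

    spectra: list[Spectrum] = []
    log: list[str] = []
    for _, row in table.iterrows():
        fpath = data_dir / str(row["filename"])
        if not fpath.exists():
            raise CohortError(f"missing spectrum file: {row['filename']}")
        stage = str(row["stage"]) if pd.notna(row["stage"]) and str(row["stage"]) else "none"
        spot_raw = row["spot"]
        spot: int | str = spot_raw if spot_raw == "mean" else int(spot_raw)
        meta = SpectrumMeta(
            patient_id=str(row["patient_id"]),
            biofluid=str(row["biofluid"]),
            state=str(row["state"]),
            spot=spot,
            label=str(row["label"]),
            stage=stage if stage != "nan" else "none",
        )
        spectra.append(read_spectrum_txt(fpath, meta=meta))
        log.append(f"loaded {fpath.name} -> {meta.key}")

    patients = (
        table[["patient_id", "label", "stage"]]
        .fillna({"stage": "none"})
        .drop_duplicates(subset="patient_id")
        .reset_index(drop=True)
    )
    patients["patient_id"] = patients["patient_id"].astype(str)
    return Cohort(
        spectra=spectra,
        patients=patients,
        provenance={"manifest": str(manifest), "log": log},
    )


def cohort_from_spectra(spectra: list[Spectrum], patients: Mapping[str, tuple[str, str]] | pd.DataFrame, **prov) -> Cohort:
    """Build a Cohort from in-memory spectra.

    ``patients`` is either a DataFrame or a mapping
    ``patient_id -> (label, stage)``.
    """
    if not isinstance(patients, pd.DataFrame):
        patients = pd.DataFrame(
            [{"patient_id": p, "label": l, "stage": st} for p, (l, st) in patients.items()]
        )
    return Cohort(spectra=list(spectra), patients=patients, provenance=dict(prov))
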