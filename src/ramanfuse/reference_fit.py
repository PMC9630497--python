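"""Reference-spectrum decomposition, difference spectra and peak assignment.

A mean biofluid spectrum is modelled as a non-negative combination of
measured metabolite standard spectra riding on a smooth background:

    y  ~=  sum_k c_k * ref_k  +  baseline,   c_k >= 0

solved by alternating (a) non-negative least squares for the coefficients
given the current baseline and (b) an asymmetric penalized-least-squares
baseline of the coefficient residual, until the coefficients stabilise.
The coefficient vector measures how much each metabolite contributes to
the biofluid signal; R-squared on the baseline-subtracted signal grades
the fit.

Also here: hierarchical clustering of samples in top-PC space, the
cancer-minus-control difference spectrum, and assignment of its extrema
to a shipped table of diagnostic Raman bands with literature functional
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .preprocess import baseline_asls, whittaker_smooth
from .spectra import Cohort, Spectrum

__all__ = [
    "ReferenceLibrary",
    "FitResult",
    "fit_references",
    "compare_fit_quality",
    "difference_spectrum",
    "PeakAssignment",
    "load_peak_table",
    "assign_peaks",
    "cluster_pc_space",
]


@dataclass
class ReferenceLibrary:
    """Named metabolite standard spectra resampled onto one common axis."""

    axis: np.ndarray
    entries: dict[str, np.ndarray]          # name -> intensities on `axis`
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, float)
        for name, y in self.entries.items():
            y = np.asarray(y, float)
            if y.shape != self.axis.shape:
                raise ValueError(f"reference {name!r} not on the common axis")
            self.entries[name] = y

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def matrix(self) -> np.ndarray:
        """(n_points, n_refs) design matrix, columns unit-normalized."""
        R = np.column_stack([self.entries[n] for n in self.names])
        norms = np.linalg.norm(R, axis=0)
        if (norms == 0).any():
            raise ValueError("a reference spectrum is all zero")
        return R / norms

    @classmethod
    def from_spectra(cls, spectra: dict[str, Spectrum], axis: np.ndarray | None = None,
                     classes: dict[str, str] | None = None) -> "ReferenceLibrary":
        """Build a library, linearly resampling each standard onto ``axis``
        (default: the first spectrum's axis)."""
        if not spectra:
            raise ValueError("empty reference library")
        names = list(spectra)
        axis = np.asarray(axis if axis is not None else spectra[names[0]].axis, float)
        entries = {
            n: np.interp(axis, s.axis, s.intensities) for n, s in spectra.items()
        }
        return cls(axis=axis, entries=entries, classes=classes or {})


@dataclass
class FitResult:
    """Non-negative reference decomposition of one spectrum."""

    coefficients: pd.Series       # c_k >= 0, indexed by reference name
    baseline: np.ndarray
    fitted: np.ndarray            # baseline + sum_k c_k ref_k
    residual: np.ndarray          # target - fitted
    r_squared: float              # on the baseline-subtracted signal
    converged: bool
    n_iter: int


def fit_references(
    target: Spectrum,
    lib: ReferenceLibrary,
    lam: float = 1e5,
    p: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> FitResult:
    """Alternating NNLS + penalized-least-squares baseline decomposition.

    Starts from the asymmetric-least-squares baseline z = AsLS(y) (peaks
    present, so asymmetry is needed), then iterates: c = argmin_{c>=0}
    ||(y - z) - R c||^2 followed by a symmetric Whittaker re-estimate
    z = smooth(y - R c), until the coefficient vector changes by less than
    ``tol`` (max-abs relative to the largest coefficient) or ``max_iter``
    sweeps. The refinement step is symmetric because once the reference
    part is subtracted the residual is baseline + noise with no one-sided
    peak excursions; keeping the asymmetric weights there biases the
    baseline below the noise floor and lets the non-negative coefficients
    absorb the gap, which diverges. References are unit-normalized so
    coefficients are comparable contribution weights.
    """
    if not lib.names:
        raise ValueError("empty reference library")
    if target.axis.shape != lib.axis.shape or not np.allclose(target.axis, lib.axis):
        # resample references onto the target grid
        lib = ReferenceLibrary(
            axis=target.axis,
            entries={
                n: np.interp(target.axis, lib.axis, y) for n, y in lib.entries.items()
            },
            classes=lib.classes,
        )
    y = target.intensities
    R = lib.matrix()
    z = baseline_asls(y, lam, p)
    c_prev = np.zeros(R.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        c, _ = nnls(R, y - z)
        z = whittaker_smooth(y - R @ c, lam)
        scale = max(float(c.max()), 1e-30)
        if np.max(np.abs(c - c_prev)) < tol * scale:
            converged = True
            c_prev = c
            break
        c_prev = c
    c = c_prev
    ref_part = R @ c
    fitted = ref_part + z
    signal = y - z
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    ss_res = float(np.sum((signal - ref_part) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")
    return FitResult(
        coefficients=pd.Series(c, index=lib.names, name="coefficient"),
        baseline=z,
        fitted=fitted,
        residual=y - fitted,
        r_squared=r2,
        converged=converged,
        n_iter=it,
    )


def compare_fit_quality(
    cancer_avg: Spectrum, control_avg: Spectrum, lib: ReferenceLibrary, **kw
) -> tuple[FitResult, FitResult, float]:
    """Fit both class averages against the library; returns
    (cancer fit, control fit, delta R^2 = R2_cancer - R2_control)."""
    fc = fit_references(cancer_avg, lib, **kw)
    fn = fit_references(control_avg, lib, **kw)
    return fc, fn, fc.r_squared - fn.r_squared


def difference_spectrum(c: Cohort, **select) -> Spectrum:
    """Pointwise mean(cancer) - mean(control) over matching spectra.

    Extra keyword filters (biofluid=..., state=..., spot=...) restrict the
    spectra considered; both classes must be present on a common axis.
    """
    cancer = [s for s in c.select(**select) if c.label_of(s.meta.patient_id) == "cancer"]
    control = [s for s in c.select(**select) if c.label_of(s.meta.patient_id) == "control"]
    if not cancer or not control:
        raise ValueError("difference spectrum needs >= 1 spectrum per class")
    axis = cancer[0].axis
    mc = np.vstack([s.intensities for s in cancer]).mean(axis=0)
    mn = np.vstack([s.intensities for s in control]).mean(axis=0)
    meta = cancer[0].meta
    out = Spectrum(axis=axis, intensities=mc - mn, meta=meta)
    return out.with_meta(patient_id="", label="unknown", source="difference(cancer-control)")


@dataclass(frozen=True)
class PeakAssignment:
    position: float               # observed extremum position (cm^-1)
    direction: str                # '+' or '-' from the sign of the difference
    assignment: str               # functional-group label, or 'unassigned'
    table_position: float | None  # matched library band (cm^-1) or None
    distance: float | None        # |observed - table| or None


def load_peak_table() -> pd.DataFrame:
    """The shipped table of diagnostic Raman bands (position, direction in
    cancer, functional-group assignment, biofluid segment)."""
    with resources.files("ramanfuse.data").joinpath("peak_table.csv").open() as fh:
        return pd.read_csv(fh)


def assign_peaks(
    diff: Spectrum,
    table: pd.DataFrame | None = None,
    prominence: float | None = None,
    tolerance: float = 6.0,
) -> list[PeakAssignment]:
    """Match extrema of a difference spectrum to known diagnostic bands.

    Local extrema of |diff| above the prominence threshold (default 2x the
    MAD-based robust noise scale of the difference trace) are matched to
    the nearest table band within ``tolerance`` cm^-1; ties break toward
    the lower-wavenumber band. Direction is the sign of the difference at
    the extremum. Unmatched extrema are reported as 'unassigned'.
    """
    table = load_peak_table() if table is None else table
    y = diff.intensities
    if prominence is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        prominence = 2.0 * 1.4826 * mad if mad > 0 else 0.0
    peaks, _ = find_peaks(np.abs(y), prominence=prominence if prominence > 0 else None)
    positions = np.sort(np.asarray(table["position_cm1"], float))
    out: list[PeakAssignment] = []
    for i in peaks:
        pos = float(diff.axis[i])
        direction = "+" if y[i] > 0 else "-"
        dists = np.abs(positions - pos)
        j = int(np.argmin(dists))  # argmin takes first minimum -> lower cm^-1 tie-break
        if dists[j] <= tolerance:
            row = table.loc[table["position_cm1"] == positions[j]].iloc[0]
            out.append(
                PeakAssignment(
                    position=pos,
                    direction=direction,
                    assignment=str(row["assignment"]),
                    table_position=float(positions[j]),
                    distance=float(dists[j]),
                )
            )
        else:
            out.append(
                PeakAssignment(
                    position=pos,
                    direction=direction,
                    assignment="unassigned",
                    table_position=None,
                    distance=None,
                )
            )
    return out


def cluster_pc_space(
    scores: np.ndarray, n_clusters: int = 2, method: str = "ward"
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of samples in top-PC space.

    ``scores`` is (samples x top PCs), typically the first five PC scores.
    Euclidean distances; Ward linkage by default. Returns
    (linkage matrix, flat labels for an ``n_clusters`` cut).
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] < 2:
        raise ValueError("clustering needs >= 2 samples")
    Z = linkage(scores, method=method, metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels
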