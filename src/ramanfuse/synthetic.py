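"""Synthetic Raman cohorts and metabolite tables with known ground truth.

The generator emulates the statistical structure of a plasma/saliva liquid
biopsy Raman study so every pipeline stage is testable without measured
data: ~850-point fingerprint-region spectra built from pseudo-Voigt peaks
on smooth fluorescence backgrounds, class-dependent peak intensities whose
signs follow the shipped diagnostic band table, patient- and spot-level
variance components, heteroscedastic detector noise (native liquids
noisier than dried drops), occasional cosmic-ray spikes, and the
class-informative signal deliberately split between the two biofluids —
plasma and saliva carry disjoint informative bands, which is what gives
spectral fusion something to gain.

Metabolite feature tables are lognormal with planted fold changes on a
handful of named metabolites against a background of class-independent
noise metabolites.

All randomness flows from a single seed through per-patient substreams, so
output is bit-reproducible and adding a patient does not perturb earlier
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsda import FeatureTable
from .reference_fit import ReferenceLibrary
from .spectra import Cohort, Spectrum, SpectrumMeta
from .reference_fit import load_peak_table

__all__ = [
    "PeakSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_peak_library",
    "simulate_cohort",
    "simulate_feature_table",
    "make_reference_library",
    "TABLE1_METABOLITES",
]

# the ten panel metabolites (plasma panel first, then saliva panel)
TABLE1_METABOLITES = {
    "valine": "Organic acids and derivatives",
    "histidine": "Organic acids and derivatives",
    "tryptophan": "Organo-heterocyclic compounds",
    "9-myristoleate": "Lipids and lipid-like molecules",
    "malonic acid": "Organic acids and derivatives",
    "trans-4-hydroxyproline": "Organic acids and derivatives",
    "propane-1,3-diol": "Organic oxygen compounds",
    "3-phosphoglycerate": "Organic oxygen compounds",
    "1-monopalmitin": "Lipids and lipid-like molecules",
    "azelaic acid": "Lipids and lipid-like molecules",
}


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: centre/width in cm^-1, base amplitude, and the
    signed fractional intensity change ``delta`` in cancer (0 = uninformative)."""

    center: float
    width: float
    amplitude: float
    delta: float = 0.0


def pseudo_voigt(x: np.ndarray, center: float, width: float, eta: float = 0.5) -> np.ndarray:
    """50/50 Gaussian/Lorentzian band profile with FWHM ``width``, height 1."""
    hw = width / 2.0
    lor = 1.0 / (1.0 + ((x - center) / hw) ** 2)
    gau = np.exp(-np.log(2.0) * ((x - center) / hw) ** 2)
    return eta * lor + (1.0 - eta) * gau


def default_peak_library(delta: float = 0.12) -> dict[str, list[PeakSpec]]:
    """Default per-fluid band libraries.

    Informative bands take their positions and signs from the shipped
    diagnostic band table (plasma segment bands for plasma, saliva segment
    bands for saliva, hence disjoint between fluids); each fluid also
    carries uninformative structural bands shared by both classes. ``delta``
    scales the magnitude of every informative effect. Plasma has fewer
    informative bands than saliva, so its per-band effect is boosted to
    keep the two fluids' single-fluid diagnostic power comparable.
    """
    table = load_peak_table()
    widths = {  # condensed-phase bandwidths, cm^-1
        488: 14, 492: 14, 543: 12, 608: 12, 679: 12, 746: 12, 814: 12,
        837: 12, 915: 14, 948: 12, 1000: 9, 1053: 14, 1328: 18, 1437: 20,
        1445: 20, 1526: 16, 1639: 22, 1658: 22, 1704: 18,
    }
    amps = {  # base band amplitudes (arbitrary counts scale)
        488: 0.8, 492: 0.7, 543: 0.4, 608: 0.45, 679: 0.4, 746: 0.45,
        814: 0.4, 837: 0.5, 915: 0.4, 948: 0.45, 1000: 0.9, 1053: 0.5,
        1328: 0.6, 1437: 0.9, 1445: 0.9, 1526: 0.5, 1639: 0.9, 1658: 1.0,
        1704: 0.5,
    }
    lib: dict[str, list[PeakSpec]] = {"plasma": [], "saliva": []}
    n_per_fluid = table.groupby("segment")["position_cm1"].count()
    for _, row in table.iterrows():
        fluid = str(row["segment"])
        pos = int(row["position_cm1"])
        sign = 1.0 if row["direction"] == "+" else -1.0
        # equalize total class-signal energy between the fluids
        boost = float(np.sqrt(n_per_fluid.max() / n_per_fluid[fluid]))
        lib[fluid].append(
            PeakSpec(center=float(pos), width=float(widths[pos]),
                     amplitude=amps[pos], delta=sign * delta * boost)
        )
    # uninformative structural bands, distinct per fluid
    lib["plasma"] += [
        PeakSpec(720, 14, 0.5), PeakSpec(890, 16, 0.4), PeakSpec(1090, 16, 0.6),
        PeakSpec(1250, 20, 0.7), PeakSpec(1340, 16, 0.5), PeakSpec(1580, 16, 0.4),
    ]
    lib["saliva"] += [
        PeakSpec(620, 12, 0.4), PeakSpec(780, 14, 0.5), PeakSpec(1160, 18, 0.5),
        PeakSpec(1260, 20, 0.6), PeakSpec(1550, 16, 0.4),
    ]
    return lib


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the cohort design the pipeline targets: 34 cancer +
    19 benign-control patients, two biofluids, 5 acquisition spots per
    sample, an 847-point grid over the 400-1800 cm^-1 fingerprint region,
    and native measurements noisier than dried ones.
    """

    n_cancer: int = 34
    n_control: int = 19
    spots_per_sample: int = 5
    grid_lo: float = 400.0
    grid_hi: float = 1800.0
    n_points: int = 847
    states: tuple[str, ...] = ("native", "dried")
    peak_delta: float = 0.10           # informative-band effect magnitude
    baseline_scale: float = 5.0        # fluorescence amplitude vs peak scale
    noise_sd_dried: float = 0.025      # detector noise, counts scale
    noise_sd_native: float = 0.05
    patient_sd: float = 0.08           # lognormal sigma, patient random effect
    peak_jitter: float = 0.15          # lognormal sigma, per-patient band jitter
    spot_jitter: float = 0.02          # lognormal sigma, per-spot gain
    spike_rate: float = 0.02           # per-spectrum cosmic-ray probability
    seed: int = 0
    peaks: dict[str, list[PeakSpec]] | None = None

    def __post_init__(self) -> None:
        if self.n_cancer < 1 or self.n_control < 1:
            raise ValueError("patient counts must be >= 1")
        if self.spots_per_sample < 1:
            raise ValueError("spots_per_sample must be >= 1")
        if not (self.grid_lo < self.grid_hi and self.n_points >= 8):
            raise ValueError("invalid spectral grid")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")
        for st in self.states:
            if st not in ("native", "dried"):
                raise ValueError(f"unknown state {st!r}")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.grid_lo, self.grid_hi, self.n_points)

    def noise_sd(self, state: str) -> float:
        return self.noise_sd_native if state == "native" else self.noise_sd_dried


@dataclass
class GroundTruth:
    """Everything needed to score detection tasks on a synthetic cohort."""

    peaks: dict[str, list[PeakSpec]]
    patient_effects: dict[str, float]
    spikes: dict = field(default_factory=dict)  # spectrum key -> spike indices
    config: SyntheticConfig | None = None

    @property
    def spiked_keys(self) -> list:
        return [k for k, v in self.spikes.items() if len(v)]


def _baseline(rng: np.random.Generator, x: np.ndarray, scale: float) -> np.ndarray:
    """Random smooth fluorescence background, strictly positive."""
    u = (x - x[0]) / (x[-1] - x[0])
    c0 = rng.uniform(0.6, 1.2)
    c1 = rng.uniform(-0.5, 0.3)
    c2 = rng.uniform(-0.3, 0.3)
    centre = rng.uniform(0.1, 0.9)
    width = rng.uniform(0.25, 0.6)
    hump = rng.uniform(0.0, 0.5) * np.exp(-0.5 * ((u - centre) / width) ** 2)
    base = c0 + c1 * u + c2 * u**2 + hump
    return scale * np.maximum(base, 0.05)


def simulate_cohort(cfg: SyntheticConfig | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a full per-spot synthetic cohort plus its ground truth.

    Per spot: intensities = baseline + patient_gain * spot_gain *
    sum_k A_k jitter_k (1 + delta_k * is_cancer) V(x; c_k, w_k) + noise,
    plus an optional 1-3 point cosmic spike of amplitude >= 20x the noise
    SD. Heteroscedastic noise scales with the local clean signal. Patient
    substreams are keyed by (seed, patient index) so the cohort is
    bit-reproducible and stable under appending patients.
    """
    cfg = cfg or SyntheticConfig()
    x = cfg.axis
    peaks = cfg.peaks if cfg.peaks is not None else default_peak_library(cfg.peak_delta)
    # precompute unit band profiles per fluid
    profiles = {
        fluid: np.vstack([pseudo_voigt(x, p.center, p.width) for p in plist])
        for fluid, plist in peaks.items()
    }

    patients: list[dict] = []
    for i in range(cfg.n_cancer):
        patients.append(
            {"patient_id": f"C{i + 1:03d}", "label": "cancer",
             "stage": ("I", "II", "III", "IV")[i % 4]}
        )
    for i in range(cfg.n_control):
        patients.append({"patient_id": f"N{i + 1:03d}", "label": "control", "stage": "none"})

    spectra: list[Spectrum] = []
    truth = GroundTruth(peaks=peaks, patient_effects={}, config=cfg)
    for idx, pat in enumerate(patients):
        rng = np.random.default_rng([cfg.seed, idx])
        is_cancer = pat["label"] == "cancer"
        patient_gain = float(np.exp(rng.normal(0.0, cfg.patient_sd)))
        truth.patient_effects[pat["patient_id"]] = patient_gain
        for fluid in ("plasma", "saliva"):
            plist = peaks[fluid]
            jitter = np.exp(rng.normal(0.0, cfg.peak_jitter, size=len(plist)))
            amp = np.array(
                [p.amplitude * (1.0 + (p.delta if is_cancer else 0.0)) for p in plist]
            ) * jitter
            clean_peaks = amp @ profiles[fluid]
            for state in cfg.states:
                sd = cfg.noise_sd(state)
                for spot in range(1, cfg.spots_per_sample + 1):
                    base = _baseline(rng, x, cfg.baseline_scale)
                    gain = float(np.exp(rng.normal(0.0, cfg.spot_jitter)))
                    clean = base + patient_gain * gain * clean_peaks
                    het = sd * (0.5 + clean / clean.max())
                    y = clean + rng.normal(0.0, 1.0, size=x.size) * het
                    key = (pat["patient_id"], fluid, state, spot)
                    if rng.random() < cfg.spike_rate:
                        width = int(rng.integers(1, 4))
                        pos = int(rng.integers(2, x.size - width - 2))
                        height = rng.uniform(25.0, 60.0) * sd
                        y[pos:pos + width] += height
                        truth.spikes[key] = list(range(pos, pos + width))
                    else:
                        truth.spikes[key] = []
                    meta = SpectrumMeta(
                        patient_id=pat["patient_id"], biofluid=fluid, state=state,
                        spot=spot, label=pat["label"], stage=pat["stage"],
                    )
                    spectra.append(Spectrum(axis=x, intensities=y, meta=meta))

    cohort = Cohort(
        spectra=spectra,
        patients=pd.DataFrame(patients),
        provenance={"generator": "synthetic", "seed": cfg.seed},
    )
    return cohort, truth


DEFAULT_PLANTED = [
    ("valine", 3.0),
    ("histidine", 3.0),
    ("tryptophan", 3.0),
    ("9-myristoleate", 3.0),
    ("malonic acid", 3.0),
]


def simulate_feature_table(
    n_cancer: int = 19,
    n_control: int = 9,
    n_noise: int = 95,
    planted: list[tuple[str, float]] | None = None,
    sigma: float = 0.4,
    seed: int = 0,
) -> tuple[FeatureTable, dict]:
    """Lognormal metabolite table with planted cancer/control fold changes.

    Planted metabolites are multiplied by their fold change in cancer
    samples; noise metabolites are class-independent. Each sample's total
    is jittered by a uniform(0.7, 1.3) gain so total-signal normalisation
    is non-trivial. Default class sizes mirror a 19 + 9 discovery subset.
    Returns (table, truth) where truth lists the planted names and folds.
    """
    planted = DEFAULT_PLANTED if planted is None else planted
    for name, fold in planted:
        if fold <= 0:
            raise ValueError(f"fold change for {name!r} must be > 0")
    rng = np.random.default_rng(seed)
    names = [n for n, _ in planted] + [f"met_{i + 1:03d}" for i in range(n_noise)]
    folds = np.array([f for _, f in planted] + [1.0] * n_noise)
    base_log = rng.normal(2.0, 1.0, size=len(names))
    n = n_cancer + n_control
    labels = np.array(["cancer"] * n_cancer + ["control"] * n_control)
    log_ab = rng.normal(0.0, sigma, size=(n, len(names))) + base_log
    log_ab[: n_cancer] += np.log(folds)
    data = np.exp(log_ab)
    data *= rng.uniform(0.7, 1.3, size=n)[:, None]  # sample-total jitter
    df = pd.DataFrame(data, columns=names,
                      index=[f"S{i + 1:03d}" for i in range(n)])
    annotations = dict(TABLE1_METABOLITES)
    table = FeatureTable(
        data=df, labels=pd.Series(labels, index=df.index, name="label"),
        annotations=annotations,
    )
    truth = {"planted": [n for n, _ in planted],
             "fold_changes": dict(planted), "seed": seed}
    return table, truth


# deterministic band positions for the synthetic metabolite standards
_REFERENCE_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "valine": [(540, 12, 0.6), (948, 10, 1.0), (1320, 16, 0.5), (1450, 18, 0.7)],
    "histidine": [(620, 12, 0.5), (1004, 10, 0.8), (1160, 14, 0.6), (1570, 16, 0.9)],
    "tryptophan": [(760, 10, 1.0), (877, 10, 0.7), (1016, 10, 0.6), (1556, 14, 0.9)],
    "9-myristoleate": [(1065, 14, 0.7), (1302, 16, 0.9), (1440, 18, 1.0), (1655, 18, 0.8)],
    "malonic acid": [(640, 12, 0.5), (910, 12, 0.8), (1430, 16, 0.7), (1720, 16, 0.4)],
    "trans-4-hydroxyproline": [(850, 12, 0.9), (1043, 12, 0.6), (1380, 16, 0.5)],
    "propane-1,3-diol": [(865, 12, 0.8), (1052, 12, 0.9), (1460, 18, 0.6)],
    "3-phosphoglycerate": [(980, 12, 0.9), (1085, 14, 0.7), (1340, 16, 0.4)],
    "1-monopalmitin": [(1062, 14, 0.8), (1129, 14, 0.7), (1296, 14, 0.9), (1440, 18, 1.0)],
    "azelaic acid": [(908, 12, 0.7), (1100, 14, 0.5), (1305, 16, 0.8), (1640, 18, 0.5)],
}


def make_reference_library(
    specs: dict[str, list[tuple[float, float, float]]] | None = None,
    grid: np.ndarray | None = None,
) -> ReferenceLibrary:
    """Synthetic metabolite standard spectra as unit-norm pseudo-Voigt sums.

    Stands in for measured analytical standards: each entry is a sum of
    (centre, width, relative amplitude) bands on the common grid, scaled
    to unit Euclidean norm. Defaults cover the ten panel metabolites.
    """
    specs = _REFERENCE_BANDS if specs is None else specs
    if len(set(specs)) != len(specs):
        raise ValueError("duplicate metabolite names")
    if not specs:
        raise ValueError("need at least one metabolite spec")
    x = np.linspace(400.0, 1800.0, 847) if grid is None else np.asarray(grid, float)
    entries: dict[str, np.ndarray] = {}
    for name, bands in specs.items():
        y = np.zeros_like(x)
        for center, width, amp in bands:
            y += amp * pseudo_voigt(x, center, width)
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError(f"reference {name!r} has no signal on the grid")
        entries[name] = y / norm
    classes = {n: TABLE1_METABOLITES.get(n, "unknown") for n in specs}
    return ReferenceLibrary(axis=x, entries=entries, classes=classes)
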