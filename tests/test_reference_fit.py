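"""Reference decomposition, clustering, difference spectra, peak assignment."""

import numpy as np
import pytest

from ramanfuse.preprocess import whittaker_smooth
from ramanfuse.reference_fit import (
    ReferenceLibrary,
    assign_peaks,
    cluster_pc_space,
    compare_fit_quality,
    difference_spectrum,
    fit_references,
    load_peak_table,
)
from ramanfuse.spectra import Spectrum, SpectrumMeta, cohort_from_spectra
from ramanfuse.synthetic import make_reference_library, pseudo_voigt


def _target(y, x):
    return Spectrum(axis=x, intensities=y)


@pytest.fixture(scope="module")
def library():
    return make_reference_library()


class TestFitReferences:
    def test_planted_mixture_recovered(self, library):
        rng = np.random.default_rng(0)
        x = library.axis
        R = library.matrix()
        u = (x - x[0]) / (x[-1] - x[0])
        baseline = 3.0 * (1 + 0.3 * u - 0.4 * u**2)
        y = baseline + 2.0 * R[:, 0] + 0.5 * R[:, 2] + rng.normal(0, 0.002, x.size)
        fit = fit_references(_target(y, x), library)
        c = fit.coefficients
        assert abs(c.iloc[0] - 2.0) / 2.0 < 0.05
        assert abs(c.iloc[2] - 0.5) / 0.5 < 0.05
        others = c.drop(index=[c.index[0], c.index[2]])
        assert others.max() < 0.01 * c.max()

    def test_pure_baseline_gives_no_coefficients(self, library):
        x = library.axis
        u = (x - x[0]) / (x[-1] - x[0])
        y = 2.0 + u - 0.5 * u**2
        fit = fit_references(_target(y, x), library)
        assert fit.coefficients.max() < 0.02

    def test_conservation_identity(self, library):
        rng = np.random.default_rng(1)
        x = library.axis
        y = 3.0 + rng.normal(0, 0.01, x.size) + library.matrix() @ rng.uniform(0, 1, 10)
        fit = fit_references(_target(y, x), library)
        recomposed = fit.baseline + library.matrix() @ fit.coefficients.to_numpy()
        np.testing.assert_allclose(fit.fitted, recomposed, atol=1e-10)
        np.testing.assert_allclose(fit.residual, y - fit.fitted, atol=1e-10)

    def test_coefficients_nonnegative_on_random_problems(self, library):
        rng = np.random.default_rng(2)
        x = library.axis
        for _ in range(100):
            y = rng.normal(1.0, 0.5, x.size)
            fit = fit_references(_target(y, x), library, max_iter=3)
            assert (fit.coefficients >= 0).all()

    def test_matches_grid_search_oracle(self):
        # two-reference problem vs dense grid over (c1, c2)
        x = np.linspace(400, 1800, 300)
        e1 = pseudo_voigt(x, 700, 20)
        e2 = pseudo_voigt(x, 1300, 25)
        lib = ReferenceLibrary(axis=x, entries={"a": e1 / np.linalg.norm(e1),
                                                "b": e2 / np.linalg.norm(e2)})
        rng = np.random.default_rng(3)
        u = (x - x[0]) / (x[-1] - x[0])
        y = 2.0 + 0.5 * u + 1.2 * lib.matrix()[:, 0] + 0.7 * lib.matrix()[:, 1]
        y += rng.normal(0, 0.003, x.size)
        fit = fit_references(_target(y, x), lib)
        R = lib.matrix()
        grid = np.arange(0.0, 2.0, 0.025)
        best, best_loss = None, np.inf
        for c1 in grid:
            for c2 in grid:
                resid = y - R @ [c1, c2]
                z = whittaker_smooth(resid)
                loss = np.sum((resid - z) ** 2)
                if loss < best_loss:
                    best_loss, best = loss, (c1, c2)
        assert abs(fit.coefficients["a"] - best[0]) <= 0.025
        assert abs(fit.coefficients["b"] - best[1]) <= 0.025

    def test_empty_library_errors(self):
        x = np.linspace(400, 500, 50)
        with pytest.raises(ValueError):
            fit_references(_target(np.ones(50), x),
                           ReferenceLibrary(axis=x, entries={}))


class TestCompareFitQuality:
    def test_identical_inputs_zero_delta(self, library):
        x = library.axis
        y = 2.0 + library.matrix()[:, 0]
        s = _target(y, x)
        _, _, delta = compare_fit_quality(s, s, library)
        assert delta == 0.0

    def test_antisymmetric_under_swap(self, library):
        rng = np.random.default_rng(4)
        x = library.axis
        a = _target(2.0 + library.matrix() @ rng.uniform(0, 1, 10)
                    + rng.normal(0, 0.01, x.size), x)
        b = _target(2.0 + rng.normal(0, 0.05, x.size) + np.abs(rng.normal(0, 0.1)), x)
        _, _, d1 = compare_fit_quality(a, b, library)
        _, _, d2 = compare_fit_quality(b, a, library)
        assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_planted_contrast_positive_delta(self, library):
        # cancer-like average built from library peaks fits better than a
        # control-like average of unrelated structure
        wins = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = library.axis
            cancer = _target(3.0 + library.matrix() @ rng.uniform(0.3, 1.0, 10)
                             + rng.normal(0, 0.01, x.size), x)
            bumps = sum(rng.uniform(0.2, 0.6) * pseudo_voigt(x, c, 40)
                        for c in rng.uniform(450, 1750, 6))
            control = _target(3.0 + bumps + rng.normal(0, 0.01, x.size), x)
            _, _, delta = compare_fit_quality(cancer, control, library)
            wins += delta > 0
        assert wins >= 23


class TestDifferenceSpectrum:
    def _cohort(self, cancer_arrays, control_arrays, x):
        spectra, patients = [], {}
        for i, arr in enumerate(cancer_arrays):
            pid = f"C{i}"
            patients[pid] = ("cancer", "I")
            spectra.append(Spectrum(axis=x, intensities=arr,
                                    meta=SpectrumMeta(patient_id=pid, biofluid="plasma",
                                                      state="dried", spot="mean",
                                                      label="cancer")))
        for i, arr in enumerate(control_arrays):
            pid = f"N{i}"
            patients[pid] = ("control", "none")
            spectra.append(Spectrum(axis=x, intensities=arr,
                                    meta=SpectrumMeta(patient_id=pid, biofluid="plasma",
                                                      state="dried", spot="mean",
                                                      label="control")))
        return cohort_from_spectra(spectra, patients)

    def test_null_difference_small(self):
        rng = np.random.default_rng(5)
        x = np.linspace(400, 1800, 200)
        n, sd = 30, 0.1
        c = self._cohort([rng.normal(1, sd, 200) for _ in range(n)],
                         [rng.normal(1, sd, 200) for _ in range(n)], x)
        d = difference_spectrum(c, biofluid="plasma", state="dried")
        se = sd * np.sqrt(2 / n)
        assert np.max(np.abs(d.intensities)) < 5 * se

    def test_planted_peak_found_at_position(self):
        rng = np.random.default_rng(6)
        x = np.linspace(400, 1800, 847)
        peak = 0.2 * pseudo_voigt(x, 1000, 12)
        c = self._cohort([1 + peak + rng.normal(0, 0.005, 847) for _ in range(10)],
                         [1 + rng.normal(0, 0.005, 847) for _ in range(10)], x)
        d = difference_spectrum(c, biofluid="plasma")
        assert abs(x[np.argmax(d.intensities)] - 1000) <= np.diff(x)[0]

    def test_label_swap_negates(self):
        rng = np.random.default_rng(7)
        x = np.linspace(400, 1800, 100)
        c = self._cohort([rng.normal(1, 0.1, 100) for _ in range(4)],
                         [rng.normal(1, 0.1, 100) for _ in range(4)], x)
        d1 = difference_spectrum(c, biofluid="plasma")
        flipped = c.patients.copy()
        flipped["label"] = flipped["label"].map({"cancer": "control", "control": "cancer"})
        c2 = cohort_from_spectra(c.spectra, flipped)
        d2 = difference_spectrum(c2, biofluid="plasma")
        np.testing.assert_allclose(d1.intensities, -d2.intensities, atol=1e-12)

    def test_missing_class_errors(self):
        rng = np.random.default_rng(8)
        x = np.linspace(400, 500, 50)
        c = self._cohort([rng.normal(1, 0.1, 50)], [], x)
        with pytest.raises(ValueError):
            difference_spectrum(c, biofluid="plasma")


class TestAssignPeaks:
    def _diff(self, x, y):
        return Spectrum(axis=x, intensities=y,
                        meta=SpectrumMeta(label="unknown"))

    def test_phenylalanine_band_positive(self):
        x = np.linspace(400, 1800, 847)
        rng = np.random.default_rng(9)
        y = 0.2 * pseudo_voigt(x, 1000, 10) + rng.normal(0, 0.002, x.size)
        out = assign_peaks(self._diff(x, y))
        hits = [a for a in out if a.table_position == 1000]
        assert len(hits) == 1
        assert hits[0].direction == "+"
        assert "phenylalanine" in hits[0].assignment

    def test_glycogen_band_negative(self):
        x = np.linspace(400, 1800, 847)
        rng = np.random.default_rng(10)
        y = -0.2 * pseudo_voigt(x, 488, 12) + rng.normal(0, 0.002, x.size)
        out = assign_peaks(self._diff(x, y))
        hits = [a for a in out if a.table_position == 488]
        assert len(hits) == 1
        assert hits[0].direction == "-"
        assert hits[0].assignment == "Glycogen"

    def test_far_peak_unassigned(self):
        x = np.linspace(400, 1800, 847)
        rng = np.random.default_rng(11)
        y = 0.2 * pseudo_voigt(x, 1130, 10) + rng.normal(0, 0.002, x.size)  # 50+ cm-1 away
        out = assign_peaks(self._diff(x, y), tolerance=6.0)
        biggest = max(out, key=lambda a: abs(a.position - 1130) < 10)
        assert biggest.assignment == "unassigned"

    def test_row_order_independent(self):
        x = np.linspace(400, 1800, 847)
        rng = np.random.default_rng(12)
        y = (0.2 * pseudo_voigt(x, 1000, 10) - 0.15 * pseudo_voigt(x, 488, 12)
             + rng.normal(0, 0.002, x.size))
        table = load_peak_table()
        a1 = assign_peaks(self._diff(x, y), table)
        a2 = assign_peaks(self._diff(x, y), table.iloc[::-1].reset_index(drop=True))
        assert [(p.table_position, p.direction) for p in a1] == \
               [(p.table_position, p.direction) for p in a2]


class TestPeakTable:
    def test_shipped_band_list(self):
        table = load_peak_table()
        assert len(table) == 19
        assert set(table["direction"]) == {"+", "-"}
        row488 = table.loc[table["position_cm1"] == 488].iloc[0]
        assert row488["direction"] == "-" and row488["assignment"] == "Glycogen"
        row1000 = table.loc[table["position_cm1"] == 1000].iloc[0]
        assert row1000["direction"] == "+"


class TestClusterPCSpace:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 0.1, (10, 5))
        b = rng.normal(5, 0.1, (8, 5))
        _, labels = cluster_pc_space(np.vstack([a, b]), n_clusters=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicates_merge_at_zero_height(self):
        pts = np.array([[1.0, 1, 1, 1, 1], [1.0, 1, 1, 1, 1], [5.0, 5, 5, 5, 5]])
        Z, _ = cluster_pc_space(pts, n_clusters=2)
        assert Z[0, 2] == 0.0

    def test_labels_permutation_invariant(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 0.2, (7, 5)), rng.normal(3, 0.2, (7, 5))])
        _, l1 = cluster_pc_space(X, 2)
        perm = rng.permutation(14)
        _, l2 = cluster_pc_space(X[perm], 2)
        # same partition up to relabeling
        pairs = {(l1[perm][i] == l1[perm][j]) == (l2[i] == l2[j])
                 for i in range(14) for j in range(14)}
        assert pairs == {True}

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            cluster_pc_space(np.ones((1, 5)))
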