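"""Single-point quantitation-error detection.

The brute-force oracle here recomputes interaction profiles and
leave-one-out autocorrelations with plain scipy loops, sharing no code
with the vectorized implementation.
"""


import numpy as np
import pytest
from scipy.stats import norm, pearsonr

import cofracnet as cn
from cofracnet.matrix import from_array
from cofracnet.modern import (
    detect_outliers,
    interaction_profile,
    leave_one_out_autocorrelation,
    remove_outliers,
)


# --- brute-force oracle ---------------------------------------------------

def brute_profile(values, proteins, target, exclude_fraction=None):
    out = {}
    ti = proteins.index(target)
    for j, pj in enumerate(proteins):
        if pj == target:
            continue
        x, y = values[ti].copy(), values[j].copy()
        if exclude_fraction is not None:
            x = np.delete(x, exclude_fraction - 1)
            y = np.delete(y, exclude_fraction - 1)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            out[pj] = np.nan
        else:
            out[pj] = pearsonr(x[ok], y[ok]).statistic
    return out


def brute_autocorrelations(values, proteins):
    ac = np.full(values.shape, np.nan)
    for i, p in enumerate(proteins):
        base = brute_profile(values, proteins, p)
        for f in range(1, values.shape[1] + 1):
            if not np.isfinite(values[i, f - 1]):
                continue
            loo = brute_profile(values, proteins, p, exclude_fraction=f)
            b = np.array([base[q] for q in proteins if q != p])
            l = np.array([loo[q] for q in proteins if q != p])
            ok = np.isfinite(b) & np.isfinite(l)
            if ok.sum() < 3:
                continue
            if np.array_equal(b[ok], l[ok]):
                ac[i, f - 1] = 1.0
            elif b[ok].std() > 0 and l[ok].std() > 0:
                ac[i, f - 1] = pearsonr(b[ok], l[ok]).statistic
    return ac


def brute_detect(values, proteins, fwer=0.05):
    ac = brute_autocorrelations(values, proteins)
    w = np.arctanh(np.clip(ac, -1 + 1e-15, 1 - 1e-15))
    med = np.nanmedian(w, axis=1, keepdims=True)
    mad = 1.4826 * np.nanmedian(np.abs(w - med), axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - med) / np.where(mad == 0, np.nan, mad)
    n = int(np.isfinite(values).sum())
    z_crit = norm.ppf((fwer / 2) / n)
    return {
        (proteins[i], j + 1) for i, j in np.argwhere(z < z_crit)
    }, ac


# --- interaction profiles -------------------------------------------------

class TestInteractionProfile:
    def test_identical_profiles_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        base = rng.random(10)
        m = from_array(np.vstack([base, base, rng.random(10)]), ["A", "B", "C"])
        assert interaction_profile(m, "A")["B"] == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        m = from_array(np.array([[1, 2, 3], [3, 2, 1.0]]), ["A", "B"])
        assert interaction_profile(m, "A")["B"] == pytest.approx(-1.0)

    def test_matches_brute_force_on_toy_matrix(self):
        rng = np.random.default_rng(1)
        values = rng.random((4, 8))
        values[rng.random((4, 8)) < 0.2] = np.nan
        proteins = ["A", "B", "C", "D"]
        m = from_array(values, proteins)
        for target in proteins:
            got = interaction_profile(m, target)
            want = brute_profile(values, proteins, target)
            for pj, expected in want.items():
                if np.isnan(expected):
                    assert np.isnan(got[pj])
                else:
                    assert got[pj] == pytest.approx(expected, abs=1e-10)

    def test_exclude_fraction_drops_it_from_both(self):
        rng = np.random.default_rng(2)
        values = rng.random((3, 9))
        proteins = ["A", "B", "C"]
        m = from_array(values, proteins)
        got = interaction_profile(m, "A", exclude_fraction=4)
        want = brute_profile(values, proteins, "A", exclude_fraction=4)
        for pj, expected in want.items():
            assert got[pj] == pytest.approx(expected, abs=1e-10)

    def test_short_overlap_is_missing(self):
        values = np.array(
            [[1.0, 2.0, np.nan, np.nan, np.nan], [3.0, 1.0, np.nan, np.nan, np.nan],
             [1.0, 2.0, 3.0, 4.0, 5.0]]
        )
        m = from_array(values, ["A", "B", "C"])
        prof = interaction_profile(m, "A")
        assert np.isnan(prof["B"])  # only two overlapping points


class TestLeaveOneOutAutocorrelation:
    def test_affine_profiles_give_autocorrelation_one(self):
        base = np.array([1.0, 4.0, 2.0, 5.0, 3.0, 6.0])
        values = np.vstack([a * base + b for a, b in [(1, 0), (2, 1), (0.5, 3), (3, 2)]])
        m = from_array(values, ["A", "B", "C", "D"])
        for f in range(1, 7):
            assert leave_one_out_autocorrelation(m, "A", f) == pytest.approx(1.0)

    def test_spike_is_the_strict_minimum_over_the_protein(self):
        truth = cn.generate_complex_truth(30, 5, (3, 4), 0.0, seed=3)
        config = cn.SimulationConfig(
            n_proteins=30, n_replicates=1, noise_sd=0.0, missing_rate=0.0,
            spike_rate=0.0, seed=4,
        )
        matrices, _ = cn.simulate_chromatograms(truth, config)
        m = matrices[0]
        protein = truth.complexes["C001"][0]
        values = m.values.copy()
        i = m.proteins.index(protein)
        values[i, 10] *= 1000.0
        spiked = m.with_values(values)
        acs = {
            f: leave_one_out_autocorrelation(spiked, protein, f)
            for f in range(1, 61)
        }
        defined = {f: v for f, v in acs.items() if v is not None}
        assert min(defined, key=defined.get) == 11

    def test_symmetric_fractions_have_equal_autocorrelation(self):
        # profiles symmetric around the middle fraction: mirror-image
        # points are exchangeable
        x = np.arange(1, 10, dtype=float)
        rows = [np.exp(-((x - 5) ** 2) / (2 * s**2)) + 0.1 for s in (1.0, 1.5, 2.0, 2.5)]
        m = from_array(np.vstack(rows), ["A", "B", "C", "D"])
        for f in (1, 2, 3, 4):
            left = leave_one_out_autocorrelation(m, "A", f)
            right = leave_one_out_autocorrelation(m, "A", 10 - f)
            assert left == pytest.approx(right, abs=1e-9)


class TestDetectOutliers:
    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(1.0, 0.4, size=(6, 10)))
        values[0, 3] *= 40  # an obvious planted error
        proteins = list("ABCDEF")
        m = from_array(values, proteins)
        report = detect_outliers(m)
        want_flags, want_ac = brute_detect(values, proteins)
        assert report.flagged == want_flags
        got_ac = report.autocorrelations.to_numpy()
        np.testing.assert_allclose(got_ac, want_ac, atol=1e-9, equal_nan=True)

    def test_all_equal_autocorrelations_flag_nothing(self):
        base = np.array([1.0, 4.0, 2.0, 5.0, 3.0, 6.0])
        values = np.vstack([a * base for a in (1.0, 2.0, 0.5, 3.0)])
        m = from_array(values, ["A", "B", "C", "D"])
        with pytest.warns(UserWarning, match="degenerate"):
            report = detect_outliers(m)
        assert report.flagged == frozenset()

    def test_flags_invariant_to_scaling_and_relabeling(self):
        rng = np.random.default_rng(6)
        values = np.abs(rng.normal(1.0, 0.4, size=(8, 12)))
        values[2, 5] *= 30
        m = from_array(values, [f"P{i}" for i in range(8)])
        base_flags = detect_outliers(m).flagged
        scaled = detect_outliers(from_array(3.7 * values, [f"P{i}" for i in range(8)]))
        assert scaled.flagged == base_flags
        renamed = detect_outliers(from_array(values, [f"Q{i}" for i in range(8)]))
        assert {(p.replace("Q", "P"), f) for p, f in renamed.flagged} == base_flags

    def test_every_flagged_point_is_below_threshold(self, noisy_run):
        _, matrices, _ = noisy_run
        m = cn.clean_matrix(matrices[0])
        report = detect_outliers(m)
        for protein, fraction in report.flagged:
            z = report.z_scores.loc[protein].iloc[fraction - 1]
            assert z < report.z_crit
        assert report.z_crit == pytest.approx(
            norm.ppf(0.025 / report.n_points)
        )


class TestRemoveOutliers:
    def test_empty_report_is_identity(self, noisy_run):
        _, matrices, _ = noisy_run
        m = cn.clean_matrix(matrices[1])
        report = detect_outliers(m, fwer=1e-30)  # threshold unreachably low
        assert report.flagged == frozenset()
        assert remove_outliers(m, report).equals(m)

    def test_each_flag_removes_exactly_one_observation(self, noisy_run):
        _, matrices, _ = noisy_run
        m = cn.clean_matrix(matrices[0])
        report = detect_outliers(m)
        out = remove_outliers(m, report)
        assert out.n_observed == m.n_observed - len(report.flagged)

    def test_removal_restores_within_complex_correlations(self):
        truth = cn.generate_complex_truth(60, 10, (3, 4), 0.0, seed=7)
        config = cn.SimulationConfig(
            n_proteins=60, n_replicates=1, spike_rate=0.004, spike_magnitude=50,
            seed=8,
        )
        matrices, spikes = cn.simulate_chromatograms(truth, config)
        m = cn.clean_matrix(matrices[0])
        report = detect_outliers(m)
        cleaned = remove_outliers(m, report)
        spiked_proteins = {
            p for _, chan, p, _ in spikes.positions
            if chan == "medium" and p in set(m.proteins)
        }

        def median_within_r(matrix):
            rs = []
            for members in truth.complexes.values():
                present = [p for p in members if p in spiked_proteins]
                for a in present:
                    for b in members:
                        if a >= b:
                            continue
                        xa, xb = matrix.profile(a), matrix.profile(b)
                        ok = np.isfinite(xa) & np.isfinite(xb)
                        if ok.sum() >= 3:
                            rs.append(np.corrcoef(xa[ok], xb[ok])[0, 1])
            return np.median(rs)

        assert median_within_r(cleaned) > median_within_r(m)
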