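"""Synthetic-data generators: determinism, noise realism, closure."""

import numpy as np
import pytest

from berquant import (
    HydroMeasurement,
    HydroParticle,
    SyntheticConfig,
    fit_four_parameter,
    fret_efficiency,
    generate_dna_pair,
    generate_fret_triplet,
    generate_hydro_observations,
    generate_titration,
    stokes_einstein_rh,
)
from berquant.binding import four_param_logistic
from berquant.hydro import OligomerCandidate, assign_oligomeric_state, ellipsoid_rh


class TestDeterminism:
    def test_same_seed_identical_titration(self):
        cfg = SyntheticConfig(ec50=120.0, seed=42)
        c1, _ = generate_titration(cfg)
        c2, _ = generate_titration(cfg)
        for p1, p2 in zip(c1.points, c2.points):
            assert p1.intensities == p2.intensities

    def test_same_seed_identical_fret(self):
        cfg = SyntheticConfig(ec50=90.0, e_true=0.3, seed=7)
        e1, _ = generate_fret_triplet(cfg)
        e2, _ = generate_fret_triplet(cfg)
        np.testing.assert_array_equal(
            e1.series_da.mean_intensities, e2.series_da.mean_intensities
        )

    def test_different_seed_differs(self):
        c1, _ = generate_titration(SyntheticConfig(seed=1))
        c2, _ = generate_titration(SyntheticConfig(seed=2))
        assert c1.points[1].intensities != c2.points[1].intensities


class TestNoiseModel:
    def test_zero_cv_reproduces_model_exactly(self):
        cfg = SyntheticConfig(ec50=84.0, hill_n=1.8, fold_change=2.8, cv=0.0)
        curve, truth = generate_titration(cfg)
        expected = four_param_logistic(
            curve.concentrations, truth["f0"], truth["f_inf"],
            truth["ec50"], truth["hill_n"],
        )
        np.testing.assert_array_equal(curve.mean_intensities, expected)
        for p in curve.points:
            assert len(set(p.intensities)) == 1  # replicates identical

    def test_empirical_cv_matches_configured(self, rng):
        cfg = SyntheticConfig(ec50=120.0, cv=0.02, replicates=2)
        rel = []
        for _ in range(300):
            curve, truth = generate_titration(cfg, rng)
            clean = four_param_logistic(
                curve.concentrations, truth["f0"], truth["f_inf"],
                truth["ec50"], truth["hill_n"],
            )
            for p, mu in zip(curve.points, clean):
                rel.extend(np.asarray(p.intensities) / mu - 1.0)
        rel = np.asarray(rel)
        assert np.std(rel) == pytest.approx(0.02, rel=0.05)
        assert abs(np.mean(rel)) < 0.001

    def test_fit_confidence_intervals_near_nominal_coverage(self, rng):
        """With intensity-proportional weighting (matching the multiplicative
        noise) and a t quantile, the 95% EC50 interval from the fit
        covariance covers the generating value at close to nominal rate."""
        from scipy import stats

        from berquant import fit_four_parameter

        cfg = SyntheticConfig(ec50=120.0, hill_n=1.8, fold_change=2.2, cv=0.02)
        n, covered = 150, 0
        for _ in range(n):
            curve, _ = generate_titration(cfg, rng)
            fit = fit_four_parameter(curve, weighting="relative")
            tq = stats.t.ppf(0.975, fit.n_points - 4)
            covered += abs(fit.ec50 - 120.0) <= tq * fit.param_sd["ec50"]
        assert 0.88 <= covered / n <= 1.0

    def test_ground_truth_serialized_with_data(self):
        curve, truth = generate_titration(SyntheticConfig(ec50=45.0, seed=0))
        assert truth["ec50"] == 45.0
        assert truth["replicates"] == 2


class TestZeroNoiseClosure:
    """Every analysis stage applied to its own noise-free generator output
    must return the ground truth to numerical precision."""

    def test_titration_fit_closure(self):
        cfg = SyntheticConfig(ec50=23.0, hill_n=2.0, fold_change=1.9, cv=0.0)
        fit = fit_four_parameter(generate_titration(cfg)[0])
        assert fit.ec50 == pytest.approx(23.0, rel=1e-7)
        assert fit.hill_n == pytest.approx(2.0, rel=1e-7)

    def test_fret_closure(self):
        cfg = SyntheticConfig(ec50=93.0, hill_n=1.8, e_true=0.37, cv=0.0)
        res = fret_efficiency(generate_fret_triplet(cfg)[0])
        assert res.efficiency == pytest.approx(0.37, abs=1e-12)

    def test_dna_pair_closure(self):
        cfg = SyntheticConfig(ec50=84.0, hill_n=1.8, e_true=0.16, cv=0.0)
        pair, truth = generate_dna_pair(cfg, affinity_ratio=2.0, delta_e=-0.06,
                                        dna_context="incised AP-DNA")
        fit_minus = fit_four_parameter(pair["minus"].series_d)
        fit_plus = fit_four_parameter(pair["plus"].series_d)
        assert fit_plus.ec50 / fit_minus.ec50 == pytest.approx(2.0, rel=1e-7)
        e_minus = fret_efficiency(pair["minus"]).efficiency
        e_plus = fret_efficiency(pair["plus"]).efficiency
        assert e_plus - e_minus == pytest.approx(-0.06, abs=1e-9)
        assert pair["plus"].series_d.dna_context == "incised AP-DNA"

    def test_hydro_closure(self):
        particles = [
            ("monomer", HydroParticle(molar_mass=69.5, axial_ratio=8.0,
                                      calibrated_radius_nm=3.349)),
        ]
        obs = generate_hydro_observations(particles, cv=0.0, seed=0)
        rh = stokes_einstein_rh(
            HydroMeasurement(d=obs.loc[0, "d_m2_per_s"], temperature=297.0)
        )
        assert rh == pytest.approx(obs.loc[0, "true_rh_nm"], rel=1e-12)


class TestDnaPairValidation:
    def test_invalid_delta_rejected(self):
        cfg = SyntheticConfig(ec50=84.0, e_true=0.9, cv=0.0)
        with pytest.raises(ValueError, match="outside"):
            generate_dna_pair(cfg, affinity_ratio=1.0, delta_e=0.2)

    def test_requires_fret_truth(self):
        with pytest.raises(ValueError, match="e_true"):
            generate_dna_pair(SyntheticConfig(ec50=84.0), affinity_ratio=2.0)

    def test_neutral_pair_statistically_identical(self, rng):
        cfg = SyntheticConfig(ec50=84.0, e_true=0.16, cv=0.02)
        ratios = []
        for _ in range(40):
            pair, _ = generate_dna_pair(cfg, affinity_ratio=1.0, delta_e=0.0, rng=rng)
            fm = fit_four_parameter(pair["minus"].series_d)
            fp = fit_four_parameter(pair["plus"].series_d)
            ratios.append(fp.ec50 / fm.ec50)
        r = np.asarray(ratios)
        assert abs(r.mean() - 1.0) < 3 * r.std(ddof=1) / np.sqrt(r.size) + 0.005


class TestHydroObservations:
    def test_seeded_reproducibility(self):
        particles = [("m", HydroParticle(molar_mass=69.5, axial_ratio=8.0))]
        a = generate_hydro_observations(particles, cv=0.05, seed=3)
        b = generate_hydro_observations(particles, cv=0.05, seed=3)
        assert a.equals(b)

    def test_assignment_accuracy_with_separated_candidates(self, rng):
        """Mw candidates >= 30% apart are assigned correctly >= 95% of the
        time at 5% observation noise."""
        mono = HydroParticle(molar_mass=69.5, axial_ratio=8.0)
        dim = HydroParticle(molar_mass=139.0, axial_ratio=8.0)
        cands = [
            OligomerCandidate("monomer", predicted_mw=69.5),
            OligomerCandidate("dimer", predicted_mw=139.0),
        ]
        correct = 0
        n = 200
        for _ in range(n):
            obs = generate_hydro_observations(
                [("monomer", mono), ("dimer", dim)], cv=0.05, rng=rng
            )
            for _, row in obs.iterrows():
                ranked = assign_oligomeric_state(
                    cands, observed_mw=row["observed_mw_kda"]
                )
                correct += ranked[0][0].label == row["label"]
        assert correct / (2 * n) >= 0.95
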