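"""Ground-truth guarantees of the synthetic-data generators."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

import gliocircuit as g
from gliocircuit.assoc import fit_outcome_model
from gliocircuit.simulate import simulate_electrode_features


class TestEcogGenerator:
    def test_unit_factors_plant_zero_psc(self):
        spec = g.EcogSimSpec(n_strips=2, fs=1000.0,
                             trial_plan=[("rest", 6.0, 1), ("easy", 6.0, 1), ("hard", 6.0, 1)])
        _, truth = g.simulate_ecog(spec)
        assert (truth["psc_easy_gt_rest"] == 0).all()
        assert (truth["psc_hard_gt_easy"] == 0).all()

    def test_factor_two_plants_psc_of_100(self):
        spec = g.EcogSimSpec(fs=1000.0, hard_vs_easy=2.0,
                             trial_plan=[("easy", 6.0, 1), ("hard", 6.0, 1)])
        _, truth = g.simulate_ecog(spec)
        assert (truth["psc_hard_gt_easy"] == 100.0).all()

    def test_fixed_seed_is_bit_identical(self):
        spec = dict(n_strips=1, fs=1000.0, rng_seed=42,
                    trial_plan=[("rest", 5.0, 1), ("easy", 3.0, 2)])
        rec1, _ = g.simulate_ecog(g.EcogSimSpec(**spec))
        rec2, _ = g.simulate_ecog(g.EcogSimSpec(**spec))
        np.testing.assert_array_equal(rec1.data, rec2.data)

    def test_markers_fit_recording_and_cover_plan(self):
        spec = g.EcogSimSpec(fs=1000.0,
                             trial_plan=[("rest", 10.0, 1), ("easy", 4.0, 3), ("hard", 5.0, 2)])
        rec, _ = g.simulate_ecog(spec)
        assert len(rec.markers) == 6
        assert rec.markers["offset"].max() <= rec.n_samples
        assert list(rec.markers["condition"]).count("easy") == 3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            g.EcogSimSpec(easy_vs_rest=0.0)
        with pytest.raises(ValueError):
            g.EcogSimSpec(trial_plan=[("rest", -1.0, 1)])
        with pytest.raises(ValueError):
            g.EcogSimSpec(electrodes_per_strip=1)


class TestBoldGenerator:
    def test_zero_coupling_gives_null_correlations(self):
        spec = g.BoldSimSpec(tumour_coupling={}, n_volumes=200, rng_seed=5)
        bold, masks, _, _ = g.simulate_bold(spec)
        net = bold[masks["network_1"]].mean(axis=0)
        net = (net - net.mean()) / net.std()
        vox = bold[masks["tumour"]]
        vox = (vox - vox.mean(1, keepdims=True)) / vox.std(1, keepdims=True)
        r = vox @ net / spec.n_volumes
        assert abs(r.mean()) < 3 / np.sqrt(spec.n_volumes)

    def test_full_coupling_no_noise_gives_r_of_one(self):
        spec = g.BoldSimSpec(tumour_coupling={2: 1.0}, noise_sd=0.0, n_volumes=50, rng_seed=6)
        bold, masks, _, _ = g.simulate_bold(spec)
        course = bold[masks["network_2"]].mean(axis=0)
        vox = bold[masks["tumour"]]
        for ts in vox[:10]:
            assert abs(np.corrcoef(ts, course)[0, 1] - 1.0) < 1e-12

    def test_attenuation_matches_closed_form(self):
        """Mean recovered correlation over >= 100 tumour voxels matches the
        closed-form attenuation w / sqrt(w^2 + sigma^2 / var(course))."""
        w, sigma = 0.6, 1.0
        spec = g.BoldSimSpec(shape=(24, 24, 24), tumour_radius_vox=3.2, n_volumes=200,
                             tumour_coupling={1: w}, noise_sd=sigma, rng_seed=7)
        bold, masks, _, truth = g.simulate_bold(spec)
        expected_pop = w / np.sqrt(w**2 + sigma**2 / spec.course_sd**2)
        tested = truth[(truth["network"] == 1) & truth["population_r"].notna()]
        assert len(tested) >= 100
        np.testing.assert_allclose(tested["population_r"], expected_pop, atol=1e-12)
        # brute-force verification: sample correlations against the course,
        # with the attenuation evaluated at the course's realized variance
        course = bold[masks["network_1"]].mean(axis=0)
        course_z = (course - course.mean()) / course.std()
        var_hat = course.var()
        expected = w * np.sqrt(var_hat) / np.sqrt(w**2 * var_hat + sigma**2)
        ijk = tested[["i", "j", "k"]].to_numpy()
        vox = bold[tuple(ijk.T)]
        vox = (vox - vox.mean(1, keepdims=True)) / vox.std(1, keepdims=True)
        r = vox @ course_z / spec.n_volumes
        assert abs(r.mean() - expected) < 0.05
        assert abs(r.mean() - expected_pop) < 0.1

    def test_tumour_outside_grid_rejected(self):
        with pytest.raises(g.RangeError):
            g.simulate_bold(g.BoldSimSpec(tumour_centre_vox=(50, 10, 10)))

    def test_network_supports_are_disjoint(self, bold_world):
        masks = bold_world["masks"]
        total = sum(masks[f"network_{k}"].astype(int) for k in range(1, 8))
        assert total.max() <= 1


class TestSphere:
    @pytest.mark.parametrize("s,n_vertices,n_faces", [(0, 12, 20), (1, 42, 80), (2, 162, 320)])
    def test_icosphere_counts(self, s, n_vertices, n_faces):
        mesh = g.make_icosphere(s)
        assert mesh.n_vertices == n_vertices == 10 * 4**s + 2
        assert len(mesh.faces) == n_faces

    def test_vertices_on_unit_sphere(self):
        mesh = g.make_icosphere(2)
        np.testing.assert_allclose(np.linalg.norm(mesh.vertices, axis=1), 1.0, atol=1e-9)

    def test_single_parcel_covers_everything(self):
        mesh = g.make_icosphere(1)
        assert (g.make_parcellation(mesh, 1, rng_seed=0) == 1).all()

    def test_seven_parcels_nonempty_and_contiguous(self, sphere_and_parcels):
        mesh, labels = sphere_and_parcels
        adj = mesh.vertex_adjacency()
        assert set(labels) == set(range(1, 8))
        for k in range(1, 8):
            members = set(np.flatnonzero(labels == k).tolist())
            # breadth-first search within the parcel must reach every member
            seen = {next(iter(members))}
            queue = deque(seen)
            while queue:
                v = queue.popleft()
                for u in adj[v]:
                    if u in members and u not in seen:
                        seen.add(u)
                        queue.append(u)
            assert seen == members, f"parcel {k} is not contiguous"

    def test_parcellation_reproducible(self):
        mesh = g.make_icosphere(2)
        np.testing.assert_array_equal(
            g.make_parcellation(mesh, 5, rng_seed=3), g.make_parcellation(mesh, 5, rng_seed=3)
        )


class TestCohortGenerator:
    def test_null_slope_confidence_coverage(self):
        """With all coefficients zero, the connectivity slope CI covers zero
        in at least 90% of replicates."""
        covered = 0
        for rep in range(100):
            spec = g.CohortSimSpec(
                n_patients=30,
                outcome_coefs={k: 0.0 for k in g.CohortSimSpec().outcome_coefs},
                missing_followup_frac=0.0,
                rng_seed=1000 + rep,
            )
            rep_model = fit_outcome_model(g.simulate_cohort(spec))
            t = rep_model.term("tumour_network_connectivity")
            covered += abs(t["estimate"]) <= 1.96 * t["se"] + 1e-12
        assert covered >= 90

    def test_planted_connectivity_coefficient_recovered(self):
        coefs = {k: 0.0 for k in g.CohortSimSpec().outcome_coefs}
        coefs["connectivity"] = 1.0
        spec = g.CohortSimSpec(n_patients=200, outcome_coefs=coefs, residual_sd=0.1,
                               missing_followup_frac=0.0, rng_seed=8)
        report = fit_outcome_model(g.simulate_cohort(spec))
        est = report.term("tumour_network_connectivity")["estimate"]
        assert abs(est - 1.0) < 0.1

    def test_missingness_pattern_honoured(self):
        spec = g.CohortSimSpec(n_patients=200, missing_followup_frac=0.4, rng_seed=9)
        df = g.simulate_cohort(spec)
        frac = df["followup_score"].isna().mean()
        assert 0.25 < frac < 0.55
        complete = df.dropna(subset=["followup_score"])
        assert complete.notna().all().all()

    def test_categoricals_use_declared_levels(self):
        df = g.simulate_cohort(g.CohortSimSpec(n_patients=60, rng_seed=10))
        assert set(df["location"]) <= {"frontal", "insula", "temporal"}
        assert set(df["hemisphere"]) <= {"left", "right"}
        assert set(df["latest_timepoint"]) <= {"post-op", "month 3", "month 12"}

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            g.CohortSimSpec(n_patients=5)


class TestElectrodeFeatures:
    def test_psc_shared_across_networks(self):
        rows = simulate_electrode_features(rng_seed=2)
        per_cell = rows.groupby(["participant", "electrode", "contrast"])["psc"].nunique()
        assert (per_cell == 1).all()

    def test_planted_slope_visible_in_target_cell(self):
        rows = simulate_electrode_features(
            n_participants=10, electrodes_per_participant=20,
            slopes={("hard_gt_easy", "DAN"): 2.0}, participant_sd=0.0,
            noise_sd=0.1, rng_seed=3,
        )
        cell = rows[(rows["contrast"] == "hard_gt_easy") & (rows["network"] == "DAN")]
        slope = np.polyfit(cell["fc"], cell["psc"], 1)[0]
        assert abs(slope - 2.0) < 0.1
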