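import numpy as np
import pandas as pd
import pytest

from clonoscope import (
    PatientLabel,
    SyntheticCohortConfig,
    Timepoint,
    filter_productive,
    generate_cohort,
    generate_longitudinal,
    generate_repertoire,
    read_airr_tsv,
    spectrum_fractions,
    stratify_patient,
    thin_repertoire,
    write_airr,
)
from clonoscope.simulate import LONGITUDINAL_TIMEPOINTS, iter_cohort
from clonoscope.usage import usage_profile


SMALL = dict(templates_per_sample=5000, n_clones=6000, n_nonproductive_clones=50)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = SyntheticCohortConfig()
        assert cfg.oligo_prevalence == {"CR/PR": 0.25, "SD": 0.45, "PD": 0.70}
        assert cfg.templates_per_sample == 20_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(templates_per_sample=0),
            dict(oligo_prevalence={"CR/PR": 1.5}),
            dict(oligo_expanded_range=(0.10, 0.40)),  # overlaps poly range
            dict(tail_freq_max=2e-3),  # tail crossing the LARGE boundary
            dict(cdr3_length_dist={13: 0.5, 14: 0.4}),  # not normalized
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(**kwargs)


class TestGenerateRepertoire:
    def test_oligoclonal_realized_expanded_in_range(self, rng):
        """Spiked mass drawn from [0.30, 0.70]; realized expanded fraction
        stays within sampling tolerance of that interval."""
        cfg = SyntheticCohortConfig(**SMALL)
        for _ in range(20):
            rep, truth = generate_repertoire("OLIGOCLONAL", cfg, rng)
            prof = spectrum_fractions(filter_productive(rep))
            assert 0.28 <= prof.expanded_fraction <= 0.72
            assert abs(prof.expanded_fraction - truth.expanded_mass) < 0.03

    def test_polyclonal_label_recovery(self, rng):
        """Polyclonal draws classify POLYCLONAL in >= 99% of 500 draws."""
        cfg = SyntheticCohortConfig(**SMALL)
        hits = 0
        for _ in range(500):
            rep, _ = generate_repertoire("POLYCLONAL", cfg, rng)
            label = stratify_patient(spectrum_fractions(filter_productive(rep)))
            hits += label is PatientLabel.POLYCLONAL
        assert hits >= 495

    def test_cdr3_shape_and_lengths(self, rng):
        cfg = SyntheticCohortConfig(**SMALL)
        rep, _ = generate_repertoire("POLYCLONAL", cfg, rng)
        cdr3s = rep.table.loc[rep.table["productive"], "cdr3_aa"]
        assert cdr3s.str.startswith("CASS").all()
        assert cdr3s.str.endswith("F").all()
        assert set(cdr3s.str.len()) <= {13, 14, 15}

    def test_trbj27_usage_matches_configured_mass(self, rng):
        """Responder-profile J usage within +-0.02 of 0.175 at full depth."""
        cfg = SyntheticCohortConfig(n_clones=12_000, n_nonproductive_clones=50)
        rep, _ = generate_repertoire("POLYCLONAL", cfg, rng, group="CR/PR")
        # clonotype weighting checks the per-clone gene draw directly
        # (template weighting is dominated by the handful of spiked clones)
        up = usage_profile(filter_productive(rep), "J", "CLONOTYPE")
        assert up.frequencies["TRBJ2-7"] == pytest.approx(0.175, abs=0.02)

    def test_zero_templates_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(templates_per_sample=0)

    def test_roundtrip_through_airr(self, rng, tmp_path):
        cfg = SyntheticCohortConfig(**SMALL)
        rep, _ = generate_repertoire("OLIGOCLONAL", cfg, rng)
        path = tmp_path / "sim.airr.tsv"
        write_airr(rep, path)
        back = read_airr_tsv(path)
        assert len(back) == len(rep)
        assert back.total_templates() == rep.total_templates()


class TestGenerateCohort:
    def test_deterministic_under_fixed_seed(self):
        cfg = SyntheticCohortConfig(seed=11, group_sizes={"CR/PR": 3, "PD": 2}, **SMALL)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for ra, rb in zip(a.repertoires, b.repertoires):
            pd.testing.assert_frame_equal(ra.table, rb.table)

    def test_zero_prevalence_group_all_polyclonal(self):
        cfg = SyntheticCohortConfig(
            seed=5, group_sizes={"SD": 10}, oligo_prevalence={"SD": 0.0}, **SMALL
        )
        bundle = generate_cohort(cfg)
        assert (bundle.truth["latent_state"] == "POLYCLONAL").all()

    def test_observed_prevalence_tracks_configuration(self):
        """Latent oligoclonal fraction near the configured 45% (binomial CI)."""
        cfg = SyntheticCohortConfig(seed=3, group_sizes={"SD": 400}, **SMALL)
        states = [
            truth.latent_state is PatientLabel.OLIGOCLONAL
            for _, _, truth in iter_cohort(cfg)
        ]
        assert np.mean(states) == pytest.approx(0.45, abs=0.07)

    def test_cohort_table_valid_and_survival_linked(self):
        cfg = SyntheticCohortConfig(seed=9, group_sizes={"CR/PR": 4, "SD": 4, "PD": 4},
                                    **SMALL)
        bundle = generate_cohort(cfg)
        from clonoscope.io import validate_cohort_table

        validate_cohort_table(bundle.cohort)  # raises on violation
        assert (bundle.cohort["os_time"] > 0).all()
        assert set(bundle.truth["response_group"]) == {"CR/PR", "SD", "PD"}


class TestLongitudinal:
    def test_zero_drift_zero_volatility_keeps_true_freqs(self, rng):
        cfg = SyntheticCohortConfig(drift_volatility=0.0,
                                    top_drift_log2={"CR/PR": 0.0}, **SMALL)
        _, truth = generate_repertoire("POLYCLONAL", cfg, rng, group="CR/PR",
                                       patient_id="P1")
        _, ltruth = generate_longitudinal(truth, cfg, rng)
        f = ltruth.true_freqs
        for tp in LONGITUDINAL_TIMEPOINTS[1:]:
            assert np.allclose(f[tp], f[Timepoint.SCREENING], atol=1e-15)

    def test_positive_drift_grows_top_clone_mass(self, rng):
        cfg = SyntheticCohortConfig(top_drift_log2={"CR/PR": 0.8},
                                    drift_volatility=0.05, **SMALL)
        _, truth = generate_repertoire("OLIGOCLONAL", cfg, rng, group="CR/PR",
                                       patient_id="P1")
        _, ltruth = generate_longitudinal(truth, cfg, rng)
        top = np.argsort(truth.clone_table["true_freq"].to_numpy())[::-1][:10]
        masses = [ltruth.true_freqs[tp].to_numpy()[top].sum()
                  for tp in LONGITUDINAL_TIMEPOINTS]
        assert all(b > a for a, b in zip(masses, masses[1:]))

    def test_programmed_drifts_respected(self, rng):
        cfg = SyntheticCohortConfig(drift_volatility=0.0, **SMALL)
        _, truth = generate_repertoire("POLYCLONAL", cfg, rng, patient_id="P1")
        n = len(truth.clone_table)
        drifts = np.zeros(n)
        drifts[0] = 3.0
        _, ltruth = generate_longitudinal(truth, cfg, rng, drifts_log2=drifts)
        f0 = ltruth.true_freqs[Timepoint.SCREENING].iloc[0]
        f1 = ltruth.true_freqs[Timepoint.C1D1].iloc[0]
        # one step of +3 log2 units, modulo renormalization (ratio vs rest)
        rest0 = 1 - f0
        rest1 = 1 - f1
        assert np.log2((f1 / rest1) / (f0 / rest0)) == pytest.approx(3.0, abs=1e-9)

    def test_timepoint_schedule(self, rng):
        cfg = SyntheticCohortConfig(**SMALL)
        _, truth = generate_repertoire("POLYCLONAL", cfg, rng, patient_id="P1")
        reps, _ = generate_longitudinal(truth, cfg, rng)
        assert list(reps) == list(LONGITUDINAL_TIMEPOINTS)
        assert all(r.patient_id == "P1" for r in reps.values())


class TestThinning:
    def test_thinning_preserves_total_and_subsets_counts(self, rng):
        cfg = SyntheticCohortConfig(**SMALL)
        rep, _ = generate_repertoire("OLIGOCLONAL", cfg, rng)
        thin = thin_repertoire(rep, factor=10, rng=rng)
        total = rep.table["templates"].sum()
        assert thin.table["templates"].sum() == int(round(total / 10))
        merged = thin.table.merge(
            rep.table, on="rearrangement_nt", suffixes=("_thin", "_full")
        )
        assert (merged["templates_thin"] <= merged["templates_full"]).all()

    def test_invalid_factor_rejected(self, rng, toy_repertoire):
        with pytest.raises(ValueError):
            thin_repertoire(toy_repertoire, factor=1, rng=rng)
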