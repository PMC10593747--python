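"""Synthetic cohort generator: determinism, boundary configs, missingness
bounds, and a brute-force re-simulation prevalence oracle."""

import numpy as np
import pytest
from scipy import stats as sps

from hdtft.cohort import FilterCriteria, filter_sessions
from hdtft.synthetic import (
    NADIR_REF,
    NORMS,
    ConfigurationError,
    SyntheticConfig,
    generate_cohort,
    inject_missingness,
)


def small_config(**kw) -> SyntheticConfig:
    base = dict(n_patients=20, sessions_per_patient=(2, 4), seed=1)
    base.update(kw)
    return SyntheticConfig(**base)


def cohort_fingerprint(cohort) -> tuple:
    parts = []
    for s in cohort.sessions:
        parts.append(
            (
                s.session_id,
                s.start_time.isoformat(),
                round(s.duration_min, 9),
                tuple(np.round(s.times, 9)),
                tuple(
                    (k, tuple(np.round(np.nan_to_num(v, nan=-1.0), 9)))
                    for k, v in sorted(s.measurements.items())
                ),
                tuple(sorted((k, str(v)) for k, v in s.static.items())),
            )
        )
    return tuple(parts)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        c1, _ = generate_cohort(small_config())
        c2, _ = generate_cohort(small_config())
        assert cohort_fingerprint(c1) == cohort_fingerprint(c2)

    def test_different_seed_differs(self):
        c1, _ = generate_cohort(small_config())
        c2, _ = generate_cohort(small_config(seed=2))
        assert cohort_fingerprint(c1) != cohort_fingerprint(c2)


class TestBoundaries:
    def test_zero_drivers_zero_noise_flat_sbp(self):
        cfg = small_config(
            driver_coefficients={},
            noise_sd=0.0,
            patient_effect_sd=0.0,
            elapsed_drift=0.0,
            missing_rate_varying=0.0,
            missing_rate_invariant=0.0,
        )
        cohort, truth = generate_cohort(cfg)
        for s in cohort.sessions:
            sbp = s.measurements["sbp"]
            assert np.allclose(sbp, sbp[0])
        assert not any(t.idh2 or t.idhtn for t in truth.sessions.values())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(small_config(n_patients=0))
        with pytest.raises(ConfigurationError):
            generate_cohort(small_config(session_duration_h=(1.0, 4.0)))
        with pytest.raises(ConfigurationError):
            generate_cohort(small_config(missing_rate_varying=1.5))
        with pytest.raises(ConfigurationError):
            generate_cohort(
                small_config(driver_coefficients={"not_a_variable": 1.0})
            )

    def test_session_invariants(self):
        cohort, _ = generate_cohort(small_config(seed=3))
        for s in cohort.sessions:
            s.validate()
            assert s.times[0] == 0.0
            assert 120.0 <= s.duration_min <= 360.0


class TestLabelability:
    def test_generated_sessions_pass_cohort_filters(self):
        cohort, _ = generate_cohort(small_config(seed=4))
        _, tally = filter_sessions(cohort.sessions, FilterCriteria())
        assert tally.kept == tally.total

    def test_violations_fail_filters_when_configured(self):
        cohort, _ = generate_cohort(
            small_config(seed=5, n_patients=60, violation_rate=0.5)
        )
        _, tally = filter_sessions(cohort.sessions, FilterCriteria())
        assert tally.kept < tally.total
        assert sum(tally.excluded.values()) > 0


class TestDriverMonotonicity:
    def test_stronger_uf_driver_does_not_decrease_idh2(self):
        prevalences = []
        for coef in (0.0, 15.0, 40.0):
            cfg = small_config(
                n_patients=80,
                seed=11,
                driver_coefficients={"ultrafiltration_rate": coef},
                driver_shift_sd=1.0,
            )
            _, truth = generate_cohort(cfg)
            prevalences.append(
                np.mean([t.idh2 for t in truth.sessions.values()])
            )
        assert prevalences[0] <= prevalences[1] + 0.02
        assert prevalences[1] <= prevalences[2] + 0.02


class TestPrevalenceOracle:
    def test_idh2_prevalence_matches_independent_resimulation(self):
        """Brute-force oracle: re-simulate the closed-form trajectory
        equations directly (own rng, no generator code) and compare IDH-2
        prevalence within +/- 10 percentage points."""
        coef, drift, noise_sd, pe_sd, rho = 18.0, 8.0, 4.0, 12.0, 0.7
        cfg = SyntheticConfig(
            n_patients=200,
            sessions_per_patient=(4, 8),
            seed=7,
            driver_coefficients={"ultrafiltration_rate": coef},
            elapsed_drift=drift,
            noise_sd=noise_sd,
            patient_effect_sd=pe_sd,
            driver_rho=rho,
        )
        _, truth = generate_cohort(cfg)
        observed = np.mean([t.idh2 for t in truth.sessions.values()])

        rng = np.random.default_rng(999)
        hits = []
        for _ in range(2000):
            base = NORMS["sbp"][0] + rng.normal(0, pe_sd)
            dur = int(60 * rng.uniform(*cfg.session_duration_h))
            z = np.empty(dur + 1)
            z[0] = rng.normal()
            z[1:] = np.sqrt(1 - rho**2) * rng.normal(size=dur)
            for i in range(1, dur + 1):
                z[i] = rho * z[i - 1] + z[i]
            z = rng.normal() + 0.5 * z
            frac = np.arange(dur + 1) / dur
            run_mean = np.cumsum(z) / np.arange(1, dur + 2)
            latent = base - drift * frac - coef * run_mean * frac
            latent += rng.normal(0, noise_sd, size=dur + 1)
            latent = np.clip(latent, 55, 230)
            dbp_all = np.clip(
                0.62 * latent + rng.normal(0, 2, dur + 1), 30, latent - 5
            )
            # adaptive recording grid: hourly, denser below 100 mmHg
            idx = [0]
            while True:
                t = idx[-1]
                step = 20 if latent[t] < 100 else 60
                nxt = t + step
                if nxt > dur or len(idx) >= cfg.max_timesteps:
                    break
                idx.append(nxt)
            sbp, dbp = latent[idx], dbp_all[idx]
            m = (2 * dbp + sbp) / 3
            hits.append(
                np.any(sbp[0] - sbp >= 20) or np.any(m[0] - m >= 10)
            )
        expected = np.mean(hits)
        assert abs(observed - expected) < 0.10


class TestMissingness:
    def test_rate_zero_identity(self):
        cfg = small_config(missing_rate_varying=0.0, missing_rate_invariant=0.0)
        cohort, truth = generate_cohort(cfg)
        for s in cohort.sessions:
            for name, mask in truth.observed_mask[s.session_id].items():
                assert mask.all()
                assert np.array_equal(
                    s.measurements[name], truth.complete[s.session_id][name]
                )

    def test_rate_one_blankets_column_except_initial_bp(self):
        cfg = small_config(missing_rate_varying=1.0)
        cohort, _ = generate_cohort(cfg)
        for s in cohort.sessions:
            hr = s.measurements["heart_rate"]
            assert np.all(np.isnan(hr))
            # initial BP protected so the cohort filter cannot fire
            assert np.isfinite(s.measurements["sbp"][0])
            assert np.isfinite(s.measurements["dbp"][0])

    def test_rate_outside_unit_interval_rejected(self):
        cohort, _ = generate_cohort(small_config())
        with pytest.raises(ConfigurationError):
            inject_missingness(cohort, 0.1, -0.2, seed=0)

    def test_observed_fraction_within_binomial_bounds(self):
        """rate 0.3 over >=10,000 cells: empirical missing fraction within
        the central 99% binomial interval (oracle: scipy binom ppf)."""
        cfg = small_config(
            n_patients=120,
            sessions_per_patient=(4, 6),
            missing_rate_varying=0.3,
            seed=13,
        )
        cohort, truth = generate_cohort(cfg)
        n_cells = 0
        n_missing = 0
        n_bp_cells = 0
        n_bp_missing = 0
        for s in cohort.sessions:
            masks = truth.observed_mask[s.session_id]
            for name, mask in masks.items():
                if name in ("sbp", "dbp"):
                    # BP cells carry a gap-safety carve-out: some draws are
                    # vetoed, so the realized rate can only be <= nominal
                    n_bp_cells += len(mask) - 1
                    n_bp_missing += int((~mask[1:]).sum())
                    continue
                n_cells += len(mask)
                n_missing += int((~mask).sum())
        assert n_cells >= 10_000
        lo = sps.binom.ppf(0.005, n_cells, 0.3)
        hi = sps.binom.ppf(0.995, n_cells, 0.3)
        assert lo <= n_missing <= hi
        assert n_bp_missing / n_bp_cells <= 0.3 + 0.02


class TestIO:
    @pytest.mark.parametrize("fmt", ["csv", "parquet"])
    def test_cohort_round_trip(self, tmp_path, fmt):
        from hdtft.data import Cohort

        cohort, truth = generate_cohort(small_config(seed=9))
        cohort.write(tmp_path, fmt=fmt)
        back = Cohort.read(tmp_path, cohort.schema)
        assert len(back) == len(cohort)
        for a, b in zip(
            sorted(cohort.sessions, key=lambda s: s.session_id),
            sorted(back.sessions, key=lambda s: s.session_id),
        ):
            assert a.session_id == b.session_id
            assert np.allclose(a.times, b.times)
            obs = np.isfinite(a.measurements["sbp"])
            assert np.allclose(
                a.measurements["sbp"][obs], b.measurements["sbp"][obs]
            )

    def test_truth_sidecar_json(self, tmp_path):
        from hdtft.synthetic import write_cohort

        cohort, truth = generate_cohort(small_config(seed=9))
        write_cohort(cohort, truth, tmp_path)
        import json

        payload = json.loads((tmp_path / "ground_truth.json").read_text())
        assert set(payload["sessions"]) == {
            s.session_id for s in cohort.sessions
        }
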