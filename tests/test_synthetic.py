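"""Generator correctness: analytic construction, schedules, determinism."""

import numpy as np
import pytest
from scipy import stats as sstats

from rhythmkit.synthetic import (
    MINUTES_PER_DAY,
    MOOD_LOADINGS,
    ChannelSpec,
    CohortSpec,
    ConfigurationError,
    GroupSpec,
    MoodSpec,
    generate_cohort,
    generate_participant,
    read_cohort,
    write_cohort,
)

from conftest import make_spec


class TestChannelConstruction:
    def test_noiseless_hr_matches_analytic_sinusoid(self, noiseless_recording):
        """With no noise/artifacts, hr[t] = M + A*cos(2*pi*(t-phase)/24) exactly."""
        t_h = noiseless_recording.t_min / 60.0
        expected = 75.0 + 8.0 * np.cos(2 * np.pi * (t_h - 14.0) / 24.0)
        assert np.nanmax(np.abs(noiseless_recording.hr - expected)) < 1e-9

    def test_noiseless_channels_pass_residual_check(self, noiseless_recording):
        """All noiseless channels equal their analytic sinusoid sum to 1e-9."""
        t_h = noiseless_recording.t_min / 60.0
        for axis, name in (("x", "accel_x"), ("y", "accel_y"), ("z", "accel_z")):
            ch = noiseless_recording.ground_truth["channels"][name]
            expected = ch.mesor + ch.amplitude * np.cos(
                2 * np.pi * (t_h - ch.phase_hours) / 24.0
            )
            assert np.nanmax(np.abs(noiseless_recording.accel[axis] - expected)) < 1e-9

    def test_ultradian_component_present_at_4_cycles_per_day(self):
        spec = make_spec(hr=ChannelSpec(14.0, 75.0, 8.0, ultradian_amplitude=3.0))
        rec = generate_participant(spec, "G", np.random.default_rng(0))
        t_h = rec.t_min / 60.0
        expected = (
            75.0
            + 8.0 * np.cos(2 * np.pi * (t_h - 14.0) / 24.0)
            + 3.0 * np.cos(2 * np.pi * 4.0 * (t_h - 14.0) / 24.0)
        )
        assert np.nanmax(np.abs(rec.hr - expected)) < 1e-9


class TestMoodPrompts:
    def test_ten_prompts_per_day_within_window(self, noiseless_recording):
        """Default schedule: exactly 10 prompts per calendar day, 10:00-20:00."""
        days = np.array([e.timestamp // MINUTES_PER_DAY for e in noiseless_recording.mood])
        counts = np.bincount(days, minlength=4)
        assert list(counts) == [10, 10, 10, 10]
        minutes_of_day = np.array(
            [e.timestamp % MINUTES_PER_DAY for e in noiseless_recording.mood]
        )
        assert minutes_of_day.min() >= 10 * 60
        assert minutes_of_day.max() <= 20 * 60

    def test_timestamps_strictly_increasing(self, noiseless_recording):
        stamps = [e.timestamp for e in noiseless_recording.mood]
        assert all(b > a for a, b in zip(stamps, stamps[1:]))

    def test_quantization_error_at_most_half_likert_unit(self):
        """Noiseless items differ from the latent signal by <= 0.5 (rounding)."""
        mood = MoodSpec(noise_sd=0.0, positive_amplitude=1.0, coupling_irritable=0.5)
        spec = make_spec(mood=mood, hr=ChannelSpec(14.0, 75.0, 8.0, ultradian_amplitude=2.0))
        rec = generate_participant(spec, "G", np.random.default_rng(1))
        t_h = np.array([e.timestamp for e in rec.mood]) / 60.0
        hr_ultra = np.cos(2 * np.pi * 4.0 * (t_h - 14.0) / 24.0)
        latents = np.stack(
            [
                np.full_like(t_h, mood.level_negative),
                mood.level_positive
                + mood.positive_amplitude
                * np.cos(2 * np.pi * (t_h - mood.positive_phase_hours) / 24.0),
                mood.level_irritable + mood.coupling_irritable * hr_ultra,
            ],
            axis=1,
        )
        latent_items = latents @ MOOD_LOADINGS.T
        items = np.array([e.items for e in rec.mood], dtype=float)
        assert np.all(np.abs(items - latent_items) <= 0.5 + 1e-12)

    def test_items_on_likert_grid(self, noiseless_recording):
        items = np.array([e.items for e in noiseless_recording.mood])
        assert items.min() >= 0 and items.max() <= 6


class TestArtifactsAndMissingness:
    def test_spike_count_within_binomial_band(self):
        """Spike counts across 100 seeds behave like Binomial(5760, 0.01)."""
        n, rate = 4 * MINUTES_PER_DAY, 0.01
        lo, hi = sstats.binom.ppf([0.005, 0.995], n, rate)
        counts = []
        for seed in range(100):
            spec = make_spec(
                days=4, hr=ChannelSpec(14.0, 75.0, 8.0, artifact_rate=rate)
            )
            rec = generate_participant(spec, "G", np.random.default_rng(seed))
            counts.append(rec.diagnostics["artifacts"]["hr"])
        counts = np.asarray(counts)
        inside = np.mean((counts >= lo) & (counts <= hi))
        assert inside >= 0.95
        assert abs(counts.mean() - n * rate) < 4 * np.sqrt(n * rate * (1 - rate) / 100)

    def test_missingness_contiguous_and_near_target(self):
        spec = make_spec(
            days=4, hr=ChannelSpec(14.0, 75.0, 8.0, missing_fraction=0.1)
        )
        rec = generate_participant(spec, "G", np.random.default_rng(5))
        miss = ~np.isfinite(rec.hr)
        frac = miss.mean()
        assert 0.05 < frac < 0.15
        # contiguity: far fewer runs than missing samples
        n_runs = int(np.sum(np.diff(miss.astype(int)) == 1) + miss[0])
        assert n_runs < 0.2 * miss.sum()

    def test_hr_positive_where_present(self):
        spec = make_spec(
            days=4,
            hr=ChannelSpec(14.0, 75.0, 8.0, noise_sd=3.0, artifact_rate=0.01),
        )
        rec = generate_participant(spec, "G", np.random.default_rng(2))
        assert np.all(rec.hr[np.isfinite(rec.hr)] > 0)


class TestCohortGeneration:
    def test_seed_determinism_byte_identical_files(self, tmp_path):
        spec = make_spec(days=2, seed=9)
        for sub in ("a", "b"):
            recs, manifest = generate_cohort(spec)
            write_cohort(recs, manifest, tmp_path / sub)
        for name in ("G-01/accel.csv", "G-01/hr.csv", "G-01/mood.csv", "G-01/manifest.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_roundtrip_through_csv(self, tmp_path):
        spec = make_spec(days=2, seed=4, hr=ChannelSpec(14.0, 75.0, 8.0, missing_fraction=0.05))
        recs, manifest = generate_cohort(spec)
        write_cohort(recs, manifest, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == 1
        orig, re = recs[0], back[0]
        assert re.group == orig.group and len(re.t_min) == len(orig.t_min)
        both = np.isfinite(orig.hr) & np.isfinite(re.hr)
        assert np.isfinite(re.hr).sum() == np.isfinite(orig.hr).sum()
        assert np.allclose(orig.hr[both], re.hr[both], atol=1e-5)
        assert [e.items for e in re.mood] == [e.items for e in orig.mood]

    def test_empty_group_accepted_with_warning(self):
        groups = [
            make_spec().groups[0],
            GroupSpec(
                label="EMPTY",
                n_participants=0,
                channels=make_spec().groups[0].channels,
            ),
        ]
        spec = CohortSpec(groups=groups, days=1, seed=0)
        with pytest.warns(UserWarning, match="EMPTY"):
            recs, manifest = generate_cohort(spec)
        assert manifest["groups"]["EMPTY"]["n_participants"] == 0
        assert len(recs) == 1

    def test_frequency_domain_cohort_sizes(self):
        """The 18/14/20 configuration generates without id clashes."""
        base = make_spec().groups[0].channels
        groups = [
            GroupSpec(label=lab, n_participants=n, channels=base)
            for lab, n in (("BD", 18), ("BPD", 14), ("HC", 20))
        ]
        recs, manifest = generate_cohort(CohortSpec(groups=groups, days=1, seed=1))
        assert len(recs) == 52
        assert len({r.id for r in recs}) == 52

    def test_hr_lag_realized_per_participant(self):
        spec = make_spec(days=2, hr_lag_hours=3.0, hr_lag_sd_hours=0.0)
        rec = generate_participant(spec, "G", np.random.default_rng(0))
        assert rec.ground_truth["hr_lag_hours"] == pytest.approx(3.0)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs, fieldname",
        [
            (dict(phase_hours=25.0, mesor=1.0, amplitude=1.0), "phase_hours"),
            (dict(phase_hours=1.0, mesor=1.0, amplitude=-1.0), "amplitude"),
            (dict(phase_hours=1.0, mesor=1.0, amplitude=1.0, missing_fraction=1.0),
             "missing_fraction"),
        ],
    )
    def test_channel_spec_errors_name_the_field(self, kwargs, fieldname):
        with pytest.raises(ConfigurationError, match=fieldname):
            ChannelSpec(**kwargs)

    def test_duplicate_group_labels_rejected(self):
        g = make_spec().groups[0]
        with pytest.raises(ConfigurationError, match="distinct"):
            CohortSpec(groups=[g, g], days=1, seed=0)
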