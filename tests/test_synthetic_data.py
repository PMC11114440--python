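import numpy as np
import pytest

from plihub.montage_io import DEFAULT_MONTAGE
from plihub.pipeline import PreprocessSettings, cohort_connectivity
from plihub.synthetic_data import (
    BprsModel,
    CohortConfig,
    HubSpec,
    default_hubs_by_group,
    generate_cohort,
    generate_paired_sessions,
    generate_subject,
)

LBL = list(DEFAULT_MONTAGE.labels)


class TestSpecValidation:
    def test_hub_cannot_target_itself(self):
        with pytest.raises(ValueError):
            HubSpec("Fz", "beta", ("Fz", "F3"))

    @pytest.mark.parametrize("lag", [0.0, np.pi, 2 * np.pi])
    def test_invisible_lags_rejected_when_coupled(self, lag):
        with pytest.raises(ValueError, match="invisible"):
            HubSpec("Fz", "beta", ("F3",), coupling=0.5, lag=lag)

    def test_zero_coupling_permits_any_lag(self):
        HubSpec("Fz", "beta", ("F3",), coupling=0.0, lag=0.0)

    def test_coupling_range(self):
        with pytest.raises(ValueError):
            HubSpec("Fz", "beta", ("F3",), coupling=1.2)

    def test_duration_floor(self):
        with pytest.raises(ValueError):
            CohortConfig(duration_s=5)

    def test_unknown_hub_electrode_raises(self):
        cfg = CohortConfig(
            n_per_group={"control": 1},
            duration_s=30,
            hubs_by_group={"control": (HubSpec("Cz", "beta", ("F3",)),)},
        )
        rng = np.random.default_rng(0)
        with pytest.raises(KeyError):
            generate_subject(cfg, "control", rng)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_per_group={"control": 2, "patient": 2},
                           duration_s=30, seed=11)
        recs_a, meta_a = generate_cohort(cfg)
        recs_b, meta_b = generate_cohort(cfg)
        assert meta_a == meta_b
        for a, b in zip(recs_a, recs_b):
            assert np.array_equal(a.data, b.data)

    def test_subjects_stable_under_group_size_change(self):
        small = CohortConfig(n_per_group={"control": 2, "patient": 1},
                             duration_s=30, seed=11)
        large = CohortConfig(n_per_group={"control": 3, "patient": 2},
                             duration_s=30, seed=11)
        ra, _ = generate_cohort(small)
        rb, _ = generate_cohort(large)
        ids_b = {r.subject_id: r for r in rb}
        for r in ra:
            assert np.array_equal(r.data, ids_b[r.subject_id].data)


class TestCohortShape:
    def test_study_sized_cohort(self):
        cfg = CohortConfig(n_per_group={"control": 31, "patient": 21},
                           duration_s=30, seed=3)
        recs, metas = generate_cohort(cfg)
        assert len(recs) == 52
        assert sum(m.group == "control" for m in metas) == 31
        assert sum(m.group == "patient" for m in metas) == 21
        assert recs[0].data.shape == (16, 6000)
        assert all(m.bprs is None for m in metas if m.group == "control")
        assert all(m.bprs is not None for m in metas if m.group == "patient")

    def test_uncorrelated_bprs_stays_within_sampling_error(self):
        cfg = CohortConfig(n_per_group={"control": 2, "patient": 21},
                           duration_s=30, seed=5,
                           bprs_model=BprsModel(rho=0.0))
        _, metas = generate_cohort(cfg)
        # recompute each patient's latent trait from its substream
        mults, scores = [], []
        from plihub.synthetic_data import _subject_rng
        gi = sorted(cfg.n_per_group).index("patient")
        for si, m in enumerate([m for m in metas if m.group == "patient"]):
            rng = _subject_rng(cfg.seed, gi, si)
            u = rng.standard_normal()
            mults.append(1 + cfg.coupling_jitter_sd * u)
            scores.append(m.bprs)
        r = np.corrcoef(mults, scores)[0, 1]
        assert abs(r) < 0.3

    def test_target_bprs_correlation_tracks_trait(self):
        cfg = CohortConfig(n_per_group={"control": 2, "patient": 40},
                           duration_s=30, seed=5,
                           bprs_model=BprsModel(rho=0.8))
        _, metas = generate_cohort(cfg)
        from plihub.synthetic_data import _subject_rng
        gi = sorted(cfg.n_per_group).index("patient")
        mults = []
        for si in range(40):
            rng = _subject_rng(cfg.seed, gi, si)
            mults.append(rng.standard_normal())
        scores = [m.bprs for m in metas if m.group == "patient"]
        r = np.corrcoef(mults, scores)[0, 1]
        assert r > 0.5


class TestPlantedStructure:
    def test_full_coupling_no_noise_gives_near_unit_pli(self, warm_kernel):
        targets = tuple(l for l in LBL if l != "Fz")
        cfg = CohortConfig(
            n_per_group={"control": 1},
            duration_s=40, seed=21,
            hubs_by_group={"control": (HubSpec("Fz", "beta", targets,
                                               coupling=1.0, lag=np.pi / 4),)},
            common_source_gain=0.0, noise_gain=0.0, coupling_jitter_sd=0.0,
        )
        recs, _ = generate_cohort(cfg)
        conn = cohort_connectivity(recs)["beta"][0]
        fz = LBL.index("Fz")
        vals = [conn.values[fz, LBL.index(t)] for t in targets]
        assert min(vals) > 0.95  # perfect fixed-lag coupling

    def test_zero_lag_common_source_invisible_to_pli(self, warm_kernel):
        """A dominant shared zero-lag source inflates amplitude correlation
        but not PLI.  Long epochs keep the estimator's sampling floor
        (~1/sqrt(T x bandwidth)) below the 0.1 line even in the delta band."""
        cfg = CohortConfig(
            n_per_group={"control": 1}, duration_s=600, seed=22,
            hubs_by_group={"control": ()}, band_amplitude_uv={},
            common_source_gain=8.0, noise_gain=0.5, coupling_jitter_sd=0.0,
        )
        recs, _ = generate_cohort(cfg)
        data = recs[0].data.astype(float)
        off = np.corrcoef(data)[~np.eye(16, dtype=bool)]
        assert np.median(off) > 0.8  # heavy zero-lag mixing...
        settings = PreprocessSettings(epoch_len_s=200.0, drop_edge_epochs=False)
        conn = cohort_connectivity(recs, settings)
        for band in conn:
            v = conn[band][0].values
            assert v[~np.eye(16, dtype=bool)].max() < 0.1, band  # ...PLI ignores

    def test_independent_channels_have_low_pli(self, warm_kernel):
        """Fast bands at the default 5-s epochs; slow bands carry a higher
        finite-sample floor (few independent phase samples per epoch)."""
        cfg = CohortConfig(
            n_per_group={"control": 1}, duration_s=40, seed=23,
            hubs_by_group={"control": ()},
            common_source_gain=0.0, noise_gain=0.5, coupling_jitter_sd=0.0,
        )
        recs, _ = generate_cohort(cfg)
        conn = cohort_connectivity(recs)
        for band in ("beta", "gamma"):
            v = conn[band][0].values
            assert np.median(v[~np.eye(16, dtype=bool)]) < 0.15


class TestPairedSessions:
    def test_sessions_paired_and_reproducible(self):
        cfg = CohortConfig(n_per_group={"control": 2, "patient": 3},
                           duration_s=30, seed=9)
        post_hubs = default_hubs_by_group(strong=0.5, weak=0.3)
        pre_a, post_a, metas = generate_paired_sessions(cfg, post_hubs)
        pre_b, post_b, _ = generate_paired_sessions(cfg, post_hubs)
        assert len(pre_a) == len(post_a) == 3
        for a, b in zip(pre_a + post_a, pre_b + post_b):
            assert np.array_equal(a.data, b.data)
        # same subject, different coupling: signals differ but share noise seed
        assert not np.array_equal(pre_a[0].data, post_a[0].data)
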