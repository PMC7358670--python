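"""Generator contracts: determinism, zero-noise collapse, parameter structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from vacuoquant.synth import (
    DEFAULT_VAC_FRACTION,
    ImageParams,
    CohortConfig,
    SeverityClass,
    expected_affected_fraction,
    generate_cell_image,
    generate_cohort,
    generate_flow_sample,
    peaked_pmf,
)


class TestCohort:
    def test_identical_seed_gives_identical_cohort(self, small_cohort_config):
        df1, pats1 = generate_cohort(small_cohort_config)
        df2, pats2 = generate_cohort(small_cohort_config)
        pd.testing.assert_frame_equal(df1, df2)
        assert [p.random_intercept for p in pats1] == [
            p.random_intercept for p in pats2
        ]

    def test_zero_noise_classical_counts_are_exact(self):
        cfg = CohortConfig(
            n_patients_per_class={"classical": 5},
            random_intercept_sd=0.0,
            random_slope_sd=0.0,
            observer_sd=0.0,
            seed=3,
        )
        df, _ = generate_cohort(cfg)
        assert (df["n_vacuolated"] == 30).all()
        assert (df["n_counted"] == 100).all()

    def test_classical_fractions_span_reported_range(self):
        """Classical-disease vacuolated percentages concentrate around ~30 %
        with spread comparable to the reported 11-69 % patient range."""
        cfg = CohortConfig(n_patients_per_class={"classical": 60}, seed=9)
        df, _ = generate_cohort(cfg)
        pct = 100.0 * df["n_vacuolated"] / df["n_counted"]
        assert 20 < np.median(pct) < 40
        lo, hi = np.percentile(pct, [2.5, 97.5])
        assert lo > 8 and hi < 72

    def test_between_patient_variance_recovers_intercept_sd(self):
        """Empirical variance of per-patient logit fractions matches the
        configured random-intercept variance (Monte-Carlo identity)."""
        cfg = CohortConfig(
            n_patients_per_class={"classical": 200},
            samples_per_patient=(1, 1),
            random_slope_sd=0.0,
            observer_sd=0.0,
            n_cells_counted=20000,
            n_observers=1,
            seed=17,
        )
        df, _ = generate_cohort(cfg)
        lo = logit(df["n_vacuolated"] / df["n_counted"])
        assert np.var(lo, ddof=1) == pytest.approx(
            cfg.random_intercept_sd**2, rel=0.15
        )

    def test_vacuole_counts_respect_cap_and_support(self, small_cohort_config):
        df, _ = generate_cohort(small_cohort_config)
        for _, row in df.iterrows():
            counts = [int(c) for c in str(row["vacuole_counts"]).split(";") if c]
            assert len(counts) <= min(20, row["n_vacuolated"])
            assert all(c >= 1 for c in counts)

    def test_empty_class_map_and_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_patients_per_class={}))
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(observer_sd=-0.1))

    def test_sample_ages_sorted(self, small_cohort_config):
        _, patients = generate_cohort(small_cohort_config)
        for p in patients:
            assert p.sample_ages == sorted(p.sample_ages)


class TestClassStructure:
    def test_default_vac_fractions_monotone_in_rank(self):
        ordered = [DEFAULT_VAC_FRACTION[c] for c in SeverityClass]
        assert ordered == sorted(ordered)

    def test_t_cell_affected_monotone_except_retina_only(self):
        ranks = [c for c in SeverityClass if c is not SeverityClass.RETINA_ONLY]
        vals = [expected_affected_fraction(c, "T4") for c in ranks]
        assert vals == sorted(vals)
        # retina-only: near-control T-cell signal, dominant B-cell signal
        assert expected_affected_fraction("retina_only", "T4") < 0.05
        b_by_class = {
            c.value: expected_affected_fraction(c, "B") for c in SeverityClass
        }
        assert max(b_by_class, key=b_by_class.get) == "retina_only"


class TestFlow:
    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            generate_flow_sample("control", 0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            generate_flow_sample("severe", 100)

    def test_control_affected_matches_baseline(self):
        ev = generate_flow_sample("control", 30000, seed=5)
        base = CohortConfig().affected_baseline
        for subset in ("T4", "T8", "B"):
            sub = ev[ev["true_subset"] == subset]
            p_hat = sub["true_affected"].mean()
            se = np.sqrt(base * (1 - base) / len(sub))
            assert abs(p_hat - base) <= 3 * se

    def test_classical_lamp_exceeds_control(self):
        cl = generate_flow_sample("classical", 5000, seed=6)
        co = generate_flow_sample("control", 5000, seed=6)
        assert (
            cl.loc[cl["true_subset"] != "NK", "LAMP1"].mean()
            > co.loc[co["true_subset"] != "NK", "LAMP1"].mean()
        )

    def test_nk_events_coelevate_lamp_and_perforin(self):
        ev = generate_flow_sample("control", 20000, seed=7)
        nk = ev[ev["true_subset"] == "NK"]
        rest = ev[ev["true_subset"] == "other"]
        assert nk["LAMP1"].mean() > rest["LAMP1"].mean() + 1.0
        assert nk["PERFORIN"].mean() > rest["PERFORIN"].mean() + 1.0
        assert np.corrcoef(nk["LAMP1"], nk["PERFORIN"])[0, 1] > 0.9

    def test_affected_implies_elevated_lamp(self):
        ev = generate_flow_sample("classical", 20000, seed=8)
        aff = ev[ev["true_affected"]]
        not_aff = ev[~ev["true_affected"] & (ev["true_subset"] != "NK")
                     & (ev["LAMP1"] < 2.0)]
        assert aff["LAMP1"].min() > not_aff["LAMP1"].mean()

    def test_determinism(self):
        a = generate_flow_sample("protracted", 1000, seed=11)
        b = generate_flow_sample("protracted", 1000, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestCellImage:
    def test_uniform_cytoplasm_mean_is_exact(self):
        params = ImageParams(noise_sd=0.0)
        pair = generate_cell_image("control", 0, seed=1, params=params)
        v = params.cytoplasm_lamp1_by_class[SeverityClass.CONTROL]
        assert pair.true_mean_lamp1 == v
        assert float(pair.lamp1_channel[pair.true_mask].mean()) == v

    def test_vacuolated_cell_brighter_than_same_base_control(self):
        flat = {c: 40.0 for c in SeverityClass}
        params = ImageParams(noise_sd=0.0, cytoplasm_lamp1_by_class=flat)
        rich = generate_cell_image("classical", 10, seed=2, params=params)
        empty = generate_cell_image("control", 0, seed=2, params=params)
        assert rich.true_mean_lamp1 > empty.true_mean_lamp1

    def test_batch_regeneration_is_pixel_identical(self):
        for j in range(100):
            a = generate_cell_image("classical", 8, seed=1000 + j)
            b = generate_cell_image("classical", 8, seed=1000 + j)
            assert np.array_equal(a.cd4_channel, b.cd4_channel)
            assert np.array_equal(a.lamp1_channel, b.lamp1_channel)

    def test_unplaceable_vacuoles_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_image(
                "classical", 1, seed=0, params=ImageParams(vacuole_radius=30.0)
            )
        with pytest.raises(ValueError):
            generate_cell_image("classical", 500, seed=0)

    def test_channels_are_8bit_and_same_shape(self):
        pair = generate_cell_image("protracted", 5, seed=3)
        assert pair.cd4_channel.dtype == np.uint8
        assert pair.cd4_channel.shape == pair.lamp1_channel.shape
        assert pair.true_mask.shape == pair.cd4_channel.shape

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_image("control", 0, image_size=(16, 16))


def test_peaked_pmf_median_matches_reported_values():
    """Default vacuoles-per-cell distributions reproduce the reported medians
    (10 for classical on 6-18, 8 for protracted on 3-12)."""
    for lo, mode, hi in ((6, 10, 18), (3, 8, 12)):
        pmf = peaked_pmf(lo, mode, hi)
        vals = np.array(sorted(pmf))
        probs = np.array([pmf[v] for v in vals])
        cum = np.cumsum(probs)
        median = vals[np.searchsorted(cum, 0.5)]
        assert median == mode
        assert abs(sum(pmf.values()) - 1.0) < 1e-12
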