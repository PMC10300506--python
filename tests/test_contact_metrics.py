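"""Force, contact area, CoP/CoC and their summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from solepress.contact_metrics import (
    centre_of_contact,
    centre_of_pressure,
    compute_frame_metrics,
    contact_area,
    contact_probability_map,
    cop_coc_relationship,
    cop_contact_stats,
    exclude_low_force,
    force_area_relationship,
    total_force,
)
from solepress.foot_model import PressureRecording, cell_centres


# ---------------------------------------------------------------- oracles

def brute_force_pct(frame, area_cm2, mass_kg):
    s = 0.0
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            s += frame[i, j]
    return 100.0 * s * area_cm2 * 0.1 / (mass_kg * 9.81)


def brute_centroids(frame, threshold=0.0):
    n_rows, n_cols = frame.shape
    wsum = np.zeros(2)
    usum = np.zeros(2)
    wtot = 0.0
    count = 0
    for i in range(n_rows):
        for j in range(n_cols):
            if frame[i, j] > threshold:
                ap = (i + 0.5) / n_rows
                ml = (j + 0.5) / n_cols
                wsum += frame[i, j] * np.array([ap, ml])
                wtot += frame[i, j]
                usum += np.array([ap, ml])
                count += 1
    cop = wsum / wtot if wtot > 0 else np.array([np.nan, np.nan])
    coc = usum / count if count > 0 else np.array([np.nan, np.nan])
    return cop, coc, count


# ----------------------------------------------------------------- tests

class TestTotalForce:
    def test_zero_frame(self):
        assert total_force(np.zeros((5, 4)), 0.258, 70.0) == 0.0

    def test_engineered_100_percent(self):
        mass, area = 70.0, 0.258
        frame = np.zeros((10, 5))
        frame[3, 2] = mass * 9.81 / (area * 0.1)
        assert total_force(frame, area, mass) == pytest.approx(100.0)

    def test_matches_brute_force_oracle(self, rng):
        frame = rng.uniform(0, 300, (56, 20))
        assert total_force(frame, 0.258, 64.7) == pytest.approx(
            brute_force_pct(frame, 0.258, 64.7), abs=1e-9
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            total_force(np.ones((2, 2)), 0.258, 0.0)


class TestExcludeLowForce:
    def test_boundary_inclusive_at_floor(self):
        df = pd.DataFrame({"force_pct_bm": [0.0, 4.9, 5.0, 80.0]})
        out = exclude_low_force(df, 5.0)
        assert list(out["force_pct_bm"]) == [5.0, 80.0]

    def test_floor_zero_keeps_everything(self):
        df = pd.DataFrame({"force_pct_bm": [0.0, 1.0, 2.0]})
        assert len(exclude_low_force(df, 0.0)) == 3


class TestContactArea:
    def test_full_contact(self, outline):
        frame = np.where(outline.in_outline_mask, 10.0, 0.0)
        assert contact_area(frame, outline) == pytest.approx(100.0)

    def test_half_contact(self, outline):
        n_in = outline.in_outline_mask.sum()
        rows, cols = np.nonzero(outline.in_outline_mask)
        frame = np.zeros(outline.grid.shape)
        frame[rows[: n_in // 2], cols[: n_in // 2]] = 5.0
        assert contact_area(frame, outline) == pytest.approx(
            100.0 * (n_in // 2) / n_in
        )

    def test_matches_count_oracle(self, outline, rng):
        frame = rng.uniform(0, 1, outline.grid.shape)
        frame[frame < 0.5] = 0.0
        active = 0
        for i in range(56):
            for j in range(20):
                if outline.in_outline_mask[i, j] and frame[i, j] > 0:
                    active += 1
        expected = 100.0 * active / outline.in_outline_mask.sum()
        assert contact_area(frame, outline) == pytest.approx(expected)


class TestContactProbabilityMap:
    def test_always_never_and_alternating(self, outline):
        T = 10
        frames = np.zeros((T,) + outline.grid.shape)
        frames[:, 10, 10] = 5000.0        # always active, carries the load
        frames[::2, 30, 10] = 1000.0      # alternating
        rec = PressureRecording(frames, outline.grid, body_mass_kg=10.0)
        prob = contact_probability_map(rec, floor_pct=0.0)
        assert prob[10, 10] == 1.0
        assert prob[30, 10] == 0.5
        assert prob[0, 10] == 0.0

    def test_empty_after_exclusion_rejected(self, outline):
        frames = np.zeros((5,) + outline.grid.shape)
        rec = PressureRecording(frames, outline.grid)
        with pytest.raises(ValueError):
            contact_probability_map(rec)


class TestCentroids:
    def test_equal_pressures_symmetric(self):
        frame = np.zeros((10, 5))
        frame[1, 2] = 7.0   # AP (1+.5)/10 = 0.15
        frame[7, 2] = 7.0   # AP 0.75
        cop = centre_of_pressure(frame)
        assert cop[0] == pytest.approx(0.45)

    def test_weighted_mean_three_to_one(self):
        frame = np.zeros((2, 1))
        frame[0, 0] = 3.0   # AP 0.25
        frame[1, 0] = 1.0   # AP 0.75
        cop = centre_of_pressure(frame)
        assert cop[0] == pytest.approx(0.375)  # (0.25*3 + 0.75*1)/4
        coc = centre_of_contact(frame)
        assert coc[0] == pytest.approx(0.5)    # weights ignored

    def test_single_cell_cop_equals_coc(self, rng):
        frame = np.zeros((8, 6))
        frame[3, 4] = rng.uniform(1, 10)
        assert centre_of_pressure(frame) == centre_of_contact(frame)

    def test_empty_frame_gives_nan_sentinel(self):
        cop = centre_of_pressure(np.zeros((4, 3)))
        assert np.isnan(cop[0]) and np.isnan(cop[1])

    def test_matches_brute_force_oracle(self, rng):
        frame = rng.uniform(0, 10, (56, 20))
        frame[frame < 3] = 0.0
        cop_o, coc_o, _ = brute_centroids(frame)
        assert centre_of_pressure(frame) == pytest.approx(tuple(cop_o), abs=1e-9)
        assert centre_of_contact(frame) == pytest.approx(tuple(coc_o), abs=1e-9)

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 999))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cop_invariant_to_positive_scaling(self, scale, seed):
        frame = np.random.default_rng(seed).uniform(0, 5, (12, 8))
        a = centre_of_pressure(frame)
        b = centre_of_pressure(frame * scale)
        assert a == pytest.approx(b, abs=1e-12)

    def test_cop_inside_hull_coc_inside_bbox(self, rng):
        for _ in range(50):
            frame = rng.uniform(0, 5, (20, 10))
            frame[frame < 4] = 0.0
            if not (frame > 0).any():
                continue
            rows, cols = np.nonzero(frame > 0)
            ap, ml = cell_centres(20, 10)
            cop = centre_of_pressure(frame)
            coc = centre_of_contact(frame)
            for c in (cop, coc):
                assert ap[rows.min()] - 1e-12 <= c[0] <= ap[rows.max()] + 1e-12
                assert ml[cols.min()] - 1e-12 <= c[1] <= ml[cols.max()] + 1e-12


class TestCopContactStats:
    def test_single_active_cell_always_in_contact(self, outline):
        frames = np.zeros((5,) + outline.grid.shape)
        frames[:, 10, 10] = 40000.0
        rec = PressureRecording(frames, outline.grid, body_mass_kg=70.0)
        stats = cop_contact_stats(rec, outline)
        assert stats.fraction_in_contact == 1.0
        assert stats.mean_pressure_percentile == pytest.approx(100.0)
        assert stats.region_occupancy_pct["heel"] == 100.0

    def test_bimodal_loading_puts_cop_outside_contact(self, outline):
        # equal blobs at heel and metatarsals: CoP lands on the unloaded arch
        frames = np.zeros((3,) + outline.grid.shape)
        frames[:, 6:10, 8:12] = 2000.0
        frames[:, 36:40, 8:12] = 2000.0
        rec = PressureRecording(frames, outline.grid, body_mass_kg=70.0)
        stats = cop_contact_stats(rec, outline)
        assert stats.fraction_in_contact == 0.0
        assert stats.region_occupancy_pct["arch"] == 100.0

    def test_region_occupancy_sums_to_100(self, standing_pair, outline):
        recs, _ = standing_pair
        stats = cop_contact_stats(recs["right"], outline)
        assert sum(stats.region_occupancy_pct.values()) == pytest.approx(100.0)

    def test_walking_cop_in_contact_more_than_standing(
        self, standing_pair, walking_recording, outline
    ):
        """Single-support gait keeps the CoP on loaded cells; two-region
        standing pushes it into the unloaded arch."""
        recs, _ = standing_pair
        walk, _ = walking_recording
        standing_stats = cop_contact_stats(recs["right"], outline)
        walking_stats = cop_contact_stats(walk, outline)
        assert walking_stats.fraction_in_contact > standing_stats.fraction_in_contact


class TestCopCocRelationship:
    def test_identical_series_r2_one(self, rng):
        n = 50
        cop = rng.uniform(0.2, 0.8, (n, 2))
        df = pd.DataFrame({
            "cop_ap": cop[:, 0], "cop_ml": cop[:, 1],
            "coc_ap": cop[:, 0], "coc_ml": cop[:, 1],
        })
        out = cop_coc_relationship(df)
        assert out["r2_ap"] == pytest.approx(1.0)
        assert out["r2_ml"] == pytest.approx(1.0)
        assert np.allclose(out["dist_ap_pct_length"], 0.0)

    def test_constant_coc_gives_nan_sentinel(self, rng):
        n = 20
        df = pd.DataFrame({
            "cop_ap": rng.uniform(0, 1, n), "cop_ml": rng.uniform(0, 1, n),
            "coc_ap": np.full(n, 0.5), "coc_ml": np.full(n, 0.5),
        })
        out = cop_coc_relationship(df)
        assert np.isnan(out["r2_ap"]) and np.isnan(out["r2_ml"])

    def test_planted_affine_relation_matches_pearson_oracle(self, rng):
        n = 500
        coc = rng.uniform(0.2, 0.8, n)
        cop = 0.8 * coc + 0.1 + rng.normal(0, 0.02, n)
        df = pd.DataFrame({
            "cop_ap": cop, "cop_ml": cop, "coc_ap": coc, "coc_ml": coc,
        })
        out = cop_coc_relationship(df)
        r_oracle = np.corrcoef(cop, coc)[0, 1] ** 2
        assert out["r2_ap"] == pytest.approx(r_oracle, abs=1e-6)


class TestForceAreaRelationship:
    def test_monotone_relation_rho_one(self):
        df = pd.DataFrame({
            "force_pct_bm": np.arange(20.0),
            "contact_area_pct": np.arange(20.0) ** 2,
        })
        out = force_area_relationship(df)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_independent_inputs_near_zero(self, rng):
        df = pd.DataFrame({
            "force_pct_bm": rng.permutation(1000).astype(float),
            "contact_area_pct": rng.permutation(1000).astype(float),
        })
        out = force_area_relationship(df)
        assert abs(out["spearman_rho"]) < 0.1

    def test_ties_match_midrank_oracle(self):
        force = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0, 5.0])
        area = np.array([2.0, 2.0, 2.0, 5.0, 5.0, 6.0, 6.0, 6.0, 9.0, 9.0])

        def midranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            sx = x[order]
            while i < len(x):
                j = i
                while j < len(x) and sx[j] == sx[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rf, ra = midranks(force), midranks(area)
        oracle = np.corrcoef(rf, ra)[0, 1]
        df = pd.DataFrame({"force_pct_bm": force, "contact_area_pct": area})
        out = force_area_relationship(df)
        assert out["spearman_rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_gives_sentinel(self):
        df = pd.DataFrame({
            "force_pct_bm": np.full(20, 50.0),
            "contact_area_pct": np.arange(20.0),
        })
        out = force_area_relationship(df)
        assert np.isnan(out["spearman_rho"])


def test_frame_metrics_table_schema(standing_pair, outline):
    recs, _ = standing_pair
    short = recs["right"].with_frames(recs["right"].frames[:20])
    df = compute_frame_metrics(short, outline)
    assert list(df.columns) == [
        "frame", "force_pct_bm", "contact_area_pct", "cop_ap", "cop_ml",
        "coc_ap", "coc_ml", "cop_in_contact", "cop_pressure_percentile",
        "cop_region", "cop_clamped",
    ]
    assert len(df) == 20
    assert df["contact_area_pct"].between(0, 100).all()
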