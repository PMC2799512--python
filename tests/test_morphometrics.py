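"""Relative wing tables, nested HSD contrasts, and seta point-pattern
estimators of cell size and number."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from haplomap.morphometrics import (
    SetaPattern,
    cell_metrics,
    cells_per_seta,
    hsd_contrasts,
    mann_whitney,
    nnd4_area,
    relative_table,
    species_fraction,
)
from haplomap.synthetic_data import (
    TABLE1_FAMILY_DESIGN,
    TABLE1_MALE_PARAMS,
    GeneratorConfig,
    gen_wing_table,
)


def _noiseless_table():
    cfg = GeneratorConfig(
        wing_params={
            g: {m: (mu, 0.0) for m, (mu, _) in meas.items()}
            for g, meas in TABLE1_MALE_PARAMS.items()
        },
        family_design=TABLE1_FAMILY_DESIGN,
    )
    return gen_wing_table(cfg, seed=0)


class TestRelativeTable:
    def test_reference_normalises_to_one(self):
        t = _noiseless_table()
        rel = relative_table(t, reference="ws1_vV", sex="male")
        ref = rel[rel["genotype"] == "ws1_vV"]
        assert np.allclose(ref["rel_mean"], 1.0)

    def test_recovers_published_relative_means_noiselessly(self):
        t = _noiseless_table()
        rel = relative_table(t, reference="ws1_vV", sex="male").set_index(
            ["genotype", "measurement"]
        )
        assert rel.loc[("ws1_gV_40kb", "area_um2"), "rel_mean"] == pytest.approx(1.45)
        assert rel.loc[("ws1_gG", "area_um2"), "rel_mean"] == pytest.approx(2.16)
        assert rel.loc[("ws1_gG", "width_um"), "rel_mean"] == pytest.approx(1.81)

    def test_coefficient_of_variation_display(self):
        # a genotype with mean 242000 and SD 13000 reads 1.00 +/- 0.05
        cfg = GeneratorConfig(
            wing_params={"ws1_vV": {"area_um2": (242000.0, 13000.0)}},
            family_design={"ws1_vV": (200, 50)},
        )
        t = gen_wing_table(cfg, seed=1)
        rel = relative_table(t, "ws1_vV", "male", measurements=("area_um2",))
        assert rel["rel_sd"].iloc[0] == pytest.approx(13000 / 242000, rel=0.15)
        assert rel["display"].iloc[0].startswith("1.00±0.05")

    def test_scale_invariance(self):
        t = _noiseless_table()
        doubled = t.copy()
        for c in ("length_um", "width_um", "area_um2", "head_width_um"):
            doubled[c] = doubled[c] * 2
        a = relative_table(t, "ws1_vV", "male")
        b = relative_table(doubled, "ws1_vV", "male")
        assert np.allclose(a["rel_mean"], b["rel_mean"])
        assert np.allclose(a["rel_sd"], b["rel_sd"])

    def test_missing_reference_rejected(self):
        t = _noiseless_table()
        with pytest.raises(ValueError, match="absent"):
            relative_table(t, "nope", "male")


class TestSpeciesFraction:
    def test_published_attribution(self):
        assert species_fraction(1.45, 2.16) == pytest.approx(38.79, abs=0.01)
        assert round(species_fraction(1.45, 2.16)) == 39

    @pytest.mark.parametrize("rel,expected", [(1.0, 0.0), (2.16, 100.0)])
    def test_boundary_cases(self, rel, expected):
        assert species_fraction(rel, 2.16) == pytest.approx(expected)

    def test_degenerate_species_ratio_rejected(self):
        with pytest.raises(ValueError):
            species_fraction(1.2, 1.0)


class TestHsdContrasts:
    def test_null_genotypes_share_a_letter(self):
        params = {
            "a_strain": {"area_um2": (242000.0, 13000.0)},
            "b_strain": {"area_um2": (242000.0, 13000.0)},
        }
        cfg = GeneratorConfig(
            wing_params=params,
            family_design={"a_strain": (8, 10), "b_strain": (8, 10)},
        )
        t = gen_wing_table(cfg, seed=21)
        rep = hsd_contrasts(
            t, sex="male", alpha=0.001, n_tests=8, measurements=("area_um2",)
        )
        letters = set(rep.table["letter"])
        assert len(letters) == 1

    def test_published_design_separates_all_three_genotypes(self):
        cfg = GeneratorConfig(seed=22)
        t = gen_wing_table(cfg, seed=22)
        rep = hsd_contrasts(
            t,
            sex="male",
            alpha=0.001,
            n_tests=8,
            reference="ws1_vV",
            measurements=("area_um2",),
        )
        area = rep.table.set_index("genotype")
        assert sorted(area["letter"]) == ["a", "b", "c"]
        assert area.loc["ws1_vV", "letter"] == "a"

    def test_letters_invariant_to_unit_change(self):
        cfg = GeneratorConfig(seed=23)
        t = gen_wing_table(cfg, seed=23)
        mm = t.copy()
        for c in ("length_um", "width_um", "area_um2", "head_width_um"):
            mm[c] = mm[c] / 1000.0
        a = hsd_contrasts(t, "male", alpha=0.001, n_tests=8)
        b = hsd_contrasts(mm, "male", alpha=0.001, n_tests=8)
        assert list(a.table["letter"]) == list(b.table["letter"])

    def test_single_family_falls_back_with_warning(self, caplog):
        cfg = GeneratorConfig(
            wing_params={
                "a_strain": {"area_um2": (100.0, 5.0)},
                "b_strain": {"area_um2": (200.0, 5.0)},
            },
            family_design={"a_strain": (1, 12), "b_strain": (3, 4)},
        )
        t = gen_wing_table(cfg, seed=24)
        with caplog.at_level("WARNING"):
            rep = hsd_contrasts(t, "male", measurements=("area_um2",))
        assert rep.error_stratum == "residual"
        assert any("single family" in r.message for r in caplog.records)

    def test_bonferroni_caps_at_one(self):
        cfg = GeneratorConfig(seed=25)
        t = gen_wing_table(cfg, seed=25)
        rep = hsd_contrasts(t, "male", alpha=0.05, n_tests=8)
        assert (rep.pairwise["p_adj"] <= 1.0).all()
        assert (rep.pairwise["p_adj"] >= rep.pairwise["p_raw"] - 1e-15).all()


def _lattice(n_side: int, spacing: float) -> np.ndarray:
    g = np.arange(n_side, dtype=float)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel()], axis=1) * spacing


def _nnd4_bruteforce(pts: np.ndarray) -> float:
    # O(n^2) all-pairs oracle, independent of the KD-tree path
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    nnd4 = np.sort(d, axis=1)[:, :4].mean(axis=1)
    return float(np.mean(np.pi * (nnd4 / 2) ** 2))


class TestNnd4Area:
    def test_square_lattice_matches_geometry(self):
        a = 12.0
        pts = _lattice(60, a)
        # interior points have their 4 nearest neighbours at exactly a;
        # boundary rows inflate the mean slightly
        assert nnd4_area(pts) == pytest.approx(np.pi * a**2 / 4, rel=0.03)

    def test_exact_scaling_identity(self, rng):
        pts = rng.uniform(0, 100, size=(150, 2))
        base = nnd4_area(pts)
        for s in (0.1, 3.7, np.sqrt(1.21)):
            assert nnd4_area(pts * s) == pytest.approx(base * s**2, rel=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        pts = rng.uniform(0, 500, size=(200, 2))
        assert abs(nnd4_area(pts) - _nnd4_bruteforce(pts)) < 1e-9

    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        theta=st.floats(0, 2 * np.pi),
    )
    def test_rigid_motion_invariance(self, dx, dy, theta):
        rng = np.random.default_rng(99)
        pts = rng.uniform(0, 100, size=(40, 2))
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pts @ rot.T + np.array([dx, dy])
        assert nnd4_area(moved) == pytest.approx(nnd4_area(pts), rel=1e-9)

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 100, size=(80, 2))
        perm = rng.permutation(80)
        assert nnd4_area(pts[perm]) == pytest.approx(nnd4_area(pts), rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nnd4_area(np.zeros((4, 2)))


class TestCellMetrics:
    def _pattern(self, pts, area):
        return SetaPattern(pts, region_area_um2=area)

    def test_identical_patterns_give_zero_changes(self, rng):
        pts = rng.uniform(0, 300, size=(200, 2))
        p = self._pattern(pts, 90000.0)
        m = cell_metrics(p, p)
        assert (m.cell_size_pct, m.cell_number_pct, m.area_pct) == (0.0, 0.0, 0.0)

    def test_planted_scaling_recovers_21_percent(self, rng):
        pts = rng.uniform(0, 300, size=(400, 2))
        ref = self._pattern(pts, 90000.0)
        test = self._pattern(pts * np.sqrt(1.21), 90000.0 * 1.21)
        m = cell_metrics(ref, test)
        assert m.cell_size_pct == pytest.approx(21.0, abs=1e-9)
        assert m.cell_number_pct == 0.0

    def test_multiplicative_consistency_on_affine_rescaling(self, rng):
        # (1 + size)(1 + number) == (1 + area) exactly when the test
        # pattern is a pure coordinate rescaling (count unchanged)
        pts = rng.uniform(0, 300, size=(300, 2))
        s2 = 1.73
        ref = self._pattern(pts, 90000.0)
        test = self._pattern(pts * np.sqrt(s2), 90000.0 * s2)
        m = cell_metrics(ref, test)
        lhs = (1 + m.cell_size_pct / 100) * (1 + m.cell_number_pct / 100)
        assert lhs == pytest.approx(1 + m.area_pct / 100, rel=1e-12)
        assert m.cell_number_pct == 0.0
        assert m.cell_number_from_area_pct == pytest.approx(0.0, abs=1e-9)

    def test_planted_size_and_number_pair_recovered(self):
        # generator pair planted at size ratio 1.21 and count ratio 1.49:
        # both patterns share the same relative jitter, so the nnd4 area is
        # proportional to 1/density up to realisation noise
        from haplomap.synthetic_data import GeneratorConfig, gen_seta_pattern

        area_per_seta = 4 * 117.0 / np.pi  # lattice cell giving nnd4 area 117
        n_ref, size_ratio, number_ratio = 580, 1.21, 1.49
        n_test = round(n_ref * number_ratio)
        ref = gen_seta_pattern(
            GeneratorConfig(
                seta_density=1 / area_per_seta,
                region_area_um2=n_ref * area_per_seta,
            ),
            seed=31,
        )
        test = gen_seta_pattern(
            GeneratorConfig(
                seta_density=1 / (area_per_seta * size_ratio),
                region_area_um2=n_test * area_per_seta * size_ratio,
            ),
            seed=32,
        )
        m = cell_metrics(ref, test)
        assert m.cell_size_pct == pytest.approx(21.0, abs=3.0)
        assert m.cell_number_pct == pytest.approx(49.0, abs=0.5)
        assert m.area_pct == pytest.approx(100 * (size_ratio * n_test / n_ref - 1), rel=1e-9)


class TestCellsPerSeta:
    def test_ratio(self):
        assert cells_per_seta(32, 10) == pytest.approx(3.2)

    def test_zero_setae_rejected(self):
        with pytest.raises(ValueError):
            cells_per_seta(10, 0)


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        res = mann_whitney([3.2] * 6, [3.2] * 6)
        assert res.p_value == 1.0
        assert res.method == "all-ties"

    def test_exact_p_matches_enumeration(self):
        a = [3.2, 3.0, 3.5, 2.9]
        b = [4.6, 4.1, 4.4, 4.9, 4.2]
        res = mann_whitney(a, b)
        assert res.method == "exact"
        pooled = np.array(a + b)
        n1 = len(a)
        us = []
        for comb in itertools.combinations(range(len(pooled)), n1):
            ga = pooled[list(comb)]
            gb = pooled[[i for i in range(len(pooled)) if i not in comb]]
            us.append(sum(1.0 for x in ga for y in gb if x > y))
        us = np.array(us)
        u_obs = sum(1.0 for x in a for y in b if x > y)
        mu = len(a) * len(b) / 2
        p_enum = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_separated_groups_significant_at_study_sample_size(self, rng):
        # cells-per-seta style contrast: n = 6 per group, well separated
        a = rng.normal(3.2, 0.4, size=6)
        b = rng.normal(4.6, 0.4, size=6)
        assert mann_whitney(a, b).p_value < 0.05
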