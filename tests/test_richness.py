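"""Incidence estimators, accumulation, standardization and occupancy."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import barcodiv as bd
from barcodiv.partition import Partition
from barcodiv.richness import (
    IncidenceMatrix,
    expected_accumulation,
    expected_standardized_richness,
)


@pytest.fixture
def fixture_matrix():
    """Frozen 5-species x 4-unit incidence with q1 = 2, q2 = 1."""
    pres = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 1, 0],
            [1, 1, 1, 1],
        ],
        dtype=bool,
    )
    return IncidenceMatrix(tuple(f"s{i}" for i in range(5)),
                           tuple(f"u{j}" for j in range(4)), pres)


@pytest.fixture
def six_species_matrix():
    """Frozen 6-species x 4-unit fixture for closed-form checks."""
    pres = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 1, 0],
            [1, 0, 0, 1],
            [1, 1, 0, 1],
            [1, 1, 1, 1],
            [0, 0, 1, 0],
        ],
        dtype=bool,
    )
    return IncidenceMatrix(tuple(f"s{i}" for i in range(6)),
                           tuple(f"u{j}" for j in range(4)), pres)


def meta_frame(rows):
    return pd.DataFrame(
        rows, columns=["specimen_id", "sampling_unit", "method", "level"]
    )


class TestBuildIncidence:
    def test_single_species_single_unit(self):
        p = Partition({"a": "sp1"})
        meta = meta_frame([("a", "u1", "sweep", 1000)])
        inc = bd.build_incidence(p, meta)
        assert inc.presence.shape == (1, 1)
        assert inc.q(1) == 1

    def test_method_filter_drops_units_and_orphan_species(self):
        p = Partition({"a": "sp1", "b": "sp2"})
        meta = meta_frame(
            [("a", "u1", "sweep", 1000), ("b", "u2", "light", 1000)]
        )
        inc = bd.build_incidence(p, meta, methods=("sweep",))
        assert inc.unit_ids == ("u1",)
        assert inc.species_ids == ("sp1",)

    def test_empty_filter_rejected(self):
        p = Partition({"a": "sp1"})
        meta = meta_frame([("a", "u1", "light", 1000)])
        with pytest.raises(ValueError, match="no sampling units"):
            bd.build_incidence(p, meta, methods=("sweep",))


class TestEstimators:
    def test_hand_evaluated_chao2_and_jack1(self, fixture_matrix):
        # S=5, q1=2, q2=1, m=4: chao2 = 5 + (3/4)*(4/2) = 6.5
        assert bd.chao2(fixture_matrix).estimate == pytest.approx(6.5)
        # jack1 = 5 + 2*(3/4) = 6.5
        assert bd.jackknife(fixture_matrix, 1).estimate == pytest.approx(6.5)
        assert bd.jackknife(fixture_matrix, 2).se is None

    def test_no_rare_species_returns_observed(self):
        pres = np.ones((3, 4), dtype=bool)
        inc = IncidenceMatrix(("a", "b", "c"), ("u1", "u2", "u3", "u4"), pres)
        assert bd.chao2(inc).estimate == 3
        assert bd.chao2(inc).se == 0.0
        assert bd.jackknife(inc, 1).estimate == 3
        assert bd.jackknife(inc, 2).estimate == 3

    def test_estimates_exceed_observed_richness(self, six_species_matrix):
        for est in (
            bd.chao2(six_species_matrix),
            bd.jackknife(six_species_matrix, 1),
            bd.jackknife(six_species_matrix, 2),
        ):
            assert est.estimate >= est.s_obs

    def test_closed_forms_on_six_species_fixture(self, six_species_matrix):
        s, q1, q2, m = 6, 2, 2, 4
        chao = s + (m - 1) / m * q1 * q1 / (2 * q2)
        jack1 = s + q1 * (m - 1) / m
        jack2 = s + q1 * (2 * m - 3) / m - q2 * (m - 2) ** 2 / (m * (m - 1))
        assert bd.chao2(six_species_matrix).estimate == pytest.approx(chao)
        assert bd.jackknife(six_species_matrix, 1).estimate == pytest.approx(jack1)
        assert bd.jackknife(six_species_matrix, 2).estimate == pytest.approx(jack2)

    def test_invariant_under_unit_permutation(self, six_species_matrix):
        perm = [2, 0, 3, 1]
        shuffled = IncidenceMatrix(
            six_species_matrix.species_ids,
            tuple(six_species_matrix.unit_ids[j] for j in perm),
            six_species_matrix.presence[:, perm],
        )
        for order in (1, 2):
            assert bd.jackknife(shuffled, order).estimate == pytest.approx(
                bd.jackknife(six_species_matrix, order).estimate
            )
        assert bd.chao2(shuffled).estimate == pytest.approx(
            bd.chao2(six_species_matrix).estimate
        )

    def test_too_few_units_rejected(self):
        inc = IncidenceMatrix(("a",), ("u1",), np.ones((1, 1), dtype=bool))
        with pytest.raises(ValueError):
            bd.chao2(inc)
        with pytest.raises(ValueError):
            bd.jackknife(inc, 2)

    def test_matches_vegan_specpool_on_random_matrix(self, tmp_path):
        """Independent oracle: the R implementation the field uses."""
        rng = np.random.default_rng(9)
        pres = rng.random((15, 7)) < 0.35
        pres = pres[pres.any(axis=1)]
        inc = IncidenceMatrix(
            tuple(f"s{i}" for i in range(len(pres))),
            tuple(f"u{j}" for j in range(7)),
            pres,
        )
        csv = tmp_path / "m.csv"
        np.savetxt(csv, pres.astype(int), delimiter=",", fmt="%d")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{csv}", header=FALSE))
            p <- specpool(t(m))
            cat(p$chao, p$chao.se, p$jack1, p$jack1.se, p$jack2, sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        chao_r, chao_se_r, j1_r, j1_se_r, j2_r = map(float, out.stdout.split())
        assert bd.chao2(inc).estimate == pytest.approx(chao_r)
        assert bd.chao2(inc).se == pytest.approx(chao_se_r)
        assert bd.jackknife(inc, 1).estimate == pytest.approx(j1_r)
        assert bd.jackknife(inc, 1).se == pytest.approx(j1_se_r)
        assert bd.jackknife(inc, 2).estimate == pytest.approx(j2_r)


class TestAccumulation:
    def test_final_point_reaches_observed_richness(self, six_species_matrix):
        sizes = {u: 3 for u in six_species_matrix.unit_ids}
        for method in ("random", "collector"):
            curve = bd.accumulation_curve(
                six_species_matrix, sizes, method, n_perm=50, seed=1
            )
            assert curve.mean_species[-1] == pytest.approx(6.0)

    def test_single_unit_gives_one_point(self):
        inc = IncidenceMatrix(("a",), ("u1",), np.ones((1, 1), dtype=bool))
        curve = bd.accumulation_curve(inc, {"u1": 4}, "collector")
        assert len(curve.mean_species) == 1

    def test_collector_is_deterministic_in_unit_order(self, six_species_matrix):
        sizes = {u: 2 for u in six_species_matrix.unit_ids}
        a = bd.accumulation_curve(six_species_matrix, sizes, "collector")
        b = bd.accumulation_curve(six_species_matrix, sizes, "collector")
        assert np.array_equal(a.mean_species, b.mean_species)

    def test_random_mean_matches_rarefaction_expectation(self):
        """Permutation mean vs the closed-form hypergeometric expectation."""
        rng = np.random.default_rng(2)
        pres = rng.random((12, 10)) < 0.3
        pres = pres[pres.any(axis=1)]
        inc = IncidenceMatrix(
            tuple(f"s{i}" for i in range(len(pres))),
            tuple(f"u{j}" for j in range(10)),
            pres,
        )
        n_perm = 1000
        curve = bd.accumulation_curve(
            inc, {u: 1 for u in inc.unit_ids}, "random", n_perm=n_perm, seed=3
        )
        for k in (2, 5, 8):
            expect = expected_accumulation(inc, k)
            spread = (curve.hi[k - 1] - curve.lo[k - 1]) / 4 + 1e-9
            se = spread / math.sqrt(n_perm)
            assert abs(curve.mean_species[k - 1] - expect) <= max(3 * se, 0.15)

    def test_unknown_method_rejected(self, six_species_matrix):
        with pytest.raises(ValueError, match="unknown"):
            bd.accumulation_curve(six_species_matrix, {}, "bogus")


class TestStandardizedRichness:
    def _pool(self):
        rows, labels = [], {}
        rng = np.random.default_rng(4)
        for i in range(60):
            sp = f"s{i}"
            rows.append((sp, f"u{i % 6}", "sweep", 2000))
            labels[sp] = f"g{rng.integers(0, 25)}"
        return Partition(labels), meta_frame(rows)

    def test_full_pool_draw_has_zero_ci_width(self):
        p, meta = self._pool()
        sr = bd.standardized_richness(p, meta, 2000, n_draw=60, reps=50, seed=0)
        assert sr.mean == p.n_groups
        assert sr.lo == sr.hi == p.n_groups

    def test_overdraw_rejected(self):
        p, meta = self._pool()
        with pytest.raises(ValueError, match="exceeds"):
            bd.standardized_richness(p, meta, 2000, n_draw=61)

    def test_mean_matches_hypergeometric_expectation(self):
        p, meta = self._pool()
        reps = 4000
        sr = bd.standardized_richness(p, meta, 2000, n_draw=20, reps=reps, seed=5)
        expect = expected_standardized_richness(p, meta, 2000, 20)
        se = (sr.hi - sr.lo) / 4 / math.sqrt(reps) + 1e-9
        assert abs(sr.mean - expect) <= max(3 * se, 0.1)

    def test_deterministic_under_seed(self):
        p, meta = self._pool()
        a = bd.standardized_richness(p, meta, 2000, 20, reps=200, seed=9)
        b = bd.standardized_richness(p, meta, 2000, 20, reps=200, seed=9)
        assert a == b


class TestLevelOccupancy:
    def test_all_groups_single_level(self):
        p = Partition({"a": "x", "b": "y"})
        meta = meta_frame(
            [("a", "u1", "sweep", 1000), ("b", "u2", "sweep", 2000)]
        )
        occ = bd.level_occupancy(p, meta)
        assert occ[1] == 100.0

    def test_one_of_five_groups_spans_two_levels(self):
        mapping = {f"s{i}": f"g{i}" for i in range(5)}
        mapping["s5"] = "g0"  # second specimen of g0 at another level
        rows = [(f"s{i}", "u1", "sweep", 1000) for i in range(5)]
        rows.append(("s5", "u2", "sweep", 2000))
        occ = bd.level_occupancy(Partition(mapping), meta_frame(rows))
        assert occ[2] == pytest.approx(20.0)
        assert occ[1] == pytest.approx(80.0)

    def test_percentages_sum_to_hundred(self, small_sim):
        occ = bd.level_occupancy(small_sim.morpho, small_sim.meta)
        assert sum(occ.values()) == pytest.approx(100.0)

    def test_exclude_rare_removes_small_groups(self):
        mapping = {"a": "big", "b": "big", "c": "big", "d": "tiny"}
        rows = [
            ("a", "u1", "sweep", 1000),
            ("b", "u2", "sweep", 2000),
            ("c", "u3", "sweep", 1000),
            ("d", "u4", "sweep", 3000),
        ]
        occ = bd.level_occupancy(Partition(mapping), meta_frame(rows),
                                 exclude_rare=True)
        assert occ[2] == 100.0  # only the 3-specimen group remains
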