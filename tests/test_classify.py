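"""NtC assignment, confal scoring, CANA mapping and connectivity checks."""

import math

import numpy as np
import pytest

from ntckit.classify import (
    StepAssignment,
    TableError,
    assign_ntc,
    class_distance,
    confal_score,
    evaluate_connectivity,
    load_ntc_table,
    map_cana,
    structure_confal,
)
from ntckit.fixtures import make_test_table, write_table_csv
from ntckit.geometry import angular_difference
from ntckit.model import PARAM_COLUMNS, extract_na_chains
from ntckit.pipeline import annotate_structure
from ntckit.steps import StepParameters, compute_step_parameters, find_steps


def brute_force_distance(pvec, record):
    """Independent re-evaluation of the tolerance-scaled distance."""
    total = 0.0
    mvec = record.means.as_vector()
    for j, key in enumerate(PARAM_COLUMNS):
        delta = pvec[j] - mvec[j]
        if key not in ("nn", "cc"):
            while delta > 180.0:
                delta -= 360.0
            while delta <= -180.0:
                delta += 360.0
        total += (delta / record.tolerances[j]) ** 2
    return math.sqrt(total)


def brute_force_nearest(pvec, table):
    best, best_d = None, float("inf")
    for record in table:
        d = brute_force_distance(pvec, record)
        if d < best_d:
            best, best_d = record.name, d
    return best


def random_param_vector(rng):
    v = np.empty(12)
    for j, key in enumerate(PARAM_COLUMNS):
        v[j] = rng.uniform(3.0, 7.0) if key in ("nn", "cc") else rng.uniform(-180.0, 180.0)
    return v


class TestTableLoading:
    def test_packaged_table_cardinality(self, table96):
        assert len(table96) == 96
        assert len(table96.cana_codes) == 14

    def test_representatives_reproduce_means(self, table96):
        for record in table96.records[::8]:
            dev = record.rep_params.as_vector() - record.means.as_vector()
            assert np.abs(dev).max() < 0.5

    def test_duplicate_class_name_rejected(self, tmp_path):
        rows = make_test_table(3, seed=0)
        rows[2]["name"] = rows[0]["name"]
        path = tmp_path / "dup.csv"
        write_table_csv(rows, path)
        with pytest.raises(TableError, match="duplicated"):
            load_ntc_table(path, allow_small=True)

    def test_small_table_requires_flag(self, tmp_path):
        path = tmp_path / "small.csv"
        write_table_csv(make_test_table(3, seed=0), path)
        with pytest.raises(TableError, match="expected 96"):
            load_ntc_table(path)
        assert len(load_ntc_table(path, allow_small=True)) == 3

    def test_nonpositive_tolerance_rejected(self, tmp_path):
        rows = make_test_table(2, seed=0)
        rows[0]["tol_e1"] = 0.0
        path = tmp_path / "tol.csv"
        write_table_csv(rows, path)
        with pytest.raises(TableError, match="non-positive tolerance"):
            load_ntc_table(path, allow_small=True)

    def test_inconsistent_representative_rejected(self, tmp_path):
        rows = make_test_table(2, seed=0)
        rows[0]["e1"] = float(rows[0]["e1"]) + 5.0  # break self-consistency
        path = tmp_path / "inc.csv"
        write_table_csv(rows, path)
        with pytest.raises(TableError, match="inconsistent"):
            load_ntc_table(path, allow_small=True)


class TestClassDistance:
    def test_zero_at_class_mean(self, table96):
        record = table96["AA00"]
        assert class_distance(record.means, record) == pytest.approx(0.0, abs=1e-12)

    def test_one_tolerance_offset_scores_one(self, table96):
        record = table96["AA00"]
        v = record.means.as_vector()
        v[1] += record.tolerances[1]  # epsilon_1 off by exactly one tolerance
        assert class_distance(StepParameters.from_vector(v), record) == pytest.approx(1.0)

    def test_matches_brute_force(self, table3, rng):
        for _ in range(100):
            v = random_param_vector(rng)
            p = StepParameters.from_vector(v)
            for record in table3:
                assert class_distance(p, record) == pytest.approx(
                    brute_force_distance(v, record), abs=1e-9)


class TestAssignment:
    def test_exact_class_build_assigns_with_tiny_rmsd(self, oligo_factory, table96):
        st = oligo_factory(["BB00"], sequence="GA")
        step = find_steps(extract_na_chains(st)[0])[0]
        p = compute_step_parameters(step)
        asg = assign_ntc(step, p, table96)
        assert asg.ntc == "BB00"
        assert asg.rmsd < 1e-6

    def test_nearest_class_equals_exhaustive_search(self, table96, oligo_factory, rng):
        # geometry-independent part of the assignment: candidate selection
        st = oligo_factory(["BB00"], sequence="GA")
        step = find_steps(extract_na_chains(st)[0])[0]
        for _ in range(200):
            p = StepParameters.from_vector(random_param_vector(rng))
            asg = assign_ntc(step, p, table96)
            assert asg.candidate == brute_force_nearest(p.as_vector(), table96)

    def test_remote_step_becomes_nant(self, table96):
        from ntckit.fixtures import build_step_from_torsions

        base = {k: getattr(table96["BB00"].means, k) for k in StepParameters.TORSION_NAMES}
        for key in ("e1", "z1", "a2", "b2", "g2"):
            base[key] = angular_difference(base[key] + 30.0, 0.0)
        _, step, p = build_step_from_torsions(base)
        asg = assign_ntc(step, p, table96)
        assert asg.rmsd > 0.5
        assert asg.ntc == "NANT" and asg.cana == "NAN"
        # diagnostics still carried
        assert asg.candidate in table96
        assert 0.0 <= asg.confal <= 100.0

    def test_noiseless_random_sequences_fully_recovered(self, table96, oligo_factory, rng):
        names = [table96.records[i].name for i in rng.integers(0, 96, size=8)]
        st = oligo_factory(names, sequence="GACUGACUG")
        result = annotate_structure(st, table96)
        assert [a.ntc for _, a, _ in result.records] == names
        assert all(a.rmsd < 0.05 for _, a, _ in result.records)

    def test_noisy_steps_rerank_generating_class_first(self, table3, oligo_factory):
        # 3-degree torsion noise on a clear-margin table must not flip ranks
        for seed in range(5):
            name = table3.records[seed % 3].name
            st = oligo_factory([name], sequence="GA", table=table3,
                               torsion_noise=3.0, seed=seed)
            step = find_steps(extract_na_chains(st)[0])[0]
            p = compute_step_parameters(step)
            ranked = sorted(table3, key=lambda c: class_distance(p, c))
            assert ranked[0].name == name


class TestConfal:
    def test_perfect_match_scores_100(self, table96):
        record = table96["AA00"]
        assert confal_score(record.means, record) == pytest.approx(100.0)

    def test_remote_vector_scores_near_zero(self, table96):
        record = table96["AA00"]
        v = record.means.as_vector()
        v += 10.0 * record.tolerances  # every parameter off by 10 tolerances
        v = np.array([angular_difference(x, 0.0) if k not in ("nn", "cc") else x
                      for x, k in zip(v, PARAM_COLUMNS)])
        assert confal_score(StepParameters.from_vector(v), record) < 1.0

    def test_single_tolerance_offset_value(self, table96):
        # geometric mean of one half-score and eleven perfect scores
        record = table96["AA00"]
        v = record.means.as_vector()
        v[1] += record.tolerances[1]
        got = confal_score(StepParameters.from_vector(v), record)
        assert got == pytest.approx(100.0 * 0.5 ** (1.0 / 12.0), abs=1e-9)
        assert round(got, 1) == 94.4

    def test_strictly_decreasing_in_each_deviation(self, table96, rng):
        record = table96["AA00"]
        for j in rng.integers(0, 12, size=6):
            scores = []
            for mag in (0.0, 0.5, 1.0, 2.0, 4.0):
                v = record.means.as_vector().copy()
                v[j] += mag * record.tolerances[j]
                scores.append(confal_score(StepParameters.from_vector(v), record))
            assert all(a > b for a, b in zip(scores, scores[1:]))
            assert all(0.0 <= s <= 100.0 for s in scores)


def _asg(confal):
    return StepAssignment(step_id="A.1-2", ntc="BB00", cana="BBB", candidate="BB00",
                          confal=confal, rmsd=0.0,
                          per_parameter_deviation=np.zeros(12), distance_to_class=0.0)


class TestStructureConfal:
    def test_all_perfect(self):
        agg, pct = structure_confal([_asg(100.0)] * 3)
        assert agg == pytest.approx(100.0)
        assert pct is None

    def test_geometric_mean(self):
        agg, _ = structure_confal([_asg(100.0), _asg(25.0)])
        assert agg == pytest.approx(50.0)

    def test_hazen_percentile_against_calibration(self):
        calibration = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        agg, pct = structure_confal([_asg(55.0)], calibration=calibration)
        assert agg == pytest.approx(55.0)
        assert pct == pytest.approx(50.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            structure_confal([])


class TestMapCana:
    def test_lookup_and_nant(self, table96):
        assert map_cana("BB00", table96) == table96["BB00"].cana
        assert map_cana("NANT", table96) == "NAN"

    def test_unknown_class_raises(self, table96):
        with pytest.raises(KeyError):
            map_cana("XX99", table96)


class TestConnectivity:
    def _three_steps(self, oligo_factory, names):
        st = oligo_factory(names, sequence="GACU")
        return find_steps(extract_na_chains(st)[0])

    def test_assigned_class_on_noiseless_fixture_is_continuous(self, oligo_factory, table96):
        prev_s, step, next_s = self._three_steps(oligo_factory, ["BB05", "BB05", "BB05"])
        report = evaluate_connectivity(prev_s, step, next_s, "BB05", table96)
        assert report.rmsd_to_prev < 1e-6 and report.rmsd_to_next < 1e-6
        for dev in {**report.torsion_deviations_prev, **report.torsion_deviations_next}.values():
            assert abs(dev) < 1e-6

    def test_target_with_remote_beta_gamma_reported(self, oligo_factory, table96):
        bb10 = table96["BB10"].means
        target = next(
            r for r in table96
            if abs(angular_difference(r.means.b2, bb10.b2)) > 70.0
            and abs(angular_difference(r.means.g2, bb10.g2)) > 70.0
        )
        prev_s, step, next_s = self._three_steps(oligo_factory, ["BB10", "BB10", "BB10"])
        report = evaluate_connectivity(prev_s, step, next_s, target.name, table96)
        assert abs(report.torsion_deviations_next["b2"]) > 70.0
        assert abs(report.torsion_deviations_next["g2"]) > 70.0

    def test_non_adjacent_steps_rejected(self, oligo_factory, table96):
        prev_s, step, next_s = self._three_steps(oligo_factory, ["BB05", "BB05", "BB05"])
        with pytest.raises(ValueError, match="not adjacent"):
            evaluate_connectivity(next_s, step, prev_s, "BB05", table96)
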