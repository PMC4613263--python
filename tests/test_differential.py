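"""SVQ statistics, coverage rule, exact Mann-Whitney test, aggregation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from spotdiff import differential as diff
from spotdiff import gelio, report, synthdata
from spotdiff.differential import (
    ABSENT_IN_BASELINE,
    ABSENT_IN_STAGE,
    DOWN,
    UNCHANGED,
    UP,
    DiffConfig,
)
from spotdiff.errors import ConfigurationError


class TestSvq:
    def test_exact_ratio(self):
        svq, per_gel = diff.compute_svq([10] * 6, [5] * 6)
        assert svq == 2.0
        assert per_gel == [2.0] * 6

    def test_identity(self):
        svq, per_gel = diff.compute_svq([3, 4, 5], [3, 4, 5])
        assert svq == 1.0

    def test_hand_arithmetic(self):
        svq, per_gel = diff.compute_svq([4, 6], [1, 3])
        assert svq == pytest.approx(2.5)
        assert per_gel == pytest.approx([5.0, 5 / 3])

    def test_reciprocity(self):
        a, b = [4.0, 6.0, 5.0], [1.0, 3.0, 2.0]
        s1, _ = diff.compute_svq(a, b)
        s2, _ = diff.compute_svq(b, a)
        assert s1 * s2 == pytest.approx(1.0, rel=1e-12)

    def test_zero_mean_is_not_a_quotient(self):
        with pytest.raises(ValueError):
            diff.compute_svq([10, 10], [0, 0])


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "svq,expected",
        [
            (3.09, DOWN),  # e.g. Gapdh at P7
            (0.52, UP),    # e.g. Pgm2l1 at P7
            (1.0, UNCHANGED),
            (1.67, DOWN),  # boundaries inclusive
            (0.6, UP),
            (0.601, UNCHANGED),
            (1.669, UNCHANGED),
        ],
    )
    def test_rule_and_boundaries(self, svq, expected):
        assert diff.classify_direction(svq) == expected

    def test_reproduces_published_labels(self, reference_calls):
        """Every printed quotient classifies to the printed regulation label."""
        for _, row in reference_calls.iterrows():
            label = row.reg_p7 if row.reg_p7 != "-" else row.reg_p637
            assert diff.classify_direction(row.svq) == label

    def test_near_antisymmetry_at_default_pair(self):
        # 1/1.67 ~ 0.599 <= 0.6, so down at s implies up at 1/s for s >= 1.67
        for s in (1.67, 2.0, 3.5, 10.0):
            assert diff.classify_direction(s) == DOWN
            assert diff.classify_direction(1.0 / s) == UP

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ConfigurationError):
            DiffConfig(svq_up_max=1.2)


class TestCoverageFilter:
    def test_four_of_six_passes(self):
        h, passes = diff.coverage_filter([2.0, 1.8, 1.7, 1.67, 1.5, 1.0], DOWN)
        assert (h, passes) == (4, True)

    def test_three_of_six_fails(self):
        h, passes = diff.coverage_filter([2.0, 1.8, 1.7, 1.0, 1.0, 1.0], DOWN)
        assert (h, passes) == (3, False)

    def test_up_side_counts_low_quotients(self):
        h, passes = diff.coverage_filter([0.5, 0.6, 0.61, 0.2, 0.9, 0.55], UP)
        assert (h, passes) == (4, True)

    def test_unchanged_consensus_not_applicable(self):
        assert diff.coverage_filter([2.0] * 6, UNCHANGED) == (0, False)

    def test_published_h_counts_respect_min_gels(self, reference_calls):
        assert int(reference_calls.h.min()) >= DiffConfig().min_gels


def _brute_force_p(x, y):
    """Independent oracle: enumerate assignments, U by pairwise comparison."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    count = total = 0
    u_obs = sum(
        1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
    )
    dev_obs = abs(u_obs - n * m / 2.0)
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in xs for yj in ys
        )
        if abs(u - n * m / 2.0) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


class TestMannWhitneyExact:
    def test_complete_separation_six_vs_six(self):
        u, p = diff.mann_whitney_exact(list(range(1, 7)), list(range(7, 13)))
        assert u == 0.0
        assert p == pytest.approx(2 / 924, abs=1e-15)

    def test_complete_ties_give_p_one(self):
        _, p = diff.mann_whitney_exact([5] * 6, [5] * 6)
        assert p == 1.0

    def test_agrees_with_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, m = rng.integers(4, 7, size=2)
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            _, p = diff.mann_whitney_exact(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_agrees_with_brute_force_on_tied_integer_data(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n, m = rng.integers(4, 7, size=2)
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=m).astype(float)
            _, p = diff.mann_whitney_exact(x, y)
            assert p == pytest.approx(_brute_force_p(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = rng.normal(loc=1.0, size=10)
        _, p = diff.mann_whitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            diff.mann_whitney_exact([], [1.0])


class TestDetectAbsence:
    @pytest.mark.parametrize(
        "nb,ns,expected",
        [
            (6, 0, ABSENT_IN_STAGE),
            (0, 5, ABSENT_IN_BASELINE),
            (2, 0, None),  # insufficient evidence on the present side
            (0, 3, None),
            (4, 2, None),
        ],
    )
    def test_definition(self, nb, ns, expected):
        assert diff.detect_absence(nb, ns) == expected


def _experiment_volumes(base, stage_vols, stage="P7"):
    """Build normalized two-stage gels holding one spot with given volumes."""
    gels = []
    for rep, v in enumerate(base):
        spots = [gelio.SpotRecord("s", 5.0, 40.0, float(v))] if v > 0 else []
        spots.append(gelio.SpotRecord("ref", 7.0, 60.0, 1000.0))
        gels.append(gelio.GelTable("P90", rep, spots))
    for rep, v in enumerate(stage_vols):
        spots = [gelio.SpotRecord("s", 5.0, 40.0, float(v))] if v > 0 else []
        spots.append(gelio.SpotRecord("ref", 7.0, 60.0, 1000.0))
        gels.append(gelio.GelTable(stage, rep, spots))
    return [gelio.normalize_volumes(g) for g in gels]


class TestCompareStage:
    def test_absence_path_emits_no_svq(self):
        gels = _experiment_volumes([10] * 6, [0] * 6)
        groups = gelio.groups_by_spot_id(gels)
        comps = {c.group_id: c for c in diff.compare_stage(groups, gels, "P7")}
        assert comps["s"].direction == ABSENT_IN_STAGE
        assert comps["s"].svq is None
        assert comps["s"].regulated

    def test_unknown_stage_rejected(self):
        gels = _experiment_volumes([10] * 6, [10] * 6)
        with pytest.raises(ConfigurationError):
            diff.compare_stage(gelio.groups_by_spot_id(gels), gels, "P999")

    def test_depressed_stage_flagged_down(self):
        gels = _experiment_volumes([30] * 6, [10] * 6)
        comps = {c.group_id: c for c in diff.compare_stage(
            gelio.groups_by_spot_id(gels), gels, "P7")}
        c = comps["s"]
        assert c.direction == DOWN and c.passes_coverage and c.h_count == 6

    def test_monotone_under_common_stage_scaling(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(3, 0.2, 6)
        stage_v = rng.lognormal(3, 0.2, 6) / 3.0
        for factor in (1.0, 1.1, 1.5):
            gels = _experiment_volumes(base, stage_v * factor)
            c = {c.group_id: c for c in diff.compare_stage(
                gelio.groups_by_spot_id(gels), gels, "P7")}["s"]
            assert c.direction != UP  # scaling stage volumes up never flips to up

    def test_regulated_records_satisfy_soundness(self):
        """Every regulated record has H >= min_gels and SVQ outside the band."""
        config = synthdata.SyntheticConfig(n_proteins=60, seed=13)
        gels, _ = synthdata.generate_experiment(config)
        gels = [gelio.normalize_volumes(g) for g in gels]
        groups = gelio.groups_by_spot_id(gels)
        dc = DiffConfig()
        for stage in ("P7", "P637"):
            for c in diff.compare_stage(groups, gels, stage, dc):
                if c.regulated and c.direction in (UP, DOWN):
                    assert c.h_count >= dc.min_gels
                    assert c.svq <= dc.svq_up_max or c.svq >= dc.svq_down_min


class TestAggregateProtein:
    def _comp(self, svq, direction=None, stage="P7", gid="g"):
        direction = direction or diff.classify_direction(svq)
        per_gel = [svq] * 6
        h, passes = diff.coverage_filter(per_gel, direction)
        return diff.StageComparison(
            group_id=gid, stage=stage, svq=svq, per_gel_svq=per_gel,
            h_count=h, direction=direction, p_value=0.01,
            passes_coverage=passes, n_baseline_detected=6, n_stage_detected=6,
        )

    def test_mean_rule(self):
        r = diff.aggregate_protein([self._comp(2.0, gid="a"), self._comp(3.0, gid="b")], "P1")
        assert r.mean_svq == pytest.approx(2.5)
        assert r.direction == DOWN and not r.conflict

    def test_single_spot_identity(self):
        c = self._comp(0.5)
        r = diff.aggregate_protein([c], "P1")
        assert r.mean_svq == c.svq and r.direction == c.direction
        assert r.n_spots == 1

    def test_conflicting_isoforms_flagged(self):
        r = diff.aggregate_protein(
            [self._comp(0.5, gid="a"), self._comp(2.2, gid="b")], "P1"
        )
        assert r.mean_svq == pytest.approx(1.35)
        assert r.direction == UNCHANGED
        assert r.conflict

    def test_mixed_stages_rejected(self):
        with pytest.raises(ConfigurationError):
            diff.aggregate_protein(
                [self._comp(2.0, stage="P7"), self._comp(2.0, stage="P637")], "P1"
            )
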