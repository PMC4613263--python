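"""Differential expression calling on matched 2DE spots.

The decision rule implemented here is the *multi condition coverage method*
used in differential 2DE studies of the rat cerebellum: for every matched
spot and every non-baseline stage, compute the spot volume quotient

    SVQ = mean normalized volume at baseline / mean normalized volume at stage

(with the adult stage P90 as baseline by convention).  A spot is called
regulated at the compared stage when

1. its SVQ falls outside the unchanged band: SVQ <= 0.6 means *up* at the
   compared stage (the baseline numerator is small relative to the stage),
   SVQ >= 1.67 means *down*; and
2. the per-gel quotients mean(baseline)/v_i pass the same cut-off, on the
   consensus side, in at least ``min_gels`` (default 4) of the stage's
   replicate gels.  The count of passing gels is the H statistic.

An exact two-sided Mann-Whitney U-test between the baseline and stage
volume vectors is computed *in addition* and reported for every tested
spot; it is not used as a gate, matching the coverage method's role as the
primary criterion.  No multiple-testing correction is applied (recorded in
output metadata).

Spots undetected in every gel of one stage but detected in at least
``min_gels`` gels of the other side are called *absent* rather than
quantified.  Proteins represented by several spots are aggregated by the
arithmetic mean of their member SVQs, with a conflict flag when member
directions disagree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .gelio import GelTable, MatchedGroup

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
ABSENT_IN_STAGE = "absent_in_stage"
ABSENT_IN_BASELINE = "absent_in_baseline"

DIRECTIONS = (UP, DOWN, UNCHANGED, ABSENT_IN_STAGE, ABSENT_IN_BASELINE)

#: largest combined sample size handled by complete enumeration
_EXACT_LIMIT = 14


@dataclass(frozen=True)
class DiffConfig:
    """Cut-offs and conventions of the coverage method."""

    svq_up_max: float = 0.6
    svq_down_min: float = 1.67
    min_gels: int = 4
    alpha: float = 0.05
    detection_floor: float = 0.0
    baseline_stage: str = "P90"

    def __post_init__(self) -> None:
        if not (0 < self.svq_up_max < 1 < self.svq_down_min):
            raise ConfigurationError(
                "cut-offs must satisfy 0 < svq_up_max < 1 < svq_down_min"
            )
        if self.min_gels < 1:
            raise ConfigurationError("min_gels must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")


@dataclass
class StageComparison:
    """Result of comparing one matched spot at one stage against baseline."""

    group_id: str
    stage: str
    svq: float | None
    per_gel_svq: list[float]
    h_count: int
    direction: str
    p_value: float
    passes_coverage: bool
    n_baseline_detected: int
    n_stage_detected: int

    @property
    def regulated(self) -> bool:
        if self.direction in (ABSENT_IN_STAGE, ABSENT_IN_BASELINE):
            return True
        return self.direction in (UP, DOWN) and self.passes_coverage


@dataclass
class ProteinResult:
    """Protein-level call aggregated over its member spots (one stage)."""

    accession: str
    stage: str
    spot_group_ids: list[str]
    mean_svq: float | None
    direction: str
    conflict: bool
    regulated: bool

    @property
    def n_spots(self) -> int:
        return len(self.spot_group_ids)


def compute_svq(
    baseline_volumes: list[float], stage_volumes: list[float]
) -> tuple[float, list[float]]:
    """Spot volume quotient and per-gel quotients.

    ``svq = mean(baseline) / mean(stage)``; the per-gel quotients divide the
    baseline mean by each detected stage-gel volume, yielding exactly one
    quotient per stage gel for the H count.
    """
    if not baseline_volumes or not stage_volumes:
        raise ValueError("both volume lists must contain at least one detection")
    mb = float(np.mean(baseline_volumes))
    ms = float(np.mean(stage_volumes))
    if ms <= 0 or mb <= 0:
        raise ValueError(
            "zero mean volume: absence is handled by detect_absence, not a quotient"
        )
    return mb / ms, [mb / float(v) for v in stage_volumes]


def classify_direction(svq: float, config: DiffConfig = DiffConfig()) -> str:
    """Classify a quotient: up iff SVQ <= 0.6, down iff SVQ >= 1.67 (inclusive).

    SVQ is baseline/stage, so a LOW quotient means the compared stage is UP.
    """
    if svq <= 0:
        raise ValueError("svq must be positive")
    if svq <= config.svq_up_max:
        return UP
    if svq >= config.svq_down_min:
        return DOWN
    return UNCHANGED


def coverage_filter(
    per_gel_svq: list[float], consensus_direction: str, config: DiffConfig = DiffConfig()
) -> tuple[int, bool]:
    """H count and pass flag of the coverage condition.

    H is the number of per-gel quotients meeting the cut-off on the
    consensus side; the spot passes when H >= min_gels.  Not applicable to
    an unchanged consensus (returns (0, False)).
    """
    if consensus_direction == UP:
        h = sum(1 for q in per_gel_svq if q <= config.svq_up_max)
    elif consensus_direction == DOWN:
        h = sum(1 for q in per_gel_svq if q >= config.svq_down_min)
    else:
        return 0, False
    return h, h >= config.min_gels


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U-test

_comb_cache: dict[tuple[int, int], np.ndarray] = {}
_null_dev_cache: dict[tuple[int, int], np.ndarray] = {}


def _comb_indices(n_total: int, n_x: int) -> np.ndarray:
    key = (n_total, n_x)
    if key not in _comb_cache:
        _comb_cache[key] = np.array(
            list(itertools.combinations(range(n_total), n_x)), dtype=np.intp
        )
    return _comb_cache[key]


def _tiefree_null_devs(n: int, m: int) -> np.ndarray:
    """Sorted |U - nm/2| over all assignments, ranks 1..n+m without ties."""
    key = (n, m)
    if key not in _null_dev_cache:
        ranks = np.arange(1, n + m + 1, dtype=float)
        combs = _comb_indices(n + m, n)
        u = ranks[combs].sum(axis=1) - n * (n + 1) / 2.0
        _null_dev_cache[key] = np.sort(np.abs(u - n * m / 2.0))
    return _null_dev_cache[key]


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test, exact for small samples.

    U is computed from rank sums with mid-ranks for ties.  For combined
    sample sizes up to 14 the p-value is exact: all C(n+m, n) assignments of
    the pooled values to the two groups are enumerated and assignments with
    |U - nm/2| at least as large as observed are counted.  Larger samples
    fall back to the normal approximation with tie correction.

    Returns ``(U, p)`` with U the statistic of the first sample and p in
    (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    if n + m > _EXACT_LIMIT:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        return u, min(max(p, np.nextafter(0, 1)), 1.0)
    obs_dev = abs(u - n * m / 2.0)
    if len(np.unique(pooled)) == n + m:
        devs = _tiefree_null_devs(n, m)
    else:
        combs = _comb_indices(n + m, n)
        u_all = ranks[combs].sum(axis=1) - n * (n + 1) / 2.0
        devs = np.abs(u_all - n * m / 2.0)
    count = int(np.sum(devs >= obs_dev - 1e-9))
    total = math.comb(n + m, n)
    return u, count / total


def detect_absence(
    baseline_detections: int, stage_detections: int, config: DiffConfig = DiffConfig()
) -> str | None:
    """Absence call from detection counts, or None.

    A spot absent from every gel of one side is called absent only when the
    other side detects it in at least ``min_gels`` gels; weaker evidence is
    left to the quotient path or dropped as unreliable.
    """
    if stage_detections == 0 and baseline_detections >= config.min_gels:
        return ABSENT_IN_STAGE
    if baseline_detections == 0 and stage_detections >= config.min_gels:
        return ABSENT_IN_BASELINE
    return None


def compare_stage(
    groups: list[MatchedGroup],
    gels: list[GelTable],
    stage: str,
    config: DiffConfig = DiffConfig(),
) -> list[StageComparison]:
    """One StageComparison per matched group detected at baseline or *stage*.

    Gels must be normalized.  A group is reported regulated iff its
    direction is up/down AND the coverage filter passes (or it takes the
    absence path); the Mann-Whitney p-value is attached whenever both sides
    have at least two detections, as a report, not a gate.
    """
    stages_present = {g.stage for g in gels}
    if stage not in stages_present:
        raise ConfigurationError(f"unknown stage {stage!r}")
    if config.baseline_stage not in stages_present:
        raise ConfigurationError(f"baseline stage {config.baseline_stage!r} not in gels")
    if stage == config.baseline_stage:
        raise ConfigurationError("stage must differ from the baseline stage")

    volumes: dict[tuple[str, int], dict[str, float]] = {}
    for gel in gels:
        tab = {}
        for s in gel.spots:
            if s.norm_volume is None:
                raise ValueError("gels must be normalized before comparison")
            tab[s.spot_id] = s.norm_volume
        volumes[(gel.stage, gel.replicate)] = tab

    base_keys = sorted(k for k in volumes if k[0] == config.baseline_stage)
    stage_keys = sorted(k for k in volumes if k[0] == stage)

    results: list[StageComparison] = []
    for grp in groups:
        base_vols = []
        for k in base_keys:
            sid = grp.members.get(k)
            if sid is not None:
                v = volumes[k].get(sid)
                if v is not None and v > config.detection_floor:
                    base_vols.append(v)
        stage_vols = []
        for k in stage_keys:
            sid = grp.members.get(k)
            if sid is not None:
                v = volumes[k].get(sid)
                if v is not None and v > config.detection_floor:
                    stage_vols.append(v)
        nb, ns = len(base_vols), len(stage_vols)
        if nb == 0 and ns == 0:
            continue
        absence = detect_absence(nb, ns, config)
        if absence is not None:
            results.append(
                StageComparison(
                    group_id=grp.group_id, stage=stage, svq=None, per_gel_svq=[],
                    h_count=0, direction=absence, p_value=float("nan"),
                    passes_coverage=True, n_baseline_detected=nb, n_stage_detected=ns,
                )
            )
            continue
        if nb == 0 or ns == 0:
            # one-sided zero with too few detections opposite: unreliable
            results.append(
                StageComparison(
                    group_id=grp.group_id, stage=stage, svq=None, per_gel_svq=[],
                    h_count=0, direction=UNCHANGED, p_value=float("nan"),
                    passes_coverage=False, n_baseline_detected=nb, n_stage_detected=ns,
                )
            )
            continue
        svq, per_gel = compute_svq(base_vols, stage_vols)
        direction = classify_direction(svq, config)
        h, passes = coverage_filter(per_gel, direction, config)
        if nb >= 2 and ns >= 2:
            _, p = mann_whitney_exact(base_vols, stage_vols)
        else:
            p = float("nan")
        results.append(
            StageComparison(
                group_id=grp.group_id, stage=stage, svq=svq, per_gel_svq=per_gel,
                h_count=h, direction=direction, p_value=p, passes_coverage=passes,
                n_baseline_detected=nb, n_stage_detected=ns,
            )
        )
    return results


def aggregate_protein(
    spot_comparisons: list[StageComparison],
    accession: str,
    config: DiffConfig = DiffConfig(),
) -> ProteinResult:
    """Aggregate the spots of one protein by the mean of their SVQs.

    All comparisons must belong to the same stage contrast.  Absence labels
    propagate only when every member spot agrees; otherwise the quotient-
    bearing members are averaged and a conflict flag is raised.  The
    conflict flag is also set when member directions disagree (the analogue
    of the asterisk marking multi-spot proteins with ambiguous regulation).
    """
    if not spot_comparisons:
        raise ValueError("need at least one spot comparison")
    stages = {c.stage for c in spot_comparisons}
    if len(stages) > 1:
        raise ConfigurationError(f"mixed stages in aggregation: {sorted(stages)}")
    stage = spot_comparisons[0].stage
    ids = [c.group_id for c in spot_comparisons]
    directions = [c.direction for c in spot_comparisons]

    if all(d == ABSENT_IN_STAGE for d in directions) or all(
        d == ABSENT_IN_BASELINE for d in directions
    ):
        return ProteinResult(
            accession=accession, stage=stage, spot_group_ids=ids, mean_svq=None,
            direction=directions[0], conflict=False, regulated=True,
        )

    svqs = [c.svq for c in spot_comparisons if c.svq is not None]
    conflict = len(set(directions)) > 1
    if not svqs:
        return ProteinResult(
            accession=accession, stage=stage, spot_group_ids=ids, mean_svq=None,
            direction=UNCHANGED, conflict=conflict, regulated=False,
        )
    mean_svq = float(np.mean(svqs))
    direction = classify_direction(mean_svq, config)
    regulated = direction in (UP, DOWN) and any(
        c.regulated for c in spot_comparisons
    )
    return ProteinResult(
        accession=accession, stage=stage, spot_group_ids=ids, mean_svq=mean_svq,
        direction=direction, conflict=conflict, regulated=regulated,
    )
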