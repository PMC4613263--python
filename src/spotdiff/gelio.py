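"""Spot-table I/O, volume normalization and cross-gel spot matching.

Two-dimensional gel electrophoresis (2DE) separates proteins by isoelectric
point (pI, first dimension) and molecular weight (MW, second dimension).
After staining and densitometry each gel reduces to a *spot table*: one row
per detected spot with its position and integrated stain intensity (the
"spot volume").  This module provides

* a plain-text TSV dialect for spot tables and strict readers/writers,
* total-volume normalization (parts-per-million-of-total), the standard
  convention that makes volumes comparable across gels loaded or stained
  slightly differently,
* reference-gel selection (the replicate with the most spots), and
* greedy nearest-neighbour spot matching across gels in (pI, log10 MW)
  space, producing :class:`MatchedGroup` objects that track one physical
  spot through every gel of the experiment.

Matching operates on spot tables, not on gel images: pixel-level warping
and segmentation are upstream concerns of densitometry software and out of
scope here.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DegenerateGelError, SpotTableFormatError

#: scale factor of the fraction-of-total normalization (ppm of total volume)
NORM_SCALE = 1e6

#: default matching tolerances: pH units and log10(kDa)
DEFAULT_TOL_PI = 0.1
DEFAULT_TOL_LOGMW = 0.02

_HEADER = ("spot_id", "pi", "mw_kda", "raw_volume")
_FILENAME_RE = re.compile(r"^(?P<stage>[^_]+)_rep(?P<rep>\d+)\.tsv$")


@dataclass(frozen=True)
class SpotRecord:
    """One detected spot on one gel."""

    spot_id: str
    pi: float
    mw_kda: float
    raw_volume: float
    norm_volume: float | None = None


@dataclass
class GelTable:
    """All spots detected on one replicate gel of one stage."""

    stage: str
    replicate: int
    spots: list[SpotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(ids) != len(set(ids)):
            raise SpotTableFormatError(
                f"duplicate spot_id in gel {self.stage}_rep{self.replicate}"
            )

    def volume_of(self, spot_id: str) -> float | None:
        for s in self.spots:
            if s.spot_id == spot_id:
                return s.norm_volume if s.norm_volume is not None else s.raw_volume
        return None


@dataclass
class MatchedGroup:
    """One physical spot tracked across the gels of an experiment.

    ``members`` maps (stage, replicate) to the spot_id that gel contributed;
    each gel contributes at most one spot, and each spot belongs to at most
    one group.
    """

    group_id: str
    members: dict[tuple[str, int], str]
    centroid: tuple[float, float]  # (pi, mw_kda)


def gel_filename(stage: str, replicate: int) -> str:
    return f"{stage}_rep{replicate}.tsv"


def read_spot_table(
    path: str | Path, stage: str | None = None, replicate: int | None = None
) -> GelTable:
    """Read one spot table in the package TSV dialect.

    The dialect is ``spot_id<TAB>pi<TAB>mw_kda<TAB>raw_volume[<TAB>norm_volume]``
    with a header line, UTF-8 and ``.`` decimal separator.  Stage and
    replicate are taken from the filename ``{stage}_rep{k}.tsv`` unless given
    explicitly.  Malformed rows raise :class:`SpotTableFormatError` naming
    the 1-based line number.
    """
    path = Path(path)
    if stage is None or replicate is None:
        m = _FILENAME_RE.match(path.name)
        if m is None:
            raise SpotTableFormatError(
                f"cannot infer stage/replicate from filename {path.name!r}; "
                "pass stage= and replicate= explicitly"
            )
        stage = stage if stage is not None else m.group("stage")
        replicate = replicate if replicate is not None else int(m.group("rep"))

    spots: list[SpotRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if tuple(row[:4]) != _HEADER:
                    raise SpotTableFormatError(
                        f"bad header {row!r}, expected {list(_HEADER)}", line=1
                    )
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) not in (4, 5):
                raise SpotTableFormatError(
                    f"expected 4 or 5 columns, got {len(row)}", line=lineno
                )
            spot_id = row[0]
            if not spot_id:
                raise SpotTableFormatError("empty spot_id", line=lineno)
            if spot_id in seen:
                raise SpotTableFormatError(f"duplicate spot_id {spot_id!r}", line=lineno)
            try:
                pi = float(row[1])
                mw = float(row[2])
                raw = float(row[3])
                norm = float(row[4]) if len(row) == 5 and row[4] != "" else None
            except ValueError as exc:
                raise SpotTableFormatError(f"non-numeric field: {exc}", line=lineno)
            if not (0.0 <= pi <= 14.0):
                raise SpotTableFormatError(f"pI {pi} outside [0, 14]", line=lineno)
            if mw <= 0:
                raise SpotTableFormatError(f"mw_kda {mw} must be > 0", line=lineno)
            if raw < 0:
                raise SpotTableFormatError(f"negative raw_volume {raw}", line=lineno)
            seen.add(spot_id)
            spots.append(SpotRecord(spot_id, pi, mw, raw, norm))
    return GelTable(stage=stage, replicate=replicate, spots=spots)


def write_spot_table(gel: GelTable, path: str | Path) -> None:
    """Write a gel table in the TSV dialect (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        has_norm = any(s.norm_volume is not None for s in gel.spots)
        header = list(_HEADER) + (["norm_volume"] if has_norm else [])
        fh.write("\t".join(header) + "\n")
        for s in gel.spots:
            cols = [s.spot_id, f"{s.pi:.4f}", f"{s.mw_kda:.4f}", f"{s.raw_volume:.4f}"]
            if has_norm:
                cols.append("" if s.norm_volume is None else f"{s.norm_volume:.4f}")
            fh.write("\t".join(cols) + "\n")


def read_experiment(directory: str | Path) -> list[GelTable]:
    """Read every ``{stage}_rep{k}.tsv`` under *directory*, sorted by name."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if _FILENAME_RE.match(p.name))
    if not paths:
        raise SpotTableFormatError(f"no spot tables found under {directory}")
    return [read_spot_table(p) for p in paths]


def normalize_volumes(gel: GelTable) -> GelTable:
    """Return a copy with ``norm_volume = raw_volume / total * 1e6``.

    The ppm-of-total convention preserves within-gel volume ratios exactly
    and removes between-gel loading/staining scale.  Idempotent: the
    normalized volume is always recomputed from the raw volumes.
    """
    total = sum(s.raw_volume for s in gel.spots)
    if total <= 0:
        raise DegenerateGelError(
            f"gel {gel.stage}_rep{gel.replicate} has zero total volume"
        )
    spots = [replace(s, norm_volume=s.raw_volume / total * NORM_SCALE) for s in gel.spots]
    return GelTable(stage=gel.stage, replicate=gel.replicate, spots=spots)


def select_reference_gel(gels: list[GelTable]) -> int:
    """Index of the gel with the most spots; ties go to the lowest index.

    Densitometry practice picks the replicate with the best separation and
    least artifacts as the registration target; at spot-table level the
    computable part of that criterion is the spot count.
    """
    if not gels:
        raise ConfigurationError("empty gel list")
    counts = [len(g.spots) for g in gels]
    return int(np.argmax(counts))


def _scaled_coords(spots: list[SpotRecord], tol_pi: float, tol_logmw: float) -> np.ndarray:
    return np.array(
        [[s.pi / tol_pi, math.log10(s.mw_kda) / tol_logmw] for s in spots],
        dtype=float,
    ).reshape(len(spots), 2)


def match_spots(
    gels: list[GelTable],
    tol_pi: float = DEFAULT_TOL_PI,
    tol_logmw: float = DEFAULT_TOL_LOGMW,
    reference: int | None = None,
) -> list[MatchedGroup]:
    """Greedy nearest-neighbour linkage of spots across gels.

    Groups are seeded from the reference gel (most spots by default).  Each
    further gel's spots are linked to the nearest existing group centroid in
    tolerance-scaled (pI, log10 MW) space, accepting a link only when
    |dpI| <= tol_pi and |dlog10 MW| <= tol_logmw.  Links are taken globally
    closest-first; among equidistant candidates the higher-volume spot wins
    (then lexicographic spot_id for determinism).  Spots that link nowhere
    seed new groups, so every spot ends in exactly one group.
    """
    if tol_pi <= 0 or tol_logmw <= 0:
        raise ConfigurationError("matching tolerances must be positive")
    if not gels:
        raise ConfigurationError("empty gel list")
    ref = select_reference_gel(gels) if reference is None else reference

    # groups as parallel lists: members, centroid accumulators
    members: list[dict[tuple[str, int], str]] = []
    cen_sum: list[np.ndarray] = []  # sums in (pi, log10 mw)
    cen_n: list[int] = []

    def new_group(spot: SpotRecord, key: tuple[str, int]) -> None:
        members.append({key: spot.spot_id})
        cen_sum.append(np.array([spot.pi, math.log10(spot.mw_kda)]))
        cen_n.append(1)

    order = [ref] + [i for i in range(len(gels)) if i != ref]
    for gi in order:
        gel = gels[gi]
        key = (gel.stage, gel.replicate)
        if gi == ref or not members:
            for s in gel.spots:
                new_group(s, key)
            continue
        if not gel.spots:
            continue
        centroids = np.array([c / n for c, n in zip(cen_sum, cen_n)])
        scaled_cen = centroids / [tol_pi, tol_logmw]
        tree = cKDTree(scaled_cen)
        coords = _scaled_coords(gel.spots, tol_pi, tol_logmw)
        # candidate links within the tolerance box (superset via L2 ball)
        candidates: list[tuple[float, float, str, int, int]] = []
        for si, s in enumerate(gel.spots):
            for g in tree.query_ball_point(coords[si], math.sqrt(2.0) + 1e-9):
                dpi = abs(s.pi - centroids[g, 0])
                dlmw = abs(math.log10(s.mw_kda) - centroids[g, 1])
                if dpi <= tol_pi and dlmw <= tol_logmw:
                    d = math.hypot(dpi / tol_pi, dlmw / tol_logmw)
                    candidates.append((d, -s.raw_volume, s.spot_id, g, si))
        candidates.sort()
        used_groups: set[int] = set()
        used_spots: set[int] = set()
        for d, _negvol, _sid, g, si in candidates:
            if g in used_groups or si in used_spots:
                continue
            used_groups.add(g)
            used_spots.add(si)
            s = gel.spots[si]
            members[g][key] = s.spot_id
            cen_sum[g] = cen_sum[g] + [s.pi, math.log10(s.mw_kda)]
            cen_n[g] += 1
        for si, s in enumerate(gel.spots):
            if si not in used_spots:
                new_group(s, key)

    groups = []
    for k, (mem, c, n) in enumerate(zip(members, cen_sum, cen_n)):
        pi_c, lmw_c = c / n
        groups.append(
            MatchedGroup(
                group_id=f"g{k:05d}", members=mem, centroid=(pi_c, 10.0 ** lmw_c)
            )
        )
    return groups


def groups_by_spot_id(gels: list[GelTable]) -> list[MatchedGroup]:
    """Group spots that share a spot_id across gels.

    Usable when the tables come from software (or a simulator) that already
    assigns consistent spot identities across gels; bypasses coordinate
    matching.
    """
    by_id: dict[str, MatchedGroup] = {}
    for gel in gels:
        key = (gel.stage, gel.replicate)
        for s in gel.spots:
            grp = by_id.get(s.spot_id)
            if grp is None:
                by_id[s.spot_id] = MatchedGroup(
                    group_id=s.spot_id, members={key: s.spot_id},
                    centroid=(s.pi, s.mw_kda),
                )
            else:
                grp.members[key] = s.spot_id
    return list(by_id.values())
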