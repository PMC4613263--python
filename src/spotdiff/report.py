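"""Functional-category assignment, summary tables and the analysis pipeline.

Differential 2DE studies conventionally bin the identified proteins into
functional groups (carbohydrate metabolism, chaperones, structural
proteins, ...) and report, per stage contrast, the number of up-, down-
regulated and absent proteins overall and per group.  The group membership
is curated externally and consumed here as a plain accession -> group TSV;
nothing is fetched over the network.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .differential import (
    ABSENT_IN_BASELINE,
    ABSENT_IN_STAGE,
    DOWN,
    UP,
    DiffConfig,
    ProteinResult,
    StageComparison,
    aggregate_protein,
    compare_stage,
)
from .errors import SpotTableFormatError
from .gelio import GelTable, MatchedGroup, groups_by_spot_id, match_spots, normalize_volumes

UNCLASSIFIED = "unclassified"

#: the 13 conventional functional groups of the cerebellum studies
DEFAULT_GROUPS = (
    "carbohydrate metabolism", "amino acid metabolism", "fat metabolism",
    "energy metabolism", "degradation", "antioxidants",
    "transmitter metabolism", "biosynthesis", "signal transduction",
    "regulation", "chaperones", "structural", "transport",
)


def load_annotation(path: str | Path) -> dict[str, str]:
    """Read an ``accession<TAB>group`` map; malformed rows name their line."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise SpotTableFormatError(
                    f"expected 'accession<TAB>group', got {line!r}", line=lineno
                )
            out[parts[0]] = parts[1]
    return out


def assign_groups(
    results: list[ProteinResult], annotation: dict[str, str]
) -> pd.DataFrame:
    """Tabulate protein results with their functional group.

    Accessions missing from the annotation map (or an empty map) fall into
    ``unclassified``.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "accession": r.accession,
                "stage": r.stage,
                "group": annotation.get(r.accession, UNCLASSIFIED),
                "direction": r.direction,
                "regulated": r.regulated,
                "mean_svq": r.mean_svq,
                "n_spots": r.n_spots,
                "conflict": r.conflict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "stage", "group", "direction", "regulated",
            "mean_svq", "n_spots", "conflict",
        ],
    )


def summarize(annotated: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Per-category regulated counts and relative frequencies for one contrast.

    Returns a table indexed by functional group with columns ``up``,
    ``down``, ``absent``, ``absent_baseline``, ``total`` and ``rel_freq``
    (fraction of all regulated proteins; sums to 1), plus a ``Total`` row.
    With no regulated proteins the table is empty.
    """
    df = annotated[(annotated["stage"] == stage) & annotated["regulated"]]
    if df.empty:
        return pd.DataFrame(
            columns=["up", "down", "absent", "absent_baseline", "total", "rel_freq"]
        )
    counts = {}
    for group, sub in df.groupby("group"):
        counts[group] = {
            "up": int((sub["direction"] == UP).sum()),
            "down": int((sub["direction"] == DOWN).sum()),
            "absent": int((sub["direction"] == ABSENT_IN_STAGE).sum()),
            "absent_baseline": int((sub["direction"] == ABSENT_IN_BASELINE).sum()),
        }
    table = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    table["total"] = table.sum(axis=1)
    table["rel_freq"] = table["total"] / table["total"].sum()
    total_row = table.sum(axis=0).to_frame().T
    total_row.index = ["Total"]
    return pd.concat([table, total_row])


def overall_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Headline counts per stage contrast.

    Rows Total / Up-regulated / Down-regulated / Absent / Absent-baseline,
    one column per compared stage.
    """
    out = {}
    for stage, sub in annotated[annotated["regulated"]].groupby("stage"):
        out[stage] = {
            "Total": len(sub),
            "Up-regulated": int((sub["direction"] == UP).sum()),
            "Down-regulated": int((sub["direction"] == DOWN).sum()),
            "Absent": int((sub["direction"] == ABSENT_IN_STAGE).sum()),
            "Absent-baseline": int((sub["direction"] == ABSENT_IN_BASELINE).sum()),
        }
    index = ["Total", "Up-regulated", "Down-regulated", "Absent", "Absent-baseline"]
    return pd.DataFrame(out).reindex(index).fillna(0).astype(int)


def comparisons_table(comparisons: list[StageComparison]) -> pd.DataFrame:
    """Spot-level results mirroring the published layout.

    Columns: accession (spot group), stage, regulation, p_value,
    ``Control/PD`` (the SVQ), ``H`` and detection counts.
    """
    rows = [
        {
            "accession": c.group_id,
            "stage": c.stage,
            "regulation": c.direction if c.regulated else "-",
            "p_value": c.p_value,
            "Control/PD": c.svq,
            "H": c.h_count,
            "n_baseline_detected": c.n_baseline_detected,
            "n_stage_detected": c.n_stage_detected,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)


def analyze_experiment(
    gels: list[GelTable],
    config: DiffConfig = DiffConfig(),
    groups: list[MatchedGroup] | None = None,
    accession_of: dict[str, str] | None = None,
    use_spot_ids: bool = False,
) -> tuple[dict[str, list[StageComparison]], list[ProteinResult]]:
    """Run normalization, matching, differential calling and aggregation.

    ``groups`` may be supplied (e.g. truth-derived); otherwise spots are
    grouped by shared spot_id when ``use_spot_ids`` is set, or matched by
    coordinates.  ``accession_of`` maps group_id -> protein accession for
    multi-spot aggregation; by default every group is its own protein.
    Returns per-stage spot comparisons and the flat protein-level results.
    No multiple-testing correction is applied to the reported p-values.
    """
    gels = [normalize_volumes(g) for g in gels]
    if groups is None:
        groups = groups_by_spot_id(gels) if use_spot_ids else match_spots(gels)
    stages = sorted(
        {g.stage for g in gels} - {config.baseline_stage},
        key=[g.stage for g in gels].index,
    )
    comparisons: dict[str, list[StageComparison]] = {}
    proteins: list[ProteinResult] = []
    for stage in stages:
        comps = compare_stage(groups, gels, stage, config)
        comparisons[stage] = comps
        by_protein: dict[str, list[StageComparison]] = {}
        for c in comps:
            acc = (accession_of or {}).get(c.group_id, c.group_id)
            by_protein.setdefault(acc, []).append(c)
        for acc, cs in sorted(by_protein.items()):
            proteins.append(aggregate_protein(cs, acc, config))
    return comparisons, proteins


def write_manifest(path: str | Path, command: str, seed: int | None, config: dict) -> None:
    """Machine-readable run manifest (config, seed, package version)."""
    manifest = {
        "package": "spotdiff",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "multiple_testing_correction": "none",
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
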