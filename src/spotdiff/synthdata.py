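"""Synthetic 2DE experiments and synthetic PMF search cases.

The generator emulates the design of a three-stage rat cerebellum ontogeny
experiment: stages P7, P90 (baseline) and P637 with six replicate gels
each.  Per-protein baseline volumes are drawn log-uniformly over three
decades (faint to saturated spots); replicate volumes are the baseline
volume times the stage fold change times multiplicative lognormal noise
with a configured coefficient of variation (2DE volumes are positive and
right-skewed).  A configured fraction of proteins is regulated per stage
with fold-change magnitudes drawn log-uniformly from ``fold_change_range``
on a random side; a fraction of regulated proteins is fully absent (volume
zero in every gel) in the compared stage.  Proteins may occupy 2-3 spots
(isoforms), and a fraction of spots hold two co-migrating proteins (mixed
spots).  Spot positions live in pI 3-10 and 10-100 kDa with per-gel
gaussian jitter in (pI, log10 MW).

Random streams
--------------
All randomness derives from ``numpy.random.SeedSequence(seed)`` spawned
into six named child streams, in this order:

0. structure  - multispot membership, spot counts, volume splits, mixed pairs
1. positions  - true spot coordinates (rejection-sampled for separation)
2. volumes    - per-protein baseline mean volumes
3. regulation - per non-baseline stage, in config stage order, four
                length-``n_proteins`` vectors in sequence: uniform u_reg
                (regulated iff u_reg < frac_regulated_per_stage), uniform
                u_side (up iff u_side < 0.5), log-uniform magnitudes, and
                uniform u_abs (absent iff regulated and u_abs < frac_absent)
4. noise      - per stage (config order), lognormal replicate factors of
                shape (n_replicates, n_spots)
5. jitter     - per gel (stage order, then replicate), per-spot gaussian
                displacements in (pI, log10 MW)

This layout makes each decision independently replayable from the seed,
which the tests use to verify the sampling against the documented
procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import pmf as _pmf
from .errors import ConfigurationError
from .gelio import GelTable, SpotRecord, gel_filename, write_spot_table

#: Swiss-Prot-style average amino-acid composition used for synthetic proteins
DEFAULT_RESIDUE_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of one synthetic 2DE experiment."""

    n_proteins: int = 100
    n_replicates: int = 6
    stages: tuple[str, ...] = ("P7", "P90", "P637")
    baseline_stage: str = "P90"
    frac_regulated_per_stage: float = 0.2
    fold_change_range: tuple[float, float] = (2.0, 4.0)  # magnitude of true ratio
    regulation_side: str = "both"  # "both" | "up" | "down"
    cv: float = 0.2
    frac_multispot: float = 0.10
    frac_mixed: float = 0.05
    frac_absent: float = 0.10
    pi_range: tuple[float, float] = (3.0, 10.0)
    mw_range_kda: tuple[float, float] = (10.0, 100.0)
    position_jitter: tuple[float, float] = (0.02, 0.004)  # sd in (pI, log10 kDa)
    min_spot_separation: tuple[float, float] = (0.12, 0.024)
    detection_floor: float = 0.0
    baseline_volume_decades: tuple[float, float] = (3.0, 6.0)  # log10 volume range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if not self.stages:
            raise ConfigurationError("stages must be nonempty")
        if self.baseline_stage not in self.stages:
            raise ConfigurationError("baseline_stage must be one of stages")
        for name in ("frac_regulated_per_stage", "frac_multispot", "frac_mixed",
                     "frac_absent"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_regulated_per_stage >= 1.0:
            raise ConfigurationError("frac_regulated_per_stage must be < 1")
        lo, hi = self.fold_change_range
        if not (0 < lo <= hi):
            raise ConfigurationError("fold_change_range must be positive and ordered")
        if lo < 1.67:
            raise ConfigurationError(
                "fold-change magnitudes must lie outside the unchanged band "
                "[0.6, 1.67]; give magnitudes >= 1.67"
            )
        if self.regulation_side not in ("both", "up", "down"):
            raise ConfigurationError("regulation_side must be both/up/down")
        if not (3.0 <= self.pi_range[0] < self.pi_range[1] <= 10.0):
            raise ConfigurationError("pi_range must be within [3, 10]")
        if not (0.0 < self.mw_range_kda[0] < self.mw_range_kda[1]):
            raise ConfigurationError("mw_range_kda must be positive and ordered")
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for one protein at one non-baseline stage.

    ``true_fold_change`` is the stage/baseline mean-volume ratio; 0.0
    encodes a protein simulated as fully absent in the compared stage.
    """

    protein_id: str
    stage: str
    true_fold_change: float
    true_direction: str  # up | down | unchanged | absent_in_stage
    n_spots: int
    spot_ids: list[str]


@dataclass(frozen=True)
class SyntheticSequenceConfig:
    """Conditions of one synthetic PMF search case."""

    n_proteins: int = 500
    length_range: tuple[int, int] = (150, 600)
    residue_frequencies: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_RESIDUE_FREQUENCIES.items()
    )
    mass_jitter_ppm: float = 20.0
    frac_peak_dropout: float = 0.3
    n_contaminant_peaks: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ConfigurationError("a search needs decoys: n_proteins >= 2")
        if self.mass_jitter_ppm < 0:
            raise ConfigurationError("mass_jitter_ppm must be >= 0")
        if not (0.0 <= self.frac_peak_dropout < 1.0):
            raise ConfigurationError("frac_peak_dropout must be in [0, 1)")
        if self.length_range[0] < 10 or self.length_range[0] > self.length_range[1]:
            raise ConfigurationError("length_range must be ordered, minimum >= 10")


# ---------------------------------------------------------------------------


def _lognormal_params(cv: float) -> tuple[float, float]:
    """(mu, sigma) of a mean-1 lognormal with the given coefficient of variation."""
    sigma2 = math.log(1.0 + cv * cv)
    return -sigma2 / 2.0, math.sqrt(sigma2)


def generate_experiment(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[GelTable], list[TruthRecord]]:
    """Generate one synthetic experiment: spot tables and ground truth.

    Returns one :class:`GelTable` per (stage, replicate) in stage-major
    order and one :class:`TruthRecord` per (protein, non-baseline stage).
    Identical configs (including seed) produce identical output.
    """
    n = config.n_proteins
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rs_struct = np.random.default_rng(streams[0])
    rs_pos = np.random.default_rng(streams[1])
    rs_vol = np.random.default_rng(streams[2])
    rs_reg = np.random.default_rng(streams[3])
    rs_noise = np.random.default_rng(streams[4])
    rs_jitter = np.random.default_rng(streams[5])

    # --- structure: spots per protein, volume shares, mixed-spot pairs
    multi = rs_struct.random(n) < config.frac_multispot
    spots_per_protein = np.ones(n, dtype=int)
    spots_per_protein[multi] = rs_struct.integers(2, 4, size=int(multi.sum()))
    shares: list[np.ndarray] = []
    for i in range(n):
        k = spots_per_protein[i]
        shares.append(rs_struct.dirichlet(np.ones(k)) if k > 1 else np.ones(1))
    single = [i for i in range(n) if spots_per_protein[i] == 1]
    n_pairs = min(int(config.frac_mixed * n / 2.0), len(single) // 2)
    mixed_partners: dict[int, int] = {}
    if n_pairs > 0:
        chosen = rs_struct.choice(len(single), size=2 * n_pairs, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            mixed_partners[single[a]] = single[b]

    # physical spots: list of (spot_id, [(protein, spot_idx, share), ...])
    spot_defs: list[tuple[str, list[tuple[int, float]]]] = []
    spot_ids_of: dict[int, list[str]] = {i: [] for i in range(n)}
    merged_into = {b: a for a, b in mixed_partners.items()}
    for i in range(n):
        if i in merged_into:
            continue  # handled with its partner
        for j in range(spots_per_protein[i]):
            contribs = [(i, float(shares[i][j]))]
            sid = f"p{i:04d}s{j}"
            if j == 0 and i in mixed_partners:
                b = mixed_partners[i]
                contribs.append((b, 1.0))
                sid = f"x{i:04d}"
                spot_ids_of[b].append(sid)
            spot_defs.append((sid, contribs))
            spot_ids_of[i].append(sid)
    n_spots = len(spot_defs)

    # --- positions: rejection-sample for minimum separation
    sep_pi, sep_lmw = config.min_spot_separation
    lo_pi, hi_pi = config.pi_range
    lo_lmw = math.log10(config.mw_range_kda[0])
    hi_lmw = math.log10(config.mw_range_kda[1])
    pos = np.empty((n_spots, 2))
    for k in range(n_spots):
        for _attempt in range(1000):
            p = rs_pos.uniform(lo_pi, hi_pi)
            l = rs_pos.uniform(lo_lmw, hi_lmw)
            if k == 0 or not np.any(
                (np.abs(pos[:k, 0] - p) <= sep_pi)
                & (np.abs(pos[:k, 1] - l) <= sep_lmw)
            ):
                break
        pos[k] = (p, l)

    # --- baseline volumes
    base_vol = 10.0 ** rs_vol.uniform(*config.baseline_volume_decades, size=n)

    # --- regulation per non-baseline stage
    other_stages = [s for s in config.stages if s != config.baseline_stage]
    ratio: dict[str, np.ndarray] = {}
    absent: dict[str, np.ndarray] = {}
    truths: list[TruthRecord] = []
    log_lo, log_hi = (math.log10(f) for f in config.fold_change_range)
    for stage in other_stages:
        u_reg = rs_reg.random(n)
        u_side = rs_reg.random(n)
        mags = 10.0 ** rs_reg.uniform(log_lo, log_hi, size=n)
        u_abs = rs_reg.random(n)
        regulated = u_reg < config.frac_regulated_per_stage
        if config.regulation_side == "both":
            up = u_side < 0.5
        else:
            up = np.full(n, config.regulation_side == "up")
        r = np.ones(n)
        r[regulated & up] = mags[regulated & up]
        r[regulated & ~up] = 1.0 / mags[regulated & ~up]
        ab = regulated & (u_abs < config.frac_absent)
        ratio[stage] = r
        absent[stage] = ab
        for i in range(n):
            if ab[i]:
                direction, fold = "absent_in_stage", 0.0
            elif regulated[i]:
                direction, fold = ("up" if up[i] else "down"), float(r[i])
            else:
                direction, fold = "unchanged", 1.0
            truths.append(
                TruthRecord(
                    protein_id=f"p{i:04d}", stage=stage, true_fold_change=fold,
                    true_direction=direction, n_spots=len(spot_ids_of[i]),
                    spot_ids=list(spot_ids_of[i]),
                )
            )

    # --- replicate noise and jitter, assemble gel tables
    mu, sigma = _lognormal_params(config.cv)
    gels: list[GelTable] = []
    noise: dict[str, np.ndarray] = {
        stage: rs_noise.lognormal(mu, sigma, size=(config.n_replicates, n_spots))
        for stage in config.stages
    }
    sd_pi, sd_lmw = config.position_jitter
    for stage in config.stages:
        for rep in range(config.n_replicates):
            dpos = rs_jitter.normal(0.0, 1.0, size=(n_spots, 2)) * [sd_pi, sd_lmw]
            spots = []
            for k, (sid, contribs) in enumerate(spot_defs):
                v = 0.0
                for i, share in contribs:
                    if stage != config.baseline_stage and absent[stage][i]:
                        continue
                    r = 1.0 if stage == config.baseline_stage else ratio[stage][i]
                    v += base_vol[i] * share * r
                v *= noise[stage][rep, k]
                if v <= config.detection_floor:
                    continue
                pi = float(np.clip(pos[k, 0] + dpos[k, 0], *config.pi_range))
                mw = float(10.0 ** (pos[k, 1] + dpos[k, 1]))
                spots.append(SpotRecord(sid, pi, mw, v))
            gels.append(GelTable(stage=stage, replicate=rep, spots=spots))
    return gels, truths


def write_experiment(
    gels: list[GelTable], truths: list[TruthRecord], directory: str | Path
) -> None:
    """Write spot tables (``{stage}_rep{k}.tsv``) and ``truth.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for gel in gels:
        write_spot_table(gel, directory / gel_filename(gel.stage, gel.replicate))
    with open(directory / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_id\tstage\tfold_change\tdirection\tspot_ids\n")
        for t in truths:
            fh.write(
                f"{t.protein_id}\t{t.stage}\t{t.true_fold_change:.6g}\t"
                f"{t.true_direction}\t{','.join(t.spot_ids)}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    truths = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            pid, stage, fold, direction, sids = line.rstrip("\n").split("\t")
            ids = sids.split(",") if sids else []
            truths.append(
                TruthRecord(pid, stage, float(fold), direction, len(ids), ids)
            )
    return truths


# ---------------------------------------------------------------------------


def generate_pmf_case(
    config: SyntheticSequenceConfig = SyntheticSequenceConfig(),
    pmf_config: "_pmf.PmfConfig | None" = None,
) -> tuple[dict[str, str], np.ndarray, str]:
    """Generate a protein database, a peak list, and the true accession.

    The peak list holds the monoisotopic masses of the tryptic peptides of
    one randomly chosen database protein (fixed carbamidomethyl-C applied,
    no variable modifications), each perturbed by gaussian ppm error, with
    the configured dropout applied and contaminant peaks appended; the
    final list is sorted ascending.
    """
    pmf_config = pmf_config if pmf_config is not None else _pmf.PmfConfig()
    rng = np.random.default_rng(config.seed)
    aas = [a for a, _ in config.residue_frequencies]
    freqs = np.array([f for _, f in config.residue_frequencies], dtype=float)
    freqs = freqs / freqs.sum()
    lo, hi = config.length_range
    db: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        db[f"SYN{i:05d}"] = "".join(rng.choice(aas, size=length, p=freqs))
    true_idx = int(rng.integers(config.n_proteins))
    true_acc = f"SYN{true_idx:05d}"

    theo = sorted({c.mono_mass for c in _pmf.digest(db[true_acc], pmf_config)})
    theo = np.array(theo)
    keep = rng.random(len(theo)) >= config.frac_peak_dropout
    peaks = theo[keep]
    if config.mass_jitter_ppm > 0:
        peaks = peaks * (
            1.0 + rng.normal(0.0, config.mass_jitter_ppm * 1e-6, size=len(peaks))
        )
    if config.n_contaminant_peaks > 0:
        span_lo, span_hi = (float(theo.min()), float(theo.max())) if len(theo) else (800.0, 4000.0)
        contaminants = rng.uniform(span_lo, span_hi, size=config.n_contaminant_peaks)
        peaks = np.concatenate([peaks, contaminants])
    return db, np.sort(peaks), true_acc
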