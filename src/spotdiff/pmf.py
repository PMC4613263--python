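"""Peptide mass fingerprinting: in-silico digestion, peak matching, scoring.

Identification of a 2DE spot proceeds by digesting the excised protein with
trypsin, measuring the peptide masses by MALDI-TOF, and comparing the
observed mass list against in-silico digests of every protein in a sequence
database.  This module implements that search with the conventional MALDI
workflow parameters: tryptic cleavage after K/R not before P with one
allowed missed cleavage, fixed carbamidomethylation of cysteines
(+57.021464 Da), variable oxidation of methionines (+15.994915 Da), a
60 ppm mass tolerance, and monoisotopic masses throughout (reflector-mode
convention; average masses are available behind a flag).

Scoring is a probability-based MOWSE-style score: for each candidate
protein the probability ``q`` that a uniformly placed peak would match one
of its digest masses by chance is estimated from the measure of the
+-tolerance windows around the candidate masses within the observed mass
range; the random-match probability of ``qm`` matched peaks out of
``n_peaks`` is then the binomial upper tail, reported as -10*log10(P)
(capped at 300).  Mascot's exact scoring is unpublished; this variant keeps
its frequency logic and is reported as such.  A hit is significant when its
score exceeds ``floor(-10*log10(alpha / n_sequences))``, the standard
database-size-corrected threshold (59 for alpha = 0.05 against 42,755
sequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pmass
from scipy import stats

from .errors import ConfigurationError

WATER_MONO = 18.0105646863
PROTON = 1.007276466
CARBAMIDOMETHYL = 57.021464
OXIDATION = 15.994915

#: maximum reported score (-10*log10 P floor)
SCORE_CAP = 300.0

#: monoisotopic residue masses of the 20 standard amino acids
RESIDUE_MASS_MONO = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}
#: average residue masses, for linear-mode instruments
RESIDUE_MASS_AVG = {
    aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

STANDARD_AA = set(RESIDUE_MASS_MONO)


@dataclass(frozen=True)
class PmfConfig:
    """Search parameters of the fingerprint engine."""

    tolerance_ppm: float = 60.0
    max_missed_cleavages: int = 1
    carbamidomethyl_c: bool = True
    oxidation_m: bool = True
    max_variable_mods: int = 6  # cap on oxidized methionines per peptide
    alpha: float = 0.05
    min_peptide_length: int = 4
    monoisotopic: bool = True
    peaks_are_mh: bool = False  # True if peaks are [M+H]+ rather than neutral

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ConfigurationError("tolerance_ppm must be > 0")
        if self.max_missed_cleavages < 0:
            raise ConfigurationError("max_missed_cleavages must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    missed_cleavages: int
    n_oxidations: int
    mono_mass: float


@dataclass
class PmfMatchResult:
    accession: str
    score: float
    qm: int
    n_peaks: int
    matched_pairs: list[tuple[float, PeptideCandidate, float]]
    significant: bool


def digest(sequence: str, config: PmfConfig = PmfConfig()) -> list[PeptideCandidate]:
    """Tryptic digest: cleave after K or R not followed by P.

    Emits every peptide with 0..max_missed_cleavages internal missed sites,
    dropping peptides shorter than ``min_peptide_length``.  Candidates carry
    zero oxidations; variable-modification states are expanded by
    :func:`peptide_masses`.
    """
    sequence = sequence.upper()
    for pos, aa in enumerate(sequence):
        if aa not in STANDARD_AA:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos + 1}"
            )
    cut_after = [
        i
        for i, aa in enumerate(sequence)
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P")
    ]
    bounds = [0] + [i + 1 for i in cut_after]
    if not cut_after or cut_after[-1] != len(sequence) - 1:
        bounds.append(len(sequence))
    # bounds[j]..bounds[j+1] is the j-th fully cleaved fragment
    n_frag = len(bounds) - 1
    out: list[PeptideCandidate] = []
    for start in range(n_frag):
        for end in range(start, min(start + config.max_missed_cleavages + 1, n_frag)):
            pep = sequence[bounds[start] : bounds[end + 1]]
            if len(pep) < config.min_peptide_length:
                continue
            out.append(
                PeptideCandidate(
                    sequence=pep,
                    missed_cleavages=end - start,
                    n_oxidations=0,
                    mono_mass=peptide_mass(pep, 0, config),
                )
            )
    return out


def peptide_mass(
    sequence: str, n_oxidations: int = 0, config: PmfConfig = PmfConfig()
) -> float:
    """Peptide mass: residue masses + water + fixed and variable mod deltas."""
    table = RESIDUE_MASS_MONO if config.monoisotopic else RESIDUE_MASS_AVG
    water = WATER_MONO if config.monoisotopic else 18.01528
    m = sum(table[aa] for aa in sequence) + water
    if config.carbamidomethyl_c:
        m += CARBAMIDOMETHYL * sequence.count("C")
    m += OXIDATION * n_oxidations
    return m


def peptide_masses(
    candidate: PeptideCandidate, config: PmfConfig = PmfConfig()
) -> list[PeptideCandidate]:
    """Expand a candidate into its variable-modification mass states.

    All methionines share one oxidation delta, so distinct masses depend
    only on the oxidized *count*; states enumerate 0..min(#M,
    max_variable_mods) oxidations rather than 2^#M subsets.
    """
    if not config.oxidation_m:
        return [candidate]
    n_m = candidate.sequence.count("M")
    k_max = min(n_m, config.max_variable_mods)
    return [
        PeptideCandidate(
            sequence=candidate.sequence,
            missed_cleavages=candidate.missed_cleavages,
            n_oxidations=k,
            mono_mass=peptide_mass(candidate.sequence, k, config),
        )
        for k in range(k_max + 1)
    ]


def match_peaks(
    peaks,
    candidates: list[PeptideCandidate],
    config: PmfConfig = PmfConfig(),
    exclusion_masses=None,
) -> list[tuple[float, PeptideCandidate, float]]:
    """Match observed masses against candidate peptides within the ppm window.

    Each peak matches at most one candidate: the one with the smallest ppm
    error; equidistant ties go to the lower-mass candidate.  Peaks within
    the tolerance of any exclusion mass (trypsin autolysis, matrix peaks)
    are skipped.  Returns (observed, candidate, ppm_error) triples.
    """
    if not candidates:
        return []
    peaks = np.sort(np.asarray(peaks, dtype=float))
    if config.peaks_are_mh:
        peaks = peaks - PROTON
    excl = np.sort(np.asarray(exclusion_masses, dtype=float)) if exclusion_masses is not None else None
    cands = sorted(candidates, key=lambda c: c.mono_mass)
    masses = np.array([c.mono_mass for c in cands])
    out = []
    for p in peaks:
        if excl is not None and len(excl):
            j = np.searchsorted(excl, p)
            near = [excl[k] for k in (j - 1, j) if 0 <= k < len(excl)]
            if any(abs(p - e) / e * 1e6 <= config.tolerance_ppm for e in near):
                continue
        j = int(np.searchsorted(masses, p))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(masses):
                ppm = abs(p - masses[k]) / masses[k] * 1e6
                if ppm <= config.tolerance_ppm:
                    # ties (equal ppm) resolve to the lower mass = lower k
                    if best is None or ppm < best[0] - 1e-12:
                        best = (ppm, k)
        if best is not None:
            out.append((float(p), cands[best[1]], best[0]))
    return out


def random_match_probability(
    candidate_masses, peak_lo: float, peak_hi: float, tolerance_ppm: float
) -> float:
    """Probability q that a uniform random peak in [lo, hi] matches a candidate.

    Computed as the measure of the union of +-tolerance windows around the
    candidate masses, clipped to the observed span and divided by its
    length.  Degenerate spans (single peak) use a 1 Da floor.
    """
    span = max(peak_hi - peak_lo, 1.0)
    masses = np.sort(np.asarray(candidate_masses, dtype=float))
    total = 0.0
    cur_lo = cur_hi = None
    for m in masses:
        w = m * tolerance_ppm * 1e-6
        lo, hi = max(m - w, peak_lo), min(m + w, peak_hi)
        if hi <= lo:
            continue
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return min(total / span, 1.0)


def mowse_score(qm: int, n_peaks: int, q: float) -> float:
    """-10*log10 of the binomial random-match probability P(X >= qm).

    qm = 0 scores 0 by convention (no evidence); q = 0 with matches scores
    the cap.
    """
    if qm < 0 or qm > n_peaks:
        raise ValueError("need 0 <= qm <= n_peaks")
    if qm == 0:
        return 0.0
    if q <= 0:
        return SCORE_CAP
    p_tail = float(stats.binom.sf(qm - 1, n_peaks, q))
    if p_tail <= 0:
        return SCORE_CAP
    return min(-10.0 * math.log10(p_tail), SCORE_CAP)


def significance_threshold(alpha: float, n_sequences: int) -> int:
    """Integer score bound: significant iff score > floor(-10*log10(alpha/N))."""
    if not (0 < alpha <= 1):
        raise ConfigurationError("alpha must be in (0, 1]")
    if n_sequences < 1:
        raise ConfigurationError("n_sequences must be >= 1")
    return math.floor(-10.0 * math.log10(alpha / n_sequences))


def digest_database(
    database: dict[str, str], config: PmfConfig = PmfConfig()
) -> dict[str, list[PeptideCandidate]]:
    """Digest and variable-mod expand every protein; reusable across searches."""
    return {
        acc: [v for c in digest(seq, config) for v in peptide_masses(c, config)]
        for acc, seq in database.items()
    }


def search(
    peaks,
    database: dict[str, str],
    config: PmfConfig = PmfConfig(),
    exclusion_masses=None,
    digests: dict[str, list[PeptideCandidate]] | None = None,
) -> list[PmfMatchResult]:
    """Search a peak list against a protein database.

    Every database protein is digested, variable-mod expanded, matched and
    scored; results are sorted by score descending with ties broken by qm
    then accession.  ``qm`` counts distinct observed peaks matched (modified
    and missed-cleavage variants of one peptide are not counted separately).
    Pass ``digests`` (from :func:`digest_database`) to amortize digestion
    over many peak lists.
    """
    if not database:
        raise ConfigurationError("empty database")
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ConfigurationError("empty peak list")
    neutral = peaks - PROTON if config.peaks_are_mh else peaks
    lo, hi = float(neutral.min()), float(neutral.max())
    threshold = significance_threshold(config.alpha, len(database))
    n_peaks = int(peaks.size)
    if digests is None:
        digests = digest_database(database, config)

    results = []
    for acc in database:
        cands = digests[acc]
        pairs = match_peaks(peaks, cands, config, exclusion_masses)
        qm = len({p for p, _, _ in pairs})
        q = random_match_probability(
            [c.mono_mass for c in cands], lo, hi, config.tolerance_ppm
        )
        score = mowse_score(qm, n_peaks, q)
        results.append(
            PmfMatchResult(
                accession=acc, score=score, qm=qm, n_peaks=n_peaks,
                matched_pairs=pairs, significant=score > threshold,
            )
        )
    results.sort(key=lambda r: (-r.score, -r.qm, r.accession))
    return results


# ---------------------------------------------------------------------------
# I/O helpers

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein database as an ordered accession -> sequence mapping."""
    db = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        db[rec.id] = str(rec.seq)
    if not db:
        raise ConfigurationError(f"no sequences in {path}")
    return db


def write_fasta(database: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in database.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_peak_list(path: str | Path) -> np.ndarray:
    """Peak list: one m/z per line, blank lines and '#' comments ignored."""
    peaks = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                peaks.append(float(line))
            except ValueError:
                raise ConfigurationError(
                    f"{path}: line {lineno}: not a mass value: {line!r}"
                )
    return np.array(peaks, dtype=float)


def write_peak_list(peaks, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in np.asarray(peaks, dtype=float):
            fh.write(f"{p:.6f}\n")
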