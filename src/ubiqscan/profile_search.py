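"""Position-specific scoring profiles and calibrated proteome search.

The search model is a gapped PSSM: per-column log2-odds scores against a
background residue distribution, searched with affine-gap Smith-Waterman
local alignment.  Score statistics are calibrated empirically on random
background sequences and summarised by a Gumbel (EVD) law fitted by the
method of moments, which turns a raw bit score into a per-target
independent E-value (i-evalue) against the searched database size.

Hits are retained when i-evalue < max_i_evalue AND profile coverage >
min_profile_coverage (both strict); when several profiles match one
sequence only the best hit (smallest i-evalue) is kept.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .io_formats import (
    ALPHABET,
    AMINO_ACIDS,
    GAP,
    SeedAlignment,
    SequenceRecord,
    ValidationError,
    make_alignment,
)

logger = logging.getLogger("ubiqscan")

EULER_GAMMA = 0.5772156649015329

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}  # X is index 20

#: floor for reported i-evalues; scores of true homologs routinely underflow exp()
MIN_I_EVALUE = 1e-300


class CalibrationError(RuntimeError):
    """Raised when decoy score statistics cannot be fitted."""


@dataclass(frozen=True)
class SearchThresholds:
    """Hit retention thresholds (curation: 1e-20/0.90; detection: 1e-20/0.80)."""

    max_i_evalue: float = 1e-20
    min_profile_coverage: float = 0.8

    def __post_init__(self) -> None:
        if not (math.isfinite(self.max_i_evalue) and self.max_i_evalue > 0):
            raise ValidationError("max_i_evalue must be finite and positive")
        if not (0.0 <= self.min_profile_coverage <= 1.0):
            raise ValidationError("min_profile_coverage outside [0, 1]")


@dataclass(frozen=True)
class ScoringProfile:
    """Per-column log2-odds scores (bits) for one protein family.

    ``log_odds`` has shape (n_columns, 21): the 20 standard residues in
    :data:`~ubiqscan.io_formats.AMINO_ACIDS` order plus a final column for
    the unknown residue X, which scores 0 everywhere.  ``mu``/``lam`` are
    the Gumbel location/scale set by :func:`calibrate_profile`.
    """

    family: str
    log_odds: np.ndarray  # (n_columns, 21) float64
    background: np.ndarray  # (20,) float64, sums to 1
    gap_open: float = 4.0
    gap_extend: float = 1.0
    mu: float | None = None
    lam: float | None = None

    @property
    def n_columns(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.lam is not None

    def consensus(self) -> str:
        """Highest-scoring standard residue per column."""
        return "".join(
            AMINO_ACIDS[int(np.argmax(self.log_odds[c, :20]))]
            for c in range(self.n_columns)
        )

    def consensus_score(self) -> float:
        """Sum of per-column maxima: the score of an exact consensus match."""
        return float(self.log_odds[:, :20].max(axis=1).sum())

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "log_odds": self.log_odds.tolist(),
            "background": self.background.tolist(),
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }
        if self.calibrated:
            d["mu"] = self.mu
            d["lam"] = self.lam
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringProfile":
        return cls(
            family=d["family"],
            log_odds=np.asarray(d["log_odds"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            gap_open=float(d.get("gap_open", 4.0)),
            gap_extend=float(d.get("gap_extend", 1.0)),
            mu=d.get("mu"),
            lam=d.get("lam"),
        )


def write_profiles(profiles: Iterable[ScoringProfile], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([p.to_dict() for p in profiles]), encoding="utf-8"
    )


def read_profiles(path: str | Path) -> list[ScoringProfile]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [ScoringProfile.from_dict(d) for d in doc]


@dataclass(frozen=True)
class ProfileHit:
    """One retained profile-to-protein local alignment."""

    protein_id: str
    family: str
    bit_score: float
    i_evalue: float
    profile_coverage: float
    target_start: int  # 0-based half-open span on the target
    target_end: int


# ---------------------------------------------------------------------------
# alignment trimming and profile construction
# ---------------------------------------------------------------------------

def gap_fractions(aln: SeedAlignment) -> np.ndarray:
    """Per-column fraction of gap characters."""
    frac = np.empty(aln.n_columns)
    for c in range(aln.n_columns):
        col = aln.column(c)
        frac[c] = col.count(GAP) / len(col)
    return frac


def trim_alignment_termini(
    aln: SeedAlignment, max_terminal_gap_fraction: float = 0.5
) -> SeedAlignment:
    """Drop gappy terminal columns, keeping the alignment core as is.

    Scanning inward from each end, leading/trailing columns whose gap
    fraction exceeds the threshold are removed; the scan stops at the first
    retained column, so internal gappy columns are never touched.
    """
    frac = gap_fractions(aln)
    lo = 0
    while lo < len(frac) and frac[lo] > max_terminal_gap_fraction:
        lo += 1
    hi = len(frac)
    while hi > lo and frac[hi - 1] > max_terminal_gap_fraction:
        hi -= 1
    if lo >= hi:
        raise ValidationError("empty core: all columns trimmed")
    if lo == 0 and hi == len(frac):
        return aln
    return make_alignment((name, s[lo:hi]) for name, s in aln.rows)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def alignment_background(aln: SeedAlignment, pseudocount: float = 1.0) -> np.ndarray:
    """Background distribution estimated from seed-alignment composition."""
    counts = np.full(20, pseudocount, dtype=float)
    for _name, s in aln.rows:
        for ch in s:
            i = _RESIDUE_INDEX.get(ch)
            if i is not None and i < 20:
                counts[i] += 1.0
    return counts / counts.sum()


def build_profile(
    aln: SeedAlignment,
    family: str,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> ScoringProfile:
    """Estimate a log-odds profile from a (trimmed) seed alignment.

    Per column c: f(a|c) = (count(a,c) + w*bg(a)) / (non-gap count(c) + w)
    and score(a,c) = log2(f(a|c)/bg(a)).  X residues are treated as missing
    data for estimation and score 0 in every column.
    """
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-9 or background.shape != (20,):
        raise ValidationError("background must be a 20-residue distribution")
    if pseudocount_weight < 0:
        raise ValidationError("pseudocount_weight must be >= 0")

    n_cols = aln.n_columns
    scores = np.zeros((n_cols, 21))
    for c in range(n_cols):
        col = aln.column(c)
        counts = np.zeros(20)
        n_obs = 0
        for ch in col:
            if ch == GAP or ch == "X":
                continue
            counts[_RESIDUE_INDEX[ch]] += 1.0
            n_obs += 1
        denom = n_obs + pseudocount_weight
        if denom == 0:
            raise ValidationError(
                f"column {c}: no observed residues and zero pseudocount"
            )
        freqs = (counts + pseudocount_weight * background) / denom
        with np.errstate(divide="ignore"):
            scores[c, :20] = np.log2(freqs / background)
        # X scores 0 (scores[c, 20] already 0)
    return ScoringProfile(
        family=family,
        log_odds=scores,
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# affine-gap Smith-Waterman kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_kernel(scores, target, gap_open, gap_extend):  # pragma: no cover - numba
    """Local profile-to-sequence alignment with affine gaps.

    Returns (best score, profile start, profile end, target start,
    target end) with half-open 0-based spans.
    """
    L = scores.shape[0]
    n = target.shape[0]
    NEG = -1.0e30
    H = np.zeros((L + 1, n + 1))
    E = np.full((L + 1, n + 1), NEG)  # gap in profile (consumes target)
    F = np.full((L + 1, n + 1), NEG)  # gap in target (consumes profile column)
    # traceback codes for H: 0 stop, 1 diag, 2 from E, 3 from F
    tb = np.zeros((L + 1, n + 1), dtype=np.int8)
    te = np.zeros((L + 1, n + 1), dtype=np.int8)  # 1 = opened from H
    tf = np.zeros((L + 1, n + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                te[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                tf[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + scores[i - 1, target[j - 1]]
            h = 0.0
            code = 0
            if diag > h:
                h = diag
                code = 1
            if E[i, j] > h:
                h = E[i, j]
                code = 2
            if F[i, j] > h:
                h = F[i, j]
                code = 3
            H[i, j] = h
            tb[i, j] = code
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback to the start of the optimal local path
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            code = tb[i, j]
            if code == 0:
                break
            if code == 1:
                i -= 1
                j -= 1
            elif code == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = te[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            opened = tf[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, i, bi, j, bj


def encode_sequence(residues: str) -> np.ndarray:
    return np.array([_RESIDUE_INDEX[ch] for ch in residues], dtype=np.int64)


def align_profile(profile: ScoringProfile, residues: str) -> tuple[float, float, int, int]:
    """Optimal local alignment of a profile against one sequence.

    Returns (bit score, profile coverage, target start, target end).
    Coverage is the fraction of profile columns spanned by the optimal
    alignment: (profile end - profile start) / n_columns.
    """
    target = encode_sequence(residues)
    score, p0, p1, t0, t1 = _sw_kernel(
        profile.log_odds, target, profile.gap_open, profile.gap_extend
    )
    coverage = (p1 - p0) / profile.n_columns if p1 > p0 else 0.0
    return float(score), float(coverage), int(t0), int(t1)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def fit_gumbel_moments(scores: Sequence[float]) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sd*sqrt(6)), mu = mean - gamma/lambda."""
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        raise CalibrationError("zero variance in decoy scores")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(arr.mean()) - EULER_GAMMA / lam
    return mu, lam


def sample_background_sequences(
    background: np.ndarray, n: int, length: int, rng: np.random.Generator
) -> list[str]:
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    draws = rng.choice(aas, size=(n, length), p=background)
    return [bytes(row).decode() for row in draws]


def calibrate_profile(
    profile: ScoringProfile,
    n_decoys: int = 1000,
    decoy_length: int = 250,
    seed: int = 0,
) -> ScoringProfile:
    """Fit the Gumbel score law on i.i.d. background decoy sequences.

    Deterministic given ``seed``.  Requires n_decoys >= 100 for a stable
    moment fit.
    """
    if n_decoys < 100:
        raise ValidationError("n_decoys must be >= 100")
    rng = np.random.default_rng(seed)
    decoys = sample_background_sequences(profile.background, n_decoys, decoy_length, rng)
    scores = [align_profile(profile, d)[0] for d in decoys]
    mu, lam = fit_gumbel_moments(scores)
    logger.debug("calibrated %s: mu=%.3f lambda=%.4f", profile.family, mu, lam)
    return replace(profile, mu=mu, lam=lam)


def i_evalue(profile: ScoringProfile, bit_score: float, n_targets: int) -> float:
    """Per-target independent E-value against a database of n_targets sequences."""
    if not profile.calibrated:
        raise ValidationError(f"profile {profile.family!r} is not calibrated")
    arg = -profile.lam * (bit_score - profile.mu)
    ev = n_targets * math.exp(max(arg, -700.0))
    return max(ev, MIN_I_EVALUE)


# ---------------------------------------------------------------------------
# search and best-hit resolution
# ---------------------------------------------------------------------------

def search_proteome(
    profiles: Sequence[ScoringProfile],
    proteome: Sequence[SequenceRecord],
    thresholds: SearchThresholds = SearchThresholds(),
) -> list[ProfileHit]:
    """Score every (profile, protein) pair and keep threshold-passing hits.

    Retention is strict: i-evalue < max_i_evalue and coverage >
    min_profile_coverage.  Output is sorted by (protein_id, i-evalue).
    """
    for p in profiles:
        if not p.calibrated:
            raise ValidationError(f"profile {p.family!r} is not calibrated")
    n_targets = len(proteome)
    hits: list[ProfileHit] = []
    for record in proteome:
        for profile in profiles:
            score, coverage, t0, t1 = align_profile(profile, record.residues)
            ev = i_evalue(profile, score, n_targets)
            if ev < thresholds.max_i_evalue and coverage > thresholds.min_profile_coverage:
                hits.append(
                    ProfileHit(
                        protein_id=record.id,
                        family=profile.family,
                        bit_score=score,
                        i_evalue=ev,
                        profile_coverage=coverage,
                        target_start=t0,
                        target_end=t1,
                    )
                )
    hits.sort(key=lambda h: (h.protein_id, h.i_evalue, -h.bit_score, h.family))
    return hits


def _span_overlap_ok(span: tuple[int, int], accepted: list[tuple[int, int]]) -> bool:
    s0, s1 = span
    for a0, a1 in accepted:
        inter = min(s1, a1) - max(s0, a0)
        if inter <= 0:
            continue
        shorter = min(s1 - s0, a1 - a0)
        if shorter > 0 and inter / shorter > 0.20:
            return False
    return True


def assign_best_hits(
    hits: Sequence[ProfileHit],
    allow_nonoverlapping_multi: bool = False,
):
    """Resolve competing family claims per protein.

    By default each protein maps to the family of its minimum-i-evalue hit
    (ties: higher bit score, then lexicographic family name) and the result
    is a mapping protein_id -> family.  With
    ``allow_nonoverlapping_multi=True`` the result maps protein_id -> list
    of families, keeping one family per non-overlapping target span (an
    overlap exceeding 20% of the shorter span disqualifies); this captures
    multi-domain fusion proteins.
    """
    by_protein: dict[str, list[ProfileHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    if not allow_nonoverlapping_multi:
        out: dict[str, str] = {}
        for pid, hs in by_protein.items():
            best = min(hs, key=lambda h: (h.i_evalue, -h.bit_score, h.family))
            out[pid] = best.family
        return out
    multi: dict[str, list[str]] = {}
    for pid, hs in by_protein.items():
        hs_sorted = sorted(hs, key=lambda h: (h.i_evalue, -h.bit_score, h.family))
        accepted_spans: list[tuple[int, int]] = []
        families: list[str] = []
        for h in hs_sorted:
            if h.family in families:
                continue
            span = (h.target_start, h.target_end)
            if _span_overlap_ok(span, accepted_spans):
                accepted_spans.append(span)
                families.append(h.family)
        multi[pid] = families
    return multi
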