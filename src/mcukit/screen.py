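"""Domain detection and family classification with lightweight profiles.

Homologs of short, divergent proteins are found with position-specific
log-odds profiles (PSSMs) scanned as ungapped sliding windows.  A profile's
acceptance threshold plays the role of a family "gathering" cutoff and is
calibrated empirically: the (1 - FPR) quantile of max-window scores over
random background sequences.  The iterative search rebuilds the profile
from the hits found so far and rescans, which is how very divergent family
members (e.g. short single-pass regulators) become detectable in a second
iteration.  Family assignment is rule-based on domain composition:

    MCU             >= 1 hit of the MCU-domain profile
    ARALAR_EXCLUDED similarity candidate for MICU carrying a Mito_carr hit
                    (mitochondrial carrier family; excluded from MICU)
    MICU            remaining MICU similarity candidates
    EMRE            >= 1 hit of the DDDD (polyaspartate) profile
    NCLX            >= 1 NCLX-domain hit, restricted to the NCLX candidate
                    set (the domain alone tags a whole exchanger superfamily)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import AMINO_ACIDS, GAP_CHARS, N_AA, encode, uniform_background

FAMILY_ROLES = ("MCU-domain", "Mito_carr", "DDDD", "NCLX-domain")


@dataclass(frozen=True)
class Alignment:
    """Rectangular protein alignment (gap characters '-' or '.')."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.rows:
            raise ValueError("alignment must have one id per non-empty row set")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("ragged alignment: rows differ in length")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    @classmethod
    def from_pairs(cls, pairs) -> "Alignment":
        ids, rows = zip(*pairs)
        return cls(tuple(ids), tuple(rows))


@dataclass
class ProfileModel:
    """Ungapped position-specific log-odds profile (bits vs background)."""

    log_odds: np.ndarray  # (length, 20) bits
    background: np.ndarray
    pseudocount_weight: float
    accept_threshold: float | None = None
    profile_id: str = "profile"
    family_role: str | None = None

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != N_AA:
            raise ValueError("log_odds must be (length, 20)")
        if self.log_odds.shape[0] < 1:
            raise ValueError("profile length must be >= 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds scores must be finite")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be strictly positive")
        # extra zero column so that unknown residues (index -1) score 0 bits
        self._padded = np.hstack([self.log_odds, np.zeros((len(self.log_odds), 1))])

    @property
    def length(self) -> int:
        return int(self.log_odds.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    seq_id: str
    start: int
    end: int
    score: float
    profile_id: str
    iteration: int | None = None


@dataclass(frozen=True)
class FamilyAssignment:
    seq_id: str
    family: str  # MCU | MICU | ARALAR_EXCLUDED | EMRE | NCLX | UNASSIGNED
    rule_trace: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScreenConfig:
    max_iterations: int = 2
    max_gap_fraction: float = 0.99  # trim columns with gap fraction strictly above
    fpr: float = 1e-3
    n_null: int = 10_000
    null_length: int = 200
    pseudocount_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must be in (0, 1]")
        if not 0.0 < self.fpr < 1.0:
            raise ValueError("fpr must be in (0, 1)")


def trim_alignment(aln: Alignment, max_gap_fraction: float = 0.99
                   ) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction is strictly greater than the cutoff.

    The boundary is inclusive: a column at exactly the cutoff is kept.
    Returns the trimmed alignment and the strictly increasing map from new
    to original column indices.  Idempotent.
    """
    kept = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        gap_fraction = sum(c in GAP_CHARS for c in col) / aln.n_seqs
        if not gap_fraction > max_gap_fraction:
            kept.append(j)
    rows = tuple("".join(r[j] for j in kept) for r in aln.rows)
    return Alignment(aln.ids, rows), kept


def build_profile(aln: Alignment, pseudocount_weight: float = 1.0,
                  background: np.ndarray | None = None,
                  profile_id: str = "profile",
                  family_role: str | None = None,
                  max_match_gap_fraction: float = 0.5) -> ProfileModel:
    """Profile from an alignment; match columns are those with <= 50% gaps.

    Per retained column c and residue a, with n_c non-gap residues observed,

        log_odds[c][a] = log2( (count_a + w * bg_a) / (n_c + w) / bg_a )

    where w is the background-proportional pseudocount weight.
    """
    if aln.n_seqs < 1 or aln.n_cols < 1:
        raise ValueError("empty alignment")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    bg = uniform_background() if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    columns = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        gap_fraction = sum(c in GAP_CHARS for c in col) / aln.n_seqs
        if gap_fraction > max_match_gap_fraction:
            continue
        idx = encode("".join(c for c in col if c not in GAP_CHARS))
        idx = idx[idx >= 0]
        counts = np.bincount(idx, minlength=N_AA).astype(float)
        n_c = counts.sum()
        with np.errstate(divide="raise"):
            if pseudocount_weight == 0 and np.any(counts == 0):
                # -inf would violate the finite-score invariant; floor at the
                # probability of an unobserved residue under one extra count
                probs = counts / max(n_c, 1.0)
                floor = (1.0 / (n_c + 1.0)) * bg
                probs = np.where(probs > 0, probs, floor)
            else:
                probs = (counts + pseudocount_weight * bg) / (n_c + pseudocount_weight)
        columns.append(np.log2(probs / bg))
    if not columns:
        raise ValueError("no match columns survive the gap rule")
    return ProfileModel(np.array(columns), bg, pseudocount_weight,
                        profile_id=profile_id, family_role=family_role)


def _window_scores(profile: ProfileModel, idx_matrix: np.ndarray) -> np.ndarray:
    """Scores of every window for each row of an index matrix (n, L)."""
    L = profile.length
    n, slen = idx_matrix.shape
    w = slen - L + 1
    if w <= 0:
        return np.empty((n, 0))
    scores = np.zeros((n, w))
    padded = profile._padded
    for c in range(L):
        scores += padded[c, idx_matrix[:, c:c + w]]
    return scores


def scan_sequence(profile: ProfileModel, seq: str,
                  threshold: float | None = None) -> list[DomainHit]:
    """All non-overlapping windows scoring >= the acceptance threshold.

    Windows are selected greedily best-score-first; ties broken by smaller
    start.  A sequence shorter than the profile yields no hits.
    """
    thr = profile.accept_threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("profile has no accept_threshold; calibrate first")
    if len(seq) < profile.length:
        return []
    scores = _window_scores(profile, encode(seq)[None, :])[0]
    candidates = sorted(
        ((s, start) for start, s in enumerate(scores) if s >= thr),
        key=lambda t: (-t[0], t[1]))
    hits: list[DomainHit] = []
    occupied: list[tuple[int, int]] = []
    for s, start in candidates:
        end = start + profile.length
        if any(start < e and b < end for b, e in occupied):
            continue
        occupied.append((start, end))
        hits.append(DomainHit("", start, end, float(s), profile.profile_id))
    return sorted(hits, key=lambda h: h.start)


def calibrate_threshold(profile: ProfileModel,
                        background: np.ndarray | None = None,
                        fpr: float = 1e-3, n_null: int = 10_000,
                        null_length: int = 200, seed: int = 0,
                        chunk: int = 5_000) -> float:
    """Empirical-null acceptance threshold in bits.

    Threshold = the (1 - fpr) quantile (upper order statistic) of the
    max-window score over ``n_null`` random background sequences of
    ``null_length`` residues.  ``fpr`` is therefore a per-sequence
    false-positive rate.  Deterministic given the seed.
    """
    if not 0.0 < fpr <= 1.0:
        raise ValueError("fpr must be in (0, 1]")
    if n_null * fpr < 10:
        warnings.warn("n_null * fpr < 10: the null quantile is unstable")
    bg = profile.background if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    length = max(null_length, profile.length)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_null)
    done = 0
    while done < n_null:
        m = min(chunk, n_null - done)
        idx = rng.choice(N_AA, size=(m, length), p=bg)
        maxima[done:done + m] = _window_scores(profile, idx).max(axis=1)
        done += m
    if fpr == 1.0:
        return float(maxima.min())
    return float(np.quantile(maxima, 1.0 - fpr, method="higher"))


def scan_proteome(profile: ProfileModel, sequences: dict[str, str],
                  threshold: float | None = None) -> list[DomainHit]:
    """Scan every sequence; hits carry their sequence id, sorted by id/start."""
    hits = []
    for seq_id in sorted(sequences):
        for h in scan_sequence(profile, sequences[seq_id], threshold):
            hits.append(replace(h, seq_id=seq_id))
    return hits


def iterative_search(seed_alignment: Alignment, sequences: dict[str, str],
                     cfg: ScreenConfig = ScreenConfig(),
                     background: np.ndarray | None = None,
                     profile_id: str = "profile",
                     family_role: str | None = None
                     ) -> tuple[list[DomainHit], list[ProfileModel]]:
    """Profile search with iterative profile rebuilding.

    Iteration 1 scans with the profile built from the (gap-trimmed) seed
    alignment.  Each later iteration stacks the ungapped windows of every
    hit found so far into a new alignment, rebuilds and recalibrates the
    profile, and rescans; newly discovered hits are tagged with the
    iteration that first found them, and the accumulated hit set only ever
    grows.  Stops early when an iteration adds nothing.
    """
    trimmed, _ = trim_alignment(seed_alignment, cfg.max_gap_fraction)
    profile = build_profile(trimmed, cfg.pseudocount_weight, background,
                            profile_id=profile_id, family_role=family_role)
    profiles = []
    accumulated: dict[tuple[str, int], DomainHit] = {}
    for iteration in range(1, cfg.max_iterations + 1):
        profile.accept_threshold = calibrate_threshold(
            profile, fpr=cfg.fpr, n_null=cfg.n_null,
            null_length=cfg.null_length, seed=cfg.seed + iteration - 1)
        profiles.append(profile)
        new = 0
        for hit in scan_proteome(profile, sequences):
            key = (hit.seq_id, hit.start)
            if key not in accumulated:
                accumulated[key] = replace(hit, iteration=iteration)
                new += 1
        if new == 0 or iteration == cfg.max_iterations:
            break
        windows = [(f"{sid}@{start}", sequences[sid][h.start:h.end])
                   for (sid, start), h in sorted(accumulated.items())]
        profile = build_profile(Alignment.from_pairs(windows),
                                cfg.pseudocount_weight, background,
                                profile_id=profile_id, family_role=family_role)
    return sorted(accumulated.values(),
                  key=lambda h: (h.seq_id, h.start)), profiles


def classify_family(hits_by_profile: dict[str, list[DomainHit]],
                    roles: dict[str, str],
                    similarity_candidates: dict[str, set[str]] | None = None,
                    all_sequences=None) -> dict[str, FamilyAssignment]:
    """Rule-based family assignment from domain composition.

    ``hits_by_profile`` maps profile id -> hits; ``roles`` maps profile id to
    its family role (one of MCU-domain, Mito_carr, DDDD, NCLX-domain);
    ``similarity_candidates`` holds the similarity-search candidate sets for
    MICU and NCLX.  A sequence claimed by several domain rules is assigned
    to the highest-scoring claim and flagged AMBIGUOUS in its rule trace.
    """
    candidates = similarity_candidates or {}
    micu_cand = set(candidates.get("MICU", set()))
    nclx_cand = set(candidates.get("NCLX", set()))
    best_role_score: dict[str, dict[str, float]] = {}
    for pid, hits in hits_by_profile.items():
        role = roles.get(pid)
        if role not in FAMILY_ROLES:
            raise ValueError(f"profile {pid!r} lacks a known family role")
        for h in hits:
            d = best_role_score.setdefault(h.seq_id, {})
            d[role] = max(d.get(role, -math.inf), h.score)
    seq_ids = set(best_role_score) | micu_cand | nclx_cand
    if all_sequences is not None:
        seq_ids |= set(all_sequences)
    out: dict[str, FamilyAssignment] = {}
    for sid in sorted(seq_ids):
        roles_hit = best_role_score.get(sid, {})
        claims: list[tuple[float, str, str]] = []  # (score, family, trace)
        if "MCU-domain" in roles_hit:
            claims.append((roles_hit["MCU-domain"], "MCU", "MCU-domain hit"))
        if "DDDD" in roles_hit:
            claims.append((roles_hit["DDDD"], "EMRE", "DDDD hit"))
        if "NCLX-domain" in roles_hit and sid in nclx_cand:
            claims.append((roles_hit["NCLX-domain"], "NCLX",
                           "NCLX-domain hit + similarity candidate"))
        if sid in micu_cand:
            if "Mito_carr" in roles_hit:
                claims.append((roles_hit["Mito_carr"], "ARALAR_EXCLUDED",
                               "MICU candidate with Mito_carr hit"))
            else:
                claims.append((-math.inf, "MICU",
                               "MICU similarity candidate, no Mito_carr hit"))
        if not claims:
            out[sid] = FamilyAssignment(sid, "UNASSIGNED")
            continue
        claims.sort(key=lambda c: (-c[0], c[1]))
        trace = [claims[0][2]]
        if len(claims) > 1:
            losers = ",".join(c[1] for c in claims[1:])
            trace.append(f"AMBIGUOUS: also matched {losers}; kept highest score")
        out[sid] = FamilyAssignment(sid, claims[0][1], tuple(trace))
    return out
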