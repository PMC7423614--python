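"""Clade-contrast residue scanning on a two-group alignment.

Scores each alignment column for subfamily-specific conservation: positions
that are conserved within one group (e.g. the animal-like MCU clade) but
divergent in the other (e.g. the fungal-specific MCUP clade).  Group
residue distributions (20 amino acids + gap as a 21st symbol, with a small
pseudocount) are compared by base-2 Jensen--Shannon divergence, which is 0
for identical distributions and 1 for disjoint support; within-group
conservation is the raw max residue frequency.  A column is flagged when
divergence and group-A conservation both clear their thresholds, and the
flagged columns are ranked by divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy

from .alphabet import AMINO_ACIDS, GAP_CHARS
from .screen import Alignment

SYMBOLS = AMINO_ACIDS + "-"  # gaps are signal (group-specific deletions)
_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}


@dataclass(frozen=True)
class ColumnScore:
    column: int
    divergence: float
    conservation_a: float
    conservation_b: float
    flagged: bool


def _distribution(residues: str, pseudocount: float) -> np.ndarray:
    # pseudocount is a *total* prior mass spread uniformly over the 21
    # symbols, so small groups can still produce concentrated distributions
    counts = np.full(len(SYMBOLS), pseudocount / len(SYMBOLS), dtype=float)
    for c in residues:
        c = "-" if c in GAP_CHARS else c.upper()
        counts[_SYM_INDEX[c]] += 1.0
    return counts / counts.sum()


def _max_frequency(residues: str) -> float:
    canon = ["-" if c in GAP_CHARS else c.upper() for c in residues]
    return max(canon.count(s) for s in set(canon)) / len(canon)


def column_divergence(residues_a: str, residues_b: str,
                      pseudocount: float = 0.5, column: int = 0,
                      thresholds: tuple[float, float] = (0.5, 0.7)
                      ) -> ColumnScore:
    """Jensen--Shannon divergence (base 2) between the group distributions.

    JSD(P, Q) = H((P+Q)/2) - (H(P) + H(Q))/2 in bits; symmetric in the
    groups and invariant to relabeling the alphabet.
    """
    if not residues_a or not residues_b:
        raise ValueError("both groups must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = _distribution(residues_a, pseudocount)
    q = _distribution(residues_b, pseudocount)
    m = 0.5 * (p + q)
    jsd = float(entropy(m, base=2) - 0.5 * (entropy(p, base=2) + entropy(q, base=2)))
    jsd = min(max(jsd, 0.0), 1.0)  # guard tiny numeric excursions
    cons_a = _max_frequency(residues_a)
    cons_b = _max_frequency(residues_b)
    theta_d, theta_c = thresholds
    flagged = jsd >= theta_d and cons_a >= theta_c
    return ColumnScore(column, jsd, cons_a, cons_b, flagged)


def score_columns(alignment: Alignment, grouping: dict[str, str],
                  pseudocount: float = 0.5,
                  thresholds: tuple[float, float] = (0.5, 0.7)
                  ) -> list[ColumnScore]:
    """ColumnScore for every column, in column order."""
    missing = [i for i in alignment.ids if i not in grouping]
    if missing:
        raise ValueError(f"sequences without a group label: {missing}")
    bad = sorted(set(grouping[i] for i in alignment.ids) - {"A", "B"})
    if bad:
        raise ValueError(f"group labels must be 'A' or 'B', got {bad}")
    rows_a = [r for i, r in zip(alignment.ids, alignment.rows) if grouping[i] == "A"]
    rows_b = [r for i, r in zip(alignment.ids, alignment.rows) if grouping[i] == "B"]
    if not rows_a or not rows_b:
        raise ValueError("both groups must be non-empty")
    return [column_divergence("".join(r[j] for r in rows_a),
                              "".join(r[j] for r in rows_b),
                              pseudocount, j, thresholds)
            for j in range(alignment.n_cols)]


def scan_specificity(alignment: Alignment, grouping: dict[str, str],
                     thresholds: tuple[float, float] = (0.5, 0.7),
                     pseudocount: float = 0.5,
                     top_k: int | None = None) -> list[ColumnScore]:
    """Flagged columns ranked by divergence (desc), ties by lower index."""
    scores = score_columns(alignment, grouping, pseudocount, thresholds)
    flagged = sorted((s for s in scores if s.flagged),
                     key=lambda s: (-s.divergence, s.column))
    return flagged if top_k is None else flagged[:top_k]


def render_strip(alignment: Alignment, scores: list[ColumnScore],
                 width: int = 60) -> str:
    """Plain-text rendering with a marker line under flagged columns."""
    flagged = {s.column for s in scores if s.flagged}
    marks = "".join("^" if j in flagged else " " for j in range(alignment.n_cols))
    name_w = max(len(i) for i in alignment.ids) + 2
    blocks = []
    for start in range(0, alignment.n_cols, width):
        lines = [f"{i:<{name_w}}{r[start:start + width]}"
                 for i, r in zip(alignment.ids, alignment.rows)]
        lines.append(f"{'':<{name_w}}{marks[start:start + width]}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)
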