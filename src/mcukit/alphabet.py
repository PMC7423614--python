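"""Amino-acid alphabet shared across the scanner and the simulator."""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_AA = len(AMINO_ACIDS)
GAP_CHARS = frozenset("-.")

# byte -> alphabet index; unknown residues map to -1 (scored as 0 bits
# via a padded zero column in the PSSM)
_LOOKUP = np.full(256, -1, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _LOOKUP[ord(_a)] = _i
    _LOOKUP[ord(_a.lower())] = _i


def uniform_background() -> np.ndarray:
    """Uniform residue background (1/20 each)."""
    return np.full(N_AA, 1.0 / N_AA)


def encode(seq: str) -> np.ndarray:
    """Map a protein string to alphabet indices (-1 for unknown symbols)."""
    return _LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_protein(length: int, rng: np.random.Generator,
                   background: np.ndarray | None = None) -> str:
    bg = uniform_background() if background is None else np.asarray(background)
    idx = rng.choice(N_AA, size=length, p=bg / bg.sum())
    return "".join(AMINO_ACIDS[i] for i in idx)


def mutate(seq: str, divergence: float, rng: np.random.Generator,
           background: np.ndarray | None = None) -> str:
    """Substitute each position independently with probability `divergence`.

    Substitutions go to a *different* residue, drawn uniformly by default or
    from ``background`` (to emulate compositionally biased, low-complexity
    families); no indels.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    out = list(seq)
    hits = rng.random(len(seq)) < divergence
    for i in np.nonzero(hits)[0]:
        if background is None:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
        else:
            while True:
                cand = AMINO_ACIDS[rng.choice(N_AA, p=background)]
                if cand != out[i]:
                    break
            out[i] = cand
    return "".join(out)


def biased_background(favored: str = "ADEGST", mass: float = 0.9) -> np.ndarray:
    """Background concentrated on a reduced alphabet (low-complexity regime)."""
    bg = np.full(N_AA, (1.0 - mass) / (N_AA - len(favored)))
    for a in favored:
        bg[AMINO_ACIDS.index(a)] = mass / len(favored)
    return bg / bg.sum()
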