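"""Species-level presence/absence profiling and co-occurrence statistics.

Phylogenetic profiles — binary presence/absence vectors of gene families
across species — are the signal behind the co-evolution argument: families
that are jointly present and jointly absent across a taxonomy are
candidates for functional interdependence (e.g. the pore subunit and its
gatekeeper).  Strain-level rows are collapsed to species by OR (presence
anywhere counts; absence calls are fragile to assembly and annotation
gaps), co-occurrence is summarized by a 2x2 tally plus Jaccard, and
significance is assessed by a row-shuffling permutation test on the match
count (both-present + both-absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TaxonomyMap:
    """strain -> species plus species -> ordered lineage of named ranks."""

    strain_to_species: dict[str, str]
    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for sp, lineage in self.lineages.items():
            if not lineage:
                raise ValueError(f"species {sp!r} has an empty lineage")

    def species_of(self, strain: str) -> str:
        return self.strain_to_species[strain]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "TaxonomyMap":
        """Build from a table with columns strain, species, lineage
        (lineage as a semicolon-joined path, e.g. 'Eukaryota;Opisthokonta;...')."""
        strain_to_species = dict(zip(df["strain"], df["species"]))
        lineages = {row.species: tuple(str(row.lineage).split(";"))
                    for row in df.itertuples()}
        return cls(strain_to_species, lineages)


@dataclass(frozen=True)
class CooccurrenceResult:
    n_both: int
    n_only_a: int
    n_only_b: int
    n_neither: int
    jaccard: float
    p_value: float | None = None

    @property
    def n_species(self) -> int:
        return self.n_both + self.n_only_a + self.n_only_b + self.n_neither


def collapse_to_species(strain_matrix: pd.DataFrame, taxonomy: TaxonomyMap
                        ) -> pd.DataFrame:
    """Collapse strain rows to one row per species (OR policy).

    Idempotent on species-level input (species map to themselves).  Raises
    with the full offender list if any strain is unmapped.
    """
    unmapped = [s for s in strain_matrix.index
                if s not in taxonomy.strain_to_species]
    if unmapped:
        raise ValueError(f"unmapped strains: {unmapped}")
    _check_binary(strain_matrix)
    species = [taxonomy.species_of(s) for s in strain_matrix.index]
    collapsed = (strain_matrix.groupby(pd.Index(species, name="species"))
                 .max().astype(int))
    return collapsed.sort_index()


def _check_binary(matrix: pd.DataFrame) -> None:
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix must be binary (0/1)")


def cooccurrence(matrix: pd.DataFrame, fam_a: str, fam_b: str
                 ) -> CooccurrenceResult:
    """2x2 presence tally over species plus the Jaccard index."""
    for fam in (fam_a, fam_b):
        if fam not in matrix.columns:
            raise ValueError(f"family {fam!r} not in the matrix")
    _check_binary(matrix[[fam_a, fam_b]])
    a = matrix[fam_a].to_numpy().astype(bool)
    b = matrix[fam_b].to_numpy().astype(bool)
    n_both = int((a & b).sum())
    n_only_a = int((a & ~b).sum())
    n_only_b = int((~a & b).sum())
    n_neither = int((~a & ~b).sum())
    denom = n_both + n_only_a + n_only_b
    jaccard = n_both / denom if denom else 0.0
    return CooccurrenceResult(n_both, n_only_a, n_only_b, n_neither, jaccard)


def coevolution_test(matrix: pd.DataFrame, fam_a: str, fam_b: str,
                     n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for profile co-evolution.

    Statistic: match count (both-present + both-absent).  Null: the fam_b
    column independently shuffled across species rows.  p = (1 + #null >=
    observed) / (n_perm + 1); a constant column yields p = 1 with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    res = cooccurrence(matrix, fam_a, fam_b)
    a = matrix[fam_a].to_numpy().astype(np.int8)
    b = matrix[fam_b].to_numpy().astype(np.int8)
    if len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
        warnings.warn("constant presence column: co-evolution test is degenerate")
        return 1.0
    observed = res.n_both + res.n_neither
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(b) for _ in range(n_perm)])
    null = (perms == a[None, :]).sum(axis=1)
    return float((1 + int((null >= observed).sum())) / (n_perm + 1))


@dataclass(frozen=True)
class ProfileReport:
    table: pd.DataFrame
    complete_losses: dict[str, list[str]] = field(default_factory=dict)


def profile_report(matrix: pd.DataFrame, taxonomy: TaxonomyMap,
                   family_order=None) -> ProfileReport:
    """Taxonomy-ordered profile plus per-family complete-loss clades.

    Species rows are sorted in taxonomy pre-order (lexicographic on the
    lineage path).  For each family, the maximal named clades in which
    every species lacks the family are reported (subclades of a reported
    clade are suppressed).
    """
    families = list(family_order or matrix.columns)
    missing = [sp for sp in matrix.index if sp not in taxonomy.lineages]
    if missing:
        raise ValueError(f"species without lineage: {missing}")
    order = sorted(matrix.index,
                   key=lambda sp: taxonomy.lineages[sp] + (sp,))
    table = matrix.loc[order, families]
    clade_members: dict[tuple[str, ...], set[str]] = {}
    for sp in matrix.index:
        lineage = taxonomy.lineages[sp]
        for depth in range(1, len(lineage) + 1):
            clade_members.setdefault(lineage[:depth], set()).add(sp)
    losses: dict[str, list[str]] = {}
    for fam in families:
        absent = set(matrix.index[matrix[fam] == 0])
        lost = [path for path, members in clade_members.items()
                if members <= absent]
        maximal = [path for path in lost
                   if not any(other != path and path[:len(other)] == other
                              for other in lost)]
        losses[fam] = sorted(";".join(path) for path in maximal)
    return ProfileReport(table, losses)
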