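"""Source-protein-mapping-based redundancy reduction of peptide sets.

Epitope databases oversample well-studied peptides and their single-residue
mutants. To remove that bias, every peptide is mapped by ungapped sliding
window onto every source protein (a mapping succeeds when more than 75% of
residues match — for a 9mer, at least 7), and two peptides are redundant
when, on some shared protein, their matched residues cover the same protein
positions in more than half of the shorter peptide's residues. Unmappable
peptides are discarded; within each redundancy cluster the record with the
highest database entry count is kept, with seeded random tie-breaking.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import PeptideSet, SourceProtein

MIN_IDENTITY = 0.75  # strict: "more than 75% of the residues"


@dataclass(frozen=True)
class MappingResult:
    """An ungapped placement of a peptide on a source protein."""

    peptide: str
    protein_id: str
    start: int  # 0-based, half-open window [start, start + len(peptide))
    match_flags: tuple[bool, ...]
    identity: float

    def matched_positions(self) -> frozenset[int]:
        """Protein positions covered by *matching* residues only."""
        return frozenset(
            self.start + i for i, m in enumerate(self.match_flags) if m
        )


def map_peptide(
    peptide: str, proteins: Sequence[SourceProtein]
) -> list[MappingResult]:
    """All ungapped windows with identity strictly above 75%.

    X and other wildcard characters in the protein never count as matches.
    """
    peptide = peptide.upper()
    n = len(peptide)
    results: list[MappingResult] = []
    for prot in proteins:
        seq = prot.sequence
        for start in range(len(seq) - n + 1):
            flags = tuple(
                seq[start + i] == peptide[i] and peptide[i] != "X"
                for i in range(n)
            )
            identity = sum(flags) / n
            if identity > MIN_IDENTITY:
                results.append(
                    MappingResult(peptide, prot.id, start, flags, identity)
                )
    return results


def are_redundant(
    p1: str,
    p2: str,
    mappings: Mapping[str, Sequence[MappingResult]],
) -> bool:
    """True if the two peptides' matched residues overlap on some protein
    in more than half of the shorter peptide's residues."""
    maps1 = [m for m in mappings.get(p1, ()) if m.peptide == p1]
    maps2 = [m for m in mappings.get(p2, ()) if m.peptide == p2]
    threshold = min(len(p1), len(p2)) / 2  # strict: "more than half"
    by_protein: dict[str, list[MappingResult]] = defaultdict(list)
    for m in maps2:
        by_protein[m.protein_id].append(m)
    for m1 in maps1:
        pos1 = m1.matched_positions()
        for m2 in by_protein.get(m1.protein_id, ()):
            if len(pos1 & m2.matched_positions()) > threshold:
                return True
    return False


def compute_mappings(
    peptides: PeptideSet, proteins: Sequence[SourceProtein]
) -> dict[str, list[MappingResult]]:
    """Mapping results per distinct peptide sequence."""
    return {
        seq: map_peptide(seq, proteins)
        for seq in {r.sequence for r in peptides}
    }


@dataclass(frozen=True)
class ReductionStats:
    """Bookkeeping of one non-redundancy selection."""

    n_input: int
    n_unmappable: int
    n_kept: int
    n_tie_broken_by_chance: int

    @property
    def chance_fraction(self) -> float:
        return self.n_tie_broken_by_chance / self.n_kept if self.n_kept else 0.0


def reduce_redundancy(
    peptides: PeptideSet,
    proteins: Sequence[SourceProtein],
    seed: int | None = None,
    mappings: Mapping[str, Sequence[MappingResult]] | None = None,
    return_stats: bool = False,
):
    """Select a non-redundant subset of a peptide set.

    Unmappable peptides are discarded. The redundancy graph is resolved
    greedily in descending entry-count order (ties shuffled with ``seed``):
    each kept peptide eliminates its remaining redundant neighbours. The
    output is idempotent — reducing twice equals reducing once — and
    contains no redundant pair. With ``return_stats`` the selection also
    reports how many keeps were decided by chance among equal priorities.
    """
    rng = np.random.default_rng(seed)
    if mappings is None:
        mappings = compute_mappings(peptides, proteins)
    records = list(peptides)
    mappable = [r for r in records if mappings.get(r.sequence)]
    n_unmappable = len(records) - len(mappable)

    # neighbour lists on the mappable records
    idx_of = {i: r for i, r in enumerate(mappable)}
    neighbours: dict[int, set[int]] = {i: set() for i in idx_of}
    for i in range(len(mappable)):
        for j in range(i + 1, len(mappable)):
            if are_redundant(mappable[i].sequence, mappable[j].sequence, mappings):
                neighbours[i].add(j)
                neighbours[j].add(i)

    tiebreak = rng.permutation(len(mappable))
    order = sorted(
        range(len(mappable)),
        key=lambda i: (-mappable[i].entry_count, tiebreak[i]),
    )
    alive = set(range(len(mappable)))
    kept: list[int] = []
    n_chance = 0
    for i in order:
        if i not in alive:
            continue
        rivals = [j for j in neighbours[i] if j in alive]
        if any(mappable[j].entry_count == mappable[i].entry_count for j in rivals):
            n_chance += 1
        kept.append(i)
        alive.discard(i)
        alive -= set(rivals)

    kept_records = tuple(mappable[i] for i in sorted(kept))
    out = PeptideSet(kept_records, peptides.required_length)
    if return_stats:
        stats = ReductionStats(
            n_input=len(records),
            n_unmappable=n_unmappable,
            n_kept=len(kept_records),
            n_tie_broken_by_chance=n_chance,
        )
        return out, stats
    return out
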