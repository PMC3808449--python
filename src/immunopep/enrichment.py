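"""Amino-acid composition statistics of immunogenic vs non-immunogenic peptides.

Counts residues at non-anchor positions only, computes per-amino-acid
log-enrichment scores E(a) = ln(f_imm(a) / f_non(a)), tests single-residue
associations with a background-based permutation test, adjusts for multiple
testing with q-values, analyses grouped physicochemical classes (large vs
small, aromatic vs non-aromatic, acidic vs basic, charged vs non-charged)
with Fisher's exact test, and correlates enrichments against user-supplied
amino-acid property scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alphabet import (
    ACIDIC,
    AMINO_ACIDS,
    AA_TO_INDEX,
    AROMATIC,
    BASIC,
    CHARGED,
    LARGE,
    N_AA,
    NON_AROMATIC,
    NON_CHARGED,
    PROTEIN_WILDCARDS,
    SMALL,
)
from .anchors import AnchorMask
from .errors import RecordError
from .io import PeptideSet, SourceProtein


@dataclass(frozen=True)
class AACounts:
    """Integer counts over the 20 amino acids."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != N_AA:
            raise RecordError(f"need {N_AA} counts, got {len(counts)}")
        if any(c < 0 for c in counts):
            raise RecordError("negative amino-acid count")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def __getitem__(self, aa: str) -> int:
        return self.counts[AA_TO_INDEX[aa]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "AACounts":
        return cls(tuple(int(d.get(aa, 0)) for aa in AMINO_ACIDS))

    @classmethod
    def from_sequences(cls, residues: Iterable[str]) -> "AACounts":
        counts = [0] * N_AA
        for chunk in residues:
            for c in chunk:
                counts[AA_TO_INDEX[c]] += 1
        return cls(tuple(counts))

    def __add__(self, other: "AACounts") -> "AACounts":
        return AACounts(tuple(a + b for a, b in zip(self.counts, other.counts)))


def count_nonanchor_aa(peptides: PeptideSet, masks: AnchorMask) -> AACounts:
    """Count residues at non-anchor positions across a 9mer peptide set.

    Each peptide contributes exactly six residues (its 9 positions minus
    the 3 anchors of its allele), so ``total == 6 * len(peptides)``.
    """
    counts = [0] * N_AA
    for rec in peptides:
        if len(rec.sequence) != 9:
            raise RecordError(
                f"peptide {rec.sequence!r} is not a 9mer; "
                "non-anchor counting is defined for 9mers"
            )
        mask = masks.mask_for(rec.mhc_allele, 9)
        for pos, aa in enumerate(rec.sequence, start=1):
            if pos not in mask:
                counts[AA_TO_INDEX[aa]] += 1
    return AACounts(tuple(counts))


def background_frequencies(proteins: Sequence[SourceProtein]) -> np.ndarray:
    """Amino-acid frequencies over source proteins (X/wildcards skipped)."""
    if not proteins:
        raise RecordError("background requires at least one source protein")
    counts = np.zeros(N_AA)
    for prot in proteins:
        for c in prot.sequence:
            idx = AA_TO_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
            elif c not in PROTEIN_WILDCARDS:
                raise RecordError(f"protein {prot.id!r}: unexpected character {c!r}")
    total = counts.sum()
    if total == 0:
        raise RecordError("source proteins contain no countable residues")
    return counts / total


@dataclass(frozen=True)
class EnrichmentTable:
    """Smoothed class frequencies and log-enrichment scores per amino acid.

    ``log_enrichment[a] == ln(freq_imm[a] / freq_non[a])`` exactly, with
    frequencies already including the pseudocount used at construction.
    """

    freq_imm: tuple[float, ...]
    freq_non: tuple[float, ...]
    log_enrichment: tuple[float, ...]
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        for name in ("freq_imm", "freq_non", "log_enrichment"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != N_AA:
                raise RecordError(f"{name} must have {N_AA} entries")
            object.__setattr__(self, name, vals)
        for name in ("freq_imm", "freq_non"):
            s = sum(getattr(self, name))
            if abs(s - 1.0) > 1e-9:
                raise RecordError(f"{name} sums to {s}, not 1")

    def __getitem__(self, aa: str) -> float:
        return self.log_enrichment[AA_TO_INDEX[aa]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.log_enrichment)


def compute_enrichment(
    imm: AACounts, non: AACounts, pseudocount: float | None = None
) -> EnrichmentTable:
    """Log-enrichment scores E(a) = ln(f_imm(a)/f_non(a)).

    Frequencies are ``(count + pc) / (total + 20 pc)``. ``pseudocount=None``
    selects 0 when all 40 counts are positive (scores are then the plain
    frequency ratio) and 0.5 otherwise, keeping every score finite.
    """
    if imm.total == 0 or non.total == 0:
        raise RecordError("both count vectors must have positive totals")
    if pseudocount is None:
        pseudocount = 0.0 if min(min(imm.counts), min(non.counts)) > 0 else 0.5
    if pseudocount < 0:
        raise RecordError("pseudocount must be >= 0")
    if pseudocount == 0:
        for aa in AMINO_ACIDS:
            if imm[aa] == 0 or non[aa] == 0:
                raise RecordError(
                    f"zero count for {aa} with pseudocount 0; "
                    "enrichment would be infinite"
                )
    fi = (imm.as_array() + pseudocount) / (imm.total + N_AA * pseudocount)
    fn = (non.as_array() + pseudocount) / (non.total + N_AA * pseudocount)
    return EnrichmentTable(
        freq_imm=tuple(fi),
        freq_non=tuple(fn),
        log_enrichment=tuple(np.log(fi / fn)),
        pseudocount=pseudocount,
    )


def permutation_test(
    aa: str,
    imm: AACounts,
    non: AACounts,
    background: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Background-resampling test for one amino acid's class association.

    Under the null, both classes are random draws from the source-protein
    background. For each permutation a sample of ``imm.total`` and one of
    ``non.total`` residues are drawn from the background and the absolute
    frequency difference of ``aa`` is compared with the observed one
    (two-sided: over- and under-representation both count). Only the focal
    amino acid's count matters, so each draw reduces to its exact
    multinomial marginal, a binomial with the background probability.
    Returns ``(k + 1) / (n_perm + 1)`` where k permutations reach the
    observed difference.
    """
    if n_perm < 1:
        raise RecordError("n_perm must be >= 1")
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-6:
        raise RecordError("background frequencies must sum to 1")
    if imm.total == 0 or non.total == 0:
        raise RecordError("both count vectors must have positive totals")
    p_aa = background[AA_TO_INDEX[aa]]
    observed = abs(imm[aa] / imm.total - non[aa] / non.total)
    rng = np.random.default_rng(seed)
    k_imm = rng.binomial(imm.total, p_aa, size=n_perm)
    k_non = rng.binomial(non.total, p_aa, size=n_perm)
    diffs = np.abs(k_imm / imm.total - k_non / non.total)
    k = int(np.count_nonzero(diffs >= observed - 1e-12))
    return (k + 1) / (n_perm + 1)


def qvalues(p_values: Sequence[float], method: str = "storey") -> np.ndarray:
    """False-discovery-rate q-values.

    ``bh``: Benjamini–Hochberg step-up (pi0 fixed at 1). ``storey``: the
    same step-up scaled by the pi0 point estimate at lambda = 0.5,
    pi0 = min(1, #{p > 0.5} / (0.5 n)).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise RecordError("qvalues requires at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise RecordError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise RecordError(f"unknown q-value method {method!r}")
    n = p.size
    if method == "storey":
        pi0 = min(1.0, np.count_nonzero(p > 0.5) / (0.5 * n))
    else:
        pi0 = 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass(frozen=True)
class ClassDefinition:
    """A named group of amino acids and the name of its opposite group."""

    name: str
    members: frozenset[str]
    opposite: str

    def __post_init__(self) -> None:
        if not self.members <= set(AMINO_ACIDS):
            raise RecordError(f"class {self.name!r} has non-canonical members")


#: the four opposed characteristic pairs (H belongs to large, aromatic,
#: charged and basic simultaneously)
AA_CLASSES: dict[str, ClassDefinition] = {
    c.name: c
    for c in (
        ClassDefinition("large", LARGE, "small"),
        ClassDefinition("small", SMALL, "large"),
        ClassDefinition("aromatic", AROMATIC, "non_aromatic"),
        ClassDefinition("non_aromatic", NON_AROMATIC, "aromatic"),
        ClassDefinition("acidic", ACIDIC, "basic"),
        ClassDefinition("basic", BASIC, "acidic"),
        ClassDefinition("charged", CHARGED, "non_charged"),
        ClassDefinition("non_charged", NON_CHARGED, "charged"),
    )
}


@dataclass(frozen=True)
class ClassResult:
    name: str
    count_imm: int
    count_non: int
    enrichment: float | None
    p_value: float


def class_count(counts: AACounts, members: Iterable[str]) -> int:
    return sum(counts[aa] for aa in members)


def class_enrichment(
    count_imm: int, total_imm: int, count_non: int, total_non: int
) -> float | None:
    """Fold enrichment of a class: (count_imm/total_imm)/(count_non/total_non)."""
    if count_non == 0:
        return None  # undefined, reported as such
    return (count_imm / total_imm) / (count_non / total_non)


def class_pair_test(
    count_imm_a: int, count_non_a: int, count_imm_b: int, count_non_b: int
) -> float:
    """Two-sided Fisher's exact test opposing class A to its opposite B."""
    table = [[count_imm_a, count_non_a], [count_imm_b, count_non_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def class_analysis(
    imm: AACounts,
    non: AACounts,
    classes: Mapping[str, ClassDefinition] = AA_CLASSES,
) -> list[ClassResult]:
    """Per-class counts, enrichments and paired Fisher tests.

    One Fisher test is performed per opposed characteristic pair (e.g.
    large vs small); both classes of a pair report that shared p-value.
    """
    results = []
    for cdef in classes.values():
        ci = class_count(imm, cdef.members)
        cn = class_count(non, cdef.members)
        opp = classes[cdef.opposite]
        oi = class_count(imm, opp.members)
        on = class_count(non, opp.members)
        results.append(
            ClassResult(
                name=cdef.name,
                count_imm=ci,
                count_non=cn,
                enrichment=class_enrichment(ci, imm.total, cn, non.total),
                p_value=class_pair_test(ci, cn, oi, on),
            )
        )
    return results


def property_correlation(
    enrichments: EnrichmentTable, property_values: Sequence[float] | Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rank correlation of E(a) against a 20-value property scale."""
    if isinstance(property_values, Mapping):
        missing = [aa for aa in AMINO_ACIDS if aa not in property_values]
        if missing:
            raise RecordError(f"property scale missing amino acids {missing}")
        prop = np.array([float(property_values[aa]) for aa in AMINO_ACIDS])
    else:
        prop = np.asarray(property_values, dtype=float)
        if prop.size != N_AA:
            raise RecordError(f"property scale must have {N_AA} values")
    if np.ptp(prop) == 0:
        raise RecordError("constant property vector: correlation undefined")
    rho, p = stats.spearmanr(enrichments.as_array(), prop)
    return float(rho), float(p)
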