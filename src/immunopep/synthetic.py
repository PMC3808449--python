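"""Synthetic labelled peptide data with known ground truth.

The generator emulates the statistical structure the enrichment analysis
assumes: non-anchor residues of non-immunogenic peptides are i.i.d. draws
from a background distribution, while immunogenic peptides draw from the
background exponentially tilted by planted per-amino-acid log-enrichments
e*, optionally scaled per position,

    p_imm(a; p)  proportional to  bg(a) * exp(e*(a) * s(p)).

Exponential tilting makes e*(a) the exact population log-enrichment at
positions with s(p) = 1, giving closed-form recovery targets for the
estimators. Anchor residues come from a fixed allele motif, mimicking a
binding motif shared by both classes. A second generator builds redundant
peptide pools — clusters of near-identical variants embedded in generated
source proteins — to exercise the redundancy filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, AA_TO_INDEX, N_AA
from .anchors import default_mask
from .errors import RecordError
from .io import Host, Label, PeptideRecord, PeptideSet, SourceProtein

PEPTIDE_LENGTH = 9

#: anchor residues written at masked positions (a simple A*02:01-like motif)
DEFAULT_ANCHOR_MOTIF: dict[int, str] = {1: "S", 2: "L", 9: "V"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic data set pair.

    Defaults mirror a typical immunogenicity-study geometry: an imbalanced
    immunogenic/non-immunogenic pair of 9mer sets on a single allele with
    the default {P1, P2, P9} anchors, uniform background, and a planted
    signal acting on all six non-anchor positions.
    """

    n_imm: int = 600
    n_non: int = 181
    planted_log_enrichment: tuple[float, ...] = (0.0,) * N_AA
    background: tuple[float, ...] = (1.0 / N_AA,) * N_AA
    #: per-position multiplier s(p); default: 1 at non-anchor positions
    position_signal: tuple[float, ...] = (0, 0, 1, 1, 1, 1, 1, 1, 0)
    allele: str = "HLA-A*02:01"
    anchor_motif: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_ANCHOR_MOTIF)
    )
    with_affinities: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.size != N_AA or np.any(bg < 0) or abs(bg.sum() - 1) > 1e-9:
            raise RecordError("background must be 20 non-negative values summing to 1")
        if len(self.planted_log_enrichment) != N_AA:
            raise RecordError("planted_log_enrichment needs 20 values")
        if len(self.position_signal) != PEPTIDE_LENGTH:
            raise RecordError("position_signal needs 9 values")
        if self.n_imm < 1 or self.n_non < 1:
            raise RecordError("set sizes must be positive")

    @classmethod
    def with_planted(
        cls, enrichments: Mapping[str, float], **kwargs
    ) -> "GeneratorConfig":
        e = [0.0] * N_AA
        for aa, v in enrichments.items():
            e[AA_TO_INDEX[aa]] = float(v)
        return cls(planted_log_enrichment=tuple(e), **kwargs)

    def expected_log_enrichment(self) -> np.ndarray:
        """Exact population log-enrichment at non-anchor positions.

        The tilted class distribution renormalizes, so the population
        value is e*(a) s(p) - ln Z(p) per position; pooled over the six
        non-anchor positions it is ln(mean_p tilted(p) / bg). This is the
        closed-form target the enrichment estimator converges to (e* up
        to the additive log-normalizer).
        """
        bg = np.asarray(self.background, dtype=float)
        e = np.asarray(self.planted_log_enrichment, dtype=float)
        nonanchor = [
            p for p in range(1, PEPTIDE_LENGTH + 1)
            if p not in default_mask(PEPTIDE_LENGTH)
        ]
        pooled = np.mean(
            [_tilted(bg, e, self.position_signal[p - 1]) for p in nonanchor],
            axis=0,
        )
        return np.log(pooled / bg)


def _tilted(bg: np.ndarray, e: np.ndarray, s: float) -> np.ndarray:
    w = bg * np.exp(e * s)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise RecordError("tilted distribution does not normalize")
    return w / total


def _draw_peptides(
    n: int,
    position_dists: list[np.ndarray],
    motif: Mapping[int, str],
    mask: frozenset[int],
    rng: np.random.Generator,
) -> list[str]:
    """Draw n unique sequences, batched; duplicates are redrawn."""
    letters = np.array(list(AMINO_ACIDS))
    seen: set[str] = set()
    out: list[str] = []
    for _round in range(60):
        m = max(2 * (n - len(out)), 32)
        cols = []
        for pos in range(1, PEPTIDE_LENGTH + 1):
            if pos in mask and motif.get(pos):
                cols.append(np.full(m, motif[pos]))
            else:
                idx = rng.choice(N_AA, size=m, p=position_dists[pos - 1])
                cols.append(letters[idx])
        for row in np.stack(cols, axis=1):
            seq = "".join(row)
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                if len(out) == n:
                    return out
    raise RecordError("cannot generate enough unique peptides")


def generate_sets(config: GeneratorConfig) -> tuple[PeptideSet, PeptideSet]:
    """Generate an (immunogenic, non-immunogenic) 9mer set pair."""
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=float)
    e = np.asarray(config.planted_log_enrichment, dtype=float)
    mask = default_mask(PEPTIDE_LENGTH)
    dists_imm = [
        _tilted(bg, e, config.position_signal[p]) for p in range(PEPTIDE_LENGTH)
    ]
    dists_non = [bg] * PEPTIDE_LENGTH

    def build(n: int, dists: list[np.ndarray], label: Label) -> PeptideSet:
        seqs = _draw_peptides(n, dists, config.anchor_motif, mask, rng)
        affinities = (
            np.exp(rng.uniform(np.log(0.1), np.log(500.0), size=n))
            if config.with_affinities
            else [None] * n
        )
        return PeptideSet(
            tuple(
                PeptideRecord(
                    sequence=s,
                    mhc_allele=config.allele,
                    host=Host.HLA_TRANSGENIC_MOUSE,
                    label=label,
                    predicted_affinity_nM=(
                        float(a) if a is not None else None
                    ),
                )
                for s, a in zip(seqs, affinities)
            ),
            required_length=PEPTIDE_LENGTH,
        )

    imm = build(config.n_imm, dists_imm, Label.IMMUNOGENIC)
    non = build(config.n_non, dists_non, Label.NON_IMMUNOGENIC)
    return imm, non


def generate_redundant_pool(
    n_clusters: int,
    variants_per_cluster: int,
    seed: int = 0,
    protein_length: int = 60,
    allele: str = "HLA-A*02:01",
    planted_entry_count: int | None = None,
) -> tuple[PeptideSet, tuple[SourceProtein, ...]]:
    """Clusters of near-identical peptides embedded in generated proteins.

    Each cluster holds one seed 9mer placed in its own random protein plus
    variants differing by at most 2 substitutions, so every variant still
    maps to the seed window (>= 7/9 matches) and all cluster members are
    mutually redundant; peptides of different clusters share no protein.
    ``planted_entry_count`` gives the first variant of each cluster that
    entry count (others keep 1), making it the deterministic survivor of
    redundancy reduction.
    """
    if variants_per_cluster < 1 or n_clusters < 1:
        raise RecordError("cluster geometry must be positive")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    proteins: list[SourceProtein] = []
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for c in range(n_clusters):
        while True:
            prot_seq = "".join(rng.choice(letters, size=protein_length))
            start = int(rng.integers(0, protein_length - PEPTIDE_LENGTH + 1))
            seed_pep = prot_seq[start : start + PEPTIDE_LENGTH]
            if seed_pep not in seen:
                break
        proteins.append(SourceProtein(f"synthetic_protein_{c}", prot_seq))
        cluster: list[str] = []
        attempts = 0
        while len(cluster) < variants_per_cluster:
            attempts += 1
            if attempts > 100 * variants_per_cluster:
                raise RecordError("cannot generate enough unique variants")
            if not cluster:
                var = seed_pep
            else:
                n_sub = int(rng.integers(1, 3))  # 1 or 2 substitutions
                pos = rng.choice(PEPTIDE_LENGTH, size=n_sub, replace=False)
                chars = list(seed_pep)
                for p in pos:
                    chars[p] = str(rng.choice(letters))
                var = "".join(chars)
            if var in seen or var in cluster:
                continue
            cluster.append(var)
        for v_idx, var in enumerate(cluster):
            seen.add(var)
            records.append(
                PeptideRecord(
                    sequence=var,
                    mhc_allele=allele,
                    label=Label.IMMUNOGENIC,
                    entry_count=(
                        planted_entry_count
                        if planted_entry_count is not None and v_idx == 0
                        else 1
                    ),
                    source_protein_ids=(f"synthetic_protein_{c}",),
                )
            )
    return PeptideSet(tuple(records), PEPTIDE_LENGTH), tuple(proteins)
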