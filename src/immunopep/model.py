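"""The immunogenicity scoring model.

A presented 9mer L on MHC molecule H receives the score

    S(L, H) = sum_p  M(H, p) * I(p) * E(A(L, p))

where E(a) is the log-enrichment score of amino acid a in immunogenic vs
non-immunogenic peptides, I(p) is the importance weight of position p (its
Kullback-Leibler divergence between the two class profiles), and
M(H, p) in {0, 1} masks the anchor positions of H. Positive S predicts an
immunogenic peptide. The model is linear in E, deterministic, and by
construction insensitive to residues at masked positions.

Training re-estimates only E from a labelled data set pair; the importance
weights are held fixed (they are far noisier to estimate than E and are
treated as a property of TCR geometry rather than of the training fold).
A bundled reference model ships with the package; see
:func:`load_published_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .alphabet import AMINO_ACIDS, AA_TO_INDEX, N_AA
from .anchors import AnchorMask
from .enrichment import AACounts, compute_enrichment, count_nonanchor_aa
from .errors import RecordError
from .io import PeptideSet
from .position_importance import PEPTIDE_LENGTH, ImportanceWeights


@dataclass(frozen=True)
class ImmunogenicityModel:
    """Log-enrichment scores + importance weights + anchor-mask table."""

    log_enrichment: tuple[float, ...]
    importance: ImportanceWeights
    masks: AnchorMask
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        le = tuple(float(v) for v in self.log_enrichment)
        if len(le) != N_AA:
            raise RecordError(f"need {N_AA} log-enrichment scores")
        if not np.all(np.isfinite(le)):
            raise RecordError("log-enrichment scores must be finite")
        object.__setattr__(self, "log_enrichment", le)

    @classmethod
    def from_scores(
        cls,
        log_enrichment: Mapping[str, float],
        importance: ImportanceWeights,
        masks: AnchorMask,
        metadata: dict | None = None,
    ) -> "ImmunogenicityModel":
        missing = [aa for aa in AMINO_ACIDS if aa not in log_enrichment]
        if missing:
            raise RecordError(f"log-enrichment scores missing for {missing}")
        return cls(
            tuple(float(log_enrichment[aa]) for aa in AMINO_ACIDS),
            importance,
            masks,
            metadata or {},
        )

    def log_enrichment_dict(self) -> dict[str, float]:
        return dict(zip(AMINO_ACIDS, self.log_enrichment))

    def enrichment_of(self, aa: str) -> float:
        return self.log_enrichment[AA_TO_INDEX[aa]]

    def score(self, peptide: str, allele: str) -> float:
        return score_peptide(self, peptide, allele)


def score_peptide(model: ImmunogenicityModel, peptide: str, allele: str) -> float:
    """Immunogenicity score S of a 9mer presented on ``allele``.

    Only 9mers are scored: the enrichment scores and position weights are
    estimated from 9mer data and no length-extension rule is defined.
    """
    peptide = peptide.upper()
    if len(peptide) != PEPTIDE_LENGTH:
        raise RecordError(
            f"peptide {peptide!r} has length {len(peptide)}; the model is "
            f"trained on and scores {PEPTIDE_LENGTH}mers only"
        )
    bad = [c for c in peptide if c not in AA_TO_INDEX]
    if bad:
        raise RecordError(f"peptide {peptide!r}: non-canonical residue {bad[0]!r}")
    mask = model.masks.mask_for(allele, PEPTIDE_LENGTH)
    score = 0.0
    for pos, aa in enumerate(peptide, start=1):
        if pos not in mask:
            score += model.importance[pos] * model.log_enrichment[AA_TO_INDEX[aa]]
    return score


def score_set(model: ImmunogenicityModel, peptides: PeptideSet) -> np.ndarray:
    """Scores for every record of a peptide set, in order."""
    return np.array([score_peptide(model, r.sequence, r.mhc_allele) for r in peptides])


def train_model(
    imm: PeptideSet,
    non: PeptideSet,
    masks: AnchorMask,
    importance: ImportanceWeights,
    pseudocount: float | None = None,
) -> ImmunogenicityModel:
    """Estimate E from non-anchor counts of a labelled 9mer set pair.

    Importance weights are taken as given, not re-estimated.
    """
    if len(imm) == 0 or len(non) == 0:
        raise RecordError("both training sets must be non-empty")
    counts_imm = count_nonanchor_aa(imm, masks)
    counts_non = count_nonanchor_aa(non, masks)
    table = compute_enrichment(counts_imm, counts_non, pseudocount)
    return ImmunogenicityModel(
        log_enrichment=table.log_enrichment,
        importance=importance,
        masks=masks,
        metadata={
            "n_immunogenic": len(imm),
            "n_non_immunogenic": len(non),
            "pseudocount": table.pseudocount,
        },
    )


def train_final_model(
    imm_pool: PeptideSet,
    non_pool: PeptideSet,
    proteins,
    masks: AnchorMask,
    importance: ImportanceWeights,
    n_resamplings: int = 100,
    seed: int | None = None,
    pseudocount: float | None = None,
) -> ImmunogenicityModel:
    """Average E over repeated non-redundancy selections of the pools.

    The redundancy filter breaks priority ties at random, so the
    non-redundant set — and hence E — varies slightly between selections.
    The final model repeats selection + training ``n_resamplings`` times
    and takes the arithmetic mean of the log-enrichment scores.
    """
    from .redundancy import reduce_redundancy

    if n_resamplings < 1:
        raise RecordError("n_resamplings must be >= 1")
    rng = np.random.default_rng(seed)
    scores = np.zeros(N_AA)
    for _ in range(n_resamplings):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        nr_imm = reduce_redundancy(imm_pool, proteins, seed=sub_seed)
        nr_non = reduce_redundancy(non_pool, proteins, seed=sub_seed + 1)
        m = train_model(nr_imm, nr_non, masks, importance, pseudocount)
        scores += np.asarray(m.log_enrichment)
    scores /= n_resamplings
    return ImmunogenicityModel(
        log_enrichment=tuple(scores),
        importance=importance,
        masks=masks,
        metadata={"n_resamplings": n_resamplings, "seed": seed},
    )


def load_published_model() -> ImmunogenicityModel:
    """The bundled reference model.

    Log-enrichment scores and position-importance weights as distributed
    with the reference MHC-I immunogenicity predictor hosted by the IEDB
    analysis resource, with the default anchor rule {P1, P2, C-terminus}
    plus the HLA-B*08:01 exception (P2/P5/P9).
    """
    from .io import read_model

    with resources.as_file(
        resources.files("immunopep.data") / "published_model.json"
    ) as path:
        return read_model(path)
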