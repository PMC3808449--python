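"""Per-position divergence between immunogenic and non-immunogenic profiles.

If T-cell receptors read a peptide position, the amino-acid profile at that
position should differ between recognized and unrecognized peptides. The
difference is quantified per position with the Kullback-Leibler divergence
D(immunogenic || non-immunogenic) over the 20-letter profiles, restricted
to peptides for which the position is not a binding anchor. Positions that
are anchors in (nearly) all peptides — P1, P2 and P9 under the default
mask rule — cannot be estimated and are reported NA, entering the scoring
model with weight 0. Significance per position comes from the 2x20
contingency test with asymptotic chi-squared probabilities when the
Cochran conditions hold, and a fixed-margin Monte-Carlo test otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .alphabet import AA_TO_INDEX, N_AA
from .anchors import AnchorMask
from .enrichment import AACounts
from .errors import RecordError
from .io import PeptideSet

PEPTIDE_LENGTH = 9


@dataclass(frozen=True)
class PositionProfiles:
    """Per-position amino-acid counts; None where no peptide contributes."""

    profiles: tuple[AACounts | None, ...]

    def __post_init__(self) -> None:
        if len(self.profiles) != PEPTIDE_LENGTH:
            raise RecordError(f"need {PEPTIDE_LENGTH} position profiles")

    def __getitem__(self, position: int) -> AACounts | None:
        """1-based position access."""
        if not 1 <= position <= PEPTIDE_LENGTH:
            raise RecordError(f"position {position} out of range 1..{PEPTIDE_LENGTH}")
        return self.profiles[position - 1]

    @property
    def estimable_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in range(1, PEPTIDE_LENGTH + 1) if self[p] is not None
        )


def position_profiles(
    imm: PeptideSet, non: PeptideSet, masks: AnchorMask
) -> tuple[PositionProfiles, PositionProfiles]:
    """Count amino acids per position, over peptides where the position
    is not an anchor for the peptide's allele."""

    def build(peptides: PeptideSet) -> PositionProfiles:
        counts = [[0] * N_AA for _ in range(PEPTIDE_LENGTH)]
        touched = [False] * PEPTIDE_LENGTH
        for rec in peptides:
            if len(rec.sequence) != PEPTIDE_LENGTH:
                raise RecordError(f"peptide {rec.sequence!r} is not a 9mer")
            mask = masks.mask_for(rec.mhc_allele, PEPTIDE_LENGTH)
            for pos, aa in enumerate(rec.sequence, start=1):
                if pos not in mask:
                    counts[pos - 1][AA_TO_INDEX[aa]] += 1
                    touched[pos - 1] = True
        return PositionProfiles(
            tuple(
                AACounts(tuple(c)) if t else None
                for c, t in zip(counts, touched)
            )
        )

    return build(imm), build(non)


def kl_divergence(P: AACounts, Q: AACounts, pseudocount: float = 0.5) -> float:
    """Kullback-Leibler divergence D(P || Q) in nats over smoothed profiles.

    Frequencies are ``(count + pseudocount) / (total + 20 pseudocount)``;
    with a shared positive pseudocount the divergence is finite,
    non-negative, and zero only for identical count proportions.
    """
    if P.total == 0 or Q.total == 0:
        raise RecordError("KL divergence requires positive totals")
    if pseudocount < 0:
        raise RecordError("pseudocount must be >= 0")
    p = (P.as_array() + pseudocount) / (P.total + N_AA * pseudocount)
    q = (Q.as_array() + pseudocount) / (Q.total + N_AA * pseudocount)
    if pseudocount == 0 and (np.any((p > 0) & (q == 0))):
        raise RecordError("KL divergence infinite: zero Q count without smoothing")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _cochran_ok(expected: np.ndarray) -> bool:
    """Cochran conditions: no expected count zero, >= 80% of cells >= 5."""
    if np.any(expected == 0):
        return False
    return np.count_nonzero(expected >= 5) >= 0.8 * expected.size


def position_divergence_test(
    P: AACounts,
    Q: AACounts,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> float:
    """Test whether two 20-category profiles differ (2x20 contingency).

    Uses the asymptotic chi-squared probability when the Cochran
    conditions hold on the expected counts; otherwise a Monte-Carlo
    p-value from ``n_mc`` random tables with fixed margins (Patefield
    sampling), with add-one smoothing.
    """
    if P.total == 0 or Q.total == 0:
        raise RecordError("degenerate table: a class margin is zero")
    table = np.vstack([P.as_array(), Q.as_array()])
    # drop amino acids absent from both profiles: zero-margin columns
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 1.0
    chi2, p_asym, _, expected = stats.chi2_contingency(table, correction=False)
    if _cochran_ok(expected):
        return float(p_asym)
    if n_mc < 1:
        raise RecordError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = sampler.rvs(n_mc, method="patefield", random_state=rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat_obs = np.sum((table - expected) ** 2 / expected)
        stat_sim = np.sum((sims - expected) ** 2 / expected, axis=(1, 2))
    k = int(np.count_nonzero(stat_sim >= stat_obs - 1e-9))
    return (k + 1) / (n_mc + 1)


@dataclass(frozen=True)
class ImportanceWeights:
    """Per-position weights I(p), p = 1..9; masked/NA positions carry 0."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        if len(w) != PEPTIDE_LENGTH:
            raise RecordError(f"need {PEPTIDE_LENGTH} importance weights")
        for v in w:
            if not math.isfinite(v):
                raise RecordError("importance weights must be finite")
            if v < 0:
                raise RecordError("importance weights must be >= 0")
        object.__setattr__(self, "weights", w)

    def __getitem__(self, position: int) -> float:
        """1-based position access."""
        return self.weights[position - 1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights)


def build_importance_weights(
    divergences: Mapping[int, float],
    na_positions: Sequence[int] = (1, 2, 9),
) -> ImportanceWeights:
    """Assemble I(p) from per-position divergences; NA positions get 0."""
    na = set(na_positions)
    weights = []
    for pos in range(1, PEPTIDE_LENGTH + 1):
        if pos in na:
            weights.append(0.0)
            continue
        if pos not in divergences:
            raise RecordError(f"no divergence supplied for estimable position {pos}")
        d = float(divergences[pos])
        if d < 0:
            raise RecordError(f"negative divergence at position {pos}")
        weights.append(d)
    return ImportanceWeights(tuple(weights))


def importance_from_sets(
    imm: PeptideSet,
    non: PeptideSet,
    masks: AnchorMask,
    pseudocount: float = 0.5,
) -> tuple[ImportanceWeights, dict[int, float]]:
    """Per-position KL divergences for a data set pair, as weights.

    Positions estimable in both classes get their divergence; the rest
    are NA (weight 0). Returns the weights and the raw divergence map.
    """
    prof_imm, prof_non = position_profiles(imm, non, masks)
    divergences: dict[int, float] = {}
    for pos in range(1, PEPTIDE_LENGTH + 1):
        P, Q = prof_imm[pos], prof_non[pos]
        if P is not None and Q is not None:
            divergences[pos] = kl_divergence(P, Q, pseudocount)
    na = [p for p in range(1, PEPTIDE_LENGTH + 1) if p not in divergences]
    return build_importance_weights(divergences, na), divergences
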