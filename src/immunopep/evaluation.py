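"""Model evaluation: ROC/AUC, cross-validation, matched sets, triage.

The central question is whether immunogenic peptides outscore
non-immunogenic ones. AUC is the probability that a random immunogenic
peptide outscores a random non-immunogenic one (ties count half), i.e. the
normalized Mann-Whitney U statistic; the ROC curve is the standard
threshold sweep. Cross-validation re-estimates only the enrichment scores
per training fold, keeping importance weights and masks fixed. A score of
zero is the natural decision threshold: positive scores predict
immunogenic. Affinity-matched control sets equalize per-bin histograms on
a logarithmic nM scale so that composition effects are not confounded by
binding strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .anchors import AnchorMask
from .errors import RecordError
from .io import PeptideSet
from .model import score_set, train_model
from .position_importance import ImportanceWeights

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class EvaluationResult:
    """ROC points, AUC, rank-sum p and fraction-positive summaries."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float
    ranksum_p: float
    frac_pos_imm: float
    frac_pos_non: float


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized U statistic (ties half-weighted)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def ranksum(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) p, normal approximation
    with tie correction; degenerate all-equal input returns 1."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise RecordError("both score sets must be non-empty")
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return 1.0
    return float(
        stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue
    )


def roc_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> EvaluationResult:
    """ROC curve and AUC for immunogenic (pos) vs non-immunogenic scores."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise RecordError("both score sets must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y, scores)
    return EvaluationResult(
        fpr=tuple(fpr),
        tpr=tuple(tpr),
        auc=_mann_whitney_auc(pos, neg),
        ranksum_p=ranksum(pos, neg),
        frac_pos_imm=float(np.mean(pos > 0)),
        frac_pos_non=float(np.mean(neg > 0)),
    )


def _stratified_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [idx[f::k] for f in range(k)]


def cross_validate(
    imm: PeptideSet,
    non: PeptideSet,
    masks: AnchorMask,
    importance: ImportanceWeights,
    k: int = 3,
    reps: int = 25,
    seed: int | None = None,
    pseudocount: float | None = None,
) -> EvaluationResult:
    """Repeated stratified k-fold cross-validation, averaged.

    Per repetition each class is split independently into k folds; the
    model's enrichment scores are re-estimated on the k-1 training folds
    (importance weights fixed) and the held-out fold is scored. Held-out
    scores are pooled within a repetition into one ROC/AUC; the mean
    curve averages repetitions vertically on a fixed 101-point FPR grid.
    Bit-reproducible for fixed (seed, reps, k).
    """
    if len(imm) < k or len(non) < k:
        raise RecordError(f"each class needs at least k={k} peptides")
    rng = np.random.default_rng(seed)
    aucs, ps, fpos_i, fpos_n = [], [], [], []
    mean_tprs = []
    for _ in range(reps):
        folds_imm = _stratified_folds(len(imm), k, rng)
        folds_non = _stratified_folds(len(non), k, rng)
        pos_all, neg_all = [], []
        for f in range(k):
            test_i = set(folds_imm[f].tolist())
            test_n = set(folds_non[f].tolist())
            train_imm = imm.subset([i for i in range(len(imm)) if i not in test_i])
            train_non = non.subset([i for i in range(len(non)) if i not in test_n])
            m = train_model(train_imm, train_non, masks, importance, pseudocount)
            pos_all.append(score_set(m, imm.subset(sorted(test_i))))
            neg_all.append(score_set(m, non.subset(sorted(test_n))))
        pos = np.concatenate(pos_all)
        neg = np.concatenate(neg_all)
        rep = roc_auc(pos, neg)
        aucs.append(rep.auc)
        ps.append(rep.ranksum_p)
        fpos_i.append(rep.frac_pos_imm)
        fpos_n.append(rep.frac_pos_non)
        mean_tprs.append(np.interp(FPR_GRID, rep.fpr, rep.tpr))
    return EvaluationResult(
        fpr=tuple(FPR_GRID),
        tpr=tuple(np.mean(mean_tprs, axis=0)),
        auc=float(np.mean(aucs)),
        ranksum_p=float(np.median(ps)),
        frac_pos_imm=float(np.mean(fpos_i)),
        frac_pos_non=float(np.mean(fpos_n)),
    )


@dataclass(frozen=True)
class BinScheme:
    """Strictly increasing bin edges on the affinity (or score) axis.

    Values below the first edge form an extra leading bin; values above
    the last edge form an extra trailing bin.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise RecordError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    def assign(self, values: np.ndarray) -> np.ndarray:
        return np.digitize(values, self.edges)


def affinity_bins() -> BinScheme:
    """Five edges log-spaced over 1-500 nM, preceded by the < 1 nM bin."""
    return BinScheme((1.0, 4.7, 22.4, 106.0, 500.0))


NETCTL_SCORE_OFFSET = 1.1625


def netctl_bins() -> BinScheme:
    """Five edges log-spaced over 1-5 for offset combined-prediction scores."""
    return BinScheme(tuple(np.logspace(0, math.log10(5), 5)))


def matched_sets(
    a: PeptideSet,
    b: PeptideSet,
    scheme: BinScheme | None = None,
    seed: int | None = None,
) -> tuple[PeptideSet, PeptideSet, float]:
    """Subsets of a and b with identical per-bin affinity histograms.

    Each bin keeps ``min(count_a, count_b)`` records from both sets — the
    maximum matched selection — subsampling the larger side with ``seed``.
    Returns the subsets and the rank-sum p comparing the matched affinity
    values (large p = successful matching).
    """
    scheme = scheme or affinity_bins()
    rng = np.random.default_rng(seed)

    def values_of(ps: PeptideSet) -> np.ndarray:
        vals = []
        for r in ps:
            if r.predicted_affinity_nM is None:
                raise RecordError(
                    f"record {r.sequence}/{r.mhc_allele} has no affinity value"
                )
            vals.append(r.predicted_affinity_nM)
        return np.asarray(vals)

    va, vb = values_of(a), values_of(b)
    bins_a, bins_b = scheme.assign(va), scheme.assign(vb)
    keep_a: list[int] = []
    keep_b: list[int] = []
    for bin_id in range(len(scheme.edges) + 1):
        ia = np.flatnonzero(bins_a == bin_id)
        ib = np.flatnonzero(bins_b == bin_id)
        m = min(ia.size, ib.size)
        if m == 0:
            continue
        keep_a.extend(sorted(rng.choice(ia, size=m, replace=False).tolist()))
        keep_b.extend(sorted(rng.choice(ib, size=m, replace=False).tolist()))
    sub_a = a.subset(sorted(keep_a))
    sub_b = b.subset(sorted(keep_b))
    if len(sub_a) == 0:
        raise RecordError("no overlapping affinity bins between the two sets")
    p = ranksum(values_of(sub_a), values_of(sub_b))
    return sub_a, sub_b, p


def triage_summary(
    scores: Sequence[float], is_epitope: Sequence[bool]
) -> tuple[float, float | None]:
    """Fraction of candidates discardable at score <= 0, and the fraction
    of epitopes that survive (score > 0).

    With no epitopes in the input, the retained fraction is undefined
    and reported as None.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(is_epitope, dtype=bool)
    if s.size != e.size or s.size == 0:
        raise RecordError("scores and labels must be equal-length and non-empty")
    frac_discarded = float(np.mean(s <= 0))
    if not e.any():
        return frac_discarded, None
    frac_epitopes_retained = float(np.mean(s[e] > 0))
    return frac_discarded, frac_epitopes_retained


def sign_test_fraction_positive(
    paired_fractions: Sequence[tuple[float, float]],
) -> float:
    """Two-sided binomial sign test on pairs of positive-score fractions.

    Used e.g. to compare, per HLA molecule, the fraction of positively
    scoring viral vs human ligands. Ties are dropped; an all-tie input
    is an error.
    """
    if not paired_fractions:
        raise RecordError("sign test requires at least one pair")
    n_greater = sum(1 for fa, fb in paired_fractions if fa > fb)
    n_less = sum(1 for fa, fb in paired_fractions if fa < fb)
    n = n_greater + n_less
    if n == 0:
        raise RecordError("all pairs tie; sign test undefined")
    return float(stats.binomtest(n_greater, n, 0.5, alternative="two-sided").pvalue)
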