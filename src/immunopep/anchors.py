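"""Anchor-position masks per MHC allele.

Anchor positions are the peptide positions whose side chains determine
binding to the MHC groove; their residues reflect the binding motif rather
than T-cell preference, so they are masked out of immunogenicity scoring.
For most HLA class I molecules the anchors of a 9mer are P1, P2 and P9
(the default rule: first two positions and the C-terminus); alleles with
unusual motifs, e.g. HLA-B*08:01 with P2/P5/P9, carry explicit entries in
the mask table. When a per-allele, per-position binding-impact profile is
available (computed externally with an MHC binding predictor), the three
highest-impact positions of a 9mer are the anchors and the remaining six
are the non-anchor positions used by every downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import AmbiguousAnchorError, MaskLookupError, RecordError
from .io import normalize_allele

N_ANCHORS_9MER = 3


def default_mask(length: int) -> frozenset[int]:
    """Default anchor mask for a peptide of ``length``: {1, 2, last}."""
    if length < 8:
        raise RecordError(f"no anchor rule for peptides shorter than 8 (got {length})")
    return frozenset({1, 2, length})


@dataclass(frozen=True)
class PositionImpactProfile:
    """Externally computed per-position impact on predicted binding affinity."""

    allele: str
    impact: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele", normalize_allele(self.allele))
        object.__setattr__(self, "impact", tuple(float(v) for v in self.impact))
        if len(self.impact) != 9:
            raise RecordError(
                f"{self.allele}: impact profile must have 9 values, "
                f"got {len(self.impact)}"
            )
        for v in self.impact:
            if not math.isfinite(v) or v < 0:
                raise RecordError(f"{self.allele}: impact values must be finite and >= 0")


def derive_anchor_mask(profile: PositionImpactProfile) -> frozenset[int]:
    """Anchors = the 3 positions with highest binding impact (of 9).

    The six lowest-impact positions are the non-anchor positions. A tie in
    impact across the 3rd/4th rank boundary makes the split ambiguous and
    raises :class:`AmbiguousAnchorError`; supply an explicit mask instead.
    """
    order = sorted(range(9), key=lambda i: (-profile.impact[i], i))
    boundary_in = profile.impact[order[N_ANCHORS_9MER - 1]]
    boundary_out = profile.impact[order[N_ANCHORS_9MER]]
    if boundary_in == boundary_out:
        raise AmbiguousAnchorError(
            f"{profile.allele}: impact {boundary_in} ties across the "
            "anchor/non-anchor boundary; pass an explicit mask for this allele"
        )
    return frozenset(i + 1 for i in order[:N_ANCHORS_9MER])


@dataclass(frozen=True)
class AnchorMask:
    """Per-allele anchor masks with the {1, 2, last} fallback rule.

    ``masks`` maps normalized allele names to 1-based masked positions.
    Alleles absent from the table fall back to :func:`default_mask` unless
    ``use_default`` is False, in which case the lookup raises.
    """

    masks: dict[str, frozenset[int]] = field(default_factory=dict)
    use_default: bool = True

    def __post_init__(self) -> None:
        normalized = {
            normalize_allele(a): frozenset(int(p) for p in pos)
            for a, pos in self.masks.items()
        }
        for allele, pos in normalized.items():
            if any(p < 1 for p in pos):
                raise RecordError(f"{allele}: mask positions must be 1-based")
        object.__setattr__(self, "masks", normalized)

    def mask_for(self, allele: str, length: int) -> frozenset[int]:
        allele = normalize_allele(allele)
        if allele in self.masks:
            mask = self.masks[allele]
            if any(p > length for p in mask):
                raise RecordError(
                    f"{allele}: mask {sorted(mask)} exceeds peptide length {length}"
                )
            return mask
        if self.use_default:
            return default_mask(length)
        raise MaskLookupError(
            f"no anchor mask for allele {allele!r} and default rule disabled"
        )

    def with_entry(self, allele: str, positions) -> "AnchorMask":
        new = dict(self.masks)
        new[normalize_allele(allele)] = frozenset(int(p) for p in positions)
        return AnchorMask(new, self.use_default)

    def with_profile(self, profile: PositionImpactProfile) -> "AnchorMask":
        return self.with_entry(profile.allele, derive_anchor_mask(profile))


def bundled_mask_table() -> AnchorMask:
    """The mask table shipped with the reference model.

    Only HLA-B*08:01 (anchors P2/P5/P9) deviates from the default rule;
    all other alleles use {1, 2, last}.
    """
    return AnchorMask({"HLA-B*08:01": frozenset({2, 5, 9})})
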