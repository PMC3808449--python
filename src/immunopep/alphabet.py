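"""The 20-letter amino-acid alphabet and physicochemical groupings.

Groupings follow the conventional definitions used in T-cell preference
analyses: size classes split at 120 Da (small) and 150 Da (large), and
aromatic / charged / acidic / basic sets follow standard biochemistry.
Histidine is deliberately a member of large, aromatic, charged and basic.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = 20

# residues tolerated (and skipped) in source proteins but rejected in peptides
PROTEIN_WILDCARDS: frozenset[str] = frozenset("XBZJUO*-")

SMALL = frozenset("AGPSTV")       # < 120 Da
LARGE = frozenset("FHRWY")        # > 150 Da
AROMATIC = frozenset("FHWY")
NON_AROMATIC = frozenset(AMINO_ACIDS) - AROMATIC
CHARGED = frozenset("DEHKR")
NON_CHARGED = frozenset(AMINO_ACIDS) - CHARGED
ACIDIC = frozenset("DE")
BASIC = frozenset("HKR")


def is_canonical(sequence: str) -> bool:
    """True if every character is one of the 20 canonical residues."""
    return all(c in AA_TO_INDEX for c in sequence)
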