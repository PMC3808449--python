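"""Reading and writing peptide tables, source proteins, and scoring models.

Peptide tables are tab-separated by default, one presented peptide per row,
with columns ``sequence`` and ``allele`` required and ``host``, ``label``,
``affinity_nM``, ``entry_count`` and ``source_proteins`` optional. Source
proteins are plain FASTA. Models are versioned JSON documents holding the
20 log-enrichment scores, the 9 position-importance weights and the
per-allele anchor-mask table.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .alphabet import AA_TO_INDEX, is_canonical
from .errors import FormatError, RecordError

_HLA_NO_COLON = re.compile(r"^(HLA-[A-Z]+\d*\*)(\d{2})(\d{2,3})$")


class Host(str, enum.Enum):
    HUMAN = "human"
    HLA_TRANSGENIC_MOUSE = "hla_transgenic_mouse"
    WILD_TYPE_MOUSE = "wild_type_mouse"


class Label(str, enum.Enum):
    IMMUNOGENIC = "immunogenic"
    NON_IMMUNOGENIC = "non_immunogenic"
    UNKNOWN = "unknown"


#: file-vocabulary -> canonical label (epitope sets use epitope/non-epitope)
LABEL_VOCABULARY: dict[str, Label] = {
    "immunogenic": Label.IMMUNOGENIC,
    "non-immunogenic": Label.NON_IMMUNOGENIC,
    "non_immunogenic": Label.NON_IMMUNOGENIC,
    "epitope": Label.IMMUNOGENIC,
    "non-epitope": Label.NON_IMMUNOGENIC,
    "non_epitope": Label.NON_IMMUNOGENIC,
    "unknown": Label.UNKNOWN,
    "": Label.UNKNOWN,
}

_HOST_VOCABULARY: dict[str, Host] = {
    "human": Host.HUMAN,
    "hla_transgenic_mouse": Host.HLA_TRANSGENIC_MOUSE,
    "hla-transgenic-mouse": Host.HLA_TRANSGENIC_MOUSE,
    "transgenic mouse": Host.HLA_TRANSGENIC_MOUSE,
    "wild_type_mouse": Host.WILD_TYPE_MOUSE,
    "mouse": Host.WILD_TYPE_MOUSE,
}


def normalize_allele(name: str) -> str:
    """Normalize an MHC allele name to the colon-separated form.

    Both ``HLA-A*0201`` and ``HLA-A*02:01`` are accepted and stored as
    ``HLA-A*02:01``; murine names such as ``H-2-Kb`` pass through with
    case preserved after the ``H-2-`` prefix.
    """
    name = name.strip()
    if not name:
        raise RecordError("empty allele name")
    if name.upper().startswith("H-2"):
        return "H-2" + name[3:]
    name = name.upper()
    m = _HLA_NO_COLON.match(name)
    if m:
        return f"{m.group(1)}{m.group(2)}:{m.group(3)}"
    return name


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide/MHC/host observation with label and provenance."""

    sequence: str
    mhc_allele: str
    host: Host = Host.HUMAN
    label: Label = Label.UNKNOWN
    predicted_affinity_nM: float | None = None
    entry_count: int = 1
    source_protein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence
        if seq != seq.upper():
            object.__setattr__(self, "sequence", seq.upper())
            seq = self.sequence
        if len(seq) < 8:
            raise RecordError(f"peptide {seq!r}: length {len(seq)} < 8")
        bad = [c for c in seq if c not in AA_TO_INDEX]
        if bad:
            raise RecordError(
                f"peptide {seq!r}: non-canonical residue {bad[0]!r}"
            )
        object.__setattr__(self, "mhc_allele", normalize_allele(self.mhc_allele))
        if self.predicted_affinity_nM is not None and not self.predicted_affinity_nM > 0:
            raise RecordError(
                f"peptide {seq!r}: affinity must be > 0 nM, "
                f"got {self.predicted_affinity_nM}"
            )
        if self.entry_count < 0:
            raise RecordError(f"peptide {seq!r}: negative entry_count")


@dataclass(frozen=True)
class PeptideSet:
    """A collection of peptide records with no duplicate (sequence, allele)."""

    records: tuple[PeptideRecord, ...]
    required_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.sequence, r.mhc_allele)
            if key in seen:
                raise RecordError(f"duplicate (sequence, allele) pair {key}")
            seen.add(key)
            if self.required_length is not None and len(r.sequence) != self.required_length:
                raise RecordError(
                    f"peptide {r.sequence!r} has length {len(r.sequence)}, "
                    f"required {self.required_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices: Iterable[int]) -> "PeptideSet":
        recs = tuple(self.records[i] for i in indices)
        return PeptideSet(recs, self.required_length)

    def with_label(self, label: Label) -> "PeptideSet":
        return PeptideSet(
            tuple(r for r in self.records if r.label is label),
            self.required_length,
        )


@dataclass(frozen=True)
class SourceProtein:
    """A source protein; may contain X, skipped in counting and mapping."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("source protein with empty id")
        if not self.sequence:
            raise RecordError(f"source protein {self.id!r} has empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class TableDialect:
    """Layout of a peptide table: separator and column-name mapping."""

    sep: str = "\t"
    #: canonical field -> column name in the file
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "sequence": "sequence",
            "allele": "allele",
            "host": "host",
            "label": "label",
            "affinity_nM": "affinity_nM",
            "entry_count": "entry_count",
            "source_proteins": "source_proteins",
        }
    )


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    required_length: int | None = None,
) -> PeptideSet:
    """Read a peptide table into a :class:`PeptideSet`.

    ``sequence`` and ``allele`` columns are required; missing optional
    columns take their defaults (host human, label unknown, entry count 1).
    Raises :class:`FormatError` naming the missing column, or
    :class:`RecordError` naming the offending row.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    cols = dialect.columns
    for required in ("sequence", "allele"):
        if cols[required] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {cols[required]!r}"
            )
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # header is line 1
        getter = row.to_dict()
        try:
            label_raw = getter.get(cols.get("label", "label"), "").strip().lower()
            if label_raw not in LABEL_VOCABULARY:
                raise RecordError(f"unrecognized label {label_raw!r}")
            host_raw = getter.get(cols.get("host", "host"), "").strip().lower()
            host = _HOST_VOCABULARY.get(host_raw, Host.HUMAN)
            aff_raw = getter.get(cols.get("affinity_nM", "affinity_nM"), "").strip()
            ec_raw = getter.get(cols.get("entry_count", "entry_count"), "").strip()
            src_raw = getter.get(cols.get("source_proteins", "source_proteins"), "").strip()
            records.append(
                PeptideRecord(
                    sequence=getter[cols["sequence"]].strip(),
                    mhc_allele=getter[cols["allele"]].strip(),
                    host=host,
                    label=LABEL_VOCABULARY[label_raw],
                    predicted_affinity_nM=float(aff_raw) if aff_raw else None,
                    entry_count=int(ec_raw) if ec_raw else 1,
                    source_protein_ids=tuple(s for s in src_raw.split(";") if s),
                )
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path}, row {i}: {exc}") from exc
    return PeptideSet(tuple(records), required_length)


def write_peptide_table(
    peptides: PeptideSet, path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    cols = dialect.columns
    rows = []
    for r in peptides:
        rows.append(
            {
                cols["sequence"]: r.sequence,
                cols["allele"]: r.mhc_allele,
                cols["host"]: r.host.value,
                cols["label"]: r.label.value,
                cols["affinity_nM"]: (
                    "" if r.predicted_affinity_nM is None else repr(r.predicted_affinity_nM)
                ),
                cols["entry_count"]: r.entry_count,
                cols["source_proteins"]: ";".join(r.source_protein_ids),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


def read_fasta(path: str | Path) -> tuple[SourceProtein, ...]:
    """Read source proteins from FASTA; ids must be unique."""
    proteins: list[SourceProtein] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        proteins.append(SourceProtein(pid, str(rec.seq).upper()))
    if not proteins:
        raise FormatError(f"{path}: no FASTA records found")
    return tuple(proteins)


MODEL_FORMAT = "immunopep-model"
MODEL_VERSION = 1


def write_model(model, path: str | Path) -> None:
    """Serialize an immunogenicity model to versioned JSON (lossless)."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "log_enrichment": {aa: float(v) for aa, v in model.log_enrichment_dict().items()},
        "importance": [float(w) for w in model.importance.weights],
        "masks": {a: sorted(m) for a, m in sorted(model.masks.masks.items())},
        "default_rule": model.masks.use_default,
        "metadata": dict(model.metadata),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_model(path: str | Path):
    """Load a model written by :func:`write_model` (round-trip exact)."""
    from .anchors import AnchorMask
    from .model import ImmunogenicityModel
    from .position_importance import ImportanceWeights

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path}: not an {MODEL_FORMAT} document")
    if doc.get("version") != MODEL_VERSION:
        raise FormatError(
            f"{path}: model version {doc.get('version')!r} is not supported "
            f"(expected {MODEL_VERSION})"
        )
    masks = AnchorMask(
        masks={a: frozenset(v) for a, v in doc["masks"].items()},
        use_default=bool(doc["default_rule"]),
    )
    return ImmunogenicityModel.from_scores(
        log_enrichment=doc["log_enrichment"],
        importance=ImportanceWeights(tuple(doc["importance"])),
        masks=masks,
        metadata=doc.get("metadata", {}),
    )
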