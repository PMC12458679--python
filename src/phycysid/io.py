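"""FASTA and tabular input/output, with class labels parsed from headers.

Training corpora encode their ground truth in the FASTA header: a subtype
token (``I1``, ``I2``, ``IwI``, ``II``) prefixes phytocystatin entries and
``No_`` prefixes the negative (non-cystatin) entries, followed by the gene
code.  Anything else is ``UNKNOWN`` and can still be classified, just not
used for training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 standard amino acids
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: ambiguity / rare codes mapped to X (kept in the sequence, excluded from
#: composition denominators downstream)
AMBIGUOUS_MAP = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}

SUBTYPES = ("I1", "I2", "IwI", "II")
LABELS = SUBTYPES + ("NEG", "UNKNOWN")

# longest prefix first so "IwI_" is tested before "I1_"/"I2_"/"II_"
_LABEL_PREFIXES = (("no_", "NEG"), ("iwi_", "IwI"), ("i1_", "I1"),
                   ("i2_", "I2"), ("ii_", "II"))


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry with an optional class label parsed from its header."""

    id: str
    description: str
    residues: str
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)}")
        if self.label not in LABELS:
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)


def parse_label(header_id: str) -> str:
    """Map a header token to its class label (total: always returns one).

    Case-insensitive prefix match; subtype tokens must be followed by "_".
    """
    low = header_id.lower()
    for prefix, label in _LABEL_PREFIXES:
        if low.startswith(prefix):
            return label
    return "UNKNOWN"


def clean_residues(raw: str) -> str:
    """Uppercase, strip terminators/gaps, map rare codes to X.

    Raises ``ValueError`` on characters that are not amino-acid codes.
    """
    seq = raw.upper().replace("*", "").replace("-", "").replace(".", "")
    seq = "".join(AMBIGUOUS_MAP.get(c, c) for c in seq)
    bad = set(seq) - STANDARD_AA - {"X"}
    if bad:
        raise ValueError(f"invalid residue characters: {sorted(bad)}")
    return seq


def make_record(header: str, raw_seq: str) -> ProteinRecord:
    """Build a ProteinRecord from a raw header line (sans '>') and sequence."""
    parts = header.split(None, 1)
    rid = parts[0] if parts else ""
    desc = parts[1] if len(parts) > 1 else ""
    return ProteinRecord(id=rid, description=desc,
                         residues=clean_residues(raw_seq),
                         label=parse_label(rid))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, order preserved.

    Wrapped sequence lines are concatenated and uppercased.  An empty file
    raises ``ValueError("no sequences")``; content before the first header
    raises a parse error with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {stripped[:30]!r}")
            break
    records = [make_record(rec.description, str(rec.seq))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def filter_by_length(records: Sequence[ProteinRecord], min_len: int,
                     max_len: float) -> list[ProteinRecord]:
    """Keep records with ``min_len < length < max_len`` (strict bounds)."""
    if not min_len < max_len:
        raise ValueError("min_len must be < max_len")
    return [r for r in records if min_len < len(r) < max_len]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (rows = sequence ids) as TSV.

    The column set must match the frozen 21-descriptor order; round-trips
    losslessly with :func:`read_feature_table`.
    """
    from .features import FEATURE_NAMES

    if list(table.columns) != list(FEATURE_NAMES):
        raise ValueError(
            "feature table columns do not match the frozen descriptor order: "
            f"{list(table.columns)}")
    table.to_csv(path, sep="\t", index=True, index_label="id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from .features import FEATURE_NAMES

    table = pd.read_csv(path, sep="\t", index_col="id")
    if list(table.columns) != list(FEATURE_NAMES):
        raise ValueError(
            f"{path}: columns do not match the frozen descriptor order")
    return table


def write_truth_table(records: Iterable[ProteinRecord],
                      path: str | Path) -> None:
    """Write an (id, label) TSV next to a generated FASTA."""
    rows = [(r.id, r.label) for r in records]
    pd.DataFrame(rows, columns=["id", "label"]).to_csv(
        path, sep="\t", index=False)
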