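"""N-terminal standardization: the GG cutter.

Phytocystatins carry a variable amino-terminal extension (often a signal
peptide) ahead of the inhibitory domain, whose first conserved residue is a
glycine frequently preceded by a second glycine.  Standardization scans the
first ``window`` residues for a diglycine (GG); failing that, for the first
lone glycine; the retained segment starts at the conserved glycine (the
second G of the pair, or the lone G).  Sequences with no glycine in the
window pass through unchanged and are flagged ``NONE``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ProteinRecord

DEFAULT_WINDOW = 50


@dataclass(frozen=True)
class CleavedRecord:
    """Output of the GG cutter: retained segment plus cleavage metadata."""

    source_id: str
    cleavage_index: int  # 0-based start of the retained segment
    mode: str            # "GG" | "G" | "NONE"
    residues: str

    def __post_init__(self) -> None:
        if self.mode not in ("GG", "G", "NONE"):
            raise ValueError(f"invalid cleavage mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.residues)


def gg_cut(record: ProteinRecord, window: int = DEFAULT_WINDOW,
           keep_glycine: bool = True) -> CleavedRecord:
    """Trim the N-terminal extension at the GG (or first G) site.

    The diglycine is searched first across the whole window (its first
    residue must start at 0-based index < ``window``); only if absent does
    the first lone glycine apply.  With ``keep_glycine`` (default) the
    conserved glycine itself is retained as the first residue of the
    segment; with ``keep_glycine=False`` the segment starts just after it.
    """
    seq = record.residues
    gg = seq.find("GG", 0, window + 1)  # pair may straddle the window edge
    if 0 <= gg < window:
        start = gg + 1 if keep_glycine else gg + 2
        mode = "GG"
    else:
        g = seq.find("G", 0, window)
        if g >= 0:
            start = g if keep_glycine else g + 1
            mode = "G"
        else:
            return CleavedRecord(record.id, 0, "NONE", seq)
    segment = seq[start:]
    if not segment:  # glycine was the terminal residue and was dropped
        return CleavedRecord(record.id, 0, "NONE", seq)
    return CleavedRecord(record.id, start, mode, segment)
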