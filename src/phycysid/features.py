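"""The 21 physicochemical descriptors computed per (cleaved) sequence.

Composition descriptors are length-normalized fractions over the standard
20-letter alphabet (X positions are excluded from both numerator and
denominator).  Propensity and hydropathy descriptors are arithmetic means
of per-residue scale values: Chou–Fasman P(alpha)/P(beta)/P(turn) for
helix/sheet/turn propensity, Kyte–Doolittle for hydrophobicity and
Hopp–Woods for hydrophilicity.  Charge-related descriptors use a
Henderson–Hasselbalch model over termini and ionizable side chains with
the EMBOSS pKa set.  All scales and pKa values live in one registry and
can be overridden from a YAML file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio.SeqUtils import ProtParamData

from .cleave import CleavedRecord

#: frozen column order of the feature table; every model and report uses it
FEATURE_NAMES = (
    "aliphatic_fraction",
    "net_charge_ph74",
    "acidic_fraction",
    "aromatic_fyw_fraction",
    "aromatic_fywh_fraction",
    "helix_propensity",
    "hydrophilicity_index",
    "hydrophobicity_index",
    "instability_index",
    "isoelectric_point",
    "strong_basic_fraction",
    "basic_fraction",
    "helix_breaker_fraction",
    "pngs_count",
    "rna_binding_fraction",
    "redox_fraction",
    "polar_fraction",
    "length",
    "sheet_propensity",
    "hydroxyl_fraction",
    "turn_propensity",
)

# residue groups behind the composition descriptors
GROUPS: dict[str, frozenset[str]] = {
    "aliphatic_fraction": frozenset("AVILM"),
    "acidic_fraction": frozenset("DE"),
    "aromatic_fyw_fraction": frozenset("FYW"),
    "aromatic_fywh_fraction": frozenset("FYWH"),
    "strong_basic_fraction": frozenset("KR"),
    "basic_fraction": frozenset("KRH"),
    "helix_breaker_fraction": frozenset("PN"),
    # interface-enriched residues as a proxy for RNA-binding potential
    "rna_binding_fraction": frozenset("RKGSY"),
    # redox potential is carried by cysteines
    "redox_fraction": frozenset("C"),
    "polar_fraction": frozenset("STYDEHQKR"),
    "hydroxyl_fraction": frozenset("TS"),
}

# Chou-Fasman conformational propensities
CHOU_FASMAN_HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
    "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
    "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
    "W": 1.08, "Y": 0.69,
}
CHOU_FASMAN_SHEET = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
    "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30, "M": 1.05, "N": 0.89,
    "P": 0.55, "Q": 1.10, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.70,
    "W": 1.37, "Y": 1.47,
}
CHOU_FASMAN_TURN = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60, "G": 1.56,
    "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59, "M": 0.60, "N": 1.56,
    "P": 1.52, "Q": 0.98, "R": 0.95, "S": 1.43, "T": 0.96, "V": 0.50,
    "W": 0.96, "Y": 1.14,
}

#: default per-residue scale registry (swappable via load_scale_registry)
DEFAULT_SCALES: dict[str, Mapping[str, float]] = {
    "helix_propensity": CHOU_FASMAN_HELIX,
    "sheet_propensity": CHOU_FASMAN_SHEET,
    "turn_propensity": CHOU_FASMAN_TURN,
    "hydrophobicity_index": dict(ProtParamData.kd),  # Kyte-Doolittle
    "hydrophilicity_index": dict(ProtParamData.hw),  # Hopp-Woods
}

#: EMBOSS pKa values, used by both net_charge and isoelectric_point
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")

#: Guruprasad dipeptide instability weight values (DIWV)
DIWV = ProtParamData.DIWV


def load_scale_registry(path: str | Path) -> dict[str, Mapping[str, float]]:
    """Load a YAML scale registry, falling back to defaults per descriptor.

    The file maps descriptor name -> {residue: value}; any descriptor not
    present keeps its default scale.
    """
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    registry = {k: dict(v) for k, v in DEFAULT_SCALES.items()}
    for name, scale in overrides.items():
        if name not in registry:
            raise ValueError(f"unknown scale descriptor {name!r}")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(scale)
        if missing:
            raise ValueError(f"scale {name!r} missing residues {sorted(missing)}")
        registry[name] = {str(k): float(v) for k, v in scale.items()}
    return registry


def _standard(seq: str) -> str:
    """Drop X positions; the remaining residues carry the descriptors."""
    return seq.replace("X", "")


def residue_group_fraction(seq: str, group: frozenset[str] | set[str] | str) -> float:
    """Fraction of standard residues belonging to ``group``."""
    if not seq:
        raise ValueError("empty sequence")
    std = _standard(seq)
    if not std:
        raise ValueError("sequence contains no standard residues")
    group = set(group)
    return sum(1 for c in std if c in group) / len(std)


def count_sequons(seq: str) -> int:
    """Count N-glycosylation sequons N-X'-[S/T] with X' != P (overlaps allowed)."""
    if not seq:
        raise ValueError("empty sequence")
    n = 0
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            n += 1
    return n


def net_charge(seq: str, pH: float = 7.4,
               pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Net charge (elementary charges) by the Henderson–Hasselbalch sum.

    One free amino and one free carboxyl terminus are assumed; D/E/C/Y side
    chains contribute negative charge, K/R/H positive.
    """
    if not seq:
        raise ValueError("empty sequence")
    std = _standard(seq)
    if not std:
        raise ValueError("sequence contains no standard residues")

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def neg(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = pos(pka["Nterm"]) - neg(pka["Cterm"])
    for aa in _POSITIVE:
        charge += std.count(aa) * pos(pka[aa])
    for aa in _NEGATIVE:
        charge -= std.count(aa) * neg(pka[aa])
    return charge


def isoelectric_point(seq: str, pka: Mapping[str, float] = EMBOSS_PKA,
                      tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing in pH, positive at pH 0 (free amino
    terminus) and negative at pH 14 (free carboxyl terminus), so a unique
    root exists.  Bisection runs to a pH interval below 1e-6, which keeps
    |charge| at the root well under ``tol`` even for weakly buffered
    sequences.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    assert abs(net_charge(seq, mid, pka)) < tol
    return mid


def instability_index(seq: str) -> float:
    """Dipeptide-weight instability statistic: (10/L) * sum of DIWV terms.

    Computed over standard residues (X positions removed before pairing);
    requires at least two standard residues.
    """
    std = _standard(seq)
    if len(std) < 2:
        raise ValueError("instability index needs >= 2 standard residues")
    total = 0.0
    for i in range(len(std) - 1):
        total += DIWV[std[i]][std[i + 1]]
    return 10.0 / len(std) * total


def mean_scale_value(seq: str, scale: Mapping[str, float]) -> float:
    """Arithmetic mean of per-residue scale values over standard residues."""
    std = _standard(seq)
    if not std:
        raise ValueError("sequence contains no standard residues")
    missing = set(std) - set(scale)
    if missing:
        raise ValueError(f"scale missing residues {sorted(missing)}")
    return sum(scale[c] for c in std) / len(std)


def compute_features(rec: CleavedRecord | str,
                     scales: Mapping[str, Mapping[str, float]] | None = None,
                     pka: Mapping[str, float] = EMBOSS_PKA) -> pd.Series:
    """All 21 descriptors of one cleaved segment, in the frozen column order."""
    seq = rec.residues if isinstance(rec, CleavedRecord) else rec
    if not seq:
        raise ValueError("empty sequence")
    scales = scales or DEFAULT_SCALES
    values = {name: residue_group_fraction(seq, group)
              for name, group in GROUPS.items()}
    values["net_charge_ph74"] = net_charge(seq, 7.4, pka)
    values["isoelectric_point"] = isoelectric_point(seq, pka)
    values["instability_index"] = instability_index(seq)
    values["pngs_count"] = float(count_sequons(seq))
    values["length"] = float(len(seq))
    for name in ("helix_propensity", "sheet_propensity", "turn_propensity",
                 "hydrophobicity_index", "hydrophilicity_index"):
        values[name] = mean_scale_value(seq, scales[name])
    return pd.Series([values[n] for n in FEATURE_NAMES], index=FEATURE_NAMES,
                     dtype=float)


def featurize_records(records, scales=None, pka=EMBOSS_PKA) -> pd.DataFrame:
    """Feature table (rows = source ids, columns = the 21 descriptors)."""
    records = list(records)
    if not records:
        return pd.DataFrame(columns=list(FEATURE_NAMES),
                            index=pd.Index([], name="id"), dtype=float)
    rows = {}
    for rec in records:
        rid = rec.source_id if isinstance(rec, CleavedRecord) else rec.id
        rows[rid] = compute_features(
            rec if isinstance(rec, CleavedRecord) else rec.residues,
            scales=scales, pka=pka)
    table = pd.DataFrame(rows).T
    table.columns = list(FEATURE_NAMES)
    table.index.name = "id"
    return table
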