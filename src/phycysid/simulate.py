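"""Synthetic labeled sequences for training and testing without downloads.

The generator emulates the sequence grammar of the cystatin inhibitory
domain: an optional hydrophobic signal-peptide-like prefix ending at a
planted diglycine, a conserved N-terminal helix block (LARFAVDEHN-like,
more degenerate in the intronless subtypes), a central QxVxG papain
inhibitory motif, an [A/P]-W pair near the carboxy terminus and — for the
carboxy-extended type II — a second domain carrying the SNS[L/I] legumain
inhibitory motif.  Class signal is also planted in feature space:
per-subtype length ranges (single-domain ~85–125 vs two-domain ~180–220
after cleavage), acidic (I1) vs basic (I2) background shifts, N/S
enrichment for type II, and a low cysteine rate in positives versus an
elevated rate in negatives.  Negatives are background-composition decoys
of 91–249 residues, rejection-sampled to exclude the QxVxG pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ProteinRecord, SUBTYPES

QXVXG = re.compile(r"Q.V.G")

#: plant-proteome-like background composition (no C or G; both are placed
#: explicitly), renormalized at sampling time
BASE_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.052, "N": 0.042, "D": 0.052, "E": 0.065,
    "Q": 0.036, "H": 0.022, "I": 0.051, "L": 0.092, "K": 0.060,
    "M": 0.024, "F": 0.041, "P": 0.047, "S": 0.090, "T": 0.050,
    "W": 0.012, "Y": 0.028, "V": 0.066,
}

# per-subtype multiplicative composition shifts (feature-space signal)
COMPOSITION_SHIFTS: dict[str, dict[str, float]] = {
    "I1": {"D": 1.8, "E": 1.8},
    "I2": {"K": 1.8, "R": 1.8},
    "IwI": {},
    "II": {"N": 1.6, "S": 1.6},
}

#: post-cleavage core length ranges per class (inclusive); the negative
#: range is the full-sequence bound of the decoy set
LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "I1": (85, 110), "I2": (85, 110), "IwI": (95, 125), "II": (180, 220),
    "NEG": (91, 249),
}

HELIX_CONSENSUS = "LARFAVDEHN"
#: per-position substitution rate of the helix block (intron-containing
#: subtypes conserve it more strongly)
HELIX_DEGENERACY = {"I1": 0.30, "I2": 0.30, "IwI": 0.10, "II": 0.10}

#: probability that a generated positive carries >= 2 cysteines
POSITIVE_CYS2_RATE = 0.108
#: same for the negative decoys
NEGATIVE_CYS2_RATE = 0.615

SIGNAL_ALPHABET = "ALIVFMWPST"  # hydrophobic-rich, glycine-free


@dataclass
class SyntheticSpec:
    """Generator configuration; the defaults are the study conditions."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"I1": 100, "I2": 100, "IwI": 100, "II": 100,
                                 "NEG": 400})
    length_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(LENGTH_RANGES))
    signal_peptide_prob: float = 0.5
    seed: int = 42


def _freqs_for(subtype: str) -> tuple[list[str], np.ndarray]:
    freqs = dict(BASE_FREQS)
    for aa, mult in COMPOSITION_SHIFTS.get(subtype, {}).items():
        freqs[aa] = freqs[aa] * mult
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters])
    return letters, probs / probs.sum()


_NEG_LETTERS = sorted(BASE_FREQS)  # uniform decoy background


def _background(n: int, rng: np.random.Generator,
                letters, probs=None) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(letters, size=n, p=probs))


def _place_cysteines(core: list[str], protected: set[int], n_cys: int,
                     rng: np.random.Generator) -> None:
    free = [i for i in range(len(core)) if i not in protected]
    if not free or n_cys <= 0:
        return
    for i in rng.choice(free, size=min(n_cys, len(free)), replace=False):
        core[i] = "C"


def _n_cysteines(rate_ge2: float, rng: np.random.Generator) -> int:
    if rng.random() < rate_ge2:
        return int(rng.integers(2, 5))
    return int(rng.integers(0, 2))


def _helix_block(subtype: str, rng: np.random.Generator, letters, probs) -> str:
    rate = HELIX_DEGENERACY[subtype]
    out = []
    for aa in HELIX_CONSENSUS:
        if rng.random() < rate:
            out.append(str(rng.choice(letters, p=probs)))
        else:
            out.append(aa)
    return "".join(out)


def _inhibitory_domain(subtype: str, length: int, rng: np.random.Generator,
                       letters, probs) -> tuple[str, set[int]]:
    """One papain-inhibitory domain of ~``length`` residues (motifs marked)."""
    helix = _helix_block(subtype, rng, letters, probs)
    x1, x2 = rng.choice(letters, p=probs), rng.choice(letters, p=probs)
    qxvxg = f"Q{x1}V{x2}G"
    apw = str(rng.choice(["A", "P"])) + "W"
    fixed = len(helix) + len(qxvxg) + len(apw) + 3  # +3 C-terminal tail
    spare = max(length - fixed, 10)
    n1 = int(rng.integers(spare // 3, 2 * spare // 3 + 1))
    n2 = spare - n1
    parts = [helix, _background(n1, rng, letters, probs), qxvxg,
             _background(n2, rng, letters, probs), apw,
             _background(3, rng, letters, probs)]
    seq = "".join(parts)
    protected: set[int] = set()
    offset = 0
    for part, is_motif in zip(parts, (True, False, True, False, True, False)):
        if is_motif:
            protected.update(range(offset, offset + len(part)))
        offset += len(part)
    return seq, protected


def sample_phytocystatin(subtype: str, spec: SyntheticSpec,
                         rng: np.random.Generator,
                         index: int = 0) -> ProteinRecord:
    """One labeled positive: [signal]-GG-helix...QxVxG...[A/P]W[-SNS[L/I] domain]."""
    if subtype not in SUBTYPES:
        raise ValueError(f"invalid subtype {subtype!r}")
    letters, probs = _freqs_for(subtype)
    lo, hi = spec.length_ranges[subtype]
    target = int(rng.integers(lo, hi + 1))

    if subtype == "II":
        first_len = target // 2
        dom1, prot1 = _inhibitory_domain(subtype, first_len, rng, letters, probs)
        linker = _background(5, rng, letters, probs)
        dom2_len = max(target - 1 - len(dom1) - len(linker) - 4, 30)
        dom2, prot2 = _inhibitory_domain(subtype, dom2_len, rng, letters, probs)
        snsl = "SNS" + str(rng.choice(["L", "I"]))
        # legumain motif sits inside the carboxy-extended second domain
        insert_at = len(dom2) // 2
        dom2 = dom2[:insert_at] + snsl + dom2[insert_at:]
        prot2 = {i if i < insert_at else i + 4 for i in prot2}
        prot2.update(range(insert_at, insert_at + 4))
        core_list = list(dom1 + linker + dom2)
        protected = set(prot1)
        off = len(dom1) + len(linker)
        protected.update(off + i for i in prot2)
    else:
        dom, protected = _inhibitory_domain(subtype, target - 1, rng,
                                            letters, probs)
        core_list = list(dom)

    n_cys = _n_cysteines(POSITIVE_CYS2_RATE, rng)
    _place_cysteines(core_list, protected, n_cys, rng)
    core = "".join(core_list)

    prefix = ""
    if rng.random() < spec.signal_peptide_prob:
        sp_len = int(rng.integers(15, 31))
        prefix = "M" + "".join(rng.choice(list(SIGNAL_ALPHABET),
                                          size=sp_len - 1))
    residues = prefix + "G" + "G" + core  # planted GG cleavage site
    header = f"{subtype}_syn_{index:04d}"
    return ProteinRecord(id=header, description="synthetic phytocystatin",
                         residues=residues, label=subtype)


def sample_negative(spec: SyntheticSpec, rng: np.random.Generator,
                    index: int = 0) -> ProteinRecord:
    """One decoy: background composition, 91-249 residues, no QxVxG match."""
    lo, hi = spec.length_ranges["NEG"]
    for _ in range(1000):
        length = int(rng.integers(lo, hi + 1))
        seq_list = list(_background(length, rng, _NEG_LETTERS))
        # decoys keep a uniform background (including glycines) so the GG
        # cutter behaves as it would on arbitrary proteome sequences
        n_gly = max(1, length // 20)
        for i in rng.choice(length, size=n_gly, replace=False):
            seq_list[i] = "G"
        _place_cysteines(seq_list, set(),
                         _n_cysteines(NEGATIVE_CYS2_RATE, rng), rng)
        seq = "".join(seq_list)
        if not QXVXG.search(seq):
            header = f"No_syn_{index:04d}"
            return ProteinRecord(id=header, description="synthetic decoy",
                                 residues=seq, label="NEG")
    raise RuntimeError("rejection sampling failed to avoid QxVxG")


def generate_dataset(spec: SyntheticSpec) -> tuple[list[ProteinRecord],
                                                   pd.DataFrame]:
    """Labeled records plus an (id, label) truth table, seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    for subtype in SUBTYPES:
        for i in range(spec.n_per_class.get(subtype, 0)):
            records.append(sample_phytocystatin(subtype, spec, rng, i))
    for i in range(spec.n_per_class.get("NEG", 0)):
        records.append(sample_negative(spec, rng, i))
    truth = pd.DataFrame([(r.id, r.label) for r in records],
                         columns=["id", "label"])
    return records, truth
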