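"""Descriptor correctness against independent brute-force oracles.

The oracles here recompute each descriptor by explicit loops (and, for
the instability index, via Biopython's ProteinAnalysis), independently of
the vectorized implementations under test.
"""

import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import ProtParamData
from hypothesis import given, settings
from hypothesis import strategies as st

from phycysid.features import (CHOU_FASMAN_HELIX, DEFAULT_SCALES, EMBOSS_PKA,
                               FEATURE_NAMES, GROUPS, compute_features,
                               count_sequons, featurize_records,
                               instability_index, isoelectric_point,
                               load_scale_registry, mean_scale_value,
                               net_charge, residue_group_fraction)
from phycysid.cleave import CleavedRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- oracles

def oracle_charge(seq: str, pH: float) -> float:
    """Henderson-Hasselbalch sum written out longhand."""
    charge = 1.0 / (1.0 + 10.0 ** (pH - EMBOSS_PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (EMBOSS_PKA["Cterm"] - pH))
    for aa in seq:
        if aa in "KRH":
            charge += 1.0 / (1.0 + 10.0 ** (pH - EMBOSS_PKA[aa]))
        elif aa in "DECY":
            charge -= 1.0 / (1.0 + 10.0 ** (EMBOSS_PKA[aa] - pH))
    return charge


def oracle_pi(seq: str) -> float:
    """Brute-force grid search for the zero-charge pH at step 1e-4."""
    grid = np.arange(0.0, 14.0001, 1e-4)
    charges = (1.0 / (1.0 + 10.0 ** (grid - EMBOSS_PKA["Nterm"]))
               - 1.0 / (1.0 + 10.0 ** (EMBOSS_PKA["Cterm"] - grid)))
    for aa in "KRH":
        charges = charges + seq.count(aa) / (1.0 + 10.0 ** (grid - EMBOSS_PKA[aa]))
    for aa in "DECY":
        charges = charges - seq.count(aa) / (1.0 + 10.0 ** (EMBOSS_PKA[aa] - grid))
    return float(grid[np.argmin(np.abs(charges))])


def random_sequences(n, rng, min_len=5, max_len=120):
    return ["".join(rng.choice(list(AA), size=rng.integers(min_len, max_len)))
            for _ in range(n)]


# ------------------------------------------------------------ composition

@pytest.mark.parametrize("seq,group,expected", [
    ("AAAA", "AVILM", 1.0),
    ("GGGG", "AVILM", 0.0),
    ("KRHD", "KR", 0.5),
    ("AXAX", "AVILM", 1.0),  # X excluded from the denominator
])
def test_group_fractions(seq, group, expected):
    assert residue_group_fraction(seq, group) == pytest.approx(expected)


def test_group_fraction_errors():
    with pytest.raises(ValueError):
        residue_group_fraction("", "KR")
    with pytest.raises(ValueError):
        residue_group_fraction("XXX", "KR")


@pytest.mark.parametrize("seq,n", [
    ("NGS", 1), ("NPS", 0), ("NGSNGT", 2), ("NNSS", 2), ("NG", 0),
    ("NNST", 2),  # overlapping sequons count independently
])
def test_sequon_counting(seq, n):
    assert count_sequons(seq) == n


# ---------------------------------------------------------------- charge

def test_glycine_pentamer_nearly_neutral():
    assert abs(net_charge("GGGGG", 7.4)) < 0.1


def test_lysine_adds_just_under_one_charge():
    rng = np.random.default_rng(3)
    for seq in random_sequences(10, rng):
        delta = net_charge(seq + "K", 7.4) - net_charge(seq, 7.4)
        assert 0.9 < delta < 1.0


def test_charge_strictly_decreasing_in_ph():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    charges = [net_charge(seq, ph) for ph in np.linspace(0, 14, 30)]
    assert all(a > b for a, b in zip(charges, charges[1:]))


def test_pi_ordering_and_definitional_root():
    assert isoelectric_point("KKKK") > isoelectric_point("DDDD")
    rng = np.random.default_rng(4)
    for seq in random_sequences(10, rng):
        assert abs(net_charge(seq, isoelectric_point(seq))) < 1e-2


def test_pi_of_gg_matches_grid_oracle():
    assert isoelectric_point("GG") == pytest.approx(oracle_pi("GG"), abs=1e-2)


# ----------------------------------------------------------- instability

def test_instability_closed_forms():
    w = ProtParamData.DIWV["W"]["W"]
    assert instability_index("WW") == pytest.approx(10.0 / 2 * w)
    for r, L in (("A", 7), ("K", 13)):
        w = ProtParamData.DIWV[r][r]
        assert instability_index(r * L) == pytest.approx(10 * (L - 1) / L * w)
    with pytest.raises(ValueError):
        instability_index("W")


# ------------------------------------------------------------ scale means

def test_scale_mean_homopolymer_and_permutation():
    scale = DEFAULT_SCALES["helix_propensity"]
    assert mean_scale_value("AAAA", scale) == pytest.approx(scale["A"])
    assert mean_scale_value("KDEL", scale) == \
        pytest.approx(mean_scale_value("LEDK", scale))


def test_kyte_doolittle_mean_of_ailv():
    kd = ProtParamData.kd
    expected = (kd["A"] + kd["I"] + kd["L"] + kd["V"]) / 4
    assert mean_scale_value("AILV", DEFAULT_SCALES["hydrophobicity_index"]) \
        == pytest.approx(expected)


# ---------------------------------------------------- full vector + oracle

def test_oracle_equivalence_on_random_sequences():
    """Every descriptor matches its brute-force oracle to 1e-9 (pI 1e-2)."""
    rng = np.random.default_rng(12345)
    for seq in random_sequences(30, rng, min_len=10, max_len=150):
        vec = compute_features(seq)
        for name, group in GROUPS.items():
            expected = sum(1 for c in seq if c in group) / len(seq)
            assert vec[name] == pytest.approx(expected, abs=1e-9)
        assert vec["net_charge_ph74"] == \
            pytest.approx(oracle_charge(seq, 7.4), abs=1e-9)
        assert vec["isoelectric_point"] == \
            pytest.approx(oracle_pi(seq), abs=1e-2)
        pa = ProteinAnalysis(seq)
        assert vec["instability_index"] == \
            pytest.approx(pa.instability_index(), abs=1e-4)
        count = 0
        for i in range(len(seq) - 2):
            if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
                count += 1
        assert vec["pngs_count"] == count
        for name in ("helix_propensity", "sheet_propensity",
                     "turn_propensity", "hydrophobicity_index",
                     "hydrophilicity_index"):
            scale = DEFAULT_SCALES[name]
            expected = sum(scale[c] for c in seq) / len(seq)
            assert vec[name] == pytest.approx(expected, abs=1e-9)
        assert vec["length"] == len(seq)


def test_vector_shape_invariants_and_trivia():
    vec = compute_features("AAAAA")
    assert list(vec.index) == list(FEATURE_NAMES) and len(vec) == 21
    assert vec["aliphatic_fraction"] == 1.0
    assert vec["acidic_fraction"] == 0.0
    assert vec["pngs_count"] == 0 and vec["length"] == 5
    assert compute_features("CCCC")["redox_fraction"] == 1.0


@settings(max_examples=40, deadline=None)
@given(seq=st.text(alphabet=AA, min_size=2, max_size=120))
def test_subset_inequalities_and_duplication_invariance(seq):
    vec = compute_features(seq)
    fractions = [n for n in FEATURE_NAMES if n.endswith("_fraction")]
    for name in fractions:
        assert 0.0 <= vec[name] <= 1.0
    assert vec["basic_fraction"] >= vec["strong_basic_fraction"]
    assert vec["aromatic_fywh_fraction"] >= vec["aromatic_fyw_fraction"]
    assert vec["polar_fraction"] >= vec["acidic_fraction"] + \
        vec["basic_fraction"] - 1e-12
    assert vec["polar_fraction"] >= vec["hydroxyl_fraction"] - 1e-12
    # doubling the sequence preserves fractions and scale means
    doubled = compute_features(seq + seq)
    assert doubled["length"] == 2 * vec["length"]
    for name in fractions + ["helix_propensity", "hydrophobicity_index"]:
        assert doubled[name] == pytest.approx(vec[name], abs=1e-12)


def test_determinism_and_cleaved_record_input():
    v1 = compute_features("MKGQVVAGDD")
    v2 = compute_features("MKGQVVAGDD")
    assert (v1 == v2).all()
    rec = CleavedRecord("s", 2, "G", "GQVVAGDD")
    assert (compute_features(rec) == compute_features("GQVVAGDD")).all()


def test_featurize_records_table(small_corpus):
    records, _ = small_corpus
    from phycysid.pipeline import cleave_and_featurize
    table, cleaved = cleave_and_featurize(records[:5])
    assert list(table.columns) == list(FEATURE_NAMES)
    assert list(table.index) == [r.id for r in records[:5]]


def test_scale_registry_override(tmp_path):
    flat = {aa: 1.0 for aa in AA}
    p = tmp_path / "scales.yaml"
    import yaml
    p.write_text(yaml.safe_dump({"helix_propensity": flat}))
    registry = load_scale_registry(p)
    assert registry["helix_propensity"]["A"] == 1.0
    assert registry["sheet_propensity"] == DEFAULT_SCALES["sheet_propensity"]
    vec = compute_features("ADKL", scales=registry)
    assert vec["helix_propensity"] == pytest.approx(1.0)
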