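import math

import numpy as np
import pytest

from cubkit.cds_io import pooled_counts
from cubkit.cub_indices import (
    cai,
    cai_weights,
    cbi_fop,
    cub_record,
    enc_expected,
    enc_observed,
    preferred_codons,
    rscu,
    select_reference_by_enc,
    CaiWeights,
)

from .conftest import make_counts, random_counts
from .oracles import (
    SYNONYMOUS_FAMILIES,
    oracle_cai,
    oracle_cai_weights,
    oracle_enc,
    oracle_rscu,
)


# ---------------------------------------------------------------------------
# RSCU

def test_rscu_uniform_usage_is_one(code, uniform_counts):
    table = rscu(uniform_counts, code)
    assert len(table.rscu) == 59
    assert all(v == pytest.approx(1.0, abs=1e-12) for v in table.rscu.values())


def test_rscu_examples(code):
    leu = rscu(make_counts({"UUA": 2, "UUG": 4}), code)
    assert leu.rscu["UUA"] == pytest.approx(2.0)
    assert leu.rscu["UUG"] == pytest.approx(4.0)
    assert leu.rscu["CUA"] == 0.0
    lys = rscu(make_counts({"AAA": 3, "AAG": 1}), code)
    assert lys.rscu["AAA"] == pytest.approx(1.5)
    assert lys.rscu["AAG"] == pytest.approx(0.5)


def test_rscu_unobserved_family_is_nan_not_zero(code):
    table = rscu(make_counts({"AAA": 3}), code)
    assert math.isnan(table.rscu["GGG"])
    assert "G" not in table.observed_families


def test_rscu_family_sum_conservation(code):
    """For every fully observed family, RSCU sums to the family size."""
    rng = np.random.default_rng(11)
    table = {c: int(rng.integers(1, 30)) for c in code.sense_codons}
    result = rscu(make_counts(table), code).rscu
    for aa, fam in code.synonymous_families.items():
        assert sum(result[c] for c in fam) == pytest.approx(len(fam), abs=1e-9)


# ---------------------------------------------------------------------------
# ENC

def test_enc_extreme_bias_floor(code, one_per_family_counts):
    assert enc_observed(one_per_family_counts, code) == pytest.approx(20.0)


def test_enc_uniform_usage_hits_ceiling(code, uniform_counts):
    assert enc_observed(uniform_counts, code) == 61.0


def test_enc_toy_gene_matches_hand_computation(code):
    """One biased Lys family, everything else uniform, against the oracle."""
    table = {c: 10 for c in code.sense_codons}
    table["AAA"], table["AAG"] = 30, 10
    counts = make_counts(table)
    assert enc_observed(counts, code) == pytest.approx(
        oracle_enc(counts.as_dict()), abs=1e-9
    )


def test_enc_undefined_when_class_average_missing(code):
    # a single Lys family cannot support the 4- and 6-fold class averages
    assert math.isnan(enc_observed(make_counts({"AAA": 5, "AAG": 5}), code))


def test_enc_ile_class_imputed(code):
    """A gene with no Ile codons still gets an ENC via F3 = (F2+F4)/2."""
    table = {
        c: 12
        for aa, fam in code.synonymous_families.items()
        if aa != "I"
        for c in fam
    }
    counts = make_counts(table)
    value = enc_observed(counts, code)
    assert not math.isnan(value)
    assert value == pytest.approx(oracle_enc(counts.as_dict()), abs=1e-9)


@pytest.mark.parametrize(
    "s, expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
)
def test_enc_expected_curve(s, expected):
    assert enc_expected(s) == pytest.approx(expected)


def test_enc_expected_out_of_range():
    with pytest.raises(ValueError):
        enc_expected(1.2)
    with pytest.raises(ValueError):
        enc_expected(-0.1)


# ---------------------------------------------------------------------------
# CAI

def test_cai_weights_examples(code):
    w = cai_weights([make_counts({"AAA": 4})], code).w
    assert w["AAA"] == 1.0
    assert w["AAG"] == 0.01  # smoothing floor
    w = cai_weights([make_counts({"AAA": 3, "AAG": 1})], code).w
    assert w["AAA"] == pytest.approx(1.0)
    assert w["AAG"] == pytest.approx(1 / 3)


def test_cai_weights_uniform_reference_all_one(code, uniform_counts):
    w = cai_weights([uniform_counts], code).w
    assert all(v == pytest.approx(1.0) for v in w.values())


def test_cai_bounds_and_geometric_mean_identity(code):
    uniform_w = CaiWeights(
        w={c: 1.0 for c in code.sense_codons}, reference_description="test"
    )
    assert cai(make_counts({"AAA": 50, "GGC": 20}), uniform_w) == pytest.approx(1.0)
    const_w = CaiWeights(
        w={c: 0.37 for c in code.sense_codons}, reference_description="test"
    )
    assert cai(make_counts({"AAA": 5, "CCC": 3}), const_w) == pytest.approx(0.37)
    mixed = CaiWeights(
        w={c: 1.0 for c in code.sense_codons}, reference_description="test"
    )
    mixed.w["AAG"] = 0.25
    assert cai(make_counts({"AAA": 1, "AAG": 1}), mixed) == pytest.approx(0.5)


def test_cai_excludes_met_trp(code):
    w = CaiWeights(
        w={c: 1.0 for c in code.sense_codons}, reference_description="test"
    )
    w.w["AAA"] = 0.5
    # AUG/UGG carry weight 1 but must not enter the geometric mean
    val = cai(make_counts({"AAA": 2, "AUG": 50, "UGG": 50}), w)
    assert val == pytest.approx(0.5)
    assert math.isnan(cai(make_counts({"AUG": 5}), w))


def test_select_reference_by_enc_picks_most_biased(code, uniform_counts,
                                                   one_per_family_counts):
    genes = [uniform_counts] * 5 + [one_per_family_counts]
    ref, desc = select_reference_by_enc(genes, code, fraction=0.05, min_genes=1)
    assert ref == [one_per_family_counts]
    assert "lowest ENC" in desc


# ---------------------------------------------------------------------------
# CBI / FOP

def test_cbi_fop_examples(code):
    lys = make_counts({"AAA": 3, "AAG": 1})
    cbi, fop = cbi_fop(lys, {"AAA"}, code)
    assert fop == pytest.approx(0.75)
    assert cbi == pytest.approx(0.5)

    only_optimal = make_counts({"AAA": 7})
    cbi, fop = cbi_fop(only_optimal, {"AAA"}, code)
    assert (cbi, fop) == (pytest.approx(1.0), pytest.approx(1.0))


def test_cbi_zero_under_uniform_usage(code, uniform_counts):
    optimal = {fam[0] for fam in code.synonymous_families.values()}
    cbi, fop = cbi_fop(uniform_counts, optimal, code)
    assert cbi == pytest.approx(0.0, abs=1e-12)


def test_cbi_fop_input_validation(code):
    with pytest.raises(ValueError, match="empty"):
        cbi_fop(make_counts({"AAA": 1}), set(), code)
    with pytest.raises(ValueError, match="non-sense"):
        cbi_fop(make_counts({"AAA": 1}), {"UAA"}, code)


# ---------------------------------------------------------------------------
# preferred codons

def test_preferred_codons(code, uniform_counts):
    assert preferred_codons(rscu(uniform_counts, code)).count == 0  # strict >
    got = preferred_codons(rscu(make_counts({"AAA": 3, "AAG": 1}), code))
    assert got.codons == ("AAA",)
    assert got.ending_base_tally == {"A/U": 1, "G": 0, "C": 0}


def test_preferred_codons_ending_base_tally(code):
    table = {"AAA": 3, "AAG": 1, "GGG": 3, "GGC": 2, "GGA": 1, "UUC": 9, "UUU": 1}
    got = preferred_codons(rscu(make_counts(table), code))
    assert set(got.codons) == {"AAA", "GGG", "GGC", "UUC"}
    assert got.ending_base_tally == {"A/U": 1, "G": 1, "C": 2}


# ---------------------------------------------------------------------------
# cross-cutting invariants

def test_indices_invariant_under_count_scaling(code):
    rng = np.random.default_rng(3)
    base = {c: int(rng.integers(1, 12)) for c in code.sense_codons}
    a, b = make_counts(base), make_counts({c: 7 * n for c, n in base.items()})
    ra, rb = rscu(a, code).rscu, rscu(b, code).rscu
    assert all(ra[c] == pytest.approx(rb[c], abs=1e-12) for c in ra)
    w = cai_weights([a], code)
    assert cai(a, w) == pytest.approx(cai(b, w), abs=1e-12)
    # ENC carries a small-sample correction, so it is convergent rather than
    # exactly scale-free: large scalings must agree closely.
    big1 = make_counts({c: 100 * n for c, n in base.items()})
    big2 = make_counts({c: 1000 * n for c, n in base.items()})
    assert enc_observed(big1, code) == pytest.approx(
        enc_observed(big2, code), abs=0.05
    )


def test_oracle_equivalence_on_random_tables(code):
    """rscu / enc_observed / cai agree with an independent brute-force
    evaluation on 100 random small count tables to 1e-9."""
    rng = np.random.default_rng(42)
    checked_enc = 0
    for _ in range(100):
        counts = random_counts(rng)
        if counts.total_codons == 0:
            continue
        table = counts.as_dict()
        ours, theirs = rscu(counts, code).rscu, oracle_rscu(table)
        for codon in ours:
            if math.isnan(theirs[codon]):
                assert math.isnan(ours[codon])
            else:
                assert ours[codon] == pytest.approx(theirs[codon], abs=1e-9)
        enc_ours, enc_theirs = enc_observed(counts, code), oracle_enc(table)
        if math.isnan(enc_theirs):
            assert math.isnan(enc_ours)
        else:
            assert enc_ours == pytest.approx(enc_theirs, abs=1e-9)
            checked_enc += 1
        w = cai_weights([counts], code)
        assert cai(counts, w) == pytest.approx(
            oracle_cai(table, oracle_cai_weights(table)), abs=1e-9
        )
    assert checked_enc > 50  # the comparison must actually exercise ENC


def test_cub_record_assembly(code, uniform_counts):
    w = cai_weights([uniform_counts], code)
    rec = cub_record(uniform_counts, code, w, {"AAA"}, gc3s_value=0.5)
    assert rec.enc_obs == 61.0
    assert rec.enc_exp == pytest.approx(60.5)
    assert rec.deviation_ratio == pytest.approx((60.5 - 61.0) / 60.5)
    assert rec.l_aa == 61 * 60
    assert rec.cai == pytest.approx(1.0)
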