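"""Genotype I/O, the Hardy-Weinberg exact test and the QC filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autozyg.genotypes import (MISSING, GenotypeMatrix, ParseError,
                               QcThresholds, SampleRecord, Variant,
                               apply_sample_qc, apply_variant_qc,
                               hwe_exact_test, read_genotypes,
                               write_genotypes)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# File round-trips
# ---------------------------------------------------------------------------

CALLS_3x5 = [[0, 1, 2, MISSING, 1],
             [2, 2, 0, 1, 0],
             [1, 0, 1, 2, 2]]


@pytest.mark.parametrize("dialect", ["text", "binary"])
def test_roundtrip_preserves_calls(tmp_path, dialect):
    g = make_matrix(CALLS_3x5)
    write_genotypes(g, tmp_path / "toy", dialect=dialect)
    g2 = read_genotypes(tmp_path / "toy", dialect=dialect)
    assert g2.calls.shape == (3, 5)
    np.testing.assert_array_equal(g2.calls, g.calls)
    assert [v.id for v in g2.variants] == [v.id for v in g.variants]
    assert [s.status for s in g2.samples] == [s.status for s in g.samples]


def test_double_roundtrip_binary_bitwise(tmp_path):
    rng = np.random.default_rng(7)
    calls = rng.integers(-1, 3, size=(11, 37)).astype(np.int8)
    g = make_matrix(calls)
    write_genotypes(g, tmp_path / "a", dialect="binary")
    g2 = read_genotypes(tmp_path / "a", dialect="binary")
    write_genotypes(g2, tmp_path / "b", dialect="binary")
    assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


def test_non_autosomal_variants_dropped(tmp_path):
    (tmp_path / "x.map").write_text(
        "1\tv1\t0\t1000\n23\tvX\t0\t500\n1\tv2\t0\t2000\n1\tv3\t0\t3000\n"
        "1\tv4\t0\t4000\n")
    ped_rows = []
    for i in range(3):
        ped_rows.append(f"f{i} s{i} 0 0 1 1 " + " ".join(["A A"] * 5))
    (tmp_path / "x.ped").write_text("\n".join(ped_rows) + "\n")
    g = read_genotypes(tmp_path / "x", dialect="text")
    assert (g.n_samples, g.n_variants) == (3, 4)
    assert all(v.chrom in range(1, 23) for v in g.variants)


def test_variants_sorted_after_read(tmp_path):
    (tmp_path / "u.map").write_text(
        "2\tv1\t0\t100\n1\tv2\t0\t900\n1\tv3\t0\t200\n")
    (tmp_path / "u.ped").write_text("f s 0 0 2 2 " + " ".join(["A A"] * 3) + "\n")
    g = read_genotypes(tmp_path / "u", dialect="text")
    keys = [(v.chrom, v.pos_bp) for v in g.variants]
    assert keys == sorted(keys)


def test_duplicate_variant_id_rejected(tmp_path):
    (tmp_path / "d.map").write_text("1\tv1\t0\t100\n1\tv1\t0\t200\n")
    (tmp_path / "d.ped").write_text("f s 0 0 1 1 A A A A\n")
    with pytest.raises(ParseError, match="duplicate"):
        read_genotypes(tmp_path / "d", dialect="text")


def test_dimension_mismatch_names_file_and_line(tmp_path):
    (tmp_path / "m.map").write_text("1\tv1\t0\t100\n1\tv2\t0\t200\n")
    (tmp_path / "m.ped").write_text("f s 0 0 1 1 A A\n")  # one genotype short
    with pytest.raises(ParseError, match=r"m\.ped:1"):
        read_genotypes(tmp_path / "m", dialect="text")


def test_calls_alphabet_enforced():
    with pytest.raises(ValueError, match="outside"):
        GenotypeMatrix([SampleRecord(id="s")],
                       [Variant(id="v", chrom=1, pos_bp=1)],
                       np.array([[3]], dtype=np.int8))


# ---------------------------------------------------------------------------
# HWE exact test vs enumeration oracle
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration of all het counts (same allele totals).

    Exact integer weights (multinomial x 2^het) are compared before any
    float rounding, then normalised once at the end.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    def weight(h):
        aa = (n_a - h) // 2
        bb = (2 * n - n_a - h) // 2
        return (math.factorial(n) * 2**h
                // (math.factorial(aa) * math.factorial(h) * math.factorial(bb)))
    hets = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return min(1.0, sum(w for w in weights.values() if w <= obs) / total)


@pytest.mark.parametrize("counts", [(57, 14, 50), (10, 0, 10), (3, 4, 3),
                                    (0, 1, 20), (20, 20, 10), (1, 1, 1)])
def test_hwe_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-12)


def test_hwe_exhaustive_small_totals():
    for total in (1, 2, 5, 11, 25, 50):
        for n_aa in range(0, total + 1, max(1, total // 5)):
            for n_ab in range(0, total - n_aa + 1, max(1, total // 5)):
                n_bb = total - n_aa - n_ab
                assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                    hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(n_aa=st.integers(0, 25), n_ab=st.integers(0, 25),
       n_bb=st.integers(0, 25))
def test_hwe_property_matches_oracle_and_is_valid_p(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    p = hwe_exact_test(n_aa, n_ab, n_bb)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(hwe_enumeration_oracle(n_aa, n_ab, n_bb),
                              abs=1e-12)


def test_hwe_perfect_config_and_extremes():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)
    # total absence of hets at p=0.5, n=20 is extreme: p ~ 1.34e-6
    assert hwe_exact_test(10, 0, 10) == pytest.approx(
        hwe_enumeration_oracle(10, 0, 10), abs=1e-12)
    assert hwe_exact_test(10, 0, 10) < 2e-6
    assert hwe_exact_test(30, 0, 0) == 1.0  # monomorphic convention
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_chisq_option_agrees_asymptotically():
    # large balanced sample: exact and chi-square p-values are close
    p_exact = hwe_exact_test(250, 500, 250)
    p_chi = hwe_exact_test(250, 500, 250, method="chisq")
    assert p_exact > 0.9 and p_chi > 0.9


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def _qc_fixture(rng):
    """100 samples x 20 variants with 3 planted QC violations."""
    n, m = 100, 20
    calls = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
    calls[:, 5] = rng.binomial(2, 0.02, size=n)  # MAF ~0.02 < 0.05
    calls[: int(0.05 * n), 7] = MISSING          # 5% missing > 3%
    calls[:, 11] = np.where(rng.random(n) < 0.5, 0, 2)  # no hets: HWE blown
    return make_matrix(calls)


def test_variant_qc_drops_planted_violations(rng):
    g = _qc_fixture(rng)
    out, report = apply_variant_qc(g)
    assert out.n_variants == 17
    assert report == {"maf": 1, "missingness": 1, "hwe": 1}
    assert sum(report.values()) == g.n_variants - out.n_variants


def test_variant_qc_boundaries(rng):
    n = 100
    calls = rng.binomial(2, 0.3, size=(n, 3)).astype(np.int8)
    # MAF exactly 0.04 < 0.05 -> dropped; 4% missing > 3% -> dropped
    calls[:, 0] = 0
    calls[: 8, 0] = 1  # 8 copies of b in 200 alleles = 0.04
    calls[: 4, 1] = MISSING
    out, report = apply_variant_qc(g := make_matrix(calls))
    survived = [v.id for v in out.variants]
    assert "v0" not in survived and "v1" not in survived and "v2" in survived


def test_variant_qc_idempotent(rng):
    g = _qc_fixture(rng)
    once, _ = apply_variant_qc(g)
    twice, rep2 = apply_variant_qc(once)
    np.testing.assert_array_equal(once.calls, twice.calls)
    assert sum(rep2.values()) == 0


def test_surviving_maf_recomputed_independently(rng):
    g = make_matrix(rng.binomial(2, rng.uniform(0.01, 0.5, size=40),
                                 size=(80, 40)).astype(np.int8))
    out, _ = apply_variant_qc(g)
    for j in range(out.n_variants):
        col = out.calls[:, j]
        col = col[col != MISSING]
        f = col.sum() / (2 * col.size)
        assert min(f, 1 - f) >= 0.05


def test_variant_qc_requires_controls():
    g = make_matrix([[0, 1], [1, 2]], statuses=["case", "case"])
    with pytest.raises(ValueError, match="hwe_among_controls"):
        apply_variant_qc(g)
    out, _ = apply_variant_qc(g, hwe_among_controls=False)
    assert out.n_variants <= 2


def test_sample_qc_callrate_and_missing_fraction():
    rng = np.random.default_rng(3)
    calls = rng.binomial(2, 0.4, size=(3, 100)).astype(np.int8)
    calls[1, :4] = MISSING   # call rate 0.96 -> dropped
    calls[2, :2] = MISSING   # call rate 0.98 -> kept, missing_fraction 0.02
    g = make_matrix(calls, statuses=["case", "control", "control"])
    out, report = apply_sample_qc(g)
    assert [s.id for s in out.samples] == ["s0", "s2"]
    assert report == {"low_callrate": 1}
    assert out.samples[0].covariates["missing_fraction"] == 0.0
    assert out.samples[1].covariates["missing_fraction"] == pytest.approx(0.02)


def test_sample_qc_all_removed_errors():
    calls = np.full((2, 100), MISSING, dtype=np.int8)
    calls[:, :50] = 1  # 50% call rate
    with pytest.raises(ValueError, match="every sample"):
        apply_sample_qc(make_matrix(calls))


def test_qc_thresholds_validate():
    with pytest.raises(ValueError):
        QcThresholds(maf_min=0.0)
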