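"""Logistic association: closed-form oracles, PCs, burden and bin testing."""

import numpy as np
import pandas as pd
import pytest

from autozyg.association import BinGrid, assign_bins, compute_pcs, \
    covariate_frame, fit_logistic
from autozyg.association import test_bins as bin_association
from autozyg.association import test_burden as burden_association
from autozyg.genotypes import SampleRecord
from autozyg.metrics import PROFILE_COLUMNS
from autozyg.roh import RohSegment, segments_to_frame
from conftest import make_matrix


def two_by_two(a, b, c, d):
    """Exposure/outcome vectors for a 2x2 table (a=exposed cases)."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    e = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return y, e


# ---------------------------------------------------------------------------
# fit_logistic
# ---------------------------------------------------------------------------

def test_logistic_matches_closed_form_odds_ratio():
    y, e = two_by_two(10, 20, 30, 40)
    r = fit_logistic(y, e)
    assert r.beta == pytest.approx(np.log(10 * 40 / (20 * 30)), abs=1e-6)
    assert r.se == pytest.approx(np.sqrt(1/10 + 1/20 + 1/30 + 1/40), abs=1e-6)
    assert r.n_case == 30 and r.n_control == 70
    assert r.converged


@pytest.mark.parametrize("table", [(5, 9, 4, 12), (40, 12, 7, 33),
                                   (15, 15, 15, 15), (3, 50, 8, 60)])
def test_logistic_closed_form_random_tables(table):
    a, b, c, d = table
    y, e = two_by_two(a, b, c, d)
    r = fit_logistic(y, e)
    assert r.beta == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
    assert r.se == pytest.approx(np.sqrt(1/a + 1/b + 1/c + 1/d), abs=1e-6)


def test_logistic_rejects_degenerate_inputs():
    y = np.r_[np.ones(5), np.zeros(5)]
    with pytest.raises(ValueError, match="zero-variance"):
        fit_logistic(y, np.ones(10))
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(np.ones(10), np.arange(10.0))


def test_logistic_drops_constant_covariate():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200).astype(float)
    y[:5] = 1; y[5:10] = 0
    e = rng.normal(size=200)
    cov = np.column_stack([np.full(200, 1.7), rng.normal(size=200)])
    r = fit_logistic(y, e, cov, covariate_names=["sex", "age"])
    assert r.dropped_covariates == ["sex"]
    assert r.converged


def test_logistic_separation_flagged_not_converged():
    y = np.r_[np.ones(20), np.zeros(20)]
    e = np.r_[np.ones(20), np.zeros(20)].astype(float)  # perfect separation
    r = fit_logistic(y, e)
    assert not r.converged


def test_rescaling_equivariance():
    rng = np.random.default_rng(4)
    froh_vals = rng.exponential(0.005, size=400)
    y = (rng.random(400) < 1 / (1 + np.exp(-(-0.5 + 30 * froh_vals)))).astype(float)
    if y.sum() in (0, len(y)):
        pytest.skip("degenerate draw")
    r1 = fit_logistic(y, froh_vals)
    r2 = fit_logistic(y, froh_vals * 100.0)
    assert r2.beta * 100.0 == pytest.approx(r1.beta, rel=1e-6)
    assert r2.se * 100.0 == pytest.approx(r1.se, rel=1e-6)
    assert r2.p == pytest.approx(r1.p, abs=1e-9)


def test_null_type_one_error_near_nominal():
    """Wald test on independent exposure rejects ~5% of the time."""
    rng = np.random.default_rng(99)
    n, reps, alpha = 400, 200, 0.05
    rejections = 0
    for _ in range(reps):
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        e = rng.normal(size=n)
        r = fit_logistic(y, e)
        rejections += r.p < alpha
    rate = rejections / reps
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rate - alpha) < 3 * se


def test_firth_close_to_mle_when_well_behaved():
    y, e = two_by_two(30, 30, 20, 40)
    r_mle = fit_logistic(y, e)
    r_f = fit_logistic(y, e, firth=True)
    assert r_f.beta == pytest.approx(r_mle.beta, abs=0.1)
    assert r_f.converged


# ---------------------------------------------------------------------------
# compute_pcs
# ---------------------------------------------------------------------------

def test_pcs_separate_planted_subpopulations(rng):
    m, n_half = 400, 60
    p1 = rng.uniform(0.1, 0.9, size=m)
    shift = np.where(rng.random(m) < 0.5, 0.25, -0.25)
    p2 = np.clip(p1 + shift, 0.05, 0.95)
    calls = np.vstack([rng.binomial(2, p1, size=(n_half, m)),
                       rng.binomial(2, p2, size=(n_half, m))]).astype(np.int8)
    g = make_matrix(calls)
    scores = compute_pcs(g, k=2)
    pc1 = scores[:, 0]
    g1, g2 = pc1[:n_half], pc1[n_half:]
    pooled_sd = np.sqrt((g1.var(ddof=1) + g2.var(ddof=1)) / 2)
    assert abs(g1.mean() - g2.mean()) > 4 * pooled_sd


def test_pcs_identical_rows_rank_deficient():
    calls = np.tile(np.array([0, 1, 2, 1, 0] * 4, dtype=np.int8), (30, 1))
    with pytest.raises(ValueError, match="rank"):
        compute_pcs(make_matrix(calls), k=5)


def test_pcs_deterministic_and_unit_variance(rng):
    calls = rng.integers(0, 3, size=(50, 300)).astype(np.int8)
    g = make_matrix(calls)
    a = compute_pcs(g, k=4)
    b = compute_pcs(g, k=4)
    np.testing.assert_array_equal(a, b)
    np.testing.assert_allclose(a.std(axis=0, ddof=1), 1.0, rtol=1e-9)


# ---------------------------------------------------------------------------
# test_burden
# ---------------------------------------------------------------------------

def _profiles(samples, froh_vals, f3_vals=None):
    f3_vals = f3_vals if f3_vals is not None else np.zeros(len(samples))
    return pd.DataFrame({
        "sample_id": [s.id for s in samples], "n_roh": 1,
        "total_roh_kb": np.asarray(froh_vals) * 3e6,
        "froh": froh_vals, "f3": f3_vals, "missing_fraction": 0.0,
    }, columns=PROFILE_COLUMNS)


def _samples_with_status(y, study="S1", sex=None):
    return [SampleRecord(id=f"s{i}", status="case" if yi else "control",
                         subtype="CLL" if yi else "none", age=60.0,
                         sex=(sex or ("male" if i % 2 else "female")),
                         study=study)
            for i, yi in enumerate(y)]


def test_burden_recovers_planted_effect(rng):
    n = 3000
    froh_vals = rng.exponential(0.005, size=n)
    true_beta = 20.0
    logit = -0.2 + true_beta * froh_vals
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    samples = _samples_with_status(y)
    r = burden_association(samples, _profiles(samples, froh_vals), metric="froh")
    assert abs(r.beta - true_beta) < 2 * r.se
    # per-0.1%-FROH interpretation: log-OR scales by 0.001
    assert np.exp(0.001 * r.beta) - 1 < 0.10


def test_burden_filters_and_errors(rng):
    y = np.r_[np.ones(40), np.zeros(40)].astype(int)
    samples = _samples_with_status(y)
    prof = _profiles(samples, rng.exponential(0.005, size=80))
    case_ids = {s.id for s in samples if s.status == "case"}
    with pytest.raises(ValueError, match="one outcome class"):
        burden_association(samples, prof, metric="froh", exclude_samples=case_ids)
    with pytest.raises(ValueError, match="unknown metric"):
        burden_association(samples, prof, metric="bogus")
    r_all = burden_association(samples, prof, metric="froh")
    r_sub = burden_association(samples, prof, metric="froh", subset_studies={"S1"})
    assert r_all.beta == r_sub.beta


def test_burden_single_sex_study_drops_sex(rng):
    y = np.r_[np.ones(50), np.zeros(50)].astype(int)
    samples = _samples_with_status(y, sex="female")
    prof = _profiles(samples, rng.exponential(0.005, size=100))
    r = burden_association(samples, prof, metric="froh")
    assert "sex" in r.dropped_covariates


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------

def test_bin_grid_tiles_chromosomes():
    grid = BinGrid.from_chrom_ends({1: 1_200_000, 2: 400_000})
    assert grid.bins == ((1, 1, 500_000), (1, 500_001, 1_000_000),
                         (1, 1_000_001, 1_500_000), (2, 1, 500_000))


def test_assign_bins_midpoint_rule():
    grid = BinGrid.from_chrom_ends({3: 3_000_000})
    segs = segments_to_frame([
        RohSegment(sample_id="a", chrom=3, start_bp=1_200_000,
                   end_bp=2_700_000, n_snps=150)])
    exp = assign_bins(segs, grid, ["a", "b"])
    assert exp.loc["a", "chr3:1500001-2000000"]
    assert exp.loc["a"].sum() == 1
    assert exp.loc["b"].sum() == 0  # sample without segments: all-zero row


def test_assign_bins_indicator_not_count():
    grid = BinGrid.from_chrom_ends({1: 4_000_000})
    segs = segments_to_frame([
        RohSegment(sample_id="a", chrom=1, start_bp=1_600_000,
                   end_bp=1_800_000, n_snps=150),
        RohSegment(sample_id="a", chrom=1, start_bp=1_850_000,
                   end_bp=1_950_000, n_snps=150)])
    exp = assign_bins(segs, grid, ["a"])
    assert exp.to_numpy().sum() == 1  # both midpoints in one bin


def test_bin_exposure_row_sums_bounded_by_segment_counts(rng):
    grid = BinGrid.from_chrom_ends({1: 50_000_000})
    segs = []
    counts = {}
    for i in range(20):
        sid = f"s{i}"
        counts[sid] = int(rng.integers(0, 5))
        for k in range(counts[sid]):
            start = int(rng.integers(1, 45_000_000))
            segs.append(RohSegment(sample_id=sid, chrom=1, start_bp=start,
                                   end_bp=start + 2_000_000, n_snps=150))
    exp = assign_bins(segments_to_frame(segs), grid, list(counts))
    for sid, c in counts.items():
        assert exp.loc[sid].sum() <= c


def test_bins_skip_rules_and_recovery(rng):
    n = 4000
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    samples = _samples_with_status(y)
    grid = BinGrid.from_chrom_ends({1: 1_500_000})
    exp = pd.DataFrame(False, index=[s.id for s in samples],
                       columns=["chr1:1-500000", "chr1:500001-1000000",
                                "chr1:1000001-1500000"])
    # bin 0: planted OR=3 exposure, ~500 exposed
    p_case, p_ctrl = 0.19, 0.072  # odds 3x
    exp.iloc[:n // 2, 0] = rng.random(n // 2) < p_case
    exp.iloc[n // 2:, 0] = rng.random(n // 2) < p_ctrl
    # bin 1: exposed in cases only (one-arm); bin 2: nobody
    exp.iloc[:10, 1] = True
    tab = bin_association(samples, exp, grid, min_exposed=5)
    assert tab.loc[1, "status"] == "skipped:one_arm_exposure"
    assert tab.loc[2, "status"] == "skipped:few_exposed"
    assert tab.loc[0, "status"] == "ok"
    assert abs(tab.loc[0, "beta"] - np.log(3)) < 2 * tab.loc[0, "se"]


def test_bins_all_unexposed_all_skipped():
    y = np.r_[np.ones(10), np.zeros(10)].astype(int)
    samples = _samples_with_status(y)
    grid = BinGrid.from_chrom_ends({1: 1_000_000})
    exp = assign_bins(segments_to_frame([]), grid, [s.id for s in samples])
    tab = bin_association(samples, exp, grid)
    assert (tab["status"] == "skipped:few_exposed").all()
    assert tab["beta"].isna().all()
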