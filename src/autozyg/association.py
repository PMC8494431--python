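"""Covariate-adjusted case-control association of homozygosity burden.

Per-study logistic regression of case status on a burden metric (FROH or
F3) or on per-bin ROH exposure, adjusting for age, sex, fraction of missing
SNPs and principal components of ancestry.  Constant covariate columns
(e.g. sex in a single-sex study) are dropped automatically with a logged
warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.utils.extmath import randomized_svd

from .genotypes import MISSING, GenotypeMatrix, SampleRecord

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "missing_fraction") + tuple(
    f"PC{i}" for i in range(1, 11))


@dataclass
class AssocResult:
    """One logistic association estimate (log-odds per unit exposure)."""

    exposure_name: str
    beta: float
    se: float
    p: float
    n_case: int
    n_control: int
    converged: bool
    dropped_covariates: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def compute_pcs(g: GenotypeMatrix, k: int = 10, *,
                random_state: int = 0) -> np.ndarray:
    """Top-``k`` principal-component scores of standardized genotypes.

    Variants are standardized by mean 2p and sd sqrt(2p(1-p)); missing
    calls are mean-imputed for this step only.  Scores have unit variance
    and a deterministic sign (each component's loading sum is positive).
    """
    if g.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} PCs")
    x = g.calls.astype(float)
    obs = g.calls != MISSING
    p = g.allele_b_freqs()
    mean = 2.0 * p
    sd = np.sqrt(np.clip(2.0 * p * (1.0 - p), 0.0, None))
    x = np.where(obs, x, mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[:, ~(sd > 0)] = 0.0
    z[:, ~np.isfinite(p)] = 0.0
    u, s, vt = randomized_svd(z, n_components=min(k + 2, min(z.shape)),
                              random_state=random_state)
    tol = max(1.0, float(s[0]) if s.size else 0.0) * 1e-8
    rank = int((s > tol).sum())
    if rank < k:
        raise ValueError(f"genotype matrix rank {rank} < requested k={k}")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if vt[j].sum() < 0:
            scores[:, j] *= -1.0
    col_sd = scores.std(axis=0, ddof=1)
    return scores / col_sd


def attach_pcs(samples: list[SampleRecord], scores: np.ndarray) -> None:
    for i, s in enumerate(samples):
        for j in range(scores.shape[1]):
            s.covariates[f"PC{j + 1}"] = float(scores[i, j])


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _firth_fit(y: np.ndarray, X: np.ndarray, maxiter: int = 50,
               tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth-penalized logistic MLE (Jeffreys-prior score correction)."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        beta = beta + info_inv @ score
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta)))
                   + 0.5 * np.linalg.slogdet(info)[1])
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.pinv((X.T * (mu * (1 - mu))) @ X)
    return beta, np.sqrt(np.diag(cov)), converged


def fit_logistic(y: np.ndarray, exposure: np.ndarray,
                 covariates: np.ndarray | pd.DataFrame | None = None,
                 *, exposure_name: str = "exposure",
                 covariate_names: list[str] | None = None,
                 firth: bool = False, maxiter: int = 50) -> AssocResult:
    """Logistic ML fit of case status on exposure plus covariates.

    Maximum likelihood by iteratively reweighted least squares (Newton);
    Wald SE from the observed-information inverse.  Constant covariate
    columns are dropped with a warning; detected separation or
    non-convergence yields ``converged=False`` with diagnostics in the log.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("y must be binary with both classes present")
    exposure = np.asarray(exposure, dtype=float)
    if not np.all(np.isfinite(exposure)):
        raise ValueError("exposure contains non-finite values")
    if np.ptp(exposure) == 0.0:
        raise ValueError("zero-variance exposure")

    cols = [np.ones_like(y), exposure]
    names = ["const", exposure_name]
    dropped: list[str] = []
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = list(covariates.columns)
            covariates = covariates.to_numpy(dtype=float)
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.size:
            covariates = covariates.T
        if covariate_names is None:
            covariate_names = [f"cov{j}" for j in range(covariates.shape[1])]
        if not np.all(np.isfinite(covariates)):
            raise ValueError("covariates contain non-finite values")
        for j, name in enumerate(covariate_names):
            col = covariates[:, j]
            if np.ptp(col) == 0.0:
                dropped.append(name)
                logger.warning("dropping constant covariate %r", name)
            else:
                cols.append(col)
                names.append(name)
    X = np.column_stack(cols)

    n_case = int(y.sum())
    n_control = int(y.size - n_case)
    if firth:
        beta_v, se_v, ok = _firth_fit(y, X, maxiter=maxiter)
        idx = names.index(exposure_name)
        beta, se = float(beta_v[idx]), float(se_v[idx])
        p = 2.0 * float(norm.sf(abs(beta / se))) if se > 0 else np.nan
        return AssocResult(exposure_name, beta, se, max(p, 0.0), n_case,
                           n_control, ok, dropped)

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=maxiter, method="newton")
        except Exception as exc:  # separation raises in some statsmodels paths
            logger.warning("logistic fit failed (%s); refitting with Firth "
                           "diagnostics", exc)
            beta_v, se_v, _ = _firth_fit(y, X, maxiter=maxiter)
            idx = names.index(exposure_name)
            return AssocResult(exposure_name, float(beta_v[idx]),
                               float(se_v[idx]), np.nan, n_case, n_control,
                               False, dropped)
        for w in caught:
            if "separation" in str(w.message).lower():
                converged = False
    if not res.mle_retvals.get("converged", True):
        converged = False
    idx = names.index(exposure_name)
    beta = float(res.params[idx])
    se = float(res.bse[idx])
    if converged and (not np.isfinite(se) or se > 1e4):
        converged = False
    p = 2.0 * float(norm.sf(abs(beta / se))) if se > 0 else np.nan
    return AssocResult(exposure_name, beta, se, p, n_case, n_control,
                       converged, dropped)


# ---------------------------------------------------------------------------
# Burden testing
# ---------------------------------------------------------------------------

_SEX_NUM = {"male": 1.0, "female": 0.0, "unknown": np.nan}


def covariate_frame(samples: list[SampleRecord],
                    names: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric covariate matrix for the standard adjustment set.

    Covariates absent for every sample (e.g. PCs that were never computed)
    are omitted; sex is coded male=1/female=0.
    """
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name == "age":
            vals = np.array([s.age for s in samples], dtype=float)
        elif name == "sex":
            vals = np.array([_SEX_NUM.get(s.sex, np.nan) for s in samples])
        else:
            vals = np.array([s.covariates.get(name, np.nan) for s in samples])
        if np.all(np.isnan(vals)):
            continue
        cols[name] = vals
    return pd.DataFrame(cols, index=[s.id for s in samples])


def test_burden(samples: list[SampleRecord], profiles: pd.DataFrame,
                metric: str = "froh", *,
                exclude_samples: set[str] | None = None,
                subset_studies: set[str] | None = None,
                covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
                firth: bool = False) -> AssocResult:
    """Covariate-adjusted burden association for one study cohort.

    ``metric`` is a column of ``profiles`` (froh or f3); β is the log-odds
    per unit of the metric, so β·0.001 is the log-OR per 0.1% FROH.
    Sensitivity filters drop named samples or restrict to named studies
    before fitting.
    """
    if metric not in profiles.columns:
        raise ValueError(f"unknown metric {metric!r}")
    prof = profiles.set_index("sample_id")
    keep = []
    for s in samples:
        if exclude_samples and s.id in exclude_samples:
            continue
        if subset_studies is not None and s.study not in subset_studies:
            continue
        if s.id in prof.index:
            keep.append(s)
    if not keep:
        raise ValueError("no samples left after filters")
    y = np.array([1.0 if s.status == "case" else 0.0 for s in keep])
    if len(np.unique(y)) < 2:
        raise ValueError("only one outcome class present after filters")
    exposure = prof.loc[[s.id for s in keep], metric].to_numpy(dtype=float)
    cov = covariate_frame(keep, covariate_names)
    cov = cov.dropna(axis=1, how="any")
    return fit_logistic(y, exposure, cov if len(cov.columns) else None,
                        exposure_name=metric, firth=firth)


# ---------------------------------------------------------------------------
# 500-kb bin scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of each autosome, 1-based inclusive bin bounds."""

    width_bp: int
    bins: tuple[tuple[int, int, int], ...]  # (chrom, start_bp, end_bp)

    @classmethod
    def from_chrom_ends(cls, chrom_last_bp: dict[int, int],
                        width_bp: int = 500_000) -> "BinGrid":
        bins = []
        for c in sorted(chrom_last_bp):
            last = chrom_last_bp[c]
            n = (last + width_bp - 1) // width_bp
            for i in range(n):
                bins.append((c, i * width_bp + 1, (i + 1) * width_bp))
        return cls(width_bp=width_bp, bins=tuple(bins))

    @classmethod
    def from_variants(cls, variants, width_bp: int = 500_000) -> "BinGrid":
        last: dict[int, int] = {}
        for v in variants:
            last[v.chrom] = max(last.get(v.chrom, 0), v.pos_bp)
        return cls.from_chrom_ends(last, width_bp)

    def bin_index(self, chrom: int, pos_bp: int) -> int:
        """Flat index of the bin containing a 1-based position."""
        for i, (c, a, b) in enumerate(self.bins):
            if c == chrom and a <= pos_bp <= b:
                return i
        raise KeyError(f"position {chrom}:{pos_bp} outside grid")


def assign_bins(segments: pd.DataFrame, grid: BinGrid,
                sample_ids: list[str]) -> pd.DataFrame:
    """Sample x bin ROH-exposure indicators by segment midpoint.

    A segment's midpoint floor((start+end)/2) places it in exactly one bin;
    a sample is exposed at a bin iff at least one of its segments lands
    there (indicator, not count).
    """
    chrom_offset: dict[int, int] = {}
    for i, (c, a, _) in enumerate(grid.bins):
        if a == 1:
            chrom_offset[c] = i
    exp = np.zeros((len(sample_ids), len(grid.bins)), dtype=bool)
    sidx = {sid: i for i, sid in enumerate(sample_ids)}
    if len(segments):
        mid = (segments["start_bp"].to_numpy() + segments["end_bp"].to_numpy()) // 2
        for sid, c, m in zip(segments["sample_id"], segments["chrom"], mid):
            if c not in chrom_offset:
                raise KeyError(f"grid does not cover chromosome {c}")
            j = chrom_offset[int(c)] + (int(m) - 1) // grid.width_bp
            if j >= len(grid.bins) or grid.bins[j][0] != c:
                raise KeyError(f"midpoint {c}:{m} outside grid")
            exp[sidx[sid], j] = True
    labels = [f"chr{c}:{a}-{b}" for c, a, b in grid.bins]
    return pd.DataFrame(exp, index=sample_ids, columns=labels)


def test_bins(samples: list[SampleRecord], exposures: pd.DataFrame,
              grid: BinGrid, *, min_exposed: int = 5,
              covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
              firth: bool = False) -> pd.DataFrame:
    """Per-bin logistic association with the standard covariate set.

    Bins with fewer than ``min_exposed`` exposed individuals overall, or
    with all exposure in one arm, are reported as skipped with a reason.
    """
    order = [s.id for s in samples]
    exp = exposures.loc[order]
    y = np.array([1.0 if s.status == "case" else 0.0 for s in samples])
    cov = covariate_frame(samples, covariate_names).dropna(axis=1, how="any")
    constant = [c for c in cov.columns if np.ptp(cov[c].to_numpy()) == 0.0]
    if constant:
        logger.warning("bin scan: dropping constant covariates %s", constant)
        cov = cov.drop(columns=constant)
    cov_arg = cov if len(cov.columns) else None
    rows = []
    for j, (c, a, b) in enumerate(grid.bins):
        e = exp.iloc[:, j].to_numpy(dtype=float)
        n_exposed = int(e.sum())
        status, beta, se, p = "ok", np.nan, np.nan, np.nan
        if n_exposed < min_exposed:
            status = "skipped:few_exposed"
        elif e[y == 1].sum() == 0 or e[y == 0].sum() == 0:
            status = "skipped:one_arm_exposure"
        elif n_exposed == y.size:
            status = "skipped:all_exposed"
        else:
            r = fit_logistic(y, e, cov_arg, exposure_name="bin", firth=firth)
            beta, se, p = r.beta, r.se, r.p
            if not r.converged:
                status = "not_converged"
        rows.append((c, a, b, n_exposed, beta, se, p, status))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end",
                                       "n_exposed", "beta", "se", "p",
                                       "status"])
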