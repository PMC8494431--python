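"""Cross-study combination of association estimates.

DerSimonian-Laird random effects for burden metrics and inverse-variance
fixed effects for the bin scan, with Cochran's Q, I², τ², leave-one-out
sensitivity rows and Bonferroni multiple-testing control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm


@dataclass(frozen=True)
class StudyEstimate:
    study: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"study {self.study}: beta/se must be finite, se > 0")


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    p: float
    k: int
    Q: float
    tau2: float
    i2: float  # percentage in [0, 100]
    p_het: float


def _heterogeneity(betas: np.ndarray, ses: np.ndarray
                   ) -> tuple[float, float, float, float, float]:
    """Fixed-effect mean, Q, tau², I² (%) and p_het from per-study (β, SE)."""
    w = 1.0 / ses**2
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    k = betas.size
    Q = float(np.sum(w * (betas - beta_fe) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
        p_het = float(chi2.sf(Q, df=k - 1))
    else:
        tau2, i2, p_het = 0.0, 0.0, 1.0
    return beta_fe, Q, tau2, i2, p_het


def dl_random_effects(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooled estimate.

    Method-of-moments τ² from Cochran's Q with weights 1/SE²; pooled β uses
    re-weights 1/(SE² + τ²).  A single study is returned unchanged.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one study estimate")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    _, Q, tau2, i2, p_het = _heterogeneity(betas, ses)
    w_star = 1.0 / (ses**2 + tau2)
    beta_re = float(np.sum(w_star * betas) / np.sum(w_star))
    se_re = float(np.sum(w_star) ** -0.5)
    p = 2.0 * float(norm.sf(abs(beta_re / se_re)))
    return MetaResult(beta_re, se_re, p, len(estimates), Q, tau2, i2, p_het)


def ivw_fixed_effects(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooled estimate."""
    if len(estimates) == 0:
        raise ValueError("need at least one study estimate")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    beta_fe, Q, tau2, i2, p_het = _heterogeneity(betas, ses)
    se_fe = float(np.sum(1.0 / ses**2) ** -0.5)
    p = 2.0 * float(norm.sf(abs(beta_fe / se_fe)))
    return MetaResult(beta_fe, se_fe, p, len(estimates), Q, tau2, i2, p_het)


_METHODS = {"dl": dl_random_effects, "ivw": ivw_fixed_effects}


def leave_one_out(estimates: Sequence[StudyEstimate],
                  method: str = "dl") -> pd.DataFrame:
    """Meta-analysis omitting each study in turn (heterogeneity diagnostics)."""
    if len(estimates) < 2:
        raise ValueError("leave-one-out needs at least two studies")
    fn = _METHODS[method]
    rows = []
    for i, omitted in enumerate(estimates):
        rest = [e for j, e in enumerate(estimates) if j != i]
        r = fn(rest)
        rows.append({"omitted": omitted.study, "beta": r.beta, "se": r.se,
                     "p": r.p, "k": r.k, "Q": r.Q, "tau2": r.tau2,
                     "i2": r.i2, "p_het": r.p_het})
    return pd.DataFrame(rows)


def bonferroni(p_values: Sequence[float], n_tests: int
               ) -> tuple[float, np.ndarray]:
    """Adjusted α = 0.05 / n_tests and per-p significance flags."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    alpha_adj = 0.05 / n_tests
    flags = np.asarray(p_values, dtype=float) < alpha_adj
    return alpha_adj, flags


def meta_bins(per_study_tables: dict[str, pd.DataFrame],
              method: str = "ivw") -> pd.DataFrame:
    """Combine per-bin association tables across studies.

    Bins are matched on (chrom, bin_start, bin_end); only studies where the
    bin's status is ``ok`` contribute.  Bonferroni flags use the number of
    combinable bins as the number of tests.
    """
    fn = _METHODS[method]
    key = ["chrom", "bin_start", "bin_end"]
    merged: dict[tuple, list[StudyEstimate]] = {}
    n_exposed: dict[tuple, int] = {}
    for study, tab in per_study_tables.items():
        ok = tab[tab["status"] == "ok"]
        for _, row in ok.iterrows():
            kk = (int(row["chrom"]), int(row["bin_start"]), int(row["bin_end"]))
            merged.setdefault(kk, []).append(
                StudyEstimate(study, float(row["beta"]), float(row["se"])))
            n_exposed[kk] = n_exposed.get(kk, 0) + int(row["n_exposed"])
    rows = []
    for kk in sorted(merged):
        r = fn(merged[kk])
        rows.append(kk + (n_exposed[kk], r.k, r.beta, r.se, r.p, r.Q,
                          r.tau2, r.i2, r.p_het))
    out = pd.DataFrame(rows, columns=key + ["n_exposed", "k", "beta", "se",
                                            "p", "Q", "tau2", "i2", "p_het"])
    if len(out):
        alpha_adj, flags = bonferroni(out["p"].to_numpy(), len(out))
        out["bonferroni_alpha"] = alpha_adj
        out["bonferroni_significant"] = flags
    else:
        out["bonferroni_alpha"] = np.nan
        out["bonferroni_significant"] = np.array([], dtype=bool)
    return out
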