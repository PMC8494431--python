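"""Per-sample genome-wide homozygosity burden: FROH and the F3 estimator.

FROH is the fraction of the autosome covered by called ROH segments,
Σ segment lengths (bp) / 3x10⁹.  The denominator stays fixed under
chromosome exclusion so that association coefficients remain comparable
across sensitivity runs (an optional flag renormalises it instead).

F3 is the genotype-based "correlation between uniting gametes" inbreeding
estimator: with genotype x in {0,1,2} copies of an allele at frequency p,
the per-SNP term is

    [x² − (1 + 2p)·x + 2p²] / [2p(1 − p)]

averaged over included non-missing SNPs.  Its expectation is 0 under
Hardy-Weinberg equilibrium and it may be negative in outbred individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .roh import RohSegment

AUTOSOME_BP: float = 3e9

PROFILE_COLUMNS = ["sample_id", "n_roh", "total_roh_kb", "froh", "f3",
                   "missing_fraction"]


@dataclass(frozen=True)
class HomozygosityProfile:
    sample_id: str
    n_roh: int
    total_roh_kb: float
    froh: float
    f3: float
    missing_fraction: float


def froh(segments: Iterable[RohSegment] | pd.DataFrame,
         exclude_chroms: Collection[int] = (),
         *, renormalize: bool = False,
         autosome_bp: float = AUTOSOME_BP,
         chrom_lengths_bp: dict[int, int] | None = None) -> float:
    """Fraction of the autosome covered by ROH for one sample's segments.

    ``renormalize=True`` shrinks the denominator by the excluded
    chromosomes' lengths (requires ``chrom_lengths_bp``); the default keeps
    the full-autosome denominator.
    """
    excl = set(exclude_chroms)
    if isinstance(segments, pd.DataFrame):
        keep = ~segments["chrom"].isin(excl)
        total_bp = float((segments.loc[keep, "end_bp"]
                          - segments.loc[keep, "start_bp"] + 1).sum())
    else:
        total_bp = float(sum(s.length_bp for s in segments
                             if s.chrom not in excl))
    denom = autosome_bp
    if renormalize and excl:
        if chrom_lengths_bp is None:
            raise ValueError("renormalize requires chrom_lengths_bp")
        denom = autosome_bp - sum(chrom_lengths_bp.get(c, 0) for c in excl)
    return total_bp / denom


def f3_terms(calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-SNP F3 terms; NaN where the call is missing or p is degenerate."""
    x = np.asarray(calls, dtype=float)
    p = np.asarray(freqs, dtype=float)
    usable = (np.asarray(calls) != MISSING) & (p > 0.0) & (p < 1.0) & np.isfinite(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))
    return np.where(usable, t, np.nan)


def f3(calls: np.ndarray, freqs: np.ndarray,
       chroms: np.ndarray | None = None,
       exclude_chroms: Collection[int] = ()) -> float:
    """F3 for one sample: mean per-SNP term over usable included SNPs."""
    terms = f3_terms(calls, freqs)
    if exclude_chroms:
        if chroms is None:
            raise ValueError("exclude_chroms requires per-SNP chromosomes")
        terms = np.where(np.isin(np.asarray(chroms), list(exclude_chroms)),
                         np.nan, terms)
    n_used = np.isfinite(terms).sum()
    if n_used == 0:
        raise ValueError("no usable SNPs for F3 (all missing or degenerate p)")
    return float(np.nanmean(terms))


def profile_cohort(g: GenotypeMatrix, segments: pd.DataFrame,
                   exclude_chroms: Collection[int] = (),
                   *, freqs: np.ndarray | None = None) -> pd.DataFrame:
    """One homozygosity-burden row per sample.

    Allele frequencies for F3 default to the study's own non-missing calls
    (cases + controls), mirroring per-study analysis.
    """
    if freqs is None:
        freqs = g.allele_b_freqs()
    chroms = g.chrom_array()
    excl = set(exclude_chroms)
    include = ~np.isin(chroms, list(excl)) if excl else np.ones(g.n_variants, bool)

    calls = g.calls[:, include]
    p = np.asarray(freqs, dtype=float)[include]
    valid_p = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    # per-genotype term values: x=0 -> p/(1-p), x=1 -> -1, x=2 -> (1-p)/p
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = np.where(valid_p, p / (1.0 - p), 0.0)
        w2 = np.where(valid_p, (1.0 - p) / p, 0.0)
    valid_f = valid_p.astype(np.float64)
    n = calls.shape[0]
    f3_sum = np.empty(n)
    n_used = np.empty(n)
    for lo in range(0, n, 256):  # chunked to keep temporaries in cache
        b = calls[lo:lo + 256]
        f3_sum[lo:lo + 256] = ((b == 0) @ w0 + (b == 2) @ w2
                               - (b == 1) @ valid_f)
        n_used[lo:lo + 256] = (b != MISSING) @ valid_f
    if calls.shape[1] == 0:
        # every chromosome excluded: FROH is 0 by construction, F3 undefined
        f3_sum[:] = np.nan
        n_used[:] = 1.0
    if g.n_variants and np.any(n_used == 0):
        raise ValueError("a sample has no usable SNPs for F3")
    f3_col = f3_sum / np.maximum(n_used, 1.0)

    if len(segments):
        seg = segments if not excl else segments[~segments["chrom"].isin(excl)]
        agg = (seg.assign(length_bp=seg["end_bp"] - seg["start_bp"] + 1)
               .groupby("sample_id")["length_bp"].agg(["count", "sum"]))
        n_roh_map = agg["count"].to_dict()
        bp_map = agg["sum"].to_dict()
    else:
        n_roh_map, bp_map = {}, {}
    miss_all = ((g.calls == MISSING).mean(axis=1) if g.n_variants
                else np.zeros(g.n_samples))
    rows = []
    for i, s in enumerate(g.samples):
        total_kb = float(bp_map.get(s.id, 0)) / 1000.0
        miss = s.covariates.get("missing_fraction", float(miss_all[i]))
        rows.append((s.id, int(n_roh_map.get(s.id, 0)), total_kb,
                     total_kb * 1000.0 / AUTOSOME_BP, float(f3_col[i]), miss))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def summarize_profiles(profiles: pd.DataFrame,
                       samples: "list" = None) -> pd.DataFrame:
    """Median/IQR summary of burden measures per study x case-control status."""
    df = profiles.copy()
    if samples is not None:
        meta = pd.DataFrame({"sample_id": [s.id for s in samples],
                             "study": [s.study for s in samples],
                             "status": [s.status for s in samples]})
        df = df.merge(meta, on="sample_id", how="left")
    else:
        df["study"] = ""
        df["status"] = ""
    out = []
    for (study, status), grp in df.groupby(["study", "status"]):
        q = grp[["total_roh_kb", "n_roh", "froh", "f3"]].quantile([0.25, 0.5, 0.75])
        out.append({
            "study": study, "status": status, "n": len(grp),
            "median_roh_kb": q.loc[0.5, "total_roh_kb"],
            "iqr_roh_kb": f"{q.loc[0.25, 'total_roh_kb']:.0f}-{q.loc[0.75, 'total_roh_kb']:.0f}",
            "median_n_roh": q.loc[0.5, "n_roh"],
            "median_froh_pct": 100.0 * q.loc[0.5, "froh"],
            "iqr_froh_pct": f"{100 * q.loc[0.25, 'froh']:.2f}-{100 * q.loc[0.75, 'froh']:.2f}",
            "median_f3": q.loc[0.5, "f3"],
        })
    return pd.DataFrame(out)
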