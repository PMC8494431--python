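"""Sliding-window runs-of-homozygosity (ROH) detection.

Two-step procedure on hard-call genotypes of one sample:

1. *Window scan* — slide a 50-SNP window along each chromosome; a window is
   "homozygous" if it holds at most one heterozygote and at most five missing
   calls.  A SNP is flagged when at least 5% of the windows covering it are
   homozygous.
2. *Run assembly* — maximal stretches of flagged SNPs become candidate runs;
   runs are split at inter-SNP gaps above 5,000 kb, trimmed inward to
   non-missing homozygous genotypes, and kept only when they contain at
   least 100 SNPs, span at least 1,500 kb and average at least one SNP per
   50 kb.

Near chromosome ends a SNP is covered by fewer than 50 windows; the hit
ratio uses the number of windows that actually exist, so edge SNPs remain
reachable.  Chromosomes shorter than one window are scanned with a single
truncated window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]


@dataclass(frozen=True)
class RohParams:
    """ROH calling parameters (defaults follow the 1.5-Mb calling recipe)."""

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_kb: float = 1500.0
    density_kb_per_snp: float = 50.0
    max_gap_kb: float = 5000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must lie in (0,1]")
        for name in ("window_snps", "window_max_het", "window_max_missing",
                     "min_snps", "min_kb", "density_kb_per_snp", "max_gap_kb"):
            if getattr(self, name) <= 0 and name not in ("window_max_het",
                                                         "window_max_missing"):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RohSegment:
    """One called run of homozygosity (1-based inclusive SNP positions)."""

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp > end_bp")


def _flags_matrix(calls2d: np.ndarray, p: RohParams) -> np.ndarray:
    """Window-scan flags for many samples on one chromosome (rows = samples)."""
    n = calls2d.shape[1]
    if n == 0:
        return np.zeros_like(calls2d, dtype=bool)
    w = min(p.window_snps, n)
    ctype = np.int16 if n < 32000 else np.int32
    zero = np.zeros((calls2d.shape[0], 1), dtype=ctype)
    het_c = np.concatenate([zero, np.cumsum(calls2d == 1, axis=1,
                                            dtype=ctype)], axis=1)
    ok = het_c[:, w:] - het_c[:, :-w] <= p.window_max_het
    mis = calls2d == MISSING
    if mis.any():  # skip the missing-call window sum when nothing is missing
        mis_c = np.concatenate([zero, np.cumsum(mis, axis=1, dtype=ctype)],
                               axis=1)
        ok &= mis_c[:, w:] - mis_c[:, :-w] <= p.window_max_missing
    ok_c = np.concatenate([zero, np.cumsum(ok, axis=1, dtype=ctype)], axis=1)
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_ok = ok_c[:, hi + 1] - ok_c[:, lo]
    n_win = hi - lo + 1
    return n_ok >= p.hit_threshold * n_win - 1e-12


def flag_homozygous_snps(calls: np.ndarray, pos_bp: np.ndarray,
                         p: RohParams = RohParams()) -> np.ndarray:
    """Per-SNP window-scan flags for one sample on one chromosome.

    ``calls`` is a 1-D int array in {0,1,2,MISSING} sorted by ``pos_bp``.
    Returns a boolean array: True where the fraction of covering homozygous
    windows reaches ``hit_threshold``.
    """
    calls = np.asarray(calls)
    if calls.size and np.any(np.diff(np.asarray(pos_bp)) < 0):
        raise ValueError("positions must be sorted")
    return _flags_matrix(calls.reshape(1, -1), p)[0]


def _segment_ok(calls: np.ndarray, pos: np.ndarray, a: int, b: int,
                p: RohParams) -> bool:
    n_snps = b - a + 1
    if n_snps < p.min_snps:
        return False
    length_kb = (pos[b] - pos[a] + 1) / 1000.0
    if length_kb < p.min_kb:
        return False
    return length_kb / n_snps <= p.density_kb_per_snp


def call_roh_sample(calls: np.ndarray, pos_bp: np.ndarray, chrom: int,
                    sample_id: str, p: RohParams = RohParams(),
                    flags: np.ndarray | None = None) -> list[RohSegment]:
    """Call ROH segments for one sample on one chromosome.

    Deterministic: candidate runs are maximal flagged stretches, split at
    gaps > ``max_gap_kb``, trimmed inward to non-missing homozygous calls,
    then filtered by the segment invariants.
    """
    calls = np.asarray(calls)
    pos = np.asarray(pos_bp, dtype=np.int64)
    if flags is None:
        flags = flag_homozygous_snps(calls, pos, p)
    if not flags.any():
        return []
    # maximal runs of flagged SNPs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    runs = list(zip(edges[0::2], edges[1::2] - 1))
    max_gap_bp = p.max_gap_kb * 1000.0
    hom = (calls == 0) | (calls == 2)
    out: list[RohSegment] = []
    for a0, b0 in runs:
        # split at oversized gaps so no gap is internal to a segment
        cut = a0 + np.flatnonzero(np.diff(pos[a0:b0 + 1]) > max_gap_bp)
        starts = [a0] + [int(c) + 1 for c in cut]
        ends = [int(c) for c in cut] + [b0]
        pieces = list(zip(starts, ends))
        for a, b in pieces:
            while a <= b and not hom[a]:
                a += 1
            while b >= a and not hom[b]:
                b -= 1
            if a > b:
                continue
            if _segment_ok(calls, pos, a, b, p):
                out.append(RohSegment(sample_id=sample_id, chrom=int(chrom),
                                      start_bp=int(pos[a]), end_bp=int(pos[b]),
                                      n_snps=int(b - a + 1)))
    return out


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    rows = [(s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_kb)
            for s in segments]
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return df.astype({"chrom": np.int64, "start_bp": np.int64,
                      "end_bp": np.int64, "n_snps": np.int64})


def call_roh_cohort(g: GenotypeMatrix, p: RohParams = RohParams()) -> pd.DataFrame:
    """Call ROH for every sample x chromosome; stable (sample, chrom, start) order."""
    chroms = g.chrom_array()
    pos = g.pos_array()
    segs: list[RohSegment] = []
    per_sample: dict[int, list[RohSegment]] = {i: [] for i in range(g.n_samples)}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        sub = g.calls[:, idx]
        pos_c = pos[idx]
        if np.any(np.diff(pos_c) < 0):
            raise ValueError("variants must be sorted by position")
        flags = _flags_matrix(sub, p)
        for i in np.flatnonzero(flags.any(axis=1)):
            per_sample[i].extend(call_roh_sample(
                sub[i], pos_c, int(c), g.samples[i].id, p, flags=flags[i]))
    for i in range(g.n_samples):
        segs.extend(per_sample[i])
    df = segments_to_frame(segs)
    order = {s.id: i for i, s in enumerate(g.samples)}
    df["_o"] = df["sample_id"].map(order)
    df = df.sort_values(["_o", "chrom", "start_bp"], kind="mergesort")
    return df.drop(columns="_o").reset_index(drop=True)


def write_segments(df: pd.DataFrame, path, *, bed: bool = False) -> None:
    """Write a segment table as TSV, or as BED (0-based half-open)."""
    if bed:
        out = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start_bp"] - 1,
            "end": df["end_bp"], "name": df["sample_id"]})
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        df.to_csv(path, sep="\t", index=False)
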