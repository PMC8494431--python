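"""Synthetic case-control cohorts with planted autozygous segments.

Autozygosity is modelled by explicit tract planting: each genome receives a
Poisson number of megabase-scale tracts (length = floor + exponential tail)
placed uniformly without overlap; inside a tract the genotype is homozygous
for an allele drawn by its frequency, outside it follows Hardy-Weinberg
draws, and every call is flipped to a heterozygote with a small error
probability.  Disease status follows a logistic model on the true planted
FROH plus age and sex effects, sampled retrospectively (candidates drawn
until the case and control quotas are met).  Mild population substructure
comes from two subpopulations with Balding-Nichols frequency divergence.

Ground truth (planted tracts, true FROH, true effect sizes, subpopulation
labels) is recorded for every sample so each pipeline stage can be tested
against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleRecord, Variant, write_genotypes, \
    write_phenotypes
from .metrics import AUTOSOME_BP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters for one synthetic case-control GWAS.

    Defaults give per-genome tract burden whose median FROH (with the fixed
    3x10⁹ bp denominator) falls in the 0.4-0.6% range typical of outbred
    European-ancestry cohorts, with a true burden effect the size seen for
    strongly associated subtypes (log-OR 20 per unit FROH).
    """

    n_studies: int = 4
    n_case: int = 500
    n_control: int = 500
    m_snps: int = 10_000
    chrom_lengths_bp: dict[int, int] = field(
        default_factory=lambda: {1: 60_000_000, 2: 60_000_000})
    freq_low: float = 0.05
    freq_high: float = 0.5
    mean_segments_per_genome: float = 6.0  # Poisson λ
    segment_floor_kb: float = 1600.0
    segment_mean_extra_kb: float = 900.0  # exponential tail above the floor
    genotype_error_rate: float = 0.002
    beta_froh: float = 20.0  # true log-OR per unit FROH
    intercept: float = -1.0
    beta_age: float = 0.02  # per year, centred at age_mean
    beta_sex_male: float = 0.3
    age_mean: float = 60.0
    age_sd: float = 10.0
    single_sex: bool = False  # all-female study (sex column constant)
    fst: float = 0.005  # Balding-Nichols divergence of the 2 subpops
    subpop_fraction: float = 0.5
    case_subtype: str = "CLL"
    risk_region: tuple[int, int, int] | None = None  # (chrom, start, end)
    risk_tract_prob: float = 0.0  # chance of an extra tract centred there
    beta_region: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("need 0 < freq_low <= freq_high < 1")
        if not 0.0 <= self.genotype_error_rate <= 0.01:
            raise ValueError("genotype_error_rate must lie in [0, 0.01]")
        for name in ("n_studies", "n_case", "n_control", "m_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedCohort:
    """One synthetic study with per-sample ground truth."""

    study: str
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # sample_id, true_froh, n_tracts, subpop, region_exposed
    tracts: dict[str, list[tuple[int, int, int]]]
    params: SimParams
    seed: int


# ---------------------------------------------------------------------------
# Map and tract machinery
# ---------------------------------------------------------------------------

def simulate_map(params: SimParams, rng: np.random.Generator
                 ) -> tuple[list[Variant], np.ndarray]:
    """Variant map with uniform-ordered positions and uniform frequencies.

    SNP counts are split across chromosomes proportionally to length.
    Warns when expected SNP density cannot support calling a minimum-length
    tract (fewer than 100 SNPs expected per 1,500 kb).
    """
    total = sum(params.chrom_lengths_bp.values())
    exp_per_1500kb = params.m_snps / total * 1.5e6
    if exp_per_1500kb < 100:
        logger.warning(
            "SNP density low: expected %.1f SNPs per 1500 kb (< 100); "
            "minimum-length tracts may be uncallable", exp_per_1500kb)
    variants: list[Variant] = []
    chroms = sorted(params.chrom_lengths_bp)
    counts = {c: int(round(params.m_snps * params.chrom_lengths_bp[c] / total))
              for c in chroms}
    counts[chroms[-1]] += params.m_snps - sum(counts.values())
    for c in chroms:
        length = params.chrom_lengths_bp[c]
        pos = np.unique(rng.integers(1, length + 1, size=counts[c]))
        for i, p in enumerate(pos):
            variants.append(Variant(id=f"rs{c}_{i}", chrom=c, pos_bp=int(p)))
    freqs = rng.uniform(params.freq_low, params.freq_high, size=len(variants))
    return variants, freqs


def _risk_tract(params: SimParams, rng: np.random.Generator
                ) -> tuple[int, int, int]:
    """Tract of random length centred on the risk region (autozygosity at
    a planted recessive locus), clipped to the chromosome."""
    rc, ra, rb = params.risk_region
    L = int((params.segment_floor_kb
             + rng.exponential(params.segment_mean_extra_kb)) * 1000)
    center = (ra + rb) // 2
    clen = params.chrom_lengths_bp[rc]
    start = max(1, min(center - L // 2, clen - L + 1))
    return (rc, start, start + L - 1)


def draw_tract_set(params: SimParams, rng: np.random.Generator,
                   preplaced: list[tuple[int, int, int]] | None = None
                   ) -> list[tuple[int, int, int]]:
    """Planted autozygous tracts for one genome: (chrom, start_bp, end_bp).

    Each tract start is drawn uniformly over every position that keeps the
    tract inside a chromosome and clear of previously placed tracts; raises
    only when no feasible position remains for a drawn length.
    ``preplaced`` tracts (e.g. a risk-locus tract) are carved out first and
    included in the result.
    """
    n = rng.poisson(params.mean_segments_per_genome)
    chroms = sorted(params.chrom_lengths_bp)
    free: dict[int, list[tuple[int, int]]] = {
        c: [(1, params.chrom_lengths_bp[c])] for c in chroms}
    placed: list[tuple[int, int, int]] = []
    for c, s, e in preplaced or []:
        for a, b in list(free[c]):
            if s <= b and e >= a:
                free[c].remove((a, b))
                if s > a:
                    free[c].append((a, s - 1))
                if e < b:
                    free[c].append((e + 1, b))
        placed.append((c, s, e))
    for _ in range(n):
        L = int((params.segment_floor_kb
                 + rng.exponential(params.segment_mean_extra_kb)) * 1000)
        # feasible start counts per free interval
        slots = [(c, a, b, b - L + 1 - a + 1) for c in chroms
                 for a, b in free[c] if b - a + 1 >= L]
        total = sum(s[3] for s in slots)
        if total <= 0:
            raise RuntimeError(
                "no space left to place an autozygous tract; reduce "
                "mean_segments_per_genome or tract length")
        r = int(rng.integers(total))
        for c, a, b, cnt in slots:
            if r < cnt:
                start = a + r
                end = start + L - 1
                free[c].remove((a, b))
                if start > a:
                    free[c].append((a, start - 1))
                if end < b:
                    free[c].append((end + 1, b))
                placed.append((c, start, end))
                break
            r -= cnt
    return sorted(placed)


def tracts_froh(tracts: list[tuple[int, int, int]]) -> float:
    return sum(e - s + 1 for _, s, e in tracts) / AUTOSOME_BP


def _region_exposed(tracts: list[tuple[int, int, int]],
                    region: tuple[int, int, int] | None) -> bool:
    if region is None:
        return False
    rc, ra, rb = region
    return any(c == rc and ra <= (s + e) // 2 <= rb for c, s, e in tracts)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def subpop_freqs(freqs: np.ndarray, params: SimParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies, shape (2, m)."""
    if params.fst <= 0:
        return np.vstack([freqs, freqs])
    a = freqs * (1.0 - params.fst) / params.fst
    b = (1.0 - freqs) * (1.0 - params.fst) / params.fst
    out = rng.beta(np.vstack([a, a]), np.vstack([b, b]))
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def simulate_genotypes(variants: list[Variant], freqs: np.ndarray,
                       params: SimParams, rng: np.random.Generator,
                       tract_sets: list[list[tuple[int, int, int]]],
                       subpop: np.ndarray,
                       pop_freqs: np.ndarray | None = None) -> np.ndarray:
    """Hard-call matrix for samples with the given planted tracts.

    Outside tracts genotypes are HWE draws at the sample's subpopulation
    frequencies; inside a tract P(x=2)=p, P(x=0)=1-p; every call is then
    flipped to a heterozygote with probability ``genotype_error_rate``.
    """
    m = len(variants)
    n = len(tract_sets)
    chrom = np.fromiter((v.chrom for v in variants), dtype=np.int64, count=m)
    pos = np.fromiter((v.pos_bp for v in variants), dtype=np.int64, count=m)
    if pop_freqs is None:
        pop_freqs = subpop_freqs(freqs, params, rng)
    calls = np.empty((n, m), dtype=np.int8)
    for k in (0, 1):
        rows = np.flatnonzero(np.asarray(subpop) == k)
        pf = pop_freqs[k].astype(np.float32)
        # HWE draw as two allele Bernoullis, chunked to bound memory
        for lo in range(0, rows.size, 1024):
            r = rows[lo:lo + 1024]
            block = ((rng.random((r.size, m), dtype=np.float32) < pf)
                     .view(np.int8)
                     + (rng.random((r.size, m), dtype=np.float32) < pf))
            calls[r] = block
    # chromosome index ranges for fast tract lookup
    spans = {c: (np.searchsorted(chrom, c, "left"),
                 np.searchsorted(chrom, c, "right"))
             for c in np.unique(chrom)}
    for i, tracts in enumerate(tract_sets):
        p_i = pop_freqs[int(subpop[i])]
        for c, s, e in tracts:
            if c not in spans:
                continue
            lo, hi = spans[c]
            a = lo + np.searchsorted(pos[lo:hi], s, "left")
            b = lo + np.searchsorted(pos[lo:hi], e, "right")
            if b > a:
                hom_b = rng.random(b - a) < p_i[a:b]
                calls[i, a:b] = np.where(hom_b, 2, 0).astype(np.int8)
    if params.genotype_error_rate > 0:
        for lo in range(0, n, 1024):
            hi = min(lo + 1024, n)
            flip = rng.random((hi - lo, m),
                              dtype=np.float32) < params.genotype_error_rate
            calls[lo:hi][flip] = 1
    return calls


# ---------------------------------------------------------------------------
# Phenotype and study assembly
# ---------------------------------------------------------------------------

def simulate_phenotype(truth: pd.DataFrame, params: SimParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Bernoulli case indicators under the logistic risk model.

    ``truth`` needs columns true_froh, age, sex_male, region_exposed.
    """
    logit = (params.intercept
             + params.beta_froh * truth["true_froh"].to_numpy()
             + params.beta_age * (truth["age"].to_numpy() - params.age_mean)
             + params.beta_sex_male * truth["sex_male"].to_numpy()
             + params.beta_region * truth["region_exposed"].to_numpy(float))
    prob = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random(len(truth)) < prob).astype(int)


def _draw_candidates(params: SimParams, rng: np.random.Generator,
                     n: int) -> tuple[pd.DataFrame, list]:
    tract_sets = []
    for _ in range(n):
        pre = None
        if (params.risk_region is not None and params.risk_tract_prob > 0
                and rng.random() < params.risk_tract_prob):
            pre = [_risk_tract(params, rng)]
        tract_sets.append(draw_tract_set(params, rng, preplaced=pre))
    age = rng.normal(params.age_mean, params.age_sd, size=n)
    sex_male = (np.zeros(n, dtype=int) if params.single_sex
                else rng.integers(0, 2, size=n))
    subpop = (rng.random(n) < params.subpop_fraction).astype(int)
    truth = pd.DataFrame({
        "true_froh": [tracts_froh(t) for t in tract_sets],
        "n_tracts": [len(t) for t in tract_sets],
        "age": age, "sex_male": sex_male, "subpop": subpop,
        "region_exposed": [_region_exposed(t, params.risk_region)
                           for t in tract_sets]})
    return truth, tract_sets


def simulate_study(params: SimParams, study: str = "S1",
                   seed: int = 0) -> SimulatedCohort:
    """One synthetic study sampled retrospectively to exact quotas.

    Candidate individuals (tracts, covariates, status) are drawn until the
    case and control quotas are met; genotypes are then generated for the
    selected samples only.  Raises if the quotas are unattainable within a
    bounded number of draws, reporting the achieved prevalence.
    """
    rng = np.random.default_rng(seed)
    variants, freqs = simulate_map(params, rng)
    pop_freqs = subpop_freqs(freqs, params, rng)

    need_case, need_ctrl = params.n_case, params.n_control
    sel_truth: list[pd.DataFrame] = []
    sel_tracts: list[list] = []
    drawn = 0
    cases = 0
    cap = 200 * (need_case + need_ctrl)
    while need_case > 0 or need_ctrl > 0:
        chunk = max(need_case + need_ctrl, 256)
        truth, tract_sets = _draw_candidates(params, rng, chunk)
        status = simulate_phenotype(truth, params, rng)
        drawn += chunk
        cases += int(status.sum())
        take = np.zeros(chunk, dtype=bool)
        case_rows = np.flatnonzero(status == 1)[:need_case]
        ctrl_rows = np.flatnonzero(status == 0)[:need_ctrl]
        take[case_rows] = True
        take[ctrl_rows] = True
        need_case -= case_rows.size
        need_ctrl -= ctrl_rows.size
        t = truth[take].copy()
        t["status"] = status[np.flatnonzero(take)]
        sel_truth.append(t)
        sel_tracts.extend(tract_sets[i] for i in np.flatnonzero(take))
        if drawn > cap and (need_case > 0 or need_ctrl > 0):
            raise RuntimeError(
                f"quota unattainable: achieved prevalence {cases / drawn:.3f} "
                f"after {drawn} draws; adjust intercept")
    truth = pd.concat(sel_truth, ignore_index=True)
    n = len(truth)
    sample_ids = [f"{study}_s{i:05d}" for i in range(n)]
    truth.insert(0, "sample_id", sample_ids)

    calls = simulate_genotypes(variants, freqs, params, rng, sel_tracts,
                               truth["subpop"].to_numpy(), pop_freqs)
    status_arr = truth["status"].to_numpy()
    age_arr = truth["age"].to_numpy()
    male_arr = truth["sex_male"].to_numpy()
    samples = []
    for i, sid in enumerate(sample_ids):
        is_case = bool(status_arr[i])
        samples.append(SampleRecord(
            id=sid, status="case" if is_case else "control",
            subtype=params.case_subtype if is_case else "none",
            age=float(age_arr[i]),
            sex="male" if male_arr[i] else "female",
            study=study))
    g = GenotypeMatrix(samples, variants, calls)
    tracts = {sid: sel_tracts[i] for i, sid in enumerate(sample_ids)}
    return SimulatedCohort(study=study, genotypes=g, truth=truth,
                           tracts=tracts, params=params, seed=seed)


def simulate_multi_study(params: SimParams, seed: int = 0,
                         single_sex_study: int | None = None
                         ) -> list[SimulatedCohort]:
    """Independent synthetic studies S1..Sn from one master seed."""
    seeds = np.random.SeedSequence(seed).spawn(params.n_studies)
    out = []
    for i, ss in enumerate(seeds):
        p = params
        if single_sex_study is not None and i == single_sex_study:
            from dataclasses import replace
            p = replace(params, single_sex=True)
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        out.append(simulate_study(p, study=f"S{i + 1}", seed=sub_seed))
    return out


def write_cohort(cohort: SimulatedCohort, outdir: str | Path,
                 dialect: str = "binary") -> None:
    """Write a study as PLINK files plus phenotype and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = outdir / cohort.study
    write_genotypes(cohort.genotypes, prefix, dialect=dialect)
    write_phenotypes(cohort.genotypes.samples, prefix.with_suffix(".pheno.tsv"))
    cohort.truth.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)
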