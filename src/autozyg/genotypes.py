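"""Genotype/phenotype data model, PLINK-dialect file I/O and pre-analysis QC.

Hard-call genotypes are stored as an ``int8`` samples x variants array in
which each value counts copies of ``allele_b`` (0, 1 or 2); missing calls are
``MISSING`` (-1) and are never imputed.  Only autosomes (chromosomes 1-22)
are modelled: non-autosomal variants are dropped at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

MISSING: int = -1
AUTOSOMES = frozenset(range(1, 23))


class ParseError(ValueError):
    """Malformed genotype file (names file and line where possible)."""


@dataclass(frozen=True)
class Variant:
    """One biallelic autosomal SNP on the variant map (1-based bp)."""

    id: str
    chrom: int
    pos_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"variant {self.id}: chrom {self.chrom} is not autosomal")
        if self.pos_bp < 1:
            raise ValueError(f"variant {self.id}: pos_bp must be >= 1")


@dataclass
class SampleRecord:
    """One study participant with phenotype and covariates.

    ``covariates`` holds named real-valued covariates (PC1..PC10,
    missing_fraction, ...).  Controls always carry subtype ``none``.
    """

    id: str
    status: str = "control"  # {case, control}
    subtype: str = "none"  # {CLL, DLBCL, FL, MZL, none}
    age: float = float("nan")
    sex: str = "unknown"  # {male, female, unknown}
    study: str = ""
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"sample {self.id}: bad status {self.status!r}")
        if self.status == "control" and self.subtype != "none":
            raise ValueError(f"control {self.id} must have subtype 'none'")


@dataclass
class GenotypeMatrix:
    """Samples x variants hard-call matrix; values in {0, 1, 2, MISSING}."""

    samples: list[SampleRecord]
    variants: list[Variant]
    calls: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.calls.size and (self.calls.min() < MISSING or self.calls.max() > 2):
            raise ValueError("calls contain values outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def chrom_array(self) -> np.ndarray:
        return np.fromiter((v.chrom for v in self.variants), dtype=np.int64,
                           count=self.n_variants)

    def pos_array(self) -> np.ndarray:
        return np.fromiter((v.pos_bp for v in self.variants), dtype=np.int64,
                           count=self.n_variants)

    def allele_b_freqs(self) -> np.ndarray:
        """Per-variant frequency of allele_b over non-missing calls (NaN if all missing)."""
        calls = self.calls
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        s = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, s / (2.0 * np.maximum(n_obs, 1)), np.nan)

    def subset(self, sample_idx: np.ndarray | None = None,
               variant_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)].copy(),
        )


@dataclass(frozen=True)
class QcThresholds:
    """Pre-analysis QC cut-offs (variant filters then sample call rate)."""

    maf_min: float = 0.05
    variant_missing_max: float = 0.03
    hwe_p_min: float = 1e-6  # tested among controls only
    sample_callrate_min: float = 0.97

    def __post_init__(self) -> None:
        for name in ("maf_min", "variant_missing_max", "hwe_p_min", "sample_callrate_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0,1)")


# ---------------------------------------------------------------------------
# File I/O: PLINK text (PED/MAP) and binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------

_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_SEX_IN = {"1": "male", "2": "female"}
_PHENO_OUT = {"control": "1", "case": "2"}


def _sorted_variant_order(variants: Sequence[Variant]) -> np.ndarray:
    keys = np.array([(v.chrom, v.pos_bp) for v in variants])
    return np.lexsort((keys[:, 1], keys[:, 0]))


def _check_unique_ids(variants: Iterable[Variant], path: str) -> None:
    seen: set[str] = set()
    for v in variants:
        if v.id in seen:
            raise ParseError(f"{path}: duplicate variant id {v.id!r}")
        seen.add(v.id)


def _read_map_like(path: Path, n_cols_pos: int) -> tuple[list[Variant | None], int]:
    """Parse MAP/BIM rows; non-autosomal rows become None (dropped, counted)."""
    rows: list[Variant | None] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < n_cols_pos + 1:
                raise ParseError(f"{path}:{lineno}: expected >= {n_cols_pos + 1} fields")
            chrom_s, vid = parts[0], parts[1]
            try:
                chrom = int(chrom_s)
                pos = int(parts[n_cols_pos])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if chrom not in AUTOSOMES:
                n_dropped += 1
                rows.append(None)
                continue
            if len(parts) >= n_cols_pos + 3:  # BIM carries alleles
                a1, a2 = parts[n_cols_pos + 1], parts[n_cols_pos + 2]
            else:
                a1, a2 = "A", "B"
            rows.append(Variant(id=vid, chrom=chrom, pos_bp=pos,
                                allele_a=a1, allele_b=a2))
    return rows, n_dropped


def read_genotypes(prefix: str | Path, dialect: str = "text") -> GenotypeMatrix:
    """Read a PLINK fileset (``prefix.ped/.map`` or ``prefix.bed/.bim/.fam``).

    Non-autosomal variants are dropped (count logged); variants are returned
    sorted by (chrom, pos_bp).  Raises :class:`ParseError` on malformed input
    or duplicate variant ids.
    """
    prefix = Path(prefix)
    if dialect == "text":
        g = _read_text(prefix)
    elif dialect == "binary":
        g = _read_binary(prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    order = _sorted_variant_order(g.variants)
    if not np.array_equal(order, np.arange(len(g.variants))):
        g = GenotypeMatrix(g.samples, [g.variants[j] for j in order],
                           g.calls[:, order])
    return g


def _read_text(prefix: Path) -> GenotypeMatrix:
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    rows, n_dropped = _read_map_like(map_path, n_cols_pos=3)
    keep = [i for i, r in enumerate(rows) if r is not None]
    variants = [rows[i] for i in keep]
    _check_unique_ids(variants, str(map_path))
    if n_dropped:
        logger.info("%s: dropped %d non-autosomal variants", map_path, n_dropped)
    n_map = len(rows)
    samples: list[SampleRecord] = []
    call_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_map:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_map} fields "
                    f"(map has {n_map} variants), got {len(parts)}")
            sid = parts[1]
            sex = _SEX_IN.get(parts[4], "unknown")
            status = "case" if parts[5] == "2" else "control"
            samples.append(SampleRecord(id=sid, status=status, sex=sex))
            alleles = parts[6:]
            row = np.empty(len(keep), dtype=np.int8)
            for out_j, j in enumerate(keep):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                v = variants[out_j]
                if a1 == "0" or a2 == "0":
                    row[out_j] = MISSING
                else:
                    try:
                        row[out_j] = (a1 == v.allele_b) + (a2 == v.allele_b)
                    except Exception:  # pragma: no cover
                        raise ParseError(f"{ped_path}:{lineno}: bad allele pair")
                    if (a1 not in (v.allele_a, v.allele_b)
                            or a2 not in (v.allele_a, v.allele_b)):
                        raise ParseError(
                            f"{ped_path}:{lineno}: allele {a1}/{a2} not in "
                            f"{{{v.allele_a},{v.allele_b}}} for {v.id}")
            call_rows.append(row)
    calls = np.vstack(call_rows) if call_rows else np.empty((0, len(keep)), np.int8)
    return GenotypeMatrix(samples, variants, calls)


# BED 2-bit codes (SNP-major): 00 hom allele_a, 01 missing, 10 het, 11 hom allele_b
_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
_CODE_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _read_binary(prefix: Path) -> GenotypeMatrix:
    bim, fam, bed = (prefix.with_suffix(s) for s in (".bim", ".fam", ".bed"))
    rows, n_dropped = _read_map_like(bim, n_cols_pos=3)
    keep = [i for i, r in enumerate(rows) if r is not None]
    variants = [rows[i] for i in keep]
    _check_unique_ids(variants, str(bim))
    if n_dropped:
        logger.info("%s: dropped %d non-autosomal variants", bim, n_dropped)
    samples: list[SampleRecord] = []
    with open(fam) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ParseError(f"{fam}:{lineno}: expected 6 fields")
            samples.append(SampleRecord(
                id=parts[1], status="case" if parts[5] == "2" else "control",
                sex=_SEX_IN.get(parts[4], "unknown")))
    n, m = len(samples), len(rows)
    raw = Path(bed).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ParseError(f"{bed}: bad magic bytes (not SNP-major PLINK BED)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise ParseError(
            f"{bed}: size mismatch ({body.size} data bytes, expected "
            f"{m * bytes_per_snp} for {n} samples x {m} variants)")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _CODE_TO_CALL[codes][keep].T.copy()  # -> samples x kept variants
    return GenotypeMatrix(samples, variants, calls)


def write_genotypes(g: GenotypeMatrix, prefix: str | Path,
                    dialect: str = "text") -> None:
    """Write ``g`` as PLINK text (PED/MAP) or binary (BED/BIM/FAM)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "text":
        with open(prefix.with_suffix(".map"), "w") as fh:
            for v in g.variants:
                fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\n")
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, s in enumerate(g.samples):
                fields = [s.id, s.id, "0", "0", _SEX_OUT.get(s.sex, "0"),
                          _PHENO_OUT[s.status]]
                for j, v in enumerate(g.variants):
                    x = int(g.calls[i, j])
                    if x == MISSING:
                        fields += ["0", "0"]
                    elif x == 0:
                        fields += [v.allele_a, v.allele_a]
                    elif x == 1:
                        fields += [v.allele_a, v.allele_b]
                    else:
                        fields += [v.allele_b, v.allele_b]
                fh.write(" ".join(fields) + "\n")
    elif dialect == "binary":
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for v in g.variants:
                fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\t{v.allele_a}\t{v.allele_b}\n")
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for s in g.samples:
                fh.write(f"{s.id} {s.id} 0 0 {_SEX_OUT.get(s.sex, '0')} "
                         f"{_PHENO_OUT[s.status]}\n")
        n, m = g.n_samples, g.n_variants
        bytes_per_snp = (n + 3) // 4
        code = np.empty((m, n), dtype=np.uint8)
        for call, c in _CALL_TO_CODE.items():
            code[g.calls.T == call] = c
        padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
        padded[:, :n] = code
        packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
                  | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.astype(np.uint8).tobytes())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_phenotypes(samples: Sequence[SampleRecord], path: str | Path) -> None:
    """Tab-delimited phenotype/covariate table with header."""
    cov_names = sorted({k for s in samples for k in s.covariates})
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "status", "subtype", "age", "sex",
                            "study"] + cov_names) + "\n")
        for s in samples:
            row = [s.id, s.status, s.subtype, repr(float(s.age)), s.sex, s.study]
            row += [repr(float(s.covariates.get(k, float("nan")))) for k in cov_names]
            fh.write("\t".join(row) + "\n")


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = ["sample_id", "status", "subtype", "age", "sex", "study"]
        if header[:6] != fixed:
            raise ParseError(f"{path}: unexpected phenotype header")
        cov_names = header[6:]
        out = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append(SampleRecord(
                id=parts[0], status=parts[1], subtype=parts[2],
                age=float(parts[3]), sex=parts[4], study=parts[5],
                covariates={k: float(v) for k, v in zip(cov_names, parts[6:])}))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_het_log_probs(n_a: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Log probabilities of all het counts compatible with allele totals."""
    n_b = 2 * n_total - n_a
    h_max = min(n_a, n_b)
    hets = np.arange(n_a % 2, h_max + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    logp = (gammaln(n_total + 1) - gammaln(n_aa + 1) - gammaln(hets + 1)
            - gammaln(n_bb + 1) + hets * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n_total + 1))
    return hets, logp


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int, *, midp: bool = False,
                   method: str = "exact") -> float:
    """Two-sided Hardy-Weinberg test p-value for one biallelic SNP.

    The exact test sums, over all heterozygote counts compatible with the
    observed allele totals, the probabilities no larger than that of the
    observed configuration.  Monomorphic input returns 1.0 by convention.
    ``method="chisq"`` gives the 1-df goodness-of-fit chi-square alternative.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be >= 0 with total >= 1")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    if method == "chisq":
        p = n_a / (2.0 * n)
        exp = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
        stat = float((((np.array([n_aa, n_ab, n_bb]) - exp) ** 2) / exp).sum())
        return float(chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    hets, logp = _hwe_het_log_probs(n_a, n)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_ab)]
    mask = probs <= obs * (1.0 + 1e-12)
    p_val = float(probs[mask].sum())
    if midp:
        p_val -= 0.5 * float(obs)
    return min(p_val, 1.0)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def apply_variant_qc(g: GenotypeMatrix, t: QcThresholds = QcThresholds(),
                     *, hwe_among_controls: bool = True
                     ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop variants failing MAF, missingness then control-HWE filters.

    MAF uses non-missing calls over all samples; the HWE exact test uses
    controls only.  The report attributes each dropped variant to the first
    filter it fails, so counts sum to the total dropped.
    """
    ctrl_idx = np.array([i for i, s in enumerate(g.samples)
                         if s.status == "control"])
    if hwe_among_controls and ctrl_idx.size == 0:
        raise ValueError(
            "no control samples: pass hwe_among_controls=False to disable "
            "the control-only HWE filter explicitly")
    calls = g.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    freq = np.where(n_obs > 0, np.where(obs, calls, 0).sum(axis=0)
                    / (2.0 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    miss_frac = 1.0 - n_obs / max(g.n_samples, 1)

    fail_maf = maf < t.maf_min
    fail_miss = (~fail_maf) & (miss_frac > t.variant_missing_max)
    fail_hwe = np.zeros(g.n_variants, dtype=bool)
    if hwe_among_controls:
        ctrl = calls[ctrl_idx]
        candidates = np.flatnonzero(~fail_maf & ~fail_miss)
        for j in candidates:
            c = ctrl[:, j]
            n_bb = int((c == 2).sum())
            n_ab = int((c == 1).sum())
            n_aa = int((c == 0).sum())
            if n_aa + n_ab + n_bb == 0:
                continue
            if hwe_exact_test(n_aa, n_ab, n_bb) < t.hwe_p_min:
                fail_hwe[j] = True
    keep = np.flatnonzero(~(fail_maf | fail_miss | fail_hwe))
    report = {"maf": int(fail_maf.sum()), "missingness": int(fail_miss.sum()),
              "hwe": int(fail_hwe.sum())}
    return g.subset(variant_idx=keep), report


def apply_sample_qc(g: GenotypeMatrix, t: QcThresholds = QcThresholds()
                    ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop samples with call rate < threshold; annotate missing_fraction.

    Call rates are computed over the (post-variant-QC) variants of ``g``.
    Survivors gain covariate ``missing_fraction`` = #missing / #variants.
    """
    m = g.n_variants
    miss = (g.calls == MISSING).sum(axis=1)
    callrate = 1.0 - miss / m if m else np.ones(g.n_samples)
    keep = np.flatnonzero(callrate >= t.sample_callrate_min)
    if keep.size == 0:
        raise ValueError("sample QC removed every sample")
    out = g.subset(sample_idx=keep)
    out.samples = [replace(s, covariates=dict(s.covariates)) for s in out.samples]
    for i, s in zip(keep, out.samples):
        s.covariates["missing_fraction"] = float(miss[i] / m) if m else 0.0
    report = {"low_callrate": int(g.n_samples - keep.size)}
    return out, report
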