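"""Config-driven orchestration: QC → ROH → profiles → association → meta.

A run is described by a single YAML config (see :class:`RunConfig`); every
stage writes tab-delimited tables under the output directory and logs its
filter counts.  Stage outputs are cached in files keyed by a content hash
of the governing config section, so re-running an unchanged stage reuses
the cached table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import association, meta, metrics, roh, simulate
from .genotypes import (GenotypeMatrix, QcThresholds, apply_sample_qc,
                        apply_variant_qc, read_genotypes, read_phenotypes)

logger = logging.getLogger(__name__)

ANALYSES = ("burden_froh", "burden_f3", "bin_scan")


@dataclass
class StudyConfig:
    name: str
    prefix: str | None = None  # PLINK fileset prefix (file-based studies)
    dialect: str = "binary"
    pheno: str | None = None
    single_sex: bool = False


@dataclass
class RunConfig:
    outdir: str = "autozyg_out"
    seed: int = 0
    analyses: list[str] = field(default_factory=lambda: ["burden_froh"])
    studies: list[StudyConfig] = field(default_factory=list)
    simulate: dict[str, Any] | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    roh: dict[str, Any] = field(default_factory=dict)
    n_pcs: int = 10
    min_exposed: int = 5
    bin_width_bp: int = 500_000
    meta_method_burden: str = "dl"
    meta_method_bins: str = "ivw"
    exclude_chroms: list[int] = field(default_factory=list)
    exclude_samples_file: str | None = None
    subset_studies: list[str] | None = None

    def validate(self) -> None:
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValueError(f"unknown analysis {a!r}")
        if not self.studies and self.simulate is None:
            raise ValueError("config needs either studies or a simulate block")
        for s in self.studies:
            for p in (s.prefix and Path(str(s.prefix) + (
                    ".bed" if s.dialect == "binary" else ".ped")),
                    s.pheno and Path(s.pheno)):
                if p is not None and not p.exists():
                    raise FileNotFoundError(f"study {s.name}: missing {p}")
        if self.exclude_samples_file and not Path(self.exclude_samples_file).exists():
            raise FileNotFoundError(self.exclude_samples_file)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    studies = [StudyConfig(**s) for s in raw.pop("studies", [])]
    cfg = RunConfig(studies=studies, **raw)
    cfg.validate()
    return cfg


def _hash(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True,
                                     default=str).encode()).hexdigest()[:12]


def _excluded_samples(cfg: RunConfig) -> set[str]:
    if not cfg.exclude_samples_file:
        return set()
    return {line.strip() for line in
            Path(cfg.exclude_samples_file).read_text().splitlines()
            if line.strip()}


def _load_studies(cfg: RunConfig) -> list[tuple[str, GenotypeMatrix]]:
    out: list[tuple[str, GenotypeMatrix]] = []
    if cfg.simulate is not None:
        params = simulate.SimParams(**cfg.simulate)
        cohorts = simulate.simulate_multi_study(params, seed=cfg.seed)
        out.extend((c.study, c.genotypes) for c in cohorts)
    for s in cfg.studies:
        g = read_genotypes(s.prefix, dialect=s.dialect)
        if s.pheno:
            by_id = {r.id: r for r in read_phenotypes(s.pheno)}
            g.samples = [by_id.get(smp.id, smp) for smp in g.samples]
        for smp in g.samples:
            smp.study = smp.study or s.name
        out.append((s.name, g))
    return out


def _prepare_study(name: str, g: GenotypeMatrix, cfg: RunConfig,
                   cache: Path) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """QC → ROH → PCs → burden profiles for one study, with cached tables."""
    qc = QcThresholds(**cfg.qc)
    params = roh.RohParams(**cfg.roh)
    g, vreport = apply_variant_qc(g, qc)
    g, sreport = apply_sample_qc(g, qc)
    logger.info("study %s QC: dropped variants %s, samples %s",
                name, vreport, sreport)

    key = _hash([name, cfg.seed, cfg.qc, cfg.roh, g.n_samples, g.n_variants])
    seg_path = cache / f"segments.{name}.{key}.tsv"
    if seg_path.exists():
        segments = pd.read_csv(seg_path, sep="\t", float_precision="round_trip")
    else:
        segments = roh.call_roh_cohort(g, params)
        segments.to_csv(seg_path, sep="\t", index=False, float_format="%.17g")

    if cfg.n_pcs > 0:
        scores = association.compute_pcs(g, k=cfg.n_pcs)
        association.attach_pcs(g.samples, scores)
    prof_key = _hash([key, cfg.exclude_chroms])
    prof_path = cache / f"profiles.{name}.{prof_key}.tsv"
    if prof_path.exists():
        profiles = pd.read_csv(prof_path, sep="\t", float_precision="round_trip")
    else:
        profiles = metrics.profile_cohort(g, segments,
                                          exclude_chroms=cfg.exclude_chroms)
        profiles.to_csv(prof_path, sep="\t", index=False, float_format="%.17g")
    return g, segments, profiles


def _prepared(cfg: RunConfig) -> list[tuple[str, GenotypeMatrix, pd.DataFrame,
                                            pd.DataFrame]]:
    outdir = Path(cfg.outdir)
    cache = outdir / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    out = []
    for name, g in _load_studies(cfg):
        try:
            out.append((name, *_prepare_study(name, g, cfg, cache)))
        except Exception as exc:
            raise RuntimeError(f"stage 'prepare' failed for study {name}: {exc}"
                               ) from exc
    return out


def run_burden(cfg: RunConfig) -> dict[str, Any]:
    """Per-study burden association plus cross-study random-effects meta.

    Writes per-study estimate tables, the combined table and a Table-1 style
    median/IQR summary under the output directory.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    excl = _excluded_samples(cfg)
    metrics_wanted = [a.removeprefix("burden_") for a in cfg.analyses
                      if a.startswith("burden_")]
    if not metrics_wanted:
        logger.info("no burden analyses requested; nothing to do")
        return {}
    prepared = _prepared(cfg)
    rows, summaries = [], []
    estimates: dict[str, list[meta.StudyEstimate]] = {m: [] for m in metrics_wanted}
    for name, g, segments, profiles in prepared:
        summaries.append(metrics.summarize_profiles(profiles, g.samples))
        for m in metrics_wanted:
            try:
                r = association.test_burden(
                    g.samples, profiles, metric=m, exclude_samples=excl,
                    subset_studies=(set(cfg.subset_studies)
                                    if cfg.subset_studies else None))
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'burden_{m}' failed for study {name}: {exc}"
                    ) from exc
            rows.append({"study": name, "metric": m, "beta": r.beta,
                         "se": r.se, "p": r.p, "n_case": r.n_case,
                         "n_control": r.n_control, "converged": r.converged})
            if r.converged:
                estimates[m].append(meta.StudyEstimate(name, r.beta, r.se))
    per_study = pd.DataFrame(rows)
    per_study.to_csv(outdir / "burden_per_study.tsv", sep="\t", index=False)
    pd.concat(summaries, ignore_index=True).to_csv(
        outdir / "profile_summary.tsv", sep="\t", index=False)

    combine = (meta.dl_random_effects if cfg.meta_method_burden == "dl"
               else meta.ivw_fixed_effects)
    combined_rows = []
    combined: dict[str, meta.MetaResult] = {}
    for m in metrics_wanted:
        if not estimates[m]:
            continue
        r = combine(estimates[m])
        combined[m] = r
        combined_rows.append({"metric": m, "beta": r.beta, "se": r.se,
                              "p": r.p, "k": r.k, "Q": r.Q, "tau2": r.tau2,
                              "i2": r.i2, "p_het": r.p_het})
    pd.DataFrame(combined_rows).to_csv(outdir / "burden_combined.tsv",
                                       sep="\t", index=False)
    return {"per_study": per_study, "combined": combined,
            "estimates": estimates}


def run_bin_scan(cfg: RunConfig) -> dict[str, Any]:
    """Per-bin per-study association combined with fixed-effects meta.

    Writes the combined per-bin table with Bonferroni flags and a top-bins
    listing ranked by p-value.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "bin_scan" not in cfg.analyses:
        logger.info("bin_scan not in analyses; nothing to do")
        return {}
    prepared = _prepared(cfg)
    chrom_last: dict[int, int] = {}
    for _, g, _, _ in prepared:
        for v in g.variants:
            chrom_last[v.chrom] = max(chrom_last.get(v.chrom, 0), v.pos_bp)
    grid = association.BinGrid.from_chrom_ends(chrom_last, cfg.bin_width_bp)
    per_study_tables: dict[str, pd.DataFrame] = {}
    for name, g, segments, _ in prepared:
        exposures = association.assign_bins(segments, grid,
                                            [s.id for s in g.samples])
        tab = association.test_bins(g.samples, exposures, grid,
                                    min_exposed=cfg.min_exposed)
        tab.to_csv(Path(cfg.outdir) / f"bins_{name}.tsv", sep="\t", index=False)
        per_study_tables[name] = tab
    combined = meta.meta_bins(per_study_tables, method=cfg.meta_method_bins)
    combined.to_csv(outdir / "bins_combined.tsv", sep="\t", index=False)
    top = combined.sort_values("p").head(20)
    top.to_csv(outdir / "bins_top.tsv", sep="\t", index=False)
    return {"grid": grid, "per_study": per_study_tables, "combined": combined,
            "top": top}


def run_all(cfg: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    if any(a.startswith("burden_") for a in cfg.analyses):
        out["burden"] = run_burden(cfg)
    if "bin_scan" in cfg.analyses:
        out["bin_scan"] = run_bin_scan(cfg)
    if not cfg.analyses:
        logger.info("empty analysis list: no-op")
    return out
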