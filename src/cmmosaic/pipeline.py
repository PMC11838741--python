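"""End-to-end orchestration of the synthetic-cohort analysis.

A single YAML config drives the run: cohort generation, amplification QC,
sensitivity-corrected burden estimation, mixed-effects fits, signature
refitting and de novo extraction, permutation enrichment, selection
statistics, and the LOO consensus DEG stage.  Every stage draws its seed
deterministically from the master seed (stable hash of the stage name), all
thresholds used are echoed into the run report, and every output file is
checksummed so a rerun with the same config is verifiable.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cmmosaic import annotation, burden, deg, enrichment, fileio, qc, sbs, signatures, synth


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


ALL_STAGES = ("synth", "qc", "burden", "fit", "signatures", "enrichment", "selection", "deg")


@dataclass
class RunConfig:
    outdir: str = "cmmosaic_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    catalog_path: str | None = None  # None -> synthesize a catalog
    ref_length: int = 400_000
    n_genes: int = 8
    n_signatures: int = 4
    n_control_donors: int = 6
    n_ihd_donors: int = 3
    cells_per_donor: int = 3
    beta0: float = 30_000.0  # scaled up so a toy genome receives mutations
    beta1: float = 2_000.0
    beta_I: float = 80_000.0
    sigma_u: float = 5_000.0
    sigma_e: float = 10_000.0
    qc_threshold: float = qc.DEFAULT_QC_THRESHOLD
    trim: tuple[float, float] = (0.25, 0.75)
    n_perm: int = 200
    nmf_ranks: tuple[int, int] = (1, 5)
    nmf_restarts: int = 10
    up_lfc: float = deg.DEFAULT_UP_LFC
    down_lfc: float = deg.DEFAULT_DOWN_LFC
    min_pct: float = deg.DEFAULT_MIN_PCT
    genome_size_gb: float = burden.DIPLOID_GENOME_GB
    n_germline_sites: int = 400
    deg_cells_per_donor: int = 60
    deg_n_genes: int = 120

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.catalog_path is not None and not os.path.exists(self.catalog_path):
            raise ConfigError(f"catalog path does not exist: {self.catalog_path}")
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        if not 0 <= self.trim[0] < self.trim[1] <= 1:
            raise ConfigError("trim quantiles must satisfy 0 <= lo < hi <= 1")


def stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in dependency order; returns the report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {
            "qc_threshold": config.qc_threshold,
            "trim": list(config.trim),
            "n_perm": config.n_perm,
            "up_lfc": config.up_lfc,
            "down_lfc": config.down_lfc,
            "min_pct": config.min_pct,
            "genome_size_gb": config.genome_size_gb,
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "stages": {},
        "checksums": {},
    }
    state: dict[str, Any] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, state, stage_seed(config.seed, stage))
        except Exception as exc:  # halt, retain partial outputs
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_report(config, report)
            raise StageError(stage, exc) from exc
        report["stages"][stage] = {"status": "ok", **outputs.get("summary", {})}
        for p in outputs.get("files", []):
            report["checksums"][os.path.relpath(p, config.outdir)] = _sha256(p)
    _write_report(config, report)
    return report


def _write_report(config: RunConfig, report: dict) -> None:
    path = os.path.join(config.outdir, "run_report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Stages


def _stage_synth(config: RunConfig, state: dict, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    ref = synth.generate_reference(config.ref_length, 0.41, seed)
    gene_models = synth.generate_gene_models(
        ref, config.n_genes, seed, gene_length=6000, flank=1500
    )
    if config.catalog_path:
        catalog = signatures.SignatureCatalog.from_tsv(config.catalog_path)
    else:
        catalog = signatures.synthetic_catalog(config.n_signatures, seed)
    design = synth.CohortDesign(
        n_control_donors=config.n_control_donors,
        n_ihd_donors=config.n_ihd_donors,
        cells_per_donor=config.cells_per_donor,
        beta0=config.beta0,
        beta1=config.beta1,
        beta_I=config.beta_I,
        sigma_u=config.sigma_u,
        sigma_e=config.sigma_e,
        seed=seed,
    )
    truth = synth.generate_cohort(design, ref, catalog)
    paths = truth.write(os.path.join(config.outdir, "cohort"))
    germline = synth.simulate_germline_variants(ref, config.n_germline_sites, rng)
    gpath = os.path.join(config.outdir, "cohort", "germline.vcf")
    fileio.write_vcf(gpath, germline, {ref.contig_name: ref.length})
    gff = os.path.join(config.outdir, "cohort", "genes.gff3")
    gene_models.to_gff3(gff)
    cat_path = os.path.join(config.outdir, "cohort", "catalog.tsv")
    catalog.to_tsv(cat_path)
    state.update(
        ref=ref, gene_models=gene_models, catalog=catalog, truth=truth, germline=germline
    )
    return {
        "files": [paths["fasta"], paths["phaseable"], paths["cells"], gpath, gff, cat_path],
        "summary": {
            "n_cells": len(truth.cells),
            "n_mutations": int(truth.cells["realized_mutations"].sum()),
        },
    }


def _stage_qc(config: RunConfig, state: dict, seed: int) -> dict:
    truth = state["truth"]
    cells = [
        qc.cell_qc_from_bins(cid, bins) for cid, bins in truth.bin_profiles.items()
    ]
    qc.score_cohort(cells)
    table = qc.qc_table(cells, config.qc_threshold)
    path = os.path.join(config.outdir, "qc.tsv")
    table.to_csv(path, sep="\t", index=False)
    state["qc_table"] = table
    state["included_cells"] = set(table.loc[table["included"], "cell_id"])
    return {"files": [path], "summary": {"n_included": int(table["included"].sum())}}


def _stage_burden(config: RunConfig, state: dict, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    truth = state["truth"]
    germline_sites = [(c.contig, c.pos) for c in state["germline"]]
    rows = []
    for _, cell in truth.cells.iterrows():
        bins = truth.bin_profiles[cell.cell_id]
        depths = burden._sites_with_depth(germline_sites, bins, must_hit=False)["depth"].to_numpy()
        recovered_mask = synth.depth_dropout_recovery(depths, rng)
        recovered = [s for s, r in zip(germline_sites, recovered_mask) if r]
        profile = burden.estimate_sensitivity(
            recovered, germline_sites, bins, trim=config.trim, method="zero-depth-refined"
        )
        call_sites = [(c.contig, c.pos) for c in truth.mutations[cell.cell_id]]
        n_calls = burden.calls_in_strata(call_sites, bins, profile)
        try:
            est = burden.genome_burden(n_calls, profile, config.genome_size_gb)
            per_gb = est.burden_per_gb
        except burden.UndefinedBurdenError:
            per_gb = np.nan
        rows.append(
            {
                "cell_id": cell.cell_id,
                "donor_id": cell.donor_id,
                "age": cell.age,
                "condition": cell.condition,
                "raw_calls": n_calls,
                "effective_callable_gb": profile.effective_callable_gb,
                "burden_per_gb_est": per_gb,
                "burden_per_gb": cell.burden_per_gb,
            }
        )
    table = pd.DataFrame(rows)
    path = os.path.join(config.outdir, "burden.tsv")
    table.to_csv(path, sep="\t", index=False)
    state["burden_table"] = table
    return {"files": [path], "summary": {"n_cells": len(table)}}


def _stage_fit(config: RunConfig, state: dict, seed: int) -> dict:
    table = state["burden_table"]
    out = {}
    controls = table[table["condition"] != "IHD"]
    if controls["donor_id"].nunique() >= 2:
        fit1 = burden.fit_burden_model(controls, burden.MixedModelSpec(model=1))
        out["model1"] = _fit_dict(fit1)
    if table["condition"].nunique() == 2:
        fit2 = burden.fit_burden_model(table, burden.MixedModelSpec(model=2))
        out["model2"] = _fit_dict(fit2)
    path = os.path.join(config.outdir, "fits.json")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
    state["fits"] = out
    return {"files": [path], "summary": {k: v["params"]["age"]["estimate"] for k, v in out.items() if "age" in v["params"]}}


def _fit_dict(fit: burden.MixedModelFit) -> dict:
    return {
        "model": fit.model,
        "fallback": fit.fallback,
        "singular": fit.singular,
        "sigma_u2": fit.sigma_u2,
        "sigma_e2": fit.sigma_e2,
        "params": {
            term: {c: float(fit.params.loc[term, c]) for c in fit.params.columns}
            for term in fit.params.index
        },
    }


def _stage_signatures(config: RunConfig, state: dict, seed: int) -> dict:
    truth = state["truth"]
    ref = state["ref"]
    catalog = state["catalog"]
    seqs = {ref.contig_name: ref.sequence}
    spectra = {}
    for cid, calls in truth.mutations.items():
        spectra[cid] = sbs.build_spectrum(calls, seqs)
    pooled = sbs.Spectrum(np.sum([s.counts for s in spectra.values()], axis=0))
    refit = signatures.fit_exposures(pooled, catalog)
    mat = np.vstack([spectra[cid].counts for cid in sorted(spectra)])
    active = mat.sum(axis=0) > 0
    lo, hi = config.nmf_ranks
    denovo = signatures.extract_denovo(
        mat, range(lo, hi + 1), n_restarts=config.nmf_restarts, seed=seed
    )
    path = os.path.join(config.outdir, "signatures.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "refit_exposures": dict(zip(refit.names, refit.exposures.tolist())),
                "refit_residual": refit.residual,
                "denovo_rank": denovo.rank,
                "cophenetic": denovo.cophenetic,
                "rss": denovo.rss,
            },
            fh,
            indent=2,
        )
    state["spectra"] = spectra
    return {"files": [path], "summary": {"denovo_rank": denovo.rank}}


def _stage_enrichment(config: RunConfig, state: dict, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    truth = state["truth"]
    ref = state["ref"]
    gene_models = state["gene_models"]
    calls = [c for calls in truth.mutations.values() for c in calls]
    if not calls:
        return {"files": [], "summary": {"skipped": "no mutations"}}
    expr = pd.Series(
        rng.lognormal(0, 1, size=len(gene_models)),
        index=[g.gene_id for g in gene_models],
    )
    footprints = {
        g.gene_id: [(g.contig, g.start - 1, g.end)] for g in gene_models
    }
    k = min(8, len(expr))
    groups = enrichment.make_groups(expr, footprints, k=k)
    perms = enrichment.permute_calls(
        calls, truth.phaseable, ref.sequence, n_perm=config.n_perm, seed=seed
    )
    result = enrichment.enrichment_ratio(calls, perms, groups)
    tsv = os.path.join(config.outdir, "enrichment.tsv")
    result.table.to_csv(tsv, sep="\t", index=False)
    js = os.path.join(config.outdir, "enrichment.json")
    with open(js, "w") as fh:
        json.dump({"R": result.r_value, "P": result.p_value}, fh, indent=2)
    return {"files": [tsv, js], "summary": {"R": result.r_value}}


def _stage_selection(config: RunConfig, state: dict, seed: int) -> dict:
    truth = state["truth"]
    ref = state["ref"]
    gene_models = state["gene_models"]
    seqs = {ref.contig_name: ref.sequence}
    somatic_calls = [c for calls in truth.mutations.values() for c in calls]
    som = annotation.annotate_calls(somatic_calls, gene_models, seqs)
    germ = annotation.annotate_calls(state["germline"], gene_models, seqs)
    exint, dnds = annotation.selection_ratios(som, germ)
    ann_path = os.path.join(config.outdir, "annotation.tsv")
    som.to_csv(ann_path, sep="\t", index=False)
    sel_path = os.path.join(config.outdir, "selection.json")
    with open(sel_path, "w") as fh:
        json.dump(
            {
                t.label: {
                    "somatic_a": t.somatic_a,
                    "somatic_b": t.somatic_b,
                    "germline_a": t.germline_a,
                    "germline_b": t.germline_b,
                    "ratio": None if np.isnan(t.ratio) else t.ratio,
                    "p": t.p_value,
                }
                for t in (exint, dnds)
            },
            fh,
            indent=2,
        )
    return {"files": [ann_path, sel_path], "summary": {"dnds_p": dnds.p_value}}


def _stage_deg(config: RunConfig, state: dict, seed: int) -> dict:
    counts, meta, genes = synth.simulate_counts_matrix(
        n_donors_per_condition=3,
        cells_per_donor=config.deg_cells_per_donor,
        n_genes=config.deg_n_genes,
        de_genes=[
            {"gene": 0, "lfc": 1.5, "condition": "IHD"},
            {"gene": 1, "lfc": -1.5, "condition": "IHD"},
        ],
        seed=seed,
    )
    data = deg.LabeledCounts(counts, meta, genes)
    result = deg.loo_consensus(
        data,
        up_threshold=config.up_lfc,
        down_threshold=config.down_lfc,
        min_pct=config.min_pct,
    )
    path = os.path.join(config.outdir, "deg_consensus.tsv")
    pd.DataFrame(
        [{"gene": g, "direction": "up"} for g in result.consensus_up]
        + [{"gene": g, "direction": "down"} for g in result.consensus_down]
    ).to_csv(path, sep="\t", index=False)
    frac, p = deg.proportion_test(meta, "cardiomyocyte")
    return {
        "files": [path],
        "summary": {
            "n_iterations": result.n_iterations,
            "n_up": len(result.consensus_up),
            "n_down": len(result.consensus_down),
        },
    }


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "qc": _stage_qc,
    "burden": _stage_burden,
    "fit": _stage_fit,
    "signatures": _stage_signatures,
    "enrichment": _stage_enrichment,
    "selection": _stage_selection,
    "deg": _stage_deg,
}
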