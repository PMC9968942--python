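"""End-to-end study-shaped pipeline: config, orchestration, report.

A :class:`RunConfig` (JSON-serialisable pydantic model) points either at
counts/taxonomy/metadata TSVs or at a simulation spec. :func:`run_pipeline`
executes ingest -> domain filter -> rarefaction -> every analysis stage,
records per-stage failures without aborting independent stages, and returns
a :class:`StudyReport` that regenerates bit-identically from the same
config and inputs (every stochastic stage's seed derives from the master
seed). The pydantic models are the committed schema: a report round-trips
through ``model_validate_json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .alpha import alpha_indices, compare_alpha_lmm, mean_alpha_over_rounds
from .beta import bray_curtis, pcoa, permanova
from .composition import diff_abundance, fb_ratio, summarize_composition
from .ncm import fit_ncm, fit_ncm_by_site
from .rf import rf_discriminate
from .simulate import (NeutralSimSpec, TwoSiteSimSpec, simulate_neutral,
                       simulate_two_site)
from .tables import filter_to_domain, rarefy, read_otu_table, site_taxon_sets, venn_counts

logger = logging.getLogger("gutassembly")

_STAGES = ("rarefy", "permanova", "rf", "alpha_rounds")


class SimulationConfig(BaseModel):
    kind: Literal["two_site", "neutral"]
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Everything needed to reproduce one pipeline run."""

    counts: Optional[str] = None
    taxonomy: Optional[str] = None
    metadata: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    domain: Optional[str] = "Bacteria"
    rarefy_depth: Union[Literal["min"], int, None] = "min"
    rarefy_rounds: int = 1
    ranks: list[str] = Field(default_factory=lambda: ["phylum", "family"])
    correction: str = "bh"
    permutations: int = 999
    rf_trees: int = 500
    ncm_by_site: bool = True
    seed: int = 17

    @model_validator(mode="after")
    def _inputs_present(self):
        have_files = all(v is not None for v in (self.counts, self.taxonomy, self.metadata))
        if not have_files and self.simulation is None:
            raise ValueError(
                "config must provide counts/taxonomy/metadata paths or a simulation spec"
            )
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()


class StudyReport(BaseModel):
    """Machine-readable pipeline output; one section per analysis stage."""

    provenance: dict
    config: RunConfig
    alpha: Optional[dict] = None
    alpha_comparisons: Optional[list] = None
    beta: Optional[dict] = None
    venn: Optional[dict] = None
    composition: Optional[dict] = None
    diff_abundance: Optional[dict] = None
    ncm: Optional[dict] = None
    rf: Optional[dict] = None
    errors: dict = Field(default_factory=dict)


def _stage_seeds(master: int) -> dict:
    states = np.random.SeedSequence(master).generate_state(len(_STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, states)}


def _load_table(config: RunConfig):
    if config.simulation is not None:
        params = dict(config.simulation.params)
        params.setdefault("seed", config.seed)
        if config.simulation.kind == "two_site":
            table, _ = simulate_two_site(TwoSiteSimSpec(**params))
        else:
            table, _ = simulate_neutral(NeutralSimSpec(**params))
        return table
    return read_otu_table(config.counts, config.taxonomy, config.metadata)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute the full analysis; cache the report under ``outdir`` by config hash."""
    cfg_hash = config.config_hash()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cached = out / "report.json"
        if cached.exists():
            try:
                prior = StudyReport.model_validate_json(cached.read_text())
                if prior.provenance.get("config_hash") == cfg_hash:
                    logger.info("reusing cached report %s", cached)
                    return prior
            except Exception:
                pass

    seeds = _stage_seeds(config.seed)
    report = StudyReport(
        provenance={
            "config_hash": cfg_hash,
            "gutassembly_version": __version__,
            "stage_seeds": seeds,
        },
        config=config,
    )

    table = _load_table(config)
    if config.domain:
        table = filter_to_domain(table, config.domain)
    if config.rarefy_depth is not None:
        depth = None if config.rarefy_depth == "min" else int(config.rarefy_depth)
        table = rarefy(table, depth, seed=seeds["rarefy"])

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
            logger.info("stage %-16s ok  (%.2fs, table %dx%d)", name,
                        time.perf_counter() - t0, table.n_taxa, table.n_samples)
            return result
        except Exception as exc:
            logger.warning("stage %s failed: %s", name, exc)
            report.errors[name] = f"{type(exc).__name__}: {exc}"
            return None

    # alpha diversity + mixed-model comparison
    def _alpha():
        if config.rarefy_rounds > 1 and config.rarefy_depth is not None:
            depth = None if config.rarefy_depth == "min" else int(config.rarefy_depth)
            a = mean_alpha_over_rounds(table, depth, config.rarefy_rounds,
                                       seeds["alpha_rounds"])
        else:
            a = alpha_indices(table)
        comparisons = compare_alpha_lmm(a, table.meta)
        return {"indices": a.reset_index().to_dict(orient="list")}, [
            asdict(c) for c in comparisons
        ]
    res = stage("alpha", _alpha)
    if res is not None:
        report.alpha, report.alpha_comparisons = res

    # beta diversity: distances, ordination, PERMANOVA
    def _beta():
        dm = bray_curtis(table)
        ord_res = pcoa(dm)
        perm = permanova(dm, table.meta["site"], config.permutations,
                         seed=seeds["permanova"])
        return {
            "pcoa_eigenvalues": ord_res.eigenvalues.tolist(),
            "pcoa_proportion_explained": ord_res.proportion_explained.to_dict(),
            "pcoa_coordinates": {
                "sample_id": list(ord_res.coordinates.index),
                "PC1": ord_res.coordinates.iloc[:, 0].tolist(),
                "PC2": (ord_res.coordinates.iloc[:, 1].tolist()
                        if ord_res.coordinates.shape[1] > 1 else None),
            },
            "permanova": {
                "pseudo_F": perm.pseudo_F, "R2": perm.R2,
                "p_value": perm.p_value, "n_permutations": perm.n_permutations,
            },
        }
    report.beta = stage("beta", _beta)

    # shared/unique taxa per rank (+ OTU level)
    def _venn():
        out_v = {}
        sets = site_taxon_sets(table)
        sites = sorted(sets)
        v = venn_counts(sets[sites[0]], sets[sites[1]])
        out_v["otu"] = {"shared": v.shared, f"unique_{sites[0]}": v.unique_a,
                        f"unique_{sites[1]}": v.unique_b}
        for rank in config.ranks:
            sets = site_taxon_sets(table, rank)
            v = venn_counts(sets[sites[0]], sets[sites[1]])
            out_v[rank] = {"shared": v.shared, f"unique_{sites[0]}": v.unique_a,
                           f"unique_{sites[1]}": v.unique_b}
        return out_v
    report.venn = stage("venn", _venn)

    # composition summaries, F/B, differential abundance
    def _composition():
        comp_out, diff_out = {}, {}
        for rank in config.ranks:
            summary = summarize_composition(table, rank)
            entry = {
                "site_mean": {c: summary.site_mean[c].to_dict()
                              for c in summary.site_mean.columns},
                "site_sd": {c: summary.site_sd[c].to_dict()
                            for c in summary.site_sd.columns},
                "displayed_taxa": summary.displayed_taxa,
                "others_by_site": summary.others_by_site.to_dict(),
            }
            if rank == "phylum":
                try:
                    fb = fb_ratio(summary)
                    entry["fb_ratio"] = {
                        "per_site": fb.per_site,
                        "overall_weighted": fb.overall_weighted,
                        "per_site_mean_of_ratios": fb.per_site_mean_of_ratios,
                        "overall_mean_of_ratios": fb.overall_mean_of_ratios,
                    }
                except KeyError:
                    pass
            comp_out[rank] = entry
            da = diff_abundance(table, rank, correction=config.correction)
            diff_out[rank] = da.reset_index().to_dict(orient="list")
        return comp_out, diff_out
    res = stage("composition", _composition)
    if res is not None:
        report.composition, report.diff_abundance = res

    # neutral community model, per site and pooled
    def _ncm():
        out_n = {"pooled": fit_ncm(table).to_dict()}
        if config.ncm_by_site:
            for site, fit in fit_ncm_by_site(table).items():
                out_n[site] = fit.to_dict()
        return out_n
    report.ncm = stage("ncm", _ncm)

    # random-forest discrimination per rank
    def _rf():
        out_r = {}
        for rank in config.ranks:
            r = rf_discriminate(table, rank, seed=seeds["rf"],
                                n_trees=config.rf_trees)
            out_r[rank] = {
                "auc_test": r.auc_test,
                "cv_auc_mean": r.cv_auc_mean,
                "top_taxa": r.importances.head(15).to_dict(orient="list"),
                "n_trees": r.n_trees,
            }
        return out_r
    report.rf = stage("rf", _rf)

    if out is not None:
        (out / "report.json").write_text(report.model_dump_json(indent=2))
    return report
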