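"""End-to-end pipeline orchestration with a single config and a run manifest.

Stage order: simulate -> pheno -> qc -> structure -> gwas -> varcomp ->
geneset -> haplo -> epi.  Every stage logs its parameters and row
counts, writes TSV intermediates under the output directory, and is
recorded in a JSON manifest (config hash, seed, per-stage outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import SNPAssociationModel
from .cytology import phenotype_table, validate_cytology
from .genio import read_ped_map, write_matrix_tsv
from .geneset import build_gene_sets, run_gene_set_analysis, set_intersections
from .haplo import (em_haplotype_freqs, epistasis_scan, gene_haplotype_blocks,
                    haplotype_assoc, pairs_between_genes)
from .qc import QCConfig, qc_pipeline
from .simulate import SimConfig, simulate_cohort, write_cohort
from .structure import group_ibs_permutation_test, ibs_matrix, mds
from .varcomp import per_chromosome_scan

log = logging.getLogger("eiphkit")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True},
    "phenotype": {"min_samples": 4, "threshold": 1, "mode": "count"},
    "qc": {"max_missing": 0.10, "hwe_p_threshold": 0.001, "min_maf": 0.02},
    "structure": {"n_perm": 1000, "case_rule": "hf_gt_zero"},
    "gwas": {"alpha": 0.05, "top_k": 20, "merge_gap": 5_000_000},
    "geneset": {"windows": [0, 5000, 20000]},
    "haplo": {"min_freq": 0.01, "max_block_snps": 12},
    "epi": {"p_threshold": 0.05},
    "mech": {"alpha": 1.0, "gamma": 5e-3, "stiffness_E": 1e3, "defect_length": 0.0},
    "vessel": {"radius": 5e-5, "viscosity": 3e-3, "length": 1e-3,
               "flow": 1e-12, "lumen_reduction": 0.0},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML file and explicit overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sim_config(cfg: dict) -> SimConfig:
    sim = {k: v for k, v in cfg.get("simulate", {}).items() if k != "enabled"}
    valid = {f.name for f in fields(SimConfig)}
    sim = {k: v for k, v in sim.items() if k in valid}
    sim.setdefault("seed", cfg.get("seed", 0))
    return SimConfig(**sim)


def run_all(config: dict | str | Path | None = None, out_dir="pipeline_out") -> dict:
    """Run every stage in order; returns the manifest dict.

    ``config`` may be a dict, a YAML path, or None for defaults.  On a
    stage failure the manifest records the failure point and downstream
    stages are skipped (the exception propagates after the manifest is
    written).
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(overrides=config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = {"version": __version__, "seed": seed,
                "config_hash": config_hash(cfg), "stages": []}

    def record(stage: str, outputs: dict):
        entry = {"stage": stage, "outputs": {}}
        for name, path in outputs.items():
            p = Path(path)
            n_rows = None
            if p.suffix == ".tsv" and p.exists():
                n_rows = sum(1 for _ in open(p)) - 1
            entry["outputs"][name] = {"path": str(p), "rows": n_rows}
        manifest["stages"].append(entry)
        log.info("stage %s done: %s", stage, {k: v["rows"] for k, v in entry["outputs"].items()})

    try:
        # --- simulate -------------------------------------------------
        if cfg.get("simulate", {}).get("enabled", True):
            sim_cfg = _sim_config(cfg)
            cohort = simulate_cohort(sim_cfg)
            paths = write_cohort(cohort, out / "inputs")
            record("simulate", paths)
            cyt_path, race_path = paths["cytology"], paths["races"]
            ped_path, map_path = paths["ped"], paths["map"]
            genes_path = paths["genes"]
        else:
            inputs = cfg.get("inputs", {})
            for key in ("cytology", "races", "ped", "map", "genes"):
                if key not in inputs or not Path(inputs[key]).exists():
                    raise FileNotFoundError(
                        f"simulate disabled and input '{key}' missing: "
                        f"{inputs.get(key, '<unset>')}")
            cyt_path, race_path = inputs["cytology"], inputs["races"]
            ped_path, map_path = inputs["ped"], inputs["map"]
            genes_path = inputs["genes"]

        # --- phenotype ------------------------------------------------
        pcfg = cfg["phenotype"]
        raw = pd.read_csv(cyt_path, sep="\t")
        races = pd.read_csv(race_path, sep="\t")
        validated, vreport = validate_cytology(raw)
        log.info("cytology: %d/%d records retained", vreport.n_retained, vreport.n_input)
        pheno = phenotype_table(validated, races, min_n=pcfg["min_samples"],
                                threshold=pcfg["threshold"], mode=pcfg["mode"])
        pheno_path = out / "phenotype.tsv"
        pheno.to_csv(pheno_path, sep="\t")
        record("pheno", {"phenotype": pheno_path})

        # --- qc -------------------------------------------------------
        qcfg = cfg["qc"]
        matrix = read_ped_map(ped_path, map_path)
        filtered, report = qc_pipeline(matrix, QCConfig(
            max_missing=qcfg["max_missing"], hwe_p_threshold=qcfg["hwe_p_threshold"],
            min_maf=qcfg["min_maf"]))
        for name, thr, n_rm in report.steps:
            log.info("qc filter %s (threshold %s): removed %d", name, thr, n_rm)
        qc_path = out / "qc_report.tsv"
        report.to_frame().to_csv(qc_path, sep="\t", index=False)
        write_matrix_tsv(filtered, out / "genotypes.tsv", out / "genotypes.map.tsv")
        record("qc", {"report": qc_path, "genotypes": out / "genotypes.tsv"})

        # --- align phenotype with genotypes ---------------------------
        common = [i for i in filtered.individuals if i in pheno.index]
        gmat = filtered.subset_individuals([i in pheno.index for i in filtered.individuals])
        ptab = pheno.loc[common]

        # --- structure ------------------------------------------------
        scfg = cfg["structure"]
        ibs = ibs_matrix(gmat)
        coords = mds(ibs, k=2)
        if scfg["case_rule"] == "hf_gt_zero":
            cases = (ptab["hf_frequency"] > 0).to_numpy()
        else:
            cases = (ptab["hf_frequency"] > float(scfg["case_rule"])).to_numpy()
        perm = group_ibs_permutation_test(ibs, cases, n_perm=scfg["n_perm"], seed=seed)
        log.info("structure: between-group IBS variance proportion %.5f (p=%.4f)",
                 perm.statistic, perm.p_value)
        ibs_path, mds_path = out / "ibs.tsv", out / "mds.tsv"
        pd.DataFrame(ibs, index=gmat.individuals, columns=gmat.individuals).to_csv(
            ibs_path, sep="\t")
        pd.DataFrame(coords, index=gmat.individuals,
                     columns=[f"dim{i+1}" for i in range(coords.shape[1])]).to_csv(
            mds_path, sep="\t", index_label="id")
        record("structure", {"ibs": ibs_path, "mds": mds_path})

        # --- gwas -----------------------------------------------------
        gcfg = cfg["gwas"]
        model = SNPAssociationModel.from_tables(ptab, gmat)
        results = model.fit()
        log.info("gwas: %s", results.summary(alpha=gcfg["alpha"]).replace("\n", " | "))
        assoc_path = out / "assoc.tsv"
        results.table.to_csv(assoc_path, sep="\t", index=False)
        regions = results.top_regions(k=gcfg["top_k"], merge_gap=gcfg["merge_gap"])
        regions_path = out / "regions.tsv"
        regions.to_csv(regions_path, sep="\t", index=False)
        results.manhattan_table().to_csv(out / "manhattan.tsv", sep="\t", index=False)
        results.qq_table().to_csv(out / "qq.tsv", sep="\t", index=False)
        record("gwas", {"assoc": assoc_path, "regions": regions_path,
                        "manhattan": out / "manhattan.tsv", "qq": out / "qq.tsv"})

        # --- varcomp --------------------------------------------------
        y = ptab["hf_frequency"].to_numpy(dtype=float)
        covar_cols = [c for c in ("gender", "age_first_start", "period_second",
                                  "period_both", "mean_days_since_race")
                      if c in ptab.columns]
        cov = ptab[covar_cols].to_numpy(dtype=float)
        vtab = per_chromosome_scan(y, gmat, covariates=cov)
        varcomp_path = out / "varcomp.tsv"
        vtab.to_csv(varcomp_path, sep="\t", index=False)
        record("varcomp", {"varcomp": varcomp_path})

        # --- geneset --------------------------------------------------
        genes = pd.read_csv(genes_path, sep="\t")
        sets = build_gene_sets(genes)
        tables = run_gene_set_analysis(results.table, genes, sets, gmat,
                                       windows=tuple(cfg["geneset"]["windows"]))
        gs_paths = {}
        for window, tab in tables.items():
            p = out / f"geneset_window{window}.tsv"
            tab.to_csv(p, sep="\t", index=False)
            gs_paths[f"window{window}"] = p
        inter = set_intersections(sets)
        inter_path = out / "set_intersections.tsv"
        inter.to_csv(inter_path, sep="\t", index=False)
        gs_paths["intersections"] = inter_path
        record("geneset", gs_paths)

        # --- haplo: blocks over the triple-intersection genes ----------
        hcfg = cfg["haplo"]
        triple = inter.loc[inter["order"] == 3, "genes"]
        triple_genes = (triple.iloc[0].split(",") if len(triple) and triple.iloc[0]
                        else [])
        focus = genes[genes["symbol"].isin(triple_genes)]
        hap_rows = []
        for gene_row, snps in gene_haplotype_blocks(gmat, focus,
                                                    max_snps=hcfg["max_block_snps"]):
            block = em_haplotype_freqs(gmat, snp_ids=snps)
            tab = haplotype_assoc(y, block, covariates=cov,
                                  min_freq=hcfg["min_freq"],
                                  chromosome=gene_row["chromosome"],
                                  bp_span=f"{gene_row['start']}-{gene_row['end']}",
                                  gene=gene_row["symbol"])
            hap_rows.append(tab)
        haplo_path = out / "haplotypes.tsv"
        (pd.concat(hap_rows, ignore_index=True) if hap_rows else pd.DataFrame()
         ).to_csv(haplo_path, sep="\t", index=False)
        record("haplo", {"haplotypes": haplo_path})

        # --- epi: cross-gene SNP pairs among the same genes ------------
        from .geneset import assign_snps_to_genes
        g2s = assign_snps_to_genes(gmat.snp_map, focus, window=0)
        pairs, labels = pairs_between_genes(g2s, list(focus["symbol"]))
        epi = epistasis_scan(y, gmat, pairs, covariates=cov,
                             p_threshold=cfg["epi"]["p_threshold"])
        if len(epi):
            epi.insert(2, "gene_1", [a for a, _ in labels])
            epi.insert(3, "gene_2", [b for _, b in labels])
        epi_path = out / "epistasis.tsv"
        epi.to_csv(epi_path, sep="\t", index=False)
        record("epi", {"epistasis": epi_path})
    finally:
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
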