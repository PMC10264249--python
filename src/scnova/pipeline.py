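"""End-to-end orchestration: ingest -> states -> counts -> DGE -> haplotype -> gene sets.

Each stage writes its result tables under the configured output directory and
records a provenance entry (inputs, parameters, seed). Stages whose inputs
are not configured are skipped and noted in the provenance file.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import (
    compute_size_factors,
    differential_activity,
    gene_features,
    retain_by_ne_probability,
    train_ne_classifier,
    mask_scna_genes,
)
from .config import PipelineConfig
from .fragments import BlacklistRegions, apply_blacklist, classify_strand_states, read_fragments
from .genesets import overrepresentation_test, pathway_lmm_test, pathway_no_scores, read_gmt
from .haplo import haplotype_unit_counts, local_scan, sv_table_from_tsv, test_haplotype_no
from .tracks import gene_body_counts, normalize_counts, pseudobulk_track, read_bed_intervals, read_genes_bed, track_to_bedgraph

logger = logging.getLogger(__name__)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns a dict of result frames.

    Raises RuntimeError naming the failing stage on error.
    """
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"version": __version__, "seed": cfg.seed, "parameters": cfg.to_dict(), "stages": {}}
    results = {}
    stage = "ingest"
    try:
        t0 = time.time()
        frags = read_fragments(cfg.fragments, mapq_min=cfg.mapq_min)
        if cfg.blacklist:
            frags = apply_blacklist(frags, BlacklistRegions.from_bed(cfg.blacklist))
        results["fragments"] = frags
        prov["stages"][stage] = {"status": "ok", "n_fragments": frags.n_fragments, "seconds": round(time.time() - t0, 2)}

        stage = "states"
        t0 = time.time()
        states = classify_strand_states(frags, min_fragments=cfg.min_fragments_state)
        states.entries.to_csv(out / "strand_states.tsv", sep="\t", index=False)
        results["states"] = states
        prov["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}

        stage = "tracks"
        t0 = time.time()
        track = pseudobulk_track(frags, bin_size=cfg.bin_size)
        track_to_bedgraph(track, out / "no_track.bedgraph")
        prov["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}

        stage = "counts"
        genes = counts = norm = None
        if cfg.genes:
            t0 = time.time()
            genes = read_genes_bed(cfg.genes)
            counts = gene_body_counts(frags, genes)
            counts.counts.to_csv(out / "gene_body_counts.tsv", sep="\t")
            cn = clones = None
            clone_of_cell = {}
            if cfg.cn_table:
                cn = pd.read_csv(cfg.cn_table, sep="\t", dtype={"chrom": str})
            if cfg.clone_table:
                clones = pd.read_csv(cfg.clone_table, sep="\t", dtype=str)
                clone_of_cell = dict(zip(clones["cell"], clones["clone"]))
            norm = normalize_counts(counts, cn, clone_of_cell)
            norm.values.to_csv(out / "gene_body_normalized.tsv", sep="\t")
            results.update(counts=counts, normalized=norm, genes=genes, clones=clones, cn=cn)
            prov["stages"][stage] = {"status": "ok", "n_genes": len(genes), "seconds": round(time.time() - t0, 2)}
        else:
            prov["stages"][stage] = {"status": "skipped", "reason": "no gene models configured"}

        stage = "dge"
        if counts is not None and cfg.clone_table:
            t0 = time.time()
            clones = results["clones"]
            labels = clones.set_index("cell")["clone"].reindex(counts.counts.columns)
            clone_ids = sorted(labels.dropna().unique())
            gene_universe = list(counts.counts.index)
            if cfg.ne_labels:
                ne = pd.read_csv(cfg.ne_labels, sep="\t")
                feats = gene_features(frags, genes)
                model = train_ne_classifier(
                    feats.loc[ne["gene_id"]], ne["ne"].to_numpy(), threshold=cfg.ne_threshold, seed=cfg.seed
                )
                probs = {}
                for cid in clone_ids:
                    sub = frags.subset(frags.df["cell"].isin(labels.index[labels == cid]).to_numpy())
                    probs[cid] = model.predict_proba(gene_features(sub, genes, chrom_lengths=track.chrom_lengths))
                gene_universe = retain_by_ne_probability(pd.DataFrame(probs), cfg.ne_threshold)
            dge_tables = []
            for i in range(len(clone_ids)):
                for j in range(i + 1, len(clone_ids)):
                    a, b = clone_ids[i], clone_ids[j]
                    keep = gene_universe
                    if results.get("cn") is not None:
                        keep = [g for g in mask_scna_genes(genes, results["cn"], a, b) if g in set(gene_universe)]
                    cells = labels.index[labels.isin([a, b])]
                    sub_counts = counts.counts.loc[keep, cells]
                    minor_cf = labels.loc[cells].value_counts().min() / len(cells)
                    res = differential_activity(sub_counts, labels.loc[cells].to_numpy(), minor_cf=minor_cf,
                                                cf_switch=cfg.cf_mode_switch, n_perm=min(cfg.n_perm, 199), seed=cfg.seed)
                    tab = res.frame.assign(clone_a=a, clone_b=b)
                    dge_tables.append(tab)
            if dge_tables:
                dge = pd.concat(dge_tables, ignore_index=True)
                dge.to_csv(out / "dge_results.tsv", sep="\t", index=False)
                results["dge"] = dge
            prov["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        else:
            prov["stages"][stage] = {"status": "skipped", "reason": "needs gene models and a clone table"}

        stage = "haplotype"
        if cfg.sv_table and genes is not None:
            t0 = time.time()
            svs = sv_table_from_tsv(cfg.sv_table)
            units = genes.rename(columns={"gene_id": "unit_id"})[["unit_id", "chrom", "start", "end"]]
            hc = haplotype_unit_counts(frags, units, states)
            haplo = test_haplotype_no(hc)
            haplo.to_csv(out / "haplotype_tests.tsv", sep="\t", index=False)
            scan = local_scan(svs, haplo, units, radius=cfg.scan_radius, fdr=cfg.fdr)
            scan.to_csv(out / "sv_local_scan.tsv", sep="\t", index=False)
            results.update(haplo=haplo, local_scan=scan)
            prov["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        else:
            prov["stages"][stage] = {"status": "skipped", "reason": "needs an SV table and gene models"}

        stage = "genesets"
        if cfg.gene_sets and results.get("dge") is not None:
            t0 = time.time()
            sets = read_gmt(cfg.gene_sets)
            dge = results["dge"]
            universe = dge["gene_id"].unique().tolist()
            hits = dge.loc[dge["q"] < cfg.fdr, "gene_id"].unique().tolist()
            enr = overrepresentation_test(hits, universe, sets, fdr=cfg.fdr)
            enr.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enr
            clones = results["clones"]
            if clones is not None and "batch" in clones.columns and cfg.sv_table:
                k = results["counts"].counts
                s = compute_size_factors(k)
                normc = np.log2(k.div(s, axis=1) + 1.0)
                ps = pathway_no_scores(normc, sets, activity_transform=True)
                ps.scores.to_csv(out / "pathway_scores.tsv", sep="\t")
                svs = sv_table_from_tsv(cfg.sv_table)
                sv_clones = {sv.clone_id for sv in svs}
                meta = clones.set_index("cell").reindex(ps.scores.index)
                sv_status = meta["clone"].isin(sv_clones).to_numpy()
                if sv_status.sum() >= 2 and (~sv_status).sum() >= 2:
                    lmm = pathway_lmm_test(ps, sv_status, meta["batch"].to_numpy(), fdr=cfg.fdr)
                    lmm.to_csv(out / "pathway_tests.tsv", sep="\t", index=False)
                    results["pathway_tests"] = lmm
            prov["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        else:
            prov["stages"][stage] = {"status": "skipped", "reason": "needs gene sets and DGE results"}
    except Exception as exc:
        prov["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    results["provenance"] = prov
    return results
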