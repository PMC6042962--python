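"""Orchestration of the two study workflows.

The occupancy workflow mirrors the ChIP-seq arm: per-condition fold-change
peak calling, consensus building, differential labelling between the two
nutrient conditions, closest-TSS gene assignment with non-Pol II genes
removed, term enrichment of the up/down gene lists, and per-condition
metagene profiles. The expression workflow mirrors the RNA-seq arm: RPKM,
expression quantile groups with quantile-stratified metagenes, the
differential-expression stand-in, and the condition-vs-mutant dependence
scatter (overall and per gene subset).

Everything is deterministic given the inputs and the single top-level
seed; per-stage seeds are derived from it with ``numpy`` SeedSequence
spawning. The run log is a JSON of parameters, input checksums and
per-stage record counts (no timestamps), so byte-identical reruns are a
meaningful contract.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .assign import assign_peaks, distinct_gene_ids, filter_genes
from .differential import build_consensus, differential_call, differential_table
from .model import GenomicInterval, Peak, PeakSet
from .peaks import PeakCallParams, call_peaks
from .profiles import ExpressionMatrix, de_genes, dependence_scatter, metagene_profile, quantile_groups
from .stats import term_enrichment
from . import simulate


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    cfg["_base"] = str(path.parent)
    return cfg


def _resolve(cfg: dict, rel: str) -> Path:
    p = Path(rel)
    return p if p.is_absolute() else Path(cfg.get("_base", ".")) / p


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(cfg: dict, key: str, stage: str):
    if key not in cfg:
        raise PipelineError(f"{stage}: missing config key {key!r}")
    return cfg[key]


def _metagene_frame(profile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": profile.positions,
            "mean_signal": profile.mean_signal,
            "n_genes": profile.n_genes,
        }
    )


def run_occupancy_pipeline(config: dict, outdir: str | Path) -> dict:
    """Peak calling -> consensus -> differential -> assignment -> enrichment
    -> metagenes. Returns the run log (also written to run_log.json)."""
    occ = _require(config, "occupancy", "occupancy")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stage_counts": {}, "inputs": {}, "parameters": {}}

    genes_path = _resolve(config, _require(occ, "genes", "occupancy"))
    sizes_path = _resolve(config, occ["chrom_sizes"]) if "chrom_sizes" in occ else None
    for p in [genes_path] + ([sizes_path] if sizes_path else []):
        if not p.exists():
            raise PipelineError(f"occupancy: input file not found: {p}")
        log["inputs"][p.name] = _checksum(p)
    genes = cio.read_gene_annotation(genes_path)
    sizes = cio.read_chrom_sizes(sizes_path) if sizes_path else None

    params = PeakCallParams(**occ.get("peak_params", {}))
    log["parameters"]["peak_params"] = params.__dict__

    conditions = _require(occ, "conditions", "occupancy")
    if len(conditions) != 2:
        raise PipelineError("occupancy: exactly two conditions required")
    (name_a, files_a), (name_b, files_b) = list(conditions.items())
    tracks = {}
    for name, files in ((name_a, files_a), (name_b, files_b)):
        for role in ("ip", "input"):
            p = _resolve(config, files[role])
            if not p.exists():
                raise PipelineError(f"occupancy: input file not found: {p}")
            log["inputs"][p.name] = _checksum(p)
            tracks[(name, role)] = cio.read_bedgraph(p, chrom_sizes=sizes)

    peak_sets = {}
    for name in (name_a, name_b):
        ps = call_peaks(tracks[(name, "ip")], tracks[(name, "input")], params)
        peak_sets[name] = ps
        cio.write_bed(ps, outdir / f"peaks_{name}.bed")
        log["stage_counts"][f"peaks_{name}"] = len(ps)

    consensus = build_consensus(
        peak_sets[name_a], peak_sets[name_b], occ.get("consensus_gap", 0)
    )
    log["stage_counts"]["consensus"] = len(consensus)

    diff = differential_call(
        consensus,
        tracks[(name_a, "ip")],
        tracks[(name_b, "ip")],
        lfc_threshold=occ.get("lfc_threshold", 1.0),
        test=occ.get("test", "none"),
        alpha=occ.get("alpha", 0.05),
    )
    dtab = differential_table(diff)
    dtab.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    log["stage_counts"]["differential_up"] = int((dtab["label"] == "up").sum())
    log["stage_counts"]["differential_down"] = int((dtab["label"] == "down").sum())

    exclude = occ.get("exclude_non_polII", True)
    universe = sorted(g.gene_id for g in filter_genes(genes, exclude))
    gene_lists = {}
    for direction in ("up", "down"):
        intervals = [
            Peak(GenomicInterval(r.chrom, r.start, r.end), 0.0)
            for r in dtab[dtab["label"] == direction].itertuples()
        ]
        assignments = assign_peaks(PeakSet(intervals), genes, exclude)
        pd.DataFrame(
            {
                "chrom": [a.peak.chrom for a in assignments],
                "start": [a.peak.start for a in assignments],
                "end": [a.peak.end for a in assignments],
                "gene_id": [a.gene_id or "" for a in assignments],
                "distance": [a.distance for a in assignments],
                "tie": [a.tie for a in assignments],
            }
        ).to_csv(outdir / f"assignments_{direction}.tsv", sep="\t", index=False)
        gene_lists[direction] = distinct_gene_ids(assignments)
        log["stage_counts"][f"genes_{direction}"] = len(gene_lists[direction])

    if "terms" in occ:
        terms_path = _resolve(config, occ["terms"])
        if not terms_path.exists():
            raise PipelineError(f"occupancy: input file not found: {terms_path}")
        log["inputs"][terms_path.name] = _checksum(terms_path)
        term_map = cio.read_term_map(terms_path)
        for direction, gene_list in gene_lists.items():
            results = term_enrichment(
                gene_list,
                universe,
                term_map,
                p_cutoff=occ.get("enrichment_p_cutoff", 0.05),
                min_k=occ.get("enrichment_min_k", 2),
                bh=occ.get("enrichment_bh", False),
            )
            pd.DataFrame(
                {
                    "term": [r.term for r in results],
                    "k": [r.k for r in results],
                    "n": [r.n for r in results],
                    "K": [r.K for r in results],
                    "N": [r.N for r in results],
                    "p_value": [r.p_value for r in results],
                    "fold_enrichment": [r.fold_enrichment for r in results],
                    "included": [r.included for r in results],
                }
            ).to_csv(outdir / f"enrichment_{direction}.tsv", sep="\t", index=False)
            log["stage_counts"][f"enriched_terms_{direction}"] = sum(
                r.included for r in results
            )

    mg = occ.get("metagene", {})
    polII = filter_genes(genes, True)
    for name in (name_a, name_b):
        profile = metagene_profile(
            tracks[(name, "ip")],
            polII,
            mode=mg.get("mode", "tss_anchored"),
            flank=mg.get("flank", 2000),
            body_points=mg.get("body_points", 1000),
            smooth_window=mg.get("smooth", 101),
        )
        _metagene_frame(profile).to_csv(
            outdir / f"metagene_{name}.tsv", sep="\t", index=False
        )

    log["parameters"]["seed"] = config.get("seed")
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return log


def run_expression_pipeline(config: dict, outdir: str | Path) -> dict:
    """RPKM -> quantile groups -> quantile metagenes; DE stand-in; scatter."""
    expr_cfg = _require(config, "expression", "expression")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stage_counts": {}, "inputs": {}, "parameters": {}}

    counts_path = _resolve(config, _require(expr_cfg, "counts", "expression"))
    genes_path = _resolve(config, _require(expr_cfg, "genes", "expression"))
    for p in (counts_path, genes_path):
        if not p.exists():
            raise PipelineError(f"expression: input file not found: {p}")
        log["inputs"][p.name] = _checksum(p)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    genes = cio.read_gene_annotation(genes_path)
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    expr = ExpressionMatrix(counts, lengths)

    rpkm_df = expr.rpkm_matrix
    rpkm_df.to_csv(outdir / "rpkm.tsv", sep="\t")
    groups_cfg: Mapping[str, list[str]] = _require(expr_cfg, "groups", "expression")
    group_means = {
        name: rpkm_df[cols].mean(axis=1) for name, cols in groups_cfg.items()
    }

    # quantiles on Pol II genes' expression in the reference condition
    polII_ids = [g.gene_id for g in filter_genes(genes, True) if g.gene_id in rpkm_df.index]
    quant_on = expr_cfg.get("quantile_on", list(groups_cfg)[0])
    k = expr_cfg.get("n_quantiles", 5)
    qgroups = quantile_groups(group_means[quant_on].loc[polII_ids], n_groups=k)
    qgroups.rename_axis("gene_id").to_frame().to_csv(
        outdir / "quantile_groups.tsv", sep="\t"
    )
    log["stage_counts"]["quantile_groups"] = int(k)

    if "track" in expr_cfg:
        track_path = _resolve(config, expr_cfg["track"])
        if not track_path.exists():
            raise PipelineError(f"expression: input file not found: {track_path}")
        log["inputs"][track_path.name] = _checksum(track_path)
        sizes = None
        occ = config.get("occupancy", {})
        if "chrom_sizes" in occ:
            sizes = cio.read_chrom_sizes(_resolve(config, occ["chrom_sizes"]))
        track = cio.read_bedgraph(track_path, chrom_sizes=sizes)
        mg = expr_cfg.get("metagene", {})
        by_id = {g.gene_id: g for g in genes}
        frames = []
        for q in range(1, k + 1):
            members = [by_id[g] for g in qgroups.index[qgroups == q]]
            profile = metagene_profile(
                track,
                members,
                mode=mg.get("mode", "tss_anchored"),
                flank=mg.get("flank", 2000),
                body_points=mg.get("body_points", 1000),
                smooth_window=mg.get("smooth", 101),
            )
            frame = _metagene_frame(profile)
            frame.insert(0, "quantile", q)
            frames.append(frame)
        pd.concat(frames).to_csv(outdir / "quantile_profiles.tsv", sep="\t", index=False)

    contrast = expr_cfg.get("de_contrast")
    if contrast:
        cond_a, cond_b = contrast
        labels = {}
        for s in groups_cfg[cond_a]:
            labels[s] = cond_a
        for s in groups_cfg[cond_b]:
            labels[s] = cond_b
        de = de_genes(
            ExpressionMatrix(expr.counts[list(labels)], lengths),
            labels,
            lfc_threshold=expr_cfg.get("lfc_threshold", 1.0),
            alpha=expr_cfg.get("alpha", 0.05),
        )
        de.to_csv(outdir / "de.tsv", sep="\t")
        log["stage_counts"]["de_genes"] = int(de["de"].sum())

    scatter_cfg = expr_cfg.get("scatter")
    if scatter_cfg:
        # scatter works on summed counts per condition (per-million inside)
        cond_counts = {
            name: expr.counts[cols].sum(axis=1).astype(float)
            for name, cols in groups_cfg.items()
        }
        subsets: dict[str, list[str] | None] = {"all": None}
        for name, listfile in (scatter_cfg.get("subsets") or {}).items():
            p = _resolve(config, listfile)
            if not p.exists():
                raise PipelineError(f"expression: subset file not found: {p}")
            subsets[name] = [
                line.strip() for line in p.read_text().splitlines() if line.strip()
            ]
        rows = []
        for name, subset in subsets.items():
            x, y, r = dependence_scatter(
                cond_counts[scatter_cfg.get("wt_glu", "wt_glu")],
                cond_counts[scatter_cfg.get("wt_gly", "wt_gly")],
                cond_counts[scatter_cfg.get("mut_gly", "mut_gly")],
                gene_subset=subset,
            )
            rows.append({"subset": name, "n_genes": len(x), "pearson_r": r})
            if name == "all":
                pd.DataFrame({"gene_id": x.index, "x": x.to_numpy(), "y": y.to_numpy()}).to_csv(
                    outdir / "scatter.tsv", sep="\t", index=False
                )
        pd.DataFrame(rows).to_csv(outdir / "scatter_r.tsv", sep="\t", index=False)
        log["stage_counts"]["scatter_subsets"] = len(rows)

    log["parameters"]["seed"] = config.get("seed")
    (outdir / "expression_run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return log


def cfu_viability(
    colony_counts: Mapping[int, int], reference_day: int = 3
) -> dict[int, float]:
    """Chronological-lifespan viability: each day's colony count as a
    percentage of the reference day's count (reference day = 100%)."""
    if reference_day not in colony_counts:
        raise ValueError(f"reference day {reference_day} missing from counts")
    ref = colony_counts[reference_day]
    if ref <= 0:
        raise ValueError("reference day colony count must be positive")
    for day, c in colony_counts.items():
        if c < 0:
            raise ValueError(f"negative colony count at day {day}")
    return {day: 100.0 * c / ref for day, c in sorted(colony_counts.items())}


def simulate_fixture(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 60,
    chrom_length: int = 300_000,
    n_up: int = 6,
    n_shared: int = 3,
    fold: float = 3.0,
    background: float = 50.0,
    noise: str = "poisson",
    reversion: float = 1.0,
) -> dict:
    """Write a complete synthetic study (annotation, coverage pairs for two
    conditions, three-condition counts, term map, config, truth sidecar).

    Condition B ("glycerol") carries ``n_up`` extra promoter-centered
    enriched regions absent from condition A ("glucose"); ``n_shared``
    regions are planted identically in both. The term map plants one term
    holding exactly the up-region genes. Expression plants a positive
    condition response at the up genes, which the mutant reverts by
    ``reversion`` (1.0 = full reversion, the anti-identity construction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]

    genes = simulate.generate_genome(
        n_chroms=1,
        chrom_length=chrom_length,
        n_genes=n_genes,
        frac_non_polII=0.1,
        seed=seeds[0],
    )
    polII = [g for g in genes if g.polymerase == "PolII"]
    chosen = [g.gene_id for g in polII[:: max(1, len(polII) // (n_up + n_shared))]][
        : n_up + n_shared
    ]
    up_ids, shared_ids = chosen[:n_up], chosen[n_up:]
    up_regions = simulate.plant_promoter_regions(genes, up_ids, fold=fold)
    shared_regions = simulate.plant_promoter_regions(genes, shared_ids, fold=fold)
    sizes = simulate.chrom_sizes_for(genes)

    ip_a, input_a, _ = simulate.generate_coverage_pair(
        genes, shared_regions, background, noise=noise, seed=seeds[1], chrom_sizes=sizes
    )
    ip_b, input_b, truth_b = simulate.generate_coverage_pair(
        genes,
        sorted(up_regions + shared_regions, key=lambda r: (r[0].chrom, r[0].start)),
        background,
        noise=noise,
        seed=seeds[2],
        chrom_sizes=sizes,
    )

    planted_lfc = {g: 2.0 for g in up_ids}
    expr, _ = simulate.generate_three_condition_counts(
        genes,
        n_samples_per_group=2,
        baseline_mean=200.0,
        planted_log2fc=planted_lfc,
        reversion=reversion,
        dispersion=0.0,
        seed=seeds[3],
    )
    term_map = simulate.generate_term_map(
        genes, n_terms=15, genes_per_term=8,
        planted_term=("TERM:PLANTED", up_ids), seed=seeds[4],
    )

    cio.write_gtf(genes, outdir / "genes.gtf")
    cio.write_chrom_sizes(sizes, outdir / "chrom.sizes")
    cio.write_bedgraph(ip_a, outdir / "ip_glucose.bedgraph")
    cio.write_bedgraph(input_a, outdir / "input_glucose.bedgraph")
    cio.write_bedgraph(ip_b, outdir / "ip_glycerol.bedgraph")
    cio.write_bedgraph(input_b, outdir / "input_glycerol.bedgraph")
    cio.write_term_map(term_map, outdir / "terms.tsv")
    expr.counts.to_csv(outdir / "counts.tsv", sep="\t")

    truth = {
        "up_gene_ids": up_ids,
        "shared_gene_ids": shared_ids,
        "up_regions": [
            [iv.chrom, iv.start, iv.end, f] for iv, f in up_regions
        ],
        "shared_regions": [
            [iv.chrom, iv.start, iv.end, f] for iv, f in shared_regions
        ],
        "planted_term": "TERM:PLANTED",
        "planted_log2fc": planted_lfc,
        "reversion": reversion,
        "seed": seed,
    }
    (outdir / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    samples = list(expr.counts.columns)
    config = {
        "seed": seed,
        "occupancy": {
            "genes": "genes.gtf",
            "chrom_sizes": "chrom.sizes",
            "terms": "terms.tsv",
            "conditions": {
                "glucose": {"ip": "ip_glucose.bedgraph", "input": "input_glucose.bedgraph"},
                "glycerol": {"ip": "ip_glycerol.bedgraph", "input": "input_glycerol.bedgraph"},
            },
            "peak_params": {
                "fold_threshold": 2.0,
                "min_run": 50,
                "merge_gap": 400,
                "pseudocount": 1.0,
                "depth_normalize": True,
            },
            "lfc_threshold": 1.0,
            "test": "none",
            "metagene": {"mode": "tss_anchored", "flank": 2000, "smooth": 101},
        },
        "expression": {
            "counts": "counts.tsv",
            "genes": "genes.gtf",
            "groups": {
                "wt_glu": [s for s in samples if s.startswith("wt_glu")],
                "wt_gly": [s for s in samples if s.startswith("wt_gly")],
                "mut_gly": [s for s in samples if s.startswith("mut_gly")],
            },
            "quantile_on": "wt_gly",
            "n_quantiles": 5,
            "track": "ip_glycerol.bedgraph",
            "metagene": {"mode": "tss_anchored", "flank": 1000, "smooth": 101},
            "de_contrast": ["wt_glu", "wt_gly"],
            "scatter": {"wt_glu": "wt_glu", "wt_gly": "wt_gly", "mut_gly": "mut_gly"},
        },
    }
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth


def run_all(config_path: str | Path, outdir: str | Path) -> dict:
    """Run both workflows from one config; any stage error aborts with the
    stage name."""
    config = load_config(config_path)
    log_occ = run_occupancy_pipeline(config, outdir)
    log_expr = run_expression_pipeline(config, outdir)
    return {"occupancy": log_occ, "expression": log_expr}
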