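"""End-to-end orchestration: profiling -> differential expression -> hairpin
screening -> target scanning -> integration, from one config.

Every stage reads and writes plain tab-separated files, so each can be run
standalone; ``run_pipeline`` chains them and writes a manifest echoing the
seed, every threshold and every output path, making the run
self-describing.  ``make_demo`` generates a full synthetic workspace with
the generators in ``capmir.simulate`` and runs the pipeline on it.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .diffexpr import de_frame, de_table
from .hairpin import (
    HairpinThresholds,
    candidate_precursor,
    evaluate_candidate,
    extract_flanks,
)
from .integration import (
    build_network,
    enrich_pathways,
    intersect_de_targets,
    select_de_mirnas,
    significant_pathways,
)
from .io import (
    CountTable,
    read_count_table,
    read_fasta,
    read_gmt,
    write_count_table,
    write_edge_list,
    write_fasta,
)
from .profiling import (
    LibraryQC,
    CategorySummary,
    category_percentages,
    first_nucleotide_bias,
    length_distribution,
    positional_nucleotide_bias,
    qc_percentages,
)
from .simulate import (
    simulate_genome,
    simulate_libraries,
    simulate_pathways,
    simulate_utrs,
    write_truth_jsonl,
)
from .targets import TargetRules, scan_utr

logger = logging.getLogger("capmir")

__all__ = ["run_pipeline", "make_demo", "STAGES"]

STAGES = ("profile", "de_mirna", "de_mrna", "hairpin", "targets", "integrate")


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_tsv(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# stages


def run_profile(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    outputs = []
    if cfg.qc_yaml:
        with open(cfg.qc_yaml) as fh:
            qc_data = yaml.safe_load(fh)
        for lib, counts in qc_data.items():
            qc = LibraryQC(**counts)
            outputs.append(_write_tsv(qc_percentages(qc), out / f"qc_{lib}.tsv"))
    if cfg.categories:
        cats = pd.read_csv(cfg.categories, sep="\t")
        for lib, sub in cats.groupby("library"):
            unique = dict(zip(sub["category"], sub["unique"]))
            reads = dict(zip(sub["category"], sub["reads"]))
            cs = CategorySummary(
                unique, reads, sum(unique.values()), sum(reads.values())
            )
            outputs.append(
                _write_tsv(category_percentages(cs), out / f"categories_{lib}.tsv")
            )
    if cfg.mature_fasta and cfg.mirna_counts and cfg.mirna_totals:
        mirnas = read_fasta(cfg.mature_fasta)
        table = read_count_table(cfg.mirna_counts, cfg.mirna_totals)
        counts = dict(zip(table.feature_ids, table.counts))
        weighted = [
            (rec, counts.get(rec.id, (0, 0))[0] + counts.get(rec.id, (0, 0))[1])
            for rec in mirnas
        ]
        ld = length_distribution([(r, w) for r, w in weighted if w > 0])
        ld_frame = pd.DataFrame(
            sorted(ld.items(), key=lambda kv: str(kv[0])), columns=["length", "fraction"]
        )
        outputs.append(_write_tsv(ld_frame, out / "length_distribution.tsv"))
        fb = first_nucleotide_bias(mirnas)
        outputs.append(_write_tsv(fb.reset_index(), out / "first_nt_bias.tsv"))
        pb = positional_nucleotide_bias(mirnas)
        outputs.append(_write_tsv(pb.reset_index(), out / "positional_bias.tsv"))
    logger.info("[profile] wrote %d tables", len(outputs))
    return outputs


def _run_de(cfg: PipelineConfig, counts_path: str, totals, stem: str) -> Path:
    table = read_count_table(counts_path, totals)
    results = de_table(table, fdr_max=cfg.fdr_max, log2_min=cfg.log2_min)
    out = _outdir(cfg) / f"{stem}_de.tsv"
    _write_tsv(de_frame(results), out)
    n_de = sum(r.de_class != "not_de" for r in results)
    logger.info("[de] %s: %d features, %d differential", stem, len(results), n_de)
    return out


def run_de_mirna(cfg: PipelineConfig) -> Path:
    return _run_de(cfg, cfg.mirna_counts, cfg.mirna_totals, "mirna")


def run_de_mrna(cfg: PipelineConfig) -> Path:
    return _run_de(cfg, cfg.mrna_counts, cfg.mrna_totals, "mrna")


def run_hairpin(cfg: PipelineConfig) -> list[Path]:
    out = _outdir(cfg)
    genomes = {g.id: g for g in read_fasta(cfg.genome_fasta)}
    hits = pd.read_csv(cfg.hairpin_hits, sep="\t")
    thresholds = HairpinThresholds(
        genome_hits_max=cfg.genome_hits_max,
        mature_len_range=cfg.mature_len,
        mfe_max=cfg.mfe_max,
        mfei_min=cfg.mfei_min,
    )
    rows = []
    vienna_lines = []
    for hit in hits.itertuples(index=False):
        genome = genomes[hit.chrom] if "chrom" in hits.columns else next(
            iter(genomes.values())
        )
        window, _, _ = extract_flanks(
            genome, int(hit.start), int(hit.end), str(hit.strand), cfg.flank
        )
        # judge only the stem-loop holding the mature read, not the flanks
        mpos = window.find(str(hit.mature_seq).upper().replace("U", "T"))
        if mpos < 0:
            raise ValueError(f"mature read absent from window at {hit.locus}")
        a, b = candidate_precursor(window, mpos, mpos + len(str(hit.mature_seq)))
        cand = evaluate_candidate(
            str(hit.locus), window[a:b], str(hit.mature_seq), int(hit.genome_hits),
            thresholds,
        )
        row = {
            "locus": cand.locus_id,
            "precursor_len": len(cand.precursor),
            "mfe": cand.mfe,
            "amfe": cand.amfe,
            "mfei": cand.mfei,
            "gc_percent": cand.gc_percent,
            "mature_start": cand.mature_start,
            "mature_end": cand.mature_end,
            "arm": cand.arm,
            "genome_hits": cand.genome_hits,
        }
        row.update({f"flag_{k}": v for k, v in cand.flags.items()})
        row["verdict"] = cand.verdict
        row["screen"] = "mipred_surrogate"
        rows.append(row)
        vienna_lines.append(f">{cand.locus_id}\n{cand.precursor}\n{cand.structure}")
    report = out / "hairpin_candidates.tsv"
    _write_tsv(pd.DataFrame(rows), report)
    vienna = out / "hairpin_structures.vienna"
    vienna.write_text("\n".join(vienna_lines) + ("\n" if vienna_lines else ""))
    n_pass = sum(r["verdict"] for r in rows)
    logger.info("[hairpin] %d candidates, %d pass", len(rows), n_pass)
    return [report, vienna]


def run_targets(cfg: PipelineConfig) -> Path:
    mirnas = read_fasta(cfg.mature_fasta)
    utrs = read_fasta(cfg.utr_fasta)
    rules = TargetRules(max_penalty=cfg.target_max_penalty)
    rows = []
    for mir in mirnas:
        for utr in utrs:
            for site in scan_utr(mir, utr, rules):
                rows.append(
                    {
                        "mirna": site.mirna_id,
                        "transcript": site.transcript_id,
                        "start": site.utr_start,
                        "end": site.utr_end,
                        "penalty": site.penalty,
                        "duplex_mfe": site.duplex_mfe,
                        "alignment": site.alignment,
                    }
                )
    out = _outdir(cfg) / "target_sites.tsv"
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "mirna", "transcript", "start", "end",
                "penalty", "duplex_mfe", "alignment",
            ],
        ),
        out,
    )
    logger.info("[targets] %d sites", len(rows))
    return out


def run_integrate(cfg: PipelineConfig) -> list[Path]:
    from .targets import TargetSite

    out = _outdir(cfg)
    mirna_de = pd.read_csv(out / "mirna_de.tsv", sep="\t")
    mrna_de = pd.read_csv(out / "mrna_de.tsv", sep="\t")
    sites_df = pd.read_csv(out / "target_sites.tsv", sep="\t")

    de_rows = mirna_de[mirna_de.de_class != "not_de"]
    selected = set(
        de_rows[de_rows.log2fc.abs() >= cfg.integration_abs_log2].feature_id
    )
    mirna_dir = dict(zip(de_rows.feature_id, de_rows.de_class))
    deg = mrna_de[mrna_de.de_class != "not_de"]
    deg_dir = dict(zip(deg.feature_id, deg.de_class))

    sites = [
        TargetSite(r.mirna, r.transcript, int(r.start), int(r.end),
                   float(r.penalty), float(r.duplex_mfe), str(r.alignment))
        for r in sites_df.itertuples(index=False)
    ]
    de_targets = intersect_de_targets(sites, selected, mirna_dir, deg_dir)
    edges = [
        (m, g, {
            "mirna_direction": de_targets.mirna_direction[m],
            "gene_direction": de_targets.gene_direction[g],
        })
        for m, g in sorted(de_targets.edges)
    ]
    edges_path = out / "de_targets.tsv"
    write_edge_list(edges, edges_path)

    pathways = read_gmt(cfg.pathways_gmt)
    annotated = set().union(*pathways.pathways.values()) if len(pathways) else set()
    expressed = set(mrna_de[(mrna_de.x > 0) | (mrna_de.y > 0)].feature_id)
    background = expressed & annotated
    enrich_path = out / "enrichment.tsv"
    top_path = out / "top_pathways.tsv"
    network_paths = []
    if background and de_targets.genes:
        results = enrich_pathways(de_targets.genes & background, pathways, background)
        frame = pd.DataFrame(
            [
                {
                    "pathway": r.pathway_id, "k": r.k, "K": r.K, "n": r.n,
                    "N": r.N, "p": r.p, "fdr": r.fdr,
                    "significant": r in significant_pathways(
                        results, cfg.enrich_p, cfg.enrich_fdr
                    ),
                }
                for r in results
            ]
        )
        _write_tsv(frame, enrich_path)
        _write_tsv(frame.head(10), top_path)
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        import networkx as nx

        for r in results[:10]:
            net = build_network(de_targets, pathways.pathways[r.pathway_id])
            if net.number_of_edges() == 0:
                continue
            pedges = [
                (m, g, {
                    "mirna_direction": net.nodes[m]["direction"],
                    "gene_direction": net.nodes[g]["direction"],
                })
                for m, g in sorted(
                    (u, v) if net.nodes[u]["kind"] == "mirna" else (v, u)
                    for u, v in net.edges
                )
            ]
            ppath = netdir / f"{r.pathway_id}.tsv"
            write_edge_list(pedges, ppath)
            nx.write_gml(net, netdir / f"{r.pathway_id}.gml")
            network_paths.append(ppath)
    else:
        _write_tsv(pd.DataFrame(
            columns=["pathway", "k", "K", "n", "N", "p", "fdr", "significant"]
        ), enrich_path)
        _write_tsv(pd.DataFrame(columns=["pathway", "k", "K", "n", "N", "p", "fdr",
                                         "significant"]), top_path)
    logger.info(
        "[integrate] %d DE-target edges, %d networks",
        len(edges), len(network_paths),
    )
    return [edges_path, enrich_path, top_path, *network_paths]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    out = _outdir(cfg)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    stage_funcs = {
        "profile": run_profile,
        "de_mirna": run_de_mirna,
        "de_mrna": run_de_mrna,
        "hairpin": run_hairpin,
        "targets": run_targets,
        "integrate": run_integrate,
    }
    for stage in STAGES:
        try:
            result = stage_funcs[stage](cfg)
        except Exception:
            logger.exception("[%s] stage failed", stage)
            manifest["stages"][stage] = {"status": "failed"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        paths = result if isinstance(result, list) else [result]
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": [str(p) for p in paths],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# demo workspace


def make_demo(seed: int = 0, workdir: str | Path = "capmir_demo",
              scale: float = 1.0) -> dict:
    """Generate a synthetic workspace and run the pipeline on it.

    ``scale`` < 1 shrinks feature counts and sequence sets proportionally
    (floor of 0.25 of the defaults) for quick smoke runs.
    """
    work = Path(workdir)
    data = work / "data"
    data.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)
    s = max(scale, 0.25)

    depth = 1_000_000
    n_mirnas = max(int(120 * s), 20)
    n_genes = max(int(400 * s), 60)
    n_utrs = max(int(30 * s), 12)

    # miRNA and mRNA count tables
    mir_table, mir_truth = simulate_libraries(
        n_features=n_mirnas, depth1=depth, depth2=depth, de_fraction=0.25,
        effect_log2=3.5, seed=rng_seed, prefix="chi-mir",
    )
    mrna_table, mrna_truth = simulate_libraries(
        n_features=n_genes, depth1=depth, depth2=depth, de_fraction=0.3,
        effect_log2=2.5, seed=rng_seed + 1, prefix="gene",
    )
    write_count_table(mir_table, data / "mirna_counts.tsv")
    write_count_table(mrna_table, data / "mrna_counts.tsv")
    write_truth_jsonl(mir_truth, data / "mirna_truth.jsonl")
    write_truth_jsonl(mrna_truth, data / "mrna_truth.jsonl")

    # mature miRNA sequences (random, typical 21-23 nt, U-start biased)
    import numpy as np

    from .io import SequenceRecord
    from .simulate import random_sequence

    rng = np.random.default_rng(rng_seed + 2)
    mirnas = []
    for fid in mir_table.feature_ids:
        length = int(rng.choice([21, 22, 22, 22, 23]))
        seq = random_sequence(length, rng, gc=0.45)
        if rng.random() < 0.8:
            seq = "T" + seq[1:]
        mirnas.append(SequenceRecord(fid, seq))
    write_fasta(mirnas, data / "mature_mirnas.fasta")

    # genome with embedded hairpins + hit table
    genome, hits, genome_truth = simulate_genome(
        n_loci=4, seed=rng_seed + 3
    )
    write_fasta([genome], data / "genome.fasta")
    pd.DataFrame(hits).to_csv(data / "hairpin_hits.tsv", sep="\t", index=False)
    write_truth_jsonl({"loci": [dict(l) for l in genome_truth.loci]},
                      data / "genome_truth.jsonl")

    # UTRs named after genes, with planted sites for a DE-miRNA subset
    utr_names = list(mrna_table.feature_ids[:n_utrs])
    strong = [
        m for m, e in zip(mir_truth.feature_ids, mir_truth.effect_log2)
        if abs(e) >= 3
    ] or list(mir_table.feature_ids[:5])
    planted_mirnas = [m for m in mirnas if m.id in strong][:10]
    utrs, utr_truth = simulate_utrs(
        planted_mirnas, n_utrs=n_utrs, sites_per_utr=1, mutation_count=0,
        utr_len=300, seed=rng_seed + 4,
    )
    utrs = [SequenceRecord(name, u.seq) for name, u in zip(utr_names, utrs)]
    renamed_sites = []
    for site, name in zip(utr_truth.sites, utr_names):
        renamed_sites.append({**site, "utr_id": name})
    write_fasta(utrs, data / "utrs.fasta")
    write_truth_jsonl({"sites": renamed_sites}, data / "utr_truth.jsonl")

    # pathways over the gene universe, biased toward planted-site genes
    pathways, pw_truth = simulate_pathways(
        list(mrna_table.feature_ids), n_pathways=30, size_range=(10, 40),
        enriched_pathways=2, favored_genes=utr_names, odds=20.0,
        seed=rng_seed + 5,
    )
    with open(data / "pathways.gmt", "w") as fh:
        for pid in sorted(pathways.pathways):
            genes = "\t".join(sorted(pathways.pathways[pid]))
            fh.write(f"{pid}\t{pathways.names.get(pid, pid)}\t{genes}\n")
    write_truth_jsonl(pw_truth, data / "pathway_truth.jsonl")

    # QC + category tables emulating a sequencing summary
    qc = {}
    for lib, total in (("fc", mir_table.totals[0]), ("smc", mir_table.totals[1])):
        discards = {
            "adapter3_null": 200, "insert_null": 150,
            "adapter5_contaminants": 1200, "smaller_than_18nt": 2500, "polyA": 5,
        }
        hq = total + sum(discards.values())
        qc[lib] = {
            "total_reads": hq + 3000, "high_quality": hq,
            "clean_reads": total, **discards,
        }
    with open(data / "qc.yaml", "w") as fh:
        yaml.safe_dump(qc, fh)

    cat_rows = []
    for lib, total in (("fc", mir_table.totals[0]), ("smc", mir_table.totals[1])):
        rng_c = np.random.default_rng(rng_seed + 6)
        fractions = {"miRNA": 0.8, "rRNA": 0.03, "tRNA": 0.01, "snoRNA": 0.005,
                     "snRNA": 0.002, "scRNA": 0.0005, "exon_sense": 0.01,
                     "exon_antisense": 0.0005, "intron_sense": 0.01,
                     "intron_antisense": 0.002}
        reads = {c: int(total * f) for c, f in fractions.items()}
        reads["unann"] = total - sum(reads.values())
        unique = {c: max(1, int(r ** 0.5)) for c, r in reads.items()}
        for c in reads:
            cat_rows.append({"library": lib, "category": c,
                             "unique": unique[c], "reads": reads[c]})
    pd.DataFrame(cat_rows).to_csv(data / "categories.tsv", sep="\t", index=False)

    cfg = PipelineConfig(
        outdir=str(work / "out"),
        seed=rng_seed,
        mirna_counts=str(data / "mirna_counts.tsv"),
        mirna_totals=mir_table.totals,
        mrna_counts=str(data / "mrna_counts.tsv"),
        mrna_totals=mrna_table.totals,
        mature_fasta=str(data / "mature_mirnas.fasta"),
        genome_fasta=str(data / "genome.fasta"),
        hairpin_hits=str(data / "hairpin_hits.tsv"),
        utr_fasta=str(data / "utrs.fasta"),
        pathways_gmt=str(data / "pathways.gmt"),
        qc_yaml=str(data / "qc.yaml"),
        categories=str(data / "categories.tsv"),
    )
    with open(work / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    return run_pipeline(cfg)
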