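"""End-to-end pipeline driver: simulate -> search -> quantify -> sip -> screen.

The pipeline is configured by a single nested mapping (YAML on disk).
Every stochastic step derives its seed from the top-level seed, so a
config plus seed fully determines every output file. Unknown config keys
are rejected rather than silently ignored.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (assign_homologs, assignments_to_frame, detect_clusters,
                      reports_to_frame)
from .io import write_sequences, write_table
from .quantify import MetagenomeStats, compare_habitats, marker_abundance
from .search import SearchParams, search_translated, verify_hits
from .sip import (EnrichmentParams, FractionProfile, call_labeled,
                  fold_enrichment, identify_fractions, make_abundance_table,
                  pool_window, records_to_frame)
from .synthetic import (GenomeModel, ReadSimConfig, SIPGradientModel,
                        build_genome, default_marker_references,
                        generate_community, iso_cluster_references,
                        simulate_gradient, simulate_reads, _mutate)
from .cluster import GeneAnnotation

log = logging.getLogger("isosip")

_SAMPLE_KEYS = {"n_taxa", "carrier_fraction", "genome_length", "gc_range",
                "abundance", "dirichlet_alpha", "n_reads", "read_length",
                "sub_error_rate", "quality_model"}
_SEARCH_KEYS = {"matrix", "gap_open", "gap_extend", "lambda_", "K",
                "evalue_cutoff_target", "evalue_cutoff_norm",
                "min_verify_identity", "min_verify_coverage"}
_SIP_KEYS = {"n_taxa", "carrier_fraction", "labeled_taxa", "abundance",
             "genome_length", "gc_range", "min_fold_13C",
             "min_control_ratio", "pseudocount", "density_noise_sd",
             "full_label_shift"}
_SCREEN_KEYS = {"demo", "max_gap", "divergence"}
_TOP_KEYS = {"seed", "samples", "search", "sip", "screen", "write_reads"}


class ConfigError(ValueError):
    pass


def _check_keys(mapping: Mapping, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys in {context}: "
                          f"{sorted(unknown)}")


def validate_config(config: Mapping) -> dict:
    """Validate the nested config; returns it as a plain dict."""
    config = dict(config)
    _check_keys(config, _TOP_KEYS, "top level")
    for name, sample in (config.get("samples") or {}).items():
        _check_keys(sample, _SAMPLE_KEYS, f"samples.{name}")
        cf = sample.get("carrier_fraction", 0.0)
        if not 0.0 <= cf <= 1.0:
            raise ConfigError(
                f"samples.{name}.carrier_fraction must be in [0, 1]")
    if "search" in config:
        _check_keys(config["search"], _SEARCH_KEYS, "search")
    if "sip" in config:
        _check_keys(config["sip"], _SIP_KEYS, "sip")
    if "screen" in config:
        _check_keys(config["screen"], _SCREEN_KEYS, "screen")
    return config


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _unique_read_count(hits) -> pd.DataFrame:
    """One hit per read (best e-value; ties to smallest query id)."""
    if not hits:
        return pd.DataFrame(columns=["query_id", "read_id", "evalue"])
    df = pd.DataFrame([(h.query_id, h.read_id, h.evalue) for h in hits],
                      columns=["query_id", "read_id", "evalue"])
    return df.sort_values(["evalue", "query_id"]).drop_duplicates("read_id")


def quantify_sample(name: str, cfg: Mapping, params: SearchParams,
                    seed: int, refs: Mapping | None = None) -> dict:
    """Simulate one metagenome and run the isoA/recA carrier screen."""
    refs = refs or default_marker_references()
    genomes, community = generate_community(
        n_taxa=int(cfg.get("n_taxa", 100)),
        carrier_fraction=float(cfg.get("carrier_fraction", 0.01)),
        seed=_child_seed(seed, 1),
        genome_length=int(cfg.get("genome_length", 10_000)),
        gc_range=tuple(cfg.get("gc_range", (0.40, 0.60))),
        abundance=cfg.get("abundance", "dirichlet"),
        dirichlet_alpha=float(cfg.get("dirichlet_alpha", 1.0)))
    rcfg = ReadSimConfig(
        n_reads=int(cfg.get("n_reads", 100_000)),
        read_length=int(cfg.get("read_length", 143)),
        sub_error_rate=float(cfg.get("sub_error_rate", 0.005)),
        quality_model=cfg.get("quality_model", "constant:30"),
        seed=_child_seed(seed, 2))
    reads, truth = simulate_reads(genomes, community, rcfg)

    iso_hits = search_translated(refs["isoA_queries"], reads, params,
                                 cutoff=params.evalue_cutoff_target)
    n_iso, iso_table = verify_hits(iso_hits, refs["isoA_verification"],
                                   params)
    rec_hits = search_translated(refs["recA_queries"], reads, params,
                                 cutoff=params.evalue_cutoff_norm)
    rec_unique = _unique_read_count(rec_hits)

    # carrier truth: abundance-weighted share of genomes carrying isoA
    carriers = {g.taxon_id for g in genomes
                if any(m[0] == "isoA" for m in g.markers)}
    true_pct = 100.0 * sum(a for t, a in community.abundances.items()
                           if t in carriers)
    iso_unique = iso_table[iso_table["unique"]]
    per_gene_iso = iso_unique.groupby("query_id").size().to_dict()
    per_gene_rec = rec_unique.groupby("query_id").size().to_dict()
    return {
        "name": name, "genomes": genomes, "community": community,
        "reads": reads, "truth": truth, "read_config": rcfg,
        "iso_hits": iso_hits, "iso_table": iso_table,
        "n_iso_unique": n_iso, "rec_unique": rec_unique,
        "per_gene_iso": per_gene_iso, "per_gene_rec": per_gene_rec,
        "true_pct_carriers": true_pct,
        "stats": MetagenomeStats(name, rcfg.n_reads, rcfg.read_length),
        "refs": refs,
    }


def carrier_survey(samples: Mapping[str, Mapping], params: SearchParams,
                   seed: int) -> tuple[list, dict]:
    """Quantify several metagenomes and normalize them jointly."""
    refs = default_marker_references()
    runs = {}
    for i, (name, cfg) in enumerate(samples.items()):
        runs[name] = quantify_sample(name, cfg, params,
                                     _child_seed(seed, 10 + i), refs)
    stats = [runs[n]["stats"] for n in runs]
    target_lengths = {q.ref_id: q.length for q in refs["isoA_queries"]}
    norm_lengths = {q.ref_id: q.length for q in refs["recA_queries"]}
    results = marker_abundance(
        {n: runs[n]["per_gene_iso"] for n in runs},
        {n: runs[n]["per_gene_rec"] for n in runs},
        stats, target_lengths, norm_lengths)
    return results, runs


def run_sip_experiment(cfg: Mapping, seed: int) -> dict:
    """Simulate paired 13C/12C gradients and call labelled taxa."""
    n_taxa = int(cfg.get("n_taxa", 30))
    labeled = list(cfg.get("labeled_taxa", []))
    common = dict(
        n_taxa=n_taxa,
        carrier_fraction=float(cfg.get("carrier_fraction", 0.0)),
        genome_length=int(cfg.get("genome_length", 10_000)),
        gc_range=tuple(cfg.get("gc_range", (0.40, 0.60))),
        abundance=cfg.get("abundance", "dirichlet"))
    genomes_13, community = generate_community(
        labeled_taxa=labeled, seed=_child_seed(seed, 1), **common)
    # the 12C control is the same community with no labelling
    genomes_12 = [GenomeModel(g.taxon_id, g.length, g.gc, g.markers, 0.0,
                              g.sequence, g.marker_loci)
                  for g in genomes_13]
    model = SIPGradientModel(
        density_noise_sd=float(cfg.get("density_noise_sd", 0.004)),
        full_label_shift=float(cfg.get("full_label_shift", 0.036)))
    frac_13 = simulate_gradient(genomes_13, community, model,
                                seed=_child_seed(seed, 2))
    frac_12 = simulate_gradient(genomes_12, community, model,
                                seed=_child_seed(seed, 3))
    prof_13 = FractionProfile.from_fractions("13C", frac_13)
    prof_12 = FractionProfile.from_fractions("12C", frac_12)
    window = identify_fractions(prof_13, prof_12)
    table = make_abundance_table({
        "13C_H": pool_window(frac_13, window.heavy),
        "13C_L": pool_window(frac_13, window.light),
        "12C_H": pool_window(frac_12, window.heavy),
        "12C_L": pool_window(frac_12, window.light),
        "13C_UF": pd.Series(community.abundances),
    })
    eparams = EnrichmentParams(
        min_fold_13C=float(cfg.get("min_fold_13C", 5.0)),
        min_control_ratio=float(cfg.get("min_control_ratio", 2.0)),
        pseudocount=float(cfg.get("pseudocount", 1e-4)))
    records = call_labeled(fold_enrichment(table, eparams), eparams)
    return {"community": community, "genomes": genomes_13,
            "fractions_13C": frac_13, "fractions_12C": frac_12,
            "window": window, "table": table, "records": records,
            "params": eparams, "labeled_truth": set(labeled)}


def run_screen_demo(cfg: Mapping, seed: int) -> dict:
    """Synthetic contig screen: plant clusters, annotate, assign, detect."""
    rng = np.random.default_rng(_child_seed(seed, 1))
    refs = iso_cluster_references()
    divergence = float(cfg.get("divergence", 0.10))
    layouts = {
        "contig_full": ["isoA", "isoB", "isoC", "isoD", "isoE", "isoF",
                        "isoG", "isoH", "isoI", "isoJ", "aldH1"],
        "contig_core": ["isoA", "isoB", "isoC", "isoD", "isoE", "isoF"],
        "contig_empty": [],
    }
    annotations = []
    for contig_id, genes in layouts.items():
        pos = 101
        for i, gene in enumerate(genes):
            prot = _mutate(refs[gene].sequence, divergence, rng)
            glen = 3 * len(prot) + 3
            annotations.append(GeneAnnotation(
                contig_id, f"{contig_id}_g{i:02d}", pos, pos + glen - 1,
                "+", prot))
            pos += glen + int(rng.integers(20, 200))
        if not genes:  # an unrelated protein so the contig is annotated
            prot = _mutate(refs["isoA"].sequence, 0.9, rng)
            annotations.append(GeneAnnotation(
                contig_id, f"{contig_id}_g00", pos, pos + 3 * len(prot) + 2,
                "+", prot))
    assignments = assign_homologs(annotations, refs)
    reports = detect_clusters(assignments, annotations,
                              max_gap=int(cfg.get("max_gap", 5000)))
    return {"annotations": annotations, "assignments": assignments,
            "reports": reports}


def run_pipeline(config, outdir) -> dict:
    """Execute the configured stages and write all output tables.

    ``config`` is a mapping or a path to a YAML file. Returns a summary
    dict of the key results; every file under ``outdir`` is regenerable
    from the config alone.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = SearchParams(**(config.get("search") or {}))
    summary: dict = {"version": __version__, "seed": seed}
    log.info("pipeline start seed=%d outdir=%s", seed, outdir)

    if config.get("samples"):
        results, runs = carrier_survey(config["samples"], params, seed)
        rows = [(r.metagenome_id, r.raw_target_hits, r.raw_norm_hits,
                 r.scaled_target_hits, r.scaled_norm_hits, r.pct_carriers,
                 runs[r.metagenome_id]["true_pct_carriers"])
                for r in results]
        carriers = pd.DataFrame(rows, columns=[
            "metagenome_id", "raw_target_hits", "raw_norm_hits",
            "scaled_target_hits", "scaled_norm_hits", "pct_carriers",
            "true_pct_carriers"])
        write_table(carriers, outdir / "carrier_stats.tsv", seed=seed)
        for name, run in runs.items():
            write_table(run["iso_table"], outdir / f"{name}_isoA_hits.tsv",
                        seed=seed)
            write_table(run["truth"], outdir / f"{name}_read_truth.tsv",
                        seed=seed)
            if config.get("write_reads", False):
                write_sequences(run["reads"], outdir / f"{name}_reads.fastq")
                with open(outdir / f"{name}_genomes.fasta", "w") as fh:
                    for g in run["genomes"]:
                        fh.write(f">{g.taxon_id}\n{g.sequence}\n")
        if len(results) >= 2:
            write_table(compare_habitats(results),
                        outdir / "habitat_ratios.tsv", seed=seed)
        summary["carriers"] = carriers
        log.info("quantify: %s",
                 {r.metagenome_id: round(r.pct_carriers, 3)
                  for r in results})

    if "sip" in config:
        sip = run_sip_experiment(config["sip"], _child_seed(seed, 20))
        frame = records_to_frame(sip["records"])
        write_table(frame, outdir / "sip_enrichment.tsv", seed=seed,
                    params={"note": ("fold-change thresholds are an "
                                     "interpretation; see docs/methods.md"),
                            "min_fold_13C": sip["params"].min_fold_13C,
                            "min_control_ratio":
                                sip["params"].min_control_ratio})
        prof = pd.DataFrame(
            [(f.fraction_index, f.mean_density, f.dna_amount)
             for f in sip["fractions_13C"]],
            columns=["fraction_index", "mean_density", "dna_amount"])
        write_table(prof, outdir / "sip_profile_13C.tsv", seed=seed)
        summary["sip"] = frame
        log.info("sip: %d labeled calls",
                 int((frame["call"] == "labeled").sum()))

    if "screen" in config:
        screen = run_screen_demo(config["screen"], _child_seed(seed, 30))
        write_table(assignments_to_frame(screen["assignments"]),
                    outdir / "screen_assignments.tsv", seed=seed)
        write_table(reports_to_frame(screen["reports"]),
                    outdir / "screen_clusters.tsv", seed=seed)
        summary["screen"] = reports_to_frame(screen["reports"])
        log.info("screen: %s",
                 {r.contig_id: r.classification for r in screen["reports"]})

    return summary
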