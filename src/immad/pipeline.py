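"""End-to-end motif-discovery pipeline with a machine-readable report.

Stages, in order: gene classification (MASS/SASS), primary k-mer enrichment
screen (corrected p < 1E-5 by default), clustering of significant oligomers
into IUPAC motif groups, stratified length-matched subsampling with a
confirmation screen (corrected p < 1E-2; motifs with no confirmed member are
dropped), gene-frequency control tests, inter-site distance analysis against
a simulated random null, homologous motif-distance distributions with peak
detection, a gene-level co-occurrence screen with heterologous distance
distributions for the significant pairs, and an optional conservation
comparison against a second species' ortholog intron table. Every stochastic
step derives its seed from the config, so identical configs produce
byte-identical reports.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import annotation_io, cooccurrence, distance_analysis, kmer_enrichment
from . import length_matching, motif_tools, splice_classifier, synthetic_data

__all__ = ["load_config", "run_full_pipeline", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "ks": [5, 6, 7],
    "alpha_primary": 1e-5,
    "alpha_confirm": 1e-2,
    "alpha_gene_frequency": 1e-2,
    "alpha_cooccurrence": 1e-2,
    "bin_width": 1000,
    "n_null_transcripts": 6510,
    "peak_min_fraction": 0.05,
    "min_isoforms": 2,
    "seed": 0,
}


class ConfigError(ValueError):
    """Raised before any computation when the configuration is unusable."""


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _sim_config_from_dict(d: Mapping[str, Any]) -> synthetic_data.SimConfig:
    planted = tuple(
        synthetic_data.PlantedMotif(**p) for p in d.get("planted", [])
    )
    repeats = tuple(synthetic_data.RepeatSpec(**r) for r in d.get("repeats", []))
    kwargs = {
        k: v
        for k, v in d.items()
        if k not in ("planted", "repeats")
    }
    if "event_mix" in kwargs:
        kwargs["event_mix"] = dict(kwargs["event_mix"])
    if "intron_length_law" in kwargs:
        law = kwargs["intron_length_law"]
        kwargs["intron_length_law"] = (law[0], dict(law[1]))
    return synthetic_data.SimConfig(planted=planted, repeats=repeats, **kwargs)


def _load_inputs(config: Mapping[str, Any], out_dir: Path):
    if "simulate" in config:
        sim_cfg = _sim_config_from_dict(config["simulate"])
        ds = synthetic_data.generate_dataset(
            sim_cfg, out_prefix=str(out_dir / "simulated")
        )
        return ds.genes, annotation_io.Genome(ds.genome)
    if "gff3" in config and "fasta" in config:
        for key in ("gff3", "fasta"):
            if not os.path.exists(config[key]):
                raise ConfigError(f"input file missing: {config[key]}")
        params = {**DEFAULTS, **config.get("params", {})}
        genes = annotation_io.read_gene_models(
            config["gff3"], min_isoforms=params["min_isoforms"]
        )
        return genes, annotation_io.Genome.from_fasta(config["fasta"])
    raise ConfigError("config must provide either 'simulate' or 'gff3'+'fasta'")


def run_full_pipeline(
    config: Mapping[str, Any] | str | os.PathLike, out_dir: str | os.PathLike
) -> dict:
    """Run the whole discovery pipeline; returns (and writes) the JSON report."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULTS, **config.get("params", {})}
    seed = int(params["seed"])

    genes, genome = _load_inputs(config, out)
    classified, excluded = splice_classifier.classify_genes(genes, genome)
    mass = [g for g in classified if g.label == splice_classifier.MASS]
    sass = [g for g in classified if g.label == splice_classifier.SASS]
    report: dict[str, Any] = {
        "params": {k: params[k] for k in sorted(params)},
        "n_genes_input": len(genes),
        "n_excluded": len(excluded),
        "n_mass": len(mass),
        "n_sass": len(sass),
    }
    genes_tsv = out / "genes.tsv"
    with open(genes_tsv, "w") as fh:
        fh.write("gene_id\tlabel\tn_sites\tn_flanking_introns\n")
        for g in classified:
            fh.write(f"{g.id}\t{g.label}\t{g.n_sites}\t{len(g.flanking_introns)}\n")

    if not mass or not sass:
        report["motifs"] = []
        report["note"] = "one group empty; screen skipped"
        _write_report(report, out)
        return report

    mass_seqs = [s for g in mass for s in g.flanking_sequences]
    sass_seqs = [s for g in sass for s in g.flanking_sequences]
    report["n_mass_introns"] = len(mass_seqs)
    report["n_sass_introns"] = len(sass_seqs)

    # --- primary screen -----------------------------------------------------
    primary: list[kmer_enrichment.EnrichmentRecord] = []
    for k in params["ks"]:
        primary.extend(
            kmer_enrichment.enrichment_screen(
                mass_seqs, sass_seqs, k, params["alpha_primary"]
            )
        )
    kmer_enrichment.write_enrichment_tsv(primary, out / "primary_screen.tsv")
    hits = sorted(r.oligomer for r in primary if r.significant)
    report["primary_oligomers"] = hits

    # --- subsample confirmation --------------------------------------------
    sub_mass, sub_sass, plan = length_matching.stratified_subsample(
        mass, sass, bin_width=params["bin_width"], seed=seed
    )
    report["subsample"] = {
        "n_mass_kept": len(sub_mass),
        "n_sass_kept": len(sub_sass),
        "removed_mass": sorted(plan.removed_a),
        "removed_sass": sorted(plan.removed_b),
    }
    confirmed: list[str] = []
    if hits:
        sub_mass_seqs = [s for g in sub_mass for s in g.flanking_sequences]
        sub_sass_seqs = [s for g in sub_sass for s in g.flanking_sequences]
        confirm_records = []
        for k in sorted({len(o) for o in hits}):
            confirm_records.extend(
                kmer_enrichment.enrichment_screen(
                    sub_mass_seqs, sub_sass_seqs, k, params["alpha_confirm"]
                )
            )
        by_oligo = {r.oligomer: r for r in confirm_records}
        confirmed = [
            o
            for o in hits
            if o in by_oligo and by_oligo[o].significant
        ]
        kmer_enrichment.write_enrichment_tsv(
            [by_oligo[o] for o in hits if o in by_oligo],
            out / "confirmation_screen.tsv",
        )
    report["confirmed_oligomers"] = confirmed

    motifs = motif_tools.cluster_oligomers(confirmed) if confirmed else []
    report["motifs"] = [
        {"consensus": m.consensus, "members": sorted(m.members)} for m in motifs
    ]
    with open(out / "motifs.tsv", "w") as fh:
        fh.write("consensus\tmembers\n")
        for m in motifs:
            fh.write(f"{m.consensus}\t{','.join(sorted(m.members))}\n")

    # --- gene-frequency control --------------------------------------------
    if motifs:
        gf = kmer_enrichment.gene_frequency_test(mass, sass, motifs)
        report["gene_frequency"] = [
            {
                "motif": r.motif.consensus,
                "genes_with_a": r.genes_with_a,
                "genes_total_a": r.genes_total_a,
                "genes_with_b": r.genes_with_b,
                "genes_total_b": r.genes_total_b,
                "p_corrected": r.p_corrected,
            }
            for r in gf
        ]

    # --- inter-site distances vs simulated null -----------------------------
    multi = [g for g in mass if g.n_sites >= 2]
    if len(multi) >= 2:
        import numpy as np

        observed = distance_analysis.DistanceDistribution(
            np.concatenate(
                [
                    distance_analysis.inter_site_distances(g).distances
                    for g in multi
                ]
            ),
            "inter-site observed",
        )
        gene_law, intron_law = synthetic_data.empirical_length_laws(mass)
        null_cfg = distance_analysis.RandomPoolConfig(
            gene_law,
            intron_law,
            n_transcripts=int(params["n_null_transcripts"]),
            seed=seed + 1,
        )
        null = distance_analysis.simulate_random_intersite(null_cfg)
        u, p = distance_analysis.compare_distance_sets(observed, null)
        report["inter_site"] = {
            "n_observed": len(observed),
            "median_observed": float(pd.Series(observed.distances).median()),
            "median_null": float(pd.Series(null.distances).median()),
            "U": u,
            "p": p,
        }
        distance_analysis.write_histogram_tsv(observed, out / "intersite_observed.tsv")
        distance_analysis.write_histogram_tsv(null, out / "intersite_null.tsv")

    # --- homologous motif distances and peaks -------------------------------
    mass_introns = [(g.id, s) for g in mass for s in g.flanking_sequences]
    homologous = {}
    for m in motifs:
        dist = distance_analysis.motif_distance_distribution(mass_introns, m)
        peaks = distance_analysis.detect_peaks(
            dist, params["peak_min_fraction"]
        )
        homologous[m.consensus] = {
            "n_intervals": len(dist),
            "peaks": [
                {"distance": p.distance, "count": p.count, "fraction": round(p.fraction, 4)}
                for p in peaks
            ],
        }
    report["homologous_distances"] = homologous

    # --- co-occurrence ------------------------------------------------------
    if len(motifs) >= 2:
        records = cooccurrence.cooccurrence_screen(
            mass, motifs, alpha=params["alpha_cooccurrence"]
        )
        cooccurrence.write_cooccurrence_tsv(records, out / "cooccurrence.tsv")
        sig = [r for r in records if r.significant]
        report["cooccurrence"] = {
            "n_pairs_tested": len(records),
            "significant_pairs": [
                {
                    "pair": [r.pair[0].consensus, r.pair[1].consensus],
                    "odds_ratio": round(r.odds_ratio, 3),
                    "n_genes": r.n_both,
                    "p_corrected": r.p_corrected,
                }
                for r in sig
            ],
        }
        heterologous = {}
        for r in sig:
            dist = distance_analysis.motif_distance_distribution(
                mass_introns, r.pair[0], r.pair[1]
            )
            peaks = distance_analysis.detect_peaks(
                dist, params["peak_min_fraction"]
            ) if len(dist) else []
            key = f"{r.pair[0].consensus}-{r.pair[1].consensus}"
            heterologous[key] = {
                "n_intervals": len(dist),
                "peaks": [
                    {"distance": p.distance, "count": p.count, "fraction": round(p.fraction, 4)}
                    for p in peaks
                ],
            }
        report["heterologous_distances"] = heterologous

    # --- conservation (optional) -------------------------------------------
    if "ortholog_table" in config and motifs:
        table = pd.read_csv(config["ortholog_table"], sep="\t")
        required = {"species", "group", "sequence"}
        if not required.issubset(table.columns):
            raise ConfigError(
                f"ortholog table needs columns {sorted(required)}"
            )
        conservation = {}
        scrambled = motif_tools.scramble_motifs(motifs, seed + 2)
        for species, sub in table.groupby("species"):
            ia = sub.loc[sub["group"] == "MASS", "sequence"].tolist()
            ib = sub.loc[sub["group"] == "SASS", "sequence"].tolist()
            if not ia or not ib:
                continue
            real = kmer_enrichment.pooled_motif_comparison(motifs, ia, ib)
            ctrl = kmer_enrichment.pooled_motif_comparison(scrambled, ia, ib)
            conservation[str(species)] = {
                "ratio": round(real.ratio, 4),
                "p": real.p,
                "scrambled_ratio": round(ctrl.ratio, 4),
                "scrambled_p": ctrl.p,
            }
        report["conservation"] = conservation

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
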