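"""End-to-end orchestration of the FISH and 4C analyses.

Both pipelines take a configuration mapping (typically loaded from
YAML), either pointing at existing input tables or carrying a generator
block, and write deterministic TSV/JSON outputs plus the resolved
configuration.  Given the same configuration and seed, outputs are
byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import allelic4c, fish_stats, io, nuclear_model, synthetic

FISH_DEFAULTS: dict[str, Any] = {
    "tau_um": fish_stats.PAIRING_THRESHOLD_UM,
    "seed": 0,
    "null_comparison": True,
    "fit_grid": {"n_mu": 6, "n_sigma": 3, "sigma_max": 0.2},
    "n_sim": 600,
}

FOURC_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "site": allelic4c.DEFAULT_SITE,
    "cut_offset": allelic4c.DEFAULT_CUT_OFFSET,
    "read_length": allelic4c.DEFAULT_READ_LENGTH,
    "cis_window": 100_000,
    "trans_window": 200_000,
    "genome_window": 1_400_000,
}


def _resolve(config: dict, defaults: dict) -> dict:
    out = dict(defaults)
    out.update(config or {})
    return out


def _write_resolved(config: dict, outdir: Path) -> None:
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _load_or_generate_nuclei(
    config: dict, rng: np.random.Generator
) -> tuple[list[fish_stats.NucleusRecord], pd.DataFrame | None, list[str]]:
    if "generator" in config:
        gen = dict(config["generator"])
        probes = []
        for probe_cfg in gen.pop("probes", [{"preset": "kvdmr_liver"}]):
            if "preset" in probe_cfg:
                probes.append(synthetic.PRESETS[probe_cfg["preset"]])
            else:
                model = probe_cfg.get("radial_model")
                kwargs = {}
                if model:
                    kwargs["radial_model"] = nuclear_model.RadialModel(**model)
                probes.append(
                    synthetic.ProbePreset(
                        probe_cfg["probe_id"], probe_cfg["pairing_probability"], **kwargs
                    )
                )
        gcfg = synthetic.NucleiGeneratorConfig(probes=tuple(probes), **gen)
        nuc_df, spot_df, truth = synthetic.simulate_nuclei(gcfg, rng)
        nuclei = fish_stats.nuclei_from_tables(nuc_df, spot_df)
        return nuclei, truth, [p.probe_id for p in probes]
    inputs = config.get("inputs", {})
    for key in ("nucleus_table", "spot_table"):
        path = inputs.get(key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing required input {key!r}: {path}")
    nuc_df = io.read_tsv(inputs["nucleus_table"])
    spot_df = io.read_tsv(inputs["spot_table"])
    nuclei = fish_stats.nuclei_from_tables(nuc_df, spot_df)
    probes = sorted(spot_df["probe_id"].unique())
    return nuclei, None, probes


def run_fish_pipeline(config: dict, outdir: str | Path) -> dict:
    """Score pairing and compute spatial statistics for every probe.

    Writes per-probe pairing TSVs, distance tables, a JSON report and
    the resolved configuration to ``outdir``; returns the report dict.
    """
    cfg = _resolve(config, FISH_DEFAULTS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    nuclei, truth, probe_ids = _load_or_generate_nuclei(cfg, rng)

    report: dict[str, Any] = {"seed": cfg["seed"], "tau_um": cfg["tau_um"], "probes": {}}
    rows = []
    for probe_id in probe_ids:
        result = fish_stats.score_pairing(nuclei, probe_id, tau=cfg["tau_um"])
        radials = []
        inter = []
        for nuc in nuclei:
            spots = nuc.spots_for(probe_id)
            radials.extend(fish_stats.radial_distance(s, nuc) for s in spots)
            if len(spots) == 2:
                inter.append(
                    fish_stats.interallelic_distance(spots[0], spots[1], nuc)
                )
        counts, overflow = fish_stats.distance_histogram(inter)
        box = fish_stats.tukey_box_stats(inter) if inter else None
        entry: dict[str, Any] = {
            "frequency_percent": result.frequency,
            "replicate_frequencies": result.replicate_frequencies,
            "n_scored": result.n_scored,
            "n_paired": result.n_paired,
            "category": fish_stats.classify_frequency(result.frequency),
            "histogram_counts": counts.tolist(),
            "histogram_overflow": overflow,
            "interallelic_box": box.__dict__ if box else None,
            "n_radials": len(radials),
        }
        if cfg["null_comparison"] and inter:
            fit = nuclear_model.fit_radial_model(
                radials,
                grid=nuclear_model.default_grid(**cfg["fit_grid"]),
                n_sim=cfg["n_sim"],
                rng=rng,
            )
            simulated = nuclear_model.simulate_pair_distances(
                fit.model, fit.model, n=len(inter), rng=rng
            )
            comparison = fish_stats.group_comparison([inter, simulated.tolist()])
            entry["null_model"] = {
                "fitted": fit.model.to_dict(),
                "ks_stat": fit.ks_stat,
                "observed_vs_simulated_p": comparison["p"],
            }
        if truth is not None:
            sub = truth[truth["probe_id"] == probe_id]
            entry["true_pairing_percent"] = 100.0 * sub["paired"].mean()
        report["probes"][probe_id] = entry
        for rep, (n_scored, n_paired) in enumerate(result.per_replicate):
            rows.append(
                {
                    "probe_id": probe_id,
                    "replicate": rep,
                    "n_scored": n_scored,
                    "n_paired": n_paired,
                    "frequency_percent": 100.0 * n_paired / n_scored if n_scored else 0.0,
                }
            )
    io.write_tsv(pd.DataFrame(rows), outdir / "pairing_per_replicate.tsv")
    with open(outdir / "fish_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_resolved(cfg, outdir)
    return report


def _load_or_generate_4c(
    cfg: dict, rng: np.random.Generator
) -> tuple[dict, pd.DataFrame, pd.DataFrame, synthetic.FourCGeneratorConfig | None]:
    if "generator" in cfg:
        gen = dict(cfg["generator"])
        genome = gen.pop("genome", {})
        haplotypes, snps = synthetic.make_haplotype_genome(rng=rng, **genome)
        rcfg = synthetic.FourCGeneratorConfig(**gen.get("reads", {}))
        return haplotypes, snps, pd.DataFrame(), rcfg
    inputs = cfg.get("inputs", {})
    for key in ("fasta_b6", "fasta_sd7", "vcf", "reads_tsv"):
        path = inputs.get(key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing required input {key!r}: {path}")
    haplotypes = {
        "B6": io.read_fasta(inputs["fasta_b6"]),
        "SD7": io.read_fasta(inputs["fasta_sd7"]),
    }
    snps = io.read_vcf(inputs["vcf"])
    reads = io.read_tsv(inputs["reads_tsv"])
    return haplotypes, snps, reads, None


def run_4c_pipeline(config: dict, outdir: str | Path) -> dict:
    """Digest, classify, call alleles, deduplicate and window 4C data.

    With a generator block, simulates the genome and reads first; with
    input paths, consumes pre-mapped reads.  Writes fragment BED,
    informative-fragment TSV, hit tables, a cis bedGraph, trans-rate
    and genome-wide summary TSVs, a JSON report and the resolved
    configuration.
    """
    cfg = _resolve(config, FOURC_DEFAULTS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    haplotypes, snps, reads, rcfg = _load_or_generate_4c(cfg, rng)

    fragments = {
        allele: allelic4c.digest_genome(
            haplotypes[allele], site=cfg["site"], cut_offset=cfg["cut_offset"]
        )
        for allele in allelic4c.ALLELES
    }
    ref_map = fragments["B6"]
    informative = allelic4c.classify_informative(
        ref_map, snps, read_length=cfg["read_length"]
    )

    truth = None
    if rcfg is not None:
        truth = synthetic.simulate_4c_reads(rcfg, fragments, haplotypes, rng)
        reads = truth[
            ["read_id", "bait_allele", "chrom", "read_start", "read_end",
             "prey_position", "sequence"]
        ].copy()
        bait_chrom, bait_position = rcfg.bait_chrom, rcfg.bait_position
    else:
        bait_chrom = cfg["bait_chrom"]
        bait_position = cfg["bait_position"]
    bait_fid = ref_map.locate(bait_chrom, bait_position)

    reads = reads.copy()
    reads["prey_allele"] = allelic4c.assign_alleles(reads, snps)
    hits = allelic4c.build_hits(reads, ref_map, bait_fid)
    deduped = allelic4c.dedupe_positions(hits)

    cis = deduped[deduped["relation"] == "cis"]
    trans_allelic = deduped[deduped["relation"] == "trans_allelic"]
    trans_all = deduped[deduped["relation"] != "cis"]

    cis_profile = allelic4c.cis_window_profile(
        cis, ref_map, bait_chrom, window=cfg["cis_window"]
    )
    trans_rate = allelic4c.trans_allelic_rate(
        trans_allelic, informative, ref_map, bait_chrom, window=cfg["trans_window"]
    )
    gw = cfg["genome_window"]
    # default: the tiling window containing the bait position
    homologous_window = tuple(
        cfg.get("homologous_window", (bait_chrom, bait_position, bait_position + 1))
    )
    genome_summary, box, flags = allelic4c.genomewide_trans_summary(
        trans_all, ref_map, homologous_window, window=gw
    )

    io.write_bed(ref_map.table.assign(name=ref_map.table["fragment_id"]), outdir / "fragments.bed")
    io.write_tsv(informative, outdir / "informative_fragments.tsv")
    io.write_tsv(deduped, outdir / "hits_deduped.tsv")
    io.write_bedgraph(cis_profile.table, outdir / "cis_profile_100kb.bedgraph")
    io.write_tsv(trans_rate.table, outdir / "trans_allelic_rate_200kb.tsv")
    io.write_tsv(genome_summary.table, outdir / "trans_genomewide_1p4mb.tsv")

    report: dict[str, Any] = {
        "seed": cfg["seed"],
        "bait": {"chrom": bait_chrom, "position": bait_position, "fragment_id": bait_fid},
        "n_reads": int(len(reads)),
        "n_hits_deduped": int(len(deduped)),
        "n_fragments": ref_map.n_fragments(),
        "n_stringent": int((informative["class"] == "stringent").sum()),
        "cis_unique_positions": int(cis_profile.total()),
        "relation_counts": deduped["relation"].value_counts().to_dict(),
        "genomewide_box": box.__dict__ | {"outliers": list(box.outliers)},
        "homologous_window": {
            "chrom": homologous_window[0],
            "start": int(flags["start"].iloc[0]),
            "end": int(flags["end"].iloc[0]),
            "count": int(flags["value"].iloc[0]),
            "outlier_high": bool(flags["outlier_high"].iloc[0]),
        },
    }
    if truth is not None:
        confusion = (
            pd.crosstab(truth["prey_allele"], reads["prey_allele"])
            .to_dict()
        )
        report["allele_confusion"] = confusion
        io.write_tsv(truth.drop(columns=["sequence"]), outdir / "truth.tsv")
    with open(outdir / "fourc_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    _write_resolved(cfg, outdir)
    return report
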