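"""End-to-end pipeline: simulate (or load) inputs, run every analysis, report.

The report is a plain JSON-serialisable dict in which every number is the
direct output of one library operation; re-running with the same config and
seed reproduces it byte-for-byte (no timestamps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import (
    bin_contacts,
    cis_fraction,
    count_strong_tads,
    expected_by_distance,
    observed_over_expected,
    rescaled_domain_pileup,
    score_domains,
)
from .expression import (
    assign_clusters,
    compute_cpm,
    compute_tpm,
    exclude_maternal,
    gene_body_density,
    intergenic_ratio,
    kd_response,
    metaprofile,
    spearman_deposition_vs_change,
)
from .genome import derive_intergenic_regions
from .microscopy import mobile_fraction, relative_intensity
from .simulate import SimulatedDataset, SimulationConfig, simulate_all, _plain

ALL_SECTIONS = ("expression", "intergenic", "deposition", "hic", "frap", "intensity")


@dataclass
class PipelineOutput:
    """Report dict plus the key per-feature tables behind it."""

    report: dict
    clusters: object | None = None  # ClusterAssignment
    repeat_clusters: object | None = None
    kd_per_gene: pd.DataFrame | None = None
    kd_per_repeat: pd.DataFrame | None = None
    maternal_excluded: pd.Index | None = None
    tpm_by_sample: pd.DataFrame | None = None
    domain_scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    body_density: pd.Series | None = None
    frap_values: dict[str, list[float]] = field(default_factory=dict)


def _mean_by_sample(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns ``sample.repN`` down to one column per sample."""
    groups = df.columns.str.rsplit(".", n=1).str[0]
    return df.T.groupby(groups.values).mean().T


def analyze(ds: SimulatedDataset, sections: tuple[str, ...] = ALL_SECTIONS) -> PipelineOutput:
    """Run every requested analysis section on a dataset."""
    config = ds.config
    report: dict = {
        "seed": config.seed,
        "version": __version__,
        "config": _plain(_config_echo(config)),
        "sections": {s: ("run" if s in sections else "skipped") for s in ALL_SECTIONS},
    }
    out = PipelineOutput(report=report)

    if "expression" in sections:
        _analyze_expression(ds, out)
    if "intergenic" in sections:
        _analyze_intergenic(ds, out)
    if "deposition" in sections:
        if out.clusters is None:
            _analyze_expression(ds, out)
        _analyze_deposition(ds, out)
    if "hic" in sections:
        _analyze_hic(ds, out)
    if "frap" in sections:
        _analyze_frap(ds, out)
    if "intensity" in sections:
        _analyze_intensity(ds, out)
    return out


def _config_echo(config: SimulationConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def _analyze_expression(ds: SimulatedDataset, out: PipelineOutput) -> None:
    config = ds.config
    tpm = compute_tpm(ds.expression.counts)
    tpm_by_sample = _mean_by_sample(tpm.data)
    out.tpm_by_sample = tpm_by_sample
    excluded = exclude_maternal(
        tpm_by_sample, mii="MII.none", early="early2C.control", late="late2C.control"
    )
    out.maternal_excluded = excluded
    embryonic = tpm_by_sample.drop(index=excluded)
    clusters = assign_clusters(
        embryonic["early2C.control"], embryonic["late2C.control"],
        pseudocount=config.pseudocount,
    )
    out.clusters = clusters
    kd_table, kd_summary = kd_response(
        embryonic["late2C.KD"], embryonic["late2C.control"], clusters,
        pseudocount=config.pseudocount,
    )
    out.kd_per_gene = kd_table

    cpm = compute_cpm(ds.expression.repeat_counts)
    cpm_by_sample = _mean_by_sample(cpm.data)
    rep_clusters = assign_clusters(
        cpm_by_sample["early2C.control"], cpm_by_sample["late2C.control"],
        pseudocount=config.pseudocount,
    )
    out.repeat_clusters = rep_clusters
    rep_kd_table, rep_kd_summary = kd_response(
        cpm_by_sample["late2C.KD"], cpm_by_sample["late2C.control"], rep_clusters,
        pseudocount=config.pseudocount,
    )
    out.kd_per_repeat = rep_kd_table

    out.report["expression"] = {
        "n_genes": int(len(tpm_by_sample)),
        "n_maternal_excluded": int(len(excluded)),
        "cluster_sizes": clusters.sizes(),
        "kd_median_log2_by_cluster": {
            c: (None if np.isnan(kd_summary.loc[c, "median"]) else float(kd_summary.loc[c, "median"]))
            for c in kd_summary.index
        },
        "repeat_cluster_sizes": rep_clusters.sizes(),
        "repeat_kd_median_log2_by_cluster": {
            c: (None if np.isnan(rep_kd_summary.loc[c, "median"]) else float(rep_kd_summary.loc[c, "median"]))
            for c in rep_kd_summary.index
        },
    }


def _analyze_intergenic(ds: SimulatedDataset, out: PipelineOutput) -> None:
    config = ds.config
    intergenic = derive_intergenic_regions(ds.annotation, config.intergenic_distance_bp)
    ratios = {
        sample: float(intergenic_ratio(frags, intergenic))
        for sample, frags in ds.fragments.items()
    }
    out.report["intergenic"] = {
        "distance_bp": config.intergenic_distance_bp,
        "total_intergenic_bp": intergenic.total_bp(),
        "ratio_by_sample": ratios,
    }


def _analyze_deposition(ds: SimulatedDataset, out: PipelineOutput) -> None:
    assert out.clusters is not None
    frags = ds.deposition
    total = len(frags)
    retained = set(out.clusters.table.index)
    genes = [g for g in ds.annotation.genes if g.name in retained]
    density = gene_body_density(frags, genes, total_fragments=total)
    out.body_density = density
    rho = spearman_deposition_vs_change(density, out.clusters.table["log2_ratio"])
    body_means = {}
    for c in ("I", "II", "III"):
        members = set(out.clusters.members(c))
        cluster_genes = [g for g in genes if g.name in members]
        if cluster_genes:
            prof = metaprofile(frags, cluster_genes, total_fragments=total)
            body_means[c] = float(prof.body().mean())
        else:
            body_means[c] = None
    out.report["deposition"] = {
        "n_fragments": total,
        "spearman_rho_vs_expression_change": float(rho),
        "metaprofile_body_mean_by_cluster": body_means,
    }


def _analyze_hic(ds: SimulatedDataset, out: PipelineOutput) -> None:
    config = ds.config
    hic_report: dict = {}
    for sample, records in ds.contacts.items():
        cis = cis_fraction(records)
        mats = bin_contacts(records, config.chrom_sizes, config.bin_size)
        oe = {
            chrom: observed_over_expected(m, expected_by_distance(m))
            for chrom, m in mats.items()
        }
        scores = score_domains(oe, ds.tads, config.bin_size)
        out.domain_scores[sample] = scores
        pileup = rescaled_domain_pileup(oe, ds.tads, config.bin_size)
        third = pileup.shape[0] // 3
        centre = float(pileup[third : 2 * third, third : 2 * third].mean())
        corner = float(pileup[:third, :third].mean())
        hic_report[sample] = {
            "cis_fraction": float(cis),
            "n_tads_scored": int(len(scores)),
            "mean_domain_score": float(scores["score"].mean()),
            "strong_tads_gt_2.5": int(count_strong_tads(scores, threshold=2.5)),
            "pileup_centre_mean": centre,
            "pileup_corner_mean": corner,
        }
    out.report["hic"] = hic_report


def _analyze_frap(ds: SimulatedDataset, out: PipelineOutput) -> None:
    frap_report = {}
    for sample, (curves, _true_mf) in ds.frap.items():
        values = [mobile_fraction(c) for c in curves]
        out.frap_values[sample] = values
        frap_report[sample] = {
            "n_embryos": len(values),
            "mean_mobile_fraction": float(np.mean(values)),
            "sem_mobile_fraction": float(np.std(values, ddof=1) / np.sqrt(len(values)))
            if len(values) > 1
            else None,
        }
    out.report["frap"] = frap_report


def _analyze_intensity(ds: SimulatedDataset, out: PipelineOutput) -> None:
    per_embryo, stats = relative_intensity(ds.intensity, control_group="control")
    out.report["intensity"] = {
        group: {"n": int(stats.loc[group, "n"]), "mean_relative": float(stats.loc[group, "mean"])}
        for group in stats.index
    }


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    sections: tuple[str, ...] = ALL_SECTIONS,
) -> PipelineOutput:
    """Simulate every input under ``outdir/inputs``, analyse it, and write
    ``outdir/report.json`` plus per-section TSV tables under ``outdir/tables``."""
    outdir = Path(outdir)
    ds = simulate_all(config, outdir / "inputs")
    out = analyze(ds, sections=sections)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    if out.clusters is not None:
        out.clusters.to_tsv(tables / "gene_clusters.tsv")
        out.repeat_clusters.to_tsv(tables / "repeat_clusters.tsv")
        out.kd_per_gene.to_csv(tables / "kd_response_genes.tsv", sep="\t",
                               index_label="feature_id", float_format="%.6g")
        pd.Series(out.maternal_excluded, name="feature_id").to_csv(
            tables / "maternal_excluded.tsv", sep="\t", index=False
        )
    for sample, scores in out.domain_scores.items():
        scores.to_csv(tables / f"tad_scores.{sample}.tsv", sep="\t", index=False,
                      float_format="%.6g")
    if out.body_density is not None:
        out.body_density.to_csv(tables / "deposition_body_density.tsv", sep="\t",
                                index_label="gene_id", header=["rpkm"],
                                float_format="%.6g")
    with open(outdir / "report.json", "w") as fh:
        json.dump(out.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
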