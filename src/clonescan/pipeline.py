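"""End-to-end orchestration: simulate (or load) -> filter -> classify ->
diversity -> relatedness -> density -> motif sets -> effects -> TE sharing,
with a machine-readable JSON summary.

Every number in the summary is re-derivable from the stage outputs written
to the run directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    clonal_variation,
    clonesim,
    density_regions,
    effect_annotation,
    motif_region_builder,
    popgen_stats,
    relatedness,
    te_sharing,
    variant_store,
)
from .core import CoverageMask, read_bed
from .summaries import percent


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run.

    Either ``simulate`` (a SimConfig) or the explicit input paths must be
    set. Thresholds default to the conventional hard-filter values used
    throughout the package.
    """

    outdir: str = "clonescan_run"
    seed: int = 0
    simulate: clonesim.SimConfig | None = None
    vcf: str | None = None
    fasta: str | None = None
    gff3: str | None = None
    te_tables: list = field(default_factory=list)
    mask_beds: dict = field(default_factory=dict)  # sample -> BED path
    outgroup_sample: str | None = None
    window: int = 50_000
    unique_window: int = 1_000_000
    min_dp: int = variant_store.DEFAULT_MIN_DP
    min_qd: float = variant_store.DEFAULT_MIN_QD
    snp_indel_window: int = variant_store.DEFAULT_SNP_INDEL_WINDOW
    indel_min_gap: int = variant_store.DEFAULT_INDEL_MIN_GAP
    indel_max_len: int = variant_store.DEFAULT_INDEL_MAX_LEN
    max_missing_fraction: float = variant_store.DEFAULT_MAX_MISSING_FRACTION
    te_radius: int = te_sharing.DEFAULT_RADIUS

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = clonesim.SimConfig(**self.simulate)
        if self.simulate is None and self.vcf is None:
            raise ValueError("config needs either a simulate block or input paths")
        for name in (
            "min_dp",
            "min_qd",
            "snp_indel_window",
            "indel_min_gap",
            "indel_max_len",
            "window",
            "unique_window",
            "te_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate is not None:
        sim = clonesim.simulate_population(config.simulate)
        clonesim.write_dataset(sim, outdir / "inputs")
        reference = sim.reference
        matrix = sim.matrix
        masks = sim.masks
        genes = sim.genes
        tei = sim.te_insertions
        truth = sim.truth
        outgroup = "OUT" if config.simulate.outgroup else config.outgroup_sample
        chrom_lengths = dict(config.simulate.chrom_lengths)
    else:
        matrix = variant_store.read_vcf(config.vcf)
        reference = clonesim.read_fasta(config.fasta) if config.fasta else {}
        chrom_lengths = {c: len(s) for c, s in reference.items()}
        genes = effect_annotation.read_gff3(config.gff3) if config.gff3 else []
        tei = (
            pd.concat([clonesim.read_te_table(p) for p in config.te_tables], ignore_index=True)
            if config.te_tables
            else pd.DataFrame(columns=clonesim.TE_COLUMNS)
        )
        masks = None
        if config.mask_beds:
            masks = CoverageMask(chrom_lengths=chrom_lengths)
            for sample, bed in config.mask_beds.items():
                masks.intervals[sample] = read_bed(bed)
        outgroup = config.outgroup_sample
        truth = None
    return reference, matrix, masks, genes, tei, truth, outgroup, chrom_lengths


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the JSON-ready summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "load"
    try:
        (
            reference,
            matrix,
            masks,
            genes,
            tei,
            truth,
            outgroup,
            chrom_lengths,
        ) = _load_inputs(config, outdir)

        stage = "filter"
        filtered, report = variant_store.apply_filter_cascade(
            matrix,
            min_dp=config.min_dp,
            min_qd=config.min_qd,
            snp_indel_window=config.snp_indel_window,
            indel_min_gap=config.indel_min_gap,
            indel_max_len=config.indel_max_len,
            max_missing_fraction=config.max_missing_fraction,
        )
        variant_store.write_vcf(filtered, outdir / "filtered.vcf", chrom_lengths or None)
        report.write_tsv(outdir / "filter_report.tsv")
        summary["filter"] = report.to_dict()

        stage = "clonal"
        clone_names = [s for s in filtered.samples if s != outgroup]
        clones_m = filtered.select_samples(clone_names)
        spectrum = clonal_variation.sharing_and_missingness(clones_m)
        spectrum.to_frame().to_csv(outdir / "spectra.tsv", sep="\t", index=False)
        poly = clonal_variation.polymorphic_sites(clones_m, require_complete=True)
        unique = clonal_variation.clone_unique_variants(clones_m)
        unique.write_beds(outdir / "unique_beds")
        density_track = clonal_variation.per_window_unique_density(
            unique, chrom_lengths, window=config.unique_window
        )
        density_track.to_csv(outdir / "unique_density.tsv", sep="\t", index=False)
        n_poly_snp = int((poly.sites["vtype"] == "SNP").sum())
        n_poly_indel = int((poly.sites["vtype"] == "INDEL").sum())
        summary["clonal"] = {
            "complete_sites": int(spectrum.missingness.get(clones_m.n_samples, 0)),
            "complete_percent": spectrum.complete_fraction_percent(),
            "polymorphic_sites": poly.n_sites,
            "polymorphic_snps": n_poly_snp,
            "polymorphic_indels": n_poly_indel,
            "unique_counts": unique.counts(),
            "unique_total": unique.total(),
            "unique_percent_of_polymorphic": percent(unique.total(), poly.n_sites),
        }

        stage = "popgen"
        poly_snp = poly.select_sites((poly.sites["vtype"] == "SNP").to_numpy())
        win = popgen_stats.windowed_stats(
            poly_snp, masks=masks, window=config.window, chrom_lengths=chrom_lengths or None
        )
        win.to_csv(outdir / "popgen_windows.tsv", sep="\t", index=False)
        chrom_stats = popgen_stats.chromosome_stats(win)
        chrom_stats.to_csv(outdir / "popgen_chromosomes.tsv", sep="\t", index=False)
        for col in ("pi_sum", "theta_w", "tajima_d"):
            popgen_stats.write_bedgraph(win, col, outdir / f"{col}.bedgraph")
        genome_row = chrom_stats[chrom_stats["chrom"] == "genome"]
        if len(genome_row):
            summary["popgen"] = {
                "S": int(genome_row["S"].iloc[0]),
                "tajima_d": float(genome_row["tajima_d"].iloc[0]),
                "pi_per_kbp": float(genome_row["pi_per_kbp"].iloc[0]),
                "theta_w_per_kbp": float(genome_row["theta_w_per_kbp"].iloc[0]),
            }

        stage = "relatedness"
        complete = filtered.select_sites(filtered.complete_mask())
        phi = relatedness.kinship_matrix(complete)
        phi.to_csv(outdir / "kinship.tsv", sep="\t")
        pca_input = clonal_variation.polymorphic_sites(
            complete.select_samples(clone_names), require_complete=True
        )
        if pca_input.n_sites >= 2:
            coords, evr = relatedness.genotype_pca(pca_input, k=2)
            coords.assign(
                explained=[*evr, *[np.nan] * (len(coords) - len(evr))][: len(coords)]
            ).to_csv(outdir / "pca.tsv", sep="\t")
            summary["pca_explained"] = [float(v) for v in evr]
            summary["pc1_extreme_sample"] = str(coords["PC1"].abs().idxmax())
        kin_vals = {}
        for i, a in enumerate(phi.index):
            for b in phi.columns[i + 1 :]:
                kin_vals[f"{a}:{b}"] = float(phi.loc[a, b])
        summary["kinship_range"] = (
            [min(kin_vals.values()), max(kin_vals.values())] if kin_vals else []
        )

        stage = "density"
        winds = density_regions.classify_windows(
            filtered.select_samples(clone_names),
            masks=masks,
            window=config.window,
            chrom_lengths=chrom_lengths or None,
        )
        winds.to_csv(outdir / "density_windows.tsv", sep="\t", index=False)
        for column, cls, tag in (
            ("snp_class", "LOW", "snp_low"),
            ("snp_class", "HIGH", "snp_high"),
            ("indel_class", "LOW", "indel_low"),
            ("indel_class", "HIGH", "indel_high"),
        ):
            regions = density_regions.merge_regions(winds, column, cls)
            with open(outdir / f"density_{tag}.bed", "w") as fh:
                for r in regions:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{cls}\n")
        summary["density"] = density_regions.class_totals_mbp(winds)
        summary["density_coverage_rho"] = density_regions.density_coverage_independence(
            winds, seed=config.seed
        )

        stage = "motifseqs"
        if reference:
            all_unique = unique.all_sites()
            control = motif_region_builder.build_control_set(all_unique, reference)
            high, very_high = motif_region_builder.build_mutation_sets(all_unique, reference)
            control.write_fasta(outdir / "control.fa")
            high.write_fasta(outdir / "high.fa")
            very_high.write_fasta(outdir / "very_high.fa")
            summary["motifseqs"] = {
                "control": len(control),
                "high": len(high),
                "very_high": len(very_high),
            }

        stage = "effects"
        if genes and reference:
            calls = effect_annotation.classify_matrix(poly, genes, reference)
            calls.to_csv(outdir / "effects.tsv", sep="\t", index=False)
            summary["effects"] = effect_annotation.summarize_high_impact(
                calls, n_poly_snp, n_poly_indel, unique_sites=unique.all_sites()
            )

        stage = "te"
        if len(tei):
            events = te_sharing.cluster_tei(tei, radius=config.te_radius)
            te_sharing.events_frame(events).to_csv(outdir / "te_events.tsv", sep="\t", index=False)
            te_sharing.write_events_bed(events, outdir / "te_events.bed")
            summary["te"] = {}
            for method in sorted(tei["method"].unique()):
                ev_m = [e for e in events if e.method == method]
                spec = te_sharing.sharing_spectrum(ev_m, n_clones=len(clone_names))
                spec.to_frame().to_csv(
                    outdir / f"te_spectrum_{method}.tsv", sep="\t", index=False
                )
                entry = {
                    "events": spec.total,
                    "exclusive": spec.counts.get(1, 0),
                    "exclusive_percent": spec.percent_at(1),
                    "shared_all_percent": spec.percent_at(len(clone_names)),
                    "by_class": spec.by_class,
                }
                excl = te_sharing.exclusive_tei_per_clone(ev_m)
                if len(excl) >= 4 and unique.total() > 0:
                    entry["snp_correlation"] = te_sharing.tei_snp_correlation(
                        excl, unique.counts(), seed=config.seed
                    )
                summary["te"][method] = entry

        if truth is not None:
            stage = "truth_deltas"
            summary["truth"] = _truth_deltas(truth, filtered, clone_names, unique, summary)
    except Exception as err:
        manifest = {"failed_stage": stage, "error": str(err)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _truth_deltas(truth, filtered, clone_names, unique, summary) -> dict:
    """Truth-vs-estimate comparison on retained complete-case sites."""
    complete = filtered.select_samples(clone_names)
    keep = complete.complete_mask()
    retained = set(
        zip(
            complete.sites["chrom"][keep],
            complete.sites["pos"][keep].astype(int),
        )
    )
    deltas = {}
    for clone, df in truth.somatic_variants.items():
        truth_retained = sum(
            (c, int(p)) in retained for c, p in zip(df["chrom"], df["pos"])
        )
        est = unique.counts().get(clone, 0)
        deltas[clone] = {
            "truth_total": len(df),
            "truth_retained": int(truth_retained),
            "estimated_unique": int(est),
            "delta": int(est) - int(truth_retained),
        }
    return {
        "somatic_per_clone": deltas,
        "varietal_truth_total": len(truth.varietal_variants),
        "te_truth_events": int(len(truth.te_events)),
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
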