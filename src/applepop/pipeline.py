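"""End-to-end orchestration: flat config, stage wiring, reproducible report.

The pipeline composes the library stages in order — genotype filtering,
fourfold-degenerate SNP selection, NJ tree and PCA, windowed diversity,
pairwise F_ST with MDS, LD decay, ancestry-mosaic classification, and the
cross-population sweep scan — writing every intermediate artifact to the
output directory.  Stages communicate only through serialized artifacts in
memory-equivalent containers; no stage reads another's internals.

Every output file embeds the config hash and seed in a header comment, and
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import phylo_pca, popgen_stats, sweep_scan, variant_filters
from .io_formats import (
    GeneModelSet,
    GeneticMap,
    GenotypeDataset,
    PopulationGrouping,
    Region,
    read_fasta,
    read_genetic_map,
    read_gff3,
    read_groups,
    read_vcf,
    write_bed,
    write_vcf,
)

logger = logging.getLogger(__name__)

#: every knob with its default; values are parsed to the type of the default
DEFAULTS: dict[str, object] = {
    "input.vcf": "",
    "input.gff3": "",
    "input.fasta": "",
    "input.map": "",
    "input.groups": "",
    "input.chrom_lengths": "",  # optional TSV chrom<TAB>length
    "seed": 0,
    "filter.min_spacing": 5,
    "filter.max_missing": 0.5,
    "snpset.min_maf": 0.05,
    "snpset.max_missing": 0.10,
    "pi.width": 10000,
    "divergent.top_frac": 0.01,
    "ld.min_maf": 0.10,
    "ld.hwe_cutoff": 0.001,
    "ld.window_bp": 500000,
    "ld.max_sites": 2000,
    "tree.bootstrap": 1000,
    "tree.outgroup": "",
    "pca.components": 10,
    "ancestry.width": 100000,
    "ancestry.threshold": 0.6,
    "ancestry.ratio": 2.0,
    "ancestry.min_snps": 5,
    "groups.domesticated": "Dom",
    "groups.progenitor": "Sie_K",
    "groups.introgressor": "Syl",
    "sweep.ref": "",
    "sweep.obj": "",
    "sweep.window": 10000,
    "sweep.join_frac": 0.8,
    "sweep.top_frac": 0.10,
    "sweep.keep_frac": 0.5,
    "sweep.grid_spacing": 100,
    "sweep.max_snps": 100,
    "sweep.corr_level": 0.7,
    "sweep.window_half_cm": 0.025,
}


@dataclass
class RunConfig:
    """Flat namespaced key-value configuration with validated keys."""

    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        for key, raw in self.values.items():
            default = DEFAULTS[key]
            if isinstance(default, bool):
                merged[key] = str(raw).lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                merged[key] = int(raw)
            elif isinstance(default, float):
                merged[key] = float(raw)
            else:
                merged[key] = str(raw)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        values: dict[str, object] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        return cls(values)

    def canonical_text(self) -> str:
        return "\n".join(f"{k}={self.values[k]}" for k in sorted(self.values))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_text().encode()).hexdigest()[:16]


def _read_chrom_lengths(path: str) -> dict[str, int] | None:
    if not path:
        return None
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def run_pipeline(config: RunConfig, out_dir: str) -> str:
    """Execute every stage; returns the path of the final report.

    Any stage failure aborts with the stage name and its inputs attached to
    the exception message.
    """
    os.makedirs(out_dir, exist_ok=True)
    hdr = [f"config_hash={config.config_hash()}", f"seed={config['seed']}"]
    report: list[str] = [
        "# applepop pipeline report",
        f"# config_hash={config.config_hash()}",
        f"# seed={config['seed']}",
    ]

    def out(name: str) -> str:
        return os.path.join(out_dir, name)

    stage = "load-inputs"
    try:
        dataset = read_vcf(config["input.vcf"])
        grouping = PopulationGrouping(read_groups(config["input.groups"]))
        genes = read_gff3(config["input.gff3"]) if config["input.gff3"] else GeneModelSet([])
        genome = read_fasta(config["input.fasta"]) if config["input.fasta"] else {}
        gmap = read_genetic_map(config["input.map"]) if config["input.map"] else None
        chrom_lengths = _read_chrom_lengths(config["input.chrom_lengths"])
        report.append(f"input_sites\t{dataset.n_sites}")
        report.append(f"input_accessions\t{dataset.n_accessions}")

        stage = "filter"
        dataset, filt_report = variant_filters.filter_sites(
            dataset,
            min_spacing=config["filter.min_spacing"],
            max_missing=config["filter.max_missing"],
        )
        filt_report.to_frame().to_csv(out("filter_report.tsv"), sep="\t", index=False)
        write_vcf(dataset, out("filtered.vcf"), header_comments=hdr)
        report.append(f"filtered_sites\t{dataset.n_sites}")

        stage = "snpset"
        core = variant_filters.maf_missing_filter(
            dataset,
            min_maf=config["snpset.min_maf"],
            max_missing=config["snpset.max_missing"],
        )
        report.append(f"core_snpset_sites\t{core.n_sites}")

        stage = "sites-4d"
        if genome and genes.genes:
            four_d = variant_filters.fourfold_degenerate_sites(core, genes, genome)
        else:
            four_d = core
        write_vcf(four_d, out("sites_4d.vcf"), header_comments=hdr)
        report.append(f"fourfold_sites\t{four_d.n_sites}")

        stage = "tree"
        tree_input = four_d if four_d.n_sites >= 10 else core
        tree = phylo_pca.bootstrap_support(
            tree_input, n_replicates=config["tree.bootstrap"], seed=config["seed"]
        )
        if config["tree.outgroup"]:
            tree = phylo_pca.root_with_outgroup(tree, config["tree.outgroup"])
        with open(out("tree.nwk"), "w") as fh:
            for comment in hdr:
                fh.write(f"[&{comment}]\n")
            fh.write(tree.to_newick() + "\n")
        report.append(f"tree_leaves\t{len(tree.leaf_labels())}")

        stage = "pca"
        scores, eigvals = phylo_pca.pca_genotypes(
            tree_input, n_components=config["pca.components"]
        )
        pca_df = pd.DataFrame(
            scores, index=tree_input.accession_ids,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        )
        with open(out("pca_scores.tsv"), "w") as fh:
            for comment in hdr:
                fh.write(f"#{comment}\n")
            pca_df.to_csv(fh, sep="\t", index_label="accession")
        report.append(f"pca_components\t{scores.shape[1]}")

        stage = "pi"
        for group in grouping.group_labels:
            if len(grouping.members(group)) < 2:
                continue
            track = popgen_stats.pi_windows(dataset, grouping, group, width=config["pi.width"])
            track.write_tsv(out(f"pi_{group}.tsv"), header_comments=hdr)
            vals = track.table["value"].to_numpy()
            report.append(f"pi_mean_{group}\t{np.nanmean(vals):.6e}")

        stage = "fst-mds"
        fst = popgen_stats.pairwise_fst(dataset, grouping)
        with open(out("fst_matrix.tsv"), "w") as fh:
            for comment in hdr:
                fh.write(f"#{comment}\n")
            fst.to_frame().to_csv(fh, sep="\t", index_label="group")
        coords, rho = popgen_stats.mds_embed(fst, dims=2)
        mds_df = pd.DataFrame(coords, index=fst.labels, columns=["dim1", "dim2"])
        with open(out("mds.tsv"), "w") as fh:
            for comment in hdr:
                fh.write(f"#{comment}\n")
            fh.write(f"#spearman_rho={rho:.6f}\n")
            mds_df.to_csv(fh, sep="\t", index_label="group")
        report.append(f"mds_spearman_rho\t{rho:.4f}")

        stage = "divergent-snps"
        dom = config["groups.domesticated"]
        prog = config["groups.progenitor"]
        intro = config["groups.introgressor"]
        if dom in grouping.group_labels and prog in grouping.group_labels:
            top = popgen_stats.per_snp_fst_top(
                dataset, grouping, dom, prog, top_frac=config["divergent.top_frac"]
            )
            if genome and genes.genes:
                top["effect"] = [
                    variant_filters.classify_coding_effect(
                        (r.chrom, int(r.pos), r.ref, r.alt), genes, genome
                    )
                    for r in top.itertuples(index=False)
                ]
            else:
                top["effect"] = "unknown"
            with open(out("divergent_snps.tsv"), "w") as fh:
                for comment in hdr:
                    fh.write(f"#{comment}\n")
                top.to_csv(fh, sep="\t", index=False)
            n_ns = int((top["effect"] == "nonsynonymous").sum())
            report.append(f"divergent_snps\t{len(top)}")
            report.append(f"divergent_nonsynonymous\t{n_ns}")

        stage = "ld"
        for group in grouping.group_labels:
            if len(grouping.members(group)) < 4:
                continue
            sub = dataset
            if dataset.n_sites > config["ld.max_sites"]:
                step = dataset.n_sites / config["ld.max_sites"]
                idx = np.unique((np.arange(config["ld.max_sites"]) * step).astype(int))
                sub = dataset.take_sites(idx)
            curve = popgen_stats.ld_decay(
                sub, grouping, group,
                min_maf=config["ld.min_maf"],
                hwe_cutoff=config["ld.hwe_cutoff"],
                window_bp=config["ld.window_bp"],
            )
            with open(out(f"ld_{group}.tsv"), "w") as fh:
                for comment in hdr:
                    fh.write(f"#{comment}\n")
                curve.to_csv(fh, sep="\t", index=False)

        stage = "ancestry"
        fractions = None
        if all(g in grouping.group_labels for g in (dom, prog, intro)):
            anc_set = anc.ancestry_snp_set(
                dataset, grouping, [dom, prog, intro],
                min_maf=config["snpset.min_maf"],
                max_missing=config["snpset.max_missing"],
            )
            assignments = anc.site_assignments(
                anc_set, grouping, dom, prog, intro, threshold=config["ancestry.threshold"]
            )
            calls = anc.classify_windows(
                assignments, anc_set,
                width=config["ancestry.width"],
                ratio=config["ancestry.ratio"],
                min_snps=config["ancestry.min_snps"],
                chrom_lengths=chrom_lengths,
            )
            frame = anc.calls_to_frame(calls)
            with open(out("ancestry_windows.tsv"), "w") as fh:
                for comment in hdr:
                    fh.write(f"#{comment}\n")
                frame.to_csv(fh, sep="\t", index=False)
            for label, regs in anc.calls_to_regions(calls).items():
                write_bed(regs, out(f"ancestry_{label}.bed"), header_comments=hdr)
            fractions = anc.genome_fractions(calls, chrom_lengths=chrom_lengths)
            for label, pct in fractions.items():
                report.append(f"ancestry_pct_{label}\t{pct:.1f}")

        stage = "sweep"
        ref_group = config["sweep.ref"] or prog
        obj_group = config["sweep.obj"] or dom
        if gmap is not None and {ref_group, obj_group} <= set(grouping.group_labels):
            params = sweep_scan.ScanParams(
                grid_spacing=config["sweep.grid_spacing"],
                window_half_cm=config["sweep.window_half_cm"],
                max_snps=config["sweep.max_snps"],
                corr_level=config["sweep.corr_level"],
            )
            grid, track, regions = sweep_scan.sweep_pipeline(
                dataset, grouping, ref_group, obj_group, gmap,
                genes=genes if genes.genes else None,
                params=params, chrom_lengths=chrom_lengths,
                window_width=config["sweep.window"],
                join_frac=config["sweep.join_frac"],
                top_frac=config["sweep.top_frac"],
                keep_frac=config["sweep.keep_frac"],
            )
            with open(out("sweep_grid.tsv"), "w") as fh:
                for comment in hdr:
                    fh.write(f"#{comment}\n")
                grid.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            track.write_tsv(out("sweep_windows.tsv"), header_comments=hdr)
            write_bed(
                [Region(r.chrom, r.start, r.end, r.score) for r in regions],
                out("sweep_regions.bed"), header_comments=hdr,
            )
            gene_rows = [(r.chrom, r.start, r.end, ",".join(r.genes)) for r in regions]
            with open(out("sweep_genes.tsv"), "w") as fh:
                for comment in hdr:
                    fh.write(f"#{comment}\n")
                pd.DataFrame(
                    gene_rows, columns=["chrom", "start", "end", "genes"]
                ).to_csv(fh, sep="\t", index=False)
            total_bp = sum(r.end - r.start + 1 for r in regions)
            genome_bp = sum(chrom_lengths.values()) if chrom_lengths else int(
                dataset.sites.groupby("chrom")["pos"].max().sum()
            )
            n_genes = len({g for r in regions for g in r.genes})
            report.append(f"sweep_regions\t{len(regions)}")
            report.append(
                f"sweep_mean_length_kb\t{(total_bp / len(regions) / 1e3 if regions else 0):.1f}"
            )
            report.append(f"sweep_total_mb\t{total_bp / 1e6:.3f}")
            report.append(f"sweep_pct_genome\t{100 * total_bp / genome_bp:.2f}")
            report.append(f"sweep_genes\t{n_genes}")
    except Exception as exc:  # noqa: BLE001 — re-raise with stage provenance
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path = out("report.txt")
    with open(report_path, "w") as fh:
        fh.write("\n".join(report) + "\n")
    logger.info("pipeline complete: %s", report_path)
    return report_path
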