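"""Shared genomic containers and readers/writers for the standard text formats.

Coordinate convention
---------------------
Every interval inside the package is 1-based and inclusive at both ends, the
convention of VCF and GFF3.  BED files are 0-based half-open; the conversion
(``start - 1``) happens in exactly one place, :func:`write_bed` (and its
inverse in :func:`read_bed`), so that off-by-one arithmetic cannot drift
through the pipeline.

Genotypes are unphased diploid dosages: 0 (hom ref), 1 (het), 2 (hom alt),
with :data:`MISSING` (= -1) as the single sentinel for no-calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.  Distinct from 0/1/2 so that
#: every statistic has to handle missingness explicitly.
MISSING: int = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class FormatError(ValueError):
    """A file violated the dialect this package reads or writes."""


@dataclass
class GenotypeDataset:
    """Accessions x biallelic sites with unphased diploid dosages.

    Parameters
    ----------
    accession_ids
        Sample labels, one per matrix row.
    sites
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based.
        Positions must be strictly increasing within each chromosome.
    dosages
        ``(n_accessions, n_sites)`` int8 matrix of {0, 1, 2, MISSING}.
    """

    accession_ids: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.accession_ids), len(self.sites)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.sites)} sites"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid][0]
            raise ValueError(f"invalid dosage value {bad}")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to sites at positional ``index`` (kept in order)."""
        index = np.asarray(index)
        return GenotypeDataset(
            list(self.accession_ids),
            self.sites.iloc[index].reset_index(drop=True),
            self.dosages[:, index],
        )

    def take_accessions(self, labels: list[str]) -> "GenotypeDataset":
        idx = [self.accession_ids.index(a) for a in labels]
        return GenotypeDataset(list(labels), self.sites.copy(), self.dosages[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PopulationGrouping:
    """Accession -> group map with optional roles (e.g. scion/rootstock).

    ``table`` has columns ``accession, group, role``.
    """

    table: pd.DataFrame

    @classmethod
    def from_dict(cls, groups: dict[str, list[str]]) -> "PopulationGrouping":
        rows = [(a, g, "") for g, accs in groups.items() for a in accs]
        return cls(pd.DataFrame(rows, columns=["accession", "group", "role"]))

    @property
    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def members(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown group {group!r}")
        return list(sub["accession"])

    def indices(self, dataset: "GenotypeDataset", group: str) -> np.ndarray:
        """Row indices of this group's accessions in ``dataset``."""
        pos = {a: i for i, a in enumerate(dataset.accession_ids)}
        return np.array([pos[a] for a in self.members(group) if a in pos], dtype=int)


@dataclass
class DepthTable:
    """Per accession x site read support: total mapped depth and alt reads."""

    accession_ids: list[str]
    sites: pd.DataFrame
    total: np.ndarray  # (n_accessions, n_sites) int
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if self.total.shape != self.alt.shape:
            raise ValueError("total and alt matrices differ in shape")
        if (self.total < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.alt > self.total).any():
            raise ValueError("alt-supporting reads exceed total depth")


@dataclass
class GeneticMap:
    """Monotone (bp, cM) anchors per chromosome for distance interpolation."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp, kind="stable")
            bp, cm = bp[order], cm[order]
            if len(bp) < 2:
                raise FormatError(f"chromosome {chrom}: need >=2 map anchors")
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"chromosome {chrom}: cM not non-decreasing with bp")
            if np.any(np.diff(bp) == 0):
                raise FormatError(f"chromosome {chrom}: duplicated bp anchor")
            clean[chrom] = (bp, cm)
        self.anchors = clean


@dataclass
class GeneModel:
    """One gene: ordered CDS segments with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int, int]]  # (start, end, phase), sorted by start

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds)
        for (s1, e1, _), (s2, _, _) in zip(self.cds, self.cds[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def is_malformed(self) -> bool:
        """Coding length (after phase trim) not divisible by 3."""
        phase = self.cds[0][2] if self.strand == "+" else self.cds[-1][2]
        return (self.coding_length() - phase) % 3 != 0


@dataclass
class GeneModelSet:
    genes: list[GeneModel] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass
class Region:
    """A 1-based inclusive genomic interval with an optional score."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_text(path: str) -> int:
    """Cheap pre-scan for structural errors, reporting 1-based line numbers.

    Returns the expected number of columns in record lines.
    """
    n_columns = None
    saw_fileformat = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if lineno == 1 and not line.startswith("##fileformat=VCF"):
                    raise FormatError(f"line 1: missing ##fileformat=VCF header")
                saw_fileformat = saw_fileformat or line.startswith("##fileformat=VCF")
                continue
            if line.startswith("#CHROM"):
                if not saw_fileformat:
                    raise FormatError(f"line {lineno}: #CHROM before ##fileformat")
                n_columns = len(line.split("\t"))
                if n_columns < 8:
                    raise FormatError(f"line {lineno}: #CHROM header has {n_columns} columns, need >=8")
                continue
            if n_columns is None:
                raise FormatError(f"line {lineno}: record before #CHROM header")
            got = len(line.split("\t"))
            if got != n_columns:
                raise FormatError(
                    f"line {lineno}: {got} columns, header declares {n_columns}"
                )
    if n_columns is None:
        raise FormatError("no #CHROM header line found")
    return n_columns


def read_vcf(path: str, with_depths: bool = False):
    """Read a VCF v4.x into a :class:`GenotypeDataset`.

    Multiallelic records are skipped with a warning.  ``./.`` genotypes become
    :data:`MISSING`; otherwise the dosage is the count of alt alleles.  With
    ``with_depths=True`` also returns a :class:`DepthTable` built from the AD
    FORMAT field (sites lacking AD get zero depth).
    """
    from cyvcf2 import VCF

    _validate_vcf_text(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    total_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        gt = np.asarray(variant.gt_types)  # 0,1,2 dosage; 3 = unknown (gts012)
        dos = np.where(gt == 3, MISSING, gt).astype(np.int8)
        dosage_cols.append(dos)
        if with_depths:
            try:
                ad = variant.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                total_cols.append(np.zeros(len(samples), dtype=np.int32))
                alt_cols.append(np.zeros(len(samples), dtype=np.int32))
            else:
                ad = np.asarray(ad, dtype=np.int64)
                ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative
                total_cols.append(ad.sum(axis=1).astype(np.int32))
                alt_cols.append(ad[:, 1].astype(np.int32))
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records in {path}")
        logger.warning("skipped %d multiallelic records in %s", n_multi, path)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = (
        np.stack(dosage_cols, axis=1) if dosage_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    dataset = GenotypeDataset(samples, sites, dosages)
    if not with_depths:
        return dataset
    total = (
        np.stack(total_cols, axis=1) if total_cols
        else np.zeros((len(samples), 0), dtype=np.int32)
    )
    altm = (
        np.stack(alt_cols, axis=1) if alt_cols
        else np.zeros((len(samples), 0), dtype=np.int32)
    )
    return dataset, DepthTable(samples, sites.copy(), total, altm)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(dataset: GenotypeDataset, path: str, header_comments: list[str] | None = None) -> None:
    """Write a GT-only VCF v4.2 with sites in coordinate order."""
    for chrom, sub in dataset.sites.groupby("chrom", sort=False):
        if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
            raise ValueError(f"unsorted sites on {chrom}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=applepop\n")
        for comment in header_comments or []:
            fh.write(f"##{comment}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(dataset.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + dataset.accession_ids) + "\n")
        sites = dataset.sites
        for j in range(dataset.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in dataset.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Genetic map / depth / groups TSVs
# ---------------------------------------------------------------------------

def read_genetic_map(path: str) -> GeneticMap:
    """Read a TSV with columns ``chromosome, bp, cM`` into a GeneticMap.

    Rows may arrive in any order; anchors are sorted per chromosome.  A
    chromosome whose cM decrease with bp, or with fewer than two anchors, is
    rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"chromosome", "bp", "cM"}
    if not expected.issubset(df.columns):
        raise FormatError(f"genetic map needs columns {sorted(expected)}, got {list(df.columns)}")
    anchors = {
        str(chrom): (sub["bp"].to_numpy(), sub["cM"].to_numpy())
        for chrom, sub in df.groupby("chromosome", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    rows = [
        (chrom, int(bp), float(cm))
        for chrom, (bps, cms) in gmap.anchors.items()
        for bp, cm in zip(bps, cms)
    ]
    pd.DataFrame(rows, columns=["chromosome", "bp", "cM"]).to_csv(path, sep="\t", index=False)


def read_depth_table(path: str) -> DepthTable:
    """Read the sidecar depth dialect: long TSV of
    ``accession, chrom, pos, ref, alt, total, alt_reads``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    sites = (
        df[["chrom", "pos", "ref", "alt"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    accessions = list(dict.fromkeys(df["accession"]))
    site_index = {
        (r.chrom, r.pos): j for j, r in enumerate(sites.itertuples(index=False))
    }
    acc_index = {a: i for i, a in enumerate(accessions)}
    total = np.zeros((len(accessions), len(sites)), dtype=np.int32)
    alt = np.zeros_like(total)
    for r in df.itertuples(index=False):
        i, j = acc_index[r.accession], site_index[(r.chrom, r.pos)]
        total[i, j] = r.total
        alt[i, j] = r.alt_reads
    return DepthTable(accessions, sites, total, alt)


def write_depth_table(depths: DepthTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tchrom\tpos\tref\talt\ttotal\talt_reads\n")
        sites = depths.sites
        for i, acc in enumerate(depths.accession_ids):
            for j in range(len(sites)):
                r = sites.iloc[j]
                fh.write(
                    f"{acc}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                    f"{depths.total[i, j]}\t{depths.alt[i, j]}\n"
                )


def read_groups(path: str) -> pd.DataFrame:
    """Accession->group table: TSV columns ``accession, group[, role]``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"accession", "group"}.issubset(df.columns):
        raise FormatError("groups table needs columns accession, group")
    if "role" not in df.columns:
        df["role"] = ""
    return df


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(regions: list[Region], path: str, header_comments: list[str] | None = None) -> None:
    """Write 1-based inclusive regions as 0-based half-open BED lines."""
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"#{comment}\n")
        for r in regions:
            if r.end < r.start:
                raise ValueError(f"region end {r.end} < start {r.start}")
            line = f"{r.chrom}\t{r.start - 1}\t{r.end}"
            if r.score is not None:
                line += f"\t.\t{r.score:g}"
            fh.write(line + "\n")


def read_bed(path: str) -> list[Region]:
    """Inverse of :func:`write_bed` (BED3 / BED5 with score in column 5)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            score = float(parts[4]) if len(parts) >= 5 else None
            regions.append(Region(parts[0], int(parts[1]) + 1, int(parts[2]), score))
    return regions


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

def read_gff3(path: str) -> GeneModelSet:
    """Load gene/mRNA/CDS features (with phase) into a GeneModelSet.

    CDS segments are grouped per gene (via their mRNA parent when present).
    """
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        cds = []
        for c in db.children(gene, featuretype="CDS"):
            phase = int(c.frame) if c.frame not in (None, ".") else 0
            cds.append((c.start, c.end, phase))
        if not cds:
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, cds))
    return GeneModelSet(genes)


def write_gff3(genes: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.genes:
            start, end = g.span
            fh.write(
                f"{g.chrom}\tapplepop\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tapplepop\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for k, (s, e, phase) in enumerate(g.cds, start=1):
                fh.write(
                    f"{g.chrom}\tapplepop\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.cds{k};Parent={g.gene_id}.t1\n"
                )


def read_fasta(path: str) -> dict[str, str]:
    """Load a genome FASTA into an upper-cased dict of sequences."""
    from pyfaidx import Fasta

    fa = Fasta(path, rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
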