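"""Reading/writing standard formats, genotype QC, marker-to-gene mapping.

Genotypes come in as VCF (biallelic SNPs; QUAL and per-genotype calls used
for QC) or as a tab-separated allele-count matrix plus a marker map.  The
default QC mirrors sequence-panel practice: Phred variant quality > 500,
genotype call rate >= 0.8, minor allele frequency >= 0.05; missing calls are
imputed to the mean allele count 2p.  Gene intervals (GFF3, 1-based
inclusive; BED, 0-based half-open) map markers to genes, and GMT files group
genes (or markers) into named sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotypes import DEFAULT_CHROM_ORDER, GenotypeData

__all__ = [
    "QCConfig",
    "FeatureCatalog",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "read_gff3",
    "map_markers_to_features",
    "read_phenotypes",
]


@dataclass
class QCConfig:
    maf_min: float = 0.05
    qual_min: float = 500.0
    callrate_min: float = 0.8

    def __post_init__(self):
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.callrate_min <= 1:
            raise ValueError("callrate_min must be in [0, 1]")


def _qc_matrix(A: np.ndarray, qc: QCConfig):
    """MAF/monomorphism filter on an allele-count matrix; returns keep mask."""
    freq = np.nanmean(A, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return (maf >= max(qc.maf_min, 1e-12)) & (maf > 0)


def read_genotypes(path, fmt: str | None = None, qc: QCConfig | None = None,
                   chrom_order=DEFAULT_CHROM_ORDER) -> GenotypeData:
    """Read and QC genotypes from VCF or TSV (matrix + .map sidecar).

    Filters: biallelic SNPs only; QUAL > qual_min; call rate >= callrate_min;
    MAF >= maf_min.  Missing genotypes are imputed to 2p (flagged via the
    returned object's float dtype).  Markers are sorted by (chromosome
    order, position).
    """
    qc = qc or QCConfig()
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        gd = _read_vcf(path, qc)
    elif fmt == "tsv":
        gd = _read_tsv(path, qc)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return gd.sort_markers(chrom_order)


def _read_vcf(path, qc: QCConfig) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples)
    cols, ids, chroms, poss = [], [], [], []
    n_dropped_nonbiallelic = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_dropped_nonbiallelic += 1
            continue
        if v.QUAL is None or v.QUAL <= qc.qual_min:
            continue
        g = np.asarray(v.gt_types, dtype=float)  # 0/1/2 alt count, 3 missing
        miss = g == 3
        callrate = 1.0 - miss.mean()
        if callrate < qc.callrate_min:
            continue
        g[miss] = np.nan
        freq = np.nanmean(g) / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < qc.maf_min or maf <= 0:
            continue
        g[np.isnan(g)] = 2.0 * freq  # mean imputation on the allele-count scale
        cols.append(g)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
    if not cols:
        raise ValueError("all markers removed by QC (or file empty)")
    A = np.column_stack(cols)
    return GenotypeData(
        line_ids=samples,
        marker_ids=np.array(ids),
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        A=A,
    )


def _read_tsv(path, qc: QCConfig) -> GenotypeData:
    path = Path(path)
    mat = pd.read_csv(path, sep="\t", index_col=0)
    map_path = path.with_suffix(".map.tsv")
    if not map_path.exists():
        raise FileNotFoundError(f"marker map {map_path} not found")
    mmap = pd.read_csv(map_path, sep="\t").set_index("marker_id").loc[mat.columns]
    A = mat.to_numpy(dtype=float)
    keep = _qc_matrix(A, qc)
    return GenotypeData(
        line_ids=mat.index.to_numpy(),
        marker_ids=mat.columns.to_numpy()[keep],
        chrom=mmap["chrom"].to_numpy()[keep],
        pos=mmap["pos"].to_numpy(dtype=np.int64)[keep],
        A=A[:, keep],
    )


def write_genotypes_tsv(genotypes: GenotypeData, path) -> None:
    """Write the allele-count matrix and its .map.tsv sidecar."""
    path = Path(path)
    pd.DataFrame(
        genotypes.A, index=genotypes.line_ids, columns=genotypes.marker_ids
    ).to_csv(path, sep="\t")
    pd.DataFrame(
        {"marker_id": genotypes.marker_ids, "chrom": genotypes.chrom, "pos": genotypes.pos}
    ).to_csv(path.with_suffix(".map.tsv"), sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Tab-separated phenotypes with at least (line_id, value) columns."""
    df = pd.read_csv(path, sep="\t")
    if "value" not in df.columns or "line_id" not in df.columns:
        raise ValueError("phenotype table needs line_id and value columns")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, tab-separated (name, description, members...)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = [p for p in parts[2:] if p]
    return out


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """BED intervals (0-based, half-open) -> columns chrom/start/end/name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=[f"iv{i}" for i in range(len(df))])
    df.columns = ["chrom", "start", "end", "name"]
    return df


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """GFF3 gene spans (1-based, inclusive) -> columns chrom/start/end/name.

    The gene identifier is taken from the ID= (else Name=) attribute.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}-{f[4]}"
            rows.append({"chrom": f[0], "start": int(f[3]), "end": int(f[4]), "name": name})
    return pd.DataFrame(rows)


@dataclass
class FeatureCatalog:
    """Gene -> marker indices and set -> genes maps.

    Sets with fewer than ``min_genes_per_set`` member genes are dropped
    (mirroring the >= 10 directly-evidenced-genes rule for GO terms).
    """

    genes: dict[str, np.ndarray]
    sets: dict[str, list[str]] = field(default_factory=dict)
    n_markers: int = 0
    min_genes_per_set: int = 10

    def set_markers(self, name: str) -> np.ndarray:
        """Union of member-gene markers, without duplicates, sorted."""
        gs = self.sets[name]
        idx = np.unique(np.concatenate([self.genes[g] for g in gs if g in self.genes]))
        return idx.astype(np.int64)

    @property
    def genic_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_markers, dtype=bool)
        for idx in self.genes.values():
            mask[idx] = True
        return mask


def map_markers_to_features(
    genotypes: GenotypeData,
    gene_intervals: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    *,
    coords: str = "gff3",
    min_genes_per_set: int = 10,
) -> FeatureCatalog:
    """Map markers into gene intervals and genes into sets.

    ``coords='gff3'`` treats start/end as 1-based inclusive; ``'bed'`` as
    0-based half-open (a marker at position == end is excluded).  A
    chromosome present in the annotation but absent from the genotype map is
    a hard error listing the offenders.
    """
    geno_chroms = set(map(str, np.unique(genotypes.chrom)))
    ann_chroms = set(map(str, gene_intervals["chrom"].unique()))
    missing = sorted(ann_chroms - geno_chroms)
    if missing:
        raise ValueError(
            "annotation chromosomes absent from genotype map: " + ", ".join(missing)
        )
    if coords == "gff3":
        lo = gene_intervals["start"].to_numpy()
        hi = gene_intervals["end"].to_numpy()
    elif coords == "bed":
        lo = gene_intervals["start"].to_numpy() + 1
        hi = gene_intervals["end"].to_numpy()
    else:
        raise ValueError("coords must be 'gff3' or 'bed'")

    trees: dict[str, IntervalTree] = {}
    for i, (c, name) in enumerate(zip(gene_intervals["chrom"], gene_intervals["name"])):
        if hi[i] < lo[i]:
            continue
        trees.setdefault(str(c), IntervalTree()).addi(int(lo[i]), int(hi[i]) + 1, name)

    genes: dict[str, list[int]] = {}
    for j, (c, p) in enumerate(zip(genotypes.chrom, genotypes.pos)):
        t = trees.get(str(c))
        if t is None:
            continue
        for iv in t.at(int(p)):
            genes.setdefault(iv.data, []).append(j)
    gene_idx = {g: np.array(sorted(v), dtype=np.int64) for g, v in genes.items()}

    sets = {}
    if gene_sets:
        for name, members in gene_sets.items():
            present = [g for g in members if g in gene_idx]
            if len(present) >= min_genes_per_set:
                sets[name] = present
    return FeatureCatalog(
        genes=gene_idx, sets=sets, n_markers=genotypes.n_markers,
        min_genes_per_set=min_genes_per_set,
    )
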