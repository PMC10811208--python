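"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (GT + optional DP per genotype, MQ as per-site quality), BED6 for
gene intervals, tab-separated tables with a header row, and Newick trees.
Readers reject malformed input explicitly rather than coercing it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import Phylo

from .datamodel import (
    MISSING,
    GeneAnnotation,
    GenotypeMatrix,
    PopulationMap,
    bed_to_pos,
)

_BASES = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF 4.x with biallelic SNP records into a :class:`GenotypeMatrix`.

    Genotype codes come from GT regardless of the phasing separator;
    ``./.`` maps to missing. Per-genotype DP and the per-site MQ INFO field
    are captured when present. Multiallelic or non-SNP records and duplicate
    positions raise errors naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    any_dp = False
    seen: set[tuple[str, int]] = set()
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ValueError(
                f"record {i} ({var.CHROM}:{var.POS}): not biallelic (ALT={var.ALT})"
            )
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(
                f"record {i} ({var.CHROM}:{var.POS}): non-SNP alleles {ref}>{alt}"
            )
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ValueError(f"record {i}: duplicate position {var.CHROM}:{var.POS}")
        seen.add(key)
        # gts012=True: 0/1/2 = alt dosage, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gt_rows.append(g)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_dp = True
            dp = np.asarray(dp, dtype=np.int64).reshape(-1)
            dp[dp < 0] = 0
        else:
            dp = np.zeros(len(samples), dtype=np.int64)
        dp_rows.append(dp)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        mq = var.INFO.get("MQ")
        quals.append(float(mq) if mq is not None else np.nan)
    lengths = {
        name: int(length)
        for name, length in zip(vcf.seqnames, vcf.seqlens or [])
    } if vcf.seqlens else None
    vcf.close()

    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "site_quality": quals}
    )
    n, m = len(samples), len(loci)
    G = (
        np.stack(gt_rows, axis=1)
        if m
        else np.zeros((n, 0), dtype=np.int8)
    )
    D = np.stack(dp_rows, axis=1) if (m and any_dp) else None
    return GenotypeMatrix(samples, loci, G, D=D, chrom_lengths=lengths)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 carrying GT (+DP when available) and MQ."""
    loci = gm.loci
    has_dp = gm.D is not None
    has_mq = "site_quality" in loci.columns and loci["site_quality"].notna().any()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if gm.chrom_lengths:
            for chrom, length in gm.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in pd.unique(loci["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        if has_mq:
            fh.write(
                '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:DP" if has_dp else "GT"
        for j in range(gm.n_loci):
            row = loci.iloc[j]
            if has_mq and np.isfinite(row.get("site_quality", np.nan)):
                info = f"MQ={row['site_quality']:g}"
            else:
                info = "."
            fields = [
                str(row["chrom"]), str(row["pos"]), ".", row["ref"], row["alt"],
                ".", "PASS", info, fmt,
            ]
            col = gm.G[:, j]
            if has_dp:
                dcol = gm.D[:, j]
                fields += [f"{gt_str[int(g)]}:{int(d)}" for g, d in zip(col, dcol)]
            else:
                fields += [gt_str[int(g)] for g in col]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED / gene annotation
# ---------------------------------------------------------------------------

def read_bed(path) -> GeneAnnotation:
    """Read BED3/BED6 gene intervals (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if df[["start", "end"]].isna().any().any():
        raise ValueError(f"{path}: malformed BED (missing coordinates)")
    if df["name"].isna().all():
        df["name"] = [f"gene{i}" for i in range(len(df))]
    df["strand"] = df["strand"].fillna("+")
    return GeneAnnotation(df[["chrom", "start", "end", "name", "strand"]])


def write_bed(ann: GeneAnnotation, path) -> None:
    df = ann.table.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]]
    df.to_csv(path, sep="\t", header=False, index=False)


def classify_locus_location(
    loci: pd.DataFrame, annotation: GeneAnnotation, flank: int = 5000
) -> pd.DataFrame:
    """Assign each locus a location class relative to gene intervals.

    Priority: genic > upstream5kb > downstream5kb > intergenic. Upstream and
    downstream are 5'/3' relative to gene strand (plus strand assumed when
    absent). Loci positions are 1-based; annotation is 0-based half-open.
    """
    out = loci.copy()
    cls = np.full(len(loci), "intergenic", dtype=object)
    pos = loci["pos"].to_numpy()
    for chrom, genes in annotation.table.groupby("chrom", sort=False):
        on = (loci["chrom"] == chrom).to_numpy()
        if not on.any():
            continue
        p = pos[on]
        hit = np.zeros(p.shape, dtype=np.int8)  # 0 intergenic 1 down 2 up 3 genic
        for _, g in genes.iterrows():
            g1, g2 = bed_to_pos(int(g["start"])), int(g["end"])  # 1-based inclusive
            minus = g["strand"] == "-"
            if minus:
                up = (p > g2) & (p <= g2 + flank)
                down = (p >= g1 - flank) & (p < g1)
            else:
                up = (p >= g1 - flank) & (p < g1)
                down = (p > g2) & (p <= g2 + flank)
            genic = (p >= g1) & (p <= g2)
            hit = np.maximum(hit, genic * 3)
            hit = np.maximum(hit, up * 2)
            hit = np.maximum(hit, down * 1)
        cls[on] = np.array(["intergenic", "downstream5kb", "upstream5kb", "genic"])[hit]
    out["location_class"] = cls
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_population_map(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        # headerless two/three-column file
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df.columns = ["sample", "population", "subgroup"][: df.shape[1]]
    return PopulationMap(df)


def write_population_map(popmap: PopulationMap, path) -> None:
    popmap.table.to_csv(path, sep="\t", index=False)


def write_window_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(sample_ids, loci: pd.DataFrame, dosage: np.ndarray, path) -> None:
    """Long-format truth table: sample, chrom, pos, ancestry-1 dosage."""
    n, m = dosage.shape
    df = pd.DataFrame(
        {
            "sample": np.repeat(sample_ids, m),
            "chrom": np.tile(loci["chrom"].to_numpy(), n),
            "pos": np.tile(loci["pos"].to_numpy(), n),
            "dosage": dosage.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path) -> None:
    import io as _io

    buf = _io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%g")
    text = buf.getvalue()
    # Bio.Phylo emits a spurious ":0" root branch; drop it for a clean
    # round trip
    text = text.replace("):0;", ");")
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path):
    return Phylo.read(str(path), "newick")


__all__ = [
    "read_vcf", "write_vcf", "read_bed", "write_bed", "classify_locus_location",
    "read_population_map", "write_population_map", "write_window_table",
    "read_window_table", "write_truth_tsv", "write_newick", "read_newick",
]
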