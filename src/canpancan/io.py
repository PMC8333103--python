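"""File-format I/O for the pipeline's stage contracts.

Stages exchange plain-text files: per-sample germline VCF (v4.2 with GT, AD,
DP FORMAT fields), somatic candidate TSV, GTF/BED annotation, SEG-style
log-ratio TSV and truth-table TSVs. Internal coordinates are 0-based
half-open; GTF is emitted 1-based inclusive and BED 0-based half-open.
"""

from __future__ import annotations

import os

import pandas as pd

__all__ = [
    "write_germline_vcf",
    "read_germline_vcf",
    "write_gtf",
    "write_bed",
    "read_gtf",
    "write_seg",
    "write_tsv",
    "read_tsv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_germline_vcf(calls: pd.DataFrame, sample_id: str, path: str) -> None:
    """Write one sample's germline calls (internal 0-based pos -> VCF 1-based)."""
    df = calls[calls["sample_id"] == sample_id].sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample_id))
        for r in df.itertuples(index=False):
            ref_d = int(r.depth) - int(r.alt_depth)
            gt = "1/1" if r.alt_depth / r.depth > 0.8 else "0/1"
            fh.write(f"{r.chrom}\t{int(r.pos) + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                     f"GT:AD:DP\t{gt}:{ref_d},{int(r.alt_depth)}:{int(r.depth)}\n")


def read_germline_vcf(path: str) -> pd.DataFrame:
    """Read a single-sample VCF written by :func:`write_germline_vcf`."""
    rows = []
    sample = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample = line.rstrip("\n").split("\t")[9]
                continue
            f = line.rstrip("\n").split("\t")
            fmt = dict(zip(f[8].split(":"), f[9].split(":")))
            ad = fmt["AD"].split(",")
            rows.append((sample, f[0], int(f[1]) - 1, f[3], f[4],
                         int(fmt["DP"]), int(ad[1])))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                                     "depth", "alt_depth"])
    df["vaf"] = df["alt_depth"] / df["depth"]
    return df


def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            name_attr = f' gene_name "{g.gene_name}";' if g.gene_name else ""
            attrs = f'gene_id "{g.gene_id}";{name_attr}'
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}"
                     f"\t.\t{attrs}\n")
            for e in exons[exons["gene_id"] == g.gene_id].itertuples(index=False):
                fh.write(f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                         f"{g.strand}\t.\t{attrs} exon_number {e.exon_number};\n")


def read_gtf(path: str) -> tuple:
    """Read gene/exon tables back from a GTF (restricted to the emitted attrs)."""
    gene_rows, exon_rows = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            for part in f[8].strip().split(";"):
                part = part.strip()
                if not part:
                    continue
                k, _, v = part.partition(" ")
                attrs[k] = v.strip().strip('"')
            start0, end = int(f[3]) - 1, int(f[4])
            if f[2] == "gene":
                gene_rows.append((attrs["gene_id"], attrs.get("gene_name", ""),
                                  f[0], f[6], start0, end))
            elif f[2] == "exon":
                exon_rows.append((attrs["gene_id"],
                                  int(attrs.get("exon_number", 0)), f[0], start0, end))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "gene_name", "chrom",
                                             "strand", "start", "end"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "exon_number", "chrom",
                                             "start", "end"])
    return genes, exons


def write_bed(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def write_seg(segments: pd.DataFrame, path: str, sample_col: str = "case_id") -> None:
    cols = [sample_col, "chrom", "start", "end", "n_bins", "mean"]
    out = segments[[c for c in cols if c in segments.columns]]
    out.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
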