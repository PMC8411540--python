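"""Readers and writers for every external format used by the pipeline.

Formats: aligned multi-FASTA, VCF 4.2 (haploid GT), Roary-style Rtab,
metadata/abundance/annotation TSV, BED masks, Newick trees, YAML run
configuration and JSON truth/result records.

Coordinate conventions: everything in memory is 1-based inclusive; BED's
0-based half-open convention is applied only at the writer/reader boundary.
Every writer round-trips through its reader without loss.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from skbio.tree import TreeNode

from .coresnp import AlignedGenomeSet, DistanceMatrix, SnpMatrix, encode_bases
from .errors import FormatError

log = logging.getLogger("strainpop")

METADATA_COLUMNS = [
    "strain_id", "sample_id", "country", "province", "city",
    "community_id", "family_id", "host_species", "age", "sex",
    "longevous_district",
]

#: COG functional category alphabet used for enrichment (20 categories).
COG_ALPHABET = "CDEFGHIJKLMNOPQRTUVZ"


# ---------------------------------------------------------------------------
# FASTA

def read_aligned_fasta(path: str | Path, reference_id: str | None = None) -> AlignedGenomeSet:
    """Read an equal-length multi-FASTA of reference-coordinate genomes.

    The reference record is ``reference_id`` if given, else the first record.
    Lowercase bases are uppercased; records of unequal length raise a
    :class:`FormatError` naming the offending record.
    """
    ids, rows = [], []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        codes = encode_bases(str(rec.seq))
        if length is None:
            length = codes.size
        elif codes.size != length:
            raise FormatError(
                f"record {rec.id!r} has length {codes.size}, expected {length}")
        ids.append(rec.id)
        rows.append(codes)
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    ref = reference_id if reference_id is not None else ids[0]
    return AlignedGenomeSet(ids, ref, np.vstack(rows))


def write_aligned_fasta(genomes: AlignedGenomeSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genomes.ids:
            seq = genomes.sequence(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs

def read_rtab(path: str | Path) -> pd.DataFrame:
    """Read a gene presence/absence matrix (genes x strains, cells 0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in Rtab")
    arr = df.to_numpy()
    bad = ~np.isin(arr, [0, 1])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary Rtab cell at gene {df.index[r]!r}, strain {df.columns[c]!r}")
    return df.astype(bool)


def write_rtab(presence: pd.DataFrame, path: str | Path) -> None:
    out = presence.astype(int)
    out.index.name = "Gene"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the strain metadata TSV; missing cells stay missing, never imputed."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True,
                     na_values=["NA", ""])
    missing = [c for c in ("strain_id",) if c not in df.columns]
    if missing:
        raise FormatError(f"metadata lacks required column(s) {missing}")
    if df["strain_id"].duplicated().any():
        dup = df.loc[df["strain_id"].duplicated(), "strain_id"].iloc[0]
        raise FormatError(f"duplicate strain_id {dup!r} in metadata")
    df = df.set_index("strain_id", drop=False)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="raise")
        if (df["age"].dropna() < 0).any():
            raise FormatError("negative age in metadata")
    if "longevous_district" in df.columns:
        df["longevous_district"] = df["longevous_district"].map(
            {"True": True, "False": False, "1": True, "0": False})
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a sample x taxon abundance table (counts or proportions)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError("negative abundance values")
    return df


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene annotations: gene_id, cog, kegg, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cog": str, "kegg": str})
    if "gene_id" not in df.columns:
        raise FormatError("annotation table lacks gene_id column")
    bad = df["cog"].dropna().map(lambda s: any(ch not in COG_ALPHABET for ch in s))
    if bad.any():
        raise FormatError(
            f"COG letter outside the {len(COG_ALPHABET)}-category alphabet: "
            f"{df['cog'].dropna()[bad].iloc[0]!r}")
    return df.set_index("gene_id", drop=False)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(snps: SnpMatrix, path: str | Path) -> None:
    """Write bi-allelic haploid calls as VCF v4.2 (GT only)."""
    from .coresnp import decode_bases

    refs = decode_bases(snps.ref_alleles)
    alts = decode_bases(snps.alt_alleles)
    gt_str = np.array([".", "0", "1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={snps.reference_id},length={snps.genome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(snps.strain_ids) + "\n")
        codes = snps.alleles + 1  # -1/0/1 -> 0/1/2
        for j in range(snps.n_sites):
            cols = gt_str[codes[:, j]]
            fh.write(f"{snps.reference_id}\t{snps.positions[j]}\t.\t{refs[j]}\t"
                     f"{alts[j]}\t.\t.\t.\tGT\t" + "\t".join(cols) + "\n")


def read_vcf(path: str | Path) -> SnpMatrix:
    """Read a haploid bi-allelic VCF back into a :class:`SnpMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    chrom = None
    length = 0
    pos, refs, alts, rows = [], [], [], []
    for var in vcf:
        chrom = var.CHROM
        pos.append(var.POS)
        refs.append(encode_bases(var.REF)[0])
        alts.append(encode_bases(var.ALT[0])[0])
        calls = np.array([g[0] for g in var.genotypes], dtype=np.int8)
        rows.append(calls)
    seqlens = dict(zip(vcf.seqnames, vcf.seqlens or []))
    length = int(seqlens.get(chrom, 0))
    alleles = (np.vstack(rows).T if rows
               else np.zeros((len(strains), 0), dtype=np.int8))
    alleles[alleles < 0] = -1
    return SnpMatrix(
        strains, chrom or "reference",
        np.asarray(pos, dtype=np.int64),
        np.asarray(refs, dtype=np.int8),
        np.asarray(alts, dtype=np.int8),
        alleles.astype(np.int8),
        genome_length=length,
    )


# ---------------------------------------------------------------------------
# Trees, BED, distances

def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    """Write intervals given 1-based inclusive as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start1, end1 in intervals:
            fh.write(f"{chrom}\t{start1 - 1}\t{end1}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED and return 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.append((chrom, int(s) + 1, int(e)))
    return out


def write_distances(d: DistanceMatrix, path: str | Path) -> None:
    d.to_dataframe().to_csv(path, sep="\t", index_label="strain_id")


def read_distances(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy())


# ---------------------------------------------------------------------------
# Config / JSON

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("YAML config must be a mapping")
    return cfg


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
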