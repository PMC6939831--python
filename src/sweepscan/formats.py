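"""Readers and writers for the on-disk formats the pipeline touches.

VCF (a biallelic-SNP GT-only subset), FASTA, GFF3/BED6 annotation, Newick
trees and BED interval export.  Internal coordinates are always 1-based
inclusive; the 0-based half-open BED convention is converted here and
nowhere else.

Only biallelic single-nucleotide records are ingested from VCF; indels,
multiallelic records and records without a GT field are counted and
skipped so that downstream estimators stay well defined.  Half-calls
(``./1``) are treated as missing because the dosage would be ambiguous.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    MISSING,
    FormatError,
    Gene,
    GeneAnnotation,
    GenotypeDataset,
    IngestReport,
    PhyloTree,
    SampleGrouping,
    ValidationError,
)

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> GenotypeDataset:
    """Read a VCF v4.x file into a :class:`GenotypeDataset`.

    Only data lines with a single-base REF, a single-base ALT and a GT
    entry in FORMAT are ingested; all other lines are skipped and counted
    in the returned dataset's ``ingest_report``.  GT mapping:
    ``0/0 -> 0``, ``0/1``/``1/0 -> 1``, ``1/1 -> 2``, ``./.``/``.`` and
    half-calls -> MISSING.  ``|`` is treated as ``/``.
    """
    path = Path(path)
    sample_ids: list[str] | None = None
    report = IngestReport()
    chroms, poss, refs, alts, rows = [], [], [], [], []
    seen_fileformat = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##fileformat=VCF"):
                    seen_fileformat = True
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise FormatError(f"{path}: header line has no samples")
                if fields[:9] != ["#CHROM", "POS", "ID", "REF", "ALT",
                                  "QUAL", "FILTER", "INFO", "FORMAT"]:
                    raise FormatError(f"{path}: malformed #CHROM header line")
                sample_ids = fields[9:]
                continue
            if sample_ids is None:
                raise FormatError(f"{path}: data line before #CHROM header (line {lineno})")
            report.n_data_lines += 1
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                raise FormatError(f"{path}: wrong column count on line {lineno}")
            chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            if (len(ref) != 1 or len(alt) != 1
                    or ref.upper() not in _BASES or alt.upper() not in _BASES
                    or "GT" not in fmt):
                report.n_skipped += 1
                continue
            gt_idx = fmt.index("GT")
            row = np.empty(len(sample_ids), dtype=np.int8)
            for i, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                row[i] = _parse_gt(gt, path, lineno)
            chroms.append(chrom)
            poss.append(int(pos_s))
            refs.append(ref.upper())
            alts.append(alt.upper())
            rows.append(row)
            report.n_ingested += 1
    if not seen_fileformat:
        raise FormatError(f"{path}: missing ##fileformat header")
    if sample_ids is None:
        raise FormatError(f"{path}: no #CHROM header line")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if len(sites):
        dup = sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = sites[dup].iloc[0]
            raise ValidationError(
                f"{path}: duplicate site {first['chrom']}:{first['pos']}")
    dosages = (np.vstack(rows).T if rows
               else np.empty((len(sample_ids), 0), dtype=np.int8))
    if report.n_skipped:
        log.info("read_vcf(%s): skipped %d of %d data lines",
                 path.name, report.n_skipped, report.n_data_lines)
    ds = GenotypeDataset(sample_ids=sample_ids, sites=sites, dosages=dosages)
    ds.ingest_report = report
    return ds


def _parse_gt(gt: str, path: Path, lineno: int) -> int:
    if gt in (".", "./."):
        return MISSING
    alleles = gt.split("/")
    if len(alleles) != 2:
        raise ValidationError(f"{path}: non-diploid GT {gt!r} on line {lineno}")
    if "." in alleles:
        return MISSING  # half-call: dosage ambiguous
    if not set(alleles) <= {"0", "1"}:
        raise ValidationError(f"{path}: non-biallelic GT {gt!r} on line {lineno}")
    return int(alleles[0]) + int(alleles[1])


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset as minimal VCF v4.2 (GT only)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        for j in range(ds.n_sites):
            site = ds.sites.iloc[j]
            gts = "\t".join(_GT_STR[int(d)] for d in ds.dosages[:, j])
            fh.write(f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t"
                     f"{site['alt']}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{chrom: uppercase sequence}`` map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED6)

def read_annotation(path: str | Path, fmt: str) -> GeneAnnotation:
    """Read gene annotation from GFF3 (gene + CDS features) or BED6.

    BED genes carry no CDS.  Minus-strand CDS lists are ordered 5'->3',
    i.e. by descending genomic coordinate.
    """
    if fmt == "bed":
        return _read_bed_genes(path)
    if fmt == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_bed_genes(path: str | Path) -> GeneAnnotation:
    genes = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}: BED6 line with {len(f)} fields")
            chrom, start0, end0, name, _score, strand = f[:6]
            genes.append(Gene(gene_id=name, chrom=chrom,
                              start=int(start0) + 1, end=int(end0),
                              strand=strand))
    return GeneAnnotation(genes=genes)


_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _read_gff3(path: str | Path) -> GeneAnnotation:
    raw_genes: dict[str, dict] = {}
    cds_rows: list[tuple[str, int, int, str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}: GFF3 line with {len(f)} fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            attr = dict(_ATTR_RE.findall(attrs))
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise FormatError(f"{path}: gene feature without ID")
                raw_genes[gid] = dict(chrom=chrom, start=int(start),
                                      end=int(end), strand=strand)
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}: CDS feature without Parent")
                cds_rows.append((parent, int(start), int(end), strand, chrom))
    cds_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in raw_genes}
    for parent, start, end, strand, chrom in cds_rows:
        # CDS may point at a transcript in full GFF3; here Parent must be a gene
        if parent not in raw_genes:
            raise ValidationError(f"{path}: CDS Parent {parent!r} matches no gene")
        g = raw_genes[parent]
        if not (g["start"] <= start and end <= g["end"] and chrom == g["chrom"]):
            raise ValidationError(f"{path}: CDS ({start},{end}) outside gene {parent}")
        cds_by_gene[parent].append((start, end))
    genes = []
    for gid, g in raw_genes.items():
        cds = sorted(cds_by_gene[gid], reverse=(g["strand"] == "-"))
        genes.append(Gene(gene_id=gid, chrom=g["chrom"], start=g["start"],
                          end=g["end"], strand=g["strand"], cds=tuple(cds)))
    return GeneAnnotation(genes=genes)


def write_gff3(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            fh.write(f"{g.chrom}\tsweepscan\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for s, e in sorted(g.cds):
                fh.write(f"{g.chrom}\tsweepscan\tCDS\t{s}\t{e}\t.\t"
                         f"{g.strand}\t0\tParent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# BED interval export

def write_bed(regions: list[tuple], path: str | Path) -> None:
    """Write 1-based inclusive intervals as sorted BED (0-based half-open).

    Each region is ``(chrom, start, end)`` or ``(chrom, start, end, name)``.
    Overlapping intervals on one chromosome produce a warning, not an error.
    """
    rows = sorted(regions, key=lambda r: (r[0], r[1], r[2]))
    prev: tuple | None = None
    for r in rows:
        if prev is not None and r[0] == prev[0] and r[1] <= prev[2]:
            log.warning("write_bed: overlapping intervals %s and %s", prev, r)
        prev = r
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# BED intervals (0-based half-open)\n")
        for r in rows:
            name = f"\t{r[3]}" if len(r) > 3 else ""
            fh.write(f"{r[0]}\t{r[1] - 1}\t{r[2]}{name}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read plain BED intervals back to 1-based inclusive tuples."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


# ---------------------------------------------------------------------------
# Newick

_PLAIN_LABEL_RE = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote_label(label: str) -> str:
    if _PLAIN_LABEL_RE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize an unrooted tree to Newick.

    Branch lengths are printed with 6 decimal places; labels containing
    whitespace or punctuation are single-quoted.  Output is deterministic:
    the tree is rooted for serialization at the internal node adjacent to
    the lexicographically smallest leaf label, and children are ordered by
    the smallest leaf label in their subtree.
    """
    leaves = tree.leaves()
    if not leaves:
        raise ValidationError("cannot serialize an empty tree")
    if len(leaves) == 1:
        only = leaves[0]
        text = f"{_quote_label(tree.leaf_labels[only])};"
    else:
        start_leaf = min(leaves, key=lambda v: tree.leaf_labels[v])
        if len(tree.nodes) == 2:  # two leaves joined by one edge
            other = next(iter(tree.neighbors(start_leaf)))
            ln = tree.neighbors(start_leaf)[other]
            a, b = sorted([start_leaf, other], key=lambda v: tree.leaf_labels[v])
            text = (f"({_quote_label(tree.leaf_labels[a])}:{ln:.6f},"
                    f"{_quote_label(tree.leaf_labels[b])}:0.000000);")
        else:
            root = next(iter(tree.neighbors(start_leaf)))

            def min_leaf(node: int, parent: int) -> str:
                if tree.is_leaf(node):
                    return tree.leaf_labels[node]
                return min(min_leaf(c, node)
                           for c in tree.neighbors(node) if c != parent)

            def render(node: int, parent: int) -> str:
                if tree.is_leaf(node):
                    return _quote_label(tree.leaf_labels[node])
                children = sorted(
                    (c for c in tree.neighbors(node) if c != parent),
                    key=lambda c: min_leaf(c, node))
                parts = [f"{render(c, node)}:{tree.neighbors(node)[c]:.6f}"
                         for c in children]
                return "(" + ",".join(parts) + ")"

            text = render(root, -1) + ";"
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# TSV helpers

def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a DataFrame as UTF-8 TSV with header; NaN serialized as NA."""
    with open(path, "wt", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def read_grouping(path: str | Path) -> SampleGrouping:
    """Read a two-column (sample_id, group) TSV."""
    df = read_tsv(path)
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError(f"{path}: grouping TSV needs sample_id and group columns")
    return SampleGrouping(assignment=dict(zip(df["sample_id"], df["group"])))


def write_grouping(grouping: SampleGrouping, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(grouping.assignment),
         "group": [grouping.assignment[s] for s in grouping.assignment]})
    write_tsv(df, path)
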