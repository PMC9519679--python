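"""Plain-text interchange: SV VCF 4.2, BED, GFF3 and TSV tables.

SV records are written with INFO ``SVTYPE``/``END``/``SVLEN``; translocations
become paired BND records linked by ``MATEID``.  Coordinates are converted
between the package's 0-based half-open convention and VCF's 1-based
inclusive one at this boundary only.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import Gene, GenomeAnnotation, SVCluster, SVRecord

__all__ = ["write_sv_vcf", "read_sv_vcf", "write_cluster_vcf", "write_bed",
           "read_bed", "write_gff3", "read_gff3", "write_presence_tsv"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svharvest
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Length of the variant">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome of the second breakpoint">
##INFO=<ID=END2,Number=1,Type=Integer,Description="Position of the second breakpoint">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Origin caller">
##INFO=<ID=TAG,Number=1,Type=String,Description="Caller annotation tag">
##FILTER=<ID=LowQual,Description="Failed the caller built-in filter">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _contig_lines(chrom_lengths: Mapping[str, int]) -> str:
    return "".join(f"##contig=<ID={c},length={l}>\n"
                   for c, l in chrom_lengths.items())


def write_sv_vcf(
    records: Iterable[SVRecord],
    path: str | os.PathLike,
    sample: str = "SAMPLE",
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Single-sample SV VCF; TRA records become BND mate pairs."""
    lines = [_VCF_HEADER]
    if chrom_lengths:
        lines.append(_contig_lines(chrom_lengths))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
    for i, r in enumerate(sorted(records, key=lambda x: (x.chrom, x.start)),
                          start=1):
        rid = r.id or f"sv{i:06d}"
        filt = "PASS" if r.filter_pass else "LowQual"
        if r.sv_type == "TRA":
            assert r.mate is not None
            m_chrom, m_pos = r.mate
            info1 = f"SVTYPE=BND;MATEID={rid}_2;CALLER={r.caller or '.'}"
            info2 = f"SVTYPE=BND;MATEID={rid}_1;CALLER={r.caller or '.'}"
            alt1 = f"N[{m_chrom}:{m_pos + 1}["
            alt2 = f"N]{r.chrom}:{r.start + 1}]"
            lines.append(f"{r.chrom}\t{r.start + 1}\t{rid}_1\tN\t{alt1}\t.\t"
                         f"{filt}\t{info1}\tGT\t{r.genotype}\n")
            lines.append(f"{m_chrom}\t{m_pos + 1}\t{rid}_2\tN\t{alt2}\t.\t"
                         f"{filt}\t{info2}\tGT\t{r.genotype}\n")
            continue
        end = r.end if r.end > r.start else r.start + 1
        info = [f"SVTYPE={r.sv_type}", f"END={end}"]
        if r.length is not None:
            svlen = -r.length if r.sv_type == "DEL" else r.length
            info.append(f"SVLEN={svlen}")
        if r.caller:
            info.append(f"CALLER={r.caller}")
        if r.tag:
            info.append(f"TAG={r.tag}")
        lines.append(f"{r.chrom}\t{r.start + 1}\t{rid}\tN\t<{r.sv_type}>\t.\t"
                     f"{filt}\t{';'.join(info)}\tGT\t{r.genotype}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_sv_vcf(path: str | os.PathLike, sample: str = "") -> list[SVRecord]:
    """Read an SV VCF written by this package (or a compatible one)."""
    records: list[SVRecord] = []
    bnd_first: dict[str, tuple] = {}
    header_sample = sample
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if not sample and len(cols) > 9:
                    header_sample = cols[9]
                continue
            cols = line.rstrip("\n").split("\t")
            chrom, pos, rid, _ref, alt, _qual, filt, info = cols[:8]
            gt = "1/1"
            if len(cols) > 9 and cols[8].startswith("GT"):
                gt = cols[9].split(":")[0]
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
                else:
                    kv[item] = "1"
            svtype = kv.get("SVTYPE", alt.strip("<>"))
            start = int(pos) - 1
            filter_pass = filt in ("PASS", ".")
            caller = kv.get("CALLER", "")
            tag = kv.get("TAG", "")
            if svtype == "BND":
                if rid.endswith("_2"):
                    continue  # second mate; handled via the first record
                # parse mate from ALT, e.g. N[chr2:123[
                body = alt.strip("N[]")
                m_chrom, m_pos = body.split(":")
                records.append(SVRecord(
                    chrom=chrom, start=start, end=start, sv_type="TRA",
                    length=None, sample=header_sample, caller=caller,
                    genotype=gt, filter_pass=filter_pass, tag=tag,
                    mate=(m_chrom, int(m_pos) - 1), id=rid[:-2]))
                continue
            end = int(kv.get("END", start + 1))
            length = None
            if "SVLEN" in kv:
                length = abs(int(kv["SVLEN"].split(",")[0]))
            mate = None
            if svtype == "TRA":
                # mate breakpoint carried as CHR2/END2 on a single row
                mate = (kv.get("CHR2", chrom), int(kv.get("END2", end)) - 1)
                end = start
            end_0 = start if svtype in ("INS", "TRA") else end
            records.append(SVRecord(
                chrom=chrom, start=start, end=end_0, sv_type=svtype,
                length=length, sample=header_sample, caller=caller,
                genotype=gt, filter_pass=filter_pass, tag=tag, id=rid,
                mate=mate))
    return records


def write_cluster_vcf(
    clusters: Sequence[SVCluster],
    sample_ids: Sequence[str],
    path: str | os.PathLike,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Multi-sample cluster VCF with presence/absence genotypes
    (1/1 carrier, 0/0 otherwise); requires genotyped clusters."""
    lines = [_VCF_HEADER]
    if chrom_lengths:
        lines.append(_contig_lines(chrom_lengths))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
    for cl in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        if cl.presence is None:
            raise ValueError(f"cluster {cl.id} is not genotyped")
        end = cl.end if cl.end > cl.start else cl.start + 1
        info = [f"SVTYPE={cl.sv_type}", f"END={end}"]
        if cl.sv_type == "TRA" and cl.mate is not None:
            info.append(f"CHR2={cl.mate[0]};END2={cl.mate[1] + 1}")
        if cl.length is not None:
            info.append(f"SVLEN={-cl.length if cl.sv_type == 'DEL' else cl.length}")
        gts = "\t".join("1/1" if p else "0/0" for p in cl.presence)
        lines.append(f"{cl.chrom}\t{cl.start + 1}\t{cl.id}\tN\t<{cl.sv_type}>"
                     f"\t.\tPASS\t{';'.join(info)}\tGT\t{gts}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def write_bed(intervals: Mapping[str, Sequence[tuple[int, int]]],
              path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    for v in out.values():
        v.sort()
    return out


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Genes and their exons as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tsvharvest\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(f"{g.chrom}\tsvharvest\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}\n")


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    """Gene models (gene + exon features) from a GFF3 file."""
    genes: dict[str, Gene] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            if ftype == "gene":
                gid = kv.get("ID", f"{chrom}:{start}-{end}")
                genes[gid] = Gene(gene_id=gid, chrom=chrom,
                                  start=int(start) - 1, end=int(end),
                                  strand=strand)
            elif ftype == "exon":
                parent = kv.get("Parent", "")
                exons.setdefault(parent, []).append((int(start) - 1, int(end)))
    for gid, g in genes.items():
        g.exons = sorted(exons.get(gid, [(g.start, g.end)]))
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start))


def write_presence_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)
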