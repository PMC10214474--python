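"""Readers and writers for the package's external formats.

Formats: transcript FASTA, gene models as BED6+ (one row per region with
the region tag in column 4), alignments as SAM (one reference per
transcript) or an equivalent tab-delimited table, and the ground-truth
TSV emitted by the simulator.  All tables are plain TSV with headers.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError
from .model import READ_COLUMNS, GeneModel

_REGIONS = ("utr5", "cds", "utr3")


def write_fasta(genes: Sequence[GeneModel], path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
               for g in genes]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(genes: Sequence[GeneModel], path) -> None:
    """BED6: chrom(gene_id) start end name(region) score strand."""
    with open(path, "w") as fh:
        for g in genes:
            for region in _REGIONS:
                start, end = getattr(g, region)
                fh.write(f"{g.gene_id}\t{start}\t{end}\t{region}\t0\t+\n")


def read_bed(path, sequences: dict[str, str] | None = None) -> list[GeneModel]:
    """Reconstruct gene models from the BED written by :func:`write_bed`.

    If ``sequences`` (e.g. from :func:`read_fasta`) is given, sequences
    are attached and validated.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "start", "end", "region", "score", "strand"])
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        regions = {r.region: (int(r.start), int(r.end))
                   for r in grp.itertuples(index=False)}
        missing = [r for r in _REGIONS if r not in regions]
        if missing:
            raise ConfigurationError(f"{gene_id}: BED missing regions {missing}")
        seq = (sequences or {}).get(str(gene_id), "")
        g = GeneModel(gene_id=str(gene_id), sequence=seq,
                      utr5=regions["utr5"], cds=regions["cds"],
                      utr3=regions["utr3"])
        g.validate(check_sequence=bool(seq))
        genes.append(g)
    return genes


def write_read_table(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False, columns=READ_COLUMNS)


def read_read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_id": str, "library": str, "sample": str})
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"alignment table missing columns: {missing}")
    return df[READ_COLUMNS]


def write_sam(reads: pd.DataFrame, genes: Sequence[GeneModel], path) -> None:
    """Write reads as a text SAM with one reference per transcript.

    Library and sample labels are carried in the ``XL``/``XS`` tags so the
    SAM round-trips to the tabular representation.
    """
    seqs = {g.gene_id: g.sequence for g in genes}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g.gene_id, "LN": g.length} for g in genes],
    }
    ref_id = {g.gene_id: i for i, g in enumerate(genes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"r{i + 1:08d}"
            a.reference_id = ref_id[row.gene_id]
            a.reference_start = int(row.start)
            a.mapping_quality = 255
            a.cigarstring = f"{int(row.length)}M"
            seq = seqs.get(row.gene_id, "")
            if seq:
                a.query_sequence = seq[int(row.start):int(row.start) + int(row.length)]
            a.set_tag("XL", str(row.library))
            a.set_tag("XS", str(row.sample))
            sam.write(a)


def read_sam(path) -> pd.DataFrame:
    rows = {c: [] for c in READ_COLUMNS}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam.fetch(until_eof=True):
            if a.is_unmapped:
                continue
            rows["gene_id"].append(a.reference_name)
            rows["start"].append(a.reference_start)
            rows["length"].append(a.query_alignment_length or a.infer_query_length())
            rows["library"].append(a.get_tag("XL") if a.has_tag("XL") else "")
            rows["sample"].append(a.get_tag("XS") if a.has_tag("XS") else "")
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
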