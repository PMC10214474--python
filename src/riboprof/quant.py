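"""Read counting, RPKM, and translational efficiency.

Counting rules: footprints are counted when their P-site (5' end +
offset) lies within the CDS (``cds_psite`` mode); total-mRNA fragments
are counted on any overlap with the transcript (``transcript_overlap``
mode).  RPKM uses CDS length as effective length for footprints and full
transcript length for mRNA by default; both are switchable.

TE = RPKM(footprints) / RPKM(mRNA) per gene, the printed formula, with an
expression filter (``min_mrna_rpkm``) instead of smoothing so retained
genes follow the formula exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LibraryMismatchError
from .model import FOOTPRINT, MRNA, GeneModel, reads_to_table
from .qc import DEFAULT_PSITE_OFFSET

COUNT_MODES = ("cds_psite", "transcript_overlap")


@dataclass
class CountMatrix:
    """Genes x samples integer counts for one library type."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray                 # shape (n_genes, n_samples), int
    effective_length: np.ndarray       # nt per gene
    library: str

    @property
    def library_size(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def validate(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ConfigurationError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise ConfigurationError("negative counts")
        if (self.effective_length <= 0).any():
            raise ConfigurationError("effective_length must be positive")

    def select_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise ConfigurationError(f"unknown samples: {missing}")
        cols = [self.samples.index(s) for s in samples]
        return CountMatrix(genes=self.genes, samples=list(samples),
                           counts=self.counts[:, cols],
                           effective_length=self.effective_length,
                           library=self.library)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.genes, columns=self.samples)
        df.insert(0, "effective_length", self.effective_length)
        df.index.name = "gene_id"
        return df.reset_index()


def count_reads(reads, genes: Sequence[GeneModel], mode: str,
                psite_offset: int = DEFAULT_PSITE_OFFSET,
                effective_length: str | None = None) -> CountMatrix:
    """Count reads per gene and sample under the given assignment rule.

    ``effective_length`` is ``"cds"`` or ``"transcript"``; default is
    ``"cds"`` for ``cds_psite`` mode and ``"transcript"`` otherwise.
    """
    if mode not in COUNT_MODES:
        raise ConfigurationError(f"unknown counting mode: {mode}")
    table = reads_to_table(reads)
    if len(table) == 0:
        raise ConfigurationError("empty read set")
    libs = set(table["library"].unique())
    if len(libs) > 1:
        raise LibraryMismatchError(f"mixed libraries in one count run: {sorted(libs)}")
    library = libs.pop()

    gene_ids = [g.gene_id for g in genes]
    unknown = sorted(set(table["gene_id"].unique()) - set(gene_ids))
    if unknown:
        raise ConfigurationError(f"reads reference unknown gene ids: {unknown}")

    if mode == "cds_psite":
        cds_start = table["gene_id"].map({g.gene_id: g.cds_start for g in genes})
        cds_end = table["gene_id"].map({g.gene_id: g.cds_end for g in genes})
        psite = table["start"] + psite_offset
        table = table[(psite >= cds_start) & (psite < cds_end)]

    samples = sorted(table["sample"].unique())
    pivot = (table.groupby(["gene_id", "sample"], observed=True)
             .size().unstack(fill_value=0)
             .reindex(index=gene_ids, columns=samples, fill_value=0))

    if effective_length is None:
        effective_length = "cds" if mode == "cds_psite" else "transcript"
    if effective_length == "cds":
        eff = np.array([g.cds_length for g in genes], dtype=float)
    elif effective_length == "transcript":
        eff = np.array([g.length for g in genes], dtype=float)
    else:
        raise ConfigurationError(f"unknown effective_length: {effective_length}")

    cm = CountMatrix(genes=gene_ids, samples=samples,
                     counts=pivot.to_numpy(dtype=np.int64),
                     effective_length=eff, library=str(library))
    cm.validate()
    return cm


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """RPKM = count * 1e9 / (effective_length * library_size), per sample."""
    lib = cm.library_size.astype(float)
    if (lib <= 0).any():
        bad = [s for s, n in zip(cm.samples, lib) if n <= 0]
        raise ConfigurationError(f"zero library size for samples: {bad}")
    values = cm.counts * 1e9 / (cm.effective_length[:, None] * lib[None, :])
    df = pd.DataFrame(values, index=cm.genes, columns=cm.samples)
    df.index.name = "gene_id"
    return df


@dataclass
class TETable:
    """Tidy per-gene, per-sample TE with the exclusion ledger.

    ``table`` columns: gene_id, sample, rpkm_fp, rpkm_mrna, te, log2_te.
    ``excluded`` columns: gene_id, reason.
    """

    table: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "reason"]))
    pseudocount: float = 0.0
    min_mrna_rpkm: float = 1.0

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def mean_log2_te(self) -> pd.Series:
        return self.table.groupby("gene_id", sort=True)["log2_te"].mean()

    def replicate_matrix(self) -> pd.DataFrame:
        """Genes x samples matrix of log2 TE."""
        return self.table.pivot(index="gene_id", columns="sample",
                                values="log2_te")


def translational_efficiency(rpkm_fp: pd.DataFrame, rpkm_mrna: pd.DataFrame,
                             pseudocount: float = 0.0,
                             min_mrna_rpkm: float = 1.0) -> TETable:
    """TE = (rpkm_fp + pc) / (rpkm_mrna + pc) per gene and sample.

    Samples are matched by label (columns shared between the two RPKM
    frames).  A gene is excluded — never returned with an unstable or
    undefined TE — if its mRNA RPKM is below ``min_mrna_rpkm`` (reason
    ``low_mrna``) or the denominator is zero (reason ``zero_mrna``) in
    any sample.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    samples = [s for s in rpkm_fp.columns if s in set(rpkm_mrna.columns)]
    if not samples:
        raise ConfigurationError("no shared samples between footprint and mRNA RPKM")
    shared_genes = rpkm_fp.index.intersection(rpkm_mrna.index)
    if len(shared_genes) == 0:
        raise ConfigurationError("no shared genes between footprint and mRNA RPKM")
    fp = rpkm_fp.loc[shared_genes, samples]
    mr = rpkm_mrna.loc[shared_genes, samples]

    zero = ((mr + pseudocount) <= 0).any(axis=1)
    low = (~zero) & (mr < min_mrna_rpkm).any(axis=1)
    zero_fp = (~zero) & (~low) & ((fp + pseudocount) <= 0).any(axis=1)
    excluded = pd.concat([
        pd.DataFrame({"gene_id": shared_genes[zero], "reason": "zero_mrna"}),
        pd.DataFrame({"gene_id": shared_genes[low], "reason": "low_mrna"}),
        pd.DataFrame({"gene_id": shared_genes[zero_fp], "reason": "zero_footprint"}),
    ], ignore_index=True)

    keep = ~(zero | low | zero_fp)
    fp, mr = fp[keep], mr[keep]
    te = (fp + pseudocount) / (mr + pseudocount)
    tidy = pd.DataFrame({
        "gene_id": np.repeat(te.index.to_numpy(), len(samples)),
        "sample": np.tile(np.array(samples, dtype=object), len(te)),
        "rpkm_fp": fp.to_numpy().ravel(),
        "rpkm_mrna": mr.to_numpy().ravel(),
        "te": te.to_numpy().ravel(),
    })
    tidy["log2_te"] = np.log2(tidy["te"])
    return TETable(table=tidy, excluded=excluded,
                   pseudocount=pseudocount, min_mrna_rpkm=min_mrna_rpkm)
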