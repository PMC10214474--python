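"""Core domain records: gene models and read alignments.

Coordinates are 0-based half-open on transcript space throughout the
package.  A transcript is tiled by three contiguous intervals:
5'UTR, CDS, 3'UTR.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError

FOOTPRINT = "footprint"
MRNA = "mrna"
LIBRARY_TYPES = (FOOTPRINT, MRNA)

#: column order of the tabular read representation used everywhere internally
READ_COLUMNS = ["gene_id", "start", "length", "library", "sample"]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned fragment on a transcript.

    ``start`` is the 0-based position of the fragment 5' end.
    """

    gene_id: str
    start: int
    length: int
    library: str
    sample: str


@dataclass
class GeneModel:
    """A transcript with 5'UTR / CDS / 3'UTR structure.

    Intervals are 0-based half-open and must tile ``[0, len(sequence))``.
    ``condition_class`` labels the simulation ground truth
    (``te_up`` / ``te_down`` / ``null``) and is ``null`` for real data.
    """

    gene_id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    condition_class: str = "null"
    planted_features: frozenset = field(default_factory=frozenset)
    te_log2_effect: float = 0.0

    @property
    def length(self) -> int:
        return self.utr3[1]

    @property
    def cds_start(self) -> int:
        return self.cds[0]

    @property
    def cds_end(self) -> int:
        return self.cds[1]

    @property
    def utr5_length(self) -> int:
        return self.utr5[1] - self.utr5[0]

    @property
    def cds_length(self) -> int:
        return self.cds[1] - self.cds[0]

    @property
    def utr3_length(self) -> int:
        return self.utr3[1] - self.utr3[0]

    @property
    def utr5_seq(self) -> str:
        return self.sequence[self.utr5[0]:self.utr5[1]]

    @property
    def cds_seq(self) -> str:
        return self.sequence[self.cds[0]:self.cds[1]]

    @property
    def utr3_seq(self) -> str:
        return self.sequence[self.utr3[0]:self.utr3[1]]

    def validate(self, check_sequence: bool = True) -> None:
        """Raise :class:`ConfigurationError` on any structural violation."""
        if self.utr5[0] != 0:
            raise ConfigurationError(f"{self.gene_id}: 5'UTR must start at 0")
        if self.utr5[1] != self.cds[0] or self.cds[1] != self.utr3[0]:
            raise ConfigurationError(
                f"{self.gene_id}: intervals must be contiguous (utr5|cds|utr3)")
        if self.cds_length < 6 or self.cds_length % 3 != 0:
            raise ConfigurationError(
                f"{self.gene_id}: CDS length {self.cds_length} invalid")
        if check_sequence and self.sequence:
            if len(self.sequence) != self.length:
                raise ConfigurationError(
                    f"{self.gene_id}: sequence/interval length mismatch")
            cds = self.cds_seq.upper().replace("U", "T")
            if not cds.startswith("ATG"):
                raise ConfigurationError(f"{self.gene_id}: CDS must start with ATG")
            if cds[-3:] not in STOP_CODONS:
                raise ConfigurationError(f"{self.gene_id}: CDS must end with a stop")
            internal = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
            if any(c in STOP_CODONS for c in internal):
                raise ConfigurationError(
                    f"{self.gene_id}: CDS has an in-frame internal stop")


def gene_index(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    return {g.gene_id: g for g in genes}


def reads_to_table(reads) -> pd.DataFrame:
    """Normalize reads to the canonical DataFrame representation.

    Accepts a DataFrame with :data:`READ_COLUMNS` or an iterable of
    :class:`ReadAlignment`.
    """
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns]
        if missing:
            raise ConfigurationError(f"read table missing columns: {missing}")
        return reads
    rows = list(reads)
    if not rows:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "start": [r.start for r in rows],
            "length": [r.length for r in rows],
            "library": [r.library for r in rows],
            "sample": [r.sample for r in rows],
        }
    )


def table_to_reads(table: pd.DataFrame) -> list[ReadAlignment]:
    return [
        ReadAlignment(str(r.gene_id), int(r.start), int(r.length),
                      str(r.library), str(r.sample))
        for r in table.itertuples(index=False)
    ]


def validate_reads(table: pd.DataFrame, genes: Sequence[GeneModel]) -> None:
    """Check that every read fits inside its transcript."""
    lengths = {g.gene_id: g.length for g in genes}
    unknown = set(table["gene_id"].unique()) - set(lengths)
    if unknown:
        raise ConfigurationError(f"reads reference unknown genes: {sorted(unknown)}")
    tx_len = table["gene_id"].map(lengths).to_numpy()
    start = table["start"].to_numpy()
    if (start < 0).any() or (start + table["length"].to_numpy() > tx_len).any():
        raise ConfigurationError("read outside transcript bounds")
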