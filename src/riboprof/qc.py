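"""Footprint library quality control.

Three criteria are evaluated: (1) the footprint length distribution is
concentrated in 28-32 nt, (2) P-sites over the CDS fall predominantly in
the protein-coding frame, and (3) the metagene profile around the CDS
start shows 3-nt periodicity (lag-3 autocorrelation dominates lags 1 and
2) with little signal upstream of the start codon.  The numeric cutoffs
are explicit parameters with documented defaults; published QC of this
kind is usually judged from plots alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LibraryMismatchError
from .model import FOOTPRINT, GeneModel, gene_index, reads_to_table

DEFAULT_PSITE_OFFSET = 12


def footprint_length_distribution(reads) -> dict[int, int]:
    """Exact footprint length histogram; empty input gives an empty map."""
    table = reads_to_table(reads)
    if len(table) == 0:
        return {}
    libs = set(table["library"].unique())
    if libs - {FOOTPRINT}:
        raise LibraryMismatchError(
            f"expected footprint reads only, got libraries {sorted(libs)}")
    counts = table["length"].value_counts().sort_index()
    return {int(k): int(v) for k, v in counts.items()}


def _psite_frames(table: pd.DataFrame, genes: Sequence[GeneModel],
                  psite_offset: int) -> np.ndarray:
    """Frame of each read whose P-site lies in its gene's CDS; others dropped."""
    idx = gene_index(genes)
    unknown = set(table["gene_id"].unique()) - set(idx)
    if unknown:
        raise ConfigurationError(f"reads map to unknown genes: {sorted(unknown)[:5]}")
    cds_start = table["gene_id"].map({g: m.cds_start for g, m in idx.items()}).to_numpy()
    cds_end = table["gene_id"].map({g: m.cds_end for g, m in idx.items()}).to_numpy()
    psite = table["start"].to_numpy() + psite_offset
    in_cds = (psite >= cds_start) & (psite < cds_end)
    return ((psite - cds_start) % 3)[in_cds]


def frame_distribution(reads, genes: Sequence[GeneModel],
                       psite_offset: int = DEFAULT_PSITE_OFFSET) -> tuple[float, float, float]:
    """Fraction of CDS P-sites in frames (0, 1, 2); sums to 1."""
    table = reads_to_table(reads)
    frames = _psite_frames(table, genes, psite_offset)
    if frames.size == 0:
        raise ConfigurationError("no read has its P-site inside any CDS")
    frac = np.bincount(frames, minlength=3) / frames.size
    return (float(frac[0]), float(frac[1]), float(frac[2]))


@dataclass
class MetageneProfile:
    """P-site counts at positions relative to the CDS start and to the
    first nucleotide of the stop codon; both vectors span [-window, window]."""

    window: int
    start_profile: np.ndarray
    stop_profile: np.ndarray
    n_genes_used: int
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)


def metagene_profile(reads, genes: Sequence[GeneModel],
                     psite_offset: int = DEFAULT_PSITE_OFFSET,
                     window: int = 30) -> MetageneProfile:
    """Aggregate P-site counts around CDS start and stop.

    Genes whose UTRs are shorter than ``window`` are excluded (and
    reported) so every included gene contributes the full window.
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    table = reads_to_table(reads)
    idx = gene_index(genes)
    unknown = set(table["gene_id"].unique()) - set(idx)
    if unknown:
        raise ConfigurationError(f"reads map to unknown genes: {sorted(unknown)[:5]}")

    included = {g.gene_id for g in genes
                if g.utr5_length >= window and g.utr3_length >= window}
    excluded = sorted(set(idx) - included)

    keep = table["gene_id"].isin(included)
    sub = table[keep]
    cds_start = sub["gene_id"].map({g: idx[g].cds_start for g in included}).to_numpy()
    cds_end = sub["gene_id"].map({g: idx[g].cds_end for g in included}).to_numpy()
    psite = sub["start"].to_numpy() + psite_offset

    size = 2 * window + 1
    start_rel = psite - cds_start
    stop_rel = psite - (cds_end - 3)
    start_prof = np.bincount(start_rel[np.abs(start_rel) <= window] + window,
                             minlength=size).astype(float)
    stop_prof = np.bincount(stop_rel[np.abs(stop_rel) <= window] + window,
                            minlength=size).astype(float)
    return MetageneProfile(window=window, start_profile=start_prof,
                           stop_profile=stop_prof, n_genes_used=len(included),
                           excluded_genes=excluded)


def periodicity_autocorrelation(profile: MetageneProfile,
                                max_lag: int = 3) -> dict[int, float]:
    """Autocorrelation of the CDS-side start profile at lags 1..max_lag."""
    x = profile.start_profile[profile.window:]  # positions >= 0
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ConfigurationError("flat metagene profile; autocorrelation undefined")
    return {lag: float(np.dot(x[:-lag], x[lag:]) / denom)
            for lag in range(1, max_lag + 1)}


@dataclass
class QCReport:
    length_histogram: dict[int, int]
    frame_fractions: tuple[float, float, float]
    metagene: MetageneProfile
    autocorrelation: dict[int, float]
    flags: dict[str, bool]
    thresholds: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "length_histogram": {str(k): v for k, v in self.length_histogram.items()},
            "frame_fractions": list(self.frame_fractions),
            "metagene_start_profile": self.metagene.start_profile.tolist(),
            "metagene_stop_profile": self.metagene.stop_profile.tolist(),
            "metagene_window": self.metagene.window,
            "metagene_genes_used": self.metagene.n_genes_used,
            "autocorrelation": {str(k): v for k, v in self.autocorrelation.items()},
            "flags": self.flags,
            "thresholds": self.thresholds,
        }


def evaluate_qc(reads, genes: Sequence[GeneModel],
                psite_offset: int = DEFAULT_PSITE_OFFSET,
                window: int = 30,
                min_length_fraction: float = 0.8,
                length_range: tuple[int, int] = (28, 32),
                min_frame0_fraction: float = 0.5) -> QCReport:
    """Run all three QC criteria on one footprint library."""
    hist = footprint_length_distribution(reads)
    total = sum(hist.values())
    in_range = sum(v for k, v in hist.items()
                   if length_range[0] <= k <= length_range[1])
    frac_in_range = in_range / total if total else 0.0

    frames = frame_distribution(reads, genes, psite_offset)
    profile = metagene_profile(reads, genes, psite_offset, window)
    ac = periodicity_autocorrelation(profile)

    flags = {
        "length": frac_in_range >= min_length_fraction,
        "frame": frames[0] >= min_frame0_fraction,
        "periodicity": ac[3] > ac[1] and ac[3] > ac[2],
    }
    thresholds = {
        "min_length_fraction": min_length_fraction,
        "length_min": length_range[0],
        "length_max": length_range[1],
        "min_frame0_fraction": min_frame0_fraction,
        "observed_length_fraction": frac_in_range,
        "observed_frame0_fraction": frames[0],
    }
    return QCReport(length_histogram=hist, frame_fractions=frames,
                    metagene=profile, autocorrelation=ac,
                    flags=flags, thresholds=thresholds)
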