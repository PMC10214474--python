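"""Synthetic transcriptomes and paired footprint / total-mRNA libraries.

The generator produces, per replicate and condition, one footprint library
(lengths 28-32 nt, strong frame-0 periodicity over the CDS) and one total
mRNA library (fragments uniform over the transcript), with per-gene
abundance drawn once from a lognormal and shared between the two library
types.  A configurable fraction of genes carries a planted translational-
efficiency fold-change applied to the footprint libraries of the treatment
condition only, and designated gene subsets carry planted 5'UTR features
(uORF, TOP, PG4, high GC, long UTR) that the feature battery can
re-detect.

Background 5'UTRs are generated ATG-free so that planted uORFs are the
only uORF signal; all other background motif incidence is left random.
All randomness flows from ``SimulationConfig.seed`` through
per-purpose child streams, so identical config + seed reproduces
byte-identical outputs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import FOOTPRINT, MRNA, READ_COLUMNS, GeneModel

PLANTABLE_FEATURES = ("uorf", "top", "pg4", "high_gc", "long_utr")

_BASES = np.array(list("ACGT"))
#: codons with no T cannot form ATG or a stop codon in any frame; used for
#: planted uORF bodies so the planted stop is always the first in-frame stop
_T_FREE_CODONS = [a + b + c for a in "ACG" for b in "ACG" for c in "ACG"
                  if a + b + c != "ATG"]
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in _STOPS]


def _default_weights() -> dict[int, float]:
    return {28: 0.1, 29: 0.4, 30: 0.3, 31: 0.15, 32: 0.05}


@dataclass
class SimulationConfig:
    n_genes: int = 500
    utr5_length_range: tuple[int, int] = (40, 150)
    cds_length_range: tuple[int, int] = (300, 1500)
    utr3_length_range: tuple[int, int] = (30, 150)
    mrna_fragment_length_range: tuple[int, int] = (25, 60)
    gc_background: float = 0.45
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 0.5
    reads_per_library: int = 50_000
    footprint_length_weights: dict[int, float] = field(default_factory=_default_weights)
    periodicity: float = 0.95
    psite_offset: int = 12
    te_effect_genes: float = 0.1
    te_log2_effect: float = 1.0
    n_replicates: int = 3
    feature_plant: dict[str, float] = field(default_factory=dict)
    feature_plant_down: dict[str, float] = field(default_factory=dict)
    plant_gc: float = 0.70
    plant_utr_extension: int = 50
    uorf_codons: int = 3
    conditions: tuple[str, str] = ("HFS", "LFS")  # (treatment, control)
    seed: int = 0

    def validate(self) -> None:
        def _range_ok(r, name, lo=1):
            if len(r) != 2 or r[0] > r[1] or r[0] < lo:
                raise ConfigurationError(f"invalid {name}: {r}")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        _range_ok(self.utr5_length_range, "utr5_length_range", lo=0)
        _range_ok(self.cds_length_range, "cds_length_range", lo=6)
        _range_ok(self.utr3_length_range, "utr3_length_range", lo=0)
        _range_ok(self.mrna_fragment_length_range, "mrna_fragment_length_range")
        for name, p in [("gc_background", self.gc_background),
                        ("periodicity", self.periodicity),
                        ("te_effect_genes", self.te_effect_genes),
                        ("plant_gc", self.plant_gc)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        for d in (self.feature_plant, self.feature_plant_down):
            for k, v in d.items():
                if k not in PLANTABLE_FEATURES:
                    raise ConfigurationError(f"unknown plantable feature: {k}")
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"feature probability out of [0,1]: {k}={v}")
        w = self.footprint_length_weights
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ConfigurationError("footprint_length_weights must sum to 1")
        if any(v < 0 for v in w.values()):
            raise ConfigurationError("footprint_length_weights must be non-negative")
        if not set(w) <= set(range(28, 33)):
            raise ConfigurationError("footprint lengths must be within 28..32")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.uorf_codons < 2:
            raise ConfigurationError("uorf_codons must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["footprint_length_weights"] = {int(k): float(v)
                                         for k, v in d["footprint_length_weights"].items()}
        d["conditions"] = list(d["conditions"])
        for k in ("utr5_length_range", "cds_length_range", "utr3_length_range",
                  "mrna_fragment_length_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        for k in ("utr5_length_range", "cds_length_range", "utr3_length_range",
                  "mrna_fragment_length_range", "conditions"):
            if k in d:
                d[k] = tuple(d[k])
        if "footprint_length_weights" in d:
            d["footprint_length_weights"] = {int(k): float(v)
                                             for k, v in d["footprint_length_weights"].items()}
        return cls(**d)


def _streams(config: SimulationConfig) -> list[np.random.SeedSequence]:
    """Fixed spawn order: 0 transcriptome, 1 abundance, 2.. per-library."""
    n_lib = 2 * 2 * config.n_replicates
    return np.random.SeedSequence(config.seed).spawn(2 + n_lib)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _scrub_atg(seq: np.ndarray) -> np.ndarray:
    """Remove every ATG by T->C substitution (cannot create a new ATG)."""
    s = "".join(seq)
    while True:
        i = s.find("ATG")
        if i < 0:
            break
        seq[i + 1] = "C"
        s = s[:i + 1] + "C" + s[i + 2:]
    return seq


def _free_slot(rng: np.random.Generator, n: int, width: int,
               occupied: list[tuple[int, int]], lo: int = 0) -> int:
    if n - width < lo:
        raise ConfigurationError("5'UTR too short to plant requested features")
    for _ in range(200):
        start = int(rng.integers(lo, n - width + 1))
        if all(start + width <= a or start >= b for a, b in occupied):
            occupied.append((start, start + width))
            return start
    for start in range(lo, n - width + 1):  # deterministic fallback
        if all(start + width <= a or start >= b for a, b in occupied):
            occupied.append((start, start + width))
            return start
    raise ConfigurationError("5'UTR too crowded to plant requested features")


def _build_utr5(rng: np.random.Generator, length: int, gc: float,
                plant: set[str], config: SimulationConfig) -> str:
    if "long_utr" in plant:
        length += config.plant_utr_extension
    if "high_gc" in plant:
        gc = config.plant_gc
    seq = _scrub_atg(_random_seq(rng, length, gc))
    occupied: list[tuple[int, int]] = []
    if "top" in plant:
        # cap-adjacent C followed by a 6-pyrimidine run
        run = rng.choice(np.array(list("CT")), size=6)
        seq[0] = "C"
        seq[1:7] = run
        occupied.append((0, 7))
    if "pg4" in plant:
        loops = ["".join(rng.choice(np.array(list("AC")),
                                    size=int(rng.integers(1, 4))))
                 for _ in range(3)]
        motif = "GGG" + "".join(lp + "GGG" for lp in loops)
        start = _free_slot(rng, length, len(motif), occupied, lo=8)
        seq[start:start + len(motif)] = list(motif)
    if "uorf" in plant:
        body = [str(rng.choice(_T_FREE_CODONS))
                for _ in range(config.uorf_codons - 1)]
        motif = "ATG" + "".join(body) + str(rng.choice(_STOPS))
        start = _free_slot(rng, length, len(motif), occupied, lo=8)
        seq[start:start + len(motif)] = list(motif)
    return "".join(seq)


def _build_cds(rng: np.random.Generator, length: int) -> str:
    n_internal = length // 3 - 2
    internal = rng.choice(_NONSTOP_CODONS, size=n_internal)
    return "ATG" + "".join(internal) + str(rng.choice(_STOPS))


def simulate_transcriptome(config: SimulationConfig) -> list[GeneModel]:
    """Generate ``config.n_genes`` gene models with planted ground truth.

    Genes are assigned to ``te_up`` / ``te_down`` / ``null`` classes
    (fraction ``te_effect_genes``, split evenly up/down); 5'UTR features
    are planted on the up set with probabilities ``feature_plant`` and on
    the down set with ``feature_plant_down``.
    """
    config.validate()
    rng = np.random.default_rng(_streams(config)[0])
    n = config.n_genes

    n_eff = int(round(config.te_effect_genes * n))
    n_up = (n_eff + 1) // 2
    perm = rng.permutation(n)
    classes = np.array(["null"] * n, dtype=object)
    classes[perm[:n_up]] = "te_up"
    classes[perm[n_up:n_eff]] = "te_down"

    width = max(4, len(str(n)))
    genes: list[GeneModel] = []
    for i in range(n):
        cls = classes[i]
        plant_probs = (config.feature_plant if cls == "te_up"
                       else config.feature_plant_down if cls == "te_down"
                       else {})
        plant = {f for f, p in plant_probs.items() if rng.random() < p}

        u5 = int(rng.integers(config.utr5_length_range[0],
                              config.utr5_length_range[1] + 1))
        cds_len = int(rng.integers(config.cds_length_range[0],
                                   config.cds_length_range[1] + 1))
        cds_len = max(6, cds_len - cds_len % 3)
        u3 = int(rng.integers(config.utr3_length_range[0],
                              config.utr3_length_range[1] + 1))

        utr5_seq = _build_utr5(rng, u5, config.gc_background, plant, config)
        u5 = len(utr5_seq)
        cds_seq = _build_cds(rng, cds_len)
        utr3_seq = "".join(_random_seq(rng, u3, config.gc_background))

        effect = (config.te_log2_effect if cls == "te_up"
                  else -config.te_log2_effect if cls == "te_down" else 0.0)
        gene = GeneModel(
            gene_id=f"g{i + 1:0{width}d}",
            sequence=utr5_seq + cds_seq + utr3_seq,
            utr5=(0, u5),
            cds=(u5, u5 + cds_len),
            utr3=(u5 + cds_len, u5 + cds_len + u3),
            condition_class=str(cls),
            planted_features=frozenset(plant),
            te_log2_effect=effect,
        )
        genes.append(gene)
    return genes


def ground_truth_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabulate the planted simulation ground truth, one row per gene."""
    rows = []
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "condition_class": g.condition_class,
            "te_log2_effect": g.te_log2_effect,
            "utr5_length": g.utr5_length,
            "cds_length": g.cds_length,
            "utr3_length": g.utr3_length,
        }
        for f in PLANTABLE_FEATURES:
            row[f"planted_{f}"] = f in g.planted_features
        rows.append(row)
    return pd.DataFrame(rows)


def sample_labels(config: SimulationConfig) -> dict[str, list[str]]:
    """Sample names per condition, treatment condition first."""
    return {cond: [f"{cond}_rep{r}" for r in range(1, config.n_replicates + 1)]
            for cond in config.conditions}


def simulate_libraries(genes: Sequence[GeneModel],
                       config: SimulationConfig) -> pd.DataFrame:
    """Simulate paired footprint/mRNA libraries for every sample.

    Returns the canonical read table (columns ``gene_id, start, length,
    library, sample``).  Footprint 5' ends are placed so that the P-site
    (5' end + ``psite_offset``) falls on a uniformly chosen CDS codon, in
    frame 0 with probability ``periodicity`` (frames 1/2 equally
    otherwise).  mRNA fragments are uniform over the transcript.  Per-gene
    allocation is multinomial with weights proportional to abundance
    (times region length), with the planted TE effect applied to
    footprint libraries of the treatment condition only.
    """
    config.validate()
    if not genes:
        raise ConfigurationError("no genes supplied")
    if config.reads_per_library <= 0:
        raise ConfigurationError("reads_per_library must be positive")

    streams = _streams(config)
    abund_rng = np.random.default_rng(streams[1])
    n = len(genes)
    abundance = abund_rng.lognormal(config.abundance_log_mean,
                                    config.abundance_log_sd, n)

    ids = np.array([g.gene_id for g in genes], dtype=object)
    tx_len = np.array([g.length for g in genes])
    cds_start = np.array([g.cds_start for g in genes])
    cds_len = np.array([g.cds_length for g in genes])
    utr5_len = np.array([g.utr5_length for g in genes])
    utr3_len = np.array([g.utr3_length for g in genes])
    effect = np.array([g.te_log2_effect for g in genes])

    fp_lens = np.array(sorted(config.footprint_length_weights))
    fp_probs = np.array([config.footprint_length_weights[int(l)] for l in fp_lens])
    fp_probs = fp_probs / fp_probs.sum()
    max_fp = int(fp_lens.max())
    m_lo, m_hi = config.mrna_fragment_length_range

    # eligibility: footprints need room for the 5'-end upstream of the
    # P-site and for the 3' tail past the last codon; mRNA fragments just
    # need to fit on the transcript
    fp_ok = ((utr5_len >= config.psite_offset)
             & (utr3_len >= max_fp - config.psite_offset - 1)
             & (tx_len >= max_fp))
    m_ok = tx_len >= m_hi
    for mask, what in ((fp_ok, "footprint"), (m_ok, "mRNA")):
        if not mask.all():
            skipped = ids[~mask]
            warnings.warn(
                f"{len(skipped)} gene(s) too short for {what} reads; skipped: "
                f"{', '.join(skipped[:5])}{'...' if len(skipped) > 5 else ''}")

    treatment = config.conditions[0]
    per = config.periodicity
    frame_p = np.array([per, (1 - per) / 2, (1 - per) / 2])
    n_codons = cds_len // 3

    chunks = []
    lib_i = 0
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            for library in (FOOTPRINT, MRNA):
                rng = np.random.default_rng(streams[2 + lib_i])
                lib_i += 1
                # shared per-gene abundance for both library types is the
                # minimal structure making TE identifiable; only planted
                # effects perturb the footprint side of the treatment
                if library == FOOTPRINT:
                    w = abundance.copy()
                    if cond == treatment:
                        w = w * np.exp2(effect)
                    w = np.where(fp_ok, w, 0.0)
                else:
                    w = np.where(m_ok, abundance, 0.0)
                if w.sum() <= 0:
                    raise ConfigurationError("no eligible genes for library")
                counts = rng.multinomial(config.reads_per_library, w / w.sum())
                gidx = np.repeat(np.arange(n), counts)
                size = gidx.size
                if library == FOOTPRINT:
                    length = rng.choice(fp_lens, size=size, p=fp_probs)
                    frame = rng.choice(3, size=size, p=frame_p)
                    codon = (rng.random(size) * n_codons[gidx]).astype(np.int64)
                    psite = cds_start[gidx] + 3 * codon + frame
                    start = psite - config.psite_offset
                else:
                    length = rng.integers(m_lo, m_hi + 1, size=size)
                    start = (rng.random(size)
                             * (tx_len[gidx] - length + 1)).astype(np.int64)
                chunks.append(pd.DataFrame({
                    "gene_id": ids[gidx],
                    "start": start,
                    "length": length.astype(np.int64),
                    "library": library,
                    "sample": sample,
                }))
    reads = pd.concat(chunks, ignore_index=True)
    return reads[READ_COLUMNS]
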