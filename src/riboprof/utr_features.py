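"""5'UTR sequence-feature battery and up- vs down-set comparison.

Features per gene: UTR length, %GC, a folding score from a Nussinov-style
interval dynamic program (base-pair scores GC -3, AU -2, GU -1, minimum
hairpin loop 3; pseudoknot-free), upstream ORF count, 5' terminal
oligopyrimidine (TOP) motif, and predicted G-quadruplex (PG4) matches of
the pattern G{3,}(N{1,7}G{3,}){3}.

Continuous features are compared between gene sets with a two-sided
Mann-Whitney U (Welch t available); binary incidence with Fisher's exact
test on the 2x2 table.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .model import GeneModel

_VALID = set("ACGTU")

DEFAULT_PAIR_SCORES = {"GC": 3.0, "AU": 2.0, "GU": 1.0}

CONTINUOUS_FEATURES = ("utr5_length", "gc", "fold_energy")
BINARY_FEATURES = ("has_top", "has_uorf", "has_pg4")


def _clean(seq: str, op: str) -> str:
    if not seq:
        raise ConfigurationError(f"{op}: empty sequence")
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ConfigurationError(f"{op}: non-nucleotide characters {sorted(bad)}")
    return s


def gc_content(seq: str) -> float:
    """(#G + #C) / length."""
    s = _clean(seq, "gc_content")
    return (s.count("G") + s.count("C")) / len(s)


def _pair_score_table(pair_scores: dict[str, float]) -> dict[frozenset, float]:
    table = {}
    for pair, score in pair_scores.items():
        if len(pair) != 2:
            raise ConfigurationError(f"bad pair key: {pair}")
        table[frozenset(pair.upper().replace("T", "U"))] = float(score)
    return table


def fold_energy(seq: str, min_loop: int = 3,
                pair_scores: dict[str, float] | None = None) -> float:
    """Minimum folding score over all nested secondary structures.

    Score of a structure is minus the sum of its base-pair scores, so the
    result is <= 0 and more negative means more structure.  Hairpin loops
    shorter than ``min_loop`` unpaired bases are forbidden.  O(n^3)
    interval DP.
    """
    if min_loop < 0:
        raise ConfigurationError("min_loop must be >= 0")
    s = _clean(seq, "fold_energy").replace("T", "U")
    table = _pair_score_table(pair_scores or DEFAULT_PAIR_SCORES)
    n = len(s)
    if n <= min_loop + 1:
        return 0.0
    alphabet = "ACGU"
    code = np.fromiter((alphabet.index(c) for c in s), dtype=np.intp, count=n)
    pairmat = np.zeros((4, 4))
    for key, v in table.items():
        a, b = sorted(key)
        i, j = alphabet.index(a), alphabet.index(b)
        pairmat[i, j] = pairmat[j, i] = v
    score = pairmat[code[:, None], code[None, :]]

    M = np.zeros((n + 1, n + 1))  # M[i, j] = best score of s[i..j-1] (half-open)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # interval s[i..j-1]
            best = M[i, j - 1]  # last base unpaired
            ks = np.arange(i, j - 1 - min_loop)  # partners for base j-1
            pair = score[ks, j - 1]
            valid = pair > 0
            if valid.any():
                cand = pair[valid] + M[i, ks[valid]] + M[ks[valid] + 1, j - 1]
                best = max(best, float(cand.max()))
            M[i, j] = best
    return -float(M[0, n])


class UORF(NamedTuple):
    start: int
    end: int            # end of the stop codon (exclusive); UTR end if none
    overlaps_cds: bool


def find_uorfs(utr5_seq: str, cds_offset: int | None = None,
               min_codons: int = 2) -> list[UORF]:
    """All upstream ORFs in a 5'UTR.

    An AUG followed by an in-frame stop before the CDS start is a
    complete uORF; an AUG with no in-frame stop in the UTR is reported
    with ``overlaps_cds=True``.  ORFs shorter than ``min_codons`` codons
    (stop excluded) are dropped.  Empty UTR gives an empty list.
    """
    if not utr5_seq:
        return []
    s = _clean(utr5_seq, "find_uorfs").replace("U", "T")
    if cds_offset is None:
        cds_offset = len(s)
    if cds_offset != len(s):
        raise ConfigurationError("cds_offset must equal the 5'UTR length")
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for m in re.finditer("ATG", s):
        start = m.start()
        end = None
        for c in range(start + 3, len(s) - 2, 3):
            if s[c:c + 3] in stops:
                end = c + 3
                break
        if end is not None:
            if (end - 3 - start) // 3 >= min_codons:
                out.append(UORF(start, end, False))
        else:
            if (len(s) - start) // 3 >= min_codons:
                out.append(UORF(start, len(s), True))
    return out


def has_top_motif(utr5_seq: str, min_pyrimidines: int = 4,
                  max_pyrimidines: int = 15) -> bool:
    """True iff the UTR starts with C followed by an uninterrupted
    pyrimidine (C/U/T) run of at least ``min_pyrimidines`` (run length
    counted up to ``max_pyrimidines``)."""
    s = _clean(utr5_seq, "has_top_motif").replace("U", "T")
    if s[0] != "C":
        return False
    run = 0
    for ch in s[1:1 + max_pyrimidines]:
        if ch in "CT":
            run += 1
        else:
            break
    return run >= min_pyrimidines


class PG4Match(NamedTuple):
    start: int
    end: int
    sequence: str


def find_pg4(seq: str, g_run: int = 3, loop_max: int = 7) -> list[PG4Match]:
    """Left-to-right, non-overlapping, greedy matches of
    ``G{g_run,}(N{1,loop_max}G{g_run,}){3}`` (regex backtracking
    semantics; U treated as T)."""
    s = _clean(seq, "find_pg4").replace("U", "T")
    pattern = re.compile(
        f"G{{{g_run},}}(?:[ACGT]{{1,{loop_max}}}G{{{g_run},}}){{3}}")
    return [PG4Match(m.start(), m.end(), m.group(0))
            for m in pattern.finditer(s)]


def feature_table(genes: Sequence[GeneModel],
                  min_loop: int = 3,
                  pair_scores: dict[str, float] | None = None,
                  min_codons: int = 2,
                  count_overlapping_uorfs: bool = False) -> pd.DataFrame:
    """One :class:`UTRFeatureRow`-shaped record per gene.

    ``n_uorfs`` counts complete uORFs only by default; CDS-overlapping
    AUGs are tallied separately in ``n_uorfs_overlapping``.
    ``fold_energy_per_nt`` is the length-normalized score.
    """
    rows = []
    for g in genes:
        u = g.utr5_seq
        if not u:
            rows.append({"gene_id": g.gene_id, "utr5_length": 0, "gc": np.nan,
                         "fold_energy": 0.0, "fold_energy_per_nt": 0.0,
                         "n_uorfs": 0, "n_uorfs_overlapping": 0,
                         "has_top": False, "n_pg4": 0})
            continue
        uorfs = find_uorfs(u, min_codons=min_codons)
        complete = [o for o in uorfs if not o.overlaps_cds]
        overlapping = [o for o in uorfs if o.overlaps_cds]
        n_uorfs = len(uorfs) if count_overlapping_uorfs else len(complete)
        fe = fold_energy(u, min_loop=min_loop, pair_scores=pair_scores)
        rows.append({
            "gene_id": g.gene_id,
            "utr5_length": len(u),
            "gc": gc_content(u),
            "fold_energy": fe,
            "fold_energy_per_nt": fe / len(u),
            "n_uorfs": n_uorfs,
            "n_uorfs_overlapping": len(overlapping),
            "has_top": has_top_motif(u),
            "n_pg4": len(find_pg4(u)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    statistic: float | None
    p_value: float | None
    direction: str          # "up_higher" | "down_higher" | "none"
    test: str               # "mannwhitney" | "welch" | "fisher" | "untestable"
    testable: bool = True


def _binary_values(df: pd.DataFrame, feature: str) -> np.ndarray:
    if feature == "has_top":
        return df["has_top"].to_numpy(bool)
    if feature == "has_uorf":
        return (df["n_uorfs"].to_numpy() > 0)
    if feature == "has_pg4":
        return (df["n_pg4"].to_numpy() > 0)
    raise ConfigurationError(f"unknown binary feature: {feature}")


def compare_feature(up_rows: pd.DataFrame, down_rows: pd.DataFrame,
                    feature: str, continuous_test: str = "mannwhitney"
                    ) -> FeatureComparison:
    """Compare one feature between the up- and down-regulated gene sets.

    Continuous features use a two-sided Mann-Whitney U (or Welch t);
    binary incidence uses Fisher's exact test.  A feature constant across
    both sets is reported untestable.
    """
    if len(up_rows) == 0 or len(down_rows) == 0:
        raise ConfigurationError("both gene sets must be nonempty")
    if feature in CONTINUOUS_FEATURES:
        a = up_rows[feature].to_numpy(float)
        b = down_rows[feature].to_numpy(float)
        if np.unique(np.concatenate([a, b])).size == 1:
            return FeatureComparison(feature, None, None, "none",
                                     "untestable", testable=False)
        if continuous_test == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        elif continuous_test == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ConfigurationError(f"unknown continuous test: {continuous_test}")
        ma, mb = np.median(a), np.median(b)
        direction = ("up_higher" if ma > mb
                     else "down_higher" if mb > ma else "none")
        return FeatureComparison(feature, stat, p, direction,
                                 continuous_test)
    if feature in BINARY_FEATURES:
        a = _binary_values(up_rows, feature)
        b = _binary_values(down_rows, feature)
        table = np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]])
        constant = (not a.any() and not b.any()) or (a.all() and b.all())
        if constant:
            return FeatureComparison(feature, None, None, "none",
                                     "untestable", testable=False)
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        fa, fb = a.mean(), b.mean()
        direction = ("up_higher" if fa > fb
                     else "down_higher" if fb > fa else "none")
        return FeatureComparison(feature, float(odds), float(p), direction,
                                 "fisher")
    raise ConfigurationError(f"unknown feature: {feature}")


def compare_all_features(up_rows: pd.DataFrame, down_rows: pd.DataFrame,
                         continuous_test: str = "mannwhitney") -> pd.DataFrame:
    comps = [compare_feature(up_rows, down_rows, f, continuous_test)
             for f in CONTINUOUS_FEATURES + BINARY_FEATURES]
    return pd.DataFrame([c.__dict__ for c in comps])
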