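"""Differential translation calling.

A gene is called differentially translated (up or down) when it passes
all three filters: TE ratio outside (lower, upper) = (0.667, 1.5),
per-gene p < alpha = 0.05, and Benjamini-Hochberg q < fdr = 0.05.

Per-gene tests on replicate log2 TE values:

* ``welch`` — two-sided Welch t-test (default; no count information
  needed, but underpowered at 2-3 replicates per group);
* ``permutation`` — exact enumeration of all group reassignments,
  two-sided on |mean difference| (small-n oracle);
* :func:`test_differential_te_counts` — a count-aware z-test that pools
  counts across replicates and uses the delta-method (Poisson/
  multinomial) variance of the pooled log2 TE ratio.  This is the test
  the bundled pipeline uses for calling, in the spirit of count-based
  differential-expression models: at 2-3 replicates a plain t-test has
  essentially no power after FDR correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .quant import CountMatrix, TETable

DEFAULT_ALPHA = 0.05
DEFAULT_FDR = 0.05
DEFAULT_LOWER = 0.667
DEFAULT_UPPER = 1.5

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class DTGRecord:
    gene_id: str
    log2_te_change: float
    p_value: float
    q_value: float
    call: str


def log2_te_change(te_treatment: TETable, te_control: TETable) -> pd.DataFrame:
    """Per-gene log2(TE_treatment / TE_control) from replicate means.

    Genes excluded in either table are excluded here (reasons are merged
    into the ``excluded`` attribute of the result frame).
    """
    mt = te_treatment.mean_log2_te()
    mc = te_control.mean_log2_te()
    shared = mt.index.intersection(mc.index)
    if len(shared) == 0:
        raise ConfigurationError("treatment and control share no genes")
    out = pd.DataFrame({
        "gene_id": shared,
        "log2_te_change": (mt[shared] - mc[shared]).to_numpy(),
    })
    dropped = pd.concat([
        te_treatment.excluded.assign(side="treatment"),
        te_control.excluded.assign(side="control"),
        pd.DataFrame({"gene_id": mt.index.difference(shared),
                      "reason": "missing_in_control", "side": "treatment"}),
        pd.DataFrame({"gene_id": mc.index.difference(shared),
                      "reason": "missing_in_treatment", "side": "control"}),
    ], ignore_index=True)
    out.attrs["excluded"] = dropped
    return out


def _replicate_arrays(te_treatment: TETable, te_control: TETable):
    rt = te_treatment.replicate_matrix()
    rc = te_control.replicate_matrix()
    shared = rt.index.intersection(rc.index)
    if len(shared) == 0:
        raise ConfigurationError("treatment and control share no genes")
    return shared, rt.loc[shared].to_numpy(), rc.loc[shared].to_numpy()


def test_differential_te(te_treatment: TETable, te_control: TETable,
                         method: str = "welch") -> pd.DataFrame:
    """Per-gene two-sided test on replicate log2 TE values.

    Returns columns ``gene_id, p_value, testable``.  Genes with fewer
    than two replicates in a group, or with zero variance in both groups
    and unequal means, are reported untestable (p = NaN).  Identical
    zero-variance groups with equal means get p = 1.
    """
    shared, xt, xc = _replicate_arrays(te_treatment, te_control)
    nt, nc = xt.shape[1], xc.shape[1]
    if nt < 2 or nc < 2:
        return pd.DataFrame({"gene_id": shared, "p_value": np.nan,
                             "testable": False})
    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
        vt, vc = xt.var(axis=1, ddof=1), xc.var(axis=1, ddof=1)
        both_flat = (vt == 0) & (vc == 0)
        equal_means = np.isclose(xt.mean(axis=1), xc.mean(axis=1))
        p = np.where(both_flat & equal_means, 1.0, p)
        p = np.where(both_flat & ~equal_means, np.nan, p)
    elif method == "permutation":
        p = np.array([permutation_p_value(xt[i], xc[i])
                      for i in range(len(shared))])
    else:
        raise ConfigurationError(f"unknown test method: {method}")
    return pd.DataFrame({"gene_id": shared, "p_value": p,
                         "testable": np.isfinite(p)})


def permutation_p_value(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p on |mean(a) - mean(b)| over all
    reassignments of the pooled values into groups of the original sizes."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    observed = abs(a.mean() - b.mean())
    total = hits = 0
    for comb in combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        stat = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if stat >= observed - 1e-12:
            hits += 1
    return hits / total


def test_differential_te_counts(fp_treatment: CountMatrix, mrna_treatment: CountMatrix,
                                fp_control: CountMatrix, mrna_control: CountMatrix,
                                pseudocount: float = 0.5) -> pd.DataFrame:
    """Count-aware z-test on the pooled log2 TE ratio.

    Counts are summed over replicates; the statistic is the library-size-
    normalized log2((fp_t/m_t)/(fp_c/m_c)) with delta-method variance
    sum(1/(count + pseudocount)) / ln(2)^2.  Returns ``gene_id,
    log2_te_change_pooled, p_value, testable``.
    """
    mats = (fp_treatment, mrna_treatment, fp_control, mrna_control)
    genes = mats[0].genes
    for m in mats[1:]:
        if m.genes != genes:
            raise ConfigurationError("count matrices must share the gene axis")
    pooled = [m.counts.sum(axis=1).astype(float) for m in mats]
    libsize = [float(m.library_size.sum()) for m in mats]
    if any(n <= 0 for n in libsize):
        raise ConfigurationError("zero library size")
    ln2 = np.log(2.0)
    adj = [c + pseudocount for c in pooled]
    d = ((np.log2(adj[0]) - np.log2(libsize[0]))
         - (np.log2(adj[1]) - np.log2(libsize[1]))
         - (np.log2(adj[2]) - np.log2(libsize[2]))
         + (np.log2(adj[3]) - np.log2(libsize[3])))
    var = sum(1.0 / a for a in adj) / ln2 ** 2
    z = d / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]
    return pd.DataFrame({"gene_id": genes, "log2_te_change_pooled": d,
                         "p_value": p, "testable": True})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    Input p must lie in (0, 1]; q_i = min_{j>=i} m * p_(j) / j.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if (~np.isfinite(p)).any() or (p <= 0).any() or (p > 1).any():
        raise ConfigurationError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(stepped, 1.0)
    return q


def call_dtgs(records: pd.DataFrame,
              alpha: float = DEFAULT_ALPHA, fdr: float = DEFAULT_FDR,
              lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three-way filter and label each gene up/down/unchanged.

    ``records`` needs columns ``gene_id, log2_te_change, p_value,
    q_value``.  Returns the frame with a ``call`` column plus summary
    counts.
    """
    for t, name in ((alpha, "alpha"), (fdr, "fdr"), (lower, "lower"), (upper, "upper")):
        if not (0 < t < np.inf):
            raise ConfigurationError(f"threshold {name} must be in (0, inf)")
    if lower >= upper:
        raise ConfigurationError("lower threshold must be < upper threshold")
    required = {"gene_id", "log2_te_change", "p_value", "q_value"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigurationError(f"records missing columns: {sorted(missing)}")

    out = records.copy()
    ratio = np.exp2(out["log2_te_change"].to_numpy())
    p = out["p_value"].to_numpy()
    q = out["q_value"].to_numpy()
    significant = np.isfinite(p) & np.isfinite(q) & (p < alpha) & (q < fdr)
    call = np.where(significant & (ratio > upper), CALL_UP,
                    np.where(significant & (ratio < lower), CALL_DOWN,
                             CALL_UNCHANGED))
    out["call"] = call
    summary = {
        "n_up": int((call == CALL_UP).sum()),
        "n_down": int((call == CALL_DOWN).sum()),
        "n_unchanged": int((call == CALL_UNCHANGED).sum()),
        "n_total": int(len(out)),
    }
    return out, summary


def condition_concordance(x, y) -> float:
    """Squared Pearson correlation of two matched per-gene vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("inputs must be matched 1-D vectors")
    if x.size < 3:
        raise ConfigurationError("need at least 3 genes")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ConfigurationError("zero variance; concordance undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r ** 2)
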