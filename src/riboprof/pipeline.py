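"""End-to-end orchestration: configuration, stage sequencing, manifest.

``run_all`` executes simulate -> qc -> quantify -> difftrans -> utrfeat
-> enrich and writes one artifact per stage into the output directory.
Given a fixed seed the whole bundle is byte-identical across runs; the
manifest records the config hash, package versions, and per-stage row
counts (no timestamps, to keep reruns reproducible).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .difftrans import (bh_fdr, call_dtgs, condition_concordance,
                        log2_te_change, test_differential_te,
                        test_differential_te_counts)
from .enrichment import (GeneSetCollection, enrichment_frame,
                         hypergeometric_enrichment, overlap_fraction, write_gmt)
from .errors import ConfigurationError, StageError
from .model import FOOTPRINT, MRNA
from .qc import evaluate_qc
from .quant import count_reads, rpkm, translational_efficiency, TETable
from .simulate import (SimulationConfig, ground_truth_table, sample_labels,
                       simulate_libraries, simulate_transcriptome)
from .utr_features import compare_all_features, feature_table

log = logging.getLogger("riboprof")

TEST_METHODS = ("counts", "welch", "permutation")


@dataclass
class Thresholds:
    alpha: float = 0.05
    fdr: float = 0.05
    ratio_lower: float = 0.667
    ratio_upper: float = 1.5
    min_mrna_rpkm: float = 1.0
    pseudocount: float = 0.0
    psite_offset: int = 12
    qc_min_length_fraction: float = 0.8
    qc_min_frame0_fraction: float = 0.5
    metagene_window: int = 30
    # effective length for mRNA RPKM: "cds" keeps TE centred at 1 under
    # shared abundance; "transcript" is the alternative convention
    mrna_effective_length: str = "cds"

    def validate(self) -> None:
        for name in ("alpha", "fdr", "ratio_lower", "ratio_upper"):
            v = getattr(self, name)
            if not 0 < v < np.inf:
                raise ConfigurationError(f"threshold {name} out of range: {v}")
        if self.ratio_lower >= self.ratio_upper:
            raise ConfigurationError("ratio_lower must be < ratio_upper")
        if self.min_mrna_rpkm < 0 or self.pseudocount < 0:
            raise ConfigurationError("min_mrna_rpkm/pseudocount must be >= 0")
        if self.metagene_window <= 0:
            raise ConfigurationError("metagene_window must be positive")
        if self.mrna_effective_length not in ("cds", "transcript"):
            raise ConfigurationError(
                f"unknown mrna_effective_length: {self.mrna_effective_length}")


@dataclass
class PipelineConfig:
    """Single config object for the whole pipeline.

    Either ``simulation`` is present (synthetic mode) or the three input
    paths (fasta, gene_models, alignments) are.  ``seed`` overrides the
    simulation seed so one flag controls all randomness.
    """

    simulation: SimulationConfig | None = None
    fasta: str | None = None
    gene_models: str | None = None
    alignments: str | None = None
    gene_sets: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    test_method: str = "counts"
    seed: int | None = None
    write_sam: bool = False

    def validate(self) -> None:
        if self.simulation is None:
            missing = [n for n in ("fasta", "gene_models", "alignments")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    f"no simulation block and missing inputs: {missing}")
        if self.test_method not in TEST_METHODS:
            raise ConfigurationError(f"unknown test_method: {self.test_method}")
        self.thresholds.validate()
        if self.simulation is not None:
            if self.seed is not None:
                self.simulation.seed = int(self.seed)
            self.simulation.validate()

    def to_dict(self) -> dict:
        return {
            "simulation": (self.simulation.to_dict()
                           if self.simulation is not None else None),
            "fasta": self.fasta,
            "gene_models": self.gene_models,
            "alignments": self.alignments,
            "gene_sets": self.gene_sets,
            "thresholds": dict(self.thresholds.__dict__),
            "test_method": self.test_method,
            "seed": self.seed,
            "write_sam": self.write_sam,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "thresholds" in d and d["thresholds"] is not None:
            th = d["thresholds"]
            unknown = set(th) - set(Thresholds.__dataclass_fields__)
            if unknown:
                raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
            d["thresholds"] = Thresholds(**th)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except ConfigurationError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def _run_simulate(config: PipelineConfig, outdir: Path, manifest: dict):
    sim = config.simulation
    genes = simulate_transcriptome(sim)
    reads = simulate_libraries(genes, sim)
    truth = ground_truth_table(genes)
    rio.write_fasta(genes, outdir / "transcripts.fasta")
    rio.write_bed(genes, outdir / "gene_models.bed")
    rio.write_read_table(reads, outdir / "alignments.tsv")
    rio.write_table(truth, outdir / "ground_truth.tsv")
    if config.write_sam:
        rio.write_sam(reads, genes, outdir / "alignments.sam")
    manifest["stages"]["simulate"] = {"n_genes": len(genes), "n_reads": len(reads)}
    log.info("stage simulate: %d genes, %d reads", len(genes), len(reads))
    return genes, reads, truth


@_stage("load")
def _run_load(config: PipelineConfig, manifest: dict):
    sequences = rio.read_fasta(config.fasta) if config.fasta else {}
    genes = rio.read_bed(config.gene_models, sequences)
    path = str(config.alignments)
    reads = rio.read_sam(path) if path.endswith(".sam") else rio.read_read_table(path)
    manifest["stages"]["load"] = {"n_genes": len(genes), "n_reads": len(reads)}
    return genes, reads, None


@_stage("qc")
def _run_qc(config, genes, reads, outdir: Path, manifest: dict):
    th = config.thresholds
    fp = reads[reads["library"] == FOOTPRINT]
    reports = {}
    hist_rows = []
    for sample, grp in fp.groupby("sample", sort=True):
        rep = evaluate_qc(grp, genes, psite_offset=th.psite_offset,
                          window=th.metagene_window,
                          min_length_fraction=th.qc_min_length_fraction,
                          min_frame0_fraction=th.qc_min_frame0_fraction)
        reports[sample] = rep.to_dict()
        for length, count in sorted(rep.length_histogram.items()):
            hist_rows.append({"sample": sample, "length": length, "count": count})
    _write_json(reports, outdir / "qc_report.json")
    rio.write_table(pd.DataFrame(hist_rows), outdir / "qc_length_histogram.tsv")
    manifest["stages"]["qc"] = {
        "n_samples": len(reports),
        "all_pass": all(all(r["flags"].values()) for r in reports.values()),
    }
    log.info("stage qc: %d samples", len(reports))
    return reports


@_stage("quantify")
def _run_quantify(config, genes, reads, outdir: Path, manifest: dict):
    th = config.thresholds
    cm_fp = count_reads(reads[reads["library"] == FOOTPRINT], genes,
                        mode="cds_psite", psite_offset=th.psite_offset)
    cm_m = count_reads(reads[reads["library"] == MRNA], genes,
                       mode="transcript_overlap",
                       effective_length=th.mrna_effective_length)
    te = translational_efficiency(rpkm(cm_fp), rpkm(cm_m),
                                  pseudocount=th.pseudocount,
                                  min_mrna_rpkm=th.min_mrna_rpkm)
    rio.write_table(cm_fp.to_frame(), outdir / "counts_footprint.tsv")
    rio.write_table(cm_m.to_frame(), outdir / "counts_mrna.tsv")
    rio.write_table(te.table, outdir / "te.tsv")
    rio.write_table(te.excluded, outdir / "te_excluded.tsv")
    manifest["stages"]["quantify"] = {
        "n_genes_retained": len(te.genes),
        "n_genes_excluded": int(te.excluded["gene_id"].nunique()),
    }
    log.info("stage quantify: %d genes retained", len(te.genes))
    return cm_fp, cm_m, te


def _split_te(te: TETable, samples: list[str]) -> TETable:
    sub = te.table[te.table["sample"].isin(samples)].reset_index(drop=True)
    return TETable(table=sub, excluded=te.excluded,
                   pseudocount=te.pseudocount, min_mrna_rpkm=te.min_mrna_rpkm)


@_stage("difftrans")
def _run_difftrans(config, cm_fp, cm_m, te, labels, outdir: Path, manifest: dict):
    th = config.thresholds
    (treat_cond, treat_samples), (ctrl_cond, ctrl_samples) = labels
    te_t = _split_te(te, treat_samples)
    te_c = _split_te(te, ctrl_samples)
    ratio = log2_te_change(te_t, te_c)

    if config.test_method == "counts":
        tests = test_differential_te_counts(
            cm_fp.select_samples(treat_samples), cm_m.select_samples(treat_samples),
            cm_fp.select_samples(ctrl_samples), cm_m.select_samples(ctrl_samples))
        tests = tests[["gene_id", "p_value", "testable"]]
    else:
        tests = test_differential_te(te_t, te_c, method=config.test_method)

    records = ratio.merge(tests, on="gene_id", how="inner")
    testable = records[records["testable"]].copy()
    testable["q_value"] = bh_fdr(testable["p_value"].to_numpy())
    called, summary = call_dtgs(testable, alpha=th.alpha, fdr=th.fdr,
                                lower=th.ratio_lower, upper=th.ratio_upper)
    called = called[["gene_id", "log2_te_change", "p_value", "q_value", "call"]]

    # cross-condition concordance of replicate-mean log2 RPKM (the same
    # statistic as the published scatterplots: mRNA and translation)
    def _mean_log2_rpkm(col):
        t = te.table[te.table["sample"].isin(treat_samples)]
        c = te.table[te.table["sample"].isin(ctrl_samples)]
        mt = np.log2(t.groupby("gene_id")[col].mean() + 1e-9)
        mc = np.log2(c.groupby("gene_id")[col].mean() + 1e-9)
        shared = mt.index.intersection(mc.index)
        return condition_concordance(mt[shared], mc[shared])

    summary["concordance_r2_mrna"] = _mean_log2_rpkm("rpkm_mrna")
    summary["concordance_r2_footprint"] = _mean_log2_rpkm("rpkm_fp")
    summary["treatment"] = treat_cond
    summary["control"] = ctrl_cond
    summary["n_untestable"] = int((~records["testable"]).sum())

    rio.write_table(called, outdir / "dtg.tsv")
    _write_json(summary, outdir / "dtg_summary.json")
    manifest["stages"]["difftrans"] = {k: summary[k] for k in
                                       ("n_up", "n_down", "n_unchanged", "n_total")}
    log.info("stage difftrans: %(n_up)d up, %(n_down)d down of %(n_total)d", summary)
    return called, summary


@_stage("utrfeat")
def _run_utrfeat(config, genes, called, outdir: Path, manifest: dict):
    by_id = {g.gene_id: g for g in genes}
    up_ids = called.loc[called["call"] == "up", "gene_id"]
    down_ids = called.loc[called["call"] == "down", "gene_id"]
    up_genes = [by_id[g] for g in up_ids if by_id[g].sequence]
    down_genes = [by_id[g] for g in down_ids if by_id[g].sequence]
    feats_up = feature_table(up_genes) if up_genes else pd.DataFrame()
    feats_down = feature_table(down_genes) if down_genes else pd.DataFrame()
    if len(feats_up):
        feats_up["set"] = "up"
    if len(feats_down):
        feats_down["set"] = "down"
    feats = pd.concat([feats_up, feats_down], ignore_index=True)
    rio.write_table(feats, outdir / "utr_features.tsv")
    if len(feats_up) and len(feats_down):
        comps = compare_all_features(feats_up, feats_down)
    else:
        comps = pd.DataFrame(columns=["feature", "statistic", "p_value",
                                      "direction", "test", "testable"])
        log.warning("stage utrfeat: up or down set empty; no comparisons")
    rio.write_table(comps, outdir / "feature_comparisons.tsv")
    manifest["stages"]["utrfeat"] = {"n_up": len(feats_up), "n_down": len(feats_down),
                                     "n_comparisons": len(comps)}
    return feats, comps


@_stage("enrich")
def _run_enrich(config, te, truth, called, outdir: Path, manifest: dict):
    universe = te.genes
    if config.gene_sets:
        from .enrichment import read_gmt
        collection = read_gmt(config.gene_sets, universe=universe)
    elif truth is not None:
        rng = np.random.default_rng(
            (config.simulation.seed if config.simulation else 0) + 104729)
        sets = {
            "planted_te_up": truth.loc[truth["condition_class"] == "te_up",
                                       "gene_id"].tolist(),
            "planted_te_down": truth.loc[truth["condition_class"] == "te_down",
                                         "gene_id"].tolist(),
        }
        for i in (1, 2):
            size = max(5, len(universe) // 20)
            sets[f"random_set_{i}"] = sorted(
                rng.choice(universe, size=min(size, len(universe)),
                           replace=False).tolist())
        collection = GeneSetCollection(sets=sets, universe=universe)
        write_gmt(collection, outdir / "gene_sets.gmt")
    else:
        log.warning("stage enrich: no gene sets available; skipped")
        manifest["stages"]["enrich"] = {"skipped": True}
        return None

    query = called.loc[called["call"] == "up", "gene_id"].tolist()
    if not query:
        log.warning("stage enrich: no upregulated DTGs; skipped")
        manifest["stages"]["enrich"] = {"skipped": True}
        return None
    results = hypergeometric_enrichment(query, collection)
    frame = enrichment_frame(results)
    rio.write_table(frame, outdir / "enrichment.tsv")
    extra = {}
    if truth is not None:
        planted_up = collection.sets.get("planted_te_up", [])
        if planted_up:
            ov = overlap_fraction(query, planted_up)
            extra = {"query_fraction_in_planted_up": ov.fraction_a_in_b,
                     "jaccard_with_planted_up": ov.jaccard}
            _write_json(extra, outdir / "enrichment_overlap.json")
    manifest["stages"]["enrich"] = {"n_sets": len(results), **extra}
    return frame


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns the result bundle.

    Artifacts written: qc_report.json, qc_length_histogram.tsv,
    counts_*.tsv, te.tsv, dtg.tsv + dtg_summary.json, utr_features.tsv +
    feature_comparisons.tsv, enrichment.tsv, manifest.json (plus the
    simulated inputs in synthetic mode).  All tables use 0-based
    half-open coordinates and documented headers.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "config_sha256": config.digest(),
                "versions": _versions(), "stages": {}}

    if config.simulation is not None:
        genes, reads, truth = _run_simulate(config, outdir, manifest)
        labels_map = sample_labels(config.simulation)
        conds = list(config.simulation.conditions)
    else:
        genes, reads, truth = _run_load(config, manifest)
        samples = sorted(reads["sample"].unique())
        conds = sorted({s.rsplit("_rep", 1)[0] for s in samples})
        if len(conds) != 2:
            raise ConfigurationError(
                f"expected 2 conditions from sample labels, got {conds}")
        labels_map = {c: [s for s in samples if s.startswith(c + "_rep")]
                      for c in conds}
    labels = [(conds[0], labels_map[conds[0]]), (conds[1], labels_map[conds[1]])]

    qc_reports = _run_qc(config, genes, reads, outdir, manifest)
    cm_fp, cm_m, te = _run_quantify(config, genes, reads, outdir, manifest)
    called, summary = _run_difftrans(config, cm_fp, cm_m, te, labels,
                                     outdir, manifest)
    feats, comps = _run_utrfeat(config, genes, called, outdir, manifest)
    enrich = _run_enrich(config, te, truth, called, outdir, manifest)

    _write_json(manifest, outdir / "manifest.json")
    return {"qc": qc_reports, "te": te, "dtg": called, "dtg_summary": summary,
            "features": feats, "feature_comparisons": comps,
            "enrichment": enrich, "manifest": manifest}


def _versions() -> dict:
    import scipy
    return {"riboprof": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}
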