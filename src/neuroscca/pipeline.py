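"""End-to-end pipeline: QC -> candidate selection -> group-wise SCCA ->
prediction validation -> mediation screen -> enrichment.

A YAML config names the input files and per-stage parameters.  Each stage
writes its outputs under the run directory and records input/output SHA-256
hashes in a deterministic manifest, so reruns with unchanged inputs are
skipped (resume) and identical seeds reproduce byte-identical outputs.
Wall-clock timings go to the log file only, never into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, ROI_COLUMNS
from .plinkio import read_plink
from .qc import QcThresholds, apply_qc
from .selection import clump, read_summary_stats
from .scca import groupwise_scca
from .validation import cross_group_validate, model_comparison_suite
from .mediation import mediation_screen
from .enrichment import read_gmt, map_snps_to_genes, fisher_enrichment, enrichment_frame

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]

log = logging.getLogger("neuroscca")

STAGES = ("qc", "select", "scca", "validate", "mediate", "enrich")


@dataclass
class PipelineConfig:
    """Paths + per-stage parameters; see ``from_yaml``."""

    bfile: str
    pheno: str
    stats: str
    gmt: str
    annotation: str
    out_dir: str
    seed: int = 0
    qc: dict = field(default_factory=dict)
    select: dict = field(default_factory=lambda: {
        "p_threshold": 1e-4, "r2_threshold": 0.1, "window_kb": 250.0})
    scca: dict = field(default_factory=lambda: {"tau1": None, "tau2": None, "top_k": 10})
    validate: dict = field(default_factory=lambda: {"folds": 5, "repeats": 10})
    mediate: dict = field(default_factory=lambda: {"n_sim": 1000, "rois": None})
    enrich: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        return {"bed": self.bfile + ".bed", "bim": self.bfile + ".bim",
                "fam": self.bfile + ".fam", "pheno": self.pheno,
                "stats": self.stats, "gmt": self.gmt,
                "annotation": self.annotation}

    _PATH_FIELDS = ("bfile", "pheno", "stats", "gmt", "annotation", "out_dir")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded, so the
        same analysis in a different directory hashes identically)."""
        blob = json.dumps({k: v for k, v in self.__dict__.items()
                           if k not in self._PATH_FIELDS},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(df: pd.DataFrame, path: Path, config_hash: str, seed: int,
                index: bool = False) -> None:
    """Write a TSV with a provenance header comment."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())
            self.data.setdefault("stages", {})

    def stage_fresh(self, stage: str, in_hashes: dict[str, str],
                    outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None or rec.get("inputs") != in_hashes:
            return False
        if set(rec.get("outputs", {})) != {p.name for p in outputs}:
            return False
        return all(p.exists() for p in outputs)

    def record(self, stage: str, in_hashes: dict[str, str],
               outputs: list[Path], params: dict, seed: int) -> None:
        # outputs keyed by file name so the manifest is location-independent
        self.data["stages"][stage] = {
            "inputs": in_hashes,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "params": json.loads(json.dumps(params, sort_keys=True, default=str)),
            "seed": seed,
        }

    def save(self, header: dict) -> None:
        self.data.update(header)
        self.path.write_text(json.dumps(self.data, sort_keys=True, indent=1) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest dict.

    A stage is skipped when its recorded input hashes match and its outputs
    still exist; any failure aborts with the stage name, keeping partial
    outputs on disk.
    """
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name!r} missing: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    manifest = _Manifest(out / "manifest.json")
    logging.basicConfig(filename=out / "pipeline.log", level=logging.INFO, force=False)

    in_hashes = {k: _sha256(v) for k, v in config.input_paths().items()}
    pheno = pd.read_csv(config.pheno, sep="\t")
    roi_cols = [c for c in ROI_COLUMNS if c in pheno.columns] or \
        [c for c in pheno.columns if c.startswith("thk_")]

    def stage_inputs(*extra: Path) -> dict[str, str]:
        d = dict(in_hashes)
        d["config"] = chash
        for p in extra:
            d[p.name] = _sha256(p)
        return d

    def run_stage(stage: str, outputs: list[Path], fn, *extra_inputs: Path) -> None:
        sin = stage_inputs(*extra_inputs)
        if manifest.stage_fresh(stage, sin, outputs):
            log.info("stage %s: up to date, skipped", stage)
            return
        t0 = time.monotonic()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: %.2fs", stage, time.monotonic() - t0)
        manifest.record(stage, sin, outputs, getattr(config, stage, {}), seed)

    # ---- qc ---------------------------------------------------------------
    qc_out = [out / "qc_report.tsv", out / "qc_keep_samples.txt", out / "qc_keep_snps.txt"]

    def do_qc():
        G = read_plink(config.bfile)
        th = QcThresholds(**config.qc) if config.qc else QcThresholds()
        Gf, report = apply_qc(G, th)
        write_table(report.to_frame(), qc_out[0], chash, seed)
        qc_out[1].write_text("\n".join(Gf.sample_ids) + "\n")
        qc_out[2].write_text("\n".join(Gf.snp_ids) + "\n")

    run_stage("qc", qc_out, do_qc)

    G = read_plink(config.bfile)
    keep_s = qc_out[1].read_text().split()
    keep_m = qc_out[2].read_text().split()
    G = G.subset_samples(np.array([sid in set(keep_s) for sid in G.sample_ids]))
    G = G.select_snps(keep_m)
    pheno = pheno[pheno["sample_id"].isin(set(keep_s))].reset_index(drop=True)
    pheno = pheno.set_index("sample_id").loc[G.sample_ids].reset_index()

    # ---- select -------------------------------------------------------------
    sel_out = [out / "candidate_panel.tsv"]

    def do_select():
        stats = read_summary_stats(config.stats)
        panel = clump(G, stats, **config.select)
        write_table(panel.to_frame(), sel_out[0], chash, seed)

    run_stage("select", sel_out, do_select, *qc_out)
    panel_ids = read_table(sel_out[0])["index_snp"].astype(str).tolist()
    Gp = G.select_snps(panel_ids)

    # ---- scca ----------------------------------------------------------------
    scca_out = [out / "scca_weights.tsv", out / "scca_roi_loadings.tsv",
                out / "scca_summary.tsv", out / "top_snps.tsv"]

    def do_scca():
        res = groupwise_scca(Gp, pheno, tau1=config.scca.get("tau1"),
                             tau2=config.scca.get("tau2"),
                             top_k=config.scca.get("top_k", 10),
                             roi_cols=roi_cols)
        wrows, lrows, srows, trows = [], [], [], []
        for grp in ("neg", "pos", "total"):
            r = res[grp]["result"]
            for j, rec in enumerate(Gp.snps):
                if r.u[j] != 0.0:
                    wrows.append({"group": grp, "snp": rec.id, "chrom": rec.chrom,
                                  "pos": rec.pos, "weight": r.u[j]})
            for roi, w in res[grp]["roi_loadings"].items():
                lrows.append({"group": grp, "roi": roi, "loading": w})
            srows.append({"group": grp, "rho": r.rho, "n": res[grp]["n"],
                          "n_iter": r.n_iter, "converged": r.converged})
            for rank, sid in enumerate(res[grp]["top_snps"], 1):
                trows.append({"group": grp, "rank": rank, "snp": sid})
        write_table(pd.DataFrame(wrows), scca_out[0], chash, seed)
        write_table(pd.DataFrame(lrows), scca_out[1], chash, seed)
        write_table(pd.DataFrame(srows), scca_out[2], chash, seed)
        write_table(pd.DataFrame(trows), scca_out[3], chash, seed)

    run_stage("scca", scca_out, do_scca, sel_out[0])
    tops = read_table(scca_out[3])
    top_neg = tops.loc[tops["group"] == "neg", "snp"].astype(str).tolist()
    top_pos = tops.loc[tops["group"] == "pos", "snp"].astype(str).tolist()

    # ---- validate ---------------------------------------------------------------
    val_out = [out / "validation_cross_group.tsv", out / "validation_models.tsv",
               out / "validation_comparisons.tsv"]

    def do_validate():
        vkw = dict(config.validate)
        rep = cross_group_validate(Gp, pheno, top_neg, top_pos, seed=seed, **vkw)
        write_table(rep.to_frame(), val_out[0], chash, seed)
        frames, comps = [], []
        for grp, mask in (("neg", pheno["amyloid"] == 0), ("pos", pheno["amyloid"] == 1)):
            top10 = top_neg if grp == "neg" else top_pos
            r2, cmp_df = model_comparison_suite(
                Gp, pheno, mask.to_numpy(), top10, Gp.snp_ids, seed=seed, **vkw)
            f = r2.to_frame(); f.insert(0, "group", grp); frames.append(f)
            cmp_df.insert(0, "group", grp); comps.append(cmp_df)
        write_table(pd.concat(frames, ignore_index=True), val_out[1], chash, seed)
        write_table(pd.concat(comps, ignore_index=True), val_out[2], chash, seed)

    run_stage("validate", val_out, do_validate, scca_out[3])

    # ---- mediate -----------------------------------------------------------------
    med_out = [out / "mediation_long.tsv", out / "mediation_direct.tsv",
               out / "mediation_indirect.tsv"]

    def do_mediate():
        rois = config.mediate.get("rois") or roi_cols
        n_sim = config.mediate.get("n_sim", 1000)
        snp_set = list(dict.fromkeys(top_neg + top_pos))
        table, mats = mediation_screen(Gp, pheno, snp_set, rois,
                                       n_sim=n_sim, seed=seed)
        write_table(table, med_out[0], chash, seed)
        write_table(mats["direct"], med_out[1], chash, seed, index=True)
        write_table(mats["indirect"], med_out[2], chash, seed, index=True)

    run_stage("mediate", med_out, do_mediate, scca_out[3])

    # ---- enrich --------------------------------------------------------------------
    enr_out = [out / "enrichment_neg.tsv", out / "enrichment_pos.tsv"]

    def do_enrich():
        annot = pd.read_csv(config.annotation, sep="\t")
        coll = read_gmt(config.gmt)
        for grp, snps, path in (("neg", top_neg, enr_out[0]),
                                ("pos", top_pos, enr_out[1])):
            genes = map_snps_to_genes(snps, annot)
            rows = fisher_enrichment(genes, coll)
            df = enrichment_frame(rows)
            df.insert(0, "group", grp)
            write_table(df, path, chash, seed)

    run_stage("enrich", enr_out, do_enrich, scca_out[3])

    manifest.save({"config_hash": chash, "seed": seed})
    return manifest.data


def run_demo(out_dir: str | os.PathLike, seed: int = 0,
             n_samples: int = 600, n_snps: int = 172, n_causal: int = 10,
             repeats: int = 2, n_sim: int = 200) -> dict:
    """Simulate a cohort, write the fixture, and run the full pipeline.

    Problem sizes are scaled below the defaults so the demo completes in a
    few minutes on one core; identical seeds give byte-identical manifests.
    """
    from .simulate import SimulationConfig, simulate_cohort, write_fixture

    out = Path(out_dir)
    data_dir = out / "data"
    cfg = SimulationConfig(n_samples=n_samples, n_snps=n_snps,
                           n_causal=n_causal, seed=seed)
    cohort = simulate_cohort(cfg)
    paths = write_fixture(cohort, data_dir, config=cfg)

    pcfg = PipelineConfig(
        bfile=str(data_dir / "genotypes"), pheno=str(paths["pheno"]),
        stats=str(paths["stats"]), gmt=str(paths["gmt"]),
        annotation=str(paths["annotation"]), out_dir=str(out / "results"),
        seed=seed,
        # a few-hundred-SNP panel only powers relatedness detection for
        # near-duplicates: the method-of-moments PI_HAT noise floor is
        # ~1/sqrt(n_snps), so the genome-wide 0.125 threshold would flag
        # unrelated pairs wholesale
        qc={"ibd_pihat_max": 0.45},
        validate={"folds": 5, "repeats": repeats},
        mediate={"n_sim": n_sim, "rois": ["thk_global_l", "thk_global_r",
                                          "thk_temporal_l", "thk_temporal_r"]},
    )
    return run_pipeline(pcfg)
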