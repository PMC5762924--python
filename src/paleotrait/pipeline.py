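"""End-to-end orchestration with reproducible seeds and a run manifest.

A run either simulates a dataset or loads one from disk, then executes the
analysis stages in the order the statistics depend on one another:
filtering, trait association, composition with bootstrap CIs, PERMANOVA of
trait composition on climatic period, OMI ordination with its
randomization test, trait-niche models and Dunn tests, spatial
diagnostics, phylogenetic grafting/PGLS, and the error-injection
sensitivity analysis. Every stochastic stage draws its sub-seed from the
master seed via a fixed splitting rule, and a JSON manifest records
inputs, seeds, per-stage status, wall time and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import io_core, omi, permanova, phylo, sensitivity, spatial
from .synthetic_data import SimConfig, simulate_dataset
from .traits import cramers_v_matrix, filter_dataset

__all__ = ["RunConfig", "run_all", "load_run_config"]

STAGES = ("traits", "composition", "permanova", "omi", "spatial", "phylo", "sensitivity")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulate: dict | None = None          # SimConfig kwargs, or None to load
    inputs: dict | None = None            # paths: read_matrix, samples, traits
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seed: int = 0
    n_perm: int = 999
    bootstrap_B: int = 1000
    sensitivity_rates: tuple = (0.01, 0.05, 0.10, 0.20)
    sensitivity_reps: int = 200
    min_reads: int = 5

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed: SHA-256 of (master seed, stage)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for k, v in raw.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        setattr(cfg, k, v)
    if isinstance(cfg.stages, dict):
        merged = {s: True for s in STAGES}
        merged.update(cfg.stages)
        cfg.stages = merged
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str, **kw) -> str:
    df.to_csv(path, lineterminator="\n", **kw)
    return path


def run_all(cfg: RunConfig, outdir) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "inputs": {}}

    def record(stage: str, status: str, outputs: list[str], t0: float, error: str | None = None):
        manifest["stages"][stage] = {
            "status": status,
            "wall_time_s": round(time.monotonic() - t0, 3),
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
        }
        if error:
            manifest["stages"][stage]["error"] = error

    # --- data ---------------------------------------------------------
    t0 = time.monotonic()
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.stage_seed("simulate"))
        sim = simulate_dataset(SimConfig(**sim_kwargs))
        rm, st, tt = sim.read_matrix, sim.samples, sim.traits
        tree = sim.phylogeny
        paths = io_core.write_dataset(outdir, rm, st, tt)
        phylo.write_newick(tree, os.path.join(outdir, "phylogeny.nwk"))
        paths["phylogeny"] = os.path.join(outdir, "phylogeny.nwk")
        record("simulate", "ok", list(paths.values()), t0)
        manifest["inputs"] = {"simulate": sim_kwargs}
    else:
        rm, st, tt = io_core.read_dataset(
            cfg.inputs["read_matrix"], cfg.inputs["samples"], cfg.inputs["traits"],
            cfg.inputs.get("config"))
        tree = phylo.read_newick(cfg.inputs["phylogeny"]) if "phylogeny" in cfg.inputs else None
        manifest["inputs"] = {k: str(v) for k, v in cfg.inputs.items()}

    rm, tt, report = filter_dataset(rm, tt, min_reads=cfg.min_reads)
    st = st[st["sample_id"].isin(rm.index)].reset_index(drop=True)
    manifest["filter"] = {
        "motus_removed_rare": report.motus_removed_rare,
        "motus_removed_undefined": report.motus_removed_undefined,
        "reads_removed": report.reads_removed,
        "samples_removed_empty": report.samples_removed_empty,
        "samples_kept": int(rm.shape[0]), "motus_kept": int(rm.shape[1]),
    }
    periods = st.set_index("sample_id")["period"].loc[rm.index]

    failed_upstream: set[str] = set()

    def run_stage(stage: str, fn, deps: tuple = ()):  # small stage harness
        if not cfg.stages.get(stage, True):
            manifest["stages"][stage] = {"status": "skipped"}
            return
        if any(d in failed_upstream for d in deps):
            manifest["stages"][stage] = {"status": "skipped_failed_dependency"}
            failed_upstream.add(stage)
            return
        t0 = time.monotonic()
        try:
            outputs = fn()
            record(stage, "ok", outputs, t0)
        except Exception as exc:  # stage failure recorded, downstream skipped
            record(stage, "failed", [], t0, error=f"{type(exc).__name__}: {exc}")
            failed_upstream.add(stage)

    # --- stages -------------------------------------------------------
    def stage_traits():
        m = cramers_v_matrix(tt)
        return [_write_csv(m, os.path.join(outdir, "trait_association.csv"))]

    def stage_composition():
        table = comp.composition_table(rm, tt, st, B=cfg.bootstrap_B,
                                       seed=cfg.stage_seed("composition"))
        return [_write_csv(table, os.path.join(outdir, "composition.csv"), index=False)]

    def stage_permanova():
        rows = []
        rng = np.random.default_rng(cfg.stage_seed("permanova"))
        for trait in io_core.TRAITS:
            for weighting in ("reads", "motus"):
                shares = comp.sample_trait_shares(rm, tt, trait, weighting)
                d = permanova.bray_curtis(shares + 1e-12)
                res = permanova.permanova(d, periods.rename("period"),
                                          n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
                pw, letters = permanova.pairwise_permanova(
                    d, periods, n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
                term = res.terms.iloc[0]
                rows.append({
                    "trait": trait, "weighting": weighting,
                    "R2": term["R2"], "p": term["p"],
                    "letters": " ".join(f"{k}:{v}" for k, v in letters.items()),
                })
        return [_write_csv(pd.DataFrame(rows), os.path.join(outdir, "permanova_periods.csv"), index=False)]

    omi_scores: dict = {}

    def stage_omi():
        res = omi.omi_analysis(rm, periods)
        _, p, _ = omi.omi_randtest(rm, periods, n_perm=cfg.n_perm,
                                   seed=cfg.stage_seed("omi"))
        res.rand_p = p
        models = omi.trait_niche_models(res.species_scores, tt, n_perm=cfg.n_perm,
                                        seed=cfg.stage_seed("omi_models"))
        rows = []
        for trait, mm in models.items():
            for model_name, pr in mm.items():
                term = pr.term(trait)
                rows.append({"trait": trait, "model": model_name,
                             "R2": term["R2"], "p": term["p"]})
        dunn_rows = []
        for trait in io_core.TRAITS:
            for axis in ("axis1", "axis2"):
                dr = omi.dunn_test(res.species_scores[axis], tt[trait])
                for _, row in dr.pairwise.iterrows():
                    dunn_rows.append({"trait": trait, "axis": axis, **row.to_dict()})
        omi_scores["scores"] = res.species_scores
        out = [
            _write_csv(res.species_scores, os.path.join(outdir, "omi_scores.csv")),
            _write_csv(res.stats, os.path.join(outdir, "omi_stats.csv")),
            _write_csv(pd.DataFrame(rows), os.path.join(outdir, "trait_niche_models.csv"), index=False),
            _write_csv(pd.DataFrame(dunn_rows), os.path.join(outdir, "dunn_tests.csv"), index=False),
        ]
        with open(os.path.join(outdir, "omi_randtest.json"), "w", encoding="utf-8") as fh:
            json.dump({"mean_omi": res.mean_omi, "rand_p": p,
                       "eigenvalues": list(map(float, res.eigenvalues))}, fh, indent=2)
        out.append(os.path.join(outdir, "omi_randtest.json"))
        return out

    def stage_spatial():
        geo = spatial.haversine_matrix(st.set_index("sample_id").loc[rm.index].reset_index())
        shares = comp.sample_trait_shares(rm, tt, "myc_status", "reads")
        d = permanova.bray_curtis(shares + 1e-12)
        resid = permanova.residual_distances(d, periods.rename("period"))
        cg = spatial.mantel_correlogram(resid, geo, n_perm=min(cfg.n_perm, 199),
                                        seed=cfg.stage_seed("spatial"))
        mso = spatial.mso_decomposition(shares, periods, geo)
        infl = spatial.type1_inflation(
            geo, periods, sill=0.25, range_km=200.0, n_sims=100,
            n_perm=99, seed=cfg.stage_seed("spatial_t1"))
        out = [
            _write_csv(cg.table, os.path.join(outdir, "mantel_correlogram.csv"), index=False),
            _write_csv(mso.table, os.path.join(outdir, "mso.csv"), index=False),
        ]
        with open(os.path.join(outdir, "type1_inflation.json"), "w", encoding="utf-8") as fh:
            json.dump(infl, fh, indent=2)
        out.append(os.path.join(outdir, "type1_inflation.json"))
        return out

    def stage_phylo():
        if tree is None:
            raise io_core.ValidationError("no phylogeny available")
        scores = omi_scores.get("scores")
        if scores is None:
            scores = omi.omi_analysis(rm, periods).species_scores
        keep = [t for t in scores.index]
        sub = tree.clone(depth=1)
        sub.retain_taxa_with_labels(keep)
        rows = []
        for trait in io_core.TRAITS:
            tbl, lam = phylo.category_niche_means(
                scores.loc[:, "axis1"], tt[trait], sub)
            tbl.insert(0, "trait", trait)
            tbl["lambda_hat"] = lam
            rows.append(tbl)
        return [_write_csv(pd.concat(rows), os.path.join(outdir, "phylo_niche_means.csv"), index=False)]

    def stage_sensitivity():
        scfg = sensitivity.SensitivityConfig(
            error_rates=tuple(cfg.sensitivity_rates), n_reps=cfg.sensitivity_reps,
            seed=cfg.stage_seed("sensitivity"))
        curve = sensitivity.sensitivity_curve(rm, tt, scfg)
        summary = curve.groupby("rate")["correlation"].agg(
            median_r="median",
            q025=lambda s: s.quantile(0.025),
            q975=lambda s: s.quantile(0.975),
        ).reset_index()
        rerun = sensitivity.sensitivity_model_rerun(
            rm, tt, periods, rate=0.10, n_reps=min(cfg.sensitivity_reps, 50),
            n_perm=min(cfg.n_perm, 199), seed=cfg.stage_seed("sensitivity_rerun"))
        out = [
            _write_csv(curve, os.path.join(outdir, "sensitivity_curve.csv"), index=False),
            _write_csv(summary, os.path.join(outdir, "sensitivity_summary.csv"), index=False),
        ]
        with open(os.path.join(outdir, "sensitivity_rerun.json"), "w", encoding="utf-8") as fh:
            json.dump(rerun, fh, indent=2)
        out.append(os.path.join(outdir, "sensitivity_rerun.json"))
        return out

    run_stage("traits", stage_traits)
    run_stage("composition", stage_composition)
    run_stage("permanova", stage_permanova)
    run_stage("omi", stage_omi)
    run_stage("spatial", stage_spatial)
    run_stage("phylo", stage_phylo, deps=("omi",))
    run_stage("sensitivity", stage_sensitivity, deps=("omi",))

    import paleotrait

    manifest["versions"] = {"paleotrait": paleotrait.__version__,
                            "numpy": np.__version__, "pandas": pd.__version__}
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
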