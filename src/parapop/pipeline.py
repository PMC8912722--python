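"""End-to-end pipeline orchestration with seeded stages and cached reruns.

Stages run in dependency order: synth (or input files) -> stats ->
admixture -> abc -> compare.  Every random stage has an explicit seed
recorded in the run manifest; each stage's outputs are cached under a key
hashing its configuration and its upstream artifacts, so editing only a
late stage's configuration reruns only that stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abc import (default_priors, estimate_posteriors, goodness_of_fit,
                  model_posterior, reject, run_reference_table)
from .admixture import classify_introgression, gibbs_admixture, introgression_geography
from .coalescent import ScenarioSpec, summarize_series
from .demography import compare_scenarios, decline_ratios
from .genio import read_genepop, read_metadata_csv, write_genepop, write_structure_table
from .sumstats import amova, diversity_table, geography_regression, pairwise_fst, private_alleles
from .synth import StudyTemplate, generate_dataset, mini_template

STAGES = ("synth", "stats", "admixture", "abc", "compare")


@dataclass
class PipelineConfig:
    """Pipeline configuration: per-stage options, seeds and output layout."""

    outdir: str
    seed: int = 0
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        outdir = raw.pop("outdir")
        seed = raw.pop("seed", 0)
        return cls(outdir=outdir, seed=seed, stages=raw)

    def stage(self, name: str) -> dict:
        return dict(self.stages.get(name, {}) or {})

    def stage_seed(self, name: str) -> int:
        cfg = self.stage(name)
        if "seed" in cfg:
            return int(cfg["seed"])
        return int(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(STAGES.index(name),)).generate_state(1)[0] % 2**31)


def _key(name: str, cfg: dict, upstream: list[str]) -> str:
    payload = json.dumps([name, cfg, upstream], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the run manifest (also written to disk).

    A stage whose cache key matches the previous run is skipped and its
    artifacts reused.  On stage failure the pipeline halts with the stage
    name; completed artifacts are preserved.
    """
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    keys: list[str] = []

    def _run_stage(name, fn, artifacts):
        cfg = config.stage(name)
        if cfg.get("enabled", True) is False:
            manifest["stages"][name] = {"skipped": True}
            return
        seed = config.stage_seed(name)
        key = _key(name, {**cfg, "seed": seed}, list(keys))
        keys.append(key)
        keyfile = out / f"{name}.hash"
        paths = [out / a for a in artifacts]
        if keyfile.exists() and keyfile.read_text() == key and all(p.exists() for p in paths):
            manifest["stages"][name] = {"cached": True, "seed": seed, "key": key,
                                        "artifacts": [str(p) for p in paths]}
            return
        t0 = time.perf_counter()
        try:
            fn(cfg, seed)
        except Exception as exc:
            manifest["stages"][name] = {"failed": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise PipelineError(name, exc) from exc
        keyfile.write_text(key)
        manifest["stages"][name] = {"cached": False, "seed": seed, "key": key,
                                    "wall_time_s": round(time.perf_counter() - t0, 3),
                                    "artifacts": [str(p) for p in paths]}

    # ---- synth / input --------------------------------------------------
    def synth_stage(cfg, seed):
        if "genepop" in cfg:
            ds = read_genepop(cfg["genepop"])
            read_metadata_csv(cfg["metadata"], ds)
            truth = None
        else:
            overrides = cfg.get("overrides", {}) or {}
            template = (mini_template(**overrides) if cfg.get("template", "mini") == "mini"
                        else StudyTemplate(**overrides))
            ds, truth = generate_dataset(template, np.random.default_rng(seed))
        write_genepop(ds, out / "dataset.gen")
        write_structure_table(ds, out / "dataset.str")
        meta = ds.geography.copy()
        meta["species"] = [ds.species_of_pop[p] for p in meta.index]
        meta.to_csv(out / "meta.csv")
        if truth is not None:
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    _run_stage("synth", synth_stage, ["dataset.gen", "meta.csv"])

    def _load_dataset():
        ds = read_genepop(out / "dataset.gen",
                          pop_names=pd.read_csv(out / "meta.csv")["population"].tolist())
        read_metadata_csv(out / "meta.csv", ds)
        return ds

    # ---- stats ----------------------------------------------------------
    def stats_stage(cfg, seed):
        ds = _load_dataset()
        div = diversity_table(ds)
        res = amova(ds, "species/pop", n_permutations=int(cfg.get("permutations", 999)),
                    rng=seed)
        fst = pairwise_fst(ds)
        priv = private_alleles(ds)
        reg = {}
        for sp in ds.species:
            pops = [p for p in ds.populations if ds.species_of_pop[p] == sp]
            y = priv["pop_private_freq"].loc[pops]
            try:
                reg[sp] = geography_regression(y, ds.geography.loc[pops]).to_dict()
            except ValueError as exc:
                reg[sp] = {"error": str(exc)}
        result = {
            "config": cfg,
            "diversity": json.loads(div.summary.to_json()),
            "amova": {"phi": res.phi, "p_values": res.p_values,
                      "table": json.loads(res.table.to_json())},
            "pairwise_fst_within_species_mean": fst.within_species_mean,
            "private_freq_regression": reg,
        }
        (out / "stats.json").write_text(json.dumps(result, indent=2, default=str))
        fst.matrix.to_csv(out / "pairwise_fst.tsv", sep="\t")

    _run_stage("stats", stats_stage, ["stats.json"])

    # ---- admixture ------------------------------------------------------
    def admixture_stage(cfg, seed):
        ds = _load_dataset()
        run = gibbs_admixture(ds, K=int(cfg.get("K", 2)),
                              chain_len=int(cfg.get("chain_len", 2000)),
                              burn_in=cfg.get("burn_in", 0.2), seed=seed)
        q = pd.DataFrame(run.Q, columns=[f"Q{k + 1}" for k in range(run.K)])
        q.insert(0, "individual", run.individual_ids)
        q.to_csv(out / "admixture_Q.tsv", sep="\t", index=False)
        calls = classify_introgression(run.Q, ds.species_of_individual(),
                                       individual_ids=run.individual_ids)
        calls.to_csv(out / "introgression_calls.tsv", sep="\t", index=False)
        geo = introgression_geography(calls, ds)
        (out / "introgression_geography.json").write_text(
            json.dumps({"config": cfg, **geo}, indent=2, default=str))

    _run_stage("admixture", admixture_stage, ["admixture_Q.tsv", "introgression_calls.tsv"])

    # ---- abc ------------------------------------------------------------
    def abc_stage(cfg, seed):
        ds = _load_dataset()
        obs = summarize_series(ds)
        base = ScenarioSpec("SI", 1e3, 1e3, 1e3, 1e3, 1e3, 0, 0, 2e4, 1e4,
                            n_loci=ds.n_loci,
                            n_cau=int(cfg.get("n_sample", 20)),
                            n_mor=int(cfg.get("n_sample", 20)))
        table = run_reference_table(default_priors(), int(cfg.get("n_sim", 2000)),
                                    seed, base, out_path=out / "sims.tsv")
        n_keep = int(cfg.get("n_keep", max(len(table) // 10, 50)))
        rej = reject(table, obs, n_keep)
        sel = model_posterior(rej, method=cfg.get("method", "mnlogistic"))
        best = sel["pp"].idxmax()
        gof = goodness_of_fit(table[table["model"] == best], obs, rng=seed)
        per_model = {}
        for m in sel["pp"].index:
            sub = table[table["model"] == m]
            if len(sub) < 20:
                continue
            rej_m = reject(sub, obs, min(n_keep, len(sub) // 2))
            post = estimate_posteriors(rej_m)
            per_model[m] = json.loads(post.summary.to_json())
            post.adjusted.assign(weight=post.weights).to_csv(
                out / f"retained_{m}.tsv", sep="\t", index=False)
        result = {
            "config": cfg, "observed": obs.to_dict(),
            "pp": sel["pp"].to_dict(),
            "bayes_factors": json.loads(sel["bayes_factors"].to_json()),
            "best_model": best, "gof_p": gof,
            "posteriors": per_model,
        }
        (out / "abc_result.json").write_text(json.dumps(result, indent=2, default=str))

    _run_stage("abc", abc_stage, ["abc_result.json"])

    # ---- compare --------------------------------------------------------
    def compare_stage(cfg, seed):
        species = cfg.get("species", "cau")
        scen = cfg.get("scenarios", ["SC", "SI"])
        posts = []
        for m in scen:
            path = out / f"retained_{m}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"no retained set for scenario {m}")
            df = pd.read_csv(path, sep="\t")
            pe_summary = pd.DataFrame()
            from .abc import PosteriorEstimate

            pe = PosteriorEstimate(pe_summary, df.drop(columns=["weight"]),
                                   df["weight"].to_numpy())
            posts.append(decline_ratios(pe, species, scenario=m))
        report = compare_scenarios(posts[0], posts[1])
        report["config"] = cfg
        (out / "compare.json").write_text(json.dumps(report, indent=2, default=str))

    _run_stage("compare", compare_stage, ["compare.json"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
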