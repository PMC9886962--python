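"""End-to-end orchestration: QC -> structure -> tree/DAPC -> GEA -> LD ->
phenotype, driven by a single YAML config with one global seed.

Every stage derives its own sub-seed by stable hashing of the stage name, so
toggling one stage on or off never shifts another stage's randomness, and
rerunning with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from grazescan import admixture, dapc as dapc_mod, gea, ld, pheno as pheno_mod, qc, trees
from grazescan import io, simulate as sim

log = logging.getLogger("grazescan")

FLOAT_FMT = "%.10g"

DEFAULTS = {
    "seed": 0,
    "stages": {
        "qc": True,
        "structure": True,
        "tree": True,
        "dapc": True,
        "gea": True,
        "ld": True,
        "pheno": True,
        "regress": True,
    },
    "qc": {"maf": 0.05, "max_locus_missing": 0.5, "max_indiv_missing": 0.5},
    "structure": {
        "kmin": 1,
        "kmax": 4,
        "runs": 4,
        "n_init": 2,
        "max_iter": 500,
        "tol": 1e-5,
        "labels": ["sativa", "falcata"],
    },
    "tree": {"boot": 200},
    "dapc": {"max_k": 6},
    "gea": {
        "axes": "broken_stick",
        "robust": "mcd",
        "q_method": "storey",
        "q_max": 0.01,
        "r_max": 0.7,
        "vif_max": 5.0,
    },
    "ld": {"max_dist": 200_000, "bin": 10_000, "maf": 0.05},
    "pheno": {"alpha": 0.05, "group_by": "population"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_all(config: dict, outdir) -> dict:
    """Run every enabled stage; returns the manifest dictionary.

    Outputs are written under ``outdir``; a failing stage raises with the
    stage name while earlier outputs are kept.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config["stages"]
    manifest: dict = {"seed": seed, "config": config, "inputs": {}, "outputs": []}

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return outdir / name

    # ------------------------------------------------------------------ data
    truth = None
    if "simulate" in config:
        sim_cfg = sim.SimConfig(**{**config["simulate"], "seed": stage_seed(seed, "simulate")})
        log.info("simulating dataset: %d pops x %d", sim_cfg.n_pops, sim_cfg.n_per_pop)
        G, env, pheno_df, truth = sim.simulate_dataset(sim_cfg)
        io.write_dosage_tsv(emit("genotypes.tsv"), G)
        env_out = env.data.copy()
        if env.zones is not None:
            env_out.insert(0, "zone", env.zones)
        _write_tsv(env_out.reset_index(), emit("environment.tsv"))
        _write_tsv(pheno_df.reset_index(), emit("phenotypes.tsv"))
        with open(emit("truth.json"), "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        annotation = None
    else:
        inputs = config.get("inputs", {})
        gpath = inputs.get("genotypes")
        if gpath is None:
            raise ValueError("config needs either a 'simulate' section or inputs.genotypes")
        manifest["inputs"] = {k: _sha256(v) for k, v in inputs.items() if v}
        gpath = str(gpath)
        G = io.read_vcf(gpath) if gpath.endswith(".vcf") else io.read_dosage_tsv(gpath)
        env = io.read_env_table(inputs["env"]) if inputs.get("env") else None
        pheno_df = io.read_phenotypes(inputs["phenotypes"]) if inputs.get("phenotypes") else None
        annotation = io.read_annotation(inputs["annotation"]) if inputs.get("annotation") else None

    # -------------------------------------------------------------------- qc
    if stages.get("qc", True):
        p = config["qc"]
        G, rep_miss = qc.missingness_filter(
            G, p["max_locus_missing"], p["max_indiv_missing"]
        )
        G, rep_maf = qc.maf_filter(G, p["maf"])
        with open(emit("qc_report.json"), "w") as fh:
            json.dump(
                {"missingness": rep_miss.to_dict(), "maf": rep_maf.to_dict()},
                fh,
                indent=1,
                sort_keys=True,
            )
        log.info("QC: kept %d/%d loci", rep_maf.n_kept, rep_maf.n_in)
    G_imp = qc.impute_mean_dosage(G)

    # -------------------------------------------------------------- structure
    consensus_q = None
    if stages.get("structure", True):
        p = config["structure"]
        rng = np.random.default_rng(stage_seed(seed, "structure"))
        ks = list(range(p["kmin"], p["kmax"] + 1))
        logliks = np.empty((p["runs"], len(ks)))
        q_runs_by_k: dict[int, list[np.ndarray]] = {k: [] for k in ks}
        for r in range(p["runs"]):
            for ki, k in enumerate(ks):
                fit = admixture.fit_admixture(
                    G,
                    k,
                    seed=int(rng.integers(2**31)),
                    n_init=p["n_init"],
                    tol=p["tol"],
                    max_iter=p["max_iter"],
                )
                logliks[r, ki] = fit.loglik
                q_runs_by_k[k].append(fit.Q)
        ll_df = pd.DataFrame(logliks, columns=ks)
        table, k_star = admixture.evanno_delta_k(ll_df)
        _write_tsv(table.table, emit("evanno.tsv"))
        consensus_q = admixture.align_runs(q_runs_by_k[k_star])
        labels = p["labels"]
        qdf = pd.DataFrame(
            consensus_q,
            columns=[
                labels[i] if i < len(labels) else f"ancestry{i + 1}"
                for i in range(k_star)
            ],
        )
        qdf.insert(0, "id", G.individuals["id"].to_numpy())
        qdf.insert(1, "population", G.individuals["population"].to_numpy())
        _write_tsv(qdf, emit("q_matrix.tsv"))
        if k_star == 2:
            parentage = admixture.classify_by_parentage(
                consensus_q[:, 0], labels[0], labels[1]
            )
            _write_tsv(
                pd.DataFrame(
                    {"id": G.individuals["id"], "cluster": parentage}
                ),
                emit("parentage.tsv"),
            )
        log.info("structure: selected K=%d", k_star)

    # ------------------------------------------------------------------ tree
    if stages.get("tree", True):
        tree = trees.bootstrap_support(
            G, n_boot=config["tree"]["boot"], seed=stage_seed(seed, "tree")
        )
        (emit("tree.nwk")).write_text(tree.newick() + "\n")
        dm = trees.nei_distance(trees.population_freqs(G))
        _write_tsv(dm.to_frame(), emit("nei_distance.tsv"), index=True)

    # ------------------------------------------------------------------ dapc
    if stages.get("dapc", True):
        res = dapc_mod.dapc(
            G_imp, max_k=config["dapc"]["max_k"], seed=stage_seed(seed, "dapc")
        )
        out = pd.DataFrame(
            {"id": G.individuals["id"], "cluster": res.assignments}
        )
        for i in range(res.scores.shape[1]):
            out[f"ld{i + 1}"] = res.scores[:, i]
        _write_tsv(out, emit("dapc_assignments.tsv"))
        _write_tsv(
            res.bic.rename("bic").rename_axis("k").reset_index(), emit("dapc_bic.tsv")
        )
        log.info("dapc: %d clusters on %d PCs", res.n_clusters, res.n_pcs)

    # ------------------------------------------------------------------- gea
    if stages.get("gea", True) and env is not None:
        p = config["gea"]
        env_s, screen_report = gea.screen_predictors(env, p["r_max"], p["vif_max"])
        G_gea = io.restrict_to_env_sites(G_imp, env_s)
        scan = gea.rda_scan(
            G_gea,
            env_s,
            axes=p["axes"],
            robust=p["robust"],
            q_method=p["q_method"],
            q_max=p["q_max"],
            annotation=annotation,
            seed=stage_seed(seed, "gea"),
        )
        _write_tsv(scan.table, emit("gea_results.tsv"))
        _write_tsv(screen_report, emit("gea_predictor_screen.tsv"))
        with open(emit("gea_summary.json"), "w") as fh:
            json.dump(
                {
                    "k_axes": scan.k_axes,
                    "lambda": scan.lam,
                    "n_outliers": int(scan.table["outlier"].sum()),
                    "predictors": scan.model.predictor_names,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        log.info("gea: %d outliers, lambda=%.3f", scan.table["outlier"].sum(), scan.lam)

    # -------------------------------------------------------------------- ld
    if stages.get("ld", True):
        p = config["ld"]
        pairs = ld.pairwise_r2(G, max_dist_bp=p["max_dist"], maf_min=p["maf"])
        _write_tsv(pairs, emit("ld_pairs.tsv"))
        if len(pairs):
            curve = ld.decay_curve(pairs, bin_width_bp=p["bin"])
            _write_tsv(curve, emit("ld_curve.tsv"))
            td = ld.threshold_distance(curve, pairs)
            with open(emit("ld_summary.json"), "w") as fh:
                json.dump(
                    {
                        "first_crossing_bp": td.first_crossing_bp,
                        "mean_subthreshold_bp": td.mean_subthreshold_bp,
                        "r2_threshold": td.r2_threshold,
                        "n_pairs": int(len(pairs)),
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )

    # ----------------------------------------------------------------- pheno
    if stages.get("pheno", True) and pheno_df is not None:
        p = config["pheno"]
        merged = pheno_df.join(
            G.individuals.set_index("id")[[p["group_by"]]], how="inner"
        )
        rows = []
        for trait in pheno_df.columns:
            tk = pheno_mod.anova_tukey(
                merged[trait].to_numpy(),
                merged[p["group_by"]].to_numpy(),
                alpha=p["alpha"],
            )
            tt = tk.table.copy()
            tt.insert(0, "trait", trait)
            tt["f_stat"] = tk.f_stat
            tt["p_value"] = tk.p_value
            tt["sem"] = tk.sem
            rows.append(tt)
        _write_tsv(pd.concat(rows, ignore_index=True), emit("tukey.tsv"))

    if stages.get("regress", True) and pheno_df is not None and consensus_q is not None:
        aligned = pheno_df.reindex(G.individuals["id"])
        rows = []
        for trait in pheno_df.columns:
            res = pheno_mod.membership_regression(
                aligned[trait].to_numpy(), consensus_q[:, 0], trait=trait
            )
            rows.append(res.__dict__)
        _write_tsv(pd.DataFrame(rows), emit("membership_regression.tsv"))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
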