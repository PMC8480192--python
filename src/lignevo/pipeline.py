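"""End-to-end orchestration with a config file and a run manifest.

Stage order mirrors the analysis: read/validate inputs (or generate the
synthetic set), fit the global birth-death rate and score families, detect
fast families, tune the wknn lifestyle classifier, predict ancestral
lifestyles from the reconstructed repertoires, run the phylogenetic
ordination (pPCA + PERMANOVA + pairwise FDR), compute diversity indices
per group, and type POD sequences/ancestors.  Outputs are TSV/Newick/JSON
written deterministically; a manifest records inputs, parameters, seeds
and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bdp, divstats, ordination, pod, synth, wknn
from .coreio import (GeneCountMatrix, read_counts, read_labels, read_msa,
                     read_newick, read_site_map, validate_bundle,
                     write_counts, write_labels, write_newick)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("lignevo")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "lignevo_out",
    "inputs": {          # all optional; missing ones are simulated
        "tree": None, "counts": None, "labels": None,
        "alignment": None, "site_map": None, "pod_tree": None,
        "pod_time_tree": None,
    },
    "stages": {
        "bdp": True, "lifestyles": True, "ordination": True,
        "diversity": True, "pod": False,
    },
    "bdp": {"n_sim": 1000, "alpha": 0.01,
            "lambda_bounds": [1e-6, 10.0],
            "lambda": None},       # fix the rate instead of estimating it
    "wknn": {"k_max": 25, "ds": [1.0, 2.0], "scale": True,
             "features": "fast"},   # "fast" = detected fast families, or "all"
    "ordination": {"n_perm": 999, "mode": "cov", "plot": False},
    "pod": {"tail_threshold": pod.DEFAULT_TAIL_THRESHOLD,
            "asr_model": "WAG", "tail_policy": "descendant_median"},
    "synthetic": {"preset": "agaricales", "n_tips": None},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(path_or_dict) -> dict:
    """Merge a user config (YAML path or dict) over the defaults;
    unknown top-level keys are rejected."""
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    unknown = set(user) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            bad = set(v) - set(cfg[k])
            if bad:
                raise ValueError(f"unknown config keys under {k!r}: {sorted(bad)}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_fmt: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_fmt)


def run_pipeline(config) -> dict:
    """Run the configured stages; returns a result bundle (also on disk)."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": seed, "config": cfg, "outputs": {}}
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            fn()
            dt = time.time() - t0
            log.info("stage %-22s done in %6.2f s", name, dt)
            manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
        return deco

    inputs = cfg["inputs"]

    @stage("load-or-simulate")
    def _load():
        if inputs.get("tree"):
            results["tree"] = read_newick(inputs["tree"], unit="My")
            results["counts"] = read_counts(inputs["counts"])
            results["labels"] = read_labels(inputs["labels"])
            results["truth"] = None
            results["true_lifestyles"] = None
        else:
            preset_name = cfg["synthetic"]["preset"]
            preset = (synth.strong_signal_preset(seed)
                      if preset_name == "strong_signal"
                      else synth.agaricales_preset(seed))
            if cfg["synthetic"].get("n_tips"):
                preset.n_tips = int(cfg["synthetic"]["n_tips"])
            tree = synth.simulate_tree(preset.n_tips, preset.root_age,
                                       seed=seed)
            ls = synth.simulate_lifestyles(tree, preset.mk_rate, seed=seed + 1)
            gcm, truth = synth.simulate_counts(tree, ls, preset, seed=seed + 2)
            results["tree"] = tree
            results["counts"] = gcm
            results["labels"] = ls[tree.tip_names]
            results["true_lifestyles"] = ls
            results["truth"] = truth
            prov = f"generated by lignevo: preset={preset_name} seed={seed}"
            write_newick(tree, outdir / "tree.nwk")
            write_counts(gcm, outdir / "counts.tsv", provenance=prov)
            write_labels(results["labels"], outdir / "labels.tsv",
                         provenance=prov)
        report = validate_bundle(results["tree"], results["counts"],
                                 results["labels"])
        if report:
            raise ValueError("input bundle inconsistent: " + "; ".join(report))

    tree = results["tree"]
    gcm: GeneCountMatrix = results["counts"]
    labels: pd.Series = results["labels"]

    if cfg["stages"]["bdp"]:
        @stage("bdp-fit")
        def _bdp():
            res = bdp.analyze_families(tree, gcm, n_sim=cfg["bdp"]["n_sim"],
                                       seed=seed + 10,
                                       alpha=cfg["bdp"]["alpha"],
                                       lam=cfg["bdp"]["lambda"])
            results["bdp"] = res
            _write_tsv(res["family_table"], outdir / "family_table.tsv")
            _write_tsv(res["ancestral_counts"], outdir / "ancestral_counts.tsv")
            branch = pd.concat({f: r.branch_table.set_index(["parent", "child"])
                                for f, r in res["per_family"].items()},
                               names=["family"])
            _write_tsv(branch, outdir / "branch_table.tsv")
            (outdir / "fast_families.txt").write_text(
                "\n".join(res["fast_families"]) + "\n")
            # annotated tree: node comments carry the reconstructed counts
            # of the fast families (or the first five focal ones)
            show = res["fast_families"] or gcm.families[:5]
            anc = res["ancestral_counts"]
            ann = {n: ",".join(f"{f}={int(anc.loc[n, f])}" for f in show)
                   for n in tree.names}
            write_newick(tree, outdir / "tree_ancestral_counts.nwk",
                         annotations=ann)

    if cfg["stages"]["lifestyles"]:
        @stage("wknn-tune+ancestors")
        def _wknn():
            feats = (results["bdp"]["fast_families"]
                     if cfg["wknn"]["features"] == "fast" and "bdp" in results
                     else gcm.families)
            feats = [f for f in feats if gcm.roles[f] == "focal"] or gcm.families
            X = gcm.counts[feats].astype(float)
            tuning = wknn.tune(X, labels,
                               ks=range(1, cfg["wknn"]["k_max"] + 1),
                               ds=tuple(cfg["wknn"]["ds"]),
                               scale=cfg["wknn"]["scale"])
            results["tuning"] = tuning
            _write_tsv(tuning.grid, outdir / "wknn_grid.tsv")
            sel = {"k": tuning.model.k, "kernel": tuning.model.kernel,
                   "d": tuning.model.d, "accuracy": tuning.best_accuracy,
                   "features": feats}
            (outdir / "wknn_model.yaml").write_text(yaml.safe_dump(sel))
            if "bdp" in results:
                anc = results["bdp"]["ancestral_counts"].loc[
                    tree.internal_names, feats].astype(float)
                pred, weights = wknn.predict_ancestral_lifestyles(
                    tuning.model, anc)
                results["ancestral_lifestyles"] = pred
                _write_tsv(weights, outdir / "ancestral_lifestyle_weights.tsv")
                write_labels(pred, outdir / "ancestral_lifestyles.tsv")
                ann = {n: f"lifestyle={v}" for n, v in pred.items()}
                write_newick(tree, outdir / "tree_lifestyles.nwk",
                             annotations=ann)

    if cfg["stages"]["ordination"]:
        @stage("ppca+permanova")
        def _ord():
            X = gcm.focal().astype(float)
            res = ordination.ppca(tree, X, mode=cfg["ordination"]["mode"])
            results["ppca"] = res
            anc = ordination.ancestral_scores(tree, res.scores)
            results["ancestral_scores"] = anc
            eig = pd.DataFrame({"eigenvalue": res.eigenvalues,
                                "percent_variance": res.percent_variance},
                               index=res.scores.columns)
            _write_tsv(eig, outdir / "ppca_eigen.tsv")
            _write_tsv(pd.concat([res.scores, anc]), outdir / "ppca_scores.tsv")
            n_pc = min(len(res.scores.columns), len(tree.tip_names) - 1)
            S = res.scores.iloc[:, :n_pc]
            pm = ordination.permanova(S, labels,
                                      n_perm=cfg["ordination"]["n_perm"],
                                      seed=seed + 20)
            pw = ordination.pairwise_permanova_fdr(
                S, labels, n_perm=cfg["ordination"]["n_perm"], seed=seed + 21)
            results["permanova"] = pm
            results["pairwise_permanova"] = pw
            _write_tsv(pw, outdir / "permanova_pairwise.tsv")
            (outdir / "permanova.json").write_text(json.dumps({
                "pseudo_F": pm.pseudo_F, "p_value": pm.p_value,
                "df_between": pm.df_between, "df_within": pm.df_within,
                "n_permutations": pm.n_permutations}, indent=1))
            if cfg["ordination"]["plot"]:
                ordination.plot_phylomorphospace(
                    tree, res.scores, anc, labels,
                    str(outdir / "phylomorphospace.png"))

    if cfg["stages"]["diversity"]:
        @stage("diversity")
        def _div():
            rows = {}
            focal = gcm.focal()
            for g in sorted(labels.unique()):
                sub = focal.loc[[s for s in focal.index if labels[s] == g]]
                rows[g] = {"n_species": len(sub),
                           "total_genes": int(sub.values.sum()),
                           "diversity": divstats.diversity_index(
                               sub.mean(axis=0).to_numpy())}
            df = pd.DataFrame(rows).T
            results["diversity"] = df
            _write_tsv(df, outdir / "diversity.tsv")

    if cfg["stages"]["pod"]:
        @stage("pod")
        def _pod():
            if inputs.get("alignment"):
                msa = read_msa(inputs["alignment"])
                sm = read_site_map(inputs["site_map"])
                ptree = read_newick(inputs["pod_tree"], unit="subs")
            else:
                ptree = synth.simulate_tree(16, 1.0, seed=seed + 30,
                                            unit="subs")
                rng = np.random.default_rng(seed + 31)
                types = {t: rng.choice(list(synth.POD_TEMPLATES))
                         for t in ptree.tip_names}
                msa, sm = synth.simulate_pod_alignment(ptree, types,
                                                       seed=seed + 32)
            tips_prof = {sid: pod.extract_profile(msa, sm, sid)
                         for sid in msa.ids}
            tail_thr = cfg["pod"]["tail_threshold"]
            tip_types = pd.Series({s: pod.classify_pod(p, tail_thr)
                                   for s, p in tips_prof.items()})
            _write_tsv(tip_types.to_frame("pod_type"),
                       outdir / "pod_tip_types.tsv")
            cols = [c for k, c in sm.columns().items() if k != "tail_anchor"]
            asr = pod.marginal_asr(ptree, msa, cols,
                                   model=cfg["pod"]["asr_model"])
            tails = pd.Series({s: p.c_tail_length
                               for s, p in tips_prof.items()})
            anc = pod.classify_ancestors(
                asr, sm, tail_policy=cfg["pod"]["tail_policy"],
                tail_threshold=tail_thr, tree=ptree, tip_tail_lengths=tails)
            _write_tsv(anc, outdir / "pod_ancestor_types.tsv")
            results["pod_tip_types"] = tip_types
            results["pod_ancestors"] = anc
            if inputs.get("pod_time_tree"):
                ttree = read_newick(inputs["pod_time_tree"], unit="My")
                all_types = pd.concat([tip_types, anc["pod_type"]])
                origins = pod.map_type_origins(ttree, all_types)
                _write_tsv(origins, outdir / "pod_type_origins.tsv")
                results["pod_origins"] = origins
                ages = ttree.node_ages()
                ann = {n: f"type={all_types[n]},age={ages[i]:.4g}"
                       for i, n in enumerate(ttree.names)}
                write_newick(ttree, outdir / "pod_tree_typed.nwk",
                             annotations=ann)

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    results["manifest"] = manifest
    return results
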