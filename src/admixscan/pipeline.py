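"""End-to-end orchestration: simulate/ingest -> QC -> Fst/MDS -> admixture -> HSA -> trees.

A single structured YAML config drives every stage.  Each run writes its
tables and trees into the output directory together with a
``manifest.json`` mapping every artifact to its SHA-256 hash, the seeds
used and a config digest — re-running with the same config and seed
reproduces identical hashes.  Timings and progress go to the run log
(``run.log``), which is deliberately excluded from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import admixture as admix
from . import genotype_io as gio
from . import hsa as hsa_mod
from . import phylo
from . import popgen
from . import simulate as sim
from .mds import mds as _mds

log = logging.getLogger("admixscan")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def load_pipeline_config(source) -> dict:
    path = Path(source)
    if path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        from importlib import resources

        ref = resources.files("admixscan") / "scenarios" / f"{source}.yaml"
        raw = yaml.safe_load(ref.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    return raw


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_scheme(name: str, spec: dict) -> gio.GroupScheme:
    return gio.GroupScheme(name, {g: frozenset(p) for g, p in spec.items()})


def _scenario_raw(sc) -> dict:
    if isinstance(sc, dict):
        return sc
    path = Path(str(sc))
    if path.exists():
        return yaml.safe_load(path.read_text())
    from importlib import resources

    ref = resources.files("admixscan") / "scenarios" / f"{sc}.yaml"
    return yaml.safe_load(ref.read_text())


def validate_config(cfg: dict) -> None:
    """Cheap validation of cross-references before any compute."""
    if "scenario" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'scenario' or 'inputs' section")
    pops: set = set()
    if "scenario" in cfg:
        pops = {p["name"] for p in _scenario_raw(cfg["scenario"])["populations"]}
    for name, spec in cfg.get("group_schemes", {}).items():
        scheme = _build_scheme(name, spec)  # checks disjoint / non-empty
        if pops:
            unknown = set().union(*scheme.groups.values()) - pops
            if unknown:
                raise ConfigError(
                    f"group scheme {name!r} references unknown populations: "
                    f"{sorted(unknown)}"
                )


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Run all configured stages; returns the manifest dict."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    base_seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest: dict = {
        "seed": base_seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {},
    }

    def _register(path: Path):
        manifest["outputs"][path.name] = _sha256(path)

    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s starting", name)
        return time.time()

    try:
        # ------------------------------------------------------ data
        t0 = _stage("data")
        if "scenario" in cfg:
            sc = cfg["scenario"]
            config = (
                sim.scenario_from_dict(sc) if isinstance(sc, dict)
                else sim.load_scenario(sc)
            )
            config.seed = base_seed
            data = sim.simulate_dataset(config)
        else:
            paths = cfg["inputs"]
            G = gio.read_genotypes(paths["ped"], paths["map"])
            labels = gio.read_labels(paths["labels"])
            H = (
                gio.read_haplotypes(paths["haplotypes"], paths["map"])
                if "haplotypes" in paths
                else None
            )
            data = sim.SimulatedDataset(G, H, labels, None)
        log.info("stage data done in %.1fs", time.time() - t0)

        # ------------------------------------------------------ qc
        t0 = _stage("qc")
        qc_cfg = cfg.get("qc", {})
        G, report = gio.qc_filter(
            data.genotypes,
            min_call_rate=qc_cfg.get("min_call_rate", 0.9),
            autosomes_only=qc_cfg.get("autosomes_only", True),
        )
        (out / "qc_report.json").write_text(
            json.dumps(report.__dict__, indent=2) + "\n"
        )
        _register(out / "qc_report.json")
        log.info("stage qc done in %.1fs", time.time() - t0)

        # ------------------------------------------------------ fst + mds
        t0 = _stage("fst")
        freqs = popgen.allele_freqs(G, data.labels)
        fst = popgen.fst_matrix(freqs)
        fst.write_tsv(out / "fst_matrix.tsv")
        _register(out / "fst_matrix.tsv")
        log.info("stage fst done in %.1fs", time.time() - t0)

        t0 = _stage("mds")
        mds_cfg = cfg.get("mds", {})
        for dims in mds_cfg.get("dims", [2, 3]):
            emb = _mds(
                fst, dims=dims,
                tol=mds_cfg.get("tol", 1e-3),
                max_iter=mds_cfg.get("max_iter", 30),
            )
            emb.write_tsv(out / f"mds_{dims}d.tsv")
            _register(out / f"mds_{dims}d.tsv")
        log.info("stage mds done in %.1fs", time.time() - t0)

        # ------------------------------------------------------ admixture
        t0 = _stage("admixture")
        ad = cfg.get("admixture", {})
        thin = cfg.get("thinning", {})
        thinned = gio.thin_by_bmd(
            G.snp_map,
            target_spacing=thin.get("target_spacing_bp", 550_000),
            n_subsets=thin.get("n_subsets", 5),
        )
        n_datasets = min(ad.get("n_datasets", 2), len(thinned.subsets))
        fits = []
        for d in range(n_datasets):
            keep = np.isin(G.snp_map.snp_id, thinned.subsets[d])
            Gd = G.subset_snps(keep)
            for k in range(ad.get("k_min", 2), ad.get("k_max", 6) + 1):
                for s in range(ad.get("seeds_per_k", 2)):
                    fits.append(
                        admix.fit_admixture(
                            Gd, K=k,
                            seed=base_seed + 1000 * d + 10 * k + s,
                            tol=ad.get("tol", 1e-4),
                            max_iter=ad.get("max_iter", 100),
                            n_starts=ad.get("n_starts", 2),
                            burn_iters=ad.get("burn_iters", 10),
                            dataset_id=f"S{d + 1}",
                        )
                    )
        k_report = admix.select_k(fits, ssc_floor=ad.get("ssc_floor", 0.90))
        k_report.table.to_csv(out / "k_report.tsv", sep="\t")
        _register(out / "k_report.tsv")
        best = max(
            (f for f in fits if f.k == k_report.recommended_k),
            key=lambda f: f.loglik,
        )
        best.write_q(out / "admixture_q.tsv")
        best.write_p(out / "admixture_p.tsv")
        _register(out / "admixture_q.tsv")
        _register(out / "admixture_p.tsv")
        mean_q = admix.cluster_mean_q(best.q, data.labels, best.individual_ids)
        mean_q.to_csv(out / "population_mean_q.tsv", sep="\t")
        _register(out / "population_mean_q.tsv")
        log.info(
            "stage admixture done in %.1fs (recommended K=%d)",
            time.time() - t0, k_report.recommended_k,
        )

        # ------------------------------------------------------ cluster trees
        t0 = _stage("cluster_trees")
        ph = cfg.get("phylogeny", {})
        out_pop = ph.get("outgroup_population")
        outgroup_cluster = None
        if out_pop is not None:
            if out_pop not in mean_q.index:
                raise ConfigError(f"outgroup population {out_pop!r} not found")
            outgroup_cluster = mean_q.columns[
                int(np.argmax(mean_q.loc[out_pop].values))
            ]
        for dist in ph.get("distances", ["cavalli_chord", "nei_da"]):
            tree = phylo.bootstrap_cluster_tree(
                best.p,
                labels=[f"cluster{k + 1}" for k in range(best.k)],
                reps=ph.get("bootstrap_reps", 1000),
                distance=dist,
                outgroup=outgroup_cluster,
                seed=base_seed + 77,
            )
            phylo.write_newick(tree, out / f"cluster_tree_{dist}.nwk")
            _register(out / f"cluster_tree_{dist}.nwk")
        log.info("stage cluster_trees done in %.1fs", time.time() - t0)

        # ------------------------------------------------------ HSA
        if data.haplotypes is not None and "hsa" in cfg:
            t0 = _stage("hsa")
            hs = cfg["hsa"]
            schemes = {
                name: _build_scheme(name, spec)
                for name, spec in cfg.get("group_schemes", {}).items()
            }
            nrs = hsa_mod.NRSConfig(
                chromosomes_per_group=hs.get("chromosomes_per_group"),
                replicates=hs.get("replicates", 100),
                min_count=hs.get("min_count", 2),
                seed=base_seed + 101,
            )
            frames = []
            enc_cache: dict = {}

            def _windows_enc(size):
                if size not in enc_cache:
                    w = hsa_mod.make_windows(data.haplotypes.snp_map, size)
                    enc_cache[size] = (w, hsa_mod._encode_windows(
                        data.haplotypes, w))
                return enc_cache[size]

            for scheme_name in hs.get("schemes", []):
                for size in hs.get("window_sizes", [50_000, 100_000, 200_000]):
                    windows, enc = _windows_enc(size)
                    parts = hsa_mod.classify_shared(
                        data.haplotypes, data.labels, schemes[scheme_name],
                        windows, nrs, encoding=enc,
                    )
                    df = hsa_mod.hs_summary(parts)
                    df.insert(0, "scheme", scheme_name)
                    frames.append(df)
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(
                out / "hs_summary.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
            _register(out / "hs_summary.tsv")
            log.info("stage hsa done in %.1fs", time.time() - t0)

            # -------------------------------------------------- HSA tree
            hd = cfg.get("hsa_distance")
            if hd:
                t0 = _stage("hsa_tree")
                scheme = schemes[hd["scheme"]]
                windows, enc = _windows_enc(hd.get("window_size", 100_000))
                nrs_d = hsa_mod.NRSConfig(
                    chromosomes_per_group=hs.get("chromosomes_per_group"),
                    replicates=hd.get("replicates", nrs.replicates),
                    min_count=hs.get("min_count", 2),
                    seed=base_seed + 202,
                )
                D = hsa_mod.hs_distance_matrix(
                    data.haplotypes, data.labels, scheme, windows, nrs_d,
                    encoding=enc,
                )
                D.write_tsv(out / "hs_distances.tsv")
                _register(out / "hs_distances.tsv")
                if len(D.labels) >= 3:
                    tree = phylo.neighbor_joining(D)
                    og = scheme.group_ids()[3] if len(scheme.group_ids()) > 3 else None
                    if og in D.labels:
                        tree = phylo.root_with_outgroup(tree, og)
                    phylo.write_newick(tree, out / "hs_tree.nwk")
                    _register(out / "hs_tree.nwk")
                log.info("stage hsa_tree done in %.1fs", time.time() - t0)
    except ConfigError:
        raise
    except Exception as exc:  # annotate with stage context
        raise StageError(
            f"pipeline aborted in stage {current_stage!r}: {exc}"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
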