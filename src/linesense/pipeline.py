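"""End-to-end orchestration: simulate (or load) a panel, fit line means and
variance components, compute sensitivity, scan, call and annotate
candidates, and run the network permutation test — all under one master
seed, with a manifest of every output file.

Per-age candidate genes from the control and treated scans are combined
before the network stage, and the network stage uses the stricter gene
input cutoff (default p < 1e-6) rather than the candidate-calling cutoff
(default p < 1e-5).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, linemodels, netperm, sensitivity as sens, simdata
from .config import AnalysisConfig, stage_rng
from .errors import DataError, LinesenseError

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def record(self, stage: str, wall_s: float, outputs: list[Path], info: dict | None = None):
        sums = {}
        for p in outputs:
            sums[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        self.stages[stage] = {
            "status": "ok",
            "wall_s": round(wall_s, 3),
            "outputs": sorted(str(p) for p in outputs),
            **(info or {}),
        }
        self.outputs.update(sums)

    def mark_failed(self, stage: str, err: Exception):
        self.stages[stage] = {"status": "failed", "error": f"{type(err).__name__}: {err}"}

    def write(self, path: Path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _corr_label(kind: str, index: int) -> str:
    if kind == "treatment":  # within-age, across treatments (weeks 1 and 5)
        return {0: "rGT1", 1: "rGT5"}.get(index, f"rGT[{index}]")
    return {0: "rGAC", 1: "rGAL"}.get(index, f"rGA[{index}]")


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """Execute every stage; returns the manifest (also written to the
    output directory).  A stage failure aborts the run with the stage name
    and cause; prior outputs and the manifest are retained."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("full_anova", _stage_full_anova),
        ("linemeans", _stage_linemeans),
        ("sensitivity", _stage_sensitivity),
        ("scan", _stage_scan),
        ("overlap", _stage_overlap),
        ("network", _stage_network),
    ]
    for name, fn in stages:
        if name == "full_anova" and not config.run_full_anova:
            continue
        if name == "sensitivity" and not config.run_sensitivity:
            continue
        t0 = time.perf_counter()
        try:
            outputs, info = fn(config, out, state)
        except LinesenseError as err:
            manifest.mark_failed(name, err)
            manifest.write(out / "manifest.json")
            raise DataError(f"pipeline stage {name!r} failed: {err}") from err
        manifest.record(name, time.perf_counter() - t0, outputs, info)
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: AnalysisConfig, out: Path, state: dict):
    sim_seed = int(stage_rng(config.seed, "simulate").integers(2**31))
    ds = simdata.simulate_dataset(config.sim.replace(seed=sim_seed))
    state["ds"] = ds
    paths = {
        "genotypes_tsv": out / "genotypes.tsv",
        "genotypes_vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.csv",
        "genes": out / "genes.bed",
        "network": out / "network.tsv",
        "truth": out / "ground_truth.json",
    }
    simdata.write_genotypes_tsv(ds.genotypes, paths["genotypes_tsv"])
    simdata.write_genotypes_vcf(ds.genotypes, paths["genotypes_vcf"])
    simdata.write_phenotypes_csv(ds.phenotypes, paths["phenotypes"])
    simdata.write_genes_bed(ds.genes, paths["genes"])
    simdata.write_network_tsv(ds.graph, paths["network"])
    simdata.write_ground_truth_json(ds.truth, paths["truth"])
    return list(paths.values()), {"sim_seed": sim_seed}


def _stage_full_anova(config: AnalysisConfig, out: Path, state: dict):
    ds = state["ds"]
    table = linemodels.fit_full_ancova(ds.phenotypes)
    p = out / "full_anova.csv"
    table.to_csv(p)
    return [p], None


def _stage_linemeans(config: AnalysisConfig, out: Path, state: dict):
    ds = state["ds"]
    sim = ds.config
    means, vcs = [], []
    for age in sim.ages:
        for tr in sim.treatments:
            means.append(linemodels.ls_line_means(ds.phenotypes, age, tr))
            vcs.append(linemodels.variance_components(ds.phenotypes, age, tr))
    linemeans = pd.concat(means, ignore_index=True)
    state["linemeans"] = linemeans
    state["vcs"] = {(vc.age, vc.treatment): vc for vc in vcs}

    p_means = out / "linemeans.csv"
    linemeans.to_csv(p_means, index=False)
    p_vc = out / "variance_components.csv"
    pd.DataFrame([dataclasses.asdict(vc) for vc in vcs]).to_csv(p_vc, index=False)

    corrs = {}
    sel = lambda a, t: linemeans[(linemeans.age == a) & (linemeans.treatment == t)]
    if len(sim.treatments) >= 2:
        t0, t1 = sim.treatments[:2]
        for i, age in enumerate(sim.ages):
            gc = linemodels.genetic_correlation(
                sel(age, t0), sel(age, t1),
                state["vcs"][(age, t0)], state["vcs"][(age, t1)],
                label=_corr_label("treatment", i),
            )
            corrs[gc.label] = dataclasses.asdict(gc)
    if len(sim.ages) >= 2:
        a0, a1 = sim.ages[:2]
        for j, tr in enumerate(sim.treatments):
            gc = linemodels.genetic_correlation(
                sel(a0, tr), sel(a1, tr),
                state["vcs"][(a0, tr)], state["vcs"][(a1, tr)],
                label=_corr_label("age", j),
            )
            corrs[gc.label] = dataclasses.asdict(gc)
    p_corr = out / "genetic_correlations.json"
    _json_dump(corrs, p_corr)
    return [p_means, p_vc, p_corr], None


def _stage_sensitivity(config: AnalysisConfig, out: Path, state: dict):
    ds = state["ds"]
    sim = ds.config
    control, treated = sim.treatments[0], sim.treatments[1]
    if config.sensitivity_on == "raw":
        frames = [
            linemodels.raw_line_means(ds.phenotypes, age, tr)
            for age in sim.ages
            for tr in (control, treated)
        ]
        base = pd.concat(frames, ignore_index=True)
    else:
        base = state["linemeans"]
    tabs = [
        sens.sensitivity_index(base, age, control=control, treated=treated) for age in sim.ages
    ]
    table = pd.concat(tabs, ignore_index=True)
    state["sensitivity"] = table
    p = out / "sensitivity.csv"
    table.to_csv(p, index=False)
    return [p], None


def _stage_scan(config: AnalysisConfig, out: Path, state: dict):
    ds = state["ds"]
    sim = ds.config
    linemeans = state["linemeans"]
    paths, scans = [], {}
    for age in sim.ages:
        for tr in sim.treatments:
            pheno = linemeans[(linemeans.age == age) & (linemeans.treatment == tr)]
            scan = assoc.run_scan(
                pheno, ds.genotypes, "trait", min_class=config.min_class_count
            )
            scans[("trait", age, tr)] = scan
            p = out / f"scan_trait_{age}_{tr}.tsv"
            scan.to_csv(p, sep="\t", index=False)
            paths.append(p)
    if config.run_sensitivity:
        control = sim.treatments[0]
        for age in sim.ages:
            s = state["sensitivity"]
            y = s[s.age == age].set_index("line_id")["S"]
            z = (
                linemeans[(linemeans.age == age) & (linemeans.treatment == control)]
                .set_index("line_id")["lsmean"]
            )
            scan = assoc.run_scan(
                y, ds.genotypes, "sensitivity_cofactor",
                cofactor=z, min_class=config.min_class_count,
            )
            scans[("sensitivity", age, None)] = scan
            p = out / f"scan_sensitivity_{age}.tsv"
            scan.to_csv(p, sep="\t", index=False)
            paths.append(p)
    state["scans"] = scans

    candidates = {}
    for key, scan in scans.items():
        model, age, tr = key
        label = f"{model}_{age}" + (f"_{tr}" if tr else "")
        cs = assoc.call_candidates(scan, config.candidate_threshold, label=label)
        cs = assoc.annotate_variants(cs, ds.genes, window=config.annotation_window)
        candidates[key] = cs
        p = out / f"candidates_{label}.tsv"
        cand_df = cs.variants.copy()
        cand_df["genes"] = [";".join(cs.gene_map.get(v, [])) for v in cand_df["variant_id"]]
        cand_df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    state["candidates"] = candidates
    counts = {
        f"{k[0]}_{k[1]}" + (f"_{k[2]}" if k[2] else ""): {
            "indels": cs.n_indels, "snps": cs.n_snps, "genes": cs.n_genes
        }
        for k, cs in candidates.items()
    }
    p = out / "candidate_counts.json"
    _json_dump(counts, p)
    paths.append(p)
    return paths, None


def _stage_overlap(config: AnalysisConfig, out: Path, state: dict):
    ds = state["ds"]
    sim = ds.config
    paths = []
    if len(sim.treatments) >= 2:
        t0, t1 = sim.treatments[:2]
        for age in sim.ages:
            rep = assoc.overlap_summary(
                state["candidates"][("trait", age, t0)],
                state["candidates"][("trait", age, t1)],
            )
            p = out / f"overlap_{age}.json"
            _json_dump(rep, p)
            paths.append(p)
    return paths, None


def _stage_network(config: AnalysisConfig, out: Path, state: dict):
    ds = state["ds"]
    sim = ds.config
    paths = []
    info = {}
    analyses: dict[str, set[str]] = {}
    for age in sim.ages:
        # trait network per age: control and treated candidates combined
        genes: set[str] = set()
        for key, scan in state["scans"].items():
            model, sage, tr = key
            if sage != age or model != "trait":
                continue
            cs = assoc.call_candidates(scan, config.network_gene_threshold)
            cs = assoc.annotate_variants(cs, ds.genes, window=config.annotation_window)
            genes |= set(cs.genes)
        analyses[f"trait_{age}"] = genes
        key = ("sensitivity", age, None)
        if key in state["scans"]:
            cs = assoc.call_candidates(state["scans"][key], config.network_gene_threshold)
            cs = assoc.annotate_variants(cs, ds.genes, window=config.annotation_window)
            analyses[f"sensitivity_{age}"] = set(cs.genes)

    for label, genes in analyses.items():
        if not genes:
            info[label] = "no candidate genes at the network threshold"
            continue
        seed = int(stage_rng(config.seed, f"network_{label}").integers(2**31))
        try:
            res = netperm.subnetwork_significance(
                ds.graph, genes, n_perm=config.n_permutations, seed=seed
            )
        except DataError as err:
            info[label] = str(err)
            continue
        node_rows, edge_rows = [], []
        for ci, comp in enumerate(res.components):
            hubs = netperm.classify_hubs(comp)
            hubs.insert(0, "component", ci)
            node_rows.append(hubs)
            edge_rows.extend((ci, u, v) for u, v in comp.edges)
        p_nodes = out / f"network_nodes_{label}.tsv"
        pd.concat(node_rows, ignore_index=True).to_csv(p_nodes, sep="\t", index=False)
        p_edges = out / f"network_edges_{label}.tsv"
        pd.DataFrame(edge_rows, columns=["component", "gene_a", "gene_b"]).to_csv(
            p_edges, sep="\t", index=False
        )
        p_sum = out / f"network_summary_{label}.json"
        _json_dump(
            {
                "n": res.n,
                "observed_size": res.observed_size,
                "n_perm": res.n_perm,
                "A": res.A,
                "p": res.p,
                "seed": res.seed,
                "n_components": len(res.components),
            },
            p_sum,
        )
        paths.extend([p_nodes, p_edges, p_sum])
        info[label] = f"p={res.p:.4g}, size={res.observed_size}"
    return paths, {"per_analysis": info}
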