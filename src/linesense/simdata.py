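"""Synthetic inbred-panel data generator.

Emulates a line-means association study: fully inbred genotypes coded 0/1
per line (two homozygous classes per biallelic site), individual phenotype
records following a factorial design (line x age x treatment, blocks nested
within age, body mass as covariate), gene models tiled along synthetic
chromosome arms, and a scale-free gene-interaction graph carrying a planted,
internally dense module.  Ground truth (causal variants, planted module,
realized line effects) is returned alongside so every downstream stage can
be tested for parameter recovery.

The phenotype model is

    value = c + age + treatment + L + L.A + L.T + L.A.T + block(age)
            + slope * (mass - mean mass) + error

with the four line terms drawn from independent normal components.  Causal
trait variants add an allelic effect to the line main term; causal
sensitivity variants add their effect to the line-by-treatment term of the
non-baseline treatment(s) only, so they shift a genotype's treatment
response without moving its baseline (control) mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimConfig, stage_rng
from .errors import ConfigurationError

CHROMOSOMES = ("2L", "2R", "3L", "3R", "X")
_GENE_PITCH = 5_000  # bp allotted per gene slot (gene body + intergenic gap)


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeTable:
    """Lines x variants homozygous genotype codes.

    ``matrix`` is (n_variants, n_lines) float32 with values 0, 1 or NaN
    (missing).  ``variants`` carries per-variant metadata (chrom, 1-based
    pos, snp/indel flag) in matrix row order.
    """

    variants: pd.DataFrame  # variant_id, chrom, pos, vtype
    matrix: np.ndarray
    line_ids: list[str]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[1]

    def row(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.matrix[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        geno = pd.DataFrame(self.matrix, columns=self.line_ids)
        return pd.concat([self.variants.reset_index(drop=True), geno], axis=1)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    causal_trait_variants: list[str] = field(default_factory=list)
    causal_sensitivity_variants: list[str] = field(default_factory=list)
    planted_module_genes: list[str] = field(default_factory=list)
    # realized line deviations, shape (n_lines, n_ages, n_treatments)
    true_line_effects: np.ndarray | None = None
    line_ids: list[str] = field(default_factory=list)
    ages: tuple[str, ...] = ()
    treatments: tuple[str, ...] = ()
    # component-implied correlations (exclude causal-variant contributions)
    true_genetic_correlations: dict[str, float] = field(default_factory=dict)
    # correlations of the realized line-effect draws
    realized_genetic_correlations: dict[str, float] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(**{**self.__dict__})
        for k, v in other.__dict__.items():
            cur = getattr(out, k)
            if cur is None or (hasattr(cur, "__len__") and len(cur) == 0):
                setattr(out, k, v)
        return out


@dataclass
class SimulatedDataset:
    config: SimConfig
    genotypes: GenotypeTable
    phenotypes: pd.DataFrame
    genes: pd.DataFrame
    graph: nx.Graph
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome layout


def genome_layout(config: SimConfig) -> dict[str, int]:
    """Deterministic chromosome lengths shared by the genotype and gene-model
    generators, so variant positions and gene bodies live on one coordinate
    system."""
    per_chrom = -(-config.network_n_genes // len(CHROMOSOMES))  # ceil
    length = per_chrom * _GENE_PITCH + _GENE_PITCH
    return {c: length for c in CHROMOSOMES}


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig) -> GenotypeTable:
    """Draw a lines x variants table of homozygous 0/1 codes.

    Each variant gets an alternate-allele frequency uniform on
    ``maf_range`` and independent Bernoulli line genotypes; positions are
    uniform over the synthetic genome; ~10% of variants are flagged indels.
    """
    config.validate()
    rng = stage_rng(config.seed, "genotypes")
    V, L = config.n_variants, config.n_lines

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=V)
    matrix = (rng.random((V, L)) < freqs[:, None]).astype(np.float32)

    layout = genome_layout(config)
    chroms = list(layout)
    lengths = np.array([layout[c] for c in chroms], dtype=float)
    offsets = np.concatenate([[0.0], np.cumsum(lengths)])
    flat = rng.uniform(0, offsets[-1], size=V)
    chrom_idx = np.searchsorted(offsets, flat, side="right") - 1
    pos = np.floor(flat - offsets[chrom_idx]).astype(np.int64) + 1
    vtype = np.where(rng.random(V) < 0.1, "indel", "snp")

    order = np.lexsort((pos, chrom_idx))
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:06d}" for i in range(V)],
            "chrom": [chroms[i] for i in chrom_idx[order]],
            "pos": pos[order],
            "vtype": vtype[order],
        }
    )
    line_ids = [f"line_{i + 1:03d}" for i in range(L)]
    return GenotypeTable(variants=variants, matrix=matrix[order], line_ids=line_ids)


# ---------------------------------------------------------------------------
# phenotypes


def _pick_causal(
    rng: np.random.Generator,
    all_ids: np.ndarray,
    n: int,
    pool: Sequence[str] | None,
    preference: float,
    taken: set[str],
) -> list[str]:
    """Sample ``n`` causal variant ids, preferring ``pool`` with the given
    probability per draw; never reuses ids in ``taken``."""
    avail_all = [v for v in all_ids if v not in taken]
    avail_pool = [v for v in (pool or []) if v not in taken]
    chosen: list[str] = []
    for _ in range(min(n, len(avail_all))):
        use_pool = avail_pool and (rng.random() < preference)
        src = avail_pool if use_pool else avail_all
        v = src[int(rng.integers(len(src)))]
        chosen.append(v)
        taken.add(v)
        avail_all.remove(v)
        if v in avail_pool:
            avail_pool.remove(v)
    return chosen


def simulate_phenotypes(
    config: SimConfig,
    genotypes: GenotypeTable,
    *,
    causal_trait_pool: Sequence[str] | None = None,
    causal_sensitivity_pool: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one record per individual under the factorial design.

    Returns the long-format phenotype table (line_id, age, treatment, block,
    mass_mg, trait, value) and the ground truth, including the realized
    (n_lines, n_ages, n_treatments) array of genetic line deviations.
    """
    config.validate()
    rng = stage_rng(config.seed, "phenotypes")
    L = config.n_lines
    ages, treats = config.ages, config.treatments
    A, T, R = len(ages), len(treats), config.n_flies_per_cell
    if genotypes.n_lines != L:
        raise ConfigurationError(
            f"genotype table has {genotypes.n_lines} lines, config says {L}"
        )

    ids = genotypes.variants["variant_id"].to_numpy()
    taken: set[str] = set()
    causal_trait = _pick_causal(
        rng, ids, config.n_causal_trait, causal_trait_pool, config.causal_module_preference, taken
    )
    causal_sens = _pick_causal(
        rng, ids, config.n_causal_sensitivity, causal_sensitivity_pool,
        config.causal_module_preference, taken,
    )

    gL = rng.normal(0, np.sqrt(config.var_line), L)
    gLA = rng.normal(0, np.sqrt(config.var_line_by_age), (L, A))
    gLT = rng.normal(0, np.sqrt(config.var_line_by_treatment), (L, T))
    gLAT = rng.normal(0, np.sqrt(config.var_line_by_age_by_treatment), (L, A, T))

    idx_of = {v: i for i, v in enumerate(ids)}
    a = config.causal_effect_size
    for v in causal_trait:
        gL = gL + a * np.nan_to_num(genotypes.matrix[idx_of[v]])
    for v in causal_sens:
        x = np.nan_to_num(genotypes.matrix[idx_of[v]])
        for t in range(1, T):  # non-baseline treatments only
            gLT[:, t] = gLT[:, t] + a * x

    G = gL[:, None, None] + gLA[:, :, None] + gLT[:, None, :] + gLAT  # (L,A,T)

    fixed = (
        config.constant
        + config.age_effect * np.arange(A)[:, None]
        + config.treatment_effect * np.arange(T)[None, :]
    )  # (A, T)

    B = config.n_blocks_per_age
    block_eff = rng.normal(0, np.sqrt(config.var_block), (A, B))
    block_of_rep = np.arange(R) % B  # balanced across lines and cells

    n_total = L * A * T * R
    line_mass_dev = rng.normal(0, config.mass_line_sd, L) if config.mass_line_sd > 0 else np.zeros(L)
    mass = rng.normal(config.mass_mean, config.mass_sd, (L, A, T, R)) + line_mass_dev[:, None, None, None]
    resid = rng.normal(0, np.sqrt(config.var_error), (L, A, T, R))

    be = block_eff[:, block_of_rep]  # (A, R)
    value = (
        fixed[None, :, :, None]
        + G[:, :, :, None]
        + be[None, :, None, :]
        + config.mass_slope * (mass - config.mass_mean)
        + resid
    )

    line_idx, age_idx, tr_idx, rep_idx = np.unravel_index(np.arange(n_total), (L, A, T, R))
    records = pd.DataFrame(
        {
            "line_id": np.array(genotypes.line_ids)[line_idx],
            "age": np.array(ages)[age_idx],
            "treatment": np.array(treats)[tr_idx],
            "block": np.array([f"b{b + 1}" for b in range(B)])[block_of_rep[rep_idx]],
            "mass_mg": mass.ravel(),
            "trait": config.trait,
            "value": value.ravel(),
        }
    )

    truth = GroundTruth(
        causal_trait_variants=causal_trait,
        causal_sensitivity_variants=causal_sens,
        true_line_effects=G,
        line_ids=list(genotypes.line_ids),
        ages=ages,
        treatments=treats,
        true_genetic_correlations=_component_correlations(config),
        realized_genetic_correlations=_realized_correlations(G, ages, treats),
    )
    return records, truth


def _component_correlations(config: SimConfig) -> dict[str, float]:
    """Correlations implied by the random variance components alone."""
    vL, vLA = config.var_line, config.var_line_by_age
    vLT, vLAT = config.var_line_by_treatment, config.var_line_by_age_by_treatment
    tot = vL + vLA + vLT + vLAT
    out: dict[str, float] = {}
    if tot <= 0:
        return out
    for i, age in enumerate(config.ages):
        if len(config.treatments) >= 2:
            out[_label("rGT", i, age)] = (vL + vLA) / tot
    for j, tr in enumerate(config.treatments):
        if len(config.ages) >= 2:
            out[_label_tr("rGA", j, tr)] = (vL + vLT) / tot
    return out


def _label(prefix: str, age_index: int, age: str) -> str:
    # conventional labels for a two-age design assayed at weeks 1 and 5
    if age_index == 0:
        return f"{prefix}1"
    if age_index == 1:
        return f"{prefix}5"
    return f"{prefix}[{age}]"


def _label_tr(prefix: str, tr_index: int, tr: str) -> str:
    if tr_index == 0:
        return f"{prefix}C"
    if tr_index == 1:
        return f"{prefix}L"
    return f"{prefix}[{tr}]"


def _realized_correlations(
    G: np.ndarray, ages: tuple[str, ...], treats: tuple[str, ...]
) -> dict[str, float]:
    out: dict[str, float] = {}
    for i, age in enumerate(ages):
        if len(treats) >= 2:
            out[_label("rGT", i, age)] = float(np.corrcoef(G[:, i, 0], G[:, i, 1])[0, 1])
    for j, tr in enumerate(treats):
        if len(ages) >= 2:
            out[_label_tr("rGA", j, tr)] = float(np.corrcoef(G[:, 0, j], G[:, 1, j])[0, 1])
    return out


# ---------------------------------------------------------------------------
# gene models and interaction network


def simulate_gene_models_and_network(
    config: SimConfig,
) -> tuple[pd.DataFrame, nx.Graph, GroundTruth]:
    """Tile gene models along the synthetic chromosomes and build a
    scale-free interaction graph with a planted connected module.

    The backbone is a preferential-attachment (Barabasi-Albert) graph.  With
    ``plant_module_edges`` (default) the module is a uniformly chosen gene
    set made internally dense by planting a random spanning tree plus
    ``module_extra_edges`` internal edges — mimicking a functional pathway,
    whose members interact far more among themselves than with the rest of
    the proteome.  With the switch off the module is a connected subgraph of
    the untouched backbone (grown by randomized BFS).
    """
    config.validate()
    rng = stage_rng(config.seed, "genes_network")
    layout = genome_layout(config)
    per_chrom = -(-config.network_n_genes // len(CHROMOSOMES))

    rows = []
    g = 0
    for chrom in CHROMOSOMES:
        for slot in range(per_chrom):
            if g >= config.network_n_genes:
                break
            slot_start = slot * _GENE_PITCH + 1
            start = slot_start + int(rng.integers(500, 2001))
            length = int(rng.integers(1000, 2501))
            rows.append(
                {
                    "gene_id": f"g{g + 1:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + length - 1,  # 1-based inclusive
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            g += 1
    genes = pd.DataFrame(rows)

    backbone_seed = int(rng.integers(2**31))
    graph = nx.barabasi_albert_graph(config.network_n_genes, config.network_attach_m, seed=backbone_seed)
    mapping = {i: genes["gene_id"].iloc[i] for i in range(config.network_n_genes)}
    graph = nx.relabel_nodes(graph, mapping)

    size = config.planted_module_size
    if config.plant_module_edges:
        module = list(rng.choice(genes["gene_id"].to_numpy(), size, replace=False))
        order = list(module)
        rng.shuffle(order)
        for i in range(1, len(order)):  # random spanning tree keeps it connected
            graph.add_edge(order[i], order[int(rng.integers(i))])
        for _ in range(config.module_extra_edges):
            u, v = rng.choice(module, 2, replace=False)
            if u != v:
                graph.add_edge(u, v)
    else:
        module = _bfs_module(graph, size, rng)

    truth = GroundTruth(planted_module_genes=sorted(module))
    return genes, graph, truth


def _bfs_module(graph: nx.Graph, size: int, rng: np.random.Generator) -> list[str]:
    nodes = sorted(graph.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    chosen = [start]
    members = {start}
    frontier = [start]
    while len(chosen) < size and frontier:
        nbrs = sorted({n for u in frontier for n in graph.neighbors(u)} - members)
        rng.shuffle(nbrs)
        take = nbrs[: size - len(chosen)]
        chosen.extend(take)
        members.update(take)
        frontier = take
    return chosen


# ---------------------------------------------------------------------------
# orchestration


def variants_in_genes(
    genotypes: GenotypeTable, genes: pd.DataFrame, gene_ids: Sequence[str] | None = None
) -> list[str]:
    """Variant ids whose position falls inside a gene body (optionally
    restricted to ``gene_ids``)."""
    sub = genes if gene_ids is None else genes[genes["gene_id"].isin(set(gene_ids))]
    hits: list[str] = []
    v = genotypes.variants
    for chrom, block in sub.groupby("chrom", sort=False):
        vc = v[v["chrom"] == chrom]
        if vc.empty:
            continue
        pos = vc["pos"].to_numpy()
        inside = np.zeros(len(vc), dtype=bool)
        for s, e in zip(block["start"].to_numpy(), block["end"].to_numpy()):
            inside |= (pos >= s) & (pos <= e)
        hits.extend(vc.loc[inside, "variant_id"].tolist())
    return hits


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full coordinated dataset: genotypes, gene models and
    network first, then phenotypes whose causal sensitivity variants are
    preferentially placed inside planted-module genes."""
    genotypes = simulate_genotypes(config)
    genes, graph, truth_net = simulate_gene_models_and_network(config)
    trait_pool = variants_in_genes(genotypes, genes)
    sens_pool = variants_in_genes(genotypes, genes, truth_net.planted_module_genes)
    phenotypes, truth = simulate_phenotypes(
        config,
        genotypes,
        causal_trait_pool=trait_pool,
        causal_sensitivity_pool=sens_pool,
    )
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        genes=genes,
        graph=graph,
        truth=truth.merged_with(truth_net),
    )


# ---------------------------------------------------------------------------
# writers (plain-text external formats)


def write_genotypes_tsv(genotypes: GenotypeTable, path: str | Path) -> None:
    df = genotypes.to_frame()
    for line in genotypes.line_ids:
        df[line] = df[line].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(genotypes: GenotypeTable, path: str | Path) -> None:
    """Minimal biallelic VCF with homozygous GT calls (inbred lines)."""
    chroms = genotypes.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=linesense-simdata\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.line_ids) + "\n")
        mat = genotypes.matrix
        for i, row in enumerate(genotypes.variants.itertuples(index=False)):
            ref, alt = ("AT", "A") if row.vtype == "indel" else ("A", "T")
            gts = [
                "./." if np.isnan(v) else ("1/1" if v == 1 else "0/0") for v in mat[i]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_phenotypes_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """BED6 (0-based half-open intervals)."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_network_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((min(e), max(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    d = {
        "causal_trait_variants": truth.causal_trait_variants,
        "causal_sensitivity_variants": truth.causal_sensitivity_variants,
        "planted_module_genes": truth.planted_module_genes,
        "true_genetic_correlations": truth.true_genetic_correlations,
        "realized_genetic_correlations": truth.realized_genetic_correlations,
        "line_ids": truth.line_ids,
        "ages": list(truth.ages),
        "treatments": list(truth.treatments),
        "true_line_effects": None
        if truth.true_line_effects is None
        else truth.true_line_effects.tolist(),
    }
    Path(path).write_text(json.dumps(d, indent=1))
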