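"""Single-marker association scans on line-level phenotypes.

Inbred lines carry one of two homozygous classes per biallelic site, so the
single-marker model ``y = u + m x + e`` reduces to a two-class comparison:
the allelic effect is the difference of class means and its t statistic has
n-2 degrees of freedom.  The sensitivity scan adds the trait line mean as a
cofactor (``sensitivity = u + g z + m x + e``) and reports the partial test
of the genotype term with n-3 df, so sensitivity hits are those that remain
after accounting for each variant's effect on the trait itself.

All per-variant statistics are computed in closed form over the whole
genotype matrix at once (complete cases per marker); variants that are
monomorphic, below the minor-class count floor, or collinear with the
cofactor are marked ``skipped`` and never receive a p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .simdata import GenotypeTable

DEFAULT_THRESHOLD = 1e-5
DEFAULT_MIN_CLASS = 4
DEFAULT_WINDOW = 5000

_TINY_P = np.finfo(float).tiny


@dataclass
class MarkerTestResult:
    variant_id: str
    n: int
    effect: float
    se: float
    stat: float
    p: float
    model: str
    status: str = "ok"  # or "skipped"
    reason: str = ""
    cofactor_coef: float | None = None


@dataclass
class CandidateSet:
    """Variants passing the scan threshold, with gene annotation."""

    label: str
    threshold: float
    variants: pd.DataFrame  # scan rows of the passing variants
    gene_map: dict[str, list[str]] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    @property
    def n_snps(self) -> int:
        return int((self.variants["vtype"] == "snp").sum()) if "vtype" in self.variants else 0

    @property
    def n_indels(self) -> int:
        return int((self.variants["vtype"] == "indel").sum()) if "vtype" in self.variants else 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# vectorized cores


def _finish_t(effect, se, dfree, ok):
    t = np.zeros_like(effect)
    pos = se > 0
    t[pos] = effect[pos] / se[pos]
    inf = ~pos & (effect != 0)  # perfect fit with nonzero effect
    t[inf] = np.inf * np.sign(effect[inf])
    p = np.ones_like(effect)
    finite = ok & np.isfinite(t) & (dfree > 0)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), dfree[finite])
    p[ok & ~np.isfinite(t)] = _TINY_P
    p = np.clip(p, _TINY_P, 1.0)
    return t, p


def _scan_trait(X: np.ndarray, y: np.ndarray, min_class: int) -> dict[str, np.ndarray]:
    """Closed-form two-class regression per row of X (NaN = missing)."""
    M = ~np.isnan(X)
    X1 = np.nan_to_num(X)
    y = np.asarray(y, float)
    n = M.sum(axis=1).astype(float)
    c1 = X1.sum(axis=1)
    c0 = n - c1
    s1 = X1 @ y
    s0 = M @ y - s1
    q1 = X1 @ (y * y)
    q0 = M @ (y * y) - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.divide(s1, c1, out=np.zeros_like(s1), where=c1 > 0)
        m0 = np.divide(s0, c0, out=np.zeros_like(s0), where=c0 > 0)
    effect = m1 - m0
    sse = np.maximum((q1 - c1 * m1**2) + (q0 - c0 * m0**2), 0.0)
    dfree = n - 2
    ok = (np.minimum(c0, c1) >= min_class) & (dfree >= 1)
    reason = np.where(
        np.minimum(c0, c1) == 0, "monomorphic", np.where(ok, "", "minor_class_below_minimum")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.divide(sse, dfree, out=np.zeros_like(sse), where=dfree > 0)
        se = np.sqrt(s2 * (1.0 / np.maximum(c0, 1) + 1.0 / np.maximum(c1, 1)))
    t, p = _finish_t(effect, se, dfree, ok)
    return {
        "n": n.astype(int), "effect": effect, "se": se, "stat": t, "p": p,
        "ok": ok, "reason": reason,
    }


def _scan_cofactor(
    X: np.ndarray, y: np.ndarray, z: np.ndarray, min_class: int
) -> dict[str, np.ndarray]:
    """Partial genotype test given the cofactor z, per row of X."""
    M = ~np.isnan(X)
    X1 = np.nan_to_num(X)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = M.sum(axis=1).astype(float)
    c1 = X1.sum(axis=1)
    c0 = n - c1
    Sz, Szz = M @ z, M @ (z * z)
    Sy, Syy = M @ y, M @ (y * y)
    Szy = M @ (y * z)
    Sxy, Szx = X1 @ y, X1 @ z

    with np.errstate(divide="ignore", invalid="ignore"):
        Czz = Szz - Sz**2 / n
        Czy = Szy - Sz * Sy / n
        Cxx = c1 - c1**2 / n  # x is 0/1 so sum x^2 = sum x
        Cxy = Sxy - c1 * Sy / n
        Czx = Szx - Sz * c1 / n
        Cyy = Syy - Sy**2 / n

    z_ok = Czz > 1e-12 * np.maximum(Szz, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rxx = np.where(z_ok, Cxx - np.divide(Czx**2, Czz, out=np.zeros_like(Czx), where=z_ok), Cxx)
        rxy = np.where(z_ok, Cxy - np.divide(Czx * Czy, Czz, out=np.zeros_like(Czx), where=z_ok), Cxy)
        ryy = np.where(z_ok, Cyy - np.divide(Czy**2, Czz, out=np.zeros_like(Czy), where=z_ok), Cyy)
    singular = rxx <= 1e-10 * np.maximum(Cxx, 1e-30)
    ok = (np.minimum(c0, c1) >= min_class) & (n - 3 >= 1) & ~singular & z_ok
    reason = np.where(
        np.minimum(c0, c1) == 0,
        "monomorphic",
        np.where(
            np.minimum(c0, c1) < min_class,
            "minor_class_below_minimum",
            np.where(singular | ~z_ok, "collinear_with_cofactor", ""),
        ),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.divide(rxy, rxx, out=np.zeros_like(rxy), where=rxx > 0)
        sse = np.maximum(ryy - np.divide(rxy**2, rxx, out=np.zeros_like(rxy), where=rxx > 0), 0.0)
        dfree = n - 3
        s2 = np.divide(sse, dfree, out=np.zeros_like(sse), where=dfree > 0)
        se = np.sqrt(np.divide(s2, rxx, out=np.zeros_like(s2), where=rxx > 0))
        bx = np.divide(Czx, Czz, out=np.zeros_like(Czx), where=z_ok)
        by = np.divide(Czy, Czz, out=np.zeros_like(Czy), where=z_ok)
    gamma = by - effect * bx
    t, p = _finish_t(effect, se, dfree, ok)
    return {
        "n": n.astype(int), "effect": effect, "se": se, "stat": t, "p": p,
        "ok": ok, "reason": reason, "cofactor_coef": gamma,
    }


# ---------------------------------------------------------------------------
# single-marker interfaces


def _complete(y, x, z=None):
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    keep = ~np.isnan(y) & ~np.isnan(x)
    if z is not None:
        z = np.asarray(z, float)
        keep &= ~np.isnan(z)
        return y[keep], x[keep], z[keep]
    return y[keep], x[keep], None


def marker_test(
    y: Sequence[float],
    x: Sequence[float],
    *,
    min_class: int = DEFAULT_MIN_CLASS,
    variant_id: str = "",
) -> MarkerTestResult:
    """OLS single-marker test of a line phenotype on a 0/1 genotype vector."""
    y2, x2, _ = _complete(y, x)
    r = _scan_trait(x2[None, :], y2, min_class)
    ok = bool(r["ok"][0])
    return MarkerTestResult(
        variant_id=variant_id,
        n=int(r["n"][0]),
        effect=float(r["effect"][0]),
        se=float(r["se"][0]),
        stat=float(r["stat"][0]),
        p=float(r["p"][0]),
        model="trait",
        status="ok" if ok else "skipped",
        reason=str(r["reason"][0]),
    )


def marker_test_with_cofactor(
    y_sens: Sequence[float],
    z: Sequence[float],
    x: Sequence[float],
    *,
    min_class: int = DEFAULT_MIN_CLASS,
    variant_id: str = "",
) -> MarkerTestResult:
    """Partial genotype test of a sensitivity phenotype given the trait
    cofactor z."""
    y2, x2, z2 = _complete(y_sens, x, z)
    r = _scan_cofactor(x2[None, :], y2, z2, min_class)
    ok = bool(r["ok"][0])
    return MarkerTestResult(
        variant_id=variant_id,
        n=int(r["n"][0]),
        effect=float(r["effect"][0]),
        se=float(r["se"][0]),
        stat=float(r["stat"][0]),
        p=float(r["p"][0]),
        model="sensitivity_cofactor",
        status="ok" if ok else "skipped",
        reason=str(r["reason"][0]),
        cofactor_coef=float(r["cofactor_coef"][0]),
    )


# ---------------------------------------------------------------------------
# whole-table scan


def run_scan(
    phenotype: pd.Series | pd.DataFrame,
    genotypes: GenotypeTable,
    model: str = "trait",
    *,
    cofactor: pd.Series | None = None,
    min_class: int = DEFAULT_MIN_CLASS,
) -> pd.DataFrame:
    """Scan every variant against a line-level phenotype.

    ``phenotype`` (and ``cofactor`` for the sensitivity model) are Series
    indexed by line id; lines are aligned by id, so consistent reordering of
    the inputs cannot change the result.  Returns one row per variant with
    columns variant_id, chrom, pos, vtype, n, effect, se, stat, p, status,
    reason, model (plus cofactor_coef for the sensitivity model).
    """
    if isinstance(phenotype, pd.DataFrame):
        phenotype = phenotype.set_index("line_id")["lsmean" if "lsmean" in phenotype else "S"]
    if model not in ("trait", "sensitivity_cofactor"):
        raise DataError(f"unknown model {model!r}")
    if model == "sensitivity_cofactor" and cofactor is None:
        raise DataError("sensitivity_cofactor model requires a cofactor series")

    shared = sorted(set(phenotype.index) & set(genotypes.line_ids))
    if model == "sensitivity_cofactor":
        shared = sorted(set(shared) & set(cofactor.index))
    y = phenotype.loc[shared].to_numpy(float)
    keep = ~np.isnan(y)
    z = None
    if model == "sensitivity_cofactor":
        z = cofactor.loc[shared].to_numpy(float)
        keep &= ~np.isnan(z)
        z = z[keep]
    shared = [s for s, k in zip(shared, keep) if k]
    y = y[keep]
    if len(shared) < 4:
        raise DataError(f"only {len(shared)} usable lines shared between phenotype and genotypes")

    col_idx = [genotypes.line_ids.index(s) for s in shared]
    X = genotypes.matrix[:, col_idx].astype(float)

    if model == "trait":
        r = _scan_trait(X, y, min_class)
    else:
        r = _scan_cofactor(X, y, z, min_class)

    out = genotypes.variants[["variant_id", "chrom", "pos", "vtype"]].copy()
    out["n"] = r["n"]
    out["effect"] = np.where(r["ok"], r["effect"], np.nan)
    out["se"] = np.where(r["ok"], r["se"], np.nan)
    out["stat"] = np.where(r["ok"], r["stat"], np.nan)
    out["p"] = np.where(r["ok"], r["p"], np.nan)
    out["status"] = np.where(r["ok"], "ok", "skipped")
    out["reason"] = r["reason"]
    out["model"] = model
    if "cofactor_coef" in r:
        out["cofactor_coef"] = np.where(r["ok"], r["cofactor_coef"], np.nan)
    if not r["ok"].any():
        raise DataError("no variant was testable (all monomorphic or under-count)")
    return out


# ---------------------------------------------------------------------------
# candidate calling, annotation, overlap


def call_candidates(
    scan: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD, label: str = ""
) -> CandidateSet:
    """Variants with p strictly below the nominal cutoff."""
    passing = scan[(scan["status"] == "ok") & (scan["p"] < threshold)].copy()
    return CandidateSet(label=label, threshold=threshold, variants=passing.reset_index(drop=True))


def annotate_variants(
    candidates: CandidateSet,
    genes: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> CandidateSet:
    """Map candidate variants to genes they fall in or near.

    A variant maps to a gene when its position lies inside [start, end] or
    strictly less than ``window`` bp from the nearer gene boundary; a
    variant within the window of several genes maps to all of them.
    Variants on chromosomes absent from the gene models are left
    unannotated with a warning.
    """
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    gene_map: dict[str, list[str]] = {}
    unknown = 0
    for row in candidates.variants.itertuples(index=False):
        block = by_chrom.get(row.chrom)
        if block is None:
            unknown += 1
            continue
        start = block["start"].to_numpy()
        end = block["end"].to_numpy()
        pos = row.pos
        gap = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
        hit = gap < window
        if hit.any():
            gene_map[row.variant_id] = block.loc[hit, "gene_id"].tolist()
    if unknown:
        warnings.warn(f"{unknown} candidate variant(s) on chromosomes absent from gene models")
    gene_list = sorted({g for gs in gene_map.values() for g in gs})
    return replace(candidates, gene_map=gene_map, genes=gene_list)


def overlap_summary(set_a: CandidateSet, set_b: CandidateSet) -> dict:
    """Gene-level intersection / union / exclusive lists for two candidate
    sets."""
    a, b = set(set_a.genes), set(set_b.genes)
    return {
        "label_a": set_a.label,
        "label_b": set_b.label,
        "n_a": len(a),
        "n_b": len(b),
        "intersection": sorted(a & b),
        "union": sorted(a | b),
        "only_a": sorted(a - b),
        "only_b": sorted(b - a),
        "n_intersection": len(a & b),
        "n_union": len(a | b),
    }
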