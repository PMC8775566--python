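"""Phenotype models on individual records from an inbred panel.

Four related fits:

* :func:`fit_full_ancova` — the full factorial ANCOVA
  ``value = c + mass + line*treatment*age + block(age) + error`` with
  partial (Type III-style) F tests per term, computed with sum-to-zero
  factor coding and full-vs-reduced model comparison.
* :func:`ls_line_means` — per (age, treatment) stratum, each line's
  least-squares mean: the model prediction at the stratum grand-mean body
  mass, averaging block effects with equal weight.
* :func:`variance_components` — among-line and residual variance by
  method of moments from a one-way ANOVA on mass-adjusted values, with the
  unbalanced-design effective replicate count
  ``n0 = (N - sum n_i^2 / N) / (k - 1)``.
* :func:`genetic_correlation` — ``cov12 / (sigma_L1 * sigma_L2)`` where
  ``cov12`` is the sample covariance of paired line means across two
  strata and the sigmas are square roots of the among-line variance
  components.  The estimator is reported as-is; |r| may exceed 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError

_MASS_EPS = 1e-10


@dataclass
class AncovaSpec:
    """Column mapping for the full ANCOVA."""

    response: str = "value"
    mass: str = "mass_mg"
    line: str = "line_id"
    treatment: str = "treatment"
    age: str = "age"
    block: str = "block"


@dataclass
class VarianceComponents:
    """Among-line variance decomposition for one (age, treatment) stratum."""

    age: str
    treatment: str
    var_line: float  # truncated at zero
    var_line_raw: float  # untruncated moment estimate
    var_error: float
    n0: float  # effective replicates per line
    ms_between: float
    ms_within: float
    n_lines: int
    n_obs: int


@dataclass
class GeneticCorrelation:
    """Cross-stratum genetic correlation from line means and variance
    components.  ``defined`` is False (and ``r`` is None) whenever either
    truncated among-line variance is zero."""

    label: str
    stratum_a: tuple[str, str]
    stratum_b: tuple[str, str]
    cov12: float
    r: float | None
    defined: bool
    n_lines: int


# ---------------------------------------------------------------------------
# factor coding helpers


def _sum_coded(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level,
    +1 at that level, -1 at the reference (first) level."""
    k = len(levels)
    out = np.zeros((len(labels), max(k - 1, 0)))
    ref = levels[0]
    for j, lev in enumerate(levels[1:]):
        out[labels == lev, j] = 1.0
        out[labels == ref, j] = -1.0
    return out


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise (Khatri-Rao) products of two coded factor blocks."""
    if a.shape[1] == 0 or b.shape[1] == 0:
        return np.zeros((a.shape[0], 0))
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _sse_of(G: np.ndarray, Xty: np.ndarray, yty: float, idx: np.ndarray) -> tuple[float, int]:
    """Residual SS and rank of the model restricted to columns ``idx``,
    solved from precomputed normal equations."""
    Gi = G[np.ix_(idx, idx)]
    bi = Xty[idx]
    beta, _, rank, _ = np.linalg.lstsq(Gi, bi, rcond=None)
    return float(yty - bi @ beta), int(rank)


# ---------------------------------------------------------------------------
# full factorial ANCOVA


def fit_full_ancova(records: pd.DataFrame, spec: AncovaSpec | None = None) -> pd.DataFrame:
    """Fit the full-design ANCOVA and return per-term partial F tests.

    Rows: mass, line, treatment, age, line:treatment, line:age,
    treatment:age, line:treatment:age, block(age), residual.  Columns: ss,
    df, ms, F, p.  On a balanced design the partial tests coincide with
    sequential ones because sum-coded terms are orthogonal.
    """
    spec = spec or AncovaSpec()
    df = records
    for col in (spec.response, spec.mass, spec.line, spec.treatment, spec.age, spec.block):
        if col not in df.columns:
            raise DataError(f"missing column {col!r}")
    mass = df[spec.mass].to_numpy(float)
    if not np.all(np.isfinite(mass)):
        raise DataError("body mass must be finite")

    lines = sorted(df[spec.line].unique())
    treats = sorted(df[spec.treatment].unique())
    ages = sorted(df[spec.age].unique())
    if min(len(lines), len(treats), len(ages)) < 2:
        raise DataError("need >=2 levels for each of line, treatment and age")

    # empty-cell check for the full interaction structure
    counts = df.groupby([spec.line, spec.age, spec.treatment], observed=True).size()
    for line in lines:
        for age in ages:
            for tr in treats:
                if (line, age, tr) not in counts.index:
                    raise DataError(
                        f"empty design cell: line={line!r}, age={age!r}, treatment={tr!r}"
                    )

    y = df[spec.response].to_numpy(float)
    lv = df[spec.line].to_numpy()
    tv = df[spec.treatment].to_numpy()
    av = df[spec.age].to_numpy()

    Xl = _sum_coded(lv, lines)
    Xt = _sum_coded(tv, treats)
    Xa = _sum_coded(av, ages)

    # block nested within age: deviation-coded blocks, separately per age
    blk_cols = []
    for age in ages:
        sel = av == age
        blevels = sorted(df.loc[sel, spec.block].unique())
        if len(blevels) < 2:
            continue
        coded = np.zeros((len(df), len(blevels) - 1))
        coded[sel] = _sum_coded(df.loc[sel, spec.block].to_numpy(), blevels)
        blk_cols.append(coded)
    Xb = np.hstack(blk_cols) if blk_cols else np.zeros((len(df), 0))

    terms: dict[str, np.ndarray] = {
        "mass": (mass - mass.mean())[:, None],
        "line": Xl,
        "treatment": Xt,
        "age": Xa,
        "line:treatment": _interact(Xl, Xt),
        "line:age": _interact(Xl, Xa),
        "treatment:age": _interact(Xt, Xa),
        "line:treatment:age": _interact(_interact(Xl, Xt), Xa),
        "block(age)": Xb,
    }
    blocks = [np.ones((len(df), 1))] + list(terms.values())
    X = np.hstack(blocks)
    spans: dict[str, np.ndarray] = {}
    start = 1
    for name, m in terms.items():
        spans[name] = np.arange(start, start + m.shape[1])
        start += m.shape[1]

    G = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    all_idx = np.arange(X.shape[1])
    sse_full, rank_full = _sse_of(G, Xty, yty, all_idx)
    df_resid = len(df) - rank_full
    if df_resid <= 0:
        raise DataError("no residual degrees of freedom in the full model")
    mse = sse_full / df_resid

    rows = []
    for name, cols in spans.items():
        if len(cols) == 0:
            continue
        reduced = np.setdiff1d(all_idx, cols)
        sse_red, rank_red = _sse_of(G, Xty, yty, reduced)
        ddf = rank_full - rank_red
        ss = max(sse_red - sse_full, 0.0)
        if ddf == 0:
            continue
        F = (ss / ddf) / mse if mse > 0 else np.inf
        p = float(stats.f.sf(F, ddf, df_resid)) if np.isfinite(F) else 0.0
        rows.append({"term": name, "ss": ss, "df": ddf, "ms": ss / ddf, "F": F, "p": p})
    rows.append(
        {"term": "residual", "ss": sse_full, "df": df_resid, "ms": mse, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# least-squares line means


def ls_line_means(
    records: pd.DataFrame,
    age: str,
    treatment: str,
    spec: AncovaSpec | None = None,
) -> pd.DataFrame:
    """Mass-adjusted least-squares mean per line within one stratum.

    Fits ``value = c + slope * mass + line + block + error`` with a common
    slope and evaluates each line at the stratum grand-mean mass with block
    effects averaged equally.  A constant mass drops the slope; lines absent
    from the stratum are omitted with a warning.
    """
    spec = spec or AncovaSpec()
    stratum = records[(records[spec.age] == age) & (records[spec.treatment] == treatment)]
    if stratum.empty:
        raise DataError(f"no records for age={age!r}, treatment={treatment!r}")
    omitted = set(records[spec.line].unique()) - set(stratum[spec.line].unique())
    if omitted:
        warnings.warn(
            f"{len(omitted)} line(s) with no flies in stratum ({age}, {treatment}) omitted",
            stacklevel=2,
        )
    lines = sorted(stratum[spec.line].unique())
    if len(lines) < 2:
        raise DataError("need >=2 lines in the stratum")

    y = stratum[spec.response].to_numpy(float)
    mass = stratum[spec.mass].to_numpy(float)
    lv = stratum[spec.line].to_numpy()

    cols = [np.ones(len(stratum))]
    use_mass = mass.std() > _MASS_EPS * max(1.0, abs(mass.mean()))
    if use_mass:
        cols.append(mass - mass.mean())
    line_dummies = np.column_stack([(lv == line).astype(float) for line in lines[1:]])
    cols.append(line_dummies)
    blevels = sorted(stratum[spec.block].unique())
    if len(blevels) > 1:
        cols.append(_sum_coded(stratum[spec.block].to_numpy(), blevels))
    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])

    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()

    rows = []
    p = X.shape[1]
    for i, line in enumerate(lines):
        x = np.zeros(p)
        x[0] = 1.0
        if i > 0:
            x[(2 if use_mass else 1) + (i - 1)] = 1.0
        lsmean = float(x @ fit.params)
        se = float(np.sqrt(max(x @ cov @ x, 0.0)))
        rows.append(
            {
                "line_id": line,
                "age": age,
                "treatment": treatment,
                "lsmean": lsmean,
                "se": se,
                "n": int((lv == line).sum()),
            }
        )
    return pd.DataFrame(rows)


def raw_line_means(
    records: pd.DataFrame, age: str, treatment: str, spec: AncovaSpec | None = None
) -> pd.DataFrame:
    """Unadjusted line means in the same schema as :func:`ls_line_means`."""
    spec = spec or AncovaSpec()
    stratum = records[(records[spec.age] == age) & (records[spec.treatment] == treatment)]
    if stratum.empty:
        raise DataError(f"no records for age={age!r}, treatment={treatment!r}")
    g = stratum.groupby(spec.line, observed=True)[spec.response]
    out = pd.DataFrame(
        {
            "line_id": g.mean().index,
            "age": age,
            "treatment": treatment,
            "lsmean": g.mean().to_numpy(),
            "se": (g.std(ddof=1) / np.sqrt(g.size())).to_numpy(),
            "n": g.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# variance components (method of moments)


def variance_components(
    records: pd.DataFrame,
    age: str,
    treatment: str,
    spec: AncovaSpec | None = None,
) -> VarianceComponents:
    """One-way method-of-moments variance decomposition on mass-adjusted
    values within one stratum.

    The common mass slope is estimated jointly with line effects (so body
    mass is adjusted without absorbing genetic signal), then
    ``sigma^2_e = MS_within`` and
    ``sigma^2_L = (MS_between - MS_within) / n0``.
    """
    spec = spec or AncovaSpec()
    stratum = records[(records[spec.age] == age) & (records[spec.treatment] == treatment)]
    if stratum.empty:
        raise DataError(f"no records for age={age!r}, treatment={treatment!r}")
    lv = stratum[spec.line].to_numpy()
    lines = sorted(stratum[spec.line].unique())
    k = len(lines)
    N = len(stratum)
    if k < 2:
        raise DataError("need >=2 lines")
    if N == k:
        raise DataError("all lines are singletons: residual variance inestimable")

    y = stratum[spec.response].to_numpy(float)
    mass = stratum[spec.mass].to_numpy(float)
    if mass.std() > _MASS_EPS * max(1.0, abs(mass.mean())):
        mc = mass - mass.mean()
        X = np.column_stack(
            [np.ones(N), mc] + [(lv == line).astype(float) for line in lines[1:]]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - beta[1] * mc

    n_i = np.array([(lv == line).sum() for line in lines], dtype=float)
    means = np.array([y[lv == line].mean() for line in lines])
    grand = y.mean()
    ss_within = float(sum(((y[lv == line] - means[i]) ** 2).sum() for i, line in enumerate(lines)))
    ms_within = ss_within / (N - k)
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ms_between = ss_between / (k - 1)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    raw = (ms_between - ms_within) / n0
    return VarianceComponents(
        age=age,
        treatment=treatment,
        var_line=max(raw, 0.0),
        var_line_raw=raw,
        var_error=ms_within,
        n0=float(n0),
        ms_between=ms_between,
        ms_within=ms_within,
        n_lines=k,
        n_obs=N,
    )


# ---------------------------------------------------------------------------
# genetic correlation


def genetic_correlation(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    vc_a: VarianceComponents,
    vc_b: VarianceComponents,
    label: str = "custom",
) -> GeneticCorrelation:
    """Genetic correlation between two strata: sample covariance of paired
    line means over shared lines, divided by the product of the square roots
    of the (truncated) among-line variance components."""
    a = means_a.set_index("line_id")["lsmean"]
    b = means_b.set_index("line_id")["lsmean"]
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise DataError(f"need >=3 shared lines, got {len(shared)}")
    av = a.loc[shared].to_numpy(float)
    bv = b.loc[shared].to_numpy(float)
    cov12 = float(np.cov(av, bv, ddof=1)[0, 1])
    if vc_a.var_line <= 0 or vc_b.var_line <= 0:
        return GeneticCorrelation(
            label=label,
            stratum_a=(vc_a.age, vc_a.treatment),
            stratum_b=(vc_b.age, vc_b.treatment),
            cov12=cov12,
            r=None,
            defined=False,
            n_lines=len(shared),
        )
    r = cov12 / float(np.sqrt(vc_a.var_line) * np.sqrt(vc_b.var_line))
    return GeneticCorrelation(
        label=label,
        stratum_a=(vc_a.age, vc_a.treatment),
        stratum_b=(vc_b.age, vc_b.treatment),
        cov12=cov12,
        r=r,
        defined=True,
        n_lines=len(shared),
    )
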