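"""Falconer sensitivity index: per-genotype treatment response scaled by
the panel-average response.

For line *i* at a given age, ``d_i`` is the treated minus control line mean
and ``D`` the mean of the ``d_j`` over every line with both treatment
means; the index is ``S_i = d_i / D``.  Positive values mean the treatment
enhanced the trait in that genotype, negative values that it impaired it,
and the included-line average of S is exactly 1 by construction.  Lines
missing either treatment mean are excluded from both the numerators and
the denominator average.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError, UndefinedPanelResponseError

DEFAULT_TOLERANCE = 1e-12


def sensitivity_index(
    linemeans: pd.DataFrame,
    age: str,
    *,
    control: str = "control",
    treated: str = "treated",
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Compute the sensitivity index from a line-means table at one age.

    ``linemeans`` must carry columns line_id, age, treatment, lsmean (as
    produced by :func:`linesense.linemodels.ls_line_means` or
    :func:`~linesense.linemodels.raw_line_means`).  Returns a table with
    columns line_id, age, d_i, D_bar, S.

    Raises :class:`UndefinedPanelResponseError` when the panel-average
    response |D| is at or below ``tolerance`` — the index is then undefined
    for every line and no silent infinities are produced.
    """
    sub = linemeans[linemeans["age"] == age]
    wide = sub.pivot_table(index="line_id", columns="treatment", values="lsmean", aggfunc="first")
    for lab in (control, treated):
        if lab not in wide.columns:
            raise DataError(f"no {lab!r} line means at age {age!r}")
    wide = wide[[control, treated]].dropna()
    if len(wide) < 2:
        raise DataError("need >=2 lines with both treatment means")
    d = wide[treated] - wide[control]
    D_bar = float(d.mean())
    if abs(D_bar) <= tolerance:
        raise UndefinedPanelResponseError(
            f"panel-average treatment response |D|={abs(D_bar):.3g} <= tolerance "
            f"{tolerance:.3g}: sensitivity undefined at age {age!r}"
        )
    out = pd.DataFrame(
        {
            "line_id": wide.index,
            "age": age,
            "d_i": d.to_numpy(),
            "D_bar": D_bar,
            "S": (d / D_bar).to_numpy(),
        }
    )
    return out.reset_index(drop=True)
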