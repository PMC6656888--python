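"""Dose-dependent candidate-target discovery.

A protein is a candidate intervention target when three conditions hold
jointly: it is elevated in the disease model versus control (p < alpha,
positive log2 fold change), suppressed by the highest treatment dose
versus the model (p < alpha, negative log2 fold change), and its group
means fall strictly monotonically along the dose ladder
model -> low -> medium -> high.  Strict monotonicity is scored as the
Spearman correlation of group mean against dose rank, requiring rho = -1;
a one-sided Jonckheere-Terpstra trend test is available as an alternative
criterion for noisier settings.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupDesign, IBAQTable, UsageError
from .ibaq import differential


def jonckheere_decreasing_p(samples: list[np.ndarray]) -> float:
    """One-sided Jonckheere-Terpstra p for a decreasing trend across ordered groups.

    Normal approximation without tie correction (values are continuous).
    """
    u = 0.0
    for (i, a), (j, b) in combinations(enumerate(samples), 2):
        # count pairs concordant with a DEcreasing trend: later group smaller
        u += float(np.sum(b[None, :] < a[:, None])) + 0.5 * float(
            np.sum(b[None, :] == a[:, None])
        )
    sizes = np.array([len(s) for s in samples], dtype=float)
    n = sizes.sum()
    mean = (n * n - (sizes**2).sum()) / 4.0
    var = (n * n * (2 * n + 3) - (sizes**2 * (2 * sizes + 3)).sum()) / 72.0
    if var == 0:
        return 1.0
    z = (u - mean) / np.sqrt(var)
    return float(stats.norm.sf(z))


def discover(
    ibaq: IBAQTable,
    design: GroupDesign,
    alpha: float = 0.05,
    monotone: str = "strict",
) -> pd.DataFrame:
    """Screen every protein for the disease-up / treatment-down / dose-monotone profile.

    Requires ``design.ladder`` of the form
    ``[control, model, dose_1, ..., dose_k]`` (k >= 2, low to high).  The
    positive-control arm, if any, must not be on the ladder.

    monotone="strict" demands strictly decreasing group means over
    model -> doses (Spearman rho of mean vs dose rank equal to -1);
    monotone="jt" instead requires a one-sided Jonckheere-Terpstra
    decreasing-trend p < alpha.

    Returns one row per protein with columns accession, up_log2fc, up_p,
    down_log2fc, down_p, monotone_stat, up_in_model,
    down_under_treatment, monotone_ok, passes — sorted by
    (passes desc, down_p asc, accession asc).
    """
    if monotone not in {"strict", "jt"}:
        raise UsageError(f"unknown monotone criterion {monotone!r}")
    ladder = design.ladder
    if len(ladder) < 4:
        raise UsageError(
            "ladder must list control, model and >= 2 dose groups (low to high)"
        )
    control, model, *doses = ladder
    design.require_groups(ladder, min_n=2)
    high = doses[-1]

    up = differential(ibaq, design, (control, model), alpha=alpha).set_index("accession")
    down = differential(ibaq, design, (model, high), alpha=alpha).set_index("accession")

    trend_groups = [model, *doses]
    cols = {g: design.samples(g) for g in trend_groups}
    dose_rank = np.arange(len(trend_groups))
    rows = []
    for acc in ibaq.norm.index:
        vals = [ibaq.norm.loc[acc, cols[g]].to_numpy(dtype=float) for g in trend_groups]
        means = np.array([v.mean() for v in vals])
        if monotone == "strict":
            if np.all(np.diff(means) < 0):
                stat = -1.0
            elif np.all(means == means[0]):
                stat = 0.0  # constant means: no trend, rho undefined
            else:
                stat = float(stats.spearmanr(dose_rank, means).statistic)
            mono_ok = stat == -1.0
        else:
            stat = jonckheere_decreasing_p(vals)
            mono_ok = stat < alpha
        up_p = float(up.loc[acc, "p"])
        up_fc = float(up.loc[acc, "log2fc"])
        down_p = float(down.loc[acc, "p"])
        down_fc = float(down.loc[acc, "log2fc"])
        up_ok = up_p < alpha and up_fc > 0
        down_ok = down_p < alpha and down_fc < 0
        rows.append({
            "accession": acc,
            "up_log2fc": up_fc,
            "up_p": up_p,
            "down_log2fc": down_fc,
            "down_p": down_p,
            "monotone_stat": stat,
            "up_in_model": up_ok,
            "down_under_treatment": down_ok,
            "monotone_ok": mono_ok,
            "passes": up_ok and down_ok and mono_ok,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(
        by=["passes", "down_p", "accession"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
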