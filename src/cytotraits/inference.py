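"""Treatment comparisons of functional diversity indices and bioassay calls.

Functional diversity indices are compared across treatments with a
Kruskal-Wallis test (small n, no normality assumption) followed by
Conover-Iman post hoc pairwise comparisons with Benjamini-Hochberg
correction at alpha = 0.01.  Nutrient-limitation bioassays are called from
4-day growth of chlorophyll-a fluorescence under +N / +P / +NP additions
relative to control.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "conover_iman",
    "bioassay_limitation",
]


def _as_groups(values) -> dict[str, np.ndarray]:
    if isinstance(values, dict):
        return {k: np.asarray(v, float) for k, v in values.items()}
    if isinstance(values, pd.DataFrame):
        if not {"treatment", "value"} <= set(values.columns):
            raise ValueError("DataFrame input needs 'treatment' and 'value' columns")
        return {
            t: g["value"].to_numpy(float) for t, g in values.groupby("treatment")
        }
    raise TypeError("expected a dict of arrays or a tidy DataFrame")


def kruskal_wallis(values) -> tuple[float, float]:
    """Rank-based H with tie correction; p from the chi-square approximation."""
    groups = _as_groups(values)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), float(p)


def conover_iman(values, alpha: float = 0.01) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons on pooled ranks, BH-adjusted.

    t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-g) * (1/n_i + 1/n_j)),
    with S^2 the tie-corrected variance of the pooled ranks and df = N - g.
    """
    groups = _as_groups(values)
    names = sorted(groups)
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    skipped = [k for k in names if k not in usable]

    pooled = np.concatenate([usable[k] for k in sorted(usable)])
    labels = np.concatenate(
        [np.full(usable[k].size, k) for k in sorted(usable)]
    )
    ranks = stats.rankdata(pooled)
    N, g = pooled.size, len(usable)
    H, _ = kruskal_wallis(usable)
    S2 = (np.sum(ranks ** 2) - N * (N + 1.0) ** 2 / 4.0) / (N - 1.0)
    df = N - g
    if df <= 0:
        raise ValueError("not enough observations for the Conover-Iman test")
    factor = S2 * (N - 1.0 - H) / df

    rows = []
    for a, b in combinations(sorted(usable), 2):
        ra = ranks[labels == a].mean()
        rb = ranks[labels == b].mean()
        na, nb = usable[a].size, usable[b].size
        se = np.sqrt(factor * (1.0 / na + 1.0 / nb))
        t = (ra - rb) / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append({"pair": f"{a} vs {b}", "statistic": float(t),
                     "p_raw": float(min(p, 1.0))})
    table = pd.DataFrame(rows)
    if len(table):
        _, p_adj, _, _ = multipletests(table["p_raw"], method="fdr_bh")
        table["p_adjusted"] = p_adj
        table["significant"] = table["p_adjusted"] <= alpha
    for k in skipped:
        table.attrs.setdefault("skipped_groups", []).append(k)
    return table


def bioassay_limitation(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Call the growth-limiting nutrient from a +N/+P/+NP addition bioassay.

    Per-replicate growth g = ln(day4/day0)/4.  Nutrient X is limiting when
    mean g(+X) exceeds mean g(control) in a one-sided Welch test at alpha;
    N+P co-limitation is called when only the combined addition responds.
    """
    required = {"control", "+N", "+P", "+NP"}
    present = set(table["treatment"])
    if not required <= present:
        raise ValueError(f"missing bioassay treatments: {sorted(required - present)}")
    if np.any(table["day0"] <= 0):
        raise ValueError("day-0 fluorescence must be strictly positive")
    work = table.copy()
    work["growth"] = np.log(work["day4"] / work["day0"]) / 4.0
    groups = {t: g["growth"].to_numpy() for t, g in work.groupby("treatment")}
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every bioassay treatment needs >= 2 replicates")

    pvals = {}
    for addition in ["+N", "+P", "+NP"]:
        if np.allclose(groups[addition], groups["control"]) and np.allclose(
            np.concatenate([groups[addition], groups["control"]]),
            groups["control"][0],
        ):
            pvals[addition] = 1.0
            continue
        _, p = stats.ttest_ind(
            groups[addition], groups["control"], equal_var=False,
            alternative="greater",
        )
        pvals[addition] = float(p)

    n_sig = pvals["+N"] <= alpha
    p_sig = pvals["+P"] <= alpha
    np_sig = pvals["+NP"] <= alpha
    return {
        "N": bool(n_sig),
        "P": bool(p_sig),
        "N+P": bool(np_sig and not n_sig and not p_sig),
        "p_values": pvals,
    }
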