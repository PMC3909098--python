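"""Differential splicing between sample groups or two single libraries.

Group designs use a two-sided Wilcoxon rank-sum test per event on the
per-sample PSI values (exact enumeration for small tie-free samples,
normal approximation with tie and continuity corrections otherwise),
followed by Benjamini–Hochberg FDR control. An event enters the test
only when the group medians already differ by a pre-filter margin, and a
significant call additionally requires the median difference to exceed a
larger post-filter margin.

Two-library designs (no replicates) instead compare inclusion vs
exclusion read counts per event with a two-sided Fisher's exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, SampleSheet
from .events import PsiTable

logger = logging.getLogger("spliceshift")

__all__ = ["wilcoxon_diff", "pairwise_fisher_diff", "benjamini_hochberg",
           "specificity_filter", "rank_sum_p"]

DIFF_COLUMNS = ["event_id", "n_group0", "n_group1",
                "median_psi_group0", "median_psi_group1", "delta_psi",
                "p_value", "q_value", "significant", "direction"]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_p(x, y, continuity: bool = True, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled sample is small (``n0+n1 <=
    exact_max_n``) and tie-free; otherwise the normal approximation with
    tie correction (and continuity correction if requested).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and len(pooled) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=continuity)
    return float(res.pvalue)


def _direction(delta: float) -> str:
    return "skipping" if delta < 0 else "inclusion"


def wilcoxon_diff(psi_table: PsiTable, sample_sheet: SampleSheet,
                  config: RunConfig, group0: str, group1: str) -> pd.DataFrame:
    """Per-event rank-sum comparison of PSI between two sample groups.

    ``group0`` is the reference (e.g. no-splicing-factor-mutation) and
    ``group1`` the condition of interest (e.g. mutant); ``delta_psi`` is
    ``median(group1) - median(group0)`` on the inclusion isoform, so a
    negative value means preferential skipping / distal-site usage in
    ``group1``. Events whose |ΔPSI| is below ``config.delta_thresh`` are
    not tested; significance requires BH q < ``fdr_alpha`` and |ΔPSI| >
    ``median_delta_filter``.
    """
    s0 = [s for s in sample_sheet.samples_in(group0) if s in psi_table.psi.columns]
    s1 = [s for s in sample_sheet.samples_in(group1) if s in psi_table.psi.columns]
    rows = []
    for event_id, row in psi_table.psi.iterrows():
        v0 = row[s0].dropna().to_numpy(dtype=float)
        v1 = row[s1].dropna().to_numpy(dtype=float)
        if len(v0) < 2 or len(v1) < 2:
            logger.debug("event %s skipped: <2 defined PSI per group", event_id)
            continue
        m0, m1 = float(np.median(v0)), float(np.median(v1))
        delta = m1 - m0
        rows.append({"event_id": event_id, "n_group0": len(v0), "n_group1": len(v1),
                     "median_psi_group0": m0, "median_psi_group1": m1,
                     "delta_psi": delta, "_v0": v0, "_v1": v1})
    if not rows:
        return pd.DataFrame(columns=DIFF_COLUMNS)
    df = pd.DataFrame(rows)
    tested = df["delta_psi"].abs() >= config.delta_thresh
    p = np.full(len(df), np.nan)
    for i in np.flatnonzero(tested.to_numpy()):
        p[i] = rank_sum_p(df["_v1"].iloc[i], df["_v0"].iloc[i],
                          continuity=config.continuity)
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = benjamini_hochberg(p[tested.to_numpy()])
    df["p_value"], df["q_value"] = p, q
    df["significant"] = ((df["q_value"] < config.fdr_alpha)
                         & (df["delta_psi"].abs() > config.median_delta_filter)).fillna(False)
    df["direction"] = df["delta_psi"].map(_direction)
    return df.drop(columns=["_v0", "_v1"])


def pairwise_fisher_diff(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                         config: RunConfig) -> pd.DataFrame:
    """Compare inclusion/exclusion counts between two single libraries.

    Inputs are DataFrames indexed by event_id with columns ``inclusion``
    and ``exclusion``. Events with inclusion+exclusion below
    ``config.psi_min_total`` in either library are excluded; each
    remaining event gets a two-sided Fisher's exact p on the 2×2 table
    [[I_a, E_a], [I_b, E_b]], then BH. Significance requires q below
    ``fdr_alpha`` and a PSI difference above ``switch_dpsi``.
    """
    shared = counts_a.index.intersection(counts_b.index)
    rows = []
    for event_id in shared:
        ia, ea = int(counts_a.loc[event_id, "inclusion"]), int(counts_a.loc[event_id, "exclusion"])
        ib, eb = int(counts_b.loc[event_id, "inclusion"]), int(counts_b.loc[event_id, "exclusion"])
        if min(ia, ea, ib, eb) < 0:
            raise ValueError(f"{event_id}: negative counts")
        if ia + ea + ib + eb == 0:
            logger.warning("event %s skipped: all-zero contingency table", event_id)
            continue
        if ia + ea < config.psi_min_total or ib + eb < config.psi_min_total:
            continue
        psi_a = 100.0 * ia / (ia + ea)
        psi_b = 100.0 * ib / (ib + eb)
        p = float(stats.fisher_exact([[ia, ea], [ib, eb]], alternative="two-sided")[1])
        rows.append({"event_id": event_id, "n_group0": 1, "n_group1": 1,
                     "median_psi_group0": psi_a, "median_psi_group1": psi_b,
                     "delta_psi": psi_b - psi_a, "p_value": p})
    if not rows:
        return pd.DataFrame(columns=DIFF_COLUMNS)
    df = pd.DataFrame(rows)
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = ((df["q_value"] < config.fdr_alpha)
                         & (df["delta_psi"].abs() > config.switch_dpsi))
    df["direction"] = df["delta_psi"].map(_direction)
    return df


def specificity_filter(diff_case: pd.DataFrame, diff_wt: pd.DataFrame,
                       diff_controls: pd.DataFrame) -> pd.DataFrame:
    """Keep events whose change is specific to the case condition.

    An event survives when it is significant in the case-vs-control
    comparison and not significant in the control-vs-control comparison
    nor in the wild-type-induction comparison. Events significant in the
    wild-type comparison with the *opposite* ΔPSI sign are still dropped
    but carried in the output flagged ``opposite_direction_in_wt`` (they
    are informative: the overexpression effect opposes the mutant one).
    """
    universes = [set(d["event_id"]) for d in (diff_case, diff_wt, diff_controls)]
    shared = set.intersection(*universes)
    if any(u != shared for u in universes):
        logger.info("specificity_filter: restricting to %d shared events "
                    "(case=%d, wt=%d, controls=%d)", len(shared),
                    *(len(u) for u in universes))

    case = diff_case[diff_case["event_id"].isin(shared)].set_index("event_id")
    wt = diff_wt[diff_wt["event_id"].isin(shared)].set_index("event_id")
    ctrl = diff_controls[diff_controls["event_id"].isin(shared)].set_index("event_id")

    out = case[case["significant"]].copy()
    wt_sig = wt["significant"].reindex(out.index).fillna(False)
    ctrl_sig = ctrl["significant"].reindex(out.index).fillna(False)
    same_sign = (np.sign(wt["delta_psi"].reindex(out.index))
                 == np.sign(out["delta_psi"]))
    out["opposite_direction_in_wt"] = (wt_sig & ~same_sign).fillna(False)
    keep = ~wt_sig & ~ctrl_sig
    dropped_flagged = out[out["opposite_direction_in_wt"] & ~keep]
    for event_id in dropped_flagged.index:
        logger.info("event %s dropped: wild-type induction changed splicing "
                    "in the opposite direction", event_id)
    result = out[keep].reset_index()
    flagged = dropped_flagged.reset_index()
    result.attrs["opposite_direction_in_wt"] = list(flagged["event_id"])
    return result
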