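"""Cross-cohort comparison of differential-splicing results.

Events from two cohorts are matched by exact genomic coordinates of
their two competing splice sites; matched pairs are checked for
direction concordance, overlap enrichment is tested with Fisher's exact
test restricted to events expressed in both cohorts, and gene lists
(e.g. a cancer-gene census) are intersected. Also includes the qRT-PCR
relative-inclusion metric used for experimental validation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("spliceshift")

__all__ = ["overlap_events", "overlap_fisher", "gene_list_intersection",
           "relative_inclusion", "expressed_universe"]

_MATCH_KEY = ["chrom", "strand", "proximal_3ss", "distal_3ss"]


def overlap_events(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Match events across cohorts by identical splice-site coordinates.

    A match requires identical chrom, strand, and both splice-site
    positions. Matches whose AS type differs between cohorts are kept
    but flagged ``type_discordant`` for manual review (a shared location
    does not guarantee the same event). ``same_direction`` compares the
    sign of ΔPSI. Symmetric in its two arguments.
    """
    def prepare(df: pd.DataFrame, suffix: str) -> pd.DataFrame:
        df = df.copy()
        usable = df[_MATCH_KEY].notna().all(axis=1)
        if (~usable).any():
            logger.info("overlap_events: excluding %d coordinate-less events (%s)",
                        int((~usable).sum()), suffix)
        cols = _MATCH_KEY + [c for c in ("event_id", "as_type", "gene", "delta_psi")
                             if c in df.columns]
        out = df.loc[usable, cols]
        return out.rename(columns={c: f"{c}_{suffix}" for c in cols if c not in _MATCH_KEY})

    merged = prepare(results_a, "a").merge(prepare(results_b, "b"), on=_MATCH_KEY)
    if merged.empty:
        return merged
    if "as_type_a" in merged.columns and "as_type_b" in merged.columns:
        merged["same_as_type"] = merged["as_type_a"] == merged["as_type_b"]
        merged["type_discordant"] = ~merged["same_as_type"]
        for row in merged[merged["type_discordant"]].itertuples(index=False):
            logger.warning("coordinate match with differing AS type flagged for review: "
                           "%s vs %s", row.event_id_a, row.event_id_b)
    if "delta_psi_a" in merged.columns and "delta_psi_b" in merged.columns:
        merged["same_direction"] = (np.sign(merged["delta_psi_a"])
                                    == np.sign(merged["delta_psi_b"]))
    return merged


def overlap_fisher(n_expressed_both: int, n_sig_a: int, n_sig_b: int,
                   n_sig_both: int) -> tuple[float, list[list[int]]]:
    """Enrichment of shared significant events among co-expressed events.

    Builds the 2×2 table [[both, a only], [b only, neither]] over the
    universe of events expressed in both cohorts and returns the
    two-sided Fisher's exact p with the table. Invariant under
    transposition (swapping the cohorts).
    """
    if not (0 <= n_sig_both <= min(n_sig_a, n_sig_b)):
        raise ValueError("n_sig_both must not exceed either cohort's significant count")
    if max(n_sig_a, n_sig_b) > n_expressed_both:
        raise ValueError("significant counts exceed the expressed universe")
    a_only = n_sig_a - n_sig_both
    b_only = n_sig_b - n_sig_both
    neither = n_expressed_both - n_sig_both - a_only - b_only
    if neither < 0:
        raise ValueError("inconsistent counts: universe too small")
    table = [[n_sig_both, a_only], [b_only, neither]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return p, table


def expressed_universe(psi_a: pd.DataFrame, psi_b: pd.DataFrame,
                       min_fraction: float = 0.5) -> set[str]:
    """Events with defined PSI in at least ``min_fraction`` of samples of
    each cohort — the universe for the overlap test."""
    def expressed(psi: pd.DataFrame) -> set[str]:
        frac = psi.notna().mean(axis=1)
        return set(psi.index[frac >= min_fraction])

    return expressed(psi_a) & expressed(psi_b)


def gene_list_intersection(events: pd.DataFrame, gene_list) -> pd.DataFrame:
    """Subset of events whose gene is in the list (case-insensitive).

    Gene symbols are normalised to uppercase on both sides; input order
    is preserved.
    """
    symbols = {str(g).strip().upper() for g in gene_list if str(g).strip()}
    if not symbols:
        logger.warning("gene_list_intersection: empty gene list")
        return events.iloc[0:0]
    mask = events["gene"].astype(str).str.upper().isin(symbols)
    return events[mask]


def relative_inclusion(ct_inclusion, ct_total, control_fold_differences) -> np.ndarray:
    """qRT-PCR relative inclusion level.

    Per sample, fold = 2^-(Ct_inclusion - Ct_total); the relative level
    normalises that fold by the median fold of non-transfected control
    samples.
    """
    ct_i = np.asarray(ct_inclusion, dtype=float)
    ct_t = np.asarray(ct_total, dtype=float)
    controls = np.asarray(control_fold_differences, dtype=float)
    if controls.size == 0:
        raise ValueError("control fold differences must be non-empty")
    if not (np.isfinite(ct_i).all() and np.isfinite(ct_t).all()):
        raise ValueError("Ct values must be finite")
    fold = np.power(2.0, -(ct_i - ct_t))
    return fold / np.median(controls)
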