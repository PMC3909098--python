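"""3' splice-site sequence analysis.

The 3' splice site (acceptor) of an intron canonically ends in AG, and
the base immediately upstream of that AG — the intronic −3 position —
distinguishes the site classes TAG, CAG and AAG that differ in their
sensitivity to 3'-end recognition by the U2AF heterodimer's small
subunit. This module extracts 23-nt acceptor windows (20 intronic + 3
exonic bases in transcript orientation), classifies the −3 trinucleotide,
tests for direction bias (skipping vs inclusion) with an exact binomial
test, builds base-frequency/information-content matrices for motif
summaries, and enumerates splice-site switches — between-condition PSI
shifts that reallocate usage between two competing acceptors of
different −3 classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .events import SpliceEvent, event_support, _junction_lookup

logger = logging.getLogger("spliceshift")

__all__ = ["ThreePrimeSite", "MotifMatrix", "extract_3ss", "classify_minus3",
           "direction_calls", "skipping_bias_test", "build_motif",
           "enumerate_switches", "switch_direction_fisher"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SITE_CLASSES = ("TAG", "CAG", "AAG")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ThreePrimeSite:
    """A 3' splice site with its 23-nt sequence context.

    ``seq23`` = 20 intronic + 3 exonic nt in transcript orientation;
    ``acceptor_pos`` is the genomic position of the last intronic base;
    ``minus3_class`` is the intronic −3..−1 trinucleotide mapped to
    {TAG, CAG, AAG, other}.
    """

    chrom: str
    strand: str
    acceptor_pos: int
    seq23: str

    def __post_init__(self) -> None:
        if len(self.seq23) != 23:
            raise ValueError(f"seq23 must be 23 nt, got {len(self.seq23)}")

    @property
    def minus3_trinucleotide(self) -> str:
        return self.seq23[17:20]

    @property
    def minus3_class(self) -> str:
        return classify_minus3(self.seq23)


def classify_minus3(seq23: str) -> str:
    tri = seq23[17:20].upper()
    return tri if tri in SITE_CLASSES else "other"


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch from a pyfaidx.Fasta or a plain mapping."""
    if hasattr(genome, "get_seq"):  # pyfaidx.Fasta
        return str(genome.get_seq(chrom, start, end))
    seq = genome[chrom]
    if start < 1 or end > len(seq):
        raise ValueError(f"window {chrom}:{start}-{end} off chromosome end (length {len(seq)})")
    return str(seq[start - 1:end])


def extract_3ss(genome, chrom: str, acceptor_pos: int, strand: str) -> ThreePrimeSite:
    """Extract the 23-nt acceptor window around the intron/exon boundary.

    Plus strand: bases ``acceptor_pos-19 .. acceptor_pos+3``; minus
    strand: reverse complement of ``acceptor_pos-3 .. acceptor_pos+19``.
    The result is uppercased; a non-AG terminal dinucleotide triggers a
    warning, not an error (non-canonical sites occur in real data).
    """
    if strand == "+":
        start, end = acceptor_pos - 19, acceptor_pos + 3
        seq = _fetch(genome, chrom, start, end).upper()
    elif strand == "-":
        start, end = acceptor_pos - 3, acceptor_pos + 19
        seq = _revcomp(_fetch(genome, chrom, start, end)).upper()
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if len(seq) != 23:
        raise ValueError(f"window {chrom}:{start}-{end} off chromosome end")
    if seq[18:20] != "AG":
        logger.warning("non-canonical acceptor at %s:%d:%s (intron ends %r)",
                       chrom, acceptor_pos, strand, seq[18:20])
    return ThreePrimeSite(chrom=chrom, strand=strand, acceptor_pos=acceptor_pos, seq23=seq)


def direction_calls(diff_results: pd.DataFrame,
                    as_types: tuple[str, ...] = ("CE", "A3SS")) -> pd.DataFrame:
    """Label each differential event as exon inclusion or skipping.

    Skipping (equivalently, distal 3'ss usage) is called when the median
    PSI of the inclusion (proximal) isoform is lower in the condition of
    interest (ΔPSI < 0); inclusion when higher. Zero-ΔPSI and
    undefined-median events are excluded.
    """
    df = diff_results.copy()
    if "as_type" in df.columns:
        df = df[df["as_type"].isin(as_types)]
    defined = df["delta_psi"].notna() & (df["delta_psi"] != 0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("direction_calls: excluding %d events with zero or undefined ΔPSI", n_dropped)
    df = df[defined].copy()
    df["direction"] = np.where(df["delta_psi"] < 0, "skipping", "inclusion")
    df["distal_usage"] = df["direction"] == "skipping"
    return df


def skipping_bias_test(calls: pd.DataFrame, as_type: str) -> tuple[float, float]:
    """Proportion of skipping/distal calls of one AS type + binomial p.

    Two-sided exact binomial test of the skipped fraction against 0.5.
    Returns ``(proportion, p_value)``.
    """
    if "as_type" in calls.columns:
        sub = calls[calls["as_type"] == as_type]
    else:
        sub = calls
    n = len(sub)
    if n == 0:
        raise ValueError(f"no direction calls of type {as_type!r}")
    k = int((sub["direction"] == "skipping").sum())
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return k / n, p


@dataclass
class MotifMatrix:
    """Column base frequencies and information content of a site group.

    ``freqs`` is a 23×4 array (columns A, C, G, T summing to 1);
    ``information`` holds per-column IC = 2 − H − e(n) bits with Shannon
    entropy H and the small-sample correction e(n) = 3 / (2·ln2·n).
    """

    freqs: np.ndarray
    information: np.ndarray
    n: int
    alphabet: str = "ACGT"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(self.alphabet))
        df.insert(0, "position", np.arange(-20, 3))
        df["information"] = self.information
        df["n"] = self.n
        return df


def build_motif(seqs: list[str], min_n: int = 10) -> MotifMatrix | None:
    """Base-frequency matrix with per-column information content.

    Returns None when fewer than ``min_n`` sequences are supplied (too
    few observations for a meaningful consensus).
    """
    if len(seqs) < min_n:
        return None
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    L = lengths.pop()
    n = len(seqs)
    arr = np.array([[c for c in s.upper()] for s in seqs])
    freqs = np.zeros((L, 4))
    for k, base in enumerate("ACGT"):
        freqs[:, k] = (arr == base).mean(axis=0)
    # renormalise columns containing ambiguity codes
    colsum = freqs.sum(axis=1, keepdims=True)
    colsum[colsum == 0] = 1.0
    freqs = freqs / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(freqs > 0, freqs * np.log2(freqs), 0.0).sum(axis=1)
    e_n = 3.0 / (2.0 * math.log(2) * n)
    info = 2.0 - h - e_n
    return MotifMatrix(freqs=freqs, information=info, n=n)


def _site_classes(event: SpliceEvent, genome) -> tuple[str, str]:
    """(-3 class of proximal site, -3 class of distal site)."""
    prox = extract_3ss(genome, event.chrom, event.proximal_3ss, event.strand)
    dist = extract_3ss(genome, event.chrom, event.distal_3ss, event.strand)
    return prox.minus3_class, dist.minus3_class


def enumerate_switches(counts_a: dict[str, pd.DataFrame],
                       counts_b: dict[str, pd.DataFrame],
                       events: list[SpliceEvent], genome,
                       config: RunConfig,
                       class_pair: tuple[str, str] = ("TAG", "CAG"),
                       pool_replicates: bool = True) -> tuple[pd.DataFrame, dict]:
    """Enumerate splice-site switches between two conditions.

    Eligible events are annotated CE/A3SS events with exactly two 3'
    splice-site choices whose −3 classes are one of each member of
    ``class_pair``, and with at least ``config.psi_min_total`` reads in
    both conditions. A switch is called when the proximal-isoform PSI
    changes by more than ``config.switch_dpsi`` percent; its direction is
    toward the site whose usage increased.

    Replicate libraries within a condition are pooled by summing counts
    (single-library designs are then the one-replicate special case).

    Returns (switch table, summary). The summary reports the eligible
    and switched tallies and the counts by direction, counting both
    distinct events and distinct site pairs.
    """
    if not pool_replicates and (len(counts_a) > 1 or len(counts_b) > 1):
        raise ValueError("unpooled multi-library designs are not supported; "
                         "set pool_replicates=True")

    def pooled_lookup(tables: dict[str, pd.DataFrame]) -> dict:
        frames = pd.concat(tables.values(), ignore_index=True)
        key = ["chrom", "intron_start", "intron_end", "strand"]
        return _junction_lookup(frames.groupby(key, as_index=False)["reads"].sum())

    lk_a, lk_b = pooled_lookup(counts_a), pooled_lookup(counts_b)
    wanted = set(class_pair)
    rows = []
    for ev in events:
        if ev.as_type not in ("CE", "A3SS") or not ev.annotated:
            continue
        if ev.proximal_3ss is None or ev.distal_3ss is None:
            continue
        prox_class, dist_class = _site_classes(ev, genome)
        if {prox_class, dist_class} != wanted:
            continue
        ia, ea = event_support(ev, lk_a, jcn_seq_len=config.jcn_seq_len)
        ib, eb = event_support(ev, lk_b, jcn_seq_len=config.jcn_seq_len)
        if ia + ea < config.psi_min_total or ib + eb < config.psi_min_total:
            continue
        psi_a = 100.0 * ia / (ia + ea)
        psi_b = 100.0 * ib / (ib + eb)
        dpsi_prox = psi_b - psi_a  # change of the proximal (inclusion) site
        switched = abs(dpsi_prox) > config.switch_dpsi
        if dpsi_prox > 0:
            gaining, losing = prox_class, dist_class
        else:
            gaining, losing = dist_class, prox_class
        rows.append({
            "event_id": ev.event_id, "gene": ev.gene, "as_type": ev.as_type,
            "chrom": ev.chrom, "strand": ev.strand,
            "proximal_3ss": ev.proximal_3ss, "distal_3ss": ev.distal_3ss,
            "proximal_class": prox_class, "distal_class": dist_class,
            "psi_a": psi_a, "psi_b": psi_b, "dpsi": abs(dpsi_prox),
            "switched": switched,
            "from_class": losing if switched else "",
            "to_class": gaining if switched else "",
        })
    table = pd.DataFrame(rows)
    summary: dict = {"eligible_events": len(table), "switched_events": 0,
                     "fraction_switched": float("nan"), "by_direction": {}}
    if len(table):
        sw = table[table["switched"]]
        pairs = table.drop_duplicates(["chrom", "strand", "proximal_3ss", "distal_3ss"])
        sw_pairs = sw.drop_duplicates(["chrom", "strand", "proximal_3ss", "distal_3ss"])
        summary.update({
            "switched_events": int(len(sw)),
            "fraction_switched": len(sw) / len(table),
            "eligible_site_pairs": int(len(pairs)),
            "switched_site_pairs": int(len(sw_pairs)),
            "fraction_switched_site_pairs": (len(sw_pairs) / len(pairs)) if len(pairs) else float("nan"),
            "by_direction": sw.groupby(["from_class", "to_class"]).size().to_dict(),
        })
    return table, summary


def switch_direction_fisher(counts_condition1: tuple[int, int],
                            counts_condition2: tuple[int, int]) -> float:
    """Two-sided Fisher's exact p comparing switch-direction proportions.

    Each argument is a ``(toward_second_class, toward_first_class)``
    count pair for one condition, e.g. (TAG→CAG, CAG→TAG).
    """
    table = [list(counts_condition1), list(counts_condition2)]
    if min(min(r) for r in table) < 0:
        raise ValueError("switch counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
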