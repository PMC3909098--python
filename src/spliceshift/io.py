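"""Readers and writers for the formats the pipeline touches.

Junction tables come in three dialects (STAR ``SJ.out.tab``, BED12
junction tracks, and a plain 5-column TSV); all are normalised on read to
one internal convention: **1-based, inclusive intronic bounds** —
``intron_start`` is the first intronic base, ``intron_end`` the last.
Annotation is a GTF with exon features (or a BED intron list), reduced to
the deduplicated intron set plus a terminal-exon index used for
alternative-last-exon classification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("spliceshift")

JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "reads"]

_STAR_STRAND = {"0": None, "1": "+", "2": "-"}

__all__ = [
    "Annotation",
    "read_junction_table",
    "write_junction_table",
    "read_annotation",
    "read_intron_bed",
    "write_results",
    "read_psi_table",
    "write_psi_table",
]


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _parse_simple_tsv(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "chrom":
                continue  # optional header
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            chrom, start, end, strand, reads = parts[:5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            try:
                rows.append((chrom, int(start), int(end), strand, int(reads)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return rows


def _parse_star_sj(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = re.split(r"\s+", line.strip())
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 fields, got {len(parts)}")
            chrom, start, end, strand_code = parts[0], parts[1], parts[2], parts[3]
            if strand_code not in _STAR_STRAND:
                raise ParseError(f"{path}:{lineno}: unknown strand code {strand_code!r}")
            strand = _STAR_STRAND[strand_code]
            if strand is None:
                logger.warning("%s:%d: dropping unstranded junction %s:%s-%s",
                               path, lineno, chrom, start, end)
                continue
            try:
                rows.append((chrom, int(start), int(end), strand, int(parts[6])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return rows


def _parse_bed_junction(path: Path) -> list[tuple]:
    # BED12 junction track (TopHat-style): each record is a read anchor
    # spanning the intron; the intron is the gap between the two blocks.
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 requires 12 fields, got {len(parts)}")
            chrom, chrom_start, chrom_end = parts[0], int(parts[1]), int(parts[2])
            score, strand = int(float(parts[4])), parts[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            block_count = int(parts[9])
            if block_count != 2:
                raise ParseError(f"{path}:{lineno}: junction record needs 2 blocks, got {block_count}")
            sizes = [int(s) for s in parts[10].rstrip(",").split(",")]
            # 0-based half-open BED -> 1-based inclusive intronic bounds:
            # intron follows block 1 and precedes block 2.
            intron_start = chrom_start + sizes[0] + 1
            intron_end = chrom_end - sizes[1]
            rows.append((chrom, intron_start, intron_end, strand, score))
    return rows


_DIALECTS = {
    "simple_tsv": _parse_simple_tsv,
    "star_sj": _parse_star_sj,
    "bed_junction": _parse_bed_junction,
}


def read_junction_table(path: str | Path, dialect: str = "simple_tsv") -> pd.DataFrame:
    """Read one sample's junction counts into the internal convention.

    Returns a DataFrame with columns ``chrom, intron_start, intron_end,
    strand, reads`` — one row per junction, duplicates summed (with a
    warning), coordinates 1-based inclusive of the first/last intronic
    base regardless of input dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    rows = _DIALECTS[dialect](path)
    if not rows:
        logger.warning("%s: empty junction table", path)
        return pd.DataFrame(columns=JUNCTION_COLUMNS)
    df = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    if (df["reads"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    if (df["intron_start"] < 0).any() or (df["intron_end"] < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    key = ["chrom", "intron_start", "intron_end", "strand"]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        logger.warning("%s: summing %d duplicate junction records", path, n_dup)
        df = df.groupby(key, as_index=False)["reads"].sum()
    return df.sort_values(key, ignore_index=True)


def write_junction_table(df: pd.DataFrame, path: str | Path) -> None:
    """Serialise junctions to the simple 5-column TSV dialect."""
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class Annotation:
    """Intron set and terminal-exon index derived from a transcript annotation.

    ``introns``: one row per distinct (chrom, start, end, strand, gene_id),
    1-based inclusive intronic bounds. ``terminal_exons``: last exon of each
    transcript in transcript orientation. ``transcript_exons``: transcript_id
    -> list of (start, end) exon intervals, sorted genomically.
    """

    introns: pd.DataFrame
    terminal_exons: pd.DataFrame
    transcript_exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    transcript_meta: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    @property
    def intron_set(self) -> set[tuple]:
        return set(map(tuple, self.introns[["chrom", "intron_start", "intron_end", "strand"]].values))

    def splice_sites(self) -> set[tuple[str, str, int]]:
        """All annotated donor/acceptor positions as (chrom, strand, pos)."""
        sites: set[tuple[str, str, int]] = set()
        for chrom, start, end, strand in self.introns[
            ["chrom", "intron_start", "intron_end", "strand"]
        ].itertuples(index=False):
            sites.add((chrom, strand, int(start)))
            sites.add((chrom, strand, int(end)))
        return sites


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str | Path) -> Annotation:
    """Parse a GTF with exon features into introns + terminal-exon index.

    Exons of each transcript must be non-overlapping; introns shared by
    several transcripts are deduplicated. Raises if a transcript's exons
    overlap, naming the transcript.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(parts)}")
            if parts[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            records.append({
                "chrom": parts[0],
                "start": int(parts[3]),
                "end": int(parts[4]),
                "strand": parts[6],
                "gene_id": attrs.get("gene_id", "unknown"),
                "transcript_id": attrs.get("transcript_id", attrs.get("gene_id", "unknown")),
            })
    if not records:
        raise ValueError(f"{path}: no exon features found")
    exons = pd.DataFrame(records)

    introns, terminal_rows = [], []
    transcript_exons: dict[str, list[tuple[int, int]]] = {}
    transcript_meta: dict[str, tuple[str, str, str]] = {}
    for tx_id, tx in exons.groupby("transcript_id", sort=True):
        tx = tx.sort_values("start")
        starts, ends = tx["start"].to_numpy(), tx["end"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise ValueError(f"transcript {tx_id}: overlapping or unsorted exons")
        chrom = tx["chrom"].iloc[0]
        strand = tx["strand"].iloc[0]
        gene = tx["gene_id"].iloc[0]
        transcript_exons[tx_id] = list(zip(starts.tolist(), ends.tolist()))
        transcript_meta[tx_id] = (chrom, strand, gene)
        for i in range(len(tx) - 1):
            introns.append((chrom, int(ends[i]) + 1, int(starts[i + 1]) - 1, strand, gene))
        term = tx.iloc[-1] if strand == "+" else tx.iloc[0]
        terminal_rows.append({
            "chrom": chrom, "start": int(term["start"]), "end": int(term["end"]),
            "strand": strand, "gene_id": gene, "transcript_id": tx_id,
        })

    intron_df = (
        pd.DataFrame(introns, columns=["chrom", "intron_start", "intron_end", "strand", "gene_id"])
        .drop_duplicates(["chrom", "intron_start", "intron_end", "strand"], ignore_index=True)
    )
    return Annotation(
        introns=intron_df,
        terminal_exons=pd.DataFrame(terminal_rows),
        transcript_exons=transcript_exons,
        transcript_meta=transcript_meta,
    )


def read_intron_bed(path: str | Path) -> Annotation:
    """Read a BED6 intron list (0-based half-open) as a bare intron set."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 fields, got {len(parts)}")
            if parts[5] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {parts[5]!r}")
            rows.append((parts[0], int(parts[1]) + 1, int(parts[2]), parts[5], parts[3]))
    introns = (
        pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end", "strand", "gene_id"])
        .drop_duplicates(["chrom", "intron_start", "intron_end", "strand"], ignore_index=True)
    )
    return Annotation(introns=introns,
                      terminal_exons=pd.DataFrame(
                          columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id"]))


RESULT_COLUMNS = [
    "event_id", "as_type", "gene", "chrom", "strand",
    "proximal_3ss", "distal_3ss",
    "median_psi_group0", "median_psi_group1", "delta_psi",
    "p_value", "q_value", "direction", "significant",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-splicing report, ordered by q then |ΔPSI|.

    Ties in q are broken by |ΔPSI| descending, then event id
    lexicographically; values round-trip through the file at 6-decimal
    precision.
    """
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["_absd"] = df["delta_psi"].abs()
    df = df.sort_values(["q_value", "_absd", "event_id"],
                        ascending=[True, False, True], na_position="last")
    df = df.drop(columns="_absd")
    ordered = RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]
    df[ordered].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_psi_table(psi: pd.DataFrame, path: str | Path) -> None:
    """Write an events × samples PSI matrix, missing entries as 'NA'."""
    psi.to_csv(path, sep="\t", na_rep="NA", index=True, index_label="event_id",
               float_format="%.6f")


def read_psi_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="event_id", na_values="NA")
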