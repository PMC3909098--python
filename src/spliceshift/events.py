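"""Build and classify alternative-splicing events from junction evidence.

An event is a small set of exon–exon junctions whose relative read
support quantifies an alternative-splicing choice:

* **CE** (cassette exon): two flanking inclusion junctions vs one
  exon-bridging exclusion junction.
* **A3SS / A5SS**: two junctions sharing a donor (resp. acceptor) and
  competing for two acceptors (resp. donors).
* **ALE** (alternative last exon): a shared donor splicing to acceptors
  of two distinct annotated terminal exons.
* **IR** (intron retention): an annotated intron's junction (exclusion)
  against reads falling in the intron body (inclusion).
* **MXE** (mutually exclusive exons): two cassette exons sharing flanks
  that never co-occur in any annotated transcript.

Coordinates are 1-based inclusive intronic bounds throughout; the donor
is the first intronic base in transcript orientation and the acceptor
the last, so on the minus strand donor = intron_end and acceptor =
intron_start.

The per-sample "percent spliced in" (PSI) of an event is
``100 * I / (I + E)`` with I/E the inclusion/exclusion read support, and
is left undefined (NaN) when ``I + E`` falls below a read-support
threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Annotation

logger = logging.getLogger("spliceshift")

Junction = tuple[str, int, int, str]  # chrom, intron_start, intron_end, strand

AS_TYPES = ("CE", "A3SS", "A5SS", "ALE", "IR", "MXE")

__all__ = ["SpliceEvent", "PsiTable", "build_events", "assign_proximal_distal",
           "compute_psi", "pool_junctions", "donor_of", "acceptor_of"]


def donor_of(junction: Junction) -> int:
    """First intronic base in transcript orientation (5' splice site)."""
    chrom, start, end, strand = junction
    return start if strand == "+" else end


def acceptor_of(junction: Junction) -> int:
    """Last intronic base in transcript orientation (3' splice site)."""
    chrom, start, end, strand = junction
    return end if strand == "+" else start


@dataclass
class SpliceEvent:
    event_id: str
    as_type: str
    gene: str
    chrom: str
    strand: str
    inclusion_junctions: tuple[Junction, ...]
    exclusion_junctions: tuple[Junction, ...]
    proximal_3ss: int | None = None
    distal_3ss: int | None = None
    annotated: bool = False
    # IR only: the retained intron's bounds, for body-count normalisation
    intron_length: int | None = None

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")
        inc, exc = set(self.inclusion_junctions), set(self.exclusion_junctions)
        if self.as_type != "IR" and (not inc or not exc):
            raise ValueError(f"{self.event_id}: inclusion and exclusion junction sets must be non-empty")
        if inc & exc:
            raise ValueError(f"{self.event_id}: inclusion and exclusion junctions overlap")


def _fmt_junctions(juncs: tuple[Junction, ...]) -> str:
    return ",".join(f"{j[1]}-{j[2]}" for j in sorted(juncs))


def _event_id(as_type: str, chrom: str, strand: str,
              inc: tuple[Junction, ...], exc: tuple[Junction, ...]) -> str:
    return f"{as_type}:{chrom}:{strand}:{_fmt_junctions(inc)}^{_fmt_junctions(exc)}"


def pool_junctions(tables: dict[str, pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Sum junction reads across samples into one pooled table."""
    if isinstance(tables, dict):
        frames = list(tables.values())
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "intron_start", "intron_end", "strand", "reads"])
    else:
        df = tables
    key = ["chrom", "intron_start", "intron_end", "strand"]
    return df.groupby(key, as_index=False)["reads"].sum()


def _gene_for_sites(annotation: Annotation, chrom: str, strand: str,
                    positions: list[int]) -> str:
    """Best-effort gene assignment: any annotated intron touching a site."""
    sub = annotation.introns
    hit = sub[(sub["chrom"] == chrom) & (sub["strand"] == strand)
              & (sub["intron_start"].isin(positions) | sub["intron_end"].isin(positions))]
    if len(hit):
        return str(hit["gene_id"].iloc[0])
    return "unknown"


def assign_proximal_distal(event: SpliceEvent) -> SpliceEvent:
    """Label the two competing acceptors as proximal/distal to the donor.

    The distal acceptor is the one farther from the shared donor in the
    direction of transcription (the longer intron); the proximal is the
    nearer. For a cassette exon, proximal is the cassette exon's own
    acceptor and distal the acceptor used by the skipping junction. The
    labelling is invariant under coordinate mirroring with strand flip.
    """
    if event.as_type not in ("CE", "A3SS", "ALE"):
        raise ValueError(f"{event.event_id}: proximal/distal undefined for {event.as_type}")
    if event.as_type == "CE":
        exc = event.exclusion_junctions[0]
        donor = donor_of(exc)
        distal = acceptor_of(exc)
        # cassette acceptor: the inclusion junction sharing the exclusion donor
        shared = [j for j in event.inclusion_junctions if donor_of(j) == donor]
        if not shared:
            raise ValueError(f"{event.event_id}: no inclusion junction shares the skip donor")
        proximal = acceptor_of(shared[0])
    else:
        juncs = list(event.inclusion_junctions) + list(event.exclusion_junctions)
        donors = {donor_of(j) for j in juncs}
        if len(donors) != 1:
            raise ValueError(f"{event.event_id}: junctions do not share a donor")
        donor = donors.pop()
        accs = sorted({acceptor_of(j) for j in juncs})
        if len(accs) != 2:
            raise ValueError(f"{event.event_id}: expected exactly two acceptor choices")
        # transcript-direction distance from the donor
        def dist(a: int) -> int:
            return a - donor if event.strand == "+" else donor - a
        proximal, distal = sorted(accs, key=dist)
    return replace(event, proximal_3ss=proximal, distal_3ss=distal)


def build_events(junctions: pd.DataFrame, annotation: Annotation,
                 min_event_count: float = 2.0,
                 body_counts: pd.DataFrame | None = None) -> list[SpliceEvent]:
    """Classify alternative-splicing events from pooled junction counts.

    Parameters
    ----------
    junctions
        Pooled (across samples) junction table.
    annotation
        Intron set + terminal-exon index.
    min_event_count
        Events are kept only if every member junction has pooled reads
        >= this count.
    body_counts
        Optional pooled intron-body read counts (same columns as a
        junction table, keyed by the intron's bounds). Intron-retention
        events are emitted only for annotated introns with both junction
        evidence and body evidence; without this table no IR events are
        produced.
    """
    key = ["chrom", "intron_start", "intron_end", "strand"]
    pooled = junctions.groupby(key, as_index=False)["reads"].sum()

    bad = pooled["intron_start"] >= pooled["intron_end"]
    if bad.any():
        for row in pooled[bad].itertuples(index=False):
            logger.warning("rejecting junction with donor == acceptor: %s:%d-%d",
                           row.chrom, row.intron_start, row.intron_end)
        pooled = pooled[~bad]

    reads: dict[Junction, int] = {}
    by_donor: dict[tuple[str, str, int], list[Junction]] = {}
    by_acceptor: dict[tuple[str, str, int], list[Junction]] = {}
    by_coords: dict[tuple[str, str], list[Junction]] = {}
    for row in pooled.itertuples(index=False):
        j: Junction = (row.chrom, int(row.intron_start), int(row.intron_end), row.strand)
        reads[j] = int(row.reads)
        by_donor.setdefault((j[0], j[3], donor_of(j)), []).append(j)
        by_acceptor.setdefault((j[0], j[3], acceptor_of(j)), []).append(j)
        by_coords.setdefault((j[0], j[3]), []).append(j)

    ann_sites = annotation.splice_sites()
    ann_introns = annotation.intron_set

    def is_annotated(juncs: tuple[Junction, ...]) -> bool:
        return all((j[0], j[3], j[1]) in ann_sites and (j[0], j[3], j[2]) in ann_sites
                   for j in juncs)

    def supported(juncs: tuple[Junction, ...]) -> bool:
        return all(reads.get(j, 0) >= min_event_count for j in juncs)

    # acceptor genomic position -> terminal-exon ids reachable through it
    terminal_acceptors: dict[tuple[str, str, int], set[tuple[int, int]]] = {}
    for row in annotation.terminal_exons.itertuples(index=False):
        pos = row.start - 1 if row.strand == "+" else row.end + 1
        terminal_acceptors.setdefault((row.chrom, row.strand, pos), set()).add(
            (int(row.start), int(row.end)))

    events: list[SpliceEvent] = []
    # junction pairs already explained by a cassette exon, keyed by the
    # shared splice site: {donor-side inclusion, exclusion} and
    # {acceptor-side inclusion, exclusion}
    ce_donor_pairs: set[frozenset[Junction]] = set()
    ce_acceptor_pairs: set[frozenset[Junction]] = set()
    cassette_exons: dict[tuple[str, str, int, int], tuple[Junction, Junction]] = {}

    # --- exon paths bounded by an upstream and a downstream junction:
    #     (s, a) + (b, e) with s < a < b < e define an internal exon
    #     a+1 .. b-1 "flanked" by outer splice sites (s, e).
    flanked_exons: dict[tuple[str, str, int, int],
                        list[tuple[tuple[int, int], Junction, Junction]]] = {}
    for (chrom, strand), juncs in sorted(by_coords.items()):
        starts: dict[int, list[Junction]] = {}
        ends: dict[int, list[Junction]] = {}
        for j in juncs:
            starts.setdefault(j[1], []).append(j)
            ends.setdefault(j[2], []).append(j)
        for s in sorted(starts):
            for j1 in starts[s]:          # (s, a)
                a = j1[2]
                for e in sorted(ends):
                    if e <= a + 1:
                        continue
                    for j2 in ends[e]:    # (b, e)
                        b = j2[1]
                        if a < b:
                            flanked_exons.setdefault((chrom, strand, s, e), []).append(
                                ((a + 1, b - 1), j1, j2))

    # --- cassette exons: a flanked exon whose outer junction (s, e) exists
    for (chrom, strand, s, e), paths in sorted(flanked_exons.items()):
        jx: Junction = (chrom, s, e, strand)
        if jx not in reads:
            continue
        for (exon, j1, j2) in paths:
            inc, exc = (j1, j2), (jx,)
            if not supported(inc + exc):
                continue
            ev = SpliceEvent(
                event_id=_event_id("CE", chrom, strand, inc, exc),
                as_type="CE", chrom=chrom, strand=strand,
                gene=_gene_for_sites(annotation, chrom, strand, [s, e]),
                inclusion_junctions=inc, exclusion_junctions=exc,
                annotated=is_annotated(inc + exc),
            )
            events.append(assign_proximal_distal(ev))
            cassette_exons[(chrom, strand, *exon)] = (j1, j2)
            donor_side = j1 if strand == "+" else j2
            acceptor_side = j2 if strand == "+" else j1
            ce_donor_pairs.add(frozenset((donor_side, jx)))
            ce_acceptor_pairs.add(frozenset((acceptor_side, jx)))

    # --- mutually exclusive exons: two flanked exons sharing outer splice
    #     sites (s, e), non-overlapping, never co-occurring in any
    #     annotated transcript, and with no junction bridging them.
    #     Their entry/exit junction pairs are then not re-reported as
    #     A3SS/A5SS.
    mxe_pairs: set[frozenset[Junction]] = set()
    for (chrom, strand, s, e), paths in sorted(flanked_exons.items()):
        for i in range(len(paths)):
            for k in range(i + 1, len(paths)):
                (exA, jAu, jAd), (exB, jBu, jBd) = sorted((paths[i], paths[k]))
                if exA[1] >= exB[0]:
                    continue  # overlapping exon choices, not mutually exclusive
                cooccur = any(exA in set(exons) and exB in set(exons)
                              for exons in annotation.transcript_exons.values())
                bridged = (chrom, exA[1] + 1, exB[0] - 1, strand) in reads
                if cooccur or bridged:
                    continue
                inc, exc = (jAu, jAd), (jBu, jBd)
                if not supported(inc + exc):
                    continue
                events.append(SpliceEvent(
                    event_id=_event_id("MXE", chrom, strand, inc, exc),
                    as_type="MXE", chrom=chrom, strand=strand,
                    gene=_gene_for_sites(annotation, chrom, strand, [s, e]),
                    inclusion_junctions=inc, exclusion_junctions=exc,
                    annotated=is_annotated(inc + exc),
                ))
                mxe_pairs.add(frozenset((jAu, jBu)))
                mxe_pairs.add(frozenset((jAd, jBd)))

    # --- events defined by two junctions sharing a donor: ALE or A3SS
    for (chrom, strand, donor), juncs in sorted(by_donor.items()):
        juncs = [j for j in juncs if reads.get(j, 0) >= min_event_count]
        if len(juncs) < 2:
            continue
        # drop pairs already explained as cassette-exon inclusion/exclusion
        candidates = sorted(juncs, key=lambda j: reads[j], reverse=True)
        if len(candidates) > 2:
            logger.info("donor %s:%s:%d has %d acceptor choices; "
                        "splitting pairwise against the most-used acceptor",
                        chrom, strand, donor, len(candidates))
        top = candidates[0]
        for other in candidates[1:]:
            pair_key = frozenset((top, other))
            if pair_key in ce_donor_pairs or pair_key in mxe_pairs:
                continue
            accs = {acceptor_of(top), acceptor_of(other)}
            term_hits = [terminal_acceptors.get((chrom, strand, a), set()) for a in accs]
            is_ale = all(term_hits) and term_hits[0] != term_hits[1]
            as_type = "ALE" if is_ale else "A3SS"
            pair = sorted((top, other), key=lambda j: abs(acceptor_of(j) - donor))
            inc, exc = (pair[0],), (pair[1],)  # inclusion isoform = proximal acceptor
            ev = SpliceEvent(
                event_id=_event_id(as_type, chrom, strand, inc, exc),
                as_type=as_type, chrom=chrom, strand=strand,
                gene=_gene_for_sites(annotation, chrom, strand,
                                     [donor, *sorted(accs)]),
                inclusion_junctions=inc, exclusion_junctions=exc,
                annotated=is_annotated(inc + exc),
            )
            events.append(assign_proximal_distal(ev))

    # --- two junctions sharing an acceptor: A5SS
    for (chrom, strand, acc), juncs in sorted(by_acceptor.items()):
        juncs = [j for j in juncs if reads.get(j, 0) >= min_event_count]
        if len(juncs) < 2:
            continue
        candidates = sorted(juncs, key=lambda j: reads[j], reverse=True)
        top = candidates[0]
        for other in candidates[1:]:
            # skip pairs already explained as the acceptor-side flank of a
            # cassette exon (skip junction vs downstream inclusion junction)
            # or as the exit junctions of mutually exclusive exons
            pair_key = frozenset((top, other))
            if pair_key in ce_acceptor_pairs or pair_key in mxe_pairs:
                continue
            pair = sorted((top, other), key=lambda j: abs(donor_of(j) - acc))
            inc, exc = (pair[0],), (pair[1],)
            ev = SpliceEvent(
                event_id=_event_id("A5SS", chrom, strand, inc, exc),
                as_type="A5SS", chrom=chrom, strand=strand,
                gene=_gene_for_sites(annotation, chrom, strand, [acc]),
                inclusion_junctions=inc, exclusion_junctions=exc,
                annotated=is_annotated(inc + exc),
            )
            events.append(ev)

    # --- intron retention: annotated introns with junction evidence
    #     (exclusion) and intron-body evidence (inclusion)
    body_reads: dict[Junction, int] = {}
    if body_counts is not None and len(body_counts):
        pooled_body = body_counts.groupby(key, as_index=False)["reads"].sum()
        body_reads = {(r.chrom, int(r.intron_start), int(r.intron_end), r.strand): int(r.reads)
                      for r in pooled_body.itertuples(index=False)}
    for row in annotation.introns.itertuples(index=False):
        j: Junction = (row.chrom, int(row.intron_start), int(row.intron_end), row.strand)
        if reads.get(j, 0) >= min_event_count and body_reads.get(j, 0) > 0:
            events.append(SpliceEvent(
                event_id=f"IR:{row.chrom}:{row.strand}:{j[1]}-{j[2]}",
                as_type="IR", chrom=row.chrom, strand=row.strand,
                gene=str(row.gene_id),
                inclusion_junctions=(), exclusion_junctions=(j,),
                annotated=True, intron_length=j[2] - j[1] + 1,
            ))

    seen: set[str] = set()
    unique: list[SpliceEvent] = []
    for ev in events:
        if ev.event_id not in seen:
            seen.add(ev.event_id)
            unique.append(ev)
    return unique


@dataclass
class PsiTable:
    """Events × samples PSI percentages with read-support totals.

    ``psi`` holds percentages in [0, 100] with NaN where support fell
    below the threshold; ``totals`` holds the inclusion+exclusion read
    support that produced each entry.
    """

    psi: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 100:
                raise ValueError("PSI values outside [0, 100]")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _junction_lookup(table: pd.DataFrame) -> dict[Junction, int]:
    return {(r.chrom, int(r.intron_start), int(r.intron_end), r.strand): int(r.reads)
            for r in table.itertuples(index=False)}


def event_support(event: SpliceEvent, lookup: dict[Junction, int],
                  body_lookup: dict[Junction, int] | None = None,
                  jcn_seq_len: int = 88) -> tuple[float, float]:
    """Inclusion/exclusion read support (I, E) for one event in one sample.

    CE and MXE inclusion pools the two flanking junctions as their mean,
    rounded half-up, so a single cDNA fragment is not double-counted.
    IR inclusion is the intron-body count scaled by
    ``jcn_seq_len / intron_length`` to put body coverage on the scale of
    junction counts.
    """
    def count(j: Junction) -> int:
        c = lookup.get(j, 0)
        if c < 0:
            raise ValueError(f"negative read count for junction {j}")
        return c

    if event.as_type in ("CE", "MXE"):
        inc_counts = [count(j) for j in event.inclusion_junctions]
        I: float = _round_half_up(sum(inc_counts) / len(inc_counts))
        if event.as_type == "MXE":
            exc_counts = [count(j) for j in event.exclusion_junctions]
            E: float = _round_half_up(sum(exc_counts) / len(exc_counts))
        else:
            E = sum(count(j) for j in event.exclusion_junctions)
    elif event.as_type == "IR":
        body = 0
        if body_lookup:
            body = body_lookup.get(event.exclusion_junctions[0], 0)
        if body < 0:
            raise ValueError("negative intron-body count")
        I = body * jcn_seq_len / float(event.intron_length or 1)
        E = sum(count(j) for j in event.exclusion_junctions)
    else:
        I = sum(count(j) for j in event.inclusion_junctions)
        E = sum(count(j) for j in event.exclusion_junctions)
    return I, E


def compute_psi(events: list[SpliceEvent],
                sample_tables: dict[str, pd.DataFrame],
                psi_min_total: int = 10,
                jcn_seq_len: int = 88,
                body_tables: dict[str, pd.DataFrame] | None = None) -> PsiTable:
    """Quantify PSI = 100·I/(I+E) for every event in every sample.

    ``sample_tables`` maps sample_id -> junction table; ``body_tables``
    optionally maps sample_id -> intron-body count table (same columns)
    for intron-retention events. Entries with I+E below ``psi_min_total``
    are left missing.
    """
    sample_ids = list(sample_tables)
    lookups = {s: _junction_lookup(t) for s, t in sample_tables.items()}
    body_lookups = ({s: _junction_lookup(t) for s, t in body_tables.items()}
                    if body_tables else {})
    psi = np.full((len(events), len(sample_ids)), np.nan)
    totals = np.zeros((len(events), len(sample_ids)))
    for i, ev in enumerate(events):
        for k, s in enumerate(sample_ids):
            I, E = event_support(ev, lookups[s], body_lookups.get(s), jcn_seq_len)
            total = I + E
            totals[i, k] = total
            if total >= psi_min_total and total > 0:
                psi[i, k] = 100.0 * I / total
    index = [ev.event_id for ev in events]
    return PsiTable(psi=pd.DataFrame(psi, index=index, columns=sample_ids),
                    totals=pd.DataFrame(totals, index=index, columns=sample_ids))


def events_frame(events: list[SpliceEvent]) -> pd.DataFrame:
    """Tabular view of events (one row each) for reports and the CLI."""
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id, "as_type": ev.as_type, "gene": ev.gene,
            "chrom": ev.chrom, "strand": ev.strand,
            "proximal_3ss": ev.proximal_3ss, "distal_3ss": ev.distal_3ss,
            "annotated": ev.annotated,
            "inclusion_junctions": ";".join(f"{j[1]}-{j[2]}" for j in ev.inclusion_junctions),
            "exclusion_junctions": ";".join(f"{j[1]}-{j[2]}" for j in ev.exclusion_junctions),
        })
    return pd.DataFrame(rows)
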