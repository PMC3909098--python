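"""Synthetic cohorts with planted splicing effects.

The generator builds a toy genome and transcript annotation in which
every gene carries one alternative-splicing event of a requested class,
then samples per-sample junction read counts with the statistical
structure the analysis assumes: per-event totals are negative-binomially
overdispersed around a mean sequencing depth, and reads are allocated
between the inclusion and exclusion isoforms binomially at the event's
true PSI. A planted subset of events shifts PSI between the control and
mutant groups; for cassette-exon and alternative-3'ss events the planted
shift is toward the distal splice site, and the −3 bases of the two
competing acceptors are oriented (proximal TAG, distal CAG) for a
configurable fraction of planted events, emulating the mutation-induced
splice-site sequence preference the pipeline is designed to detect.

Every intron is canonical: GT donor, AG acceptor, with the −3 base
drawn per the configured class. All outputs are deterministic under the
spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SampleSheet
from .events import SpliceEvent, _event_id, assign_proximal_distal
from .io import Annotation, read_annotation
from .splice_sites import _revcomp

logger = logging.getLogger("spliceshift")

__all__ = ["SimulationSpec", "SimulatedLoci", "generate_genome_and_annotation",
           "simulate_counts", "write_simulation"]

_PAD = 60  # flanking pad per chromosome so acceptor windows stay in bounds
_CLASS_BASE = {"TAG": "T", "CAG": "C", "AAG": "A"}


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort structure and noise model for a simulated experiment.

    Defaults describe the scenario the pipeline targets: a small mutant
    group (8 samples) against a larger control group, events at ~100x
    junction coverage with moderate overdispersion, a quarter of events
    carrying a 30-percentage-point PSI shift toward the distal splice
    site, and 80% of the planted two-acceptor events oriented with a TAG
    proximal and a CAG distal site.
    """

    events_per_class: dict = field(default_factory=lambda: {"CE": 100, "A3SS": 100})
    n_mutant: int = 8
    n_control: int = 20
    baseline_psi_range: tuple[float, float] = (5.0, 95.0)
    planted_fraction: float = 0.25
    planted_delta: float = 30.0
    planted_orientation: float = 0.8
    mean_depth: float = 100.0
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_fraction", "planted_orientation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("mean_depth and dispersion must be positive")
        lo, hi = self.baseline_psi_range
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"invalid baseline_psi_range {self.baseline_psi_range}")
        bad = set(self.events_per_class) - {"CE", "A3SS", "A5SS", "ALE", "IR", "MXE"}
        if bad:
            raise ValueError(f"unknown event classes: {sorted(bad)}")


@dataclass
class SimulatedLoci:
    """Generated genome, annotation, event set, and ground truth."""

    genome: dict[str, str]
    gtf_text: str
    annotation: Annotation
    events: list[SpliceEvent]
    truth: pd.DataFrame  # event_id, as_type, is_planted, baseline_psi, true_delta, ...


def _tx_to_genomic(pos: int, strand: str, locus_len: int) -> int:
    """Map a 1-based transcript-orientation position to genomic (with pad)."""
    return _PAD + pos if strand == "+" else _PAD + locus_len + 1 - pos


def _interval_to_genomic(a: int, b: int, strand: str, locus_len: int) -> tuple[int, int]:
    x, y = _tx_to_genomic(a, strand, locus_len), _tx_to_genomic(b, strand, locus_len)
    return (x, y) if x <= y else (y, x)


class _GeneBuilder:
    """One gene locus in transcript orientation, with canonical introns."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.seq: list[str] = []

    def random_seq(self, n: int) -> int:
        start = len(self.seq) + 1
        self.seq.extend(self.rng.choice(list("ACGT"), size=n))
        return start

    def set_donor(self, ts: int) -> None:
        self.seq[ts - 1], self.seq[ts] = "G", "T"

    def set_acceptor(self, te: int, minus3: str) -> None:
        self.seq[te - 3], self.seq[te - 2], self.seq[te - 1] = minus3, "A", "G"


def _pick_classes(rng: np.random.Generator, planted: bool, orientation: float) -> tuple[str, str]:
    """(-3 class of proximal acceptor, -3 class of distal acceptor)."""
    if planted:
        if rng.random() < orientation:
            return "TAG", "CAG"
        return "CAG", "TAG"
    classes = ("TAG", "CAG", "AAG")
    return str(rng.choice(classes)), str(rng.choice(classes))


def generate_genome_and_annotation(spec: SimulationSpec) -> SimulatedLoci:
    """Build the toy genome, GTF annotation, events and truth table.

    Each gene sits on its own chromosome with flanking pads; strands
    alternate. Byte-identical output under the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    gtf_lines: list[str] = []
    events: list[SpliceEvent] = []
    truth_rows: list[dict] = []

    order = [(cls, i) for cls in sorted(spec.events_per_class)
             for i in range(spec.events_per_class[cls])]
    n_events = len(order)
    planted_mask = np.zeros(n_events, dtype=bool)
    n_planted = int(round(spec.planted_fraction * n_events))
    planted_mask[rng.choice(n_events, size=n_planted, replace=False)] = True

    lo, hi = spec.baseline_psi_range
    for gi, ((cls, _), planted) in enumerate(zip(order, planted_mask)):
        chrom = f"chr{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        gene = f"gene{gi + 1}"
        b = _GeneBuilder(rng)
        prox_class, dist_class = _pick_classes(rng, planted, spec.planted_orientation)

        exon_len = lambda: int(rng.integers(80, 151))
        intron_len = lambda: int(rng.integers(120, 301))

        tx1_exons: list[tuple[int, int]] = []
        tx2_exons: list[tuple[int, int]] = []
        inc: list[tuple[int, int]] = []  # transcript-coord introns, inclusion isoform
        exc: list[tuple[int, int]] = []

        if cls == "CE":
            e1 = (b.random_seq(exon_len()), len(b.seq))
            i1s = b.random_seq(intron_len()); i1 = (i1s, len(b.seq))
            e2 = (b.random_seq(exon_len()), len(b.seq))
            i2s = b.random_seq(intron_len()); i2 = (i2s, len(b.seq))
            e3 = (b.random_seq(exon_len()), len(b.seq))
            b.set_donor(i1[0]); b.set_acceptor(i1[1], _CLASS_BASE[prox_class])
            b.set_donor(i2[0]); b.set_acceptor(i2[1], _CLASS_BASE[dist_class])
            tx1_exons, tx2_exons = [e1, e2, e3], [e1, e3]
            inc, exc = [i1, i2], [(i1[0], i2[1])]
        elif cls in ("A3SS", "ALE"):
            e1 = (b.random_seq(exon_len()), len(b.seq))
            istart = b.random_seq(intron_len()); prox_acc = len(b.seq)
            mid = b.random_seq(exon_len()) if cls == "ALE" else b.random_seq(20)
            if cls == "ALE":
                # terminal exon A then a gap, then terminal exon B
                exonA_end = len(b.seq)
                b.random_seq(intron_len())
                dist_acc = len(b.seq)
                eB = (b.random_seq(exon_len()), len(b.seq))
                b.set_donor(istart); b.set_acceptor(prox_acc, _CLASS_BASE[prox_class])
                b.set_acceptor(dist_acc, _CLASS_BASE[dist_class])
                exonA = (prox_acc + 1, exonA_end)
                tx1_exons, tx2_exons = [e1, exonA], [e1, eB]
                inc, exc = [(istart, prox_acc)], [(istart, dist_acc)]
            else:
                dist_acc = len(b.seq)
                e2 = (b.random_seq(exon_len()), len(b.seq))
                # shared downstream intron + terminal exon keep the
                # alternative acceptors internal, not transcript ends
                i2s = b.random_seq(intron_len()); i2 = (i2s, len(b.seq))
                e3 = (b.random_seq(exon_len()), len(b.seq))
                b.set_donor(istart)
                b.set_acceptor(prox_acc, _CLASS_BASE[prox_class])
                b.set_acceptor(dist_acc, _CLASS_BASE[dist_class])
                b.set_donor(i2[0]); b.set_acceptor(i2[1], "CAG")
                tx1_exons = [e1, (prox_acc + 1, e2[1]), e3]
                tx2_exons = [e1, (dist_acc + 1, e2[1]), e3]
                inc, exc = [(istart, prox_acc)], [(istart, dist_acc)]
        elif cls == "A5SS":
            e1 = (b.random_seq(exon_len()), len(b.seq))
            prox_don = b.random_seq(20)  # distal donor extends the exon
            dist_don_start = b.random_seq(intron_len())
            acc = len(b.seq)
            e2 = (b.random_seq(exon_len()), len(b.seq))
            b.set_donor(prox_don); b.set_donor(dist_don_start)
            b.set_acceptor(acc, _CLASS_BASE[prox_class])
            tx1_exons = [(e1[0], dist_don_start - 1), e2]   # long exon, short intron
            tx2_exons = [(e1[0], prox_don - 1), e2]         # short exon, long intron
            inc, exc = [(dist_don_start, acc)], [(prox_don, acc)]
        elif cls == "IR":
            e1 = (b.random_seq(exon_len()), len(b.seq))
            i1s = b.random_seq(intron_len()); i1 = (i1s, len(b.seq))
            e2 = (b.random_seq(exon_len()), len(b.seq))
            b.set_donor(i1[0]); b.set_acceptor(i1[1], _CLASS_BASE[prox_class])
            tx1_exons, tx2_exons = [e1, e2], [(e1[0], e2[1])]
            inc, exc = [], [i1]
        elif cls == "MXE":
            e1 = (b.random_seq(exon_len()), len(b.seq))
            i1s = b.random_seq(intron_len()); a1 = len(b.seq)
            eA = (b.random_seq(exon_len()), len(b.seq))
            i2s = b.random_seq(intron_len()); a2 = len(b.seq)
            eB = (b.random_seq(exon_len()), len(b.seq))
            i3s = b.random_seq(intron_len()); a3 = len(b.seq)
            e4 = (b.random_seq(exon_len()), len(b.seq))
            for don in (i1s, i2s, i3s):
                b.set_donor(don)
            b.set_acceptor(a1, _CLASS_BASE[prox_class])
            b.set_acceptor(a2, _CLASS_BASE[dist_class])
            b.set_acceptor(a3, "CAG")
            tx1_exons, tx2_exons = [e1, eA, e4], [e1, eB, e4]
            inc = [(i1s, a1), (eA[1] + 1, a3)]
            exc = [(i1s, a2), (eB[1] + 1, a3)]
        else:  # pragma: no cover
            raise AssertionError(cls)

        locus = "".join(b.seq)
        L = len(locus)
        pad5 = "".join(rng.choice(list("ACGT"), size=_PAD))
        pad3 = "".join(rng.choice(list("ACGT"), size=_PAD))
        genome[chrom] = pad5 + (locus if strand == "+" else _revcomp(locus)) + pad3

        def g_interval(iv: tuple[int, int]) -> tuple[int, int]:
            return _interval_to_genomic(iv[0], iv[1], strand, L)

        for tx_idx, exons in enumerate((tx1_exons, tx2_exons), start=1):
            g_exons = sorted(g_interval(e) for e in exons)
            for s, e in g_exons:
                gtf_lines.append(
                    f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f'gene_id "{gene}"; transcript_id "{gene}.t{tx_idx}";')

        inc_j = tuple((chrom, *g_interval(iv), strand) for iv in inc)
        exc_j = tuple((chrom, *g_interval(iv), strand) for iv in exc)
        if cls == "MXE":
            # canonical orientation: isoform 1 = genomically leftmost exon
            if min(j[2] for j in inc_j) > min(j[2] for j in exc_j):
                inc_j, exc_j = exc_j, inc_j
        if cls == "IR":
            s, e = g_interval(exc[0])
            event = SpliceEvent(
                event_id=f"IR:{chrom}:{strand}:{s}-{e}", as_type="IR",
                gene=gene, chrom=chrom, strand=strand,
                inclusion_junctions=(), exclusion_junctions=exc_j,
                annotated=True, intron_length=e - s + 1)
        else:
            event = SpliceEvent(
                event_id=_event_id(cls, chrom, strand, inc_j, exc_j),
                as_type=cls, gene=gene, chrom=chrom, strand=strand,
                inclusion_junctions=inc_j, exclusion_junctions=exc_j,
                annotated=True)
            if cls in ("CE", "A3SS", "ALE"):
                event = assign_proximal_distal(event)
        events.append(event)

        baseline = float(rng.uniform(lo, hi))
        true_delta = -spec.planted_delta if planted else 0.0
        mutant_psi = baseline + true_delta
        if planted and not (1.0 <= mutant_psi <= 99.0):
            clipped = min(max(mutant_psi, 1.0), 99.0)
            logger.info("clipping planted PSI %.1f -> %.1f for %s",
                        mutant_psi, clipped, event.event_id)
            mutant_psi = clipped
            true_delta = mutant_psi - baseline
        truth_rows.append({
            "event_id": event.event_id, "as_type": cls, "gene": gene,
            "is_planted": bool(planted), "baseline_psi": baseline,
            "true_delta": true_delta if planted else 0.0,
            "proximal_class": prox_class if cls in ("CE", "A3SS", "ALE") else "",
            "distal_class": dist_class if cls in ("CE", "A3SS", "ALE") else "",
            "direction": ("skipping" if planted and true_delta < 0 else
                          "inclusion" if planted else ""),
        })

    gtf_text = "\n".join(gtf_lines) + "\n"
    annotation = _annotation_from_gtf_text(gtf_text)
    truth = pd.DataFrame(truth_rows)
    assert truth["event_id"].is_unique
    return SimulatedLoci(genome=genome, gtf_text=gtf_text, annotation=annotation,
                         events=events, truth=truth)


def _annotation_from_gtf_text(text: str) -> Annotation:
    import os
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_annotation(name)
    finally:
        os.unlink(name)


def simulate_counts(spec: SimulationSpec, loci: SimulatedLoci,
                    jcn_seq_len: int = 88
                    ) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], SampleSheet]:
    """Sample per-sample junction tables under the spec's noise model.

    Returns (junction tables, intron-body tables, sample sheet). Totals
    per event per sample are NegBin(mean_depth, dispersion); inclusion
    reads are Binomial(total, PSI/100) with the event's group PSI.
    Intron-body counts for IR events are scaled so that the pipeline's
    ``jcn_seq_len``-normalised inclusion support matches the drawn reads.
    """
    rng = np.random.default_rng(spec.seed + 1)
    samples = ([(f"mut{i + 1}", "mutant") for i in range(spec.n_mutant)]
               + [(f"ctl{i + 1}", "control") for i in range(spec.n_control)])
    sheet = SampleSheet(pd.DataFrame(samples, columns=["sample_id", "group"]))

    truth = loci.truth.set_index("event_id")
    nb_p = spec.dispersion / (spec.dispersion + spec.mean_depth)
    tables: dict[str, pd.DataFrame] = {}
    body_tables: dict[str, pd.DataFrame] = {}
    for sample_id, group in samples:
        rows, body_rows = [], []
        for ev in loci.events:
            info = truth.loc[ev.event_id]
            psi = info["baseline_psi"] + (info["true_delta"] if group == "mutant" else 0.0)
            total = int(rng.negative_binomial(spec.dispersion, nb_p))
            inclusion = int(rng.binomial(total, psi / 100.0)) if total else 0
            exclusion = total - inclusion
            for j in ev.inclusion_junctions:
                rows.append((*j, inclusion))
            for j in ev.exclusion_junctions:
                rows.append((*j, exclusion))
            if ev.as_type == "IR":
                body = int(round(inclusion * (ev.intron_length or 1) / jcn_seq_len))
                body_rows.append((*ev.exclusion_junctions[0], body))
        df = pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end",
                                         "strand", "reads"])
        key = ["chrom", "intron_start", "intron_end", "strand"]
        tables[sample_id] = df.groupby(key, as_index=False)["reads"].sum()
        if body_rows:
            body_tables[sample_id] = pd.DataFrame(
                body_rows, columns=["chrom", "intron_start", "intron_end",
                                    "strand", "reads"])
    return tables, body_tables, sheet


def write_simulation(loci: SimulatedLoci, tables: dict[str, pd.DataFrame],
                     body_tables: dict[str, pd.DataFrame], sheet: SampleSheet,
                     outdir) -> None:
    """Write FASTA + GTF + per-sample TSVs + sample sheet + truth table."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in loci.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    (outdir / "annotation.gtf").write_text(loci.gtf_text)
    loci.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sheet_df = sheet.table.copy()
    for sample_id, df in tables.items():
        path = outdir / f"{sample_id}.junctions.tsv"
        df.to_csv(path, sep="\t", index=False)
        sheet_df.loc[sheet_df["sample_id"] == sample_id, "file_path"] = str(path)
    for sample_id, df in body_tables.items():
        df.to_csv(outdir / f"{sample_id}.intron_body.tsv", sep="\t", index=False)
    sheet_df.to_csv(outdir / "samples.tsv", sep="\t", index=False)
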