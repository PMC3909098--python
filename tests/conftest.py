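"""Shared fixtures: tiny hand-built loci and a small simulated cohort."""

import pandas as pd
import pytest

import spliceshift as ss


def make_junctions(rows):
    """rows: iterable of (chrom, start, end, strand, reads)."""
    return pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end",
                                       "strand", "reads"])


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    """Three-gene annotation: a plus-strand 3-exon gene (cassette exon),
    a gene with two transcripts sharing an intron, and an A3SS gene."""
    text = "\n".join([
        # geneA: exons 1-100, 201-300, 401-500 (+); skip transcript 1-100,401-500
        'chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "geneA"; transcript_id "A.t1";',
        'chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "geneA"; transcript_id "A.t1";',
        'chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "geneA"; transcript_id "A.t1";',
        'chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "geneA"; transcript_id "A.t2";',
        'chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "geneA"; transcript_id "A.t2";',
        # geneB: two transcripts sharing intron 1101-1200 (+)
        'chr1\ttest\texon\t1001\t1100\t.\t+\t.\tgene_id "geneB"; transcript_id "B.t1";',
        'chr1\ttest\texon\t1201\t1300\t.\t+\t.\tgene_id "geneB"; transcript_id "B.t1";',
        'chr1\ttest\texon\t1001\t1100\t.\t+\t.\tgene_id "geneB"; transcript_id "B.t2";',
        'chr1\ttest\texon\t1201\t1320\t.\t+\t.\tgene_id "geneB"; transcript_id "B.t2";',
    ]) + "\n"
    path = tmp_path_factory.mktemp("ann") / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def toy_annotation(toy_gtf):
    return ss.read_annotation(toy_gtf)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort at the standard scenario (seeded)."""
    spec = ss.SimulationSpec(seed=2024)
    loci = ss.generate_genome_and_annotation(spec)
    tables, body, sheet = ss.simulate_counts(spec, loci)
    events = ss.build_events(ss.pool_junctions(tables), loci.annotation,
                             min_event_count=2.0,
                             body_counts=ss.pool_junctions(body) if body else None)
    return spec, loci, tables, body, sheet, events
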