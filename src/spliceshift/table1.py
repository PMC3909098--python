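"""The 30 commonly altered splicing events shared by the two cancer cohorts.

A machine-readable transcription of the published table of splicing
alterations associated with U2AF1 S34F/Y mutation in both lung
adenocarcinoma and AML: gene symbol, AS type (CE = cassette exon, A3S =
alternative 3' splice site, ALE = alternative last exon), whether the
mutant samples shifted toward the distal 3' splice site, whether the
event was also significantly affected by S34F induction in HeLa cells,
the genomic positions of the two competing splice sites (hg19, 1-based),
strand, and the 3' splice-site preference class (a = TAG→CAG, b =
TAG→AAG, c = other).

Notes preserved from the source: the SERF1B symbol appears twice with
distinct coordinate pairs; one A3S event lists two distal splice-site
choices separated by ';'; the CTNNB1 event also changed upon wild-type
induction but in the opposite direction (``hela_opposite_in_wt``).
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = ["table1_fixture", "TABLE1_TSV"]

TABLE1_TSV = """\
gene	as_type	distal_usage	hela	hela_opposite_in_wt	proximal_site	distal_site	strand	pref
ACAD8	CE	Y	Y		chr11:134126981	chr11:134128408	+	a
C12orf11	CE	Y	Y		chr12:27067512	chr12:27067062	-	a
C17orf45	A3S	Y	Y		chr17:16342841	chr17:16342973;chr17:16342894	+	c
CHCHD7	A3S	Y	Y		chr8:57128947	chr8:57128991	+	b
CTNNB1	A3S		Y	Y	chr3:41281150	chr3:41281309	+	c
FAM60A	CE		Y		chr12:31458058	chr12:31451159	-	c
FXR1	CE		Y		chr3:180693100	chr3:180693909	+	c
GUSB	CE	Y	Y		chr7:65440059	chr7:65439692	-	c
HMGCR	CE	Y	Y		chr5:74650880	chr5:74651189	+	c
KARS	CE	Y	Y		chr16:75678361	chr16:75675622	-	a
KIAA0182	A3S	Y			chr16:85696949	chr16:85696991	+	a
MAP3K3	CE				chr17:61712068	chr17:61723393	+	c
MARK3	A3S	Y			chr14:103934369	chr14:103934417	+	b
MR1	CE	Y	Y		chr1:181021370	chr1:181022708	+	a
NSUN2	CE	Y			chr5:6632091	chr5:6625783	-	a
PABPC4	CE	Y			chr1:40029595	chr1:40029414	-	b
PICALM	A3S				chr11:85693047	chr11:85693032	-	b
PPHLN1	CE	Y	Y		chr12:42745686	chr12:42748962	+	a
PPM1B	ALE				chr2:44457551	chr2:44459454	+	b
PTBP1	CE	Y			chr19:805512	chr19:806407	+	a
RIPK2	CE	Y	Y		chr8:90775056	chr8:90777568	+	b
SERF1B	ALE	Y			chr5:69328141	chr5:69337350	+	a
SERF1B	ALE	Y			chr5:70203560	chr5:70212767	+	a
SETD4	CE		Y		chr21:37429776	chr21:37429503	-	b
SETX	CE		Y		chr9:135144877	chr9:135140373	-	c
STRAP	CE	Y			chr12:16036474	chr12:16042861	+	c
TMEM131	CE	Y	Y		chr2:98411579	chr2:98410017	-	a
USP25	CE				chr21:17222095	chr21:17236586	+	c
USP33	A3S		Y		chr1:78187611	chr1:78187587	-	a
ZRANB2	CE				chr1:71531436	chr1:71530821	-	c
"""


def _split_site(site: str) -> tuple[str, int]:
    chrom, pos = site.split(":")
    return chrom, int(pos)


def table1_fixture() -> pd.DataFrame:
    """The 30 shared events as a DataFrame with parsed coordinates.

    Adds ``chrom``, ``proximal_3ss`` and ``distal_3ss`` (for rows with
    several distal choices, the first listed), and boolean versions of
    the Y/blank flag columns.
    """
    df = pd.read_csv(_io.StringIO(TABLE1_TSV), sep="\t", keep_default_na=False)
    for col in ("distal_usage", "hela", "hela_opposite_in_wt"):
        df[col] = df[col] == "Y"
    prox = df["proximal_site"].map(_split_site)
    dist = df["distal_site"].map(lambda s: _split_site(s.split(";")[0]))
    df["chrom"] = prox.map(lambda t: t[0])
    df["proximal_3ss"] = prox.map(lambda t: t[1])
    df["distal_3ss"] = dist.map(lambda t: t[1])
    df["event_id"] = (df["gene"] + ":" + df["as_type"] + ":" + df["chrom"] + ":"
                      + df["proximal_3ss"].astype(str) + "-" + df["distal_3ss"].astype(str))
    return df
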