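#!/usr/bin/env python
"""Scan the anchor set for epistasis and classify the named cases.

Enumerates every observable (background, A, B) quadruple in the anchor set
(wild type included), computes ε on the fold-repression scale and writes
the full report; then prints the four named group combinations — negative
ε for D33E x S57R, positive for [S57R P94L] x V188F, magnitude epistasis
for D33E x [P94L V188F] and reciprocal-sign for P94L x [G83V V188F A199S
G212S], the latter two in the S57R background.
"""

from pathlib import Path

from anchorscape import (
    EpistasisQuery,
    Variant,
    enumerate_quadruples,
    fixture_with_wildtype,
    scan_epistasis,
)
from anchorscape.io import write_epistasis_table
from anchorscape.variants import parse_mutation

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

anchors = fixture_with_wildtype()
queries = enumerate_quadruples(anchors, max_group_size=4)
report = scan_epistasis(anchors, queries)
write_epistasis_table(report, OUT / "epistasis.tsv")
print(f"{len(queries)} observable quadruples, {len(report.results)} evaluated")
by_class = {}
for r in report.results:
    by_class[r.klass] = by_class.get(r.klass, 0) + 1
print("class counts:", by_class)


def fs(*toks):
    return frozenset(parse_mutation(t) for t in toks)


wt = Variant(frozenset(), anchors.reference_id)
s57r = Variant(fs("S57R"), anchors.reference_id)
named = [
    ("D33E x S57R (WT bg)", EpistasisQuery(wt, fs("D33E"), fs("S57R"))),
    ("[S57R P94L] x V188F (WT bg)",
     EpistasisQuery(wt, fs("S57R", "P94L"), fs("V188F"))),
    ("D33E x [P94L V188F] (S57R bg)",
     EpistasisQuery(s57r, fs("D33E"), fs("P94L", "V188F"))),
    ("P94L x [G83V V188F A199S G212S] (S57R bg)",
     EpistasisQuery(s57r, fs("P94L"),
                    fs("G83V", "V188F", "A199S", "G212S"))),
]
print("\nnamed combinations:")
for label, q in named:
    [res] = scan_epistasis(anchors, [q]).results
    print(f"  {label:45s} eps = {res.epsilon:+8.3f}  {res.klass}")
print(f"\nwrote {OUT/'epistasis.tsv'}")
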