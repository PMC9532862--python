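"""Predict seed-match targets of the hypoxia-responsive miRNAs.

mRNA 3'UTRs are scanned linearly; circRNAs are scanned as circles so
binding sites spanning the back-splice junction are found.
"""

from pathlib import Path

import pandas as pd

import cernet
from cernet import diffexpr, targets

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "targets"
OUT.mkdir(parents=True, exist_ok=True)

matrices, design, truth, mir, utr, circ = cernet.read_fixture_bundle(
    ROOT / "fixture")
de_ids = {
    layer: diffexpr.de_features(pd.read_csv(
        ROOT / "de" / f"de_{layer}_TN_vs_TL.tsv", sep="\t",
        index_col=0).rename(columns=str))
    for layer in ("circRNA", "miRNA", "mRNA")}

de_mirs = {m: mir[m] for m in de_ids["miRNA"]}
cands_mrna = targets.predict_pairs(de_mirs,
                                   {g: utr[g] for g in de_ids["mRNA"]},
                                   "mRNA")
cands_circ = targets.predict_pairs(de_mirs,
                                   {c: circ[c] for c in de_ids["circRNA"]},
                                   "circRNA")
frame = targets.candidates_to_frame(cands_mrna + cands_circ)
frame.to_csv(OUT / "candidates_TN_vs_TL.tsv", sep="\t", index=False)

planted = {(m, t) for _, m, t in truth.planted_triples} | \
    {(m, c) for c, m, _ in truth.planted_triples}
found = {(c.mirna, c.target) for c in cands_mrna + cands_circ}
print(f"{len(cands_mrna)} miRNA-mRNA and {len(cands_circ)} miRNA-circRNA "
      "candidate pairs")
print(f"planted pairs recovered: {len(planted & found)}/{len(planted)}")
print(f"wrote candidates to {OUT}")
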