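"""Call differential expression for the within-breed hypoxia contrasts.

circRNA/miRNA: FC >= 2 and raw p < 0.05; mRNA: |FC| >= 2 and FDR < 0.05,
on the exact conditional negative-binomial test.
"""

from pathlib import Path

import cernet
from cernet import diffexpr, pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "de"
OUT.mkdir(parents=True, exist_ok=True)

matrices, design, truth, *_ = cernet.read_fixture_bundle(ROOT / "fixture")
for group_a, group_b in design.comparisons():
    print(f"comparison {group_a} vs {group_b}:")
    for layer in ("circRNA", "miRNA", "mRNA"):
        tab = diffexpr.de_table(matrices[layer], design, group_a, group_b)
        tab.to_csv(OUT / f"de_{layer}_{group_a}_vs_{group_b}.tsv", sep="\t")
        print(f"  DE{layer}s: {pipeline.de_summary(tab)}")
print(f"wrote DE tables to {OUT}")
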