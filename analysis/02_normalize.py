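"""Normalize each layer with its unit: RPM (circRNA), TPM (miRNA),
FPKM (mRNA); write the normalized matrices."""

from pathlib import Path

import cernet
from cernet import normalize
from cernet.containers import FeatureLengths

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "normalized"
OUT.mkdir(parents=True, exist_ok=True)

matrices, design, truth, mir, utr, circ = cernet.read_fixture_bundle(
    ROOT / "fixture")
norm = {
    "circRNA": normalize.rpm(matrices["circRNA"]),
    "miRNA": normalize.tpm(matrices["miRNA"],
                           FeatureLengths.from_sequences(mir)),
    "mRNA": normalize.fpkm(matrices["mRNA"],
                           FeatureLengths.from_sequences(utr)),
}
for layer, m in norm.items():
    m.to_tsv(OUT / f"{m.unit.lower()}_{layer}.tsv")
    colsum = m.values.sum(axis=0)
    print(f"{layer}: {m.unit}; column sums "
          f"{colsum.min():.6g}..{colsum.max():.6g}")
print(f"wrote normalized matrices to {OUT}")
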