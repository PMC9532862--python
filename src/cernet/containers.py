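"""Core data containers: expression matrices, sample designs, feature lengths.

Expression values travel through the pipeline as a pandas DataFrame
(features x samples) wrapped with two tags: the abundance unit
(``raw-count``, ``RPM``, ``TPM`` or ``FPKM``) and the RNA layer
(``circRNA``, ``miRNA`` or ``mRNA``).  Unit transitions are one-way:
raw counts may be normalized, normalized values are never re-normalized.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_UNITS = ("raw-count", "RPM", "TPM", "FPKM")
VALID_LAYERS = ("circRNA", "miRNA", "mRNA")

#: group labels: breed initial (Tibetan/Landrace) + oxygen initial
#: (Normoxic 21% O2 / Low-oxygen 2% O2)
GROUP_LABELS = ("TN", "TL", "LN", "LL")


@dataclasses.dataclass
class ExpressionMatrix:
    """Features x samples abundance matrix tagged with unit and layer."""

    values: pd.DataFrame
    unit: str = "raw-count"
    layer: str = "mRNA"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(),
                                self.unit, self.layer)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str = "raw-count",
                 layer: str = "mRNA") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, unit=unit, layer=layer)


@dataclasses.dataclass
class SampleDesign:
    """Per-sample breed / oxygen condition / replicate table.

    ``breed`` is "Tibetan" or "Landrace"; ``oxygen`` is "normoxic"
    (21% O2) or "hypoxic" (2% O2).  Group labels TN/TL/LN/LL follow.
    """

    table: pd.DataFrame  # index = sample id; columns breed, oxygen, replicate

    def __post_init__(self) -> None:
        required = {"breed", "oxygen", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        bad_breed = set(self.table["breed"]) - {"Tibetan", "Landrace"}
        if bad_breed:
            raise ValueError(f"unknown breed values {sorted(bad_breed)}")
        bad_oxy = set(self.table["oxygen"]) - {"normoxic", "hypoxic"}
        if bad_oxy:
            raise ValueError(f"unknown oxygen values {sorted(bad_oxy)}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids in design")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        """TN/TL/LN/LL label per sample."""
        breed = self.table["breed"].str[0]  # T or L
        oxy = self.table["oxygen"].map({"normoxic": "N", "hypoxic": "L"})
        return (breed + oxy).rename("group")

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUP_LABELS:
            raise ValueError(f"unknown group {group!r}")
        g = self.groups
        return list(g.index[g == group])

    def comparisons(self) -> list[tuple[str, str]]:
        """Within-breed normoxic-vs-hypoxic contrasts present in the design."""
        present = set(self.groups)
        pairs = [("TN", "TL"), ("LN", "LL")]
        return [(a, b) for a, b in pairs if a in present and b in present]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


class FeatureLengths(dict):
    """Feature id -> effective length in nucleotides (positive int)."""

    def __init__(self, mapping: Mapping[str, int] | None = None):
        super().__init__()
        if mapping:
            for k, v in mapping.items():
                self[k] = v

    def __setitem__(self, key: str, value: int) -> None:
        value = int(value)
        if value < 1:
            raise ValueError(f"length for {key!r} must be >= 1, got {value}")
        super().__setitem__(key, value)

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(self, name="length").to_csv(path, sep="\t",
                                              index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureLengths":
        s = pd.read_csv(path, sep="\t", index_col=0)["length"]
        return cls(s.to_dict())

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "FeatureLengths":
        return cls({k: len(v) for k, v in seqs.items()})


# ---------------------------------------------------------------------------
# FASTA helpers (sequences held in memory as plain id -> string dicts)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> RNA-string dict (T mapped to U)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper().replace("T", "U")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
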