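"""Canonical miRNA seed-site prediction on linear and circular targets.

Sites are anchored at a match to the reverse complement of the miRNA seed
(positions 2-7, 5'->3') and classified into the canonical classes by the
two flanking positions:

* ``8mer``     — seed match extended by a position-8 pair and a target A
  opposite miRNA position 1;
* ``7mer-m8``  — seed match extended by the position-8 pair only;
* ``7mer-A1``  — seed match plus the target A only;
* ``6mer``     — the bare seed match.

The target A in 8mer/7mer-A1 is a literal adenosine on the target, not a
pairing requirement.  No G:U wobble is allowed in the seed.  circRNAs are
scanned as circular sequences: positions wrap across the back-splice
junction, so sites invisible to a linear scan are still found and flagged
``spans_junction``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

_RC = str.maketrans("ACGU", "UGCA")
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
#: span (matched nucleotides incl. the target A) per class
SITE_SPAN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
#: additive evidence weights used by :func:`score_interaction`
SITE_WEIGHTS = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 2, "6mer": 1}


def _normalize_rna(seq: str, what: str = "sequence") -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (DNA T accepted, mapped to U)."""
    return _normalize_rna(seq)[::-1].translate(_RC)


@dataclasses.dataclass(frozen=True, order=True)
class SeedMatch:
    """One seed site on one target."""

    mirna: str
    target: str
    position: int  # 1-based start (5'-most matched target nucleotide)
    site_type: str
    spans_junction: bool = False
    topology: str = "linear"

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.spans_junction and self.topology != "circular":
            raise ValueError("junction-spanning site on a linear target")


def find_seed_sites(mirna: str, target: str, topology: str = "linear",
                    mirna_id: str = "miRNA",
                    target_id: str = "target") -> list[SeedMatch]:
    """All canonical seed sites of ``mirna`` on ``target``.

    Each seed-match anchor reports exactly one site of its highest-priority
    class (8mer > 7mer-m8 > 7mer-A1 > 6mer).  ``topology="circular"``
    wraps all lookups modulo the target length.
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"unknown topology {topology!r}")
    mir = _normalize_rna(mirna, "miRNA")
    tgt = _normalize_rna(target, "target")
    if len(mir) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    if len(tgt) < 6:
        raise ValueError("target shorter than 6 nt")

    rc6 = reverse_complement(mir[1:7])          # match to seed positions 2-7
    m8_comp = _COMP[mir[7]]                     # target base pairing miRNA pos 8
    L = len(tgt)
    circular = topology == "circular"

    def char(i: int) -> str | None:
        if circular:
            return tgt[i % L]
        return tgt[i] if 0 <= i < L else None

    anchors = range(L) if circular else range(L - 5)
    sites: list[SeedMatch] = []
    for q in anchors:
        if any(char(q + i) != rc6[i] for i in range(6)):
            continue
        has_m8 = char(q - 1) == m8_comp
        has_a1 = char(q + 6) == "A"
        if has_m8 and has_a1:
            stype, start0 = "8mer", q - 1
        elif has_m8:
            stype, start0 = "7mer-m8", q - 1
        elif has_a1:
            stype, start0 = "7mer-A1", q
        else:
            stype, start0 = "6mer", q
        span = SITE_SPAN[stype]
        if circular:
            start0 %= L
            spans = start0 + span > L
        else:
            spans = False
        sites.append(SeedMatch(mirna_id, target_id, start0 + 1, stype,
                               spans, topology))
    sites.sort(key=lambda s: (s.position, SITE_RANK[s.site_type]))
    return sites


@dataclasses.dataclass
class InteractionCandidate:
    """A (miRNA, target) pair with its seed-site evidence."""

    mirna: str
    target: str
    target_layer: str  # mRNA | circRNA
    site_counts: dict[str, int]
    score: float

    @property
    def n_sites(self) -> int:
        return sum(self.site_counts.values())


def score_interaction(matches: Sequence[SeedMatch]) -> float:
    """Additive site-class score: 3*8mer + 2*7mer-m8 + 2*7mer-A1 + 1*6mer."""
    if not matches:
        return 0.0
    pairs = {(m.mirna, m.target) for m in matches}
    if len(pairs) > 1:
        raise ValueError(f"matches mix several pairs: {sorted(pairs)}")
    return float(sum(SITE_WEIGHTS[m.site_type] for m in matches))


def predict_pairs(mirnas: Mapping[str, str], targets: Mapping[str, str],
                  layer: str, min_site_type: str = "7mer-A1"
                  ) -> list[InteractionCandidate]:
    """All-vs-all seed scan; emit pairs with >= 1 site of class >= ``min_site_type``.

    circRNA targets are scanned with circular topology, mRNA targets
    linearly.  Output order is deterministic: (miRNA id, target id).
    """
    if layer not in ("mRNA", "circRNA"):
        raise ValueError(f"unknown target layer {layer!r}")
    if min_site_type not in SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    topology = "circular" if layer == "circRNA" else "linear"
    min_rank = SITE_RANK[min_site_type]

    out: list[InteractionCandidate] = []
    for mir_id in sorted(mirnas):
        for tgt_id in sorted(targets):
            sites = find_seed_sites(mirnas[mir_id], targets[tgt_id],
                                    topology, mir_id, tgt_id)
            if not any(SITE_RANK[s.site_type] >= min_rank for s in sites):
                continue
            counts = {t: 0 for t in SITE_TYPES}
            for s in sites:
                counts[s.site_type] += 1
            out.append(InteractionCandidate(mir_id, tgt_id, layer, counts,
                                            score_interaction(sites)))
    return out


def has_any_seed_anchor(mirna: str, target: str, circular: bool) -> bool:
    """Fast check: does the bare 6-nt seed anchor occur anywhere on the target?

    Every canonical site class contains the seed anchor, so absence of the
    anchor implies absence of any site.  Used by the simulator's rejection
    sampling of background sequences.
    """
    rc6 = reverse_complement(_normalize_rna(mirna)[1:7])
    tgt = _normalize_rna(target)
    hay = tgt + tgt[:5] if circular else tgt
    return rc6 in hay


def candidates_to_frame(cands: Iterable[InteractionCandidate]):
    """Tabular TSV-ready view of interaction candidates."""
    import pandas as pd

    rows = [{"mirna": c.mirna, "target": c.target, "layer": c.target_layer,
             **{f"n_{t}": c.site_counts.get(t, 0) for t in SITE_TYPES},
             "score": c.score} for c in cands]
    cols = ["mirna", "target", "layer"] + [f"n_{t}" for t in SITE_TYPES] + ["score"]
    return pd.DataFrame(rows, columns=cols)
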