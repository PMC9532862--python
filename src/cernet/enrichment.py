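"""Over-representation analysis against a user-supplied annotation.

A generic hypergeometric ORA: for each term, the overlap between the
query set and the term's members is tested one-sided against drawing the
query at random from the universe; p-values are Benjamini-Hochberg
adjusted and terms are significant at FDR <= 0.05.  The universe
defaults to all features in the annotation map (the common ORA
convention), configurable by the caller.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .diffexpr import bh_adjust
from .network import hypergeom_sf

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnnotationMap:
    """term id -> feature set, with an explicit feature universe."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = dataclasses.field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self):
        empties = [t for t, members in self.terms.items() if not members]
        if empties:
            raise ValueError(f"empty terms: {empties[:5]}")
        annotated = frozenset().union(*self.terms.values()) if self.terms \
            else frozenset()
        if not self.universe:
            self.universe = annotated
        elif not annotated <= self.universe:
            raise ValueError("annotated features outside the universe")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 names_path: str | Path | None = None) -> "AnnotationMap":
        """Two-column TSV (term, feature); optional (term, name) TSV."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["term", "feature"], dtype=str,
                         comment="#")
        terms = {t: frozenset(g["feature"])
                 for t, g in df.groupby("term", sort=True)}
        names = {}
        if names_path is not None:
            nd = pd.read_csv(names_path, sep="\t", header=None,
                             names=["term", "name"], dtype=str)
            names = dict(zip(nd["term"], nd["name"]))
        return cls(terms=terms, names=names)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "AnnotationMap":
        """GMT lines: term <TAB> description <TAB> feature1 <TAB> ..."""
        terms: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            terms[parts[0]] = frozenset(parts[2:])
            names[parts[0]] = parts[1]
        return cls(terms=terms, names=names)


def ora(query: Iterable[str], annotation: AnnotationMap,
        fdr_threshold: float = 0.05,
        universe: Iterable[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Returns a frame sorted by p ascending with columns term, name, k, K,
    n, N, p, fdr, significant.  Query features outside the universe are
    dropped with a warning.
    """
    uni = frozenset(universe) if universe is not None else annotation.universe
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q:
        raise ValueError("empty query")
    outside = q - uni
    if outside:
        logger.warning("%d query features outside the universe dropped",
                       len(outside))
        q &= uni
    if not q:
        raise ValueError("no query features inside the universe")

    rows = []
    n = len(q)
    N = len(uni)
    for term in sorted(annotation.terms):
        members = annotation.terms[term] & uni
        if not members:
            continue
        K = len(members)
        k = len(members & q)
        rows.append({"term": term,
                     "name": annotation.names.get(term, ""),
                     "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_sf(k, K, n, N)})
    out = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] <= fdr_threshold
    return out.sort_values(["p", "term"]).reset_index(drop=True)
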