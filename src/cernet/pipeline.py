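"""End-to-end orchestration of the ceRNA inference stages.

Stage order mirrors the study workflow: simulate (or load) counts,
design and sequences; normalize each layer with its unit (RPM for
circRNA, TPM for miRNA, FPKM for mRNA); call differential expression for
one within-breed comparison; predict seed-match targets of the DE
miRNAs among the DE mRNAs and DE circRNAs; apply the coexpression
filters; run the shared-sponge test; assemble triples and the network;
extract the top-k sub-network; optionally run ORA; and write every
artifact with a checksummed manifest.

Correlations are computed on log2(normalized + 1) values over the
samples of the two groups being compared.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, normalize, network as net, simulate, targets
from .containers import FeatureLengths
from .enrichment import AnnotationMap, ora

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the study's decision rules)."""

    simulation: simulate.SimulationConfig = dataclasses.field(
        default_factory=simulate.SimulationConfig)
    input_dir: str | None = None          # load a fixture bundle instead
    comparison: tuple[str, str] = ("TN", "TL")
    lfc_threshold: float = 1.0            # |log2 FC| >= 1  <=>  FC >= 2
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    scc_threshold: float = -0.7
    pcc_threshold: float = 0.9
    sponge_alpha: float = 0.05
    sponge_bh: bool = False               # optional BH on sponge p-values
    sponge_universe: str = "predicted"    # or "all"
    min_site_type: str = "7mer-A1"
    ora_fdr: float = 0.05
    top_k: int = 50
    annotation_path: str | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        self.simulation.validate()
        if not (0 < self.p_threshold <= 1 and 0 < self.fdr_threshold <= 1
                and 0 < self.sponge_alpha <= 1 and 0 < self.ora_fdr <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if not -1 <= self.scc_threshold <= 0:
            raise ValueError("scc_threshold must lie in [-1, 0]")
        if not 0 <= self.pcc_threshold <= 1:
            raise ValueError("pcc_threshold must lie in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.sponge_universe not in ("predicted", "all"):
            raise ValueError("sponge_universe must be 'predicted' or 'all'")
        if len(self.comparison) != 2 or self.comparison[0] == self.comparison[1]:
            raise ValueError("comparison must name two distinct groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simulate.SimulationConfig(**raw.pop("simulation", {}))
        if "comparison" in raw:
            raw["comparison"] = tuple(raw["comparison"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparison"] = list(self.comparison)
        return d


@dataclasses.dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    candidates_mrna: list[targets.InteractionCandidate]
    candidates_circ: list[targets.InteractionCandidate]
    mir_mrna_edges: list[net.CorrelationEdge]
    circ_mir_edges: list[net.CorrelationEdge]
    circ_mrna_edges: list[net.CorrelationEdge]
    sponge_results: dict[tuple[str, str], net.SpongeResult]
    triples: list[net.CeRNATriple]
    network: net.CeRNANetwork
    top_network: net.CeRNANetwork
    enrichment: pd.DataFrame | None
    recovery: dict | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    if config.input_dir is not None:
        (matrices, design, truth, mirna_seqs, utr_seqs,
         circ_seqs) = simulate.read_fixture_bundle(config.input_dir)
    else:
        (matrices, design, truth, mirna_seqs, utr_seqs,
         circ_seqs) = simulate.simulate_all(config.simulation)

    group_a, group_b = config.comparison
    for g in (group_a, group_b):
        if not design.samples_in_group(g):
            raise ValueError(f"comparison group {g!r} absent from the design")
    logger.info("stage normalize: RPM(circRNA), TPM(miRNA), FPKM(mRNA)")
    mir_lengths = FeatureLengths.from_sequences(mirna_seqs)
    mrna_lengths = FeatureLengths.from_sequences(utr_seqs)
    norm = {
        "circRNA": normalize.rpm(matrices["circRNA"]),
        "miRNA": normalize.tpm(matrices["miRNA"], mir_lengths),
        "mRNA": normalize.fpkm(matrices["mRNA"], mrna_lengths),
    }

    logger.info("stage de: %s vs %s", group_a, group_b)
    de_tables = {
        layer: diffexpr.de_table(matrices[layer], design, group_a, group_b)
        for layer in ("circRNA", "miRNA", "mRNA")}
    de_ids = {layer: diffexpr.de_features(t) for layer, t in de_tables.items()}
    for layer in de_ids:
        logger.info("  %s: %s", layer, de_summary(de_tables[layer]))

    logger.info("stage targets: seed matching restricted to DE features")
    de_mirs = {m: mirna_seqs[m] for m in de_ids["miRNA"]}
    de_utrs = {g: utr_seqs[g] for g in de_ids["mRNA"]}
    de_circs = {c: circ_seqs[c] for c in de_ids["circRNA"]}
    cand_mrna = targets.predict_pairs(de_mirs, de_utrs, "mRNA",
                                      config.min_site_type)
    cand_circ = targets.predict_pairs(de_mirs, de_circs, "circRNA",
                                      config.min_site_type)

    logger.info("stage correlation: SCC < %s, PCC > %s on log2(norm+1), "
                "samples of %s and %s", config.scc_threshold,
                config.pcc_threshold, group_a, group_b)
    samples = (design.samples_in_group(group_a)
               + design.samples_in_group(group_b))
    logexpr = {layer: normalize.log2p1(norm[layer].subset_samples(samples))
               for layer in norm}
    mm_edges = net.filter_negative_pairs(cand_mrna, logexpr["miRNA"],
                                         logexpr["mRNA"],
                                         config.scc_threshold)
    cm_edges = net.filter_negative_pairs(cand_circ, logexpr["miRNA"],
                                         logexpr["circRNA"],
                                         config.scc_threshold)
    cg_pairs = net.derive_circ_mrna_candidates(cm_edges, mm_edges)
    cg_edges = net.filter_positive_pairs(cg_pairs, logexpr["circRNA"],
                                         logexpr["mRNA"],
                                         config.pcc_threshold)

    logger.info("stage sponge: one-sided hypergeometric, alpha %s "
                "(universe: %s miRNAs)", config.sponge_alpha,
                config.sponge_universe)
    # target sets for the sponge test are the negatively coexpressed
    # pairs (the intersection step operates on SCC-passed pairs)
    mirnas_of: dict[str, set[str]] = {}
    for e in cm_edges + mm_edges:
        mirnas_of.setdefault(e.node_b, set()).add(e.node_a)
    if config.sponge_universe == "predicted":
        universe = {c.mirna for c in cand_mrna + cand_circ}
    else:
        universe = set(matrices["miRNA"].features)
    sponge_results: dict[tuple[str, str], net.SpongeResult] = {}
    for e in cg_edges:
        circ, gene = e.node_a, e.node_b
        sponge_results[(circ, gene)] = net.sponge_test(
            mirnas_of.get(circ, set()), mirnas_of.get(gene, set()),
            universe, config.sponge_alpha)
    if config.sponge_bh and sponge_results:
        keys = sorted(sponge_results)
        fdrs = diffexpr.bh_adjust([sponge_results[k].p for k in keys])
        for key, q in zip(keys, fdrs):
            r = sponge_results[key]
            sponge_results[key] = net.SpongeResult(
                r.shared, r.circ_set, r.mrna_set, r.universe, r.p,
                passed=(q < config.sponge_alpha and r.shared >= 1))

    triples = net.assemble_triples(mm_edges, cm_edges, cg_edges,
                                   sponge_results)
    network = net.build_network(triples)
    top_network = net.top_edges(network, config.top_k)
    logger.info("stage network: %s", network.summary_line())

    enrich = None
    if config.annotation_path is not None:
        ann = AnnotationMap.from_tsv(config.annotation_path)
        enrich = ora(de_ids["mRNA"], ann, config.ora_fdr)

    recovery = None
    if truth is not None and truth.planted_triples:
        recovery = evaluate_recovery(
            [(t.circ, t.mirna, t.mrna) for t in triples], truth)

    result = PipelineResult(de_tables, cand_mrna, cand_circ, mm_edges,
                            cm_edges, cg_edges, sponge_results, triples,
                            network, top_network, enrich, recovery,
                            manifest={})
    result.manifest = {"parameters": config.to_dict(),
                       "comparison": f"{group_a}_vs_{group_b}",
                       "n_sponge_tests": len(sponge_results),
                       "n_triples": len(triples),
                       "network": network.summary_line(),
                       "recovery": recovery}
    if config.out_dir is not None:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, table in result.de_tables.items():
        table.to_csv(out / f"de_{layer}.tsv", sep="\t")
    targets.candidates_to_frame(
        result.candidates_mrna + result.candidates_circ
    ).to_csv(out / "target_candidates.tsv", sep="\t", index=False)
    edges = pd.DataFrame([dataclasses.asdict(e) for e in
                          (result.mir_mrna_edges + result.circ_mir_edges
                           + result.circ_mrna_edges)])
    edges.to_csv(out / "correlation_edges.tsv", sep="\t", index=False)
    net.triples_to_frame(result.triples).to_csv(out / "cerna_triples.tsv",
                                                sep="\t", index=False)
    net.write_graphml(result.network, out / "network.graphml")
    net.write_sif(result.network, out / "network.sif")
    net.write_sif(result.top_network, out / f"network_top{config.top_k}.sif")
    result.network.degree_table().to_csv(out / "node_degrees.tsv", sep="\t",
                                         index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t",
                                 index=False)
    if result.recovery is not None:
        (out / "recovery.json").write_text(json.dumps(result.recovery,
                                                      indent=1))
    files = {}
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            files[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    result.manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1,
                                                  sort_keys=True))


# ---------------------------------------------------------------------------
# reporting utilities
# ---------------------------------------------------------------------------

def summarize_apoptosis(records: pd.DataFrame) -> pd.DataFrame:
    """Total apoptosis rate (late + early, %) per group, to 2 decimals.

    Input columns: ``group``, ``late_pct``, ``early_pct`` and optionally
    ``viable_pct``; row order is preserved.
    """
    for col in ("late_pct", "early_pct"):
        vals = records[col]
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    out = records.copy()
    out["total_pct"] = (out["late_pct"] + out["early_pct"]).round(2)
    return out


def load_apoptosis_rates() -> pd.DataFrame:
    """Bundled flow-cytometry late/early apoptosis rates per group."""
    from importlib.resources import files

    path = files("cernet").joinpath("data/apoptosis_flow_cytometry.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def de_summary(table: pd.DataFrame) -> str:
    """Counts line: "N (U upregulated and D downregulated)"."""
    up = int((table["call"] == "up").sum())
    down = int((table["call"] == "down").sum())
    return f"{up + down} ({up} upregulated and {down} downregulated)"


def evaluate_recovery(triples: list[tuple[str, str, str]],
                      truth: simulate.GroundTruth) -> dict:
    """Precision / recall / F1 of emitted triples against the planted set."""
    found = {tuple(t) for t in triples}
    planted = {tuple(t) for t in truth.planted_triples}
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted) if planted else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"n_emitted": len(found), "n_planted": len(planted),
            "true_positives": tp, "precision": precision,
            "recall": recall, "f1": f1}
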