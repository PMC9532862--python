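"""Synthetic three-layer RNA-seq data with planted ceRNA ground truth.

The generator emulates the study design the inference pipeline assumes:
two pig breeds (Tibetan, Landrace) x two oxygen conditions (normoxic 21%
O2, hypoxic 2% O2), three sequenced replicates per group (TN/TL/LN/LL),
negative-binomial counts for three RNA layers, and planted structure at
two levels:

* **planted DE features** whose group mean is shifted by ``effect_log2fc``
  in the hypoxic groups of both breeds;
* **planted ceRNA sponge clusters**: one circRNA and one mRNA sharing
  ``shared_mirnas_per_pair`` planted miRNAs, with the miRNAs shifted in
  the opposite direction to the circRNA/mRNA pair.  Cluster members form
  a co-regulated module: their count noise is coupled through a Gaussian
  copula (correlation ``cluster_noise_rho``, sign-flipped for the
  miRNAs), so the miRNA is anticorrelated with both the sponge and the
  target while the circRNA and mRNA are positively correlated across
  samples — the correlation structure a ceRNA filter screens for.  The
  copula only reorders noise quantiles; each feature's marginal count
  distribution stays exactly negative-binomial.

Sequences are generated to match: each planted (miRNA, target) pair has a
physical seed site written into the target (circRNA sites optionally
spanning the back-splice junction), and background sequences are
rejection-sampled to carry no seed anchor of any planted miRNA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (ExpressionMatrix, FeatureLengths, SampleDesign,
                         read_fasta, write_fasta)
from .targets import (SITE_SPAN, _COMP, find_seed_sites, has_any_seed_anchor,
                      reverse_complement)

HYPOXIC_GROUPS = ("TL", "LL")
_ALPHABET = np.array(list("ACGU"))


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the fixture conditions."""

    n_mrna: int = 200
    n_mirna: int = 50
    n_circ: int = 60
    replicates_per_group: int = 3
    groups: tuple[str, ...] = ("TN", "TL", "LN", "LL")
    n_planted_triples: int = 10
    n_planted_de_per_layer: int = 15
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean_log_range: tuple[float, float] = (7.0, 11.0)  # log2 scale
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    utr_length_range: tuple[int, int] = (300, 800)
    circ_length_range: tuple[int, int] = (200, 1000)
    mirna_length_range: tuple[int, int] = (21, 24)
    shared_mirnas_per_pair: int = 2
    cluster_noise_rho: float = 0.9
    junction_site_fraction: float = 0.5
    breed_offset_log2fc: float = 0.0
    seed: int = 42

    def validate(self) -> None:
        for name in ("n_mrna", "n_mirna", "n_circ", "n_planted_triples",
                     "n_planted_de_per_layer"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if self.n_planted_triples > min(self.n_mrna, self.n_mirna, self.n_circ):
            raise ValueError("more planted triples than features in a layer")
        if not (math.isfinite(self.effect_log2fc) and self.effect_log2fc > 0):
            raise ValueError("effect_log2fc must be positive and finite")
        if not (math.isfinite(self.nb_dispersion) and self.nb_dispersion >= 0):
            raise ValueError("nb_dispersion must be >= 0 and finite")
        if self.shared_mirnas_per_pair < 1:
            raise ValueError("shared_mirnas_per_pair must be >= 1")
        if not 0 <= self.junction_site_fraction <= 1:
            raise ValueError("junction_site_fraction must be in [0, 1]")
        if not 0 <= self.cluster_noise_rho < 1:
            raise ValueError("cluster_noise_rho must lie in [0, 1)")
        for name in ("baseline_mean_log_range", "library_size_range",
                     "utr_length_range", "circ_length_range",
                     "mirna_length_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name} must be a finite (lo, hi) pair")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        if not (21 <= self.mirna_length_range[0]
                and self.mirna_length_range[1] <= 24):
            raise ValueError("mirna_length_range must lie in [21, 24]")
        if set(self.groups) != {"TN", "TL", "LN", "LL"}:
            raise ValueError("groups must be a permutation of TN/TL/LN/LL")

    @property
    def n_clusters(self) -> int:
        if self.n_planted_triples == 0:
            return 0
        return math.ceil(self.n_planted_triples / self.shared_mirnas_per_pair)


@dataclasses.dataclass
class GroundTruth:
    """Planted structure: DE features, ceRNA triples, and seed sites."""

    planted_de: dict[str, set[tuple[str, str]]]
    planted_triples: list[tuple[str, str, str]]
    planted_sites: list[dict]

    def de_ids(self, layer: str) -> set[str]:
        return {fid for fid, _ in self.planted_de[layer]}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_de": {layer: sorted(list(pairs))
                           for layer, pairs in self.planted_de.items()},
            "planted_triples": [list(t) for t in self.planted_triples],
            "planted_sites": self.planted_sites,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_de={layer: {tuple(p) for p in pairs}
                        for layer, pairs in payload["planted_de"].items()},
            planted_triples=[tuple(t) for t in payload["planted_triples"]],
            planted_sites=payload["planted_sites"],
        )


def _feature_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "circRNA": [f"circ_{i:04d}" for i in range(1, config.n_circ + 1)],
        "miRNA": [f"mir_{i:04d}" for i in range(1, config.n_mirna + 1)],
        "mRNA": [f"gene_{i:04d}" for i in range(1, config.n_mrna + 1)],
    }


def _plan_truth(config: SimulationConfig) -> GroundTruth:
    """Deterministic assignment of planted clusters and DE features.

    Cluster j uses circ_{j+1}, gene_{j+1} and the next block of miRNAs;
    even clusters shift the miRNAs down in hypoxia (circRNA/mRNA up),
    odd clusters are mirrored.  Standalone planted DE features follow the
    cluster members in each layer, alternating direction.
    """
    ids = _feature_ids(config)
    triples: list[tuple[str, str, str]] = []
    de: dict[str, set[tuple[str, str]]] = {l: set() for l in ids}

    mir_cursor = 0
    for j in range(config.n_clusters):
        circ, gene = ids["circRNA"][j], ids["mRNA"][j]
        mir_dir = "down" if j % 2 == 0 else "up"
        other = "up" if mir_dir == "down" else "down"
        n_mir = min(config.shared_mirnas_per_pair,
                    config.n_planted_triples - len(triples))
        for _ in range(n_mir):
            mir = ids["miRNA"][mir_cursor]
            mir_cursor += 1
            triples.append((circ, mir, gene))
            de["miRNA"].add((mir, mir_dir))
        de["circRNA"].add((circ, other))
        de["mRNA"].add((gene, other))

    used = {"circRNA": config.n_clusters, "miRNA": mir_cursor,
            "mRNA": config.n_clusters}
    for layer in ids:
        if config.n_planted_de_per_layer < len(de[layer]):
            raise ValueError(
                f"n_planted_de_per_layer smaller than the {len(de[layer])} "
                f"planted triple members in layer {layer}")
        k = 0
        while len(de[layer]) < config.n_planted_de_per_layer:
            idx = used[layer] + k
            if idx >= len(ids[layer]):
                raise ValueError(f"not enough {layer} features for planted DE")
            de[layer].add((ids[layer][idx], "up" if k % 2 == 0 else "down"))
            k += 1
    return GroundTruth(planted_de=de, planted_triples=triples,
                       planted_sites=[])


def _make_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for group in config.groups:
        breed = "Tibetan" if group[0] == "T" else "Landrace"
        oxygen = "normoxic" if group[1] == "N" else "hypoxic"
        for r in range(1, config.replicates_per_group + 1):
            rows.append({"sample": f"{group}_r{r}", "breed": breed,
                         "oxygen": oxygen, "replicate": r})
    return SampleDesign(pd.DataFrame(rows).set_index("sample"))


def _cluster_map(truth: GroundTruth) -> dict[str, tuple[int, float]]:
    """Member feature id -> (cluster index, copula sign).

    A cluster is one (circRNA, mRNA) sponge pair with its shared miRNAs;
    the circRNA/mRNA carry sign +1 and the miRNAs sign -1 (anti-coupled
    residuals), matching the planted direction pattern.
    """
    clusters: dict[tuple[str, str], int] = {}
    members: dict[str, tuple[int, float]] = {}
    for c, m, g in truth.planted_triples:
        idx = clusters.setdefault((c, g), len(clusters))
        members[c] = (idx, 1.0)
        members[g] = (idx, 1.0)
        members[m] = (idx, -1.0)
    return members


def _noise_quantile_counts(mu: np.ndarray, z: np.ndarray,
                           phi: float) -> np.ndarray:
    """Counts with the marginal NB(mu, phi) law at Gaussian noise quantile z."""
    from scipy import stats as sps

    q = sps.norm.cdf(z)
    if phi == 0:
        return sps.poisson.ppf(q, mu).astype(np.int64)
    r = 1.0 / phi
    return sps.nbinom.ppf(q, r, r / (r + mu)).astype(np.int64)


def simulate_counts(config: SimulationConfig
                    ) -> tuple[dict[str, ExpressionMatrix], SampleDesign,
                               GroundTruth]:
    """Draw the three count matrices, the design and the ground truth.

    Counts are negative-binomial with Var = mu + phi*mu^2 (Poisson at
    phi = 0); library sizes act as relative per-sample depth factors.
    Planted DE features (including sponge-cluster members) have their
    mean shifted by ``effect_log2fc`` in the hypoxic groups of both
    breeds; cluster members additionally share copula-coupled noise.
    Identical config (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _plan_truth(config)
    design = _make_design(config)
    ids = _feature_ids(config)

    groups = design.groups
    hypoxic = groups.isin(HYPOXIC_GROUPS).to_numpy().astype(float)
    tibetan = (design.table["breed"] == "Tibetan").to_numpy()
    n_samples = len(design.samples)

    members = _cluster_map(truth)
    n_clusters = 1 + max((idx for idx, _ in members.values()), default=-1)
    cluster_u = rng.standard_normal((n_clusters, n_samples))
    rho = config.cluster_noise_rho

    direction: dict[str, dict[str, float]] = {l: {} for l in ids}
    for layer, pairs in truth.planted_de.items():
        for fid, d in pairs:
            direction[layer][fid] = 1.0 if d == "up" else -1.0

    matrices: dict[str, ExpressionMatrix] = {}
    lo, hi = config.baseline_mean_log_range
    for layer in ("circRNA", "miRNA", "mRNA"):
        feats = ids[layer]
        base = 2.0 ** rng.uniform(lo, hi, size=len(feats))
        libs = rng.integers(config.library_size_range[0],
                            config.library_size_range[1] + 1, size=n_samples)
        depth = libs / libs.mean()

        shift = np.zeros((len(feats), n_samples))
        for i, fid in enumerate(feats):
            d = direction[layer].get(fid)
            if d is not None:
                shift[i] = d * config.effect_log2fc * hypoxic
        mu = base[:, None] * 2.0 ** shift * depth[None, :]
        if config.breed_offset_log2fc:
            mu = mu * 2.0 ** (config.breed_offset_log2fc * tibetan[None, :])

        if config.nb_dispersion == 0:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        # sponge-cluster members: same marginals, copula-coupled noise
        for i, fid in enumerate(feats):
            if fid not in members:
                continue
            idx, sign = members[fid]
            eps = rng.standard_normal(n_samples)
            z = sign * (np.sqrt(rho) * cluster_u[idx]
                        + np.sqrt(1.0 - rho) * eps)
            counts[i] = _noise_quantile_counts(mu[i], z,
                                               config.nb_dispersion)
        matrices[layer] = ExpressionMatrix(
            pd.DataFrame(counts, index=feats, columns=design.samples),
            unit="raw-count", layer=layer)
    return matrices, design, truth


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def write_site(seq: list[str], start0: int, mirna: str, site_type: str,
               circular: bool) -> None:
    """Write one canonical seed site into a mutable target sequence.

    ``start0`` is the 0-based start of the site's 5'-most nucleotide; for
    circular targets writes wrap modulo the length.  Flanking positions
    that would promote the site to a higher class are overwritten so the
    written class is exact.
    """
    L = len(seq)
    span = SITE_SPAN[site_type]
    if circular:
        if not 0 <= start0 < L:
            raise ValueError("site start outside target")
    elif start0 < 0 or start0 + span > L:
        raise ValueError("site position beyond target length")
    rc6 = reverse_complement(mirna[1:7])
    m8c = _COMP[mirna.upper().replace("T", "U")[7]]

    if site_type == "8mer":
        payload = m8c + rc6 + "A"
    elif site_type == "7mer-m8":
        payload = m8c + rc6
    elif site_type == "7mer-A1":
        payload = rc6 + "A"
    else:
        payload = rc6

    def put(i: int, ch: str) -> None:
        seq[i % L if circular else i] = ch

    def get(i: int) -> str | None:
        if circular:
            return seq[i % L]
        return seq[i] if 0 <= i < L else None

    for k, ch in enumerate(payload):
        put(start0 + k, ch)
    # demote flanks where the class excludes them
    anchor = start0 + 1 if site_type in ("8mer", "7mer-m8") else start0
    if site_type in ("7mer-A1", "6mer") and get(anchor - 1) == m8c:
        put(anchor - 1, "G" if m8c != "G" else "C")
    if site_type in ("7mer-m8", "6mer") and get(anchor + 6) == "A":
        put(anchor + 6, "C")


def _background_target(rng: np.random.Generator, length: int,
                       forbidden_mirnas: list[str], circular: bool,
                       max_tries: int = 2000) -> list[str]:
    for _ in range(max_tries):
        seq = _random_rna(rng, length)
        if not any(has_any_seed_anchor(m, seq, circular)
                   for m in forbidden_mirnas):
            return list(seq)
    raise RuntimeError("rejection sampling failed; sequences too short "
                       "or too many planted miRNAs")


def simulate_sequences(config: SimulationConfig, truth: GroundTruth,
                       site_type: str = "8mer"
                       ) -> tuple[dict[str, str], dict[str, str],
                                  dict[str, str]]:
    """Generate miRNA / 3'UTR / circRNA FASTA record sets.

    Planted sites (class ``site_type``) are written into each planted
    triple's mRNA and circRNA; a ``junction_site_fraction`` share of the
    circRNA sites wraps across the back-splice junction.  Background
    sequences carry no seed anchor of any planted miRNA (rejection
    sampled), and ``truth.planted_sites`` is filled in.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 7])
    ids = _feature_ids(config)

    mirna_seqs = {
        mid: _random_rna(rng, int(rng.integers(config.mirna_length_range[0],
                                               config.mirna_length_range[1] + 1)))
        for mid in ids["miRNA"]}

    planted_by_target: dict[str, list[str]] = {}
    for c, m, g in truth.planted_triples:
        planted_by_target.setdefault(c, []).append(m)
        planted_by_target.setdefault(g, []).append(m)
    planted_mirnas = sorted({m for _, m, _ in truth.planted_triples})

    span = SITE_SPAN[site_type]
    sites: list[dict] = []

    def build_target(tid: str, length: int, circular: bool) -> str:
        """One target: clean background, then planted sites, re-checked."""
        mirs = planted_by_target.get(tid, [])
        forbidden = [mirna_seqs[m] for m in planted_mirnas]
        for _ in range(200):
            seq = _background_target(rng, length, forbidden, circular)
            placed: list[dict] = []
            taken: set[int] = set()
            ok = True
            for k, m in enumerate(mirs):
                wrap = circular and rng.random() < config.junction_site_fraction
                for _ in range(200):
                    if wrap:
                        start0 = int(rng.integers(length - span + 1, length))
                    else:
                        start0 = int(rng.integers(0, length - span + 1))
                    # occupied positions incl. 1-nt flanks, wrapped if circular
                    occ = {(start0 - 1 + i) % length if circular
                           else start0 - 1 + i for i in range(span + 2)}
                    if not occ & taken:
                        break
                else:
                    ok = False
                    break
                write_site(seq, start0, mirna_seqs[m], site_type, circular)
                taken |= occ
                placed.append({"mirna": m, "target": tid,
                               "target_layer": "circRNA" if circular else "mRNA",
                               "position": start0 + 1, "site_type": site_type,
                               "spans_junction": bool(wrap)})
            if not ok:
                continue
            # writing sites may create accidental anchors for *other*
            # planted miRNAs; resample the target if so
            s = "".join(seq)
            others = [mirna_seqs[m] for m in planted_mirnas if m not in mirs]
            if any(has_any_seed_anchor(m, s, circular) for m in others):
                continue
            sites.extend(placed)
            return s
        raise RuntimeError(f"could not place sites on {tid}")

    circ_seqs = {
        cid: build_target(cid, int(rng.integers(config.circ_length_range[0],
                                                config.circ_length_range[1] + 1)),
                          circular=True)
        for cid in ids["circRNA"]}
    utr_seqs = {
        gid: build_target(gid, int(rng.integers(config.utr_length_range[0],
                                                config.utr_length_range[1] + 1)),
                          circular=False)
        for gid in ids["mRNA"]}

    # sanity: every planted site must be found by the scanner
    for rec in sites:
        tgt = circ_seqs if rec["target_layer"] == "circRNA" else utr_seqs
        topo = "circular" if rec["target_layer"] == "circRNA" else "linear"
        found = find_seed_sites(mirna_seqs[rec["mirna"]], tgt[rec["target"]],
                                topo)
        if not any(s.position == rec["position"]
                   and s.site_type == rec["site_type"] for s in found):
            raise AssertionError(f"planted site not recovered: {rec}")

    truth.planted_sites = sites
    return mirna_seqs, utr_seqs, circ_seqs


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "counts_circRNA": "counts_circRNA.tsv",
    "counts_miRNA": "counts_miRNA.tsv",
    "counts_mRNA": "counts_mRNA.tsv",
    "design": "design.tsv",
    "mirna_fasta": "mirna.fasta",
    "utr_fasta": "utr3.fasta",
    "circ_fasta": "circrna.fasta",
    "truth": "ground_truth.json",
}


def write_fixture_bundle(path: str | Path,
                         matrices: dict[str, ExpressionMatrix],
                         design: SampleDesign, truth: GroundTruth,
                         mirna_seqs: dict[str, str],
                         utr_seqs: dict[str, str],
                         circ_seqs: dict[str, str],
                         config: SimulationConfig | None = None) -> dict:
    """Write all simulated artifacts plus a checksum manifest; return it."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for layer in ("circRNA", "miRNA", "mRNA"):
        matrices[layer].to_tsv(out / _BUNDLE_FILES[f"counts_{layer}"])
    design.to_tsv(out / _BUNDLE_FILES["design"])
    write_fasta(mirna_seqs, out / _BUNDLE_FILES["mirna_fasta"])
    write_fasta(utr_seqs, out / _BUNDLE_FILES["utr_fasta"])
    write_fasta(circ_seqs, out / _BUNDLE_FILES["circ_fasta"])
    truth.to_json(out / _BUNDLE_FILES["truth"])

    manifest: dict = {"files": {}}
    if config is not None:
        manifest["config"] = dataclasses.asdict(config)
    for fname in sorted(_BUNDLE_FILES.values()):
        digest = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        manifest["files"][fname] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def read_fixture_bundle(path: str | Path):
    """Round-trip loader for :func:`write_fixture_bundle` output."""
    p = Path(path)
    matrices = {
        layer: ExpressionMatrix.from_tsv(p / _BUNDLE_FILES[f"counts_{layer}"],
                                         unit="raw-count", layer=layer)
        for layer in ("circRNA", "miRNA", "mRNA")}
    design = SampleDesign.from_tsv(p / _BUNDLE_FILES["design"])
    truth = GroundTruth.from_json(p / _BUNDLE_FILES["truth"])
    mirna_seqs = read_fasta(p / _BUNDLE_FILES["mirna_fasta"])
    utr_seqs = read_fasta(p / _BUNDLE_FILES["utr_fasta"])
    circ_seqs = read_fasta(p / _BUNDLE_FILES["circ_fasta"])
    return matrices, design, truth, mirna_seqs, utr_seqs, circ_seqs


def simulate_all(config: SimulationConfig):
    """Counts + sequences in one call (the pipeline entry point)."""
    matrices, design, truth = simulate_counts(config)
    mirna_seqs, utr_seqs, circ_seqs = simulate_sequences(config, truth)
    return matrices, design, truth, mirna_seqs, utr_seqs, circ_seqs


def mirna_lengths(mirna_seqs: dict[str, str]) -> FeatureLengths:
    return FeatureLengths.from_sequences(mirna_seqs)
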