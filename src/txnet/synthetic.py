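"""Seeded synthetic data with planted structure for pipeline validation.

Three generators emulate the statistical shape of the pipeline's inputs
and record ground truth for recovery tests:

* ``simulate_counts`` — a two-group RNA-seq count matrix.  Counts are
  negative binomial with variance ``mu + alpha * mu**2`` (one shared
  dispersion ``alpha``), per-sample size factors drawn log-uniform in
  [0.5, 2] so normalization has real work to do, and a planted fraction
  of genes whose treated-condition mean is multiplied by
  ``2**(+-effect_log2)``.
* ``simulate_interactome`` — a channel-scored edge list containing a hub
  cluster wired as a star with short chains hanging off the leaves (the
  designated hub has maximal degree and betweenness), a ribosomal clique
  attached by a single bridge edge, decoy edges supported only by
  excluded channels (text-mining), and sparse background edges whose
  direct-evidence scores straddle the 0.900 confidence threshold.
* ``simulate_genesets`` — a GMT collection with one planted term drawn
  (>= 80%) from the planted genes and uniform random terms otherwise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from txnet.network import CHANNELS, ChannelEdge, recombine_score
from txnet.ora import GeneSet

__all__ = [
    "SimulationConfig",
    "InteractomeSpec",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_interactome",
    "simulate_genesets",
]

#: group labels used by the simulated designs
GROUP_CONTROL = "control"
GROUP_TREATED = "treated"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-group count simulation.

    ``mean_log_range`` bounds the natural log of the baseline mean
    (log-uniform draw).  ``effect_log2`` is the planted absolute log2 fold
    change; signs are assigned at random.  ``effect_log2 = 0`` or
    ``de_fraction = 0`` yields a global-null simulation with no genes
    recorded as planted.
    """

    n_genes: int = 2000
    n_reps_per_group: int = 2
    de_fraction: float = 0.1
    effect_log2: float = 2.0
    dispersion: float = 0.1
    mean_log_range: tuple[float, float] = (np.log(50.0), np.log(5000.0))
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_reps_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")
        lo, hi = self.mean_log_range
        if not lo <= hi:
            raise ValueError("mean_log_range must be an increasing pair")
        if self.de_fraction > 0 and int(round(self.de_fraction * self.n_genes)) < 1:
            raise ValueError("de_fraction * n_genes must be >= 1 when planting effects")


@dataclass(frozen=True)
class InteractomeSpec:
    """Sizes of the planted interactome structures.

    The hub cluster is a star of ``hub_size`` genes (hub + leaves) with
    ``n_chords`` extra leaf-leaf edges; ``n_chains`` chains of
    ``chain_len`` genes hang off distinct leaves to stretch the
    component's diameter.  ``ribo_size`` genes form a clique bridged to
    one leaf.  ``n_decoys`` edges carry text-mining-only evidence;
    ``n_background`` sparse edges over the remaining genes carry
    direct-evidence scores spanning the confidence threshold.
    """

    hub_size: int = 6
    n_chains: int = 4
    chain_len: int = 2
    n_chords: int = 0
    ribo_size: int = 8
    n_decoys: int = 20
    n_background: int = 150

    def __post_init__(self):
        if self.hub_size < 2:
            raise ValueError("hub_size must be >= 2")
        if self.n_chains > self.hub_size - 1:
            raise ValueError("n_chains cannot exceed the number of leaves")
        for name in ("chain_len", "n_chords", "ribo_size", "n_decoys", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_structural(self) -> int:
        return self.hub_size + self.n_chains * self.chain_len + self.ribo_size


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels recorded by the generators."""

    de_genes: dict = field(default_factory=dict)  # gene -> signed log2 effect
    hub_gene: str | None = None
    hub_cluster: frozenset = frozenset()
    chain_genes: frozenset = frozenset()
    ribosomal_genes: frozenset = frozenset()
    decoy_edges: frozenset = frozenset()  # frozenset of (a, b) sorted tuples
    planted_term: str | None = None

    def __post_init__(self):
        if self.hub_gene is not None and self.hub_gene not in self.hub_cluster:
            raise ValueError("hub_gene must belong to hub_cluster")
        if self.hub_cluster & self.ribosomal_genes:
            raise ValueError("hub cluster and ribosomal genes must be disjoint")
        cluster_pairs = {
            tuple(sorted((a, b)))
            for a in self.hub_cluster
            for b in self.hub_cluster
            if a < b
        }
        if set(self.decoy_edges) & cluster_pairs:
            raise ValueError("decoy edges must be disjoint from hub-cluster edges")

    def merged(self, **kwargs) -> "SyntheticTruth":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "de_genes": {g: float(e) for g, e in sorted(self.de_genes.items())},
            "hub_gene": self.hub_gene,
            "hub_cluster": sorted(self.hub_cluster),
            "chain_genes": sorted(self.chain_genes),
            "ribosomal_genes": sorted(self.ribosomal_genes),
            "decoy_edges": sorted(list(e) for e in self.decoy_edges),
            "planted_term": self.planted_term,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            de_genes=dict(d.get("de_genes", {})),
            hub_gene=d.get("hub_gene"),
            hub_cluster=frozenset(d.get("hub_cluster", ())),
            chain_genes=frozenset(d.get("chain_genes", ())),
            ribosomal_genes=frozenset(d.get("ribosomal_genes", ())),
            decoy_edges=frozenset(tuple(e) for e in d.get("decoy_edges", ())),
            planted_term=d.get("planted_term"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_counts(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a two-group NB count matrix with planted DE genes.

    Returns
    -------
    (counts, samples, truth)
        ``counts``: integer DataFrame genes x samples; ``samples``: sample
        sheet with columns ``sample, group`` (control first); ``truth``
        records the planted signed effects.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    n_reps = cfg.n_reps_per_group
    sample_names = [f"ctrl_{i+1}" for i in range(n_reps)] + [
        f"trt_{i+1}" for i in range(n_reps)
    ]
    groups = [GROUP_CONTROL] * n_reps + [GROUP_TREATED] * n_reps

    lo, hi = cfg.mean_log_range
    base_mu = np.exp(rng.uniform(lo, hi, size=cfg.n_genes))

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = np.sort(rng.choice(cfg.n_genes, size=n_de, replace=False)) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(cfg.n_genes)
    if cfg.effect_log2 > 0:
        effects[de_idx] = signs * cfg.effect_log2

    mu = np.tile(base_mu[:, None], (1, 2 * n_reps))
    mu[:, n_reps:] *= 2.0 ** effects[:, None]

    size_f = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2 * n_reps))
    mu_scaled = mu * size_f[None, :]

    # NB(mean m, dispersion a) as Gamma-Poisson: shape r = 1/a, p = r/(r+m)
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu_scaled))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_names)
    samples_df = pd.DataFrame({"sample": sample_names, "group": groups})
    de_genes = {genes[i]: float(effects[i]) for i in de_idx if effects[i] != 0.0}
    return counts_df, samples_df, SyntheticTruth(de_genes=de_genes)


def _draw_score(rng, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _direct_edge(rng, a: str, b: str, lo: float = 0.92, hi: float = 0.985) -> ChannelEdge:
    """Edge with strong direct (experimental) evidence, surviving 0.900."""
    scores = {"experimental": _draw_score(rng, lo, hi)}
    return ChannelEdge(a, b, scores, recombine_score(scores, CHANNELS))


def simulate_interactome(
    genes: Sequence[str],
    spec: InteractomeSpec,
    seed: int,
    candidates: Sequence[str] | None = None,
) -> tuple[list[ChannelEdge], SyntheticTruth]:
    """Simulate a channel-scored interactome with planted structure.

    ``candidates`` (default: all genes) is the pool from which the planted
    structures and decoy endpoints are drawn — pass the planted DE genes
    so the structures survive DEG restriction downstream.  Background
    edges are placed only between non-structural genes so the planted
    topology is exactly as constructed.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    pool = list(candidates) if candidates is not None else genes
    if spec.n_structural > len(pool):
        raise ValueError(
            f"requested {spec.n_structural} structural genes but only "
            f"{len(pool)} candidates available"
        )
    picked = list(rng.choice(pool, size=spec.n_structural, replace=False))
    hub_cluster = picked[: spec.hub_size]
    hub = hub_cluster[0]
    leaves = hub_cluster[1:]
    k = spec.hub_size
    chain_flat = picked[k : k + spec.n_chains * spec.chain_len]
    ribo = picked[k + spec.n_chains * spec.chain_len :]
    structural = set(picked)

    edges: list[ChannelEdge] = []
    seen: set[tuple[str, str]] = set()

    def add(edge: ChannelEdge) -> None:
        if edge.pair in seen:
            return
        seen.add(edge.pair)
        edges.append(edge)

    # star: hub to every leaf
    for leaf in leaves:
        add(_direct_edge(rng, hub, leaf))
    # optional chords between leaves
    if spec.n_chords:
        leaf_pairs = [(a, b) for i, a in enumerate(leaves) for b in leaves[i + 1 :]]
        idx = rng.choice(len(leaf_pairs), size=min(spec.n_chords, len(leaf_pairs)), replace=False)
        for i in sorted(idx):
            add(_direct_edge(rng, *leaf_pairs[i]))
    # chains hanging off distinct leaves
    for c in range(spec.n_chains):
        prev = leaves[c]
        for j in range(spec.chain_len):
            nxt = chain_flat[c * spec.chain_len + j]
            add(_direct_edge(rng, prev, nxt))
            prev = nxt
    # ribosomal clique, bridged to one leaf (the last, chain-free if possible)
    for i, a in enumerate(ribo):
        for b in ribo[i + 1 :]:
            add(_direct_edge(rng, a, b))
    if ribo:
        add(_direct_edge(rng, ribo[0], leaves[-1]))

    # decoys: text-mining only, between non-structural candidate genes
    decoy_pool = [g for g in pool if g not in structural]
    decoy_edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(decoy_edges) < spec.n_decoys and attempts < 50 * max(spec.n_decoys, 1):
        attempts += 1
        if len(decoy_pool) < 2:
            break
        a, b = rng.choice(decoy_pool, size=2, replace=False)
        pair = tuple(sorted((str(a), str(b))))
        if pair in seen or pair in decoy_edges:
            continue
        scores = {"textmining": _draw_score(rng, 0.90, 0.99)}
        add(ChannelEdge(pair[0], pair[1], scores, recombine_score(scores, CHANNELS)))
        decoy_edges.add(pair)

    # sparse background among non-structural genes, scores spanning 0.900
    bg_pool = [g for g in genes if g not in structural]
    n_bg = 0
    attempts = 0
    while n_bg < spec.n_background and attempts < 50 * max(spec.n_background, 1):
        attempts += 1
        if len(bg_pool) < 2:
            break
        a, b = rng.choice(bg_pool, size=2, replace=False)
        pair = tuple(sorted((str(a), str(b))))
        if pair in seen:
            continue
        channel = str(rng.choice(["experimental", "coexpression", "database"]))
        scores = {channel: _draw_score(rng, 0.5, 0.99)}
        add(ChannelEdge(pair[0], pair[1], scores, recombine_score(scores, CHANNELS)))
        n_bg += 1

    truth = SyntheticTruth(
        hub_gene=hub,
        hub_cluster=frozenset(hub_cluster),
        chain_genes=frozenset(chain_flat),
        ribosomal_genes=frozenset(ribo),
        decoy_edges=frozenset(decoy_edges),
    )
    return edges, truth


def simulate_genesets(
    genes: Sequence[str],
    planted_de_genes: Sequence[str],
    n_terms: int = 50,
    size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
    planted_min_fraction: float = 0.8,
) -> tuple[dict[str, GeneSet], str]:
    """Simulate a GMT collection with one planted term.

    The planted term draws at least ``planted_min_fraction`` of its
    members from ``planted_de_genes`` (padding with random genes where
    the size budget allows); the remaining ``n_terms - 1`` terms are
    uniform draws from the universe.

    Returns ``(collection, planted_term_id)``.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= len(genes)")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    planted = list(dict.fromkeys(planted_de_genes))
    if not planted:
        raise ValueError("planted_de_genes must be non-empty")

    core = planted if len(planted) <= hi else list(rng.choice(planted, size=hi, replace=False))
    max_pad = int(len(core) * (1.0 - planted_min_fraction) / planted_min_fraction)
    n_pad = min(max_pad, hi - len(core))
    others = [g for g in genes if g not in set(core)]
    pad = list(rng.choice(others, size=n_pad, replace=False)) if n_pad else []
    members = frozenset(str(g) for g in core + pad)
    if len(members) < lo:
        raise ValueError(
            f"planted term of size {len(members)} cannot reach the minimum term size {lo} "
            f"without diluting below {planted_min_fraction:.0%} planted membership"
        )

    width = max(3, len(str(n_terms)))
    planted_id = f"T{0:0{width}d}"
    collection: dict[str, GeneSet] = {
        planted_id: GeneSet(planted_id, "planted signal set (synthetic)", members)
    }
    for t in range(1, n_terms):
        term = f"T{t:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        mem = frozenset(str(g) for g in rng.choice(genes, size=size, replace=False))
        collection[term] = GeneSet(term, "random background set (synthetic)", mem)
    return collection, planted_id


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame, counts_path, samples_path) -> None:
    """Write the count matrix and sample sheet as TSV."""
    counts.to_csv(counts_path, sep="\t")
    samples.to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, samples_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a count TSV (first column gene id) and its sample sheet.

    Returns ``(counts, groups)`` with ``groups`` a Series mapping sample
    name to group label, ordered as in the sample sheet.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    if not {"sample", "group"} <= set(samples.columns):
        raise ValueError(f"sample sheet {samples_path} needs columns 'sample' and 'group'")
    groups = pd.Series(samples["group"].values, index=samples["sample"].values, name="group")
    missing = [s for s in counts.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing}")
    return counts, groups.reindex(counts.columns)
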