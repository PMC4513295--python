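"""Synthetic barcode datasets with known species structure.

The generator chains a Yule species tree, a censored (multispecies)
coalescent for within-species genealogies, HKY sequence evolution over the
genealogy, and record degradation (amplicon-length truncation plus ambiguity
injection), then scatters per-record coordinates around species range
centres.  Every stage is keyed by an integer seed, so the ground truth
(which record belongs to which species/entity) is exactly reproducible and
every pipeline stage can be tested against it.

Units: species trees are in Myr; genealogies and mutation rates are in
generations (per-site per-generation mu), converted via generations/year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import expm

from .barcode_io import BarcodeDataset, BarcodeRecord
from .gmyc import EntityPartition
from .trees import node_ages

__all__ = [
    "SimulationConfig", "SyntheticTruth", "simulate_yule_tree",
    "simulate_msc_genealogy", "evolve_sequences", "degrade_records",
    "generate",
]

_BASES = np.array(list("ACGT"))

#: Amplicon windows on the 658-site frame: (length, start) — a 609-bp and a
#: 307-bp fragment anchored at the 5' end, a 407-bp fragment at the 3' end.
AMPLICON_WINDOWS = {609: (0, 609), 307: (0, 307), 407: (251, 658)}

#: Invertebrate-mitochondrial stop codons, avoided in the root sequence so
#: synthetic data stay translatable in frame 0.
_STOPS = {"TAA", "TAG"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_species: int = 10
    birth_rate: float = 0.0455         # per lineage per Myr (continental
                                       # butterfly crown estimate)
    ne: float = 2e5                    # haploid effective size
    samples_per_species: int = 10
    seq_length: int = 658
    mu: float = 1.15e-8                # per site per generation
    generations_per_year: float = 1.0
    kappa: float = 2.0                 # HKY ts/tv ratio; 1 => Jukes-Cantor
    truncate_prob: float = 0.0
    ambiguity_rate: float = 0.0
    dispersion_km: float = 100.0
    overlap_pairs: tuple[tuple[int, int], ...] = ()
    families: tuple[str, ...] = ("Lycaenidae", "Nymphalidae", "Hesperiidae")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.samples_per_species < 1:
            raise ValueError("need >= 2 species and >= 1 sample per species")
        for name in ("birth_rate", "ne", "mu", "generations_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("truncate_prob", "ambiguity_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    species_of: dict[str, str]
    species_tree: dendropy.Tree
    gene_genealogy: dendropy.Tree
    true_partition: EntityPartition

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("record_id\ttrue_species\n")
            for rid in sorted(self.species_of):
                fh.write(f"{rid}\t{self.species_of[rid]}\n")


def _build_tree(labels: list[str], root) -> dendropy.Tree:
    """Assemble a dendropy tree from (children, edge length) tuples."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    def convert(spec) -> dendropy.Node:
        node = dendropy.Node()
        label, length, children = spec
        node.edge.length = length
        if label is not None:
            node.taxon = taxa.get_taxon(label)
        for ch in children:
            node.add_child(convert(ch))
        return node

    tree.seed_node = convert(root)
    tree.seed_node.edge.length = None
    return tree


def simulate_yule_tree(n_species: int, birth_rate: float,
                       seed: int | np.random.Generator = 0) -> dendropy.Tree:
    """Pure-birth species tree, crown start with 2 lineages, Myr units.

    Waiting times between the k -> k+1 lineage events are Exp(k * birth_rate);
    after the n-th lineage appears the process holds for one more Exp(n * rate)
    draw before the present, so no pendant edge has zero length.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # active lineages as [birth_time, subtree-spec or tip placeholder]
    t = 0.0
    active: list[list] = [[0.0, None], [0.0, None]]
    splits: list[tuple] = []  # (time, lineage idx) applied onto a tree spec
    # store as nested lists: each active lineage is [birth_time, node_record]
    # node_record = [label, children(list of node_record), birth_time]
    recs = [["", [], 0.0], ["", [], 0.0]]
    root_children = [recs[0], recs[1]]
    while len(recs) < n_species:
        k = len(recs)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(0, k))
        parent = recs[idx]
        c1, c2 = ["", [], t], ["", [], t]
        parent[1] = [c1, c2]
        parent.append(t)          # death time
        recs[idx] = c1
        recs.append(c2)
    t += rng.exponential(1.0 / (n_species * birth_rate))
    labels = [f"species_{i + 1:03d}" for i in range(n_species)]
    for lab, rec in zip(labels, recs):
        rec[0] = lab
        rec.append(t)             # tips die at the present

    def spec_of(rec):
        label, children, birth, death = rec[0], rec[1], rec[2], rec[3]
        if children:
            return (None, death - birth if birth is not None else None,
                    [spec_of(c) for c in children])
        return (label, death - birth, [])

    root_spec = (None, None, [spec_of(root_children[0]),
                              spec_of(root_children[1])])
    # root children were born at 0; their recorded birth is 0, death set above
    tree = _build_tree(labels, root_spec)
    return tree


def simulate_msc_genealogy(species_tree: dendropy.Tree, ne: float,
                           k_samples: int,
                           generations_per_year: float = 1.0,
                           seed: int | np.random.Generator = 0) -> dendropy.Tree:
    """Censored multispecies-coalescent gene genealogy, in generations.

    Within each species-tree branch, j lineages coalesce pairwise at rate
    j(j-1)/(2*ne) per generation (haploid ne); lineages surviving to the top
    of a branch enter the ancestral population.  Sample labels are
    ``<species>_<i>``.
    """
    if ne <= 0 or k_samples < 1:
        raise ValueError("ne must be > 0 and k_samples >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    to_gen = 1e6 * generations_per_year
    ages = node_ages(species_tree)

    labels: list[str] = []
    for leaf in species_tree.leaf_node_iter():
        labels.extend(f"{leaf.taxon.label}_{i + 1:02d}" for i in range(k_samples))

    # gene-tree nodes as dicts {label, children, age}
    lineages: dict[dendropy.Node, list[dict]] = {}
    for leaf in species_tree.leaf_node_iter():
        lineages[leaf] = [
            {"label": f"{leaf.taxon.label}_{i + 1:02d}", "children": [],
             "age": 0.0}
            for i in range(k_samples)
        ]

    def coalesce(pool: list[dict], t0: float, t1: float | None) -> list[dict]:
        t = t0
        while len(pool) > 1:
            j = len(pool)
            rate = j * (j - 1) / (2.0 * ne)
            t_next = t + rng.exponential(1.0 / rate)
            if t1 is not None and t_next >= t1:
                return pool
            a, b = rng.choice(j, size=2, replace=False)
            a, b = sorted((int(a), int(b)))
            parent = {"label": None, "children": [pool[a], pool[b]],
                      "age": t_next}
            pool = [x for i, x in enumerate(pool) if i not in (a, b)]
            pool.append(parent)
            t = t_next
        return pool

    # bottom-up over species-tree internal nodes by age
    order = sorted(species_tree.preorder_internal_node_iter(),
                   key=lambda n: ages[n])
    for leaf in species_tree.leaf_node_iter():
        top = ages[leaf.parent_node] * to_gen
        lineages[leaf] = coalesce(lineages[leaf], 0.0, top)
    for node in order:
        pool = []
        for child in node.child_nodes():
            pool.extend(lineages[child])
        t0 = ages[node] * to_gen
        if node.parent_node is None:
            lineages[node] = coalesce(pool, t0, None)
        else:
            lineages[node] = coalesce(pool, t0, ages[node.parent_node] * to_gen)

    root = lineages[species_tree.seed_node][0]

    def spec_of(rec, parent_age):
        length = parent_age - rec["age"] if parent_age is not None else None
        return (rec["label"], length,
                [spec_of(c, rec["age"]) for c in rec["children"]])

    return _build_tree(labels, spec_of(root, None))


def simulate_coalescent(ne: float, k_samples: int,
                        seed: int | np.random.Generator = 0,
                        label: str = "sample") -> dendropy.Tree:
    """Single-population Kingman coalescent genealogy, in generations.

    Pairwise coalescence among j lineages at rate j(j-1)/(2*ne) per
    generation (haploid ne); the expected pairwise coalescence time is ne
    generations."""
    if ne <= 0 or k_samples < 2:
        raise ValueError("ne must be > 0 and k_samples >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pool = [{"label": f"{label}_{i + 1:02d}", "children": [], "age": 0.0}
            for i in range(k_samples)]
    t = 0.0
    while len(pool) > 1:
        j = len(pool)
        t += rng.exponential(2.0 * ne / (j * (j - 1)))
        a, b = sorted(int(x) for x in rng.choice(j, size=2, replace=False))
        parent = {"label": None, "children": [pool[a], pool[b]], "age": t}
        pool = [x for i, x in enumerate(pool) if i not in (a, b)] + [parent]

    def spec_of(rec, parent_age):
        length = parent_age - rec["age"] if parent_age is not None else None
        return (rec["label"], length,
                [spec_of(c, rec["age"]) for c in rec["children"]])

    labels = [f"{label}_{i + 1:02d}" for i in range(k_samples)]
    return _build_tree(labels, spec_of(pool[0], None))


def _hky_q(kappa: float) -> np.ndarray:
    """HKY rate matrix, equal base frequencies, total rate 1 per site.

    Order ACGT; transitions are A<->G and C<->T."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    q = np.full((4, 4), beta)
    q[0, 2] = q[2, 0] = alpha   # A<->G
    q[1, 3] = q[3, 1] = alpha   # C<->T
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _stop_free_root(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random root sequence without frame-0 stop codons (codes 0..3)."""
    codon_pool = [c for c in
                  ("".join((a, b, d)) for a in "ACGT" for b in "ACGT"
                   for d in "ACGT")
                  if c not in _STOPS]
    idx = {b: i for i, b in enumerate("ACGT")}
    n_codons = length // 3
    picks = rng.integers(0, len(codon_pool), size=n_codons)
    seq = [idx[b] for p in picks for b in codon_pool[p]]
    while len(seq) < length:
        seq.append(int(rng.integers(0, 4)))
    return np.array(seq[:length], dtype=np.int8)


def evolve_sequences(genealogy: dendropy.Tree, seq_length: int, mu: float,
                     kappa: float = 2.0,
                     seed: int | np.random.Generator = 0,
                     root_sequence: np.ndarray | None = None) -> dict[str, str]:
    """Site-independent HKY evolution down a genealogy (branch lengths in
    generations, mu per site per generation); kappa=1 gives Jukes-Cantor."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    q = _hky_q(kappa) * mu
    states: dict[dendropy.Node, np.ndarray] = {}
    out: dict[str, str] = {}
    for node in genealogy.preorder_node_iter():
        if node.parent_node is None:
            if root_sequence is None:
                states[node] = _stop_free_root(seq_length, rng)
            else:
                states[node] = np.asarray(root_sequence, dtype=np.int8)
        else:
            t = node.edge.length or 0.0
            p = expm(q * t)
            cum = np.cumsum(p, axis=1)
            parent = states[node.parent_node]
            u = rng.random(seq_length)
            child = np.empty(seq_length, dtype=np.int8)
            for s in range(4):
                sel = parent == s
                if sel.any():
                    child[sel] = np.searchsorted(cum[s], u[sel], side="right")
            np.clip(child, 0, 3, out=child)
            states[node] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[states[node]])
    return out


def degrade_records(records: list[BarcodeRecord], truncate_prob: float,
                    ambiguity_rate: float,
                    seed: int | np.random.Generator = 0,
                    window_weights: dict[int, float] | None = None,
                    ) -> list[BarcodeRecord]:
    """Truncate a fraction of records to real amplicon windows and inject Ns.

    Selected records keep only a contiguous window of 609, 407 or 307 sites
    (609 and 307 anchored at the 5' end, 407 at the 3' end); everything else
    becomes missing.  Ns are injected per retained site at ``ambiguity_rate``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    weights = window_weights or {609: 0.5, 407: 0.35, 307: 0.15}
    lengths = sorted(weights)
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    out = []
    for rec in records:
        seq = np.array(list(rec.sequence))
        if rng.random() < truncate_prob:
            length = lengths[int(rng.choice(len(lengths), p=probs))]
            start, stop = AMPLICON_WINDOWS[length]
            keep = np.zeros(len(seq), dtype=bool)
            keep[start:stop] = True
            seq[~keep] = "-"
        present = seq != "-"
        if ambiguity_rate > 0:
            hit = (rng.random(len(seq)) < ambiguity_rate) & present
            seq[hit] = "N"
        out.append(BarcodeRecord(
            record_id=rec.record_id, species=rec.species, family=rec.family,
            sequence="".join(seq), latitude=rec.latitude,
            longitude=rec.longitude, country=rec.country,
        ))
    return out


def _coordinates(config: SimulationConfig,
                 rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """Species range centres in an Iberia-like window, overlap pairs close."""
    centres: dict[int, tuple[float, float]] = {}
    for i in range(config.n_species):
        centres[i] = (float(rng.uniform(36.0, 43.5)),
                      float(rng.uniform(-9.0, 3.0)))
    for a, b in config.overlap_pairs:
        lat, lon = centres[a]
        centres[b] = (lat + float(rng.normal(0, 0.05)),
                      lon + float(rng.normal(0, 0.05)))
    return {f"species_{i + 1:03d}": c for i, c in centres.items()}


def generate(config: SimulationConfig) -> tuple[BarcodeDataset, SyntheticTruth]:
    """End-to-end synthetic dataset plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_yule_tree(config.n_species, config.birth_rate, rng)
    genealogy = simulate_msc_genealogy(
        species_tree, config.ne, config.samples_per_species,
        config.generations_per_year, rng)
    seqs = evolve_sequences(genealogy, config.seq_length, config.mu,
                            config.kappa, rng)
    centres = _coordinates(config, rng)
    deg_lat = 1.0 / 111.32  # degrees latitude per km

    records: list[BarcodeRecord] = []
    species_of: dict[str, str] = {}
    counter = 0
    for leaf in genealogy.leaf_node_iter():
        label = leaf.taxon.label
        species = label.rsplit("_", 1)[0]
        counter += 1
        rid = f"SIM{counter:05d}"
        clat, clon = centres[species]
        sd_lat = config.dispersion_km * deg_lat
        sd_lon = config.dispersion_km * deg_lat / max(
            math.cos(math.radians(clat)), 0.1)
        lat = float(np.clip(clat + rng.normal(0, sd_lat), -90, 90))
        lon = float(np.clip(clon + rng.normal(0, sd_lon), -180, 180))
        sp_index = int(species.rsplit("_", 1)[1]) - 1
        records.append(BarcodeRecord(
            record_id=rid, species=species,
            family=config.families[sp_index % len(config.families)],
            sequence=seqs[label], latitude=lat, longitude=lon,
            country="Simulandia",
        ))
        species_of[rid] = species

    records = degrade_records(records, config.truncate_prob,
                              config.ambiguity_rate, rng)
    ds = BarcodeDataset(records, alignment_length=config.seq_length)
    truth = SyntheticTruth(
        species_of=species_of,
        species_tree=species_tree,
        gene_genealogy=genealogy,
        true_partition=EntityPartition.from_assignment(species_of),
    )
    if set(truth.species_of) != {r.record_id for r in ds.records}:
        raise RuntimeError("truth and dataset disagree on record ids")
    return ds, truth
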