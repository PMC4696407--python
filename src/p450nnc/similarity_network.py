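"""Chemical similarity networks: Tanimoto edges, clusters, representatives.

Compounds become nodes; an undirected edge joins two compounds whose
fingerprint Tanimoto coefficient is at least the threshold (default 0.8,
i.e. >=80% structural similarity).  Connected components are the structural
clusters, each represented by its member with the most within-cluster
neighbors.  A similarity-aware train/validation split keeps all structurally
similar compounds in training so that validation compounds are dissimilar to
everything in both sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


@dataclass(frozen=True)
class Fingerprint:
    """Binary structural fingerprint as a set of on-bit indices."""

    id: str
    bits: frozenset[int]
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.n_bits:
            raise ValueError("bit index out of range")


@dataclass
class Cluster:
    members: list[str]
    representative: str

    @property
    def size(self) -> int:
        return len(self.members)


def fingerprint_from_smiles(compound_id: str, smiles: str, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """Circular (Morgan/ECFP-style) fingerprint of a structure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(compound_id, frozenset(fp.GetOnBits()), n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b| of two equal-length fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint length mismatch")
    if not a.bits or not b.bits:
        raise ValueError("empty fingerprint")
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def build_csn(
    fingerprints: Sequence[Fingerprint],
    categories: Mapping[str, str] | None = None,
    threshold: float = 0.8,
) -> nx.Graph:
    """Build the chemical similarity network at the given Tanimoto threshold.

    Edges are inclusive (similarity >= threshold) and carry the similarity as
    a ``weight`` attribute; nodes carry a ``category`` attribute when
    supplied.
    """
    g = nx.Graph(threshold=threshold)
    for fp in fingerprints:
        cat = categories.get(fp.id) if categories else None
        g.add_node(fp.id, category=cat)
    for i, a in enumerate(fingerprints):
        for b in fingerprints[i + 1 :]:
            s = tanimoto(a, b)
            if s >= threshold:
                g.add_edge(a.id, b.id, weight=s)
    return g


def clusters(network: nx.Graph, min_size: int = 1, strict: bool = False) -> list[Cluster]:
    """Connected components of the network as clusters, largest first.

    ``min_size`` filters by component size (inclusive by default; ``strict``
    demands size > min_size).  The representative is the member with maximal
    within-cluster degree, ties resolved by lexicographic id.
    """
    out: list[Cluster] = []
    for comp in nx.connected_components(network):
        size = len(comp)
        if (size <= min_size) if strict else (size < min_size):
            continue
        members = sorted(comp)
        rep = min(members, key=lambda m: (-network.degree(m), m))
        out.append(Cluster(members, rep))
    out.sort(key=lambda c: (-c.size, c.representative))
    return out


def split_by_similarity(
    fingerprints: Sequence[Fingerprint],
    ratio: tuple[int, int] = (2, 1),
    threshold: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Similarity-aware training/validation split (default 2:1).

    Every compound with at least one neighbor at the threshold goes to
    training; only structurally isolated compounds are eligible for
    validation, so no validation compound has a similar partner in either
    set.  Isolated compounds are allocated randomly (seeded) to approach the
    requested ratio; when too few exist a warning is emitted and a
    best-effort split is returned.
    """
    g = build_csn(fingerprints, threshold=threshold)
    connected = sorted(n for n in g.nodes if g.degree(n) > 0)
    isolated = sorted(n for n in g.nodes if g.degree(n) == 0)
    n = len(fingerprints)
    target_val = round(n * ratio[1] / sum(ratio))
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(isolated)))
    val = [isolated[i] for i in order[:target_val]]
    extra_train = [isolated[i] for i in order[target_val:]]
    if len(val) < target_val:
        warnings.warn(
            f"only {len(val)} dissimilar compounds available for a validation "
            f"target of {target_val}; returning best-effort split",
            stacklevel=2,
        )
    train = sorted(connected + extra_train)
    return train, sorted(val)


def cluster_report(network: nx.Graph, clusts: Iterable[Cluster]) -> list[dict]:
    """Per-cluster summary rows: id, size, representative, category counts."""
    rows = []
    for i, c in enumerate(clusts):
        cats: dict[str, int] = {}
        for m in c.members:
            cat = network.nodes[m].get("category")
            if cat is not None:
                cats[cat] = cats.get(cat, 0) + 1
        rows.append(
            {
                "cluster": i,
                "size": c.size,
                "representative": c.representative,
                "categories": cats,
            }
        )
    return rows


def write_sif(network: nx.Graph, path) -> None:
    """Export edges in simple interaction format (id1 sim id2)."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\tsim\t{v}\n")
    # isolated nodes appear as bare ids
    with open(path, "a") as fh:
        for node in sorted(network.nodes):
            if network.degree(node) == 0:
                fh.write(f"{node}\n")


def write_graphml(network: nx.Graph, path) -> None:
    g = network.copy()
    for _, data in g.nodes(data=True):
        if data.get("category") is None:
            data.pop("category", None)
    g.graph.pop("threshold", None)
    nx.write_graphml(g, path)
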