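"""DnaSP-style mitochondrial diversity summaries and median-joining networks.

Summaries follow the complete-deletion convention: any alignment column
containing a gap or an ambiguous base (anything outside A/C/G/T) is excluded
from haplotype collapsing, segregating-site counting and nucleotide
diversity alike, so the three statistics are computed on the same set of
"analyzed" sites. Haplotype diversity carries Nei's n/(n-1) small-sample
correction, matching what DnaSP reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "read_fasta",
    "write_fasta",
    "collapse_haplotypes",
    "segregating_sites",
    "haplotype_diversity",
    "haplotype_diversity_variance",
    "nucleotide_diversity",
    "median_joining_network",
    "write_network",
]

_VALID_STATES = frozenset("ACGT")


@dataclass
class Alignment:
    """Equal-length sequences; residues outside A/C/G/T count as missing."""

    sequences: list[tuple[str, str]]  # (id, residues)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        self.sequences = [(sid, s.upper()) for sid, s in self.sequences]
        L = len(self.sequences[0][1])
        if L == 0:
            raise ValueError("alignment length must be > 0")
        bad = [sid for sid, s in self.sequences if len(s) != L]
        if bad:
            raise ValueError(f"sequences with length != {L}: {bad}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    def analyzed_sites(self) -> np.ndarray:
        """Column indices free of gaps/ambiguities in every sequence."""
        arr = self._array()
        ok = np.isin(arr, list(_VALID_STATES)).all(axis=0)
        return np.nonzero(ok)[0]

    def _array(self) -> np.ndarray:
        return np.array([list(s) for _, s in self.sequences])


def read_fasta(path: str | Path) -> Alignment:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return Alignment(records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=sid, description="") for sid, s in aln.sequences]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class HaplotypeTable:
    """Sequence variants collapsed over analyzed sites, with counts."""

    haplotypes: list[tuple[str, int, list[str]]]  # (representative, count, member ids)
    n: int
    L: int  # number of analyzed sites
    analyzed: np.ndarray  # analyzed column indices into the representatives

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c, _ in self.haplotypes])

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": [f"H{i + 1}" for i in range(self.n_haplotypes)],
                "count": self.counts,
                "members": [";".join(m) for _, _, m in self.haplotypes],
                "sequence": [s for s, _, _ in self.haplotypes],
            }
        )


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group sequences identical over analyzed sites, in first-seen order."""
    sites = aln.analyzed_sites()
    groups: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    for sid, s in aln.sequences:
        key = "".join(s[i] for i in sites)
        groups.setdefault(key, []).append(sid)
        reps.setdefault(key, s)
    haplotypes = [(reps[k], len(m), m) for k, m in groups.items()]
    return HaplotypeTable(haplotypes, aln.n, len(sites), sites)


def segregating_sites(aln: Alignment) -> int:
    """Number of analyzed sites with at least two distinct states."""
    sites = aln.analyzed_sites()
    arr = aln._array()[:, sites]
    return int(sum(len(set(arr[:, j])) > 1 for j in range(arr.shape[1])))


def haplotype_diversity(tab: HaplotypeTable) -> float:
    """Nei's unbiased haplotype diversity H = n/(n-1) * (1 - sum p_i^2)."""
    if tab.n < 2:
        raise ValueError("haplotype diversity needs n >= 2 sequences")
    p = tab.counts / tab.n
    return tab.n / (tab.n - 1) * (1.0 - float(np.sum(p**2)))


def haplotype_diversity_variance(tab: HaplotypeTable) -> float:
    """Nei's sampling variance of H (Nei 1987, eq. 8.12)."""
    if tab.n < 2:
        raise ValueError("needs n >= 2 sequences")
    n = tab.n
    p = tab.counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    return 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)


def nucleotide_diversity(aln: Alignment) -> float:
    """Per-site nucleotide diversity: mean pairwise differences / analyzed sites."""
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2 sequences")
    sites = aln.analyzed_sites()
    if len(sites) == 0:
        raise ValueError("no analyzed sites (every column has missing data)")
    arr = aln._array()[:, sites]
    total = 0
    for i, j in itertools.combinations(range(aln.n), 2):
        total += int(np.sum(arr[i] != arr[j]))
    n_pairs = aln.n * (aln.n - 1) // 2
    return total / n_pairs / len(sites)


# ---------------------------------------------------------------------------
# median-joining network


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _minimax_connection_levels(labels: list[str], dist: dict[tuple[str, str], int]) -> dict[tuple[str, str], int]:
    """For each pair, the smallest w such that the pair is connected using
    only edges of weight <= w (minimax path weight)."""
    inf = 10**9
    n = len(labels)
    lvl = {(a, b): dist[(a, b)] for a, b in itertools.combinations(labels, 2)}

    def get(a: str, b: str) -> int:
        return lvl[(a, b)] if (a, b) in lvl else lvl[(b, a)]

    def put(a: str, b: str, v: int) -> None:
        if (a, b) in lvl:
            lvl[(a, b)] = v
        else:
            lvl[(b, a)] = v

    for k in labels:
        for a, b in itertools.combinations(labels, 2):
            if a == k or b == k:
                continue
            via = max(get(a, k), get(k, b))
            if via < get(a, b):
                put(a, b, via)
    return lvl


def _msn_edges(seqs: dict[str, str], epsilon: int) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum spanning network."""
    labels = sorted(seqs)
    if len(labels) < 2:
        return []
    dist = {(a, b): _hamming(seqs[a], seqs[b]) for a, b in itertools.combinations(labels, 2)}
    lvl = _minimax_connection_levels(labels, dist)
    edges = []
    for a, b in itertools.combinations(labels, 2):
        d = dist[(a, b)]
        c = lvl[(a, b)] if (a, b) in lvl else lvl[(b, a)]
        if d <= c + epsilon:
            edges.append((a, b, d))
    return edges


def _mst_length(seqs: dict[str, str]) -> int:
    labels = sorted(seqs)
    if len(labels) < 2:
        return 0
    g = nx.Graph()
    for a, b in itertools.combinations(labels, 2):
        g.add_edge(a, b, weight=_hamming(seqs[a], seqs[b]))
    return int(sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)))


def _median_seq(sa: str, sb: str, sc: str) -> str:
    """Per-site majority consensus; three-way ties keep the first sequence's
    state (the triplet is supplied in lexicographic label order)."""
    out = []
    for x, y, z in zip(sa, sb, sc):
        if y == z:
            out.append(y)
        else:
            out.append(x)  # x==y, x==z, or all distinct -> x wins
    return "".join(out)


def median_joining_network(tab: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Bandelt-style median-joining network on Hamming distances.

    Iteratively: take the epsilon-relaxed minimum spanning network over the
    current node set; for each triplet of nodes form the majority-consensus
    median vector and add the one that most shortens the minimum
    spanning-tree length; stop when no median helps, then prune median nodes
    whose removal leaves the total length unchanged. Observed nodes carry
    their haplotype counts; inferred medians have count 0. Deterministic:
    candidate triplets are visited in lexicographic label order.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if tab.n_haplotypes == 0:
        raise ValueError("empty haplotype table")

    sites = tab.analyzed
    seqs: dict[str, str] = {}
    counts: dict[str, int] = {}
    for i, (rep, count, _members) in enumerate(tab.haplotypes):
        label = f"H{i + 1}"
        seqs[label] = "".join(rep[j] for j in sites)
        counts[label] = count

    n_medians = 0
    max_medians = 4 * max(1, tab.n_haplotypes)
    while n_medians < max_medians:
        current_len = _mst_length(seqs)
        best: tuple[int, str] | None = None
        seen = set(seqs.values())
        for a, b, c in itertools.combinations(sorted(seqs), 3):
            m = _median_seq(seqs[a], seqs[b], seqs[c])
            if m in seen:
                continue
            trial = dict(seqs)
            trial["_m"] = m
            new_len = _mst_length(trial)
            if new_len < current_len and (best is None or new_len < best[0]):
                best = (new_len, m)
        if best is None:
            break
        n_medians += 1
        seqs[f"mv{n_medians}"] = best[1]

    # prune medians that no longer shorten the network
    changed = True
    while changed:
        changed = False
        for label in sorted(s for s in seqs if s.startswith("mv")):
            trial = {k: v for k, v in seqs.items() if k != label}
            if _mst_length(trial) == _mst_length(seqs):
                del seqs[label]
                changed = True

    g = nx.Graph()
    for label in sorted(seqs):
        g.add_node(
            label,
            count=counts.get(label, 0),
            is_median=label.startswith("mv"),
            sequence=seqs[label],
        )
    for a, b, d in _msn_edges(seqs, epsilon):
        g.add_edge(a, b, weight=d)
    if len(seqs) == 1:
        pass  # single-node network is trivially connected
    return g


def write_network(g: nx.Graph, out_dir: str | Path, stem: str = "network") -> tuple[Path, Path]:
    """Write a haplotype network as GML plus a plain edge list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gml = out_dir / f"{stem}.gml"
    edges = out_dir / f"{stem}.edges.tsv"
    nx.write_gml(g, str(gml))
    with open(edges, "w") as fh:
        fh.write("node_a\tnode_b\tdistance\n")
        for a, b, d in sorted(g.edges(data="weight")):
            fh.write(f"{a}\t{b}\t{d}\n")
    return gml, edges
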