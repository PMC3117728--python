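"""Minimum-spanning haplotype networks over allele sequences.

Identical sequences are merged into single nodes (frequencies summed).
Construction is a minimum-spanning network: unique pairwise distances
are processed in increasing order and, at each level, every edge that
joins two components distinct at the start of that level is retained —
tied connections therefore create loops ("reticulations").  Edges carry
the nucleotide distance and the amino-acid substitutions between their
endpoints, labeled ``<from><codon><to>`` in 1-based codon numbering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from ._codon import translate
from .io_model import AlleleSet, CodonAlignment, MhdivError


@dataclass(frozen=True)
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: frequency, members; edge attrs: distance, aa_changes
    distance_mode: str

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def loops(self) -> list[list[str]]:
        return [list(c) for c in nx.cycle_basis(self.graph)]

    def edge_rows(self) -> list[dict]:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append(
                {
                    "from": u,
                    "to": v,
                    "distance": d["distance"],
                    "aa_changes": ";".join(d["aa_changes"]),
                }
            )
        return rows

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for n, d in self.graph.nodes(data=True):
            size = 0.3 + 2.0 * d.get("frequency", 0.0)
            lines.append(
                f'  "{n}" [width={size:.2f}, label="{n}\\n'
                f'{d.get("frequency", 0):.3f}"];'
            )
        for u, v, d in self.graph.edges(data=True):
            label = ",".join(d["aa_changes"]) or str(d["distance"])
            lines.append(f'  "{u}" -- "{v}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def _nt_distance(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _aa_changes(a: str, b: str) -> list[str]:
    pa, pb = translate(a), translate(b)
    return [
        f"{x}{i + 1}{y}" for i, (x, y) in enumerate(zip(pa, pb)) if x != y
    ]


def build_network(
    alleles: AlleleSet,
    alignment: CodonAlignment,
    distance_mode: str = "nt",
) -> HaplotypeNetwork:
    """Minimum-spanning network over the alleles of ``alleles``.

    ``distance_mode``: "nt" (nucleotide differences, default) or
    "nonsyn" (amino-acid differences).
    """
    if len(alleles) < 1:
        raise MhdivError("no alleles to network")
    if distance_mode not in ("nt", "nonsyn"):
        raise ValueError("distance_mode must be 'nt' or 'nonsyn'")
    # merge identical sequences
    by_seq: dict[str, list[str]] = {}
    for aid in alleles.ids:
        seq = alleles.alleles[aid][0]
        by_seq.setdefault(seq, []).append(aid)
    reps = []  # (node_label, seq, freq, members)
    for seq, members in by_seq.items():
        label = "+".join(sorted(members))
        freq = sum(alleles.frequency(m) for m in members)
        reps.append((label, seq, freq, sorted(members)))
    g = nx.Graph()
    for label, _, freq, members in reps:
        g.add_node(label, frequency=freq, members=members)
    if len(reps) > 1:
        dist = {}
        for (la, sa, _, _), (lb, sb, _, _) in itertools.combinations(
            reps, 2
        ):
            if distance_mode == "nt":
                d = _nt_distance(sa, sb)
            else:
                d = len(_aa_changes(sa, sb))
            dist[(la, lb)] = (d, _aa_changes(sa, sb), _nt_distance(sa, sb))
        levels = sorted({d for d, _, _ in dist.values()})
        for level in levels:
            if nx.is_connected(g):
                break
            comp = {
                n: i
                for i, c in enumerate(nx.connected_components(g))
                for n in c
            }
            for (la, lb), (d, aa, nt) in dist.items():
                if d == level and comp[la] != comp[lb]:
                    g.add_edge(la, lb, distance=nt, aa_changes=aa)
    return HaplotypeNetwork(g, distance_mode)


def prune_and_rebuild(
    alleles: AlleleSet,
    alignment: CodonAlignment,
    exclude: Iterable[str],
    distance_mode: str = "nt",
) -> HaplotypeNetwork:
    """Rebuild the network from scratch without the ``exclude`` alleles
    (remaining frequencies renormalised)."""
    drop = set(exclude)
    unknown = drop - set(alleles.ids)
    if unknown:
        raise MhdivError(f"cannot exclude unknown alleles: {sorted(unknown)}")
    kept = {
        aid: alleles.alleles[aid] for aid in alleles.ids if aid not in drop
    }
    if not kept:
        raise MhdivError("cannot exclude every allele")
    total = sum(c for _, c, _ in kept.values())
    if total > 0:
        kept = {
            aid: (seq, cnt, cnt / total)
            for aid, (seq, cnt, _) in kept.items()
        }
    else:  # count-free allele sets: renormalise frequencies directly
        fsum = sum(f for _, _, f in kept.values())
        kept = {
            aid: (seq, cnt, f / fsum)
            for aid, (seq, cnt, f) in kept.items()
        }
    return build_network(AlleleSet(kept), alignment, distance_mode)


def write_graphml(network: HaplotypeNetwork, path) -> None:
    g = network.graph.copy()
    for _, _, d in g.edges(data=True):
        d["aa_changes"] = ";".join(d["aa_changes"])
    for _, d in g.nodes(data=True):
        d["members"] = ";".join(d["members"])
    nx.write_graphml(g, path)
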