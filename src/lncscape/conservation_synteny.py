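"""Cross-species conservation of lncRNAs.

Sequence level: BLASTN tabular output (outfmt 6) is summarised at two
E-value cutoffs (1e-3 loose, 1e-10 strict); each query counts once no
matter how many hits it has, and counts at the strict cutoff can never
exceed the loose ones.

Synteny level: an lncRNA locus's neighbourhood is its three nearest
protein-coding genes on each side (genomic order, strand-agnostic).  Two
loci from different species form a syntenic pair when their neighbourhoods
share at least three distinct ortholog groups with at least one shared
group on each side in each species.  Accepted pairs are chained into
families as connected components of the pair graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io_formats import Annotation
from .lncrna_identification import round_half_up

logger = logging.getLogger("lncscape")

__all__ = [
    "BlastSummary",
    "Neighborhood",
    "SyntenyFamily",
    "summarize_blast",
    "relative_decrease",
    "build_neighborhood",
    "syntenic_pair",
    "build_families",
    "find_synteny_families",
]

E_LOOSE = 1e-3
E_STRICT = 1e-10


@dataclass
class BlastSummary:
    cutoff: float
    n_query_with_hit: int
    n_target_hit: int
    queries_with_hit: set[str] = field(default_factory=set)
    targets_hit: set[str] = field(default_factory=set)


def summarize_blast(
    hits: pd.DataFrame,
    cutoff: float,
    query_ids: set[str] | None = None,
    target_lnc_ids: set[str] | None = None,
) -> BlastSummary:
    """Distinct-query and distinct-subject hit counts at an E-value cutoff.

    ``query_ids``, when given, is the full query universe: hit rows whose
    query is unknown are warned about but still counted.  When the targets
    are lncRNA transcripts (``target_lnc_ids``), subjects outside that set
    are ignored for the target tally.
    """
    kept = hits[hits["evalue"] <= cutoff]
    queries = set(kept["qseqid"].astype(str))
    if query_ids is not None:
        unknown = queries - query_ids
        if unknown:
            logger.warning(
                "summarize_blast: %d hit queries not in the query set "
                "(counted anyway): %s",
                len(unknown), ", ".join(sorted(unknown)[:5]),
            )
    subjects = set(kept["sseqid"].astype(str))
    if target_lnc_ids is not None:
        subjects &= target_lnc_ids
    return BlastSummary(
        cutoff=cutoff,
        n_query_with_hit=len(queries),
        n_target_hit=len(subjects),
        queries_with_hit=queries,
        targets_hit=subjects,
    )


def relative_decrease(n_loose: int, n_strict: int) -> float | None:
    """100*(n_loose - n_strict)/n_loose, round-half-up to 2 decimals;
    None when n_loose = 0."""
    if n_loose < n_strict or n_strict < 0:
        raise ValueError("need n_loose >= n_strict >= 0")
    if n_loose == 0:
        return None
    return round_half_up(100.0 * (n_loose - n_strict) / n_loose, 2)


@dataclass
class Neighborhood:
    """Up to k protein-coding genes on each side of an lncRNA locus,
    nearest first."""

    locus_id: str
    chrom: str
    left: list[str]
    right: list[str]

    def groups(self, gene_to_group: Mapping[str, str]) -> tuple[set, set]:
        left = {gene_to_group[g] for g in self.left if g in gene_to_group}
        right = {gene_to_group[g] for g in self.right if g in gene_to_group}
        return left, right


def build_neighborhood(
    locus_id: str,
    chrom: str,
    start: int,
    end: int,
    pcg_annotation: Annotation,
    k: int = 3,
) -> Neighborhood:
    """The k nearest PCGs strictly left and right of the locus span, by
    genomic coordinate and strand-agnostic.

    A PCG overlapping the locus is assigned to the side of its midpoint
    relative to the locus midpoint.  Chromosome ends yield fewer than k.
    """
    spans = pcg_annotation.gene_spans()
    spans = spans[spans["chrom"] == chrom]
    if spans.empty:
        return Neighborhood(locus_id, chrom, [], [])
    locus_mid = (start + end) / 2.0
    left: list[tuple[float, str]] = []
    right: list[tuple[float, str]] = []
    for gene_id, row in spans.iterrows():
        gs, ge = int(row["start"]), int(row["end"])
        mid = (gs + ge) / 2.0
        if ge < start:
            left.append((mid, gene_id))
        elif gs > end:
            right.append((mid, gene_id))
        elif mid <= locus_mid:  # overlapping: side of its midpoint
            left.append((mid, gene_id))
        else:
            right.append((mid, gene_id))
    left.sort(key=lambda p: -p[0])   # nearest (largest midpoint) first
    right.sort(key=lambda p: p[0])
    return Neighborhood(
        locus_id, chrom,
        [g for _, g in left[:k]],
        [g for _, g in right[:k]],
    )


def syntenic_pair(
    n_a: Neighborhood,
    n_b: Neighborhood,
    gene_to_group_a: Mapping[str, str],
    gene_to_group_b: Mapping[str, str],
    min_shared: int = 3,
    allow_inversion: bool = False,
) -> tuple[bool, set, dict]:
    """Accept a cross-species locus pair on shared orthologous flankers.

    Shared ortholog groups are counted as distinct groups (a tandem
    duplication contributes once).  Acceptance requires at least
    ``min_shared`` shared groups and, in each species' neighbourhood, at
    least one shared group on its left and one on its right.
    ``allow_inversion`` relaxes the side requirement to a single species:
    a local inversion or fragmentation may push all shared flankers to one
    side of the other species' locus.
    """
    la, ra = n_a.groups(gene_to_group_a)
    lb, rb = n_b.groups(gene_to_group_b)
    shared = (la | ra) & (lb | rb)
    support = {
        "left_a": shared & la, "right_a": shared & ra,
        "left_b": shared & lb, "right_b": shared & rb,
    }
    if len(shared) < min_shared:
        return False, shared, support
    sides_a = bool(support["left_a"]) and bool(support["right_a"])
    sides_b = bool(support["left_b"]) and bool(support["right_b"])
    accepted = (sides_a or sides_b) if allow_inversion else (sides_a and sides_b)
    return accepted, shared, support


@dataclass
class SyntenyFamily:
    family_id: int
    members: dict[str, set[str]]  # species -> locus ids
    supporting_groups: set = field(default_factory=set)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())


def build_families(
    accepted_pairs: Iterable[tuple[tuple[str, str], tuple[str, str], set]],
) -> list[SyntenyFamily]:
    """Connected components of the accepted-pair graph.

    Each pair is ((species_a, locus_a), (species_b, locus_b), shared
    ortholog groups).  Loci in no accepted pair form no family.
    """
    graph = nx.Graph()
    shared_by_edge: dict[frozenset, set] = {}
    for node_a, node_b, shared in accepted_pairs:
        graph.add_edge(node_a, node_b)
        shared_by_edge[frozenset((node_a, node_b))] = set(shared)
    families = []
    for fid, component in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)), start=1
    ):
        members: dict[str, set[str]] = {}
        for species, locus in component:
            members.setdefault(species, set()).add(locus)
        groups: set = set()
        for u, v in graph.subgraph(component).edges:
            groups |= shared_by_edge.get(frozenset((u, v)), set())
        families.append(SyntenyFamily(fid, members, groups))
    return families


def find_synteny_families(
    loci_a: Mapping[str, tuple[str, int, int]],
    loci_b: Mapping[str, tuple[str, int, int]],
    pcg_a: Annotation,
    pcg_b: Annotation,
    orthologs: pd.DataFrame,
    species_a: str = "A",
    species_b: str = "B",
    k: int = 3,
    min_shared: int = 3,
    allow_inversion: bool = False,
) -> tuple[list[SyntenyFamily], pd.DataFrame]:
    """End-to-end synteny families between two species.

    ``loci_*`` map locus id -> (chrom, start, end).  Candidate pairs are
    restricted to loci whose neighbourhoods share at least one ortholog
    group, then filtered by :func:`syntenic_pair`.  Returns the families
    and a table of accepted pairs.
    """
    gene_to_group_a = dict(zip(orthologs["gene_a"], orthologs["group_id"]))
    gene_to_group_b = dict(zip(orthologs["gene_b"], orthologs["group_id"]))

    neigh_a = {
        lid: build_neighborhood(lid, *span, pcg_a, k=k)
        for lid, span in loci_a.items()
    }
    neigh_b = {
        lid: build_neighborhood(lid, *span, pcg_b, k=k)
        for lid, span in loci_b.items()
    }

    # invert: ortholog group -> loci in B whose neighbourhood contains it
    group_to_b: dict[str, set[str]] = {}
    for lid, nb in neigh_b.items():
        lb, rb = nb.groups(gene_to_group_b)
        for grp in lb | rb:
            group_to_b.setdefault(grp, set()).add(lid)

    accepted = []
    rows = []
    for lid_a, na in neigh_a.items():
        la, ra = na.groups(gene_to_group_a)
        candidates: set[str] = set()
        for grp in la | ra:
            candidates |= group_to_b.get(grp, set())
        for lid_b in sorted(candidates):
            ok, shared, _support = syntenic_pair(
                na, neigh_b[lid_b], gene_to_group_a, gene_to_group_b,
                min_shared=min_shared, allow_inversion=allow_inversion,
            )
            if ok:
                accepted.append(
                    ((species_a, lid_a), (species_b, lid_b), shared)
                )
                rows.append({
                    "locus_a": lid_a, "locus_b": lid_b,
                    "n_shared_groups": len(shared),
                })
    families = build_families(accepted)
    return families, pd.DataFrame(rows, columns=["locus_a", "locus_b",
                                                 "n_shared_groups"])
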