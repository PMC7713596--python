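"""Panel evaluation: which species can each amplicon tell apart, which
minimal amplicon set covers all species pairs, and in what order should an
unknown be pushed through the assays.

Two species are considered resolvable by an amplicon when *every* pairing
of their haplotype curves differs by at least the Tm threshold or the
curve-shape threshold (instrument-grade defaults 0.3 degC / 0.02 helicity).
Panel selection is greedy set cover over species pairs, with an exhaustive
optimum available as an oracle for small instances.  The decision tree
mirrors the familiar two-amplicon flowchart: each assay splits the still
unresolved species into Tm clusters, singletons become leaves.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_design import CandidateAmplicon
from .barcode_io import SNP_CLASS_RANK, SnpClass, VariantColumn
from .errors import DesignError, GridMismatchError, InputError
from .melt_thermo import MeltCurve, ThermoParams, curve_distance, helicity_curve


@dataclass(frozen=True)
class ResolutionThresholds:
    """Operational definition of "same melting curve": a haplotype pair is
    distinguishable when |dTm| >= delta_tm_c OR max-abs curve distance >=
    curve_dist.  Defaults reflect typical HRM instrument resolution."""

    delta_tm_c: float = 0.3
    curve_dist: float = 0.02


@dataclass
class SpeciesProfile:
    """Predicted melt behavior of one species under one amplicon."""

    species: str
    amplicon: str
    curves: list[MeltCurve]
    tm_set: list[float]


def species_profiles(
    a: CandidateAmplicon, p: ThermoParams | None = None
) -> list[SpeciesProfile]:
    """One profile per species: a melt curve per amplicon haplotype."""
    p = p or ThermoParams.default()
    out = []
    for sp, haps in a.per_species_haplotypes.items():
        if not haps:
            raise InputError(f"{a.name}: species {sp} has no haplotypes")
        curves = [helicity_curve(h, p) for h in haps]
        out.append(
            SpeciesProfile(
                species=sp, amplicon=a.name, curves=curves, tm_set=[c.tm for c in curves]
            )
        )
    return out


@dataclass(frozen=True)
class PairResolution:
    resolvable: bool
    min_delta_tm: float
    min_curve_distance: float
    worst_snp_class: SnpClass | None = None


@dataclass
class ResolvabilityMatrix:
    """Symmetric pairwise resolvability under one amplicon; entries keyed by
    the unordered species pair."""

    amplicon: str
    entries: dict[frozenset, PairResolution]
    thresholds: ResolutionThresholds = field(default_factory=ResolutionThresholds)

    def species(self) -> set[str]:
        out: set[str] = set()
        for pair in self.entries:
            out |= pair
        return out

    def resolved_pairs(self) -> frozenset:
        return frozenset(p for p, e in self.entries.items() if e.resolvable)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, e in sorted(self.entries.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            rows.append(
                {
                    "amplicon": self.amplicon,
                    "species_a": a,
                    "species_b": b,
                    "resolvable": e.resolvable,
                    "min_delta_tm": e.min_delta_tm,
                    "min_curve_distance": e.min_curve_distance,
                    "worst_snp_class": e.worst_snp_class.value if e.worst_snp_class else "",
                }
            )
        return pd.DataFrame(rows)


def _worst_class_for_pair(
    variants: Iterable[VariantColumn], sp_a: str, sp_b: str
) -> SnpClass | None:
    """Least-discriminable substitution class among the variant columns that
    actually distinguish the pair (class 4 A/T is worst)."""
    worst: SnpClass | None = None
    for v in variants:
        ma, mb = v.majority.get(sp_a), v.majority.get(sp_b)
        if ma is None or mb is None or ma == mb:
            continue
        rank = SNP_CLASS_RANK.get(v.snp_class)
        if rank is None:
            continue
        if worst is None or rank > SNP_CLASS_RANK[worst]:
            worst = v.snp_class
    return worst


def resolvability_matrix(
    profiles: Sequence[SpeciesProfile],
    thresholds: ResolutionThresholds | None = None,
    variants: Iterable[VariantColumn] = (),
) -> ResolvabilityMatrix:
    """Worst-case pairwise resolvability: a species pair is resolvable iff
    every cross-species haplotype pairing clears a threshold; the reported
    deltas are the minima over pairings."""
    thresholds = thresholds or ResolutionThresholds()
    if len(profiles) < 2:
        raise DesignError("resolvability needs at least two species profiles")
    entries: dict[frozenset, PairResolution] = {}
    for pa, pb in itertools.combinations(profiles, 2):
        min_dtm = float("inf")
        min_dist = float("inf")
        for ca, cb in itertools.product(pa.curves, pb.curves):
            try:
                dist = curve_distance(ca, cb)
            except GridMismatchError:
                raise GridMismatchError(
                    f"profiles {pa.species}/{pb.species} on different grids"
                )
            dtm = abs(ca.tm - cb.tm)
            min_dtm = min(min_dtm, dtm)
            min_dist = min(min_dist, dist)
        resolvable = (min_dtm >= thresholds.delta_tm_c) or (min_dist >= thresholds.curve_dist)
        entries[frozenset((pa.species, pb.species))] = PairResolution(
            resolvable=resolvable,
            min_delta_tm=min_dtm,
            min_curve_distance=min_dist,
            worst_snp_class=_worst_class_for_pair(variants, pa.species, pb.species),
        )
    return ResolvabilityMatrix(
        amplicon=profiles[0].amplicon, entries=entries, thresholds=thresholds
    )


@dataclass
class Panel:
    """An ordered amplicon selection with its species-pair coverage."""

    amplicons: list[Any]  # CandidateAmplicon or any named amplicon object
    covered_pairs: frozenset
    uncovered_pairs: frozenset

    def names(self) -> list[str]:
        return [getattr(a, "name", str(a)) for a in self.amplicons]


def _rank_key(amplicon: Any, index: int) -> tuple:
    """Deterministic candidate preference: more informative variants, then
    shorter product, then leftmost start, then input order."""
    n_var = len(getattr(amplicon, "contained_variants", ()) or ())
    try:
        size = amplicon.max_product_size()
    except AttributeError:
        size = 0
    start = getattr(amplicon, "interval", (0, 0))[0]
    return (-n_var, size, start, index)


def _all_pairs(matrices: Sequence[ResolvabilityMatrix]) -> frozenset:
    species: set[str] = set()
    for m in matrices:
        species |= m.species()
    return frozenset(frozenset(p) for p in itertools.combinations(sorted(species), 2))


def greedy_panel(
    entries: Sequence[tuple[Any, ResolvabilityMatrix]]
) -> Panel:
    """Greedy set cover over species pairs: repeatedly add the amplicon
    resolving the most still-uncovered pairs (ties by the candidate rank),
    until everything is covered or no amplicon adds coverage."""
    if not entries:
        raise DesignError("greedy_panel needs at least one candidate")
    matrices = [m for _, m in entries]
    universe = _all_pairs(matrices)
    remaining = set(universe)
    available = [
        (amp, m.resolved_pairs(), _rank_key(amp, i)) for i, (amp, m) in enumerate(entries)
    ]
    chosen: list[Any] = []
    while remaining and available:
        best = max(
            available,
            key=lambda item: (len(item[1] & remaining), tuple(-x for x in item[2][:3]), -item[2][3]),
        )
        gain = len(best[1] & remaining)
        if gain == 0:
            break
        chosen.append(best[0])
        remaining -= best[1]
        available = [it for it in available if it[0] is not best[0]]
    covered = universe - frozenset(remaining)
    return Panel(
        amplicons=chosen, covered_pairs=frozenset(covered), uncovered_pairs=frozenset(remaining)
    )


def exhaustive_panel(
    entries: Sequence[tuple[Any, ResolvabilityMatrix]], max_candidates: int = 12
) -> Panel:
    """Minimum-cardinality fully covering subset by exhaustive search
    (lexicographic tie-break on candidate indices); if full coverage is
    impossible, the maximal-coverage subset of minimal size.  Test oracle;
    refuses more than ``max_candidates`` candidates."""
    if not entries:
        raise DesignError("exhaustive_panel needs at least one candidate")
    if len(entries) > max_candidates:
        raise InputError(f"exhaustive search refused above {max_candidates} candidates")
    matrices = [m for _, m in entries]
    universe = _all_pairs(matrices)
    coverages = [m.resolved_pairs() for m in matrices]
    best: tuple[frozenset, tuple[int, ...]] | None = None
    for size in range(1, len(entries) + 1):
        for combo in itertools.combinations(range(len(entries)), size):
            cov = frozenset().union(*(coverages[i] for i in combo))
            if cov == universe:
                chosen = [entries[i][0] for i in combo]
                return Panel(
                    amplicons=chosen, covered_pairs=cov, uncovered_pairs=frozenset()
                )
            if best is None or len(cov) > len(best[0]):
                best = (cov, combo)
    cov, combo = best  # type: ignore[misc]
    return Panel(
        amplicons=[entries[i][0] for i in combo],
        covered_pairs=cov,
        uncovered_pairs=universe - cov,
    )


@dataclass
class TreeNode:
    amplicon: str
    partition: list[list[str]]  # Tm clusters of the species still in play


@dataclass
class TreeLeaf:
    species: list[str]
    resolved: bool  # True: single species; False: unresolved group


@dataclass
class DecisionTree:
    """Hierarchical identification logic: assays in panel order, each
    splitting the remaining species into Tm clusters."""

    nodes: list[TreeNode]
    leaves: list[TreeLeaf]

    def all_species(self) -> set[str]:
        out: set[str] = set()
        for leaf in self.leaves:
            out |= set(leaf.species)
        return out

    def amplicon_order(self) -> list[str]:
        return [n.amplicon for n in self.nodes]

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"amplicon": n.amplicon, "partition": n.partition} for n in self.nodes
                ],
                "leaves": [
                    {"species": l.species, "resolved": l.resolved} for l in self.leaves
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        raw = json.loads(text)
        return cls(
            nodes=[TreeNode(n["amplicon"], [list(g) for g in n["partition"]]) for n in raw["nodes"]],
            leaves=[TreeLeaf(list(l["species"]), bool(l["resolved"])) for l in raw["leaves"]],
        )

    def to_dot(self) -> str:
        """Graphviz-compatible rendering of the flowchart."""
        lines = ["digraph identification {", '  rankdir="TB";']
        prev = "start"
        lines.append('  start [label="sample", shape=oval];')
        for i, node in enumerate(self.nodes):
            nid = f"node{i}"
            lines.append(f'  {nid} [label="{node.amplicon}", shape=box];')
            lines.append(f"  {prev} -> {nid};")
            for j, group in enumerate(node.partition):
                gid = f"{nid}_g{j}"
                label = "\\n".join(group)
                shape = "oval" if len(group) == 1 else "box"
                lines.append(f'  {gid} [label="{label}", shape={shape}];')
                lines.append(f"  {nid} -> {gid};")
            prev = nid
        lines.append("}")
        return "\n".join(lines)


def _single_linkage_tm_clusters(
    members: Sequence[str], tm_sets: Mapping[str, Sequence[float]], threshold: float
) -> list[list[str]]:
    """Single-linkage clusters: species are linked when the closest pair of
    their Tm values is below the resolvability threshold."""
    members = sorted(members)
    parent = {sp: sp for sp in members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(members, 2):
        d = min(abs(x - y) for x in tm_sets[a] for y in tm_sets[b])
        if d < threshold:
            parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for sp in members:
        clusters.setdefault(find(sp), []).append(sp)
    return sorted(clusters.values(), key=lambda g: min(np.min(tm_sets[sp]) for sp in g))


def _tree_from_tm_table(
    amplicon_order: Sequence[str],
    tm_table: Mapping[str, Mapping[str, Sequence[float]]],
    thresholds: ResolutionThresholds,
) -> DecisionTree:
    all_species = sorted({sp for amp in amplicon_order for sp in tm_table[amp]})
    groups: list[list[str]] = [all_species]
    nodes: list[TreeNode] = []
    leaves: list[TreeLeaf] = []
    for amp in amplicon_order:
        if not groups:
            break
        partition: list[list[str]] = []
        next_groups: list[list[str]] = []
        for group in groups:
            for cluster in _single_linkage_tm_clusters(
                group, tm_table[amp], thresholds.delta_tm_c
            ):
                partition.append(cluster)
                if len(cluster) == 1:
                    leaves.append(TreeLeaf(species=cluster, resolved=True))
                else:
                    next_groups.append(cluster)
        nodes.append(TreeNode(amplicon=amp, partition=partition))
        groups = next_groups
    for group in groups:
        leaves.append(TreeLeaf(species=group, resolved=False))
    return DecisionTree(nodes=nodes, leaves=leaves)


def build_decision_tree(
    panel: Panel,
    profiles: Mapping[str, Sequence[SpeciesProfile]],
    thresholds: ResolutionThresholds | None = None,
) -> DecisionTree:
    """Decision tree over the panel's amplicons in selection order.

    ``profiles`` maps amplicon name to its species profiles.  At each node
    the species still unresolved are grouped by single-linkage Tm
    clustering; singleton clusters become leaves, larger clusters descend to
    the next amplicon, and groups left after the last assay become
    unresolved leaves.
    """
    thresholds = thresholds or ResolutionThresholds()
    if not panel.amplicons:
        raise DesignError("cannot build a tree from an empty panel")
    order = panel.names()
    tm_table = {
        amp: {pr.species: list(pr.tm_set) for pr in profiles[amp]} for amp in order
    }
    return _tree_from_tm_table(order, tm_table, thresholds)


def tree_from_reference_tms(
    amplicon_order: Sequence[str],
    reference_tms: Mapping[str, Mapping[str, float]],
    thresholds: ResolutionThresholds | None = None,
) -> DecisionTree:
    """Decision tree from observed reference mean Tms (amplicon -> species
    -> mean Tm), e.g. a reference panel measured on the instrument."""
    thresholds = thresholds or ResolutionThresholds()
    tm_table = {
        amp: {sp: [tm] for sp, tm in by_sp.items()} for amp, by_sp in reference_tms.items()
    }
    return _tree_from_tm_table(list(amplicon_order), tm_table, thresholds)
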