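"""UPGMA dendrograms, genetic species group delimitation, and within-group
mitotype structure.

Merge heights are stored as distance/2 (the conventional ultrametric height);
every user-facing threshold is on the *distance* scale, i.e. the cophenetic
distance between two leaves is twice the height of their lowest common
ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ClassifierConfig, DEFAULT_CONFIG
from .genetic_distance import (
    JC69,
    DistanceMatrix,
    distance_matrix,
    fixed_differences,
    max_intragroup_divergence,
)
from .specimen_io import AlignmentSet, Specimen, REGIONS


@dataclass
class Node:
    """A dendrogram node; leaves carry a name, internal nodes a merge
    height (distance/2 units)."""

    height: float = 0.0
    name: Optional[str] = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Ultrametric merge tree over specimen ids."""

    root: Node
    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[frozenset, frozenset, float], ...] = ()

    @property
    def root_height(self) -> float:
        return self.root.height

    def cophenetic_matrix(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Leaf ids (sorted) and the matrix of cophenetic *distances*
        (2 x merge height)."""
        ids = tuple(sorted(self.leaf_ids))
        index = {sid: i for i, sid in enumerate(ids)}
        n = len(ids)
        mat = np.zeros((n, n))

        def fill(node: Node) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [fill(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            ia, ib = index[a], index[b]
                            mat[ia, ib] = mat[ib, ia] = 2.0 * node.height
            return [leaf for g in groups for leaf in g]

        fill(self.root)
        return ids, mat

    def is_ultrametric(self, tol: float = 1e-12) -> bool:
        def check(node: Node, parent_height: float) -> bool:
            if node.is_leaf:
                return True
            if node.height > parent_height + tol:
                return False
            return all(check(c, node.height) for c in node.children)

        return check(self.root, self.root.height)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage agglomeration.

    Repeatedly merges the pair of clusters with minimum average inter-cluster
    distance at height = distance/2, updating distances as size-weighted
    arithmetic means. Ties are broken deterministically: the candidate pair
    whose smallest member id sorts first wins (then the next-smallest id).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 ids")
    if not np.isfinite(dm.values).all():
        raise ValueError("non-finite distances")

    d = dm.values.astype(float).copy()
    active: dict[int, Node] = {
        i: Node(name=dm.ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    min_ids = {i: dm.ids[i] for i in range(n)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_index = n
    # grow matrix as merges happen; use dict-of-dict for clarity at small n
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def pair_key(i: int, j: int):
        a, b = sorted((min_ids[i], min_ids[j]))
        return (dist[(min(i, j), max(i, j))], a, b)

    while len(active) > 1:
        keys = list(active)
        best = None
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                i, j = keys[x], keys[y]
                k = pair_key(i, j)
                if best is None or k < best[0]:
                    best = (k, i, j)
        (dmin, _, _), i, j = best
        height = dmin / 2.0
        left, right = active[i], active[j]
        node = Node(height=height, children=(left, right))
        merges.append(
            (frozenset(left.leaves()), frozenset(right.leaves()), height)
        )
        new = next_index
        next_index += 1
        si, sj = sizes[i], sizes[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(new, k), max(new, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[new] = node
        sizes[new] = si + sj
        min_ids[new] = min(min_ids[i], min_ids[j])
        del sizes[i], sizes[j], min_ids[i], min_ids[j]

    root = next(iter(active.values()))
    return Dendrogram(root=root, leaf_ids=dm.ids, merges=tuple(merges))


@dataclass
class GeneticGroup:
    """A delimited barcode cluster (candidate species)."""

    group_id: str
    member_ids: tuple[str, ...]
    marker: str
    max_divergence: float = 0.0
    composition: dict[str, int] = field(default_factory=dict)
    subregion_composition: dict[str, int] = field(default_factory=dict)


def cut_tree(tree: Dendrogram, threshold: float) -> list[tuple[str, ...]]:
    """Cut a dendrogram into groups at a cophenetic *distance* threshold.

    Groups are the maximal subtrees whose internal cophenetic distances are
    all below the threshold; zero-height merges (identical sequences) always
    co-cluster, so threshold = 0 yields one group per distinct sequence.
    Raising the threshold can only merge groups, never split them.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")

    groups: list[tuple[str, ...]] = []

    def walk(node: Node) -> None:
        if node.is_leaf:
            groups.append((node.name,))
            return
        coph = 2.0 * node.height
        if coph < threshold or coph == 0.0:
            groups.append(tuple(sorted(node.leaves())))
        else:
            for c in node.children:
                walk(c)

    walk(tree.root)
    return groups


def delimit_groups(
    aln: AlignmentSet,
    threshold: float,
    marker: Optional[str] = None,
    prefix: str = "G",
) -> tuple[Dendrogram, list[GeneticGroup]]:
    """Distance matrix -> UPGMA -> cut, returning groups with max intra-group
    divergence filled in. Single-record alignments yield one singleton group."""
    marker = marker or aln.marker
    if len(aln.records) == 1:
        sid = next(iter(aln.records))
        tree = Dendrogram(root=Node(name=sid), leaf_ids=(sid,))
        return tree, [
            GeneticGroup(group_id=f"{prefix}1", member_ids=(sid,), marker=marker)
        ]
    dm = distance_matrix(aln, model=JC69)
    tree = upgma(dm)
    members = cut_tree(tree, threshold)
    groups = []
    for k, ids in enumerate(sorted(members), start=1):
        groups.append(
            GeneticGroup(
                group_id=f"{prefix}{k}",
                member_ids=ids,
                marker=marker,
                max_divergence=max_intragroup_divergence(aln, ids),
            )
        )
    return tree, groups


def regional_composition(
    group: GeneticGroup, specimens: list[Specimen]
) -> dict[str, int]:
    """Zero-filled counts of group members per region; also recorded on the
    group in place."""
    by_id = {s.specimen_id: s for s in specimens}
    counts = {r: 0 for r in REGIONS}
    subregions: dict[str, int] = {}
    for sid in group.member_ids:
        if sid not in by_id:
            raise KeyError(f"specimen {sid!r} not in metadata")
        sp = by_id[sid]
        counts[sp.region] += 1
        if sp.subregion:
            subregions[sp.subregion] = subregions.get(sp.subregion, 0) + 1
    group.composition = counts
    group.subregion_composition = subregions
    return counts


MATCHES_ATLANTIC = "matches_atlantic"
MATCHES_PACIFIC = "matches_pacific"
MATCHES_BOTH = "matches_both"
UNIQUE = "unique"
UNDIFFERENTIATED = "undifferentiated"
UNDEFINED = "undefined"


@dataclass
class MitotypeStructure:
    """Population-level structure of one genetic group: fixed differences
    between its Atlantic and Pacific members and where the Churchill
    mitotypes fall relative to them."""

    n_fixed_atl_vs_pac: int = 0
    churchill_matches: str = UNDEFINED
    differentiated: bool = False
    fixed_site_columns: tuple[int, ...] = ()
    regional_clusters: tuple[tuple[str, ...], ...] = ()
    # evidence against the single sampled region when only one is present
    n_fixed_churchill: int = 0
    nearest_region: Optional[str] = None


def _assign_churchill(seq_codes, atl_states, pac_states) -> str:
    """Classify one Churchill sequence by the diagnostic states it carries."""
    hits_atl = hits_pac = usable = 0
    for col, a_state in atl_states.items():
        p_state = pac_states[col]
        ch = seq_codes[col]
        if ch == 255:
            continue
        usable += 1
        if ch == a_state:
            hits_atl += 1
        elif ch == p_state:
            hits_pac += 1
    if usable == 0:
        return UNIQUE
    if hits_atl == usable:
        return MATCHES_ATLANTIC
    if hits_pac == usable:
        return MATCHES_PACIFIC
    return UNIQUE


def within_group_structure(
    group: GeneticGroup,
    aln: AlignmentSet,
    specimens: list[Specimen],
    pop_threshold: float | None = None,
    cfg: ClassifierConfig = DEFAULT_CONFIG,
) -> MitotypeStructure:
    """Diagnose the mitotype geography of one genetic group.

    With both Atlantic and Pacific members present, fixed differences between
    them take precedence: each Churchill sequence is scored by whether it
    carries the Atlantic or the Pacific diagnostic states, giving
    ``matches_atlantic`` / ``matches_pacific`` / ``matches_both`` (specimens
    split between the signatures) / ``unique`` (neither). Without fixed
    differences, regional sub-clusters at ``pop_threshold`` are consulted;
    failing both, the group is ``undifferentiated``. With only one source
    region present, the structure records fixed differences between the
    Churchill members and that region instead.
    """
    from .genetic_distance import encode_sequence  # local to avoid cycle noise

    if pop_threshold is None:
        pop_threshold = cfg.pop_threshold
    by_id = {s.specimen_id: s for s in specimens}
    regional = {r: [i for i in group.member_ids if by_id[i].region == r] for r in REGIONS}
    churchill = regional["churchill"]
    atl, pac = regional["atlantic"], regional["pacific"]

    st = MitotypeStructure()
    if not churchill:
        st.churchill_matches = UNDEFINED
    if atl and pac:
        rep = fixed_differences(aln, atl, pac)
        st.n_fixed_atl_vs_pac = rep.n_fixed
        st.fixed_site_columns = rep.fixed_site_columns
        if rep.n_fixed >= 1:
            st.differentiated = True
            if churchill:
                atl_codes = encode_sequence(aln.records[atl[0]])
                pac_codes = encode_sequence(aln.records[pac[0]])
                atl_states = {c: int(atl_codes[c]) for c in rep.fixed_site_columns}
                pac_states = {c: int(pac_codes[c]) for c in rep.fixed_site_columns}
                calls = {
                    _assign_churchill(encode_sequence(aln.records[c]), atl_states, pac_states)
                    for c in churchill
                }
                if calls == {MATCHES_ATLANTIC}:
                    st.churchill_matches = MATCHES_ATLANTIC
                elif calls == {MATCHES_PACIFIC}:
                    st.churchill_matches = MATCHES_PACIFIC
                elif calls == {MATCHES_ATLANTIC, MATCHES_PACIFIC}:
                    st.churchill_matches = MATCHES_BOTH
                else:
                    st.churchill_matches = UNIQUE
        else:
            # fall back to sub-cluster evidence at the population threshold
            sub_tree, _ = delimit_groups(
                aln.subset(group.member_ids), pop_threshold, marker=group.marker
            )
            clusters = cut_tree(sub_tree, pop_threshold)
            st.regional_clusters = tuple(clusters)
            region_of = {}
            pure = True
            for ci, cluster in enumerate(clusters):
                regs = {by_id[i].region for i in cluster} - {"churchill"}
                if regs == {"atlantic"}:
                    region_of[ci] = "atlantic"
                elif regs == {"pacific"}:
                    region_of[ci] = "pacific"
                elif regs:
                    pure = False
            if pure and {"atlantic", "pacific"} <= set(region_of.values()):
                st.differentiated = True
                ch_regions = set()
                for ci, cluster in enumerate(clusters):
                    if any(by_id[i].region == "churchill" for i in cluster):
                        ch_regions.add(region_of.get(ci, "unique"))
                if ch_regions == {"atlantic"}:
                    st.churchill_matches = MATCHES_ATLANTIC
                elif ch_regions == {"pacific"}:
                    st.churchill_matches = MATCHES_PACIFIC
                elif ch_regions == {"atlantic", "pacific"}:
                    st.churchill_matches = MATCHES_BOTH
                else:
                    st.churchill_matches = UNIQUE
            else:
                st.churchill_matches = UNDIFFERENTIATED
    elif churchill and (atl or pac):
        present, region = (atl, "atlantic") if atl else (pac, "pacific")
        rep = fixed_differences(aln, churchill, present)
        st.n_fixed_churchill = rep.n_fixed
        st.nearest_region = region
        if rep.n_fixed >= cfg.min_fixed_elim:
            st.nearest_region = None
            st.differentiated = True
    elif churchill:
        st.churchill_matches = UNIQUE if len(group.member_ids) == len(churchill) else UNDEFINED
    return st
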