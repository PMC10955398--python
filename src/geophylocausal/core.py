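"""Geo-annotated time-calibrated trees and distance computations.

A *geo-phylo tree* is a rooted, time-calibrated phylogeny in which every
node (ancestral nodes included) carries an age (thousands of years before
present, ky BP) and an estimated geographic location (latitude/longitude in
degrees).  Branch lengths are in ky, so ages decrease from the root towards
the present and ``age(child) = age(parent) - branch_length(child)``.

Topology and branch lengths travel as Newick; node annotations travel as a
CSV node table with columns ``id, parent, age, lat, lon`` plus one column
per trait variable.  The node table is authoritative for ages.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
AGE_TOLERANCE = 1e-9


class TreeValidationError(ValueError):
    """Raised when a node table or Newick string violates tree invariants."""


@dataclass
class NodeRecord:
    """One node of a geo-phylo tree."""

    id: str
    parent: str | None
    branch_length: float  # ky; 0.0 for the root
    age: float  # ky BP
    lat: float
    lon: float
    traits: dict[str, float] = field(default_factory=dict)

    @property
    def is_root(self) -> bool:
        return self.parent is None


class GeoPhyloTree:
    """Rooted time-calibrated tree with per-node ages, locations and traits.

    Parameters
    ----------
    nodes:
        Mapping from node id to :class:`NodeRecord`.  Must contain exactly
        one root (``parent is None``) and be cycle-free.
    """

    def __init__(self, nodes: dict[str, NodeRecord], validate: bool = True):
        self.nodes: dict[str, NodeRecord] = dict(nodes)
        self._children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        roots = []
        for nid, rec in self.nodes.items():
            if rec.parent is None:
                roots.append(nid)
            else:
                if rec.parent not in self.nodes:
                    raise TreeValidationError(
                        f"node {nid!r} references unknown parent {rec.parent!r}"
                    )
                self._children[rec.parent].append(nid)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots!r}")
        self.root_id: str = roots[0]
        for kids in self._children.values():
            kids.sort()
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def children(self, node_id: str) -> list[str]:
        return self._children[node_id]

    def is_leaf(self, node_id: str) -> bool:
        return not self._children[node_id]

    @property
    def leaf_ids(self) -> list[str]:
        return [nid for nid in self.preorder() if self.is_leaf(nid)]

    @property
    def node_ids(self) -> list[str]:
        """All node ids in preorder (root first, deterministic)."""
        return self.preorder()

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self._children[nid]))
        return out

    def postorder(self) -> list[str]:
        return list(reversed(self.preorder()))

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs in preorder of the child."""
        return [
            (self.nodes[nid].parent, nid)
            for nid in self.preorder()
            if self.nodes[nid].parent is not None
        ]

    def subtree_leaves(self, node_id: str) -> list[str]:
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            if self.is_leaf(nid):
                out.append(nid)
            else:
                stack.extend(self._children[nid])
        return sorted(out)

    def validate(self) -> None:
        root = self.nodes[self.root_id]
        if root.branch_length not in (0.0, None) and root.branch_length != 0.0:
            raise TreeValidationError("root must have branch length 0")
        # cycle check: preorder must reach every node
        reached = set(self.preorder())
        if reached != set(self.nodes):
            missing = sorted(set(self.nodes) - reached)
            raise TreeValidationError(f"unreachable nodes (cycle?): {missing!r}")
        for nid, rec in self.nodes.items():
            if rec.branch_length < 0:
                raise TreeValidationError(f"negative branch length at node {nid!r}")
            if not (-90.0 <= rec.lat <= 90.0):
                raise TreeValidationError(f"latitude out of range at node {nid!r}")
            if not (-180.0 <= rec.lon <= 180.0):
                raise TreeValidationError(f"longitude out of range at node {nid!r}")
            if rec.parent is not None:
                parent = self.nodes[rec.parent]
                expected = parent.age - rec.branch_length
                if abs(rec.age - expected) > AGE_TOLERANCE:
                    raise TreeValidationError(
                        f"age inconsistency at node {nid!r}: age {rec.age} but "
                        f"parent age {parent.age} - branch {rec.branch_length} "
                        f"= {expected}"
                    )
                if rec.age > parent.age + AGE_TOLERANCE:
                    raise TreeValidationError(
                        f"age of node {nid!r} exceeds its parent's age"
                    )

    # -- traits ------------------------------------------------------------

    def trait_vector(self, variable: str, node_ids: list[str] | None = None) -> np.ndarray:
        ids = node_ids if node_ids is not None else self.node_ids
        vals = []
        for nid in ids:
            if variable not in self.nodes[nid].traits:
                raise KeyError(f"node {nid!r} has no value for trait {variable!r}")
            vals.append(self.nodes[nid].traits[variable])
        return np.asarray(vals, dtype=float)

    def set_trait(self, variable: str, values: dict[str, float]) -> None:
        for nid, v in values.items():
            self.nodes[nid].traits[variable] = float(v)

    def leaf_trait_map(self, variable: str) -> dict[str, float]:
        return {nid: self.nodes[nid].traits[variable] for nid in self.leaf_ids}

    # -- I/O -----------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(nid: str) -> str:
            rec = self.nodes[nid]
            if self.is_leaf(nid):
                return f"{nid}:{rec.branch_length:.12g}"
            inner = ",".join(fmt(c) for c in self._children[nid])
            if rec.parent is None:
                return f"({inner}){nid};"
            return f"({inner}){nid}:{rec.branch_length:.12g}"

        return fmt(self.root_id)

    def to_node_table(self) -> pd.DataFrame:
        variables = sorted({v for rec in self.nodes.values() for v in rec.traits})
        rows = []
        for nid in self.preorder():
            rec = self.nodes[nid]
            row = {
                "id": nid,
                "parent": rec.parent if rec.parent is not None else "",
                "age": rec.age,
                "lat": rec.lat,
                "lon": rec.lon,
            }
            for v in variables:
                row[v] = rec.traits.get(v, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, newick_path, table_path) -> None:
        with open(newick_path, "w") as fh:
            fh.write(self.to_newick() + "\n")
        self.to_node_table().to_csv(table_path, index=False)

    @property
    def root_age(self) -> float:
        return self.nodes[self.root_id].age


def load_geophylo(newick_text: str, node_table: pd.DataFrame) -> GeoPhyloTree:
    """Build a validated :class:`GeoPhyloTree` from Newick plus a node table.

    The Newick string provides topology; the table (columns ``id, parent,
    age, lat, lon`` plus trait columns) is authoritative for node ages.
    Branch lengths are recomputed from ages and must agree with any branch
    lengths present in the Newick within ``1e-6`` ky.

    Raises
    ------
    TreeValidationError
        On unmatched ids, negative branch lengths, or age inconsistencies,
        naming the offending node.
    """
    dtree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    table = node_table.set_index(node_table["id"].astype(str))
    trait_cols = [c for c in node_table.columns if c not in ("id", "parent", "age", "lat", "lon")]

    records: dict[str, NodeRecord] = {}
    for dnode in dtree.preorder_node_iter():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None:
            raise TreeValidationError("Newick contains an unlabelled node")
        if label not in table.index:
            raise TreeValidationError(f"Newick node {label!r} missing from node table")
        row = table.loc[label]
        parent = None
        if dnode.parent_node is not None:
            pnode = dnode.parent_node
            parent = pnode.taxon.label if pnode.taxon is not None else pnode.label
        tparent = str(row["parent"]) if str(row["parent"]) not in ("", "nan") else None
        if parent != tparent:
            raise TreeValidationError(
                f"parent mismatch for node {label!r}: Newick says {parent!r}, "
                f"table says {tparent!r}"
            )
        age = float(row["age"])
        if parent is not None:
            page = float(table.loc[parent]["age"])
            blen = page - age
            if blen < -AGE_TOLERANCE:
                raise TreeValidationError(
                    f"age of node {label!r} ({age}) exceeds parent age ({page})"
                )
            blen = max(blen, 0.0)
            if dnode.edge.length is not None and abs(dnode.edge.length - blen) > 1e-6:
                raise TreeValidationError(
                    f"branch length mismatch for node {label!r}: Newick "
                    f"{dnode.edge.length} vs ages {blen}"
                )
        else:
            blen = 0.0
        traits = {}
        for c in trait_cols:
            v = row[c]
            if pd.notna(v):
                traits[c] = float(v)
        records[label] = NodeRecord(
            id=label, parent=parent, branch_length=blen, age=age,
            lat=float(row["lat"]), lon=float(row["lon"]), traits=traits,
        )

    extra = set(table.index) - set(records)
    if extra:
        raise TreeValidationError(f"node table rows with no Newick node: {sorted(extra)!r}")
    return GeoPhyloTree(records)


def read_geophylo(newick_path, table_path) -> GeoPhyloTree:
    with open(newick_path) as fh:
        newick_text = fh.read()
    return load_geophylo(newick_text, pd.read_csv(table_path))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered set of node ids.

    ``kind`` is ``"geographic"`` (km) or ``"cophenetic"`` (tree branch-length
    units, i.e. ky for time-calibrated trees).
    """

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def cophenetic_matrix(tree: GeoPhyloTree) -> DistanceMatrix:
    """Pairwise path-length (cophenetic) distances between *all* nodes.

    d(i, j) = depth(i) + depth(j) - 2 * depth(mrca(i, j)) where depth is the
    branch-length distance from the root.  Computed over interior nodes as
    well as leaves, because phylogenetic neighbourhoods in the causal model
    are defined over nodes, not only tips.
    """
    ids = tree.node_ids
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    depth = np.zeros(n)
    # ancestor sets (including self) for MRCA lookup
    anc_path: dict[str, list[str]] = {}
    for nid in tree.preorder():
        rec = tree.nodes[nid]
        if rec.parent is None:
            depth[index[nid]] = 0.0
            anc_path[nid] = [nid]
        else:
            depth[index[nid]] = depth[index[rec.parent]] + rec.branch_length
            anc_path[nid] = anc_path[rec.parent] + [nid]
    anc_set = {nid: set(p) for nid, p in anc_path.items()}
    d = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            b = ids[j]
            # deepest shared ancestor on a's root path
            common = anc_set[b]
            mrca = a
            for nid in reversed(anc_path[a]):
                if nid in common:
                    mrca = nid
                    break
            dist = depth[i] + depth[j] - 2 * depth[index[mrca]]
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids, d, "cophenetic")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km); vectorised."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def greatcircle_matrix(tree: GeoPhyloTree) -> DistanceMatrix:
    """Pairwise haversine great-circle distances (km) between all nodes."""
    ids = tree.node_ids
    lat = np.array([tree.nodes[i].lat for i in ids])
    lon = np.array([tree.nodes[i].lon for i in ids])
    for nid, la, lo in zip(ids, lat, lon):
        if not (np.isfinite(la) and np.isfinite(lo)):
            raise ValueError(f"node {nid!r} is missing coordinates")
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return DistanceMatrix(ids, d, "geographic")


def interpolation_proportion(age_anc: float, age_desc: float, t: float) -> float:
    """Proportional position of time t along an edge: 0 at the ancestor,
    1 at the descendant.  Requires ``age_anc >= t >= age_desc``."""
    if age_anc <= age_desc:
        raise ValueError("edge must have age_anc > age_desc")
    if not (age_desc - AGE_TOLERANCE <= t <= age_anc + AGE_TOLERANCE):
        raise ValueError(f"time {t} outside edge span [{age_desc}, {age_anc}]")
    p = (age_anc - t) / (age_anc - age_desc)
    return float(min(max(p, 0.0), 1.0))


def lineages_at_time(tree: GeoPhyloTree, t: float) -> list[dict]:
    """Edges alive at time ``t`` (ky BP), with interpolation proportions.

    Returns one record per edge whose ancestor age > t >= descendant age:
    ``{"anc": id, "desc": id, "p": proportion}`` where ``p`` runs from 0 at
    the ancestor to 1 at the descendant.  The number of records equals the
    number of lineages through time at ``t``.
    """
    min_age = min(rec.age for rec in tree.nodes.values())
    if not (min_age - AGE_TOLERANCE <= t <= tree.root_age + AGE_TOLERANCE):
        raise ValueError(f"time {t} outside tree span [{min_age}, {tree.root_age}]")
    out = []
    for anc, desc in tree.edges():
        a_anc = tree.nodes[anc].age
        a_desc = tree.nodes[desc].age
        if a_anc > t >= a_desc:
            out.append({
                "anc": anc,
                "desc": desc,
                "p": interpolation_proportion(a_anc, a_desc, t),
            })
    return out
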