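"""Synthetic geo-phylo data generation.

Generates the inputs the downstream analysis assumes: a time-calibrated
pure-birth tree, a Brownian dispersal history over latitude/longitude
(optionally with a single early "founder" jump that produces two
geographic clusters), a smooth space-time humidity field sampled at node
locations (inheriting very high phylogenetic signal from the dispersal
process), and trait histories under either a null model or a causal model
with an explicit environment effect.

Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from geophylocausal.core import (
    GeoPhyloTree,
    NodeRecord,
    cophenetic_matrix,
    haversine_km,
    lineages_at_time,
)


@dataclass
class FounderJump:
    """A single early-branch displacement that splits the tree's geography
    into two clusters (the founder-effect phenomenon).

    depth_quantile: how early the jumped edge must start, as a fraction of
    crown age measured from the root (0.25 = ancestor within the oldest
    quarter of the tree).  Among qualifying internal edges the one whose
    subtree holds the leaf fraction closest to one half is jumped, so the
    two clusters are of comparable size.  The jump is a fixed displacement
    in latitude (degrees) — the direction of the default humidity
    gradient, so the jump also separates the clusters in humidity.
    """

    depth_quantile: float = 0.25
    jump_deg: float = 20.0


@dataclass
class HumidityFieldConfig:
    """Smooth deterministic humidity surface plus observation noise.

    h(lat, lon, age) = base + grad_lat*(lat - lat0) + grad_lon*(lon - lon0)
                       + drift*age + Normal(0, noise_sd).

    Units are arbitrary humidity units; defaults give node humidities of
    order 1-3 over a continental-scale extent.
    """

    base: float = 2.0
    lat0: float = 0.0
    lon0: float = 20.0
    grad_lat: float = 0.05
    grad_lon: float = 0.0
    drift: float = 0.0  # per ky of age
    noise_sd: float = 0.02


@dataclass
class TraitModelConfig:
    """Trait-history model: 'null' (random walk, increment sd = branch
    length) or 'causal' (environment/geography/phylogeny effects on the
    per-ky change rate)."""

    kind: str = "null"  # {null, causal}
    root_value: float = 2.0  # proto-language fossil: two tones
    variance_scaling: str = "linear_B"  # {linear_B, sqrt_B}; null model only
    # causal-model parameters
    alpha: float = 0.0
    eta: float = 0.0
    gamma: float = 0.0
    rho: float = 0.0
    sigma0: float = 0.5
    beta: float = 0.0
    geo_radius_km: float = 500.0
    phylo_radius: float = 0.02


@dataclass
class SimulationConfig:
    """Full configuration of a synthetic geo-phylo dataset."""

    n_tips: int = 100
    crown_age: float = 5.0  # ky
    birth_rate: float = 1.0  # 1/ky (only shapes relative node ages)
    dispersal_sd: float = 2.0  # degrees per sqrt(ky)
    root_lat: float = 0.0
    root_lon: float = 20.0
    founder_jump: FounderJump | None = None
    humidity: HumidityFieldConfig = field(default_factory=HumidityFieldConfig)
    trait: TraitModelConfig = field(default_factory=TraitModelConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.crown_age <= 0 or self.birth_rate <= 0 or self.dispersal_sd < 0:
            raise ValueError("rates and ages must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {
            "n_tips", "crown_age", "birth_rate", "dispersal_sd", "root_lat",
            "root_lon", "founder_jump", "humidity", "trait", "seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("founder_jump") is not None and not isinstance(d["founder_jump"], FounderJump):
            d["founder_jump"] = FounderJump(**d["founder_jump"])
        if "humidity" in d and not isinstance(d["humidity"], HumidityFieldConfig):
            d["humidity"] = HumidityFieldConfig(**d["humidity"])
        if "trait" in d and not isinstance(d["trait"], TraitModelConfig):
            d["trait"] = TraitModelConfig(**d["trait"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# tree topology
# ---------------------------------------------------------------------------


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> GeoPhyloTree:
    """Pure-birth (Yule) crown tree conditioned on ``n_tips``, rescaled so
    the crown age equals ``config.crown_age`` and all tips are extant at
    age 0 (ultrametric).

    Node locations are placed at the root location; run
    :func:`simulate_dispersal` to evolve them.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lam = config.birth_rate
    # active lineages: list of (parent_id, birth_time); root splits at t=0
    counter = [0]

    def new_internal() -> str:
        counter[0] += 1
        return f"n{counter[0]}"

    root = new_internal()
    parents: dict[str, tuple[str | None, float]] = {root: (None, 0.0)}
    active: list[tuple[str, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < config.n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * lam))
        i = rng.integers(k)
        parent_id, _ = active[i]
        node = new_internal()
        parents[node] = (parent_id, t)
        active[i] = (node, t)
        active.append((node, t))
    t_end = t + rng.exponential(1.0 / (len(active) * lam))

    records: dict[str, NodeRecord] = {}
    scale = config.crown_age / t_end

    def age_of(time: float) -> float:
        return (t_end - time) * scale

    for nid, (parent, birth) in parents.items():
        page = age_of(parents[parent][1]) if parent is not None else None
        age = age_of(birth)
        records[nid] = NodeRecord(
            id=nid,
            parent=parent,
            branch_length=(page - age) if parent is not None else 0.0,
            age=age,
            lat=config.root_lat,
            lon=config.root_lon,
        )
    for j, (parent, _) in enumerate(active, start=1):
        leaf = f"t{j}"
        page = age_of(parents[parent][1])
        records[leaf] = NodeRecord(
            id=leaf, parent=parent, branch_length=page, age=0.0,
            lat=config.root_lat, lon=config.root_lon,
        )
    return GeoPhyloTree(records)


def star_tree(n_tips: int, branch_length: float = 1.0,
              lat: float = 0.0, lon: float = 20.0) -> GeoPhyloTree:
    """Star phylogeny: all tips attached directly to the root with equal
    branch lengths.  Useful as a no-shared-history control."""
    records = {"root": NodeRecord("root", None, 0.0, branch_length, lat, lon)}
    for j in range(1, n_tips + 1):
        records[f"t{j}"] = NodeRecord(f"t{j}", "root", branch_length, 0.0, lat, lon)
    return GeoPhyloTree(records)


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------


def _choose_jump_edge(tree: GeoPhyloTree, depth_quantile: float) -> tuple[str, str]:
    crown = tree.root_age
    cutoff = crown * (1.0 - depth_quantile)
    n_leaves = len(tree.leaf_ids)
    best = None
    best_score = np.inf
    for anc, desc in tree.edges():
        if tree.is_leaf(desc):
            continue
        if tree.nodes[anc].age < cutoff:
            continue
        frac = len(tree.subtree_leaves(desc)) / n_leaves
        score = abs(frac - 0.5)
        if score < best_score:
            best_score = score
            best = (anc, desc)
    if best is None:  # fall back to the earliest internal edge
        internal = [(a, d) for a, d in tree.edges() if not tree.is_leaf(d)]
        best = max(internal, key=lambda e: tree.nodes[e[0]].age)
    return best


def simulate_dispersal(tree: GeoPhyloTree, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GeoPhyloTree:
    """Brownian dispersal of lat/lon down the tree (per-edge displacement
    sd = dispersal_sd * sqrt(branch length)), in place.

    Dispersal operates on raw degrees with clamping at the poles and the
    date line; no spherical projection correction is applied (adequate at
    continental extents, a documented limitation).  If ``founder_jump`` is
    configured, one early internal edge additionally receives a fixed
    longitude displacement, producing the two-cluster founder phenomenon.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    jump_edge = None
    if config.founder_jump is not None:
        jump_edge = _choose_jump_edge(tree, config.founder_jump.depth_quantile)
    root = tree.nodes[tree.root_id]
    root.lat, root.lon = config.root_lat, config.root_lon
    for anc, desc in tree.edges():
        rec = tree.nodes[desc]
        sd = config.dispersal_sd * np.sqrt(max(rec.branch_length, 0.0))
        dlat, dlon = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
        if jump_edge == (anc, desc):
            dlat += config.founder_jump.jump_deg
        rec.lat = float(np.clip(tree.nodes[anc].lat + dlat, -90.0, 90.0))
        rec.lon = float(np.clip(tree.nodes[anc].lon + dlon, -180.0, 180.0))
    return tree


# ---------------------------------------------------------------------------
# humidity
# ---------------------------------------------------------------------------


def humidity_surface(cfg: HumidityFieldConfig, lat, lon, age):
    """Deterministic part of the synthetic humidity field."""
    return (
        cfg.base
        + cfg.grad_lat * (np.asarray(lat) - cfg.lat0)
        + cfg.grad_lon * (np.asarray(lon) - cfg.lon0)
        + cfg.drift * np.asarray(age)
    )


def simulate_humidity(tree: GeoPhyloTree, config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      variable: str = "humidity") -> dict[str, float]:
    """Sample the smooth humidity field (plus iid noise) at every node.

    Because node locations evolve along the tree, the sampled humidity
    inherits very high phylogenetic signal even though the field itself is
    a plain function of space and time.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    cfg = config.humidity
    out = {}
    for nid in tree.node_ids:
        rec = tree.nodes[nid]
        h = float(humidity_surface(cfg, rec.lat, rec.lon, rec.age))
        if cfg.noise_sd > 0:
            h += rng.normal(0.0, cfg.noise_sd)
        out[nid] = h
    tree.set_trait(variable, out)
    return out


def humidity_grid(cfg: HumidityFieldConfig, years, lats, lons,
                  tree_ref_year: float = 2000.0,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gridded (year, lat, lon, humidity) table from the same surface, for
    exercising the space-time interpolation stage.  ``years`` are calendar
    years CE; the surface's age argument is (tree_ref_year - year)/1000 ky."""
    yy, la, lo = np.meshgrid(np.asarray(years), np.asarray(lats), np.asarray(lons),
                             indexing="ij")
    age = (tree_ref_year - yy) / 1000.0
    h = humidity_surface(cfg, la, lo, age)
    if rng is not None and cfg.noise_sd > 0:
        h = h + rng.normal(0.0, cfg.noise_sd, size=h.shape)
    return pd.DataFrame({
        "year": yy.ravel(), "lat": la.ravel(), "lon": lo.ravel(),
        "humidity": np.asarray(h, dtype=float).ravel(),
    })


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_traits_null(tree: GeoPhyloTree, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         variable: str = "trait") -> dict[str, float]:
    """Null trait history: no environment effect.

    Down every edge, T_desc = T_anc + eps * B with eps ~ Normal(0, 1), so
    the increment standard deviation scales linearly with the branch length
    B.  (This linear-in-B scaling is deliberate; standard Brownian motion
    would scale with sqrt(B) and is available as
    ``variance_scaling='sqrt_B'``.)
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    scaling = config.trait.variance_scaling
    if scaling not in ("linear_B", "sqrt_B"):
        raise ValueError(f"unknown variance_scaling {scaling!r}")
    values = {tree.root_id: float(config.trait.root_value)}
    for anc, desc in tree.edges():
        b = tree.nodes[desc].branch_length
        sd = b if scaling == "linear_B" else np.sqrt(b)
        values[desc] = values[anc] + (rng.normal(0.0, 1.0) * sd if sd > 0 else 0.0)
    tree.set_trait(variable, values)
    return values


def simulate_traits_causal(tree: GeoPhyloTree, humidity: dict[str, float],
                           config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           variable: str = "trait") -> dict[str, float]:
    """Causal trait history with an explicit environment effect.

    Per edge (processed root-to-tip in ancestor-age order):

        dT ~ Normal((alpha + eta*H + gamma*Gt + rho*Pt) * dA,  sigma0 + beta*dA)

    where H is the mean of ancestor and descendant humidity, dA the edge
    duration in ky, Gt the mean trait of geographically close contemporary
    lineages and Pt the mean trait of phylogenetically close nodes.  Gt/Pt
    are computed from the partial simulation state: lineages crossing the
    descendant's age use their interpolated value where both endpoints are
    already simulated, otherwise the most recent simulated value on their
    root path; empty neighbourhoods contribute zero.  The second argument
    of Normal is the standard deviation.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    p = config.trait
    edges = sorted(tree.edges(), key=lambda e: (-tree.nodes[e[0]].age, e[1]))
    for _, desc in edges:
        da = tree.nodes[desc].branch_length
        if p.sigma0 + p.beta * da <= 0:
            raise ValueError(
                f"sigma0 + beta*dA <= 0 on edge to {desc!r}; configuration rejected"
            )
    needs_phylo = p.rho != 0.0
    coph = cophenetic_matrix(tree) if needs_phylo else None
    values: dict[str, float] = {tree.root_id: float(p.root_value)}

    def lineage_value(anc: str, desc: str, prop: float) -> float:
        if desc in values:
            return values[anc] + prop * (values[desc] - values[anc])
        nid = anc
        while nid not in values:
            nid = tree.nodes[nid].parent
        return values[nid]

    for anc, desc in edges:
        rec = tree.nodes[desc]
        da = rec.branch_length
        if da <= 0:
            values[desc] = values[anc]
            continue
        h = 0.5 * (humidity[anc] + humidity[desc])
        gt = 0.0
        if p.gamma != 0.0:
            vals = []
            for lin in lineages_at_time(tree, rec.age):
                if lin["desc"] == desc:
                    continue
                a, d, prop = lin["anc"], lin["desc"], lin["p"]
                la = tree.nodes[a].lat + prop * (tree.nodes[d].lat - tree.nodes[a].lat)
                lo = tree.nodes[a].lon + prop * (tree.nodes[d].lon - tree.nodes[a].lon)
                if haversine_km(rec.lat, rec.lon, la, lo) <= p.geo_radius_km:
                    vals.append(lineage_value(a, d, prop))
            if vals:
                gt = float(np.mean(vals))
            else:
                gt = 0.0  # degenerate neighbourhood: no contribution
        pt = 0.0
        if needs_phylo:
            vals = [
                values[other]
                for other in values
                if other not in (desc, anc) and coph.get(desc, other) < p.phylo_radius
            ]
            pt = float(np.mean(vals)) if vals else 0.0
        mu = (p.alpha + p.eta * h + p.gamma * gt + p.rho * pt) * da
        sd = p.sigma0 + p.beta * da
        values[desc] = values[anc] + float(rng.normal(mu, sd))
    tree.set_trait(variable, values)
    return values


def simulate_dataset(config: SimulationConfig) -> GeoPhyloTree:
    """Convenience: tree + dispersal + humidity + traits in one call."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    simulate_dispersal(tree, config, rng)
    humidity = simulate_humidity(tree, config, rng)
    if config.trait.kind == "null":
        simulate_traits_null(tree, config, rng)
    elif config.trait.kind == "causal":
        simulate_traits_causal(tree, humidity, config, rng)
    else:
        raise ValueError(f"unknown trait model {config.trait.kind!r}")
    return tree
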