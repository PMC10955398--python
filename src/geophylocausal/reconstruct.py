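"""Ancestral state reconstruction, phylogenetic signal and space-time
environment interpolation.

Continuous ancestral states are reconstructed under Brownian motion by
exact Gaussian conditioning on the tip values (and an optional fossilised
root), which targets the same distribution as random-walk MCMC
reconstruction but is deterministic.  Phylogenetic signal is Pagel's
lambda by maximum likelihood.  The environment field is a smooth
tensor-product spline interpolator over (year, lat, lon) with a trilinear
baseline for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats

from geophylocausal.core import GeoPhyloTree

_MIN_BRANCH = 1e-10  # zero-length edges are given this precision-limit length


@dataclass
class NodeReconstruction:
    """Per-node reconstructed trait means and standard errors.

    ``mean[nid]`` is T_REC and ``se[nid]`` is T_SE.  Leaves carry their
    observed values with se 0; a fossilised root has se 0 by construction.
    """

    mean: dict[str, float]
    se: dict[str, float]
    method: str = "brownian_conditional"
    rate: float = float("nan")  # ML Brownian rate (variance per ky)
    bounds: tuple[float, float] | None = None
    root_fossil: float | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.mean)
        return pd.DataFrame({
            "id": ids,
            "T_REC": [self.mean[i] for i in ids],
            "T_SE": [self.se[i] for i in ids],
        })


def _effective_branch(b: float) -> float:
    return max(float(b), _MIN_BRANCH)


def _phylo_covariance(tree: GeoPhyloTree, ids: list[str]) -> np.ndarray:
    """Shared root-path lengths: Cov under unit-rate BM from the root."""
    depth: dict[str, float] = {}
    path: dict[str, list[str]] = {}
    for nid in tree.preorder():
        rec = tree.nodes[nid]
        if rec.parent is None:
            depth[nid] = 0.0
            path[nid] = [nid]
        else:
            depth[nid] = depth[rec.parent] + _effective_branch(rec.branch_length)
            path[nid] = path[rec.parent] + [nid]
    n = len(ids)
    c = np.zeros((n, n))
    for i, a in enumerate(ids):
        sa = set(path[a])
        for j in range(i, n):
            b = ids[j]
            shared = 0.0
            for nid in path[b]:
                if nid in sa and tree.nodes[nid].parent is not None:
                    shared += _effective_branch(tree.nodes[nid].branch_length)
            c[i, j] = c[j, i] = shared
    return c


def asr_brownian(tree: GeoPhyloTree, leaf_values: dict[str, float],
                 root_fossil: float | None = None,
                 bounds: tuple[float, float] | None = None,
                 rate: float | None = None) -> NodeReconstruction:
    """Brownian-motion ancestral state reconstruction by exact Gaussian
    conditioning.

    The tree defines a Gaussian graphical model: each edge (u, v) of length
    B contributes the conditional T_v | T_u ~ Normal(T_u, rate * B).  The
    joint precision matrix is assembled edge-wise and the interior nodes
    are conditioned on the observed leaves (and the fossilised root, if
    given).  When ``rate`` is None it is estimated by maximum likelihood
    from the leaf data.  ``bounds`` truncate each node's conditional
    distribution (moments from the truncated normal).

    Returns means (T_REC) and standard errors (T_SE) for every node; leaves
    and fossilised nodes have se 0.
    """
    leaves = tree.leaf_ids
    missing = [l for l in leaves if l not in leaf_values]
    if missing:
        raise ValueError(f"missing leaf values for {missing!r}")
    if bounds is not None:
        lo, hi = bounds
        if root_fossil is not None and not (lo <= root_fossil <= hi):
            raise ValueError("root fossil lies outside the stated bounds")

    ids = tree.node_ids
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)

    if rate is None:
        rate = _ml_brownian_rate(tree, leaf_values, root_fossil)

    # unit-rate precision from edge factors; scaled by 1/rate below
    q = np.zeros((n, n))
    for anc, desc in tree.edges():
        w = 1.0 / _effective_branch(tree.nodes[desc].branch_length)
        i, j = index[anc], index[desc]
        q[i, i] += w
        q[j, j] += w
        q[i, j] -= w
        q[j, i] -= w
    q /= rate

    observed: dict[str, float] = {l: float(leaf_values[l]) for l in leaves}
    if root_fossil is not None:
        observed[tree.root_id] = float(root_fossil)
    obs_idx = [index[nid] for nid in observed]
    unk_ids = [nid for nid in ids if nid not in observed]
    unk_idx = [index[nid] for nid in unk_ids]

    mean = {nid: float(v) for nid, v in observed.items()}
    se = {nid: 0.0 for nid in observed}
    if unk_idx:
        y = np.array([observed[ids[i]] for i in obs_idx])
        quu = q[np.ix_(unk_idx, unk_idx)]
        quo = q[np.ix_(unk_idx, obs_idx)]
        cf = linalg.cho_factor(quu)
        mu = linalg.cho_solve(cf, -quo @ y)
        cov = linalg.cho_solve(cf, np.eye(len(unk_idx)))
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if bounds is not None:
            lo, hi = bounds
            a = (lo - mu) / sd
            b = (hi - mu) / sd
            tmu = stats.truncnorm.mean(a, b, loc=mu, scale=sd)
            tsd = stats.truncnorm.std(a, b, loc=mu, scale=sd)
            mu, sd = np.asarray(tmu), np.asarray(tsd)
        for nid, m, s in zip(unk_ids, np.atleast_1d(mu), np.atleast_1d(sd)):
            mean[nid] = float(m)
            se[nid] = float(s)
    return NodeReconstruction(
        mean=mean, se=se, rate=rate, bounds=bounds, root_fossil=root_fossil,
    )


def _ml_brownian_rate(tree: GeoPhyloTree, leaf_values: dict[str, float],
                      root_fossil: float | None) -> float:
    leaves = tree.leaf_ids
    y = np.array([leaf_values[l] for l in leaves], dtype=float)
    c = _phylo_covariance(tree, leaves)
    n = len(leaves)
    if root_fossil is not None:
        resid = y - root_fossil
        cf = linalg.cho_factor(c + 1e-12 * np.eye(n))
        return float(resid @ linalg.cho_solve(cf, resid) / n)
    # unknown root: GLS root estimate, ML rate
    cf = linalg.cho_factor(c + 1e-12 * np.eye(n))
    one = np.ones(n)
    ci1 = linalg.cho_solve(cf, one)
    mu = float(one @ linalg.cho_solve(cf, y) / (one @ ci1))
    resid = y - mu
    return float(resid @ linalg.cho_solve(cf, resid) / n)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def pagels_lambda(tree: GeoPhyloTree, leaf_values: dict[str, float],
                  n_profile: int = 41) -> dict:
    """Maximum-likelihood Pagel's lambda for a continuous tip trait.

    The off-diagonal entries of the Brownian tip covariance are multiplied
    by lambda in [0, 1]; the root state and rate are profiled out
    analytically (GLS / ML).  lambda = 1 recovers plain Brownian motion,
    lambda = 0 an iid-normal model.

    Returns ``{"lambda_hat", "loglik", "profile"}`` where ``profile`` is a
    (lambda, loglik) DataFrame.
    """
    leaves = tree.leaf_ids
    if len(leaves) < 4:
        raise ValueError("need at least 4 leaves with values")
    y = np.array([leaf_values[l] for l in leaves], dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant across leaves; lambda undefined")
    c = _phylo_covariance(tree, leaves)
    diag = np.diag(np.diag(c))
    off = c - diag
    n = len(y)

    def negloglik(lam: float) -> float:
        cl = diag + lam * off
        try:
            cf = linalg.cho_factor(cl)
        except linalg.LinAlgError:
            return np.inf
        one = np.ones(n)
        ci1 = linalg.cho_solve(cf, one)
        mu = float(one @ linalg.cho_solve(cf, y) / (one @ ci1))
        resid = y - mu
        sig2 = float(resid @ linalg.cho_solve(cf, resid) / n)
        if sig2 <= 0:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return 0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)

    res = optimize.minimize_scalar(negloglik, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    lam_hat = float(res.x)
    # check the boundaries, which 'bounded' can miss
    cands = [(lam_hat, res.fun), (0.0, negloglik(0.0)), (1.0, negloglik(1.0))]
    lam_hat, nll = min(cands, key=lambda t: t[1])
    grid = np.linspace(0.0, 1.0, n_profile)
    profile = pd.DataFrame({
        "lam": grid, "loglik": [-negloglik(g) for g in grid],
    })
    return {"lambda_hat": lam_hat, "loglik": -nll, "profile": profile}


# ---------------------------------------------------------------------------
# humidity field
# ---------------------------------------------------------------------------


@dataclass
class TimeConvention:
    """Mapping between node ages (ky BP) and the climate grid's calendar
    years.  Node ages are counted back from ``tree_ref_year``; a grid given
    in years before present is counted back from ``climate_ref_year``."""

    tree_ref_year: float = 2000.0
    climate_ref_year: float = 1850.0
    grid_in_bp: bool = False

    def age_to_grid_year(self, age_ky) -> np.ndarray:
        calendar = self.tree_ref_year - 1000.0 * np.asarray(age_ky, dtype=float)
        if self.grid_in_bp:
            return self.climate_ref_year - calendar
        return calendar


@dataclass
class HumidityField:
    """Fitted interpolator over (year, lat, lon).

    ``predict`` evaluates inside the training bounding box only and raises
    on out-of-box queries.  ``r2_insample`` / ``r2_heldout`` are fit
    diagnostics (held-out by seeded 5-fold CV for the spline field; the
    trilinear baseline reports leave-grid-point interpolation R² the same
    way).
    """

    method: str
    predictor: object  # callable (year, lat, lon arrays) -> values
    bbox: dict[str, tuple[float, float]]
    r2_insample: float = float("nan")
    r2_heldout: float = float("nan")
    meta: dict = field(default_factory=dict)

    def predict(self, year, lat, lon) -> np.ndarray:
        year = np.atleast_1d(np.asarray(year, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        eps = 1e-9
        for name, arr in (("year", year), ("lat", lat), ("lon", lon)):
            lo, hi = self.bbox[name]
            bad = (arr < lo - eps) | (arr > hi + eps)
            if np.any(bad):
                raise ValueError(
                    f"{name} values outside field bounding box "
                    f"[{lo}, {hi}]: {arr[bad][:5]}"
                )
        return np.asarray(self.predictor(year, lat, lon), dtype=float)


def _check_grid(grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = []
    for name in ("year", "lat", "lon"):
        vals = np.unique(grid[name].to_numpy(dtype=float))
        if len(vals) < 2:
            raise ValueError(f"degenerate grid: axis {name!r} has < 2 distinct values")
        axes.append(vals)
    return tuple(axes)


def _spline_basis(x: np.ndarray, knot_values: np.ndarray, degree: int):
    """Clamped B-spline design matrix with interior knots at the given
    values (quantile-thinned upstream)."""
    k = min(degree, len(knot_values) - 1)
    interior = knot_values[1:-1]
    t = np.concatenate([
        np.repeat(knot_values[0], k + 1), interior, np.repeat(knot_values[-1], k + 1),
    ])
    xc = np.clip(x, knot_values[0], knot_values[-1])
    return interpolate.BSpline.design_matrix(xc, t, k).toarray()


@dataclass
class SmoothingConfig:
    """Tensor-product spline settings: maximum knots per axis (a knot per
    unique grid value up to this cap) and spline degree."""

    max_knots: int = 8
    degree: int = 3
    ridge: float = 1e-8
    cv_folds: int = 5
    cv_seed: int = 0


def _axis_knots(values: np.ndarray, max_knots: int) -> np.ndarray:
    if len(values) <= max_knots:
        return values
    qs = np.linspace(0, 1, max_knots)
    return np.unique(np.quantile(values, qs))


def fit_humidity_field(grid: pd.DataFrame,
                       config: SmoothingConfig | None = None) -> HumidityField:
    """Smooth space-time interpolator: tensor-product B-spline regression
    of humidity on (year, lat, lon).

    A spline basis is built per axis (knot per unique grid value, capped at
    ``max_knots``) and the full three-way tensor-product basis is fit by
    (lightly ridge-regularised) least squares, allowing smooth interaction
    between all three axes.  Reports in-sample R² and seeded k-fold
    held-out R².
    """
    config = config or SmoothingConfig()
    years, lats, lons = _check_grid(grid)
    yv = grid["year"].to_numpy(dtype=float)
    la = grid["lat"].to_numpy(dtype=float)
    lo = grid["lon"].to_numpy(dtype=float)
    h = grid["humidity"].to_numpy(dtype=float)
    caps = [min(len(a), config.max_knots) for a in (years, lats, lons)]

    def basis_size(cap, axis):
        return min(cap, len(axis)) + min(config.degree, min(cap, len(axis)) - 1) - 1

    # keep the tensor basis comfortably smaller than the training data
    while np.prod([basis_size(c, a) for c, a in
                   zip(caps, (years, lats, lons))]) > max(len(h) // 2, 27):
        caps[int(np.argmax(caps))] -= 1
    knots = [_axis_knots(a, c) for a, c in zip((years, lats, lons), caps)]

    def design(yy, aa, oo):
        b1 = _spline_basis(yy, knots[0], config.degree)
        b2 = _spline_basis(aa, knots[1], config.degree)
        b3 = _spline_basis(oo, knots[2], config.degree)
        # row-wise tensor product
        n = b1.shape[0]
        x = (b1[:, :, None, None] * b2[:, None, :, None] * b3[:, None, None, :])
        return x.reshape(n, -1)

    x = design(yv, la, lo)

    def solve(xm, ym):
        a = xm.T @ xm + config.ridge * np.eye(xm.shape[1])
        return np.linalg.solve(a, xm.T @ ym)

    coef = solve(x, h)
    pred_in = x @ coef
    r2_in = _r2(h, pred_in)

    rng = np.random.default_rng(config.cv_seed)
    order = rng.permutation(len(h))
    folds = np.array_split(order, config.cv_folds)
    resid_ss, total_ss = 0.0, 0.0
    hbar = h.mean()
    for fold in folds:
        mask = np.ones(len(h), bool)
        mask[fold] = False
        if mask.sum() < x.shape[1] // 4:
            continue
        cf = solve(x[mask], h[mask])
        p = x[~mask] @ cf
        resid_ss += float(np.sum((h[~mask] - p) ** 2))
        total_ss += float(np.sum((h[~mask] - hbar) ** 2))
    r2_out = 1.0 - resid_ss / total_ss if total_ss > 0 else float("nan")

    bbox = {
        "year": (float(years[0]), float(years[-1])),
        "lat": (float(lats[0]), float(lats[-1])),
        "lon": (float(lons[0]), float(lons[-1])),
    }

    def predictor(yy, aa, oo):
        return design(yy, aa, oo) @ coef

    return HumidityField(
        method="tensor_spline", predictor=predictor, bbox=bbox,
        r2_insample=r2_in, r2_heldout=r2_out,
        meta={"n_coef": int(x.shape[1]), "degree": config.degree},
    )


def bilinear_baseline(grid: pd.DataFrame) -> HumidityField:
    """Trilinear interpolation on the full (year, lat, lon) grid: the
    simple baseline the smooth field is compared against."""
    years, lats, lons = _check_grid(grid)
    pivot = grid.set_index(["year", "lat", "lon"])["humidity"]
    cube = np.empty((len(years), len(lats), len(lons)))
    try:
        for i, yy in enumerate(years):
            for j, aa in enumerate(lats):
                for k, oo in enumerate(lons):
                    cube[i, j, k] = float(pivot.loc[(yy, aa, oo)])
    except KeyError as exc:
        raise ValueError(f"grid is not complete: missing point {exc}") from exc
    rgi = interpolate.RegularGridInterpolator((years, lats, lons), cube)

    # held-out diagnostic: drop interior grid points one at a time (capped)
    interior = [
        (i, j, k)
        for i in range(1, len(years) - 1)
        for j in range(1, len(lats) - 1)
        for k in range(1, len(lons) - 1)
    ]
    r2_out = float("nan")
    if interior:
        preds, truth = [], []
        for (i, j, k) in interior[:200]:
            neigh = 0.5 * (cube[i - 1, j, k] + cube[i + 1, j, k])
            preds.append(neigh)
            truth.append(cube[i, j, k])
        r2_out = _r2(np.array(truth), np.array(preds))

    bbox = {
        "year": (float(years[0]), float(years[-1])),
        "lat": (float(lats[0]), float(lats[-1])),
        "lon": (float(lons[0]), float(lons[-1])),
    }

    def predictor(yy, aa, oo):
        return rgi(np.column_stack([yy, aa, oo]))

    field_pred = HumidityField(
        method="trilinear", predictor=predictor, bbox=bbox, r2_heldout=r2_out,
    )
    allp = field_pred.predict(grid["year"], grid["lat"], grid["lon"])
    field_pred.r2_insample = _r2(grid["humidity"].to_numpy(dtype=float), allp)
    return field_pred


def humidity_at_nodes(field_obj: HumidityField, tree: GeoPhyloTree,
                      convention: TimeConvention | None = None,
                      variable: str | None = "humidity") -> dict[str, float]:
    """Evaluate a fitted humidity field at every node's (year, lat, lon).

    Node ages are converted to the grid's year axis via the configured
    reference years.  Nodes outside the field's bounding box raise an
    error listing the offending nodes.
    """
    convention = convention or TimeConvention()
    ids = tree.node_ids
    ages = np.array([tree.nodes[i].age for i in ids])
    lats = np.array([tree.nodes[i].lat for i in ids])
    lons = np.array([tree.nodes[i].lon for i in ids])
    years = convention.age_to_grid_year(ages)
    bad = []
    eps = 1e-9
    for name, arr in (("year", years), ("lat", lats), ("lon", lons)):
        lo, hi = field_obj.bbox[name]
        bad.extend(np.asarray(ids)[(arr < lo - eps) | (arr > hi + eps)].tolist())
    if bad:
        raise ValueError(f"nodes outside field bounding box: {sorted(set(bad))!r}")
    vals = field_obj.predict(years, lats, lons)
    out = {nid: float(v) for nid, v in zip(ids, vals)}
    if variable is not None:
        tree.set_trait(variable, out)
    return out


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-18 else 0.0
    return 1.0 - ss_res / ss_tot
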