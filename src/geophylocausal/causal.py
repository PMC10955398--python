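"""Diachronic Bayesian causal models of trait change along a geo-phylo tree.

The unit of analysis is the ancestor->descendant edge.  The change in the
trait down edge i is modelled as

    T_desc,i - T_anc,i ~ Normal(mu_i, sigma_i)
    mu_i    = (alpha + eta * H_i + gamma * Gt_i + rho * Pt_i) * dA_i
    sigma_i = sigma0 + beta * dA_i

with dA_i the edge duration in ky (effects are per-1000-years rates),
H_i the mean of ancestor and descendant humidity, Gt_i the mean trait of
geographically close contemporaneous lineages and Pt_i the mean trait of
phylogenetically close nodes.  Reconstructed interior-node traits enter
through a measurement layer T_node ~ Normal(T_REC, T_SE), and Gt/Pt
through Gt_i ~ Normal(Gt_MEAN, Gt_SD) (likewise Pt).  *Model LIN* uses
the linear Gt/Pt terms; *Model GP* replaces them with latent per-node
effects g + p drawn from Gaussian processes over geographic and
cophenetic distance.

All latent layers are Gaussian and linear, so they are marginalised
analytically into a closed-form multivariate-normal likelihood over the
top-level parameters, which is sampled with an affine-invariant ensemble
MCMC (emcee).  Latent draws are recovered afterwards by exact Gaussian
conditioning.  Savage-Dickey density ratios and PSIS-LOO ELPD (via arviz)
provide hypothesis testing and model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import linalg, stats

from geophylocausal.core import (
    DistanceMatrix,
    GeoPhyloTree,
    cophenetic_matrix,
    greatcircle_matrix,
    haversine_km,
    lineages_at_time,
)
from geophylocausal.reconstruct import NodeReconstruction


# ---------------------------------------------------------------------------
# node-pair table
# ---------------------------------------------------------------------------


def interpolate_lineage_value(p: float, v_anc: float, v_desc: float) -> float:
    """Linearly interpolated trait value of a lineage at proportional time
    p along its edge (0 at the ancestor, 1 at the descendant):
    v_anc + p * (v_desc - v_anc)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"interpolation proportion {p} outside [0, 1]")
    return float(v_anc + p * (v_desc - v_anc))


@dataclass
class NodePairTable:
    """One row per retained ancestor->descendant edge plus the metadata
    needed to fit and un-scale the models.

    ``df`` columns: anc, desc, T_anc, T_desc, T_anc_SE, T_desc_SE, dA, H,
    Gt_MEAN, Gt_SD, Pt_MEAN, Pt_SD, gt_empty, pt_empty.  H/Gt/Pt columns
    are stored z-scaled (divided by the sample SD, not centred) when
    scaling is on; ``scale_factors`` holds the divisors so raw values are
    recoverable.
    """

    df: pd.DataFrame
    scale_factors: dict[str, float]
    dropped_edges: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.df["dA"] <= 0).any():
            raise ValueError("retained rows must have dA > 0")
        if (self.df["Gt_SD"] < 0).any() or (self.df["Pt_SD"] < 0).any():
            raise ValueError("neighbourhood SDs must be nonnegative")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        """Observed (reconstruction-mean) trait change per row."""
        return (self.df["T_desc"] - self.df["T_anc"]).to_numpy(dtype=float)

    def latent_nodes(self) -> list[str]:
        """Node ids with nonzero reconstruction SE (shared latent states)."""
        se = {}
        for _, row in self.df.iterrows():
            se[row["anc"]] = row["T_anc_SE"]
            se[row["desc"]] = row["T_desc_SE"]
        return sorted(nid for nid, s in se.items() if s > 0)

    def incidence(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Signed incidence of rows on latent nodes (desc +1, anc -1) and
        the latent nodes' SEs."""
        nodes = self.latent_nodes()
        index = {nid: j for j, nid in enumerate(nodes)}
        u = np.zeros((len(self.df), len(nodes)))
        se = np.zeros(len(nodes))
        for i, (_, row) in enumerate(self.df.iterrows()):
            if row["desc"] in index:
                u[i, index[row["desc"]]] += 1.0
                se[index[row["desc"]]] = row["T_desc_SE"]
            if row["anc"] in index:
                u[i, index[row["anc"]]] -= 1.0
                se[index[row["anc"]]] = row["T_anc_SE"]
        return u, se, nodes

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _as_reconstruction(tree: GeoPhyloTree, traits) -> NodeReconstruction:
    if isinstance(traits, NodeReconstruction):
        return traits
    mean = {nid: float(v) for nid, v in dict(traits).items()}
    return NodeReconstruction(mean=mean, se={nid: 0.0 for nid in mean},
                              method="observed")


def build_node_pair_table(
    tree: GeoPhyloTree,
    traits,
    humidity_per_node: dict[str, float],
    geo_radius_km: float = 500.0,
    phylo_radius: float = 0.02,
    phylo_radius_mode: str = "native",
    gt_eval: str = "descendant",
    scale: bool = True,
    exclude_self_ancestor: bool = True,
) -> NodePairTable:
    """Assemble the ancestor->descendant node-pair dataset.

    Per edge: H is the mean of ancestor and descendant humidity; Gt_MEAN/SD
    summarise the linearly interpolated trait values of lineages alive at
    the evaluation time (the descendant's age by default, the edge
    midpoint with ``gt_eval='midpoint'``) whose interpolated location lies
    within ``geo_radius_km`` of the descendant; Pt_MEAN/SD summarise the
    trait values of all nodes within ``phylo_radius`` cophenetic distance
    of the descendant (not filtered for contemporaneity), excluding the
    descendant itself and its own ancestor.  ``phylo_radius_mode`` is
    ``'native'`` (tree branch-length units) or ``'fraction_of_depth'``
    (radius times twice the root age).  Zero-length edges are dropped and
    logged; empty neighbourhoods are flagged and their mean/SD pinned to 0
    so the coefficient contributes nothing.

    ``traits`` is either a mapping node id -> value (observed everywhere,
    SE 0) or a :class:`NodeReconstruction`.  With ``scale=True`` the H,
    Gt and Pt columns are divided by their sample SD (no centring); the
    divisors are stored in ``scale_factors``.
    """
    rec = _as_reconstruction(tree, traits)
    if gt_eval not in ("descendant", "midpoint"):
        raise ValueError(f"unknown gt_eval {gt_eval!r}")
    if phylo_radius_mode == "fraction_of_depth":
        radius = phylo_radius * 2.0 * tree.root_age
    elif phylo_radius_mode == "native":
        radius = phylo_radius
    else:
        raise ValueError(f"unknown phylo_radius_mode {phylo_radius_mode!r}")

    coph = cophenetic_matrix(tree)
    rows = []
    dropped = []
    for anc, desc in tree.edges():
        da = tree.nodes[desc].age, tree.nodes[anc].age
        da = da[1] - da[0]
        if da <= 0:
            dropped.append(desc)
            continue
        h = 0.5 * (humidity_per_node[anc] + humidity_per_node[desc])
        t_eval = (tree.nodes[desc].age if gt_eval == "descendant"
                  else tree.nodes[desc].age + 0.5 * da)
        ref = tree.nodes[desc]
        gvals = []
        for lin in lineages_at_time(tree, t_eval):
            if lin["desc"] == desc:
                continue
            a, d, p = lin["anc"], lin["desc"], lin["p"]
            la = tree.nodes[a].lat + p * (tree.nodes[d].lat - tree.nodes[a].lat)
            lo = tree.nodes[a].lon + p * (tree.nodes[d].lon - tree.nodes[a].lon)
            if haversine_km(ref.lat, ref.lon, la, lo) <= geo_radius_km:
                gvals.append(interpolate_lineage_value(p, rec.mean[a], rec.mean[d]))
        pvals = []
        for other in tree.node_ids:
            if other == desc:
                continue
            if exclude_self_ancestor and other == anc:
                continue
            if coph.get(desc, other) < radius:
                pvals.append(rec.mean[other])
        gt_empty = len(gvals) == 0
        pt_empty = len(pvals) == 0
        rows.append({
            "anc": anc, "desc": desc,
            "T_anc": rec.mean[anc], "T_desc": rec.mean[desc],
            "T_anc_SE": rec.se[anc], "T_desc_SE": rec.se[desc],
            "dA": da, "H": h,
            "Gt_MEAN": float(np.mean(gvals)) if gvals else 0.0,
            "Gt_SD": float(np.std(gvals)) if gvals else 0.0,
            "Pt_MEAN": float(np.mean(pvals)) if pvals else 0.0,
            "Pt_SD": float(np.std(pvals)) if pvals else 0.0,
            "gt_empty": gt_empty, "pt_empty": pt_empty,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no edges with positive dA")

    factors = {"H": 1.0, "Gt": 1.0, "Pt": 1.0}
    if scale:
        for col, key, mask in (
            ("H", "H", np.ones(len(df), bool)),
            ("Gt", "Gt", ~df["gt_empty"].to_numpy()),
            ("Pt", "Pt", ~df["pt_empty"].to_numpy()),
        ):
            src = df[f"{col}_MEAN"] if col != "H" else df["H"]
            vals = src.to_numpy(dtype=float)[mask]
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            factors[key] = sd if sd > 0 else 1.0
        df["H"] = df["H"] / factors["H"]
        for col in ("Gt_MEAN", "Gt_SD"):
            df[col] = df[col] / factors["Gt"]
        for col in ("Pt_MEAN", "Pt_SD"):
            df[col] = df[col] / factors["Pt"]
    return NodePairTable(
        df=df, scale_factors=factors, dropped_edges=dropped,
        meta={
            "geo_radius_km": geo_radius_km, "phylo_radius": phylo_radius,
            "phylo_radius_mode": phylo_radius_mode, "gt_eval": gt_eval,
            "scaled": scale,
        },
    )


# ---------------------------------------------------------------------------
# conditional (unmarginalised) densities
# ---------------------------------------------------------------------------


def loglik_model_lin(params: dict, pair_table: NodePairTable,
                     gt: np.ndarray | None = None,
                     pt: np.ndarray | None = None,
                     t_anc: np.ndarray | None = None,
                     t_desc: np.ndarray | None = None) -> float:
    """Model-LIN log-likelihood conditional on latent arguments.

    ``params`` needs alpha, eta, gamma, rho, sigma0, beta.  Latent Gt/Pt
    and ancestor/descendant trait vectors default to the table's means.
    Returns -inf when any row's sigma0 + beta * dA is nonpositive.
    """
    df = pair_table.df
    da = df["dA"].to_numpy(dtype=float)
    h = df["H"].to_numpy(dtype=float)
    gt = df["Gt_MEAN"].to_numpy(dtype=float) if gt is None else np.asarray(gt, float)
    pt = df["Pt_MEAN"].to_numpy(dtype=float) if pt is None else np.asarray(pt, float)
    t_anc = df["T_anc"].to_numpy(dtype=float) if t_anc is None else np.asarray(t_anc, float)
    t_desc = df["T_desc"].to_numpy(dtype=float) if t_desc is None else np.asarray(t_desc, float)
    if not (len(da) == len(gt) == len(pt) == len(t_anc) == len(t_desc)):
        raise ValueError("dimension mismatch between table and latent arguments")
    sigma = params["sigma0"] + params["beta"] * da
    if np.any(sigma <= 0):
        return -np.inf
    mu = (params["alpha"] + params["eta"] * h + params["gamma"] * gt
          + params["rho"] * pt) * da
    resid = (t_desc - t_anc) - mu
    return float(np.sum(-0.5 * (resid / sigma) ** 2 - np.log(sigma)
                        - 0.5 * np.log(2 * np.pi)))


def latent_measurement_layers(reconstruction: NodeReconstruction,
                              pair_table: NodePairTable,
                              t_values: dict[str, float],
                              gt: np.ndarray, pt: np.ndarray) -> float:
    """Log density of the latent measurement layers.

    Adds Normal(T_node | T_REC, T_SE) for each node with T_SE > 0 (one
    shared latent per node), and Normal(Gt_i | Gt_MEAN_i, Gt_SD_i) and
    Normal(Pt_i | Pt_MEAN_i, Pt_SD_i) per row; zero-SE nodes and zero-SD
    rows are fixed constants and contribute nothing (their latent must
    equal the stated mean).
    """
    total = 0.0
    for nid, se in reconstruction.se.items():
        if se > 0 and nid in t_values:
            total += float(stats.norm.logpdf(t_values[nid],
                                             reconstruction.mean[nid], se))
    df = pair_table.df
    gt = np.asarray(gt, float)
    pt = np.asarray(pt, float)
    for name, arr in (("Gt", gt), ("Pt", pt)):
        m = df[f"{name}_MEAN"].to_numpy(dtype=float)
        s = df[f"{name}_SD"].to_numpy(dtype=float)
        free = s > 0
        if np.any(~free) and not np.allclose(arr[~free], m[~free]):
            raise ValueError(f"{name} with zero SD must equal its mean")
        total += float(np.sum(stats.norm.logpdf(arr[free], m[free], s[free])))
    return total


# ---------------------------------------------------------------------------
# GP kernels
# ---------------------------------------------------------------------------


def gp_kernel_geo(delta_km: np.ndarray, amplitude: float, lengthscale: float,
                  jitter: float = 1e-6) -> np.ndarray:
    """Squared-exponential kernel over geographic distance:
    amplitude^2 * exp(-delta^2 / (2 lengthscale^2)) + jitter on delta=0."""
    if amplitude <= 0 or lengthscale <= 0:
        raise ValueError("kernel hyperparameters must be positive")
    delta = np.asarray(delta_km, dtype=float)
    if np.any(delta < 0):
        raise ValueError("distances must be nonnegative")
    k = amplitude ** 2 * np.exp(-delta ** 2 / (2.0 * lengthscale ** 2))
    return k + jitter * (delta == 0)


def gp_kernel_phylo(delta_tree: np.ndarray, amplitude: float,
                    lengthscale: float) -> np.ndarray:
    """Ornstein-Uhlenbeck (exponential) kernel over cophenetic distance:
    amplitude^2 * exp(-delta / lengthscale)."""
    if amplitude <= 0 or lengthscale <= 0:
        raise ValueError("kernel hyperparameters must be positive")
    delta = np.asarray(delta_tree, dtype=float)
    if np.any(delta < 0):
        raise ValueError("distances must be nonnegative")
    return amplitude ** 2 * np.exp(-delta / lengthscale)


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Variant, confound set, priors and sampler settings.

    Priors: coefficients (alpha, eta, gamma, rho) and the variance slope
    beta ~ Normal(0, coef_prior_sd); sigma0 ~ Exponential(sigma0_rate).
    Defaults coef_prior_sd=1, sigma0_rate=1; ratio-type outcomes use 0.5
    and 5.  GP hyperpriors: amplitude ~ half-Normal(0, gp_amp_prior_sd);
    lengthscale ~ Lognormal(gp_ls_prior) with location/scale chosen from
    the observed distance range when left unset.

    The sampler is an affine-invariant ensemble: ``nwalkers`` walkers are
    treated as chains and ``nsteps - burn`` thinned draws retained per
    walker.
    """

    variant: str = "lin"  # {lin, gp}
    include_geography: bool = True
    include_phylogeny: bool = True
    coef_prior_sd: float = 1.0
    sigma0_rate: float = 1.0
    gp_amp_prior_sd: float = 1.0
    gp_ls_prior: tuple[float, float] | None = None  # lognormal (mu, sigma)
    nwalkers: int = 32
    nsteps: int = 6000
    burn: int = 3000
    thin: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("lin", "gp"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def param_names(self) -> list[str]:
        names = ["alpha", "eta"]
        if self.variant == "lin":
            if self.include_geography:
                names.append("gamma")
            if self.include_phylogeny:
                names.append("rho")
            names += ["sigma0", "beta"]
        else:
            names += ["sigma0", "beta"]
            if self.include_geography:
                names += ["amp_g", "ls_g"]
            if self.include_phylogeny:
                names += ["amp_p", "ls_p"]
        return names

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorFit:
    """Posterior samples plus diagnostics for one fitted model."""

    idata: az.InferenceData
    spec: ModelSpec
    param_names: list[str]
    scale_factors: dict[str, float]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    seed: int
    acceptance_fraction: float
    meta: dict = field(default_factory=dict)

    def samples(self, name: str) -> np.ndarray:
        return self.idata.posterior[name].to_numpy().ravel()

    def raw_coefficient(self, name: str) -> np.ndarray:
        """Coefficient samples on the raw (un-z-scaled) predictor scale."""
        divisor = {"eta": "H", "gamma": "Gt", "rho": "Pt"}.get(name)
        s = self.samples(name)
        return s / self.scale_factors[divisor] if divisor else s

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            s = self.samples(name)
            lo, hi = np.quantile(s, [0.025, 0.975])
            rows.append({
                "parameter": name, "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)), "q2.5": float(lo),
                "q97.5": float(hi), "rhat": self.rhat.get(name, np.nan),
                "ess": self.ess.get(name, np.nan),
            })
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        """Write the fit as a directory: posterior draws (CSV, one column
        per parameter), a diagnostics JSON and the model-spec echo."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({n: self.samples(n) for n in self.param_names}).to_csv(
            d / "draws.csv", index=False)
        diag = {
            "rhat": self.rhat, "ess": self.ess, "converged": self.converged,
            "seed": self.seed, "acceptance_fraction": self.acceptance_fraction,
            "scale_factors": self.scale_factors, "meta": self.meta,
        }
        (d / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        (d / "model_spec.json").write_text(
            json.dumps(self.spec.to_dict(), indent=2))


class _MarginalModel:
    """Closed-form marginal likelihood over the top-level parameters.

    The observed trait-change vector y (from reconstruction means) is
    multivariate normal with mean m(theta) and covariance
    D(theta) + U S U' (+ dA-scaled GP covariance for the GP variant),
    where D collects per-row variances (sigma_i^2 plus, for LIN, the
    gamma/rho-propagated Gt/Pt measurement variances), U is the signed
    incidence of rows on latent interior nodes and S their reconstruction
    variances.
    """

    def __init__(self, spec: ModelSpec, table: NodePairTable,
                 distance_matrices: dict[str, DistanceMatrix] | None = None):
        self.spec = spec
        self.table = table
        df = table.df
        self.y = table.y
        self.da = df["dA"].to_numpy(dtype=float)
        self.h = df["H"].to_numpy(dtype=float)
        self.gt_m = df["Gt_MEAN"].to_numpy(dtype=float)
        self.gt_s = df["Gt_SD"].to_numpy(dtype=float)
        self.pt_m = df["Pt_MEAN"].to_numpy(dtype=float)
        self.pt_s = df["Pt_SD"].to_numpy(dtype=float)
        self.u, self.node_se, self.latent_ids = table.incidence()
        self.s2 = self.node_se ** 2
        self.has_latents = len(self.latent_ids) > 0
        if self.has_latents:
            self.usu = (self.u * self.s2) @ self.u.T  # fixed n x n low-rank part
        self.names = spec.param_names()
        self.ix = {n: i for i, n in enumerate(self.names)}
        self.gp_cov_geo = None
        self.gp_cov_phylo = None
        if spec.variant == "gp":
            desc = df["desc"].tolist()
            need = []
            if spec.include_geography:
                need.append("geographic")
            if spec.include_phylogeny:
                need.append("cophenetic")
            if need and distance_matrices is None:
                raise ValueError("GP variant requires distance matrices")
            if spec.include_geography:
                self.delta_geo = distance_matrices["geographic"].subset(desc).values
            if spec.include_phylogeny:
                self.delta_phylo = distance_matrices["cophenetic"].subset(desc).values
            if spec.gp_ls_prior is None:
                # prior mass spanning the observed distance range
                ref = (self.delta_geo if spec.include_geography
                       else self.delta_phylo)
                med = float(np.median(ref[ref > 0])) if np.any(ref > 0) else 1.0
                spec.gp_ls_prior = (np.log(med), 1.0)

    # -- priors ----------------------------------------------------------

    def log_prior(self, theta: np.ndarray) -> float:
        spec = self.spec
        log2pi = np.log(2 * np.pi)
        lp = 0.0
        for name, val in zip(self.names, theta):
            if name in ("alpha", "eta", "gamma", "rho", "beta"):
                s = spec.coef_prior_sd
                lp += -0.5 * (val / s) ** 2 - np.log(s) - 0.5 * log2pi
            elif name == "sigma0":
                if val <= 0:
                    return -np.inf
                lp += np.log(spec.sigma0_rate) - spec.sigma0_rate * val
            elif name.startswith("amp"):
                if val <= 0:
                    return -np.inf
                s = spec.gp_amp_prior_sd
                lp += -0.5 * (val / s) ** 2 - np.log(s) + np.log(2.0) - 0.5 * log2pi
            elif name.startswith("ls"):
                if val <= 0:
                    return -np.inf
                mu, sd = spec.gp_ls_prior
                z = (np.log(val) - mu) / sd
                lp += -0.5 * z ** 2 - np.log(val * sd) - 0.5 * log2pi
        return float(lp)

    def sample_prior(self, rng: np.random.Generator, size: int) -> np.ndarray:
        spec = self.spec
        cols = []
        for name in self.names:
            if name in ("alpha", "eta", "gamma", "rho", "beta"):
                cols.append(rng.normal(0.0, spec.coef_prior_sd, size))
            elif name == "sigma0":
                cols.append(rng.exponential(1.0 / spec.sigma0_rate, size))
            elif name.startswith("amp"):
                cols.append(np.abs(rng.normal(0.0, spec.gp_amp_prior_sd, size)))
            elif name.startswith("ls"):
                mu, sd = spec.gp_ls_prior
                cols.append(np.exp(rng.normal(mu, sd, size)))
        return np.column_stack(cols)

    # -- likelihood -------------------------------------------------------

    def _mean_and_diag(self, theta: np.ndarray):
        g = dict(zip(self.names, theta))
        sigma = g["sigma0"] + g["beta"] * self.da
        if np.any(sigma <= 0):
            return None, None
        mean = (g["alpha"] + g["eta"] * self.h) * self.da
        diag = sigma ** 2
        if self.spec.variant == "lin":
            if self.spec.include_geography:
                mean = mean + g["gamma"] * self.gt_m * self.da
                diag = diag + (g["gamma"] * self.da * self.gt_s) ** 2
            if self.spec.include_phylogeny:
                mean = mean + g["rho"] * self.pt_m * self.da
                diag = diag + (g["rho"] * self.da * self.pt_s) ** 2
        return mean, diag

    def _gp_cov(self, theta: np.ndarray) -> np.ndarray | None:
        if self.spec.variant != "gp":
            return None
        g = dict(zip(self.names, theta))
        cov = None
        if self.spec.include_geography:
            cov = gp_kernel_geo(self.delta_geo, g["amp_g"], g["ls_g"])
        if self.spec.include_phylogeny:
            k = gp_kernel_phylo(self.delta_phylo, g["amp_p"], g["ls_p"])
            cov = k if cov is None else cov + k
        if cov is None:
            return None
        return self.da[:, None] * cov * self.da[None, :]

    def log_likelihood(self, theta: np.ndarray) -> float:
        mean, diag = self._mean_and_diag(theta)
        if mean is None:
            return -np.inf
        resid = self.y - mean
        gp_cov = self._gp_cov(theta)
        if gp_cov is None and not self.has_latents:
            return float(-0.5 * np.sum(resid ** 2 / diag + np.log(diag))
                         - 0.5 * len(resid) * np.log(2 * np.pi))
        if gp_cov is None:
            # Woodbury with the fixed low-rank latent part
            dinv = 1.0 / diag
            m = len(self.latent_ids)
            a = np.diag(1.0 / self.s2) + (self.u.T * dinv) @ self.u
            try:
                cf = linalg.cho_factor(a)
            except linalg.LinAlgError:
                return -np.inf
            udr = self.u.T @ (dinv * resid)
            quad = float(resid @ (dinv * resid) - udr @ linalg.cho_solve(cf, udr))
            logdet = float(np.sum(np.log(diag)) + np.sum(np.log(self.s2))
                           + 2.0 * np.sum(np.log(np.diag(cf[0]))))
            n = len(resid)
            return -0.5 * (quad + logdet + n * np.log(2 * np.pi))
        cov = np.diag(diag) + gp_cov
        if self.has_latents:
            cov = cov + self.usu
        try:
            cf = linalg.cho_factor(cov)
        except linalg.LinAlgError:
            return -np.inf
        alpha_v = linalg.cho_solve(cf, resid)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        n = len(resid)
        return -0.5 * (float(resid @ alpha_v) + logdet + n * np.log(2 * np.pi))

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-row marginal normal log densities log N(y_i; m_i, V_ii)."""
        mean, diag = self._mean_and_diag(theta)
        if mean is None:
            return np.full(len(self.y), -np.inf)
        var = diag.copy()
        if self.has_latents:
            var = var + np.diag(self.usu)
        gp_cov = self._gp_cov(theta)
        if gp_cov is not None:
            var = var + np.diag(gp_cov)
        return stats.norm.logpdf(self.y, mean, np.sqrt(var))


def fit_model(spec: ModelSpec, pair_table: NodePairTable,
              distance_matrices: dict[str, DistanceMatrix] | None = None,
              prior_only: bool = False) -> PosteriorFit:
    """Sample the posterior of a causal-model variant.

    Runs the affine-invariant ensemble sampler on the marginal
    log-posterior; walkers are initialised from the prior (tempered toward
    its centre).  Convergence is summarised by split-chain R-hat (< 1.01
    for all parameters) and bulk ESS; an unconverged fit is returned
    flagged, never silently.  ``prior_only=True`` switches the likelihood
    off (prior-predictive mode).
    """
    model = _MarginalModel(spec, pair_table, distance_matrices)
    names = model.names
    ndim = len(names)
    rng = np.random.default_rng(spec.seed)

    def log_prob(theta):
        lp = model.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        if prior_only:
            return lp
        ll = model.log_likelihood(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    # initialise walkers in a small ball around the posterior mode: the
    # ensemble then mixes within the burn-in on these low-dimensional
    # marginal posteriors
    from scipy import optimize as _opt

    starts = model.sample_prior(rng, 8)
    starts = 0.25 * starts + 0.75 * np.median(starts, axis=0)
    best = None
    if not prior_only:
        for s0 in starts:
            if not np.isfinite(log_prob(s0)):
                continue
            res = _opt.minimize(lambda t: -log_prob(t), s0, method="Nelder-Mead",
                                options={"maxiter": 2000, "fatol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
    if best is not None and np.isfinite(best.fun):
        centre = best.x
        scale = np.maximum(np.abs(centre) * 0.05, 0.01)
        p0 = centre + rng.normal(0.0, 1.0, (spec.nwalkers, ndim)) * scale
    else:
        p0 = model.sample_prior(rng, spec.nwalkers)
        p0 = 0.5 * p0 + 0.5 * np.median(p0, axis=0)
    for i in range(spec.nwalkers):
        tries = 0
        while not np.isfinite(log_prob(p0[i])) and tries < 100:
            p0[i] = model.sample_prior(rng, 1)[0]
            tries += 1

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(spec.nwalkers, ndim, log_prob, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(spec.seed).get_state())
    sampler.run_mcmc(state, spec.nsteps, progress=False)

    chain = sampler.get_chain(discard=spec.burn, thin=spec.thin)  # (draw, walker, dim)
    chain = np.moveaxis(chain, 0, 1)  # (walker/chain, draw, dim)
    posterior = {name: chain[:, :, k] for k, name in enumerate(names)}

    n_chain, n_draw, _ = chain.shape
    ll = np.empty((n_chain, n_draw, len(pair_table)))
    for c in range(n_chain):
        for d in range(n_draw):
            ll[c, d] = model.pointwise_loglik(chain[c, d])
    idata = az.from_dict(posterior=posterior, log_likelihood={"y": ll})

    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {n: float(rhat_ds[n].values) for n in names}
    ess = {n: float(ess_ds[n].values) for n in names}
    converged = all(np.isfinite(v) and v < 1.01 for v in rhat.values())
    if not converged:
        warnings.warn(
            f"fit not converged: max rhat = {max(rhat.values()):.4f}",
            stacklevel=2,
        )
    return PosteriorFit(
        idata=idata, spec=spec, param_names=names,
        scale_factors=dict(pair_table.scale_factors), rhat=rhat, ess=ess,
        converged=converged, seed=spec.seed,
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        meta={"prior_only": prior_only, "n_rows": len(pair_table),
              "n_latent_nodes": len(model.latent_ids)},
    )


def sample_latents(fit: PosteriorFit, pair_table: NodePairTable,
                   distance_matrices: dict[str, DistanceMatrix] | None = None,
                   n_draws: int = 100, seed: int = 0) -> dict[str, np.ndarray]:
    """Posterior draws of the latent quantities by exact conditioning.

    For a subset of posterior parameter draws, samples the shared interior
    node states T (and for the LIN variant the per-row Gt/Pt; for the GP
    variant the combined per-row GP effect) from their exact Gaussian
    conditional given the observed trait changes.
    """
    model = _MarginalModel(fit.spec, pair_table, distance_matrices)
    rng = np.random.default_rng(seed)
    chain = np.stack([fit.samples(n) for n in fit.param_names], axis=1)
    take = rng.choice(len(chain), size=min(n_draws, len(chain)), replace=False)
    rec_mean = {}
    for _, row in pair_table.df.iterrows():
        rec_mean[row["anc"]] = row["T_anc"]
        rec_mean[row["desc"]] = row["T_desc"]
    t0 = np.array([rec_mean[nid] for nid in model.latent_ids])
    da = model.da
    out_t, out_gp, out_gt, out_pt = [], [], [], []

    def draw_mvn(mean, cov):
        cov = 0.5 * (cov + cov.T)
        return rng.multivariate_normal(mean, cov, method="eigh")

    for theta in chain[take]:
        g = dict(zip(fit.param_names, theta))
        mean, diag = model._mean_and_diag(theta)
        cov = np.diag(diag)
        if model.has_latents:
            cov = cov + model.usu
        gp_cov = model._gp_cov(theta)
        if gp_cov is not None:
            cov = cov + gp_cov
        # residual model: r = -U e + [c_g eps_g + c_p eps_p or f_gp] + noise
        resid = model.y - mean
        cf = linalg.cho_factor(cov)
        vinv_r = linalg.cho_solve(cf, resid)
        if model.has_latents:
            su = model.s2[:, None] * model.u.T  # m x n, = Cov(e, r)^T sign apart
            cond_mean = t0 - su @ vinv_r
            cond_cov = np.diag(model.s2) - su @ linalg.cho_solve(cf, su.T)
            out_t.append(draw_mvn(cond_mean, cond_cov))
        if fit.spec.variant == "lin":
            if fit.spec.include_geography:
                c = g["gamma"] * da * model.gt_s ** 2  # Cov(r, eps_g)
                cond_mean = model.gt_m + c * vinv_r
                cond_cov = np.diag(model.gt_s ** 2) - (
                    c[:, None] * linalg.cho_solve(cf, np.diag(c)))
                out_gt.append(draw_mvn(cond_mean, cond_cov))
            if fit.spec.include_phylogeny:
                c = g["rho"] * da * model.pt_s ** 2
                cond_mean = model.pt_m + c * vinv_r
                cond_cov = np.diag(model.pt_s ** 2) - (
                    c[:, None] * linalg.cho_solve(cf, np.diag(c)))
                out_pt.append(draw_mvn(cond_mean, cond_cov))
        if gp_cov is not None:
            cond_mean = gp_cov @ vinv_r
            cond_cov = gp_cov - gp_cov @ linalg.cho_solve(cf, gp_cov)
            out_gp.append(draw_mvn(cond_mean, cond_cov))
    result: dict[str, np.ndarray] = {}
    if out_t:
        result["T_interior"] = np.asarray(out_t)
        result["T_interior_ids"] = np.asarray(model.latent_ids)
    if out_gt:
        result["Gt"] = np.asarray(out_gt)
    if out_pt:
        result["Pt"] = np.asarray(out_pt)
    if out_gp:
        result["gp_effect"] = np.asarray(out_gp)
    return result


# ---------------------------------------------------------------------------
# Savage-Dickey and ELPD
# ---------------------------------------------------------------------------


def savage_dickey(fit: PosteriorFit, parameter: str,
                  prior_density=None) -> dict:
    """Savage-Dickey Bayes factor for a point null at zero.

    BF10 = prior density at 0 / posterior density at 0; BF10 < 1 supports
    the null.  The posterior density is a Gaussian KDE with Silverman
    bandwidth.  If the posterior puts essentially no mass near zero, the
    KDE underflows and the BF is reported as a lower bound.
    """
    samples = fit.samples(parameter)
    if prior_density is None:
        sd = fit.spec.coef_prior_sd
        prior_at_zero = float(stats.norm.pdf(0.0, 0.0, sd))
    else:
        prior_at_zero = float(prior_density(0.0))
    m, s = float(np.mean(samples)), float(np.std(samples, ddof=1))
    if s > 0 and abs(m) / s > 3.0:
        # zero lies in the far tail, beyond the reach of kernel smoothing:
        # use the moment-matched normal tail density instead
        post_at_zero = float(stats.norm.pdf(0.0, m, s))
        method = "normal_tail"
    else:
        kde = stats.gaussian_kde(samples, bw_method="silverman")
        post_at_zero = float(kde(0.0)[0])
        method = "kde"
    floor = 1e-300
    if post_at_zero <= floor:
        return {"bf10": prior_at_zero / floor, "lower_bound": True,
                "method": method, "prior_at_zero": prior_at_zero,
                "posterior_at_zero": post_at_zero}
    return {"bf10": prior_at_zero / post_at_zero, "lower_bound": False,
            "method": method, "prior_at_zero": prior_at_zero,
            "posterior_at_zero": post_at_zero}


def elpd_compare(fits: dict[str, PosteriorFit]) -> pd.DataFrame:
    """PSIS-LOO expected log predictive density comparison across fits.

    All fits must share the same observation set (same pair table rows).
    Returns the arviz comparison table (elpd_loo, elpd differences, SEs,
    Pareto-k warnings propagate as arviz warnings).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    sizes = {name: f.idata.log_likelihood["y"].shape[-1] for name, f in fits.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"mismatched observation sets: {sizes}")
    return az.compare({name: f.idata for name, f in fits.items()},
                      ic="loo", scale="log")


def loo_elpd(fit: PosteriorFit) -> dict:
    """PSIS-LOO ELPD of a single fit."""
    res = az.loo(fit.idata, pointwise=True)
    return {
        "elpd_loo": float(res.elpd_loo), "se": float(res.se),
        "p_loo": float(res.p_loo),
        "n_high_pareto_k": int(np.sum(res.pareto_k.values > 0.7)),
    }
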