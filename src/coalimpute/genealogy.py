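"""Bayesian inference of gene genealogies from measured biallelic sites.

Within an LD-block (no recombination) a four-gamete-compatible binary
matrix determines a unique perfect phylogeny whose clades are the
derived-carrier sets of the columns.  Under the infinite-sites model the
posterior over genealogies is supported entirely on time-resolved binary
refinements of that skeleton, so the Metropolis-within-Gibbs sampler here
explores (i) coalescence times, (ii) the binary resolution of each
skeleton multifurcation and (iii) the scaled mutation rate theta (plus the
growth rate alpha or subpopulation proportions when a demographic
extension is active).  The target density is the coalescent prior on times
(optionally growth-rescaled or structured) times an explicit
infinite-sites likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._tree import GeneTree
from .simulate import DemographyModel, HaplotypeMatrix

__all__ = [
    "IncompatibleSitesError",
    "PriorConfig",
    "TreeSample",
    "four_gamete_compatible",
    "build_perfect_phylogeny",
    "coalescent_log_prior",
    "infinite_sites_loglik",
    "mcmc_sample",
]


class IncompatibleSitesError(ValueError):
    """A pair of sites fails the (rooted) four-gamete screen."""

    def __init__(self, site_a: int, site_b: int):
        self.site_pair = (site_a, site_b)
        super().__init__(
            f"sites {site_a} and {site_b} are incompatible with a single gene tree "
            "(four-gamete violation); exclude incompatible sites first"
        )


# ----------------------------------------------------------------------
def four_gamete_compatible(col_a, col_b) -> bool:
    """Pairwise four-gamete test.

    Returns ``False`` iff all four gametes 00/01/10/11 occur across the two
    binary columns, i.e. the pair cannot descend from a single tree without
    recurrent mutation or recombination.
    """
    a = np.asarray(col_a, dtype=np.uint8)
    b = np.asarray(col_b, dtype=np.uint8)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("columns must have length >= 2")
    gametes = np.unique(2 * a + b)
    return gametes.size < 4


def _column_masks(alleles: np.ndarray):
    """Distinct proper carrier sets of a binary matrix, with compatibility
    checking.  Returns (masks, site_to_mask) where ``site_to_mask[j]`` is
    the index into ``masks`` of column j's carrier set."""
    n, S = alleles.shape
    masks: list[np.ndarray] = []
    key_to_idx: dict[bytes, int] = {}
    site_to_mask = np.empty(S, dtype=np.int64)
    first_site: list[int] = []
    for j in range(S):
        col = alleles[:, j].astype(bool)
        cnt = int(col.sum())
        if cnt == 0 or cnt == n:
            raise ValueError(
                f"column {j} is monomorphic in the supplied matrix; "
                "monomorphic sites carry no genealogical signal"
            )
        key = np.packbits(col).tobytes()
        if key in key_to_idx:
            site_to_mask[j] = key_to_idx[key]
        else:
            key_to_idx[key] = len(masks)
            site_to_mask[j] = len(masks)
            masks.append(col)
            first_site.append(j)
    # pairwise rooted compatibility: nested or disjoint
    for i in range(len(masks)):
        for k in range(i + 1, len(masks)):
            inter = masks[i] & masks[k]
            if inter.any() and not (
                (inter == masks[i]).all() or (inter == masks[k]).all()
            ):
                raise IncompatibleSitesError(first_site[i], first_site[k])
    return masks, site_to_mask


# ----------------------------------------------------------------------
class _Skeleton:
    """Perfect-phylogeny skeleton with binary-node id allocation.

    Binary nodes: leaves ``0..n-1``; each skeleton internal node ``s`` with
    ``m_s`` children owns the id range ``local_ids[s]`` (length ``m_s-1``)
    whose last entry, ``top_id``, is the binary node subtending exactly
    ``clade(s)`` in every refinement.
    """

    def __init__(self, alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=np.uint8)
        n, S = alleles.shape
        self.n = n
        self.n_sites = S
        masks, site_to_mask = _column_masks(alleles)

        # skeleton internal nodes: non-singleton proper masks + root (full set)
        clade_masks = [m for m in masks if m.sum() >= 2]
        clade_masks.sort(key=lambda m: int(m.sum()))
        root_mask = np.ones(n, dtype=bool)
        clade_masks.append(root_mask)
        K = len(clade_masks)
        sizes = [int(m.sum()) for m in clade_masks]

        # parent skeleton node: smallest strictly-larger containing clade
        parent_sk = np.full(K, -1, dtype=np.int64)
        for i in range(K - 1):
            for j in range(i + 1, K):
                if sizes[j] > sizes[i] and bool((clade_masks[i] & ~clade_masks[j]).sum() == 0):
                    parent_sk[i] = j
                    break

        # leaves attach to the smallest containing clade
        leaf_attach = np.full(n, K - 1, dtype=np.int64)
        for i in range(K):
            # iterate small to large; first hit wins
            members = np.flatnonzero(clade_masks[i])
            for lf in members:
                if leaf_attach[lf] == K - 1 and i < K - 1:
                    leaf_attach[lf] = i

        # children items per skeleton node (binary ids filled after allocation)
        child_sk: list[list[int]] = [[] for _ in range(K)]
        for i in range(K - 1):
            child_sk[parent_sk[i]].append(i)
        leaves_of: list[list[int]] = [[] for _ in range(K)]
        for lf in range(n):
            leaves_of[leaf_attach[lf]].append(lf)

        # allocate local internal ids, children-first (ascending size order)
        next_id = n
        self.local_ids: list[np.ndarray] = [None] * K
        top_id = np.empty(K, dtype=np.int64)
        for i in range(K):  # ascending size; root last
            m = len(child_sk[i]) + len(leaves_of[i])
            if m < 2:
                raise AssertionError("skeleton node with <2 children")
            ids = np.arange(next_id, next_id + m - 1, dtype=np.int64)
            next_id += m - 1
            self.local_ids[i] = ids
            top_id[i] = ids[-1]
        assert next_id == 2 * n - 1
        self.top_id = top_id
        self.items: list[np.ndarray] = [
            np.array([top_id[c] for c in child_sk[i]] + leaves_of[i], dtype=np.int64)
            for i in range(K)
        ]
        self.parent_sk = parent_sk
        self.clade_masks = clade_masks
        self.root_sk = K - 1
        self.n_skeleton = K

        # map each column to the binary node subtending its carriers:
        # non-singleton mask -> top_id of its skeleton node; singleton -> leaf
        mask_to_node: dict[bytes, int] = {}
        for i in range(K - 1):
            mask_to_node[np.packbits(clade_masks[i]).tobytes()] = int(top_id[i])
        self.site_nodes = np.empty(S, dtype=np.int64)
        for j in range(S):
            m = masks[site_to_mask[j]]
            if m.sum() == 1:
                self.site_nodes[j] = int(np.flatnonzero(m)[0])
            else:
                self.site_nodes[j] = mask_to_node[np.packbits(m).tobytes()]

    def multifurcation_order(self):
        """Skeleton node indices with >= 3 children."""
        return [i for i in range(self.n_skeleton) if len(self.items[i]) >= 3]


def build_perfect_phylogeny(measured) -> GeneTree:
    """Deterministic perfect-phylogeny topology of a compatible matrix.

    Clades are exactly the distinct derived-carrier sets of the columns;
    nodes where the columns do not resolve branching order remain
    multifurcations, and internal times are left unset (NaN).
    """
    alleles = measured.alleles if isinstance(measured, HaplotypeMatrix) else np.asarray(measured)
    sk = _Skeleton(alleles)
    n, K = sk.n, sk.n_skeleton
    parent = np.full(n + K, -1, dtype=np.int32)
    time = np.concatenate([np.zeros(n), np.full(K, np.nan)])
    for i in range(K - 1):
        parent[n + i] = n + sk.parent_sk[i]
    for i in range(K):
        for item in sk.items[i]:
            if item < n:
                parent[item] = n + i
    return GeneTree(parent, time, n)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PriorConfig:
    """Hyper-parameters of the genealogy posterior.

    theta ~ uniform(theta_lo, theta_hi); in growth mode
    alpha ~ Gamma(growth_shape, rate=growth_rate) -- with ``growth_rate``
    left ``None`` the rate is chosen so the prior mean equals the
    scenario's growth rate; in structure mode the subpopulation
    proportions are symmetric-Dirichlet(dirichlet_conc) and the split time
    is fixed (``split_time_generations``, defaulting to the demography's
    value).
    """

    theta_lo: float = 0.0
    theta_hi: float = 100.0
    growth_shape: float = 2.0
    growth_rate: float | None = None
    dirichlet_conc: float = 2.0
    split_time_generations: float | None = None

    def validate(self) -> None:
        if not 0 <= self.theta_lo < self.theta_hi:
            raise ValueError("theta prior requires 0 <= lo < hi")
        if self.growth_shape <= 0 or (self.growth_rate is not None and self.growth_rate <= 0):
            raise ValueError("gamma prior parameters must be positive")
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be positive")

    def growth_rate_for(self, demography: DemographyModel) -> float:
        if self.growth_rate is not None:
            return self.growth_rate
        alpha = demography.growth_rate_alpha
        if alpha <= 0:
            raise ValueError(
                "growth prior rate unset and scenario growth rate is zero; "
                "supply PriorConfig.growth_rate explicitly"
            )
        return self.growth_shape / alpha


@dataclass
class TreeSample:
    """Posterior sample of genealogies plus sampled scalars."""

    trees: list[GeneTree]
    thetas: np.ndarray
    alphas: np.ndarray | None = None
    subpop_props: np.ndarray | None = None
    settings: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)


# ----------------------------------------------------------------------
# coalescent log densities (times measured in units of 2*N_e generations)
def _intensity(t, a, t0):
    """Per-pair coalescent intensity for relative size exp(-a*min(t,t0))."""
    t = np.asarray(t, dtype=float)
    if a == 0:
        return t
    below = np.minimum(t, t0)
    lam = np.expm1(a * below) / a
    return lam + np.where(t > t0, (t - t0) * np.exp(a * t0), 0.0)


def _log_nu(t, a, t0):
    t = np.asarray(t, dtype=float)
    if a == 0:
        return np.zeros_like(t)
    return -a * np.minimum(t, t0)


def _panmictic_log_density(t_events, dk, n_start, a, t0, size_fraction=1.0,
                           t_begin=0.0, t_end=np.inf, k_final_ok=True):
    """Log density of ordered coalescence times in one panmictic phase.

    ``t_events`` sorted ascending within [t_begin, t_end); ``dk[j]`` is the
    drop in lineage count at event j (1 for binary mergers).  The per-pair
    rate at time t is ``1/(size_fraction * nu(t))``.  Includes the survival
    term to ``t_end`` when finite.
    """
    t_events = np.asarray(t_events, dtype=float)
    dk = np.asarray(dk, dtype=np.int64)
    k_before = n_start - np.concatenate([[0], np.cumsum(dk)[:-1]])
    if np.any(k_before < 2):
        return -np.inf
    rates = 0.5 * k_before * (k_before - 1) / size_fraction
    lam = _intensity(t_events, a, t0)
    lam_prev = np.concatenate([[_intensity(t_begin, a, t0)], lam[:-1]])
    lp = float(np.sum(np.log(rates) - _log_nu(t_events, a, t0) - rates * (lam - lam_prev)))
    k_end = n_start - int(dk.sum())
    if np.isfinite(t_end) and k_end >= 2:
        rate_end = 0.5 * k_end * (k_end - 1) / size_fraction
        lam_last = lam[-1] if t_events.size else _intensity(t_begin, a, t0)
        lp -= rate_end * (_intensity(t_end, a, t0) - lam_last)
    elif not np.isfinite(t_end) and k_end >= 2 and not k_final_ok:
        return -np.inf
    return lp


def _structured_log_density(t_events, dk, event_demes, leaf_counts, props,
                            t_split, a, t0):
    """Log density under a clean-split structured coalescent.

    ``event_demes[j]`` is the deme of event j (-1 for events merging
    lineages of different demes); cross-deme events before ``t_split`` have
    density zero.  Demes hold fractions ``props`` of the total size.
    """
    t_events = np.asarray(t_events, dtype=float)
    dk = np.asarray(dk, dtype=np.int64)
    event_demes = np.asarray(event_demes, dtype=np.int64)
    pre = t_events < t_split
    if np.any(pre & (event_demes < 0)):
        return -np.inf
    lp = 0.0
    survivors = 0
    for d, n_d in enumerate(leaf_counts):
        sel = pre & (event_demes == d)
        lp_d = _panmictic_log_density(
            t_events[sel], dk[sel], n_d, a, t0,
            size_fraction=float(props[d]), t_begin=0.0, t_end=t_split,
        )
        if not np.isfinite(lp_d):
            return -np.inf
        lp += lp_d
        survivors += n_d - int(dk[sel].sum())
    post = ~pre
    lp_post = _panmictic_log_density(
        t_events[post], dk[post], survivors, a, t0,
        size_fraction=1.0, t_begin=t_split, t_end=np.inf,
    )
    return lp + lp_post


def coalescent_log_prior(
    tree: GeneTree,
    demography: DemographyModel | None = None,
    alpha: float | None = None,
    subpop_props=None,
) -> float:
    """Log density of a genealogy's coalescence times under the coalescent.

    For a constant-size population with ``k`` lineages the waiting time to
    the next coalescence is Exponential(k(k-1)/2) in internal units; growth
    rescales time through the shrinking backward population size and a
    clean split restricts pre-split coalescences to within-deme pairs.
    ``alpha`` (per generation) overrides the demography's growth rate, e.g.
    to evaluate a posterior draw.
    """
    dem = DemographyModel() if demography is None else demography
    if np.any(np.isnan(tree.time)):
        raise ValueError("tree must have coalescence times set")
    tree.validate()
    a = (alpha * 2.0 * dem.n_e) if alpha is not None else dem.alpha_internal
    t0 = dem.onset_internal
    internal = np.arange(tree.n_leaves, tree.n_nodes)
    ch = tree.children()
    dk_all = np.array([len(ch[i]) - 1 for i in internal], dtype=np.int64)
    order = np.argsort(tree.time[internal], kind="stable")
    t_ev = tree.time[internal][order]
    dk = dk_all[order]
    if dem.n_subpops_beta <= 1:
        return _panmictic_log_density(t_ev, dk, tree.n_leaves, a, t0)
    if tree.demes is None:
        raise ValueError("structured prior requires per-leaf deme assignment")
    beta = dem.n_subpops_beta
    props = (np.full(beta, 1.0 / beta) if subpop_props is None
             else np.asarray(subpop_props, dtype=float))
    # deme of each internal node: d if its leaf set is pure-d, else -1
    node_deme = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_deme[: tree.n_leaves] = tree.demes
    for node in tree.postorder():
        kids = ch[node]
        if kids:
            ds = {int(node_deme[c]) for c in kids}
            node_deme[node] = ds.pop() if len(ds) == 1 and -1 not in ds else -1
    leaf_counts = np.bincount(tree.demes, minlength=beta)
    return _structured_log_density(
        t_ev, dk, node_deme[internal][order], leaf_counts, props,
        dem.split_internal, a, t0,
    )


# ----------------------------------------------------------------------
def infinite_sites_loglik(tree: GeneTree, measured, theta: float) -> float:
    """Infinite-sites log likelihood of a measured matrix given a genealogy.

    Conditional on the tree, the number of segregating sites is
    Poisson(theta*T/2) with T the total tree length, and each site's
    mutation falls on a branch with probability proportional to branch
    length; a column whose carrier set is not a clade of the tree has
    likelihood zero (returned as -inf).
    """
    alleles = measured.alleles if isinstance(measured, HaplotypeMatrix) else np.asarray(measured)
    alleles = alleles.astype(np.uint8)
    n, S = alleles.shape
    if n != tree.n_leaves:
        raise ValueError("matrix rows must match tree leaves")
    b = tree.branch_lengths()
    T = float(b.sum())
    packed = tree.leaf_masks_packed()
    # branch length subtending each distinct leaf set (summed over
    # zero-length chains so degenerate ties keep their full mass)
    clade_len: dict[bytes, float] = {}
    for node in range(tree.n_nodes):
        key = packed[node].tobytes()
        clade_len[key] = clade_len.get(key, 0.0) + float(b[node])
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if theta == 0.0:
        return 0.0 if S == 0 else -np.inf
    ll = S * math.log(theta * T / 2.0) - theta * T / 2.0 - float(gammaln(S + 1))
    for j in range(S):
        key = np.packbits(alleles[:, j].astype(bool)).tobytes()
        bj = clade_len.get(key, 0.0)
        if bj <= 0.0:
            return -np.inf
        ll += math.log(bj / T)
    return float(ll)


# ----------------------------------------------------------------------
class _RefinementSampler:
    """Metropolis-within-Gibbs over refinements of the perfect phylogeny."""

    def __init__(self, alleles, demography, priors, mode, rng, leaf_demes=None):
        self.alleles = np.asarray(alleles, dtype=np.uint8)
        self.n, self.S = self.alleles.shape
        self.dem = demography
        self.priors = priors
        self.mode = mode
        self.rng = rng
        self.sk = _Skeleton(self.alleles)
        n = self.n

        self.grow = mode in ("growth", "growth-structure")
        self.struct = mode in ("structure", "growth-structure")
        if self.struct:
            if leaf_demes is None:
                raise ValueError("structure mode requires per-leaf deme assignment")
            self.leaf_demes = np.asarray(leaf_demes, dtype=np.int64)
            self.beta = demography.n_subpops_beta
            self.leaf_counts = np.bincount(self.leaf_demes, minlength=self.beta)
            if priors.split_time_generations is not None:
                self.t_split = priors.split_time_generations / (2.0 * demography.n_e)
            else:
                self.t_split = demography.split_internal
        else:
            self.leaf_demes = None
            self.t_split = None

        # binary-tree state arrays
        m = 2 * n - 1
        self.parent = np.full(m, -1, dtype=np.int64)
        self.child0 = np.full(m, -1, dtype=np.int64)
        self.child1 = np.full(m, -1, dtype=np.int64)
        self.t = np.zeros(m)
        self.demeset = np.zeros(m, dtype=np.int64)
        if self.struct:
            self.demeset[:n] = 1 << self.leaf_demes
            self._popcount = np.array([bin(i).count("1") for i in range(1 << self.beta)])
            self._mask_to_deme = np.array(
                [int(math.log2(i)) if bin(i).count("1") == 1 else -1
                 for i in range(1, 1 << self.beta)],
            )
        self.root_id = int(self.sk.top_id[self.sk.root_sk])
        self.internal_ids = np.arange(n, m, dtype=np.int64)
        self.nonroot = np.array([i for i in range(m) if i != self.root_id], dtype=np.int64)
        self.site_nodes = self.sk.site_nodes

        # parameters
        self.theta = self._init_theta()
        self.alpha = None
        self.props = None
        if self.grow:
            self.gamma_rate = priors.growth_rate_for(demography)
            self.alpha = priors.growth_shape / self.gamma_rate  # prior mean
        if self.struct:
            self.props = np.full(self.beta, 1.0 / self.beta)

        # proposal scales (adapted during burn-in only)
        self.rescale_step = 0.3
        self.theta_step = 0.8
        self.alpha_step = 0.5
        self.prop_step = 0.08
        self.root_exp_rate = 1.0

        self._init_state()
        self.lp = self._log_posterior()
        if not np.isfinite(self.lp):
            raise RuntimeError("failed to initialise MCMC at a valid state")
        self.n_prop = {}
        self.n_acc = {}

    # -- initialisation -------------------------------------------------
    def _init_theta(self):
        lo, hi = self.priors.theta_lo, self.priors.theta_hi
        if self.S > 0:
            watterson = self.S / np.sum(1.0 / np.arange(1, self.n))
        else:
            watterson = 1.0
        return float(np.clip(watterson, lo + 1e-3 * (hi - lo), hi - 1e-3 * (hi - lo)))

    def _resolve_topology(self, s):
        """Draw a uniform labeled history for skeleton node ``s`` (parents,
        child slots and deme sets of its local ids; times untouched)."""
        rng = self.rng
        active = list(self.sk.items[s])
        for lid in self.sk.local_ids[s]:
            i = rng.integers(len(active))
            a = active.pop(i)
            j = rng.integers(len(active))
            b = active.pop(j)
            self.parent[a] = lid
            self.parent[b] = lid
            self.child0[lid] = a
            self.child1[lid] = b
            if self.struct:
                self.demeset[lid] = self.demeset[a] | self.demeset[b]
            active.append(lid)

    def _init_state(self):
        rng = self.rng
        # resolve children-first so child top times exist when parents init
        for s in range(self.sk.n_skeleton):
            self._resolve_topology(s)
        scale = 2.0 / self.n
        for s in range(self.sk.n_skeleton):
            for lid in self.sk.local_ids[s]:
                lo = max(self.t[self.child0[lid]], self.t[self.child1[lid]])
                if self.struct and self._popcount[self.demeset[lid]] > 1:
                    lo = max(lo, self.t_split)
                self.t[lid] = lo + rng.exponential(scale) + 1e-9
        span = self.t[self.root_id] - max(
            (self.t[self.sk.items[self.sk.root_sk]]).max(), 0.0
        )
        m_root = len(self.sk.items[self.sk.root_sk])
        self.root_exp_rate = max(m_root - 1, 1) / max(span, 1e-6)

    # -- posterior ------------------------------------------------------
    def _log_posterior(self):
        t = self.t
        parent = self.parent
        tc = t[self.nonroot]
        tp = t[parent[self.nonroot]]
        diff = tp - tc
        if np.any(diff <= 0.0):
            return -np.inf
        T_tot = float(diff.sum())

        a = (self.alpha * 2.0 * self.dem.n_e) if self.grow else 0.0
        t0 = self.dem.onset_internal
        t_int = t[self.internal_ids]
        order = np.argsort(t_int, kind="stable")
        t_ev = t_int[order]
        dk = np.ones(t_ev.size, dtype=np.int64)
        if self.struct:
            masks = self.demeset[self.internal_ids][order]
            demes_ev = np.where(
                self._popcount[masks] == 1, self._mask_to_deme[masks - 1], -1
            )
            lp = _structured_log_density(
                t_ev, dk, demes_ev, self.leaf_counts, self.props,
                self.t_split, a, t0,
            )
        else:
            lp = _panmictic_log_density(t_ev, dk, self.n, a, t0)
        if not np.isfinite(lp):
            return -np.inf

        # infinite-sites likelihood: sum log b_s + S log(theta/2) - theta*T/2
        if self.S > 0:
            b_sites = t[parent[self.site_nodes]] - t[self.site_nodes]
            lp += float(np.sum(np.log(b_sites))) + self.S * math.log(self.theta / 2.0)
        lp -= self.theta * T_tot / 2.0

        # parameter priors
        if self.grow:
            shape, rate = self.priors.growth_shape, self.gamma_rate
            lp += (shape - 1.0) * math.log(self.alpha) - rate * self.alpha \
                + shape * math.log(rate) - float(gammaln(shape))
        if self.struct:
            lp += float((self.priors.dirichlet_conc - 1.0) * np.sum(np.log(self.props)))
        return lp

    # -- MH bookkeeping -------------------------------------------------
    def _try(self, kind, log_hastings=0.0):
        self.n_prop[kind] = self.n_prop.get(kind, 0) + 1
        lp_new = self._log_posterior()
        if np.log(self.rng.uniform()) < lp_new - self.lp + log_hastings:
            self.lp = lp_new
            self.n_acc[kind] = self.n_acc.get(kind, 0) + 1
            return True
        return False

    # -- moves ----------------------------------------------------------
    def _move_time(self, v):
        t, rng = self.t, self.rng
        old = t[v]
        lo = max(t[self.child0[v]], t[self.child1[v]])
        p = self.parent[v]
        if p >= 0:
            hi = t[p]
            if hi <= lo:
                return
            t[v] = rng.uniform(lo, hi)
            lh = 0.0
        else:
            fac = math.exp(rng.uniform(-1.0, 1.0))
            t[v] = lo + (old - lo) * fac
            lh = math.log(fac)
        if not self._try("time", lh):
            t[v] = old

    def _move_rescale(self):
        rng = self.rng
        c = math.exp(rng.uniform(-self.rescale_step, self.rescale_step))
        old = self.t[self.internal_ids].copy()
        self.t[self.internal_ids] *= c
        lh = self.internal_ids.size * math.log(c)
        if not self._try("rescale", lh):
            self.t[self.internal_ids] = old

    def _move_swap(self, s):
        rng = self.rng
        items = self.sk.items[s]
        i = rng.integers(items.size)
        j = rng.integers(items.size - 1)
        if j >= i:
            j += 1
        a, b = int(items[i]), int(items[j])
        pa, pb = int(self.parent[a]), int(self.parent[b])
        if pa == pb:
            return
        lids = self.sk.local_ids[s]
        saved_demes = self.demeset[lids].copy() if self.struct else None

        def set_child(p, old, new):
            if self.child0[p] == old:
                self.child0[p] = new
            else:
                self.child1[p] = new

        set_child(pa, a, b)
        set_child(pb, b, a)
        self.parent[a], self.parent[b] = pb, pa
        if self.struct:
            for lid in lids:
                self.demeset[lid] = self.demeset[self.child0[lid]] | self.demeset[self.child1[lid]]
        if not self._try("swap"):
            set_child(pa, b, a)
            set_child(pb, a, b)
            self.parent[a], self.parent[b] = pa, pb
            if self.struct:
                self.demeset[lids] = saved_demes

    def _move_reresolve(self, s):
        rng = self.rng
        items = self.sk.items[s]
        lids = self.sk.local_ids[s]
        m = items.size
        saved_parent_items = self.parent[items].copy()
        saved_parent_lids = self.parent[lids].copy()
        saved_c0 = self.child0[lids].copy()
        saved_c1 = self.child1[lids].copy()
        saved_t = self.t[lids].copy()
        saved_demes = self.demeset[lids].copy() if self.struct else None

        top = int(self.sk.top_id[s])
        saved_top_parent = int(self.parent[top])
        self._resolve_topology(s)
        self.parent[top] = saved_top_parent

        lo = float(self.t[items].max())
        if saved_top_parent >= 0:
            hi = float(self.t[saved_top_parent])
            if hi <= lo:
                new_t = None
            else:
                new_t = np.sort(rng.uniform(lo, hi, size=m - 1))
            lh = 0.0
        else:
            lam = self.root_exp_rate
            new_t = lo + np.sort(rng.exponential(1.0 / lam, size=m - 1))
            # exponential proposal density ratio q(old)/q(new)
            lh = lam * (float(new_t.sum()) - float(saved_t.sum()))
        ok = new_t is not None
        if ok:
            self.t[lids] = new_t
            ok = self._try("reresolve", lh)
        if not ok:
            self.parent[items] = saved_parent_items
            self.parent[lids] = saved_parent_lids
            self.child0[lids] = saved_c0
            self.child1[lids] = saved_c1
            self.t[lids] = saved_t
            if self.struct:
                self.demeset[lids] = saved_demes

    def _move_theta(self):
        rng = self.rng
        old = self.theta
        new = old * math.exp(rng.uniform(-self.theta_step, self.theta_step))
        if not (self.priors.theta_lo < new < self.priors.theta_hi):
            self.n_prop["theta"] = self.n_prop.get("theta", 0) + 1
            return
        self.theta = new
        if not self._try("theta", math.log(new / old)):
            self.theta = old

    def _move_alpha(self):
        rng = self.rng
        old = self.alpha
        new = old * math.exp(rng.uniform(-self.alpha_step, self.alpha_step))
        self.alpha = new
        if not self._try("alpha", math.log(new / old)):
            self.alpha = old

    def _move_props(self):
        rng = self.rng
        i = rng.integers(self.beta)
        j = rng.integers(self.beta - 1)
        if j >= i:
            j += 1
        delta = rng.uniform(-self.prop_step, self.prop_step)
        if self.props[i] + delta <= 0 or self.props[j] - delta <= 0:
            self.n_prop["props"] = self.n_prop.get("props", 0) + 1
            return
        old = self.props.copy()
        self.props[i] += delta
        self.props[j] -= delta
        if not self._try("props"):
            self.props = old

    # -- sweeps ---------------------------------------------------------
    def sweep(self):
        rng = self.rng
        for v in rng.permutation(self.internal_ids):
            self._move_time(int(v))
        self._move_rescale()
        for s in self.sk.multifurcation_order():
            m = len(self.sk.items[s])
            for _ in range(1 + m // 4):
                self._move_swap(s)
            if m <= 10:
                self._move_reresolve(s)
        self._move_theta()
        if self.grow:
            self._move_alpha()
        if self.struct:
            self._move_props()

    def _adapt(self):
        def tune(step, kind, lo=1e-3, hi=5.0):
            prop = self.n_prop.get(kind, 0)
            if prop < 10:
                return step
            rate = self.n_acc.get(kind, 0) / prop
            fac = math.exp(0.5 * (rate - 0.3))
            return float(np.clip(step * fac, lo, hi))

        self.rescale_step = tune(self.rescale_step, "rescale")
        self.theta_step = tune(self.theta_step, "theta")
        if self.grow:
            self.alpha_step = tune(self.alpha_step, "alpha")
        if self.struct:
            self.prop_step = tune(self.prop_step, "props", lo=1e-3, hi=0.4)
        self.n_prop.clear()
        self.n_acc.clear()

    def snapshot(self) -> GeneTree:
        return GeneTree(
            self.parent.copy().astype(np.int32),
            self.t.copy(),
            self.n,
            demes=self.leaf_demes,
        )

    def run(self, n_samples, burn_in, thinning):
        trees: list[GeneTree] = []
        thetas = np.empty(n_samples)
        alphas = np.empty(n_samples) if self.grow else None
        props = np.empty((n_samples, self.beta)) if self.struct else None
        for i in range(burn_in):
            self.sweep()
            if (i + 1) % 25 == 0:
                self._adapt()
        self.n_prop.clear()
        self.n_acc.clear()
        for i in range(n_samples):
            for _ in range(thinning):
                self.sweep()
            trees.append(self.snapshot())
            thetas[i] = self.theta
            if self.grow:
                alphas[i] = self.alpha
            if self.struct:
                props[i] = self.props
        acc = {
            k: self.n_acc.get(k, 0) / v for k, v in self.n_prop.items() if v > 0
        }
        return trees, thetas, alphas, props, acc


# ----------------------------------------------------------------------
def mcmc_sample(
    measured,
    priors: PriorConfig | None = None,
    demography: DemographyModel | None = None,
    mode: str = "basic",
    n_samples: int = 1000,
    burn_in: int | None = None,
    thinning: int = 3,
    rng: np.random.Generator | None = None,
    leaf_demes=None,
) -> TreeSample:
    """Sample genealogies compatible with the measured sites.

    Parameters
    ----------
    measured
        :class:`HaplotypeMatrix` (or 0/1 array, haplotypes x sites)
        restricted to the directly measured sites of all study plus
        reference haplotypes.  Must be pairwise four-gamete compatible.
    mode
        ``basic``, ``growth``, ``structure`` or ``growth-structure`` --
        which demographic extension the coalescent prior carries.
    n_samples, burn_in, thinning
        Post-burn-in states are recorded every ``thinning`` sweeps; the
        default burn-in is 20% of the total chain length.
    leaf_demes
        Per-haplotype subpopulation labels (structure modes only).

    Returns a :class:`TreeSample` whose trees are ultrametric binary
    refinements of the perfect phylogeny, all compatible with every
    measured column.
    """
    if mode not in ("basic", "growth", "structure", "growth-structure"):
        raise ValueError(f"unknown demography mode {mode!r}")
    priors = PriorConfig() if priors is None else priors
    priors.validate()
    demography = DemographyModel() if demography is None else demography
    rng = np.random.default_rng() if rng is None else rng
    alleles = measured.alleles if isinstance(measured, HaplotypeMatrix) else measured
    if burn_in is None:
        burn_in = max(1, round(0.25 * n_samples * thinning))
    sampler = _RefinementSampler(alleles, demography, priors, mode, rng, leaf_demes)
    trees, thetas, alphas, props, acc = sampler.run(n_samples, burn_in, thinning)
    return TreeSample(
        trees=trees,
        thetas=thetas,
        alphas=alphas,
        subpop_props=props,
        settings={
            "mode": mode,
            "n_samples": n_samples,
            "burn_in": burn_in,
            "thinning": thinning,
        },
        acceptance=acc,
    )
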