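"""Phylogenetic signal statistics for a continuous trait.

Implements the two standard signal measures on a rooted tree with branch
lengths — Pagel's lambda (maximum-likelihood multiplier on the off-diagonal
Brownian covariance) and Blomberg's K (observed vs Brownian-expected ratio
of trait variance to phylogenetically corrected variance) — plus a
randomization test for trait conservatism of named clades (orders).

Trees are :class:`dendropy.Tree` objects; traits are mappings from tip
label to value.  Under Brownian motion a trait vector is multivariate
normal with covariance ``sigma^2 * C`` where ``C[i, j]`` is the shared
root-to-MRCA path length of tips i and j.  Pagel's transform rescales the
off-diagonal of ``C`` by lambda and leaves the diagonal unchanged, so
lambda = 0 is star-like independence and lambda = 1 full Brownian
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "SignalResult",
    "brownian_covariance",
    "pagels_lambda",
    "blombergs_K",
    "order_conservatism_test",
    "read_newick",
    "write_newick",
]


# ---------------------------------------------------------------------------
# tree plumbing
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; underscores in labels are literal."""
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write plain Newick (unquoted labels, decimal branch lengths)."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def brownian_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip-by-tip matrix of shared root-to-MRCA path lengths.

    Returns ``(labels, C)`` with ``C[i, i]`` the root-to-tip distance and
    ``C[i, j]`` the depth of the most recent common ancestor of tips i, j.
    Symmetric positive semi-definite by construction.
    """
    tips = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in tips]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique")
    idx = {id(lf): i for i, lf in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    # depth of every node (root edge length, if any, ignored)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            el = node.edge.length if node.edge.length is not None else 0.0
            if el < 0:
                raise ValueError("negative branch length")
            depth[id(node)] = depth[id(node.parent_node)] + el

    zero_terminal = any(
        (lf.edge.length or 0.0) == 0.0 for lf in tips if lf.parent_node is not None
    )
    if zero_terminal:
        warnings.warn(
            "zero-length terminal branches make the Brownian covariance "
            "singular; consider jittering branch lengths",
            stacklevel=2,
        )

    # postorder: leaf sets per child, pairwise MRCA depth at the joining node
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[id(node)]
            C[i, i] = depth[id(node)]
            below[id(node)] = [i]
        else:
            groups = [below.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        C[i, groups[b]] = d
                        C[np.asarray(groups[b]), i] = d
            below[id(node)] = [i for g in groups for i in g]
    return labels, C


def _match_traits(labels: Sequence[str], traits: Mapping[str, float]) -> np.ndarray:
    missing = [l for l in labels if l not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:10]}")
    return np.array([float(traits[l]) for l in labels])


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    statistic: float
    p_value: float
    n_tips: int
    method: str
    log_likelihood: float | None = None
    null_log_likelihood: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood with mu and sigma^2 profiled out analytically."""
    n = y.size
    cf = linalg.cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cf, ones)
    mu = (Vi1 @ y) / (Vi1 @ ones)
    r = y - mu
    Vir = linalg.cho_solve(cf, r)
    s2 = (r @ Vir) / n
    if s2 <= 0:
        raise FloatingPointError("degenerate profiled variance")
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def _lambda_upper_bound(C: np.ndarray, cap: float = 1.5) -> float:
    """Largest lambda in [1, cap] keeping C(lambda) positive-definite."""

    def pd(lam: float) -> bool:
        try:
            linalg.cho_factor(_lambda_cov(C, lam))
            return True
        except linalg.LinAlgError:
            return False

    if not pd(1.0):
        # fall back: shrink below 1 until PD
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if not pd(mid) else (lo, mid)
        return max(hi - 1e-6, 1e-6)
    if pd(cap):
        return cap
    lo, hi = 1.0, cap
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if pd(mid) else (lo, mid)
    return lo


def pagels_lambda(tree: dendropy.Tree, traits: Mapping[str, float]) -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio p-value.

    mu and sigma^2 are profiled analytically at each lambda; lambda is
    optimized by bounded scalar search on [0, lambda_max] (tolerance 1e-6),
    with lambda_max the largest value keeping the transformed covariance
    positive-definite (>= 1 on ultrametric trees).  p is the chi-squared
    (1 df) likelihood-ratio test against lambda = 0.
    """
    labels, C = brownian_covariance(tree)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 tips with trait values")
    y = _match_traits(labels, traits)
    if np.ptp(y) == 0:
        raise ValueError("constant trait: likelihood is degenerate")

    lam_max = _lambda_upper_bound(C)

    def nll(lam: float) -> float:
        try:
            return -_profile_loglik(y, _lambda_cov(C, lam))
        except (linalg.LinAlgError, FloatingPointError):
            return np.inf

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, lam_max), method="bounded", options={"xatol": 1e-6}
    )
    # bounded search can miss a boundary optimum in flat likelihoods
    cand = [(res.x, res.fun), (0.0, nll(0.0)), (lam_max, nll(lam_max))]
    lam_hat, nll_hat = min(cand, key=lambda t: t[1])
    ll_hat = -nll_hat
    ll0 = -nll(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(
        statistic=float(lam_hat),
        p_value=p,
        n_tips=n,
        method="pagels_lambda (profiled ML, bounded search)",
        log_likelihood=float(ll_hat),
        null_log_likelihood=float(ll0),
        extra={"lambda_max": lam_max},
    )


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def blombergs_K(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K = (MSE0/MSE) / E[MSE0/MSE | BM], where MSE0 is the mean squared
    deviation from the phylogenetically corrected mean, MSE the
    C^-1-weighted generalized mean squared error, and the Brownian
    expectation is (tr(C) - n / (1' C^-1 1)) / (n - 1).  The one-tailed
    p-value is the +1-smoothed fraction of tip permutations whose
    generalized error (variance of the phylogenetically whitened scores)
    is at most the observed one.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, C = brownian_covariance(tree)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 tips with trait values")
    y = _match_traits(labels, traits)
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "singular Brownian covariance; jitter zero-length branches"
        ) from err
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cf, ones)
    denom_1C1 = ones @ Ci1

    def gen_mse(vec: np.ndarray) -> tuple[float, float]:
        a0 = (Ci1 @ vec) / denom_1C1
        r = vec - a0
        mse0 = (r @ r) / (n - 1)
        mse = (r @ linalg.cho_solve(cf, r)) / (n - 1)
        return mse0, mse

    mse0_obs, mse_obs = gen_mse(y)
    if mse_obs <= 0:
        raise ValueError("constant trait: K undefined")
    expected = (np.trace(C) - n / denom_1C1) / (n - 1)
    K = (mse0_obs / mse_obs) / expected

    rng = np.random.default_rng(seed)
    Ci = linalg.cho_solve(cf, np.eye(n))  # reused across permutations
    count = 0
    for _ in range(n_perm):
        yp = y[rng.permutation(n)]
        a0 = (Ci1 @ yp) / denom_1C1
        r = yp - a0
        mse_p = (r @ (Ci @ r)) / (n - 1)
        if mse_p <= mse_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SignalResult(
        statistic=float(K),
        p_value=float(p),
        n_tips=n,
        method=f"blombergs_K ({n_perm} tip permutations)",
        extra={"mse0": mse0_obs, "mse": mse_obs, "expected_ratio": expected},
    )


# ---------------------------------------------------------------------------
# order-level conservatism
# ---------------------------------------------------------------------------

def order_conservatism_test(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
    order_map: Mapping[str, str],
    n_rand: int = 999,
    min_species: int = 50,
    seed: int | None = None,
) -> dict[str, dict]:
    """Two-tailed randomization test of order-level trait means.

    The observed mean of each order (average over its tips) is compared
    with ``n_rand`` random shuffles of the whole trait vector across all
    tips.  p = 2 * min(rank_low, rank_high) / (n_rand + 1), with inclusive
    ranks and a cap at 1.  Orders with fewer than ``min_species`` tips are
    reported but flagged ``untested``.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unmapped = [l for l in labels if l not in order_map]
    if unmapped:
        raise ValueError(f"order_map missing tips: {unmapped[:10]}")
    y = _match_traits(labels, traits)
    n = len(labels)
    orders: dict[str, np.ndarray] = {}
    for o in sorted(set(order_map[l] for l in labels)):
        members = np.array([i for i, l in enumerate(labels) if order_map[l] == o])
        if members.size:
            orders[o] = members

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_rand)])
    Y = y[perms]  # (n_rand, n)

    out: dict[str, dict] = {}
    for o, members in orders.items():
        obs = float(y[members].mean())
        if members.size < min_species:
            out[o] = {"mean": obs, "n_species": int(members.size), "p": None, "flag": "untested"}
            continue
        null = Y[:, members].mean(axis=1)
        # inclusive ranks with a float tolerance so exact ties count as ties
        tol = 1e-9 * max(1.0, abs(obs))
        r_low = int(np.sum(null <= obs + tol)) + 1
        r_high = int(np.sum(null >= obs - tol)) + 1
        p = min(1.0, 2.0 * min(r_low, r_high) / (n_rand + 1))
        sign = "higher" if obs > float(np.mean(y)) else "lower"
        out[o] = {
            "mean": obs,
            "n_species": int(members.size),
            "p": p,
            "flag": f"significant-{sign}" if p <= 0.05 else "ns",
        }
    return out
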