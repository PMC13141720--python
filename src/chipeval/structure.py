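"""Population-structure inference: PCA, neighbor-joining trees, admixture.

Three complementary views of structure from one genotype table:

* :func:`pca` -- Patterson-scaled principal components of the dosage
  matrix, with per-site mean imputation of missing genotypes.
* :func:`distance_matrix` + :func:`nj_tree` + :func:`bootstrap_support` --
  allele-sharing distances, Saitou-Nei neighbor joining, and site-resampling
  bootstrap support for internal edges.
* :class:`AdmixtureModel` -- a maximum-likelihood admixture model
  (genotypes binomial in f = Q P) fitted by monotone EM updates, with
  genotype-masking cross-validation over the number of components K
  (:func:`cv_error`).

The admixture model follows a Model/Results split: ``AdmixtureModel(gt,
K).fit(seed=...)`` returns :class:`AdmixtureResults` holding Q, P, the
log-likelihood path and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable

logger = logging.getLogger(__name__)

_EPS = 1e-6


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal-component scores and eigenvalues.

    ``scores`` has one row per sample and one column per component;
    ``means``/``scales`` are the per-site centring (2 p-hat) and scaling
    (sqrt(p-hat (1 - p-hat))) factors over the retained sites.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str]
    means: np.ndarray
    scales: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame(cols, index=self.sample_ids)


def pca(gt: GenotypeTable, n_components: int = 10) -> PCAResult:
    """Genotype PCA with Patterson scaling.

    Missing dosages are mean-imputed per site, sites are centred by 2 p-hat
    and scaled by sqrt(p-hat (1 - p-hat)) with p-hat the mean dosage / 2;
    fixed sites (p-hat 0 or 1) are dropped.  Scores are the leading left
    singular vectors scaled by their singular values; each component's sign
    is fixed by making its largest-magnitude site loading positive.
    """
    if gt.n_samples < 2 or gt.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 sites")
    X = gt.dosages.copy()
    p_hat = np.nanmean(X, axis=0) / 2.0
    keep = ~np.isnan(p_hat) & (p_hat > 0.0) & (p_hat < 1.0)
    if keep.sum() < n_components:
        raise ValueError(
            f"only {int(keep.sum())} informative sites for {n_components} components"
        )
    X = X[:, keep]
    p_hat = p_hat[keep]
    means = 2.0 * p_hat
    scales = np.sqrt(p_hat * (1.0 - p_hat))
    inds = np.where(np.isnan(X))
    X[inds] = np.take(means, inds[1])
    Z = (X - means) / scales

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n_components, len(S))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-magnitude loading positive per component
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * S
    eigenvalues = S**2 / (gt.n_samples - 1)
    return PCAResult(scores, eigenvalues, list(gt.sample_ids), means, scales)


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def distance_matrix(gt: GenotypeTable) -> pd.DataFrame:
    """Allele-sharing distance: mean over pairwise-complete sites of |g_i - g_j| / 2."""
    X = gt.dosages
    obs = ~np.isnan(X)
    counts = obs.astype(np.float64) @ obs.T.astype(np.float64)
    if np.any(counts[~np.eye(len(X), dtype=bool)] == 0):
        raise ValueError("a sample pair shares zero complete sites")
    ind = [(np.where(obs, X == v, False)).astype(np.float64) for v in (0.0, 1.0, 2.0)]
    diff = np.zeros_like(counts)
    for a in range(3):
        for b in range(3):
            if a != b:
                diff += abs(a - b) * (ind[a] @ ind[b].T)
    d = diff / (2.0 * counts)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=gt.sample_ids, columns=gt.sample_ids)


class TreeNode:
    """Node of an unrooted tree stored with a trifurcating root."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.length = float(length)
        self.support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class TreeResult:
    """Unrooted NJ tree with optional bootstrap supports on internal edges."""

    root: TreeNode
    leaf_names: list[str]
    n_clamped: int = 0  # negative branch lengths clamped to zero

    def newick(self) -> str:
        inner = ",".join(c._newick() for c in self.root.children)
        return f"({inner});"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def bipartitions(self) -> set[frozenset]:
        """Leaf bipartitions induced by internal edges, canonicalised.

        Each internal edge splits the leaves in two; the side not containing
        the lexicographically smallest leaf is the canonical representative.
        Trivial (single-leaf) splits are excluded.
        """
        ref = min(self.leaf_names)
        total = len(self.leaf_names)
        out = set()

        def walk(node: TreeNode):
            for child in node.children:
                side = frozenset(child.leaves())
                if 2 <= len(side) <= total - 2:
                    if ref in side:
                        side = frozenset(self.leaf_names) - side
                    out.add(side)
                walk(child)

        walk(self.root)
        return out


def nj_tree(dist: pd.DataFrame) -> TreeResult:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Repeatedly joins the pair minimising the Q-criterion (ties broken by
    smallest (row, column) index), computes branch lengths by the standard
    formulas, reduces the matrix, and finishes with a trifurcating root.
    Negative branch lengths are clamped to 0 (counted in ``n_clamped``).
    """
    D = dist.to_numpy(dtype=float).copy()
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 leaves")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")

    nodes = [TreeNode(name=l) for l in labels]
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        # smallest (i, j) on ties: row-major argmin over the upper triangle
        iu = np.triu_indices(n, 1)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    root = TreeNode()
    lens = [(d01 + d02 - d12) / 2.0, (d01 + d12 - d02) / 2.0, (d02 + d12 - d01) / 2.0]
    for node, ln in zip(nodes, lens):
        node.length = _clamp(ln)
        root.children.append(node)
    if clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", clamped)
    return TreeResult(root, labels, n_clamped=clamped)


def bootstrap_support(
    gt: GenotypeTable, n_replicates: int = 100, seed: int = 0
) -> TreeResult:
    """NJ tree with bootstrap support from site resampling.

    Sites are resampled with replacement ``n_replicates`` times (seeded);
    the support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same leaf bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = nj_tree(distance_matrix(gt))
    target = point.bipartitions()
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, gt.n_variants, size=gt.n_variants)
        rep = nj_tree(distance_matrix(gt.take_variants(idx)))
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1

    ref = min(point.leaf_names)
    total = len(point.leaf_names)

    def annotate(node: TreeNode):
        for child in node.children:
            side = frozenset(child.leaves())
            if 2 <= len(side) <= total - 2:
                key = side if ref not in side else frozenset(point.leaf_names) - side
                child.support = 100.0 * hits[key] / n_replicates
            annotate(child)

    annotate(point.root)
    return point


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------

class AdmixtureModel:
    """Maximum-likelihood admixture model for diploid dosages.

    Each individual i carries ancestry proportions ``q_i`` over K source
    populations with allele frequencies ``p_k``; the dosage g_ij is
    binomial(2, f_ij) with f_ij = sum_k q_ik p_kj.  Missing entries are
    excluded from the likelihood.  :meth:`fit` maximises the log-likelihood
    by alternating EM updates of Q and P, which are monotone in the
    log-likelihood.
    """

    def __init__(self, data, K: int):
        if isinstance(data, GenotypeTable):
            self.sample_ids = list(data.sample_ids)
            G = data.dosages
        else:
            G = np.asarray(data, dtype=float)
            self.sample_ids = [f"s{i}" for i in range(G.shape[0])]
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > G.shape[0]:
            raise ValueError(f"K={K} exceeds the number of samples {G.shape[0]}")
        self.G = G
        self.K = int(K)
        self.mask = ~np.isnan(G)
        self.G0 = np.where(self.mask, G, 0.0)

    @classmethod
    def from_genotypes(cls, gt: GenotypeTable, K: int) -> "AdmixtureModel":
        return cls(gt, K)

    def loglike(self, Q: np.ndarray, P: np.ndarray) -> float:
        F = np.clip(Q @ P, _EPS, 1 - _EPS)
        ll = self.G0 * np.log(F) + (2.0 - self.G0) * np.log(1.0 - F)
        return float(ll[self.mask].sum())

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 2000,
        tol: float = 1e-4,
    ) -> "AdmixtureResults":
        """Fit by EM; stops when the log-likelihood gain drops below ``tol``."""
        rng = np.random.default_rng(seed)
        N, M = self.G.shape
        K = self.K
        Q = rng.uniform(0.5, 1.5, size=(N, K))
        Q /= Q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            pooled = np.nansum(self.G0, axis=0) / np.maximum(
                2.0 * self.mask.sum(axis=0), 1.0
            )
        P = np.clip(
            pooled[None, :] + rng.uniform(-0.1, 0.1, size=(K, M)), _EPS, 1 - _EPS
        )

        W = self.mask.astype(float)
        G0 = self.G0
        G2 = np.where(self.mask, 2.0 - G0, 0.0)
        J2 = 2.0 * W.sum(axis=1)  # alleles observed per sample
        path = [self.loglike(Q, P)]
        converged = False
        for _ in range(max_iter):
            F = np.clip(Q @ P, _EPS, 1 - _EPS)
            RA = G0 / F            # observed-alt weight, zero where missing
            RB = G2 / (1.0 - F)    # observed-ref weight
            # E-step fractions fold into multiplicative updates
            A = RA @ P.T           # N x K
            B = RB @ (1.0 - P).T
            Q_new = Q * (A + B) / J2[:, None]
            Q_new /= Q_new.sum(axis=1, keepdims=True)

            F = np.clip(Q_new @ P, _EPS, 1 - _EPS)
            RA = G0 / F
            RB = G2 / (1.0 - F)
            num = P * (Q_new.T @ RA)      # K x M, alt-allele expected counts
            den = num + (1.0 - P) * (Q_new.T @ RB)
            with np.errstate(invalid="ignore", divide="ignore"):
                P_new = np.where(den > 0, num / den, P)
            P_new = np.clip(P_new, _EPS, 1 - _EPS)

            Q, P = Q_new, P_new
            path.append(self.loglike(Q, P))
            if path[-1] - path[-2] < tol:
                converged = True
                break
        return AdmixtureResults(
            model=self,
            Q=Q,
            P=P,
            loglike=path[-1],
            loglike_path=np.asarray(path),
            converged=converged,
            seed=seed,
        )


@dataclass
class AdmixtureResults:
    """Fitted admixture model: ancestry proportions and source frequencies."""

    model: AdmixtureModel
    Q: np.ndarray
    P: np.ndarray
    loglike: float
    loglike_path: np.ndarray
    converged: bool
    seed: int
    cv_error: float | None = None

    @property
    def K(self) -> int:
        return self.model.K

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q,
            index=self.model.sample_ids,
            columns=[f"K{i + 1}" for i in range(self.K)],
        )

    def predict_dosage(self) -> np.ndarray:
        """Expected dosage 2 f_ij under the fitted model."""
        return 2.0 * (self.Q @ self.P)

    def summary(self) -> str:
        lines = [
            "Admixture model fit",
            "===================",
            f"samples:        {self.Q.shape[0]}",
            f"sites:          {self.P.shape[1]}",
            f"K:              {self.K}",
            f"log-likelihood: {self.loglike:.4f}",
            f"iterations:     {len(self.loglike_path) - 1}",
            f"converged:      {self.converged}",
        ]
        if self.cv_error is not None:
            lines.append(f"CV error:       {self.cv_error:.6f}")
        mean_q = self.Q.mean(axis=0)
        lines.append(
            "mean ancestry:  " + "  ".join(f"{v:.3f}" for v in mean_q)
        )
        return "\n".join(lines)


def _make_folds(mask: np.ndarray, n_folds: int, rng: np.random.Generator, max_retries: int = 10):
    """Partition observed entries into folds, keeping every row/column covered.

    A fold is rejected if masking it would leave some sample or site with no
    observed entry; the partition is redrawn up to ``max_retries`` times.
    """
    obs = np.argwhere(mask)
    for _ in range(max_retries):
        perm = rng.permutation(len(obs))
        folds = np.array_split(obs[perm], n_folds)
        ok = True
        for fold in folds:
            rem_rows = mask.sum(axis=1).copy()
            rem_cols = mask.sum(axis=0).copy()
            np.subtract.at(rem_rows, fold[:, 0], 1)
            np.subtract.at(rem_cols, fold[:, 1], 1)
            if (rem_rows < 1).any() or (rem_cols < 1).any():
                ok = False
                break
        if ok:
            return folds
    raise ValueError("could not partition entries without emptying a sample or site")


def cv_error(
    gt: GenotypeTable | np.ndarray,
    K_values=range(1, 7),
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Genotype-masking cross-validation error for each candidate K.

    Non-missing entries are split into ``n_folds`` masks; per fold the model
    is refitted without the held-out entries and each masked dosage g is
    predicted as 2 f; the fold error is the RMSE of (g - 2 f).  The returned
    table has one row per K with the fold-mean error; the optimum is the
    argmin row.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    G = gt.dosages if isinstance(gt, GenotypeTable) else np.asarray(gt, dtype=float)
    mask = ~np.isnan(G)
    ss = np.random.SeedSequence(seed)
    fold_ss, fit_ss = ss.spawn(2)
    folds = _make_folds(mask, n_folds, np.random.default_rng(fold_ss))
    fit_seeds = fit_ss.generate_state(len(list(K_values)) * n_folds) % (2**31)

    rows = []
    s = 0
    for K in K_values:
        errs = []
        for fold in folds:
            G_train = G.copy()
            G_train[fold[:, 0], fold[:, 1]] = np.nan
            res = AdmixtureModel(G_train, K).fit(
                seed=int(fit_seeds[s]), max_iter=max_iter, tol=tol
            )
            s += 1
            pred = res.predict_dosage()[fold[:, 0], fold[:, 1]]
            truth = G[fold[:, 0], fold[:, 1]]
            errs.append(float(np.sqrt(np.mean((truth - pred) ** 2))))
        rows.append({"K": int(K), "cv_error": float(np.mean(errs))})
    out = pd.DataFrame(rows).set_index("K")
    out.attrs["best_K"] = int(out["cv_error"].idxmin())
    return out
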