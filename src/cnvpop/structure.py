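"""Population structure on CNVR genotypes.

CNVR copy states are first recoded to biallelic dosages (0/1/2 copies of the
variant allele): at a loss region the dosage is ``2 - copy`` and at a gain
region ``copy - 2`` (clipped to [0, 2]); a mixed region contributes two
pseudo-loci, one per allele.  On the dosage matrix the module computes

* identity-by-state individual distances and Weir-Cockerham F_ST breed
  distances,
* a neighbor-joining tree (Saitou-Nei agglomeration, deterministic
  tie-breaks, Newick output) that reconstructs additive metrics exactly,
* PCA with the variance-standardized genotype convention (center by ``2p``,
  scale by ``sqrt(2p(1-p))``) and percent variance explained per component,
* the maximum-likelihood admixture model ``g_il ~ Binomial(2, sum_k Q_ik
  F_kl)`` fitted by EM (monotone in log-likelihood, multiple seeded
  restarts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from .cnvr import CnvrGenotypes

__all__ = [
    "BiallelicMatrix",
    "PcaResult",
    "AdmixtureEM",
    "recode_biallelic",
    "distance_matrix",
    "nj_tree",
    "to_newick",
    "tree_distances",
    "pca",
    "admixture_em",
    "align_q",
]


@dataclass
class BiallelicMatrix:
    """Individuals x loci variant-allele dosages in {0, 1, 2}."""

    sample_ids: List[str]
    dosages: np.ndarray  # (N, L) int
    loci: pd.DataFrame  # columns: locus_id, source_cnvr, allele
    breed_labels: Optional[List[str]] = None

    @property
    def freqs(self) -> np.ndarray:
        """Per-locus variant-allele frequency p_hat = sum(g) / 2n."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def monomorphic(self) -> np.ndarray:
        p = self.freqs
        return (p == 0.0) | (p == 1.0)


def recode_biallelic(geno: CnvrGenotypes) -> BiallelicMatrix:
    """Recode copy states to dosages; mixed CNVRs become two pseudo-loci."""
    cols: List[np.ndarray] = []
    rows: List[dict] = []
    for j, r in enumerate(geno.cnvrs):
        states = geno.states[:, j].astype(int)
        if r.type in ("loss", "mixed"):
            cols.append(np.clip(2 - states, 0, 2))
            rows.append(dict(locus_id=f"{r.id}_loss", source_cnvr=r.id, allele="loss"))
        if r.type in ("gain", "mixed"):
            cols.append(np.clip(states - 2, 0, 2))
            rows.append(dict(locus_id=f"{r.id}_gain", source_cnvr=r.id, allele="gain"))
    if not cols:
        dosages = np.zeros((len(geno.sample_ids), 0), dtype=int)
    else:
        dosages = np.column_stack(cols)
    return BiallelicMatrix(
        sample_ids=list(geno.sample_ids),
        dosages=dosages,
        loci=pd.DataFrame(rows, columns=["locus_id", "source_cnvr", "allele"]),
        breed_labels=list(geno.breed_labels),
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(
    mat: BiallelicMatrix, mode: str = "ibs_individual"
) -> Tuple[List[str], np.ndarray]:
    """Pairwise distances between individuals (IBS) or breeds (F_ST).

    ibs_individual: ``d_ij = mean_l |g_il - g_jl| / 2`` (1 - IBS similarity).
    fst_population: pairwise multi-locus Weir-Cockerham F_ST (ratio of sums),
    clamped at 0.
    """
    G = mat.dosages
    if G.shape[1] == 0:
        raise ValueError("no loci")
    if mode == "ibs_individual":
        labels = list(mat.sample_ids)
        diff = np.abs(G[:, None, :] - G[None, :, :]).mean(axis=2) / 2.0
        return labels, diff.astype(float)
    if mode == "fst_population":
        from .selscan import wc_fst_components, weighted_fst

        if mat.breed_labels is None:
            raise ValueError("breed labels required for fst_population distances")
        labels = sorted(set(mat.breed_labels))
        if len(labels) < 2:
            raise ValueError("need at least two breeds")
        b = np.asarray(mat.breed_labels)
        D = np.zeros((len(labels), len(labels)))
        for i, j in itertools.combinations(range(len(labels)), 2):
            groups = np.where(b == labels[i], 0, np.where(b == labels[j], 1, -1))
            keep = groups >= 0
            tab = wc_fst_components(G[keep], groups[keep])
            fst = weighted_fst(tab)
            D[i, j] = D[j, i] = max(0.0, fst)
        return labels, D
    raise ValueError(f"unknown distance mode {mode!r}")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels: Sequence[str], D: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimising ``Q_ij = (n-2) d_ij - r_i - r_j`` is joined (ties go
    to the smallest index pair); branch lengths use the standard rate
    correction and are clamped at 0.  On an additive matrix the path metric
    of the output reproduces the input exactly.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes: List[TreeNode] = [TreeNode(name=str(lbl)) for lbl in labels]
    Dw = D.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(Dw[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * Dw[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * Dw[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = Dw[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node
        Dw = np.pad(Dw, ((0, 1), (0, 1)))
        u = Dw.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            Dw[u, k] = Dw[k, u] = 0.5 * (Dw[i, k] + Dw[j, k] - Dw[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    d = Dw[i, j]
    nodes[i].length = d / 2.0
    nodes[j].length = d / 2.0
    root = TreeNode(children=[nodes[i], nodes[j]])
    root.length = None
    return root


def to_newick(tree: TreeNode, precision: int = 6) -> str:
    """Newick with fixed-precision branch lengths."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            core = node.name or ""
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                core += node.name
        if node.length is not None:
            core += f":{node.length:.{precision}f}"
        return core

    return fmt(tree) + ";"


def tree_distances(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the given label order."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    out = np.zeros((len(labels), len(labels)))
    for a, la in enumerate(labels):
        for b, lb in enumerate(labels):
            if a != b:
                out[a, b] = dm[ids.index(str(la)), ids.index(str(lb))]
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Sample coordinates, eigenvalues and percent variance explained."""

    coords: np.ndarray  # (N, K)
    eigenvalues: np.ndarray  # descending, >= 0
    pct_variance: np.ndarray  # sums to 100
    n_monomorphic_dropped: int


def pca(mat: BiallelicMatrix) -> PcaResult:
    """Variance-standardized genotype PCA.

    Monomorphic loci are dropped; genotypes are centered by ``2p`` and scaled
    by ``sqrt(2p(1-p))``; the eigendecomposition of the sample covariance
    ``Z Z^T / L`` gives coordinates ``U sqrt(lambda)``.  Sign convention: the
    largest-magnitude entry of each eigenvector is positive.
    """
    keep = ~mat.monomorphic
    if not keep.any():
        raise ValueError("all loci are monomorphic")
    G = mat.dosages[:, keep].astype(float)
    p = mat.freqs[keep]
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    L = Z.shape[1]
    C = Z @ Z.T / L
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(vals)[None, :]
    total = vals.sum()
    pct = 100.0 * vals / total if total > 0 else np.zeros_like(vals)
    return PcaResult(
        coords=coords,
        eigenvalues=vals,
        pct_variance=pct,
        n_monomorphic_dropped=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

class AdmixtureEM:
    """Maximum-likelihood admixture model fitted by EM.

    Model: dosage ``g_il ~ Binomial(2, pi_il)`` with ``pi_il = sum_k Q_ik
    F_kl``; ``Q`` (n x K ancestry proportions) and ``F`` (K x L ancestral
    allele frequencies) maximise ``sum_il g log pi + (2 - g) log(1 - pi)``.
    EM updates are multiplicative and monotone in the log-likelihood; the
    best of ``n_init`` seeded random restarts is kept.

    Fitted attributes: ``Q_``, ``F_``, ``loglik_``, ``loglik_trace_``,
    ``n_iter_``.
    """

    F_EPS = 1e-6

    def __init__(
        self,
        n_components: int = 2,
        n_init: int = 5,
        max_iter: int = 2000,
        tol: float = 1e-6,
        random_state: int | None = None,
    ) -> None:
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _loglik(self, G: np.ndarray, pi: np.ndarray) -> float:
        pi = np.clip(pi, self.F_EPS, 1 - self.F_EPS)
        return float((G * np.log(pi) + (2 - G) * np.log1p(-pi)).sum())

    def _run(self, G: np.ndarray, rng: np.random.Generator):
        n, L = G.shape
        K = self.n_components
        Q = rng.dirichlet(np.ones(K), size=n)
        phat = G.mean(axis=0) / 2.0
        F = np.clip(
            phat[None, :] + rng.uniform(-0.1, 0.1, size=(K, L)),
            self.F_EPS,
            1 - self.F_EPS,
        )
        trace: List[float] = []
        ll = -np.inf
        for it in range(self.max_iter):
            pi = np.clip(Q @ F, self.F_EPS, 1 - self.F_EPS)
            A = G / pi  # (n, L)
            B = (2 - G) / (1 - pi)
            # responsibilities summed over loci / individuals
            Q_new = Q * ((A @ F.T) + (B @ (1 - F).T)) / (2 * L)
            num = F * (Q.T @ A)  # (K, L): sum_i g r
            den = num + (1 - F) * (Q.T @ B)
            F_new = np.clip(num / np.where(den == 0, 1.0, den), self.F_EPS, 1 - self.F_EPS)
            Q = Q_new / Q_new.sum(axis=1, keepdims=True)
            F = F_new
            ll_new = self._loglik(G, Q @ F)
            trace.append(ll_new)
            if ll_new - ll < self.tol and it > 0:
                ll = ll_new
                break
            ll = ll_new
        return Q, F, ll, trace

    def fit(self, G: np.ndarray) -> "AdmixtureEM":
        G = np.asarray(G, dtype=float)
        if np.any((G < 0) | (G > 2)):
            raise ValueError("dosages must lie in {0, 1, 2}")
        n = G.shape[0]
        if self.n_components > n:
            raise ValueError("more ancestral components than individuals")
        root = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            rng = np.random.default_rng(root.integers(2**31))
            Q, F, ll, trace = self._run(G, rng)
            if best is None or ll > best[2]:
                best = (Q, F, ll, trace)
        self.Q_, self.F_, self.loglik_, self.loglik_trace_ = best
        self.n_iter_ = len(self.loglik_trace_)
        return self

    def get_params(self, deep: bool = True) -> dict:
        return dict(
            n_components=self.n_components,
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )

    def set_params(self, **params) -> "AdmixtureEM":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def admixture_em(
    mat: BiallelicMatrix,
    K: int,
    seed: int | None = None,
    restarts: int = 5,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureEM:
    """Fit the admixture model on a dosage matrix; returns the fitted object."""
    model = AdmixtureEM(
        n_components=K, n_init=restarts, max_iter=max_iter, tol=tol, random_state=seed
    )
    return model.fit(mat.dosages)


def align_q(Q_hat: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated ancestry columns to best match the truth (RMSE)."""
    K = Q_hat.shape[1]
    best = None
    for perm in itertools.permutations(range(K)):
        rmse = float(np.sqrt(((Q_hat[:, perm] - Q_true) ** 2).mean()))
        if best is None or rmse < best[0]:
            best = (rmse, perm)
    return Q_hat[:, best[1]]
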