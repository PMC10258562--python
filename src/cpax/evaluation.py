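"""Scoring harness: R2 on condition means/variances, DEG subsets, random and
linear baselines, gene-wise distributional distance, clustering agreement.

Counterfactual predictions are scored as pseudobulk: the R2 (coefficient of
determination) between per-gene means (and unbiased variances) of predicted
versus real cells of a condition, on all genes and on the top-N
differentially expressed genes (rank-sum test versus control).  The random
baseline scores a random training subset against the target condition; the
linear baseline for a combination is the average of the two single-
perturbation pseudobulks, (x_A + x_B)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as skm

from .data import ExpressionDataset

__all__ = [
    "ConditionScore",
    "probe_disentanglement",
    "r2_score",
    "select_top_degs",
    "random_baseline",
    "linear_baseline",
    "gene_wise_wasserstein",
    "clustering_agreement",
    "condition_moments",
]


@dataclass
class ConditionScore:
    condition_id: str
    r2_mean_all: float
    r2_var_all: float
    r2_mean_degs: float
    r2_var_degs: float
    n_cells_real: int
    wasserstein_mean: float


def probe_disentanglement(model, ds: ExpressionDataset, seed: int = 0) -> tuple[float, float, float]:
    """Accuracy of freshly trained logistic-regression probes predicting the
    applied perturbation from (a) the learned basal states and (b) the
    composed latent states, plus the majority-class chance rate.

    A well-disentangled model keeps (a) near chance while (b) stays high:
    the perturbation signal lives in the dictionaries, not the basal space.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labels = model.perturbation_targets(ds.doses)
    if labels.ndim == 2:  # multilabel indicator -> one class per applied-set
        labels = np.unique(labels, axis=0, return_inverse=True)[1]
    basal = model.encode_basal(ds.X)
    cov = {k: ds.covariate_indices(k) for k in ds.covariate_schemas}
    composed = model.compose(basal, model.scale_doses(ds.doses), cov)
    chance = float(np.max(np.bincount(labels)) / len(labels))
    accs = []
    for rep in (basal, composed):
        Xtr, Xte, ytr, yte = train_test_split(
            rep, labels, test_size=0.3, random_state=seed, stratify=labels
        )
        probe = LogisticRegression(max_iter=1000).fit(Xtr, ytr)
        accs.append(float(probe.score(Xte, yte)))
    return accs[0], accs[1], chance


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (undefined for
    constant y_true)."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValueError("r2_score needs two equal-length vectors of length >= 2")
    if np.ptp(y_true) == 0:
        raise ValueError("r2_score undefined for constant y_true")
    return float(skm.r2_score(y_true, y_pred))


def condition_moments(ds: ExpressionDataset, cid: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gene mean and unbiased variance over the cells of one condition."""
    idx = ds.cells_of(cid)
    if idx.size == 0:
        raise ValueError(f"condition {cid!r} has no cells")
    X = ds.X[idx]
    var = X.var(axis=0, ddof=1) if idx.size > 1 else np.zeros(ds.n_genes)
    return X.mean(axis=0), var, int(idx.size)


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized two-sample Wilcoxon rank-sum statistic with tie correction."""
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:
        return 0.0
    return float((u1 - mu) / np.sqrt(sigma2))


def select_top_degs(ds: ExpressionDataset, condition: str, control: str, n: int) -> np.ndarray:
    """Indices of the top-n genes by |rank-sum z| condition vs control,
    deterministic tie-break by gene index."""
    if n > ds.n_genes:
        raise ValueError(f"n={n} exceeds gene count {ds.n_genes}")
    idx_c = ds.cells_of(condition)
    idx_0 = ds.cells_of(control)
    for name, idx in ((condition, idx_c), (control, idx_0)):
        if idx.size < 2:
            raise ValueError(f"condition {name!r} needs >= 2 cells")
    Xc, X0 = ds.X[idx_c], ds.X[idx_0]
    z = np.array([_ranksum_z(Xc[:, g], X0[:, g]) for g in range(ds.n_genes)])
    order = np.lexsort((np.arange(ds.n_genes), -np.abs(z)))
    return order[:n]


def random_baseline(
    ds: ExpressionDataset, target_condition: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean/variance of a random training subset matched in size to
    the target condition (capped at the train split size)."""
    if ds.split is None or not np.any(ds.split == "train"):
        raise ValueError("empty train split")
    train_idx = np.flatnonzero(ds.split == "train")
    n_target = ds.cells_of(target_condition).size
    if n_target == 0:
        raise ValueError(f"condition {target_condition!r} has no cells")
    rng = np.random.default_rng(seed)
    sub = rng.choice(train_idx, size=min(n_target, train_idx.size), replace=False)
    X = ds.X[sub]
    var = X.var(axis=0, ddof=1) if sub.size > 1 else np.zeros(ds.n_genes)
    return X.mean(axis=0), var


def linear_baseline(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Combination baseline: the average of two single-perturbation pseudobulks."""
    mean_a = np.asarray(mean_a, dtype=np.float64)
    mean_b = np.asarray(mean_b, dtype=np.float64)
    if mean_a.shape != mean_b.shape:
        raise ValueError("pseudobulk vectors must have equal length")
    return (mean_a + mean_b) / 2.0


def gene_wise_wasserstein(real_cells: np.ndarray, pred_samples: np.ndarray) -> float:
    """Mean over genes of the 1-D Wasserstein-1 distance between the empirical
    per-gene distributions of real and predicted cells."""
    real = np.atleast_2d(np.asarray(real_cells, dtype=np.float64))
    pred = np.atleast_2d(np.asarray(pred_samples, dtype=np.float64))
    if real.size == 0 or pred.size == 0:
        raise ValueError("empty sample matrix")
    if real.shape[1] != pred.shape[1]:
        raise ValueError("gene dimension mismatch")
    return float(
        np.mean(
            [stats.wasserstein_distance(real[:, g], pred[:, g]) for g in range(real.shape[1])]
        )
    )


def clustering_agreement(
    embeddings: np.ndarray,
    labels: np.ndarray,
    k_grid: list[int] | None = None,
    resolution_grid: list[float] | None = None,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Leiden clustering of a kNN graph over a (k, resolution) grid; returns
    (best NMI vs labels, silhouette, homogeneity) at the NMI optimum."""
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two distinct labels")
    k_grid = k_grid or [3, 4, 5, 6, 7, 8, 9, 10]
    resolution_grid = resolution_grid or [0.3, 0.4, 0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 1.0]
    n = embeddings.shape[0]
    if n <= min(k_grid):
        raise ValueError(f"{n} conditions is fewer than the smallest k={min(k_grid)}")
    best = (-np.inf, None)
    for k in k_grid:
        if k >= n:
            continue
        adj = kneighbors_graph(embeddings, n_neighbors=k, mode="connectivity")
        adj = adj.maximum(adj.T).tocoo()
        graph = igraph.Graph(
            n=n, edges=list(zip(adj.row.tolist(), adj.col.tolist())), directed=False
        ).simplify()
        for res in resolution_grid:
            part = leidenalg.find_partition(
                graph,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=res,
                seed=seed,
            )
            clusters = np.asarray(part.membership)
            nmi = skm.normalized_mutual_info_score(labels, clusters)
            if nmi > best[0]:
                best = (nmi, clusters)
    nmi, clusters = best
    homogeneity = float(skm.homogeneity_score(labels, clusters))
    if len(set(clusters.tolist())) > 1:
        silhouette = float(skm.silhouette_score(embeddings, clusters))
    else:
        silhouette = float("nan")
    return float(nmi), silhouette, homogeneity
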