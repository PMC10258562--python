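"""Counterfactual prediction by embedding swap, and distance-based uncertainty.

A trained model answers "what would this cell's expression look like under
dose vector d' instead of the observed one" by encoding the cell's basal
state, recombining it with the *target* condition's scaled-dose and
covariate embeddings, and decoding.  Swapping to the observed condition
reproduces the model's reconstruction exactly.

Condition-level uncertainty is the minimum distance between the queried
condition's basal-free dictionary embedding

    z_comb = V_pert @ [f_1(d'_1) ... f_M(d'_M)] + sum_j V_cov[j][:, c_j]

and the embeddings of all training conditions, under both the cosine and
the euclidean distance (the embeddings are not normalized, so the two
orderings differ: cosine compares orientation, euclidean also magnitude).
A condition seen in training has uncertainty exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset, parse_condition_id
from .model import CPAModel, GaussianPrediction

__all__ = [
    "CounterfactualQuery",
    "UncertaintyScore",
    "predict_counterfactual",
    "predict_condition",
    "condition_embedding",
    "uncertainty",
    "training_conditions",
]


@dataclass
class CounterfactualQuery:
    """One cell's expression, its covariates, and the target dose vector."""

    x: np.ndarray
    cov_idx: dict[str, int]
    d_prime: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.d_prime = np.asarray(self.d_prime, dtype=np.float64)
        if np.any(self.d_prime < 0):
            raise ValueError("target doses must be >= 0")


@dataclass
class UncertaintyScore:
    u_cosine: float
    u_euclidean: float
    nearest_condition: str


def predict_counterfactual(model: CPAModel, q: CounterfactualQuery) -> GaussianPrediction:
    """Encode basal state, swap in the target condition, decode."""
    basal = model.encode_basal(q.x)
    scaled = model.scale_doses(q.d_prime)
    cov = {k: np.asarray([v]) for k, v in q.cov_idx.items()}
    z = model.compose(basal, scaled, cov)
    return model.decode_gaussian(z)


def predict_condition(
    model: CPAModel,
    cells: np.ndarray,
    cov_idx: dict[str, np.ndarray],
    d_prime: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, GaussianPrediction]:
    """Counterfactuals for a batch of cells sharing covariates; returns the
    across-cell mean of predicted means, mean of predicted variances, and
    the per-cell predictions."""
    cells = np.atleast_2d(np.asarray(cells, dtype=np.float64))
    if cells.shape[0] == 0:
        raise ValueError("empty cell batch")
    cov = {}
    for key, idx in cov_idx.items():
        idx = np.broadcast_to(np.atleast_1d(np.asarray(idx, dtype=np.int64)), (cells.shape[0],))
        if len(set(idx.tolist())) > 1:
            raise ValueError(f"mixed covariate levels for {key!r} in one condition batch")
        cov[key] = idx
    basal = model.encode_basal(cells)
    scaled = model.scale_doses(np.tile(np.asarray(d_prime, dtype=np.float64), (cells.shape[0], 1)))
    pred = model.decode_gaussian(model.compose(basal, scaled, cov))
    return pred.mean.mean(axis=0), pred.variance.mean(axis=0), pred


def condition_embedding(
    model: CPAModel, d: np.ndarray, cov_idx: dict[str, int]
) -> np.ndarray:
    """Basal-free dictionary embedding of a condition (no encoder involved)."""
    scaled = model.scale_doses(np.asarray(d, dtype=np.float64))
    cov = {k: np.asarray([v]) for k, v in cov_idx.items()}
    return model.compose(np.zeros(model.latent_dim), scaled, cov)


def _cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 0.0  # identical vectors: distance axiom, exact
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 1.0  # zero-norm embedding treated as orthogonal-equivalent
    return float(1.0 - np.dot(a, b) / (na * nb))


def training_conditions(ds: ExpressionDataset) -> list[str]:
    """Sorted unique condition keys of the train split (whole dataset if unsplit)."""
    cids = ds.condition_ids
    if ds.split is not None:
        cids = cids[ds.split == "train"]
    return sorted(set(cids))


def _cov_level_indices(model: CPAModel, cov_values: dict[str, str]) -> dict[str, int]:
    out = {}
    for key, levels in model.covariate_schemas.items():
        value = cov_values[key]
        if value not in levels:
            raise ValueError(f"covariate level {value!r} unseen in training for {key!r}")
        out[key] = levels.index(value)
    return out


def uncertainty(
    model: CPAModel,
    query: tuple[np.ndarray, dict[str, int]],
    train_condition_ids: list[str],
) -> UncertaintyScore:
    """Minimum cosine/euclidean distance from the query condition's embedding
    to the training-condition embedding set; the arg-min (euclidean) key is
    reported as the nearest condition."""
    if not train_condition_ids:
        raise ValueError("training condition set is empty")
    d, cov_idx = query
    zq = condition_embedding(model, d, cov_idx)
    cov_keys = list(model.covariate_schemas)
    best_cos, best_euc, nearest = np.inf, np.inf, None
    for cid in train_condition_ids:
        d_t, cov_t = parse_condition_id(cid, model.perturbation_names, cov_keys)
        zt = condition_embedding(model, d_t, _cov_level_indices(model, cov_t))
        cos = _cosine_distance(zq, zt)
        euc = float(np.linalg.norm(zq - zt))
        best_cos = min(best_cos, cos)
        if euc < best_euc:
            best_euc, nearest = euc, cid
    return UncertaintyScore(u_cosine=best_cos, u_euclidean=best_euc, nearest_condition=nearest)
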