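"""Pairwise genetic-interaction analysis of measured or predicted conditions.

For a gene pair (a, b), expression deltas versus control (delta_a, delta_b,
delta_ab, per-gene condition mean minus control mean) are summarized by the
intercept-free regression

    delta_ab = c1 * delta_a + c2 * delta_b

and a set of distance-correlation similarities.  Rule-based thresholds on
these metrics suggest an interaction mode (epistasis, potentiation, strong
synergy, additivity, redundancy); when zero or several rules match, no mode
is assigned.

Note on thresholds: the similarity rules are phrased as dissimilarity
exceeding a threshold; since dcor lies in [0, 1], "abs(dcor) - 1 > t" is
read as |dcor - 1| > t (i.e. dcor < 1 - t), and the additive band on the
coefficient magnitude is the two-sided |magnitude - 1| < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd

from .counterfactual import predict_condition, training_conditions, uncertainty
from .data import ExpressionDataset, condition_id, parse_condition_id
from .model import CPAModel

__all__ = [
    "DeltaProfiles",
    "InteractionMetrics",
    "InteractionMode",
    "MODE_NAMES",
    "compute_deltas",
    "fit_pair_regression",
    "distance_correlation",
    "interaction_metrics",
    "classify_mode",
    "count_missing_pairs",
    "impute_all_pairs",
]

MODE_NAMES = (
    "epistatic",
    "potentiation",
    "strong_synergy_similar",
    "strong_synergy_different",
    "additive",
    "redundant",
)


@dataclass
class DeltaProfiles:
    """Per-gene mean differences versus control for a, b and the double ab."""

    delta_a: np.ndarray
    delta_b: np.ndarray
    delta_ab: np.ndarray

    def __post_init__(self) -> None:
        self.delta_a = np.asarray(self.delta_a, dtype=np.float64)
        self.delta_b = np.asarray(self.delta_b, dtype=np.float64)
        self.delta_ab = np.asarray(self.delta_ab, dtype=np.float64)
        if not (self.delta_a.shape == self.delta_b.shape == self.delta_ab.shape):
            raise ValueError("delta profiles must share gene order and length")


@dataclass
class InteractionMetrics:
    c1: float
    c2: float
    fit_dcor: float
    magnitude: float
    dominance: float
    dcor_ab_singles: float  # dcor(delta_a, delta_b)
    dcor_joint_double: float  # dcor([delta_a delta_b], delta_ab)
    equal_contrib: float


@dataclass
class InteractionMode:
    mode: str
    matched_rules: list[str] = field(default_factory=list)


def compute_deltas(
    source: ExpressionDataset | Mapping[str, np.ndarray],
    a: str,
    b: str,
    control: str,
    double: str | None = None,
) -> DeltaProfiles:
    """Deltas from a dataset (full condition keys) or a mapping of condition
    means.  When ``double`` is omitted it is derived: for a dataset, the keys
    of ``a`` and ``b`` are parsed and their dose vectors combined under the
    shared covariates; for a mapping, ``"a+b"`` / ``"b+a"`` are tried."""

    def mean_of(cid: str) -> np.ndarray:
        if isinstance(source, ExpressionDataset):
            idx = source.cells_of(cid)
            if idx.size == 0:
                raise ValueError(f"condition {cid!r} has no cells")
            return source.X[idx].mean(axis=0)
        if cid not in source:
            raise ValueError(f"condition {cid!r} missing from predictions")
        return np.asarray(source[cid], dtype=np.float64)

    if double is None:
        if isinstance(source, ExpressionDataset):
            keys = list(source.covariate_schemas)
            dose_a, cov_a = parse_condition_id(a, source.perturbation_names, keys)
            dose_b, cov_b = parse_condition_id(b, source.perturbation_names, keys)
            if cov_a != cov_b:
                raise ValueError("single conditions differ in covariates; pass `double` explicitly")
            double = condition_id(dose_a + dose_b, cov_a, source.perturbation_names)
        else:
            candidates = [f"{a}+{b}", f"{b}+{a}"]
            double = next((c for c in candidates if c in source), None)
            if double is None:
                raise ValueError(f"double condition for ({a!r}, {b!r}) not found")

    ctrl = mean_of(control)
    return DeltaProfiles(
        delta_a=mean_of(a) - ctrl,
        delta_b=mean_of(b) - ctrl,
        delta_ab=mean_of(double) - ctrl,
    )


def fit_pair_regression(d: DeltaProfiles) -> tuple[float, float, float]:
    """Least squares without intercept; collinear/rank-deficient designs get
    the minimal-norm pseudoinverse solution.  Returns (c1, c2, fit_dcor)."""
    A = np.column_stack([d.delta_a, d.delta_b])
    if A.shape[0] < 2:
        raise ValueError("need at least two genes")
    if not A.any():
        raise ValueError("both single-perturbation deltas are exactly zero")
    c = np.linalg.pinv(A) @ d.delta_ab
    fitted = A @ c
    return float(c[0]), float(c[1]), distance_correlation(fitted, d.delta_ab)


def distance_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Szekely sample distance correlation in [0, 1] via double-centered
    pairwise-distance matrices; defined as 0 for constant input."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.ndim == 1:
        u = u[:, None]
    if v.ndim == 1:
        v = v[:, None]
    if u.shape[0] != v.shape[0] or u.shape[0] < 2:
        raise ValueError("inputs must share first dimension of length >= 2")

    def centered(m: np.ndarray) -> np.ndarray:
        dist = np.sqrt(np.maximum(
            np.sum(m**2, axis=1)[:, None] + np.sum(m**2, axis=1)[None, :] - 2.0 * m @ m.T,
            0.0,
        ))
        return dist - dist.mean(axis=0) - dist.mean(axis=1)[:, None] + dist.mean()

    A, B = centered(u), centered(v)
    dcov2 = float((A * B).mean())
    dvar_u = float((A * A).mean())
    dvar_v = float((B * B).mean())
    if dvar_u <= 0 or dvar_v <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_u * dvar_v)))


_DOMINANCE_CLIP = 6.0


def interaction_metrics(d: DeltaProfiles) -> InteractionMetrics:
    c1, c2, fit_dcor = fit_pair_regression(d)
    magnitude = float(np.sqrt(c1**2 + c2**2))
    a1, a2 = abs(c1), abs(c2)
    if a1 == 0.0 and a2 == 0.0:
        dominance = 0.0
    elif a2 == 0.0:
        dominance = _DOMINANCE_CLIP
    elif a1 == 0.0:
        dominance = -_DOMINANCE_CLIP
    else:
        dominance = float(np.clip(np.log10(a1 / a2), -_DOMINANCE_CLIP, _DOMINANCE_CLIP))
    d_ab = distance_correlation(d.delta_a, d.delta_b)
    d_joint = distance_correlation(np.column_stack([d.delta_a, d.delta_b]), d.delta_ab)
    d_a_ab = distance_correlation(d.delta_a, d.delta_ab)
    d_b_ab = distance_correlation(d.delta_b, d.delta_ab)
    hi = max(d_a_ab, d_b_ab)
    equal_contrib = float(min(d_a_ab, d_b_ab) / hi) if hi > 0 else 0.0
    return InteractionMetrics(
        c1=c1,
        c2=c2,
        fit_dcor=fit_dcor,
        magnitude=magnitude,
        dominance=dominance,
        dcor_ab_singles=d_ab,
        dcor_joint_double=d_joint,
        equal_contrib=equal_contrib,
    )


def classify_mode(m: InteractionMetrics) -> InteractionMode:
    """Evaluate all six threshold rules; assign a mode only when exactly one
    fires, otherwise 'unassigned' with the matched rules recorded."""
    for v in (m.c1, m.c2, m.magnitude, m.dcor_ab_singles, m.dcor_joint_double):
        if not np.isfinite(v):
            raise ValueError("metrics must be finite")
    a1, a2 = abs(m.c1), abs(m.c2)
    rules = {
        "epistatic": min(a1, a2) > 0.2 and (a1 > 2 * a2 or a2 > 2 * a1),
        "potentiation": m.magnitude > 1 and abs(m.dcor_ab_singles - 1) > 0.2,
        "strong_synergy_similar": m.magnitude > 1 and abs(m.dcor_joint_double - 1) > 0.2,
        "strong_synergy_different": m.magnitude > 1 and abs(m.dcor_ab_singles - 1) > 0.5,
        "additive": abs(m.magnitude - 1) < 0.1,
        "redundant": abs(m.dcor_joint_double - 1) < 0.2 and abs(m.dcor_ab_singles - 1) < 0.2,
    }
    matched = [name for name in MODE_NAMES if rules[name]]
    mode = matched[0] if len(matched) == 1 else "unassigned"
    return InteractionMode(mode=mode, matched_rules=matched)


def count_missing_pairs(n_single_genes: int, n_measured_pairs: int) -> tuple[int, float]:
    """Unmeasured unordered pairs among C(n, 2) possibilities, and the
    percentage they represent (one decimal)."""
    total = comb(n_single_genes, 2)
    if n_measured_pairs > total or n_measured_pairs < 0:
        raise ValueError(f"{n_measured_pairs} measured pairs impossible for n={n_single_genes}")
    missing = total - n_measured_pairs
    percent = round(100.0 * missing / total, 1) if total else 0.0
    return missing, percent


def impute_all_pairs(
    model: CPAModel,
    ds: ExpressionDataset,
    n_cells_per_pair: int = 50,
    dose: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Predict condition means for every unordered perturbation pair absent
    from the dataset, with a per-condition uncertainty score.

    Source cells are drawn from the control (all-zero dose) population; the
    pair is applied counterfactually at the given dose.
    """
    rng = np.random.default_rng(seed)
    names = model.perturbation_names
    applied = ds.applied
    measured = set()
    for i in range(ds.n_cells):
        on = np.flatnonzero(applied[i])
        if on.size == 2:
            measured.add(tuple(sorted(names[j] for j in on)))
    control_idx = np.flatnonzero(~applied.any(axis=1))
    if control_idx.size == 0:
        raise ValueError("no control (all-zero dose) cells to source basal states from")
    train_cids = training_conditions(ds)

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = (names[i], names[j])
            if pair in measured:
                continue
            src = rng.choice(control_idx, size=min(n_cells_per_pair, control_idx.size), replace=False)
            cov_idx = {
                key: np.full(src.size, ds.covariate_indices(key)[src[0]])
                for key in ds.covariate_schemas
            }
            d_prime = np.zeros(model.M)
            d_prime[[i, j]] = dose
            mean, var, _ = predict_condition(model, ds.X[src], cov_idx, d_prime)
            score = uncertainty(model, (d_prime, {k: int(v[0]) for k, v in cov_idx.items()}), train_cids)
            rows.append(
                {
                    "pair_id": f"{pair[0]}+{pair[1]}",
                    "mean": mean,
                    "variance": var,
                    "u_cosine": score.u_cosine,
                    "u_euclidean": score.u_euclidean,
                    "nearest_condition": score.nearest_condition,
                }
            )
    return pd.DataFrame(rows)
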