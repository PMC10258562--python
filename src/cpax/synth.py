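"""Synthetic perturbation datasets with known ground truth.

The generator mirrors the model's own generative assumptions: every cell has
a latent basal state drawn from a small Gaussian mixture of cell states
(shared across covariate levels, so covariate identity never leaks into the
basal space by construction); applied perturbations add their latent effect
vectors scaled by saturating Hill dose curves; covariates add their own
latent offsets; a fixed random nonlinear map decodes the composed latent
state to gene space, where i.i.d. Gaussian noise is added on the log scale.

Structure the model must work to capture comes from three knobs: the
decoder's first-layer tanh gain (how nonlinear the latent-to-gene map is),
an optional shared-program weight tying perturbation effect vectors to one
transcriptional axis (as perturbation clusters in real combinatorial
screens do), and optional pairwise latent offsets (``interaction_terms``)
that plant genuine synergy/epistasis no additive gene-space model can
explain.

The hidden parameters are returned as a :class:`SyntheticTruth` so parameter
recovery and counterfactual accuracy are directly testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset, SplitPlan, ValidationError, make_split

__all__ = [
    "SyntheticTruth",
    "Condition",
    "make_truth",
    "generate_dataset",
    "holdout_design",
    "default_design",
    "disentanglement_fixture",
    "recovery_fixture",
    "gi_additive_fixture",
]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class SyntheticTruth:
    """Hidden parameters of the generative process."""

    latent_dim: int
    perturbation_names: list[str]
    covariate_schemas: dict[str, list[str]]
    V_pert: np.ndarray  # (latent_dim, M)
    V_cov: dict[str, np.ndarray]  # name -> (latent_dim, K_j)
    hill_k: np.ndarray  # (M,) half-max doses, > 0
    hill_n: np.ndarray  # (M,) Hill exponents, > 0
    basal_means: np.ndarray  # (n_components, latent_dim)
    basal_weights: np.ndarray  # (n_components,)
    basal_sd: float
    decoder_weights: list[np.ndarray]  # [W1, b1, W2, b2, W3, b3] or [W, b]
    decoder_kind: str  # "tanh" | "linear"
    noise_sd: float
    interaction_terms: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.perturbation_names)

    def hill(self, doses: np.ndarray) -> np.ndarray:
        """Saturating dose curves h_j(d) = d^n / (d^n + k^n), h_j(0)=0, sup 1."""
        d = np.asarray(doses, dtype=np.float64)
        dn = d ** self.hill_n
        return np.where(d > 0, dn / (dn + self.hill_k**self.hill_n), 0.0)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if self.decoder_kind == "linear":
            w, b = self.decoder_weights
            return z @ w + b
        w1, b1, w2, b2, w3, b3 = self.decoder_weights
        h = np.tanh(z @ w1 + b1)
        h = np.tanh(h @ w2 + b2)
        return h @ w3 + b3

    def latent_effect(self, pert_doses: dict[str, float]) -> np.ndarray:
        """Composed latent offset for a set of applied perturbations."""
        d = np.zeros(self.M)
        for name, dose in pert_doses.items():
            d[self.perturbation_names.index(name)] = dose
        eff = self.V_pert @ self.hill(d)
        applied = sorted(pert_doses)
        for i in range(len(applied)):
            for j in range(i + 1, len(applied)):
                off = self.interaction_terms.get(_pair_key(applied[i], applied[j]))
                if off is not None:
                    eff = eff + off
        return eff

    # JSON sidecar ----------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "latent_dim": self.latent_dim,
            "perturbation_names": self.perturbation_names,
            "covariate_schemas": self.covariate_schemas,
            "V_pert": self.V_pert.tolist(),
            "V_cov": {k: v.tolist() for k, v in self.V_cov.items()},
            "hill_k": self.hill_k.tolist(),
            "hill_n": self.hill_n.tolist(),
            "basal_means": self.basal_means.tolist(),
            "basal_weights": self.basal_weights.tolist(),
            "basal_sd": self.basal_sd,
            "decoder_weights": [w.tolist() for w in self.decoder_weights],
            "decoder_kind": self.decoder_kind,
            "noise_sd": self.noise_sd,
            "interaction_terms": {f"{a}{'+'}{b}": v.tolist() for (a, b), v in self.interaction_terms.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        p = json.loads(text)
        return cls(
            latent_dim=p["latent_dim"],
            perturbation_names=p["perturbation_names"],
            covariate_schemas=p["covariate_schemas"],
            V_pert=np.array(p["V_pert"]),
            V_cov={k: np.array(v) for k, v in p["V_cov"].items()},
            hill_k=np.array(p["hill_k"]),
            hill_n=np.array(p["hill_n"]),
            basal_means=np.array(p["basal_means"]),
            basal_weights=np.array(p["basal_weights"]),
            basal_sd=p["basal_sd"],
            decoder_weights=[np.array(w) for w in p["decoder_weights"]],
            decoder_kind=p["decoder_kind"],
            noise_sd=p["noise_sd"],
            interaction_terms={
                tuple(k.split("+")): np.array(v) for k, v in p["interaction_terms"].items()
            },
        )


def make_truth(
    seed: int = 0,
    *,
    n_genes: int = 200,
    latent_dim: int = 8,
    perturbation_names: list[str] | None = None,
    covariate_schemas: dict[str, list[str]] | None = None,
    n_components: int = 2,
    effect_norm: float = 1.2,
    shared_program_weight: float = 0.0,
    cov_effect_norm: float = 0.8,
    basal_sd: float = 0.4,
    component_spread: float = 1.0,
    decoder_kind: str = "tanh",
    decoder_hidden: int = 64,
    decoder_gain: float = 1.4,
    noise_sd: float = 0.1,
    interaction_pairs: list[tuple[str, str]] | None = None,
    interaction_norm: float = 1.5,
) -> SyntheticTruth:
    """Draw a random ground truth.

    Defaults describe the desk-scale study conditions used throughout the
    test suite: 200 genes, latent dimension 8, one covariate with two levels,
    perturbation effect vectors of norm 1.2 against a basal spread of ~1,
    Hill curves saturating at 1, and Gaussian noise of sd 0.1 on the log
    scale.  ``interaction_pairs`` plants non-additive latent offsets.
    """
    rng = np.random.default_rng(seed)
    if perturbation_names is None:
        perturbation_names = ["A", "B", "C", "D"]
    if covariate_schemas is None:
        covariate_schemas = {"cell_line": ["line0", "line1"]}
    M = len(perturbation_names)

    def _unit_cols(k: int, norm: float) -> np.ndarray:
        v = rng.standard_normal((latent_dim, k))
        return v / np.linalg.norm(v, axis=0, keepdims=True) * norm

    if shared_program_weight > 0.0:
        # perturbations form one tight transcriptional program: each effect
        # vector carries weight w on a shared axis plus an orthogonal residual
        if not (0.0 < shared_program_weight < 1.0) or M >= latent_dim:
            raise ValidationError("shared_program_weight in (0,1) requires M < latent_dim")
        Q, _ = np.linalg.qr(rng.standard_normal((latent_dim, latent_dim)))
        w = shared_program_weight
        V_pert = (np.sqrt(w) * Q[:, :1] + np.sqrt(1.0 - w) * Q[:, 1 : 1 + M]) * effect_norm
    else:
        V_pert = _unit_cols(M, effect_norm)
    V_cov = {key: _unit_cols(len(levels), cov_effect_norm) for key, levels in covariate_schemas.items()}
    hill_k = rng.uniform(0.3, 0.7, size=M)
    hill_n = rng.uniform(1.5, 2.5, size=M)
    basal_means = rng.standard_normal((n_components, latent_dim)) * component_spread / np.sqrt(latent_dim)
    basal_weights = np.full(n_components, 1.0 / n_components)

    if decoder_kind == "linear":
        w = rng.standard_normal((latent_dim, n_genes)) / np.sqrt(latent_dim)
        b = rng.uniform(0.1, 2.0, size=n_genes)
        decoder_weights = [w, b]
    elif decoder_kind == "tanh":
        w1 = rng.standard_normal((latent_dim, decoder_hidden)) * decoder_gain / np.sqrt(latent_dim)
        b1 = rng.standard_normal(decoder_hidden) * 0.3
        w2 = rng.standard_normal((decoder_hidden, decoder_hidden)) / np.sqrt(decoder_hidden)
        b2 = rng.standard_normal(decoder_hidden) * 0.3
        w3 = rng.standard_normal((decoder_hidden, n_genes)) / np.sqrt(decoder_hidden)
        b3 = rng.uniform(0.1, 2.0, size=n_genes)
        decoder_weights = [w1, b1, w2, b2, w3, b3]
    else:
        raise ValueError(f"unknown decoder_kind {decoder_kind!r}")

    interactions: dict[tuple[str, str], np.ndarray] = {}
    for a, b in interaction_pairs or []:
        if a not in perturbation_names or b not in perturbation_names:
            raise ValidationError(f"interaction pair ({a}, {b}) references unknown perturbation")
        v = rng.standard_normal(latent_dim)
        interactions[_pair_key(a, b)] = v / np.linalg.norm(v) * interaction_norm

    return SyntheticTruth(
        latent_dim=latent_dim,
        perturbation_names=list(perturbation_names),
        covariate_schemas={k: list(v) for k, v in covariate_schemas.items()},
        V_pert=V_pert,
        V_cov=V_cov,
        hill_k=hill_k,
        hill_n=hill_n,
        basal_means=basal_means,
        basal_weights=basal_weights,
        basal_sd=basal_sd,
        decoder_weights=decoder_weights,
        decoder_kind=decoder_kind,
        noise_sd=noise_sd,
        interaction_terms=interactions,
    )


@dataclass(frozen=True)
class Condition:
    """One design row: which perturbations at which doses, covariate levels, cell count."""

    pert_doses: tuple[tuple[str, float], ...]
    covariates: tuple[tuple[str, str], ...]
    n_cells: int

    @classmethod
    def make(cls, pert_doses: dict[str, float], covariates: dict[str, str], n_cells: int) -> "Condition":
        return cls(
            pert_doses=tuple(sorted(pert_doses.items())),
            covariates=tuple(sorted(covariates.items())),
            n_cells=int(n_cells),
        )


def default_design(
    truth: SyntheticTruth,
    *,
    n_cells_per_condition: int = 200,
    dose: float = 1.0,
    pairs: list[tuple[str, str]] | None = None,
    covariate_levels: list[dict[str, str]] | None = None,
) -> list[Condition]:
    """Control + every single perturbation (+ requested pairs) at a fixed dose,
    replicated over the given covariate-level assignments."""
    if covariate_levels is None:
        key = next(iter(truth.covariate_schemas))
        covariate_levels = [{key: lvl} for lvl in truth.covariate_schemas[key]]
    design = []
    for cov in covariate_levels:
        design.append(Condition.make({}, cov, n_cells_per_condition))
        for p in truth.perturbation_names:
            design.append(Condition.make({p: dose}, cov, n_cells_per_condition))
        for a, b in pairs or []:
            design.append(Condition.make({a: dose, b: dose}, cov, n_cells_per_condition))
    return design


def generate_dataset(
    truth: SyntheticTruth, design: list[Condition], seed: int = 0
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Sample cells for every design row and decode them to gene space."""
    rng = np.random.default_rng(seed)
    n_genes = truth.decoder_weights[-1].shape[-1]
    rows_X, rows_d, rows_cov = [], [], []
    for cond in design:
        if cond.n_cells <= 0:
            raise ValidationError("cell counts must be > 0")
        pert_doses = dict(cond.pert_doses)
        for name in pert_doses:
            if name not in truth.perturbation_names:
                raise ValidationError(f"unknown perturbation {name!r} in design")
        covs = dict(cond.covariates)
        for key, lvl in covs.items():
            if lvl not in truth.covariate_schemas.get(key, []):
                raise ValidationError(f"unknown covariate level {key}={lvl!r} in design")
        n = cond.n_cells
        comp = rng.choice(len(truth.basal_weights), size=n, p=truth.basal_weights)
        basal = truth.basal_means[comp] + rng.standard_normal((n, truth.latent_dim)) * truth.basal_sd
        z = basal + truth.latent_effect(pert_doses)[None, :]
        for key, lvl in covs.items():
            z = z + truth.V_cov[key][:, truth.covariate_schemas[key].index(lvl)][None, :]
        x = truth.decode(z) + rng.standard_normal((n, n_genes)) * truth.noise_sd
        d_row = np.zeros(truth.M)
        for name, dose in pert_doses.items():
            d_row[truth.perturbation_names.index(name)] = dose
        rows_X.append(x)
        rows_d.append(np.tile(d_row, (n, 1)))
        rows_cov.append(pd.DataFrame([covs] * n))

    covariates = pd.concat(rows_cov, ignore_index=True)[list(truth.covariate_schemas)]
    ds = ExpressionDataset(
        X=np.vstack(rows_X),
        gene_names=[f"gene{i}" for i in range(n_genes)],
        perturbation_names=truth.perturbation_names,
        doses=np.vstack(rows_d),
        covariate_schemas=truth.covariate_schemas,
        covariates=covariates,
    )
    return ds, truth


def holdout_design(
    ds: ExpressionDataset,
    held_pairs: list[tuple[str, str]],
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Plan marking every condition whose applied set is exactly a held pair as OOD."""
    cids = ds.condition_ids
    applied = ds.applied
    names = np.array(ds.perturbation_names, dtype=object)
    ood = set()
    for a, b in held_pairs:
        want = {a, b}
        hit = [
            cids[i]
            for i in range(ds.n_cells)
            if set(names[applied[i]]) == want
        ]
        if not hit:
            raise ValidationError(f"pair ({a}, {b}) has no condition in the dataset")
        ood.update(hit)
    return SplitPlan(ood_conditions=frozenset(ood), test_fraction=test_fraction, seed=seed)


# ---------------------------------------------------------------------------
# Reference fixtures (the desk-scale study conditions used by the test suite)
# ---------------------------------------------------------------------------

def disentanglement_fixture(seed: int = 0):
    """2,000 cells x 200 genes: control + 4 single perturbations across one
    covariate with two levels.  Basal cell states are independent of the
    perturbation by construction, so any perturbation signal recoverable from
    the learned basal space is an encoder leak."""
    truth = make_truth(
        seed,
        n_genes=200,
        latent_dim=8,
        perturbation_names=["A", "B", "C", "D"],
        covariate_schemas={"cell_line": ["line0", "line1"]},
    )
    design = default_design(truth, n_cells_per_condition=200)
    ds, truth = generate_dataset(truth, design, seed=seed)
    ds = make_split(ds, SplitPlan(test_fraction=0.15, seed=seed))
    return ds, truth


def recovery_fixture(seed: int = 0, interaction: bool = False):
    """Counterfactual-recovery conditions: 4 perturbations, three trained
    pairs and the held-out pair (A, B); optionally a planted non-additive
    latent offset on (A, B) that no additive gene-space model can explain.

    Returns (dataset with ood split on the held pair, truth)."""
    truth = make_truth(
        seed,
        n_genes=200,
        latent_dim=8,
        perturbation_names=["A", "B", "C", "D"],
        covariate_schemas={"cell_line": ["line0", "line1"]},
        interaction_pairs=[("A", "B")] if interaction else None,
    )
    pairs = [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
    design = default_design(truth, n_cells_per_condition=100, pairs=pairs)
    ds, truth = generate_dataset(truth, design, seed=seed)
    ds = make_split(ds, holdout_design(ds, [("A", "B")], test_fraction=0.15, seed=seed))
    return ds, truth


def gi_additive_fixture(seed: int = 0, n_cells_per_condition: int = 1000):
    """No-interaction genetic-screen emulation: six perturbations forming one
    tight shared transcriptional program (as perturbation clusters in real
    combinatorial screens do), composed strictly additively in latent space
    and decoded in the near-linear regime; all 15 pairs measured."""
    names = ["A", "B", "C", "D", "E", "F"]
    truth = make_truth(
        seed,
        n_genes=200,
        latent_dim=8,
        perturbation_names=names,
        covariate_schemas={"cell_line": ["line0"]},
        effect_norm=1.6,
        shared_program_weight=0.92,
        decoder_gain=0.5,
    )
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    design = default_design(truth, n_cells_per_condition=n_cells_per_condition, pairs=pairs)
    return generate_dataset(truth, design, seed=seed)
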