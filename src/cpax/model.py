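"""Network components and the latent composition rule.

A cell's expression vector x is encoded into a *basal* latent state stripped
(by adversarial training, see :mod:`cpax.train`) of perturbation and
covariate information.  The perturbed latent state is the exactly linear
composition

    z = z_basal + V_pert @ [f_1(d_1), ..., f_M(d_M)] + sum_j V_cov[j][:, c_j]

where each column of V_pert is a learned perturbation embedding, each
covariate dictionary column a learned covariate embedding, and each f_j is a
learned scalar dose(or time)-response curve satisfying f_j(0) = 0 exactly at
every parameter value (implemented as g_j(d) - g_j(0) for an unconstrained
scalar network g_j).  A Gaussian decoder maps z to a per-gene mean and a
per-gene variance, the latter through a softplus link with a 1e-3 floor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import MLP, Parameter, softplus

__all__ = [
    "ModelConfig",
    "EmbeddingDictionaries",
    "GaussianPrediction",
    "CPAModel",
    "variance_link",
    "compose_latent",
    "VARIANCE_FLOOR",
]

VARIANCE_FLOOR = 1e-3


@dataclass
class ModelConfig:
    """Architecture sizes; defaults follow the published configuration.

    Desk-scale runs shrink these via keyword overrides.
    """

    latent_dim: int = 256
    encoder_hidden: int = 512
    encoder_layers: int = 4
    doser_hidden: int = 64
    doser_layers: int = 2
    discriminator_hidden: int = 128
    discriminator_layers: int = 3
    seed: int = 0


@dataclass
class EmbeddingDictionaries:
    """Learned perturbation and covariate embedding matrices."""

    V_perturbation: Parameter  # (latent_dim, M)
    V_cov: dict[str, Parameter]  # name -> (latent_dim, K_j)

    @property
    def latent_dim(self) -> int:
        return self.V_perturbation.value.shape[0]


@dataclass
class GaussianPrediction:
    """Per-gene predicted mean and strictly positive variance."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.variance <= 0):
            raise ValueError("predicted variances must be strictly positive")


def variance_link(v: np.ndarray | float) -> np.ndarray | float:
    """softplus(v) + 1e-3: strictly positive, monotone, floored for stability."""
    arr = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("variance_link requires finite input")
    out = softplus(arr) + VARIANCE_FLOOR
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def compose_latent(
    basal: np.ndarray,
    scaled: np.ndarray,
    cov_onehots: list[np.ndarray],
    dictionaries: EmbeddingDictionaries,
) -> np.ndarray:
    """Exactly linear composition of basal state, scaled doses, covariates."""
    basal = np.asarray(basal, dtype=np.float64)
    scaled = np.asarray(scaled, dtype=np.float64)
    single = basal.ndim == 1
    basal2, scaled2 = np.atleast_2d(basal), np.atleast_2d(scaled)
    V = dictionaries.V_perturbation.value
    if basal2.shape[1] != V.shape[0]:
        raise ValueError(f"basal dim {basal2.shape[1]} != latent_dim {V.shape[0]}")
    if scaled2.shape[1] != V.shape[1]:
        raise ValueError(f"scaled dose length {scaled2.shape[1]} != M {V.shape[1]}")
    z = basal2 + scaled2 @ V.T
    covs = list(dictionaries.V_cov.values())
    if len(cov_onehots) != len(covs):
        raise ValueError(f"{len(cov_onehots)} covariate one-hots for {len(covs)} dictionaries")
    for onehot, vc in zip(cov_onehots, covs):
        onehot2 = np.atleast_2d(np.asarray(onehot, dtype=np.float64))
        if onehot2.shape[1] != vc.value.shape[1]:
            raise ValueError("covariate one-hot length mismatch")
        z = z + onehot2 @ vc.value.T
    return z[0] if single else z


class CPAModel:
    """Encoder, Gaussian decoder, embedding dictionaries, dose scalers and
    adversarial discriminators, wired for manual backpropagation."""

    def __init__(
        self,
        n_genes: int,
        perturbation_names: list[str],
        covariate_schemas: dict[str, list[str]],
        config: ModelConfig | None = None,
        adv_mode: str = "multilabel",
    ) -> None:
        cfg = config or ModelConfig()
        if adv_mode not in ("multilabel", "softmax"):
            raise ValueError(f"unknown adversary mode {adv_mode!r}")
        self.config = cfg
        self.n_genes = int(n_genes)
        self.perturbation_names = list(perturbation_names)
        self.covariate_schemas = {k: list(v) for k, v in covariate_schemas.items()}
        self.adv_mode = adv_mode
        M, d = len(self.perturbation_names), cfg.latent_dim
        rng = np.random.default_rng(cfg.seed)

        enc_sizes = [n_genes] + [cfg.encoder_hidden] * cfg.encoder_layers + [d]
        dec_sizes = [d] + [cfg.encoder_hidden] * cfg.encoder_layers + [2 * n_genes]
        self.encoder = MLP(rng, enc_sizes, activation="relu", batchnorm=True, name="enc")
        self.decoder = MLP(rng, dec_sizes, activation="relu", batchnorm=True, name="dec")
        self.dictionaries = EmbeddingDictionaries(
            V_perturbation=Parameter(rng.standard_normal((d, M)) / np.sqrt(d), name="V_pert"),
            V_cov={
                key: Parameter(
                    rng.standard_normal((d, len(levels))) / np.sqrt(d), name=f"V_cov.{key}"
                )
                for key, levels in self.covariate_schemas.items()
            },
        )
        doser_sizes = [1] + [cfg.doser_hidden] * cfg.doser_layers + [1]
        self.dosers = [
            MLP(rng, doser_sizes, activation="tanh", final_activation="tanh", name=f"doser{j}")
            for j in range(M)
        ]  # bounded output: saturating dose-response, scale carried by V_pert

        n_pert_classes = M if adv_mode == "multilabel" else M + 1  # + control class
        adv_sizes = [d] + [cfg.discriminator_hidden] * cfg.discriminator_layers
        self.adv_pert = MLP(rng, adv_sizes + [n_pert_classes], activation="relu", batchnorm=True, name="adv_pert")
        self.adv_cov = {
            key: MLP(rng, adv_sizes + [len(levels)], activation="relu", batchnorm=True, name=f"adv_cov.{key}")
            for key, levels in self.covariate_schemas.items()
        }

    # -- parameter groups ---------------------------------------------------
    def autoencoder_parameters(self) -> list[Parameter]:
        params = self.encoder.parameters() + self.decoder.parameters()
        params.append(self.dictionaries.V_perturbation)
        params.extend(self.dictionaries.V_cov.values())
        return params

    def doser_parameters(self) -> list[Parameter]:
        return [p for m in self.dosers for p in m.parameters()]

    def discriminator_parameters(self) -> list[Parameter]:
        params = self.adv_pert.parameters()
        for m in self.adv_cov.values():
            params.extend(m.parameters())
        return params

    def all_parameters(self) -> list[Parameter]:
        return (
            self.autoencoder_parameters()
            + self.doser_parameters()
            + self.discriminator_parameters()
        )

    def all_buffers(self) -> list[np.ndarray]:
        """Batch-norm running statistics (state that is not a Parameter)."""
        nets = [self.encoder, self.decoder, self.adv_pert, *self.adv_cov.values(), *self.dosers]
        return [b for net in nets for b in net.buffers()]

    # -- forward operations -------------------------------------------------
    @property
    def M(self) -> int:
        return len(self.perturbation_names)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def encode_basal(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        x2 = np.atleast_2d(x)
        if x2.shape[1] != self.n_genes:
            raise ValueError(f"expression length {x2.shape[1]} != G={self.n_genes}")
        out = self.encoder(x2)
        return out[0] if single else out

    def scale_doses(self, d: np.ndarray) -> np.ndarray:
        """Componentwise f_j(d_j) = g_j(d_j) - g_j(0); exactly 0 at zero dose."""
        d = np.asarray(d, dtype=np.float64)
        single = d.ndim == 1
        d2 = np.atleast_2d(d)
        if d2.shape[1] != self.M:
            raise ValueError(f"dose vector length {d2.shape[1]} != M={self.M}")
        if np.any(d2 < 0):
            raise ValueError("doses must be >= 0")
        out = np.zeros_like(d2)
        zero = np.zeros((1, 1))
        for j, doser in enumerate(self.dosers):
            col = d2[:, j : j + 1]
            out[:, j : j + 1] = doser(col) - doser(zero)
        return out[0] if single else out

    def cov_onehots(self, cov_idx: dict[str, np.ndarray]) -> list[np.ndarray]:
        onehots = []
        for key, levels in self.covariate_schemas.items():
            idx = np.atleast_1d(np.asarray(cov_idx[key], dtype=np.int64))
            if np.any(idx < 0) or np.any(idx >= len(levels)):
                raise ValueError(f"covariate index out of range for {key!r}")
            onehots.append(np.eye(len(levels))[idx])
        return onehots

    def compose(self, basal: np.ndarray, scaled: np.ndarray, cov_idx: dict[str, np.ndarray]) -> np.ndarray:
        return compose_latent(basal, scaled, self.cov_onehots(cov_idx), self.dictionaries)

    def decode_gaussian(self, z: np.ndarray) -> GaussianPrediction:
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        z2 = np.atleast_2d(z)
        if z2.shape[1] != self.latent_dim:
            raise ValueError(f"latent length {z2.shape[1]} != latent_dim {self.latent_dim}")
        out = self.decoder(z2)
        mean, raw_var = out[:, : self.n_genes], out[:, self.n_genes :]
        var = variance_link(raw_var)
        if single:
            return GaussianPrediction(mean=mean[0], variance=var[0])
        return GaussianPrediction(mean=mean, variance=var)

    def reconstruct(
        self, x: np.ndarray, d: np.ndarray, cov_idx: dict[str, np.ndarray]
    ) -> GaussianPrediction:
        """Full forward pass: encode, compose with the observed condition, decode."""
        basal = self.encode_basal(x)
        scaled = self.scale_doses(d)
        return self.decode_gaussian(self.compose(basal, scaled, cov_idx))

    # -- adversary targets --------------------------------------------------
    def perturbation_targets(self, doses: np.ndarray) -> np.ndarray:
        """Applied-indicator matrix (multilabel) or class index (softmax, with
        a dedicated control class at index M)."""
        doses = np.atleast_2d(np.asarray(doses, dtype=np.float64))
        applied = doses > 0
        if self.adv_mode == "multilabel":
            return applied.astype(np.float64)
        n_applied = applied.sum(axis=1)
        if np.any(n_applied > 1):
            raise ValueError("softmax adversary requires at most one applied perturbation per cell")
        idx = np.full(doses.shape[0], self.M, dtype=np.int64)
        rows, cols = np.nonzero(applied)
        idx[rows] = cols
        return idx

    # -- checkpointing ------------------------------------------------------
    def _named_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.all_parameters())}
        arrays.update({f"b{i}": b for i, b in enumerate(self.all_buffers())})
        return arrays

    def save(self, path) -> None:
        manifest = {
            "config": asdict(self.config),
            "n_genes": self.n_genes,
            "perturbation_names": self.perturbation_names,
            "covariate_schemas": self.covariate_schemas,
            "adv_mode": self.adv_mode,
        }
        np.savez(path, __manifest__=json.dumps(manifest), **self._named_arrays())

    @classmethod
    def load(cls, path) -> "CPAModel":
        with np.load(path, allow_pickle=False) as archive:
            manifest = json.loads(str(archive["__manifest__"]))
            model = cls(
                n_genes=manifest["n_genes"],
                perturbation_names=manifest["perturbation_names"],
                covariate_schemas=manifest["covariate_schemas"],
                config=ModelConfig(**manifest["config"]),
                adv_mode=manifest["adv_mode"],
            )
            for i, p in enumerate(model.all_parameters()):
                p.value[...] = archive[f"p{i}"]
            for i, b in enumerate(model.all_buffers()):
                b[...] = archive[f"b{i}"]
        return model

    def copy_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_parameters()] + [
            b.copy() for b in self.all_buffers()
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        arrays = self.all_parameters()
        for p, v in zip(arrays, state[: len(arrays)]):
            p.value[...] = v
        for b, v in zip(self.all_buffers(), state[len(arrays) :]):
            b[...] = v
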