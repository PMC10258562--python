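"""Containers and I/O for annotated perturbation expression data.

The central container is :class:`ExpressionDataset`: a cells x genes matrix of
log-normalized expression together with, per cell, a length-M dose vector
(one slot per perturbation, 0 = not applied; time courses use the same slot
mechanism), categorical covariate assignments (cell line, species, patient,
...), a derived condition key, and an optional train/test/ood split label.

A *condition* is the unit of holdout and evaluation: the exact combination of
applied perturbations, their doses, and covariate levels.  Condition keys are
pure functions of the dose and covariate rows: perturbation names inside a
combination are sorted lexicographically (``A+B`` and ``B+A`` are the same
condition) and doses are aligned to the sorted order, formatted so that the
key round-trips the dose vector exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "ExpressionDataset",
    "SplitPlan",
    "condition_id",
    "parse_condition_id",
    "read_dataset",
    "write_dataset",
    "preprocess_expression",
    "make_split",
]

DELIM = "+"
CONTROL_TOKEN = "ctrl"


class SchemaError(ValueError):
    """A required annotation column or vocabulary entry is missing."""


class ValidationError(ValueError):
    """Data violate a container invariant (negative dose, shape mismatch...)."""


def _format_dose(d: float) -> str:
    return repr(float(d))


def condition_id(
    dose_row: np.ndarray,
    cov_row: dict[str, str] | list[str],
    perturbation_names: list[str],
) -> str:
    """Build the canonical ``perts@doses|cov1|...|covK`` key for one cell."""
    dose_row = np.asarray(dose_row, dtype=np.float64)
    applied = [(perturbation_names[j], dose_row[j]) for j in np.flatnonzero(dose_row > 0)]
    applied.sort(key=lambda t: t[0])
    if applied:
        pert_part = DELIM.join(name for name, _ in applied)
        dose_part = DELIM.join(_format_dose(d) for _, d in applied)
    else:
        pert_part, dose_part = CONTROL_TOKEN, "0"
    cov_values = list(cov_row.values()) if isinstance(cov_row, dict) else list(cov_row)
    return "|".join([f"{pert_part}@{dose_part}", *map(str, cov_values)])


def parse_condition_id(
    cid: str, perturbation_names: list[str], covariate_keys: list[str]
) -> tuple[np.ndarray, dict[str, str]]:
    """Invert :func:`condition_id` back to a dose vector and covariate dict."""
    head, *cov_values = cid.split("|")
    if len(cov_values) != len(covariate_keys):
        raise ValidationError(
            f"condition key {cid!r} has {len(cov_values)} covariate fields, "
            f"expected {len(covariate_keys)}"
        )
    pert_part, dose_part = head.split("@")
    doses = np.zeros(len(perturbation_names))
    if pert_part != CONTROL_TOKEN:
        names = pert_part.split(DELIM)
        values = dose_part.split(DELIM)
        for name, value in zip(names, values):
            if name not in perturbation_names:
                raise SchemaError(f"unknown perturbation {name!r} in key {cid!r}")
            doses[perturbation_names.index(name)] = float(value)
    return doses, dict(zip(covariate_keys, cov_values))


@dataclass
class ExpressionDataset:
    """Annotated cells x genes expression matrix.

    Attributes
    ----------
    X
        (N, G) log-normalized expression, float64.
    gene_names
        G gene identifiers.
    perturbation_names
        The M perturbations the dose vector indexes.
    doses
        (N, M) nonnegative doses; a perturbation is applied iff its dose > 0.
    covariate_schemas
        Ordered mapping covariate name -> list of valid levels.
    covariates
        (N, K) DataFrame of per-cell level assignments.
    split
        Optional per-cell label in {"train", "test", "ood"}.
    """

    X: np.ndarray
    gene_names: list[str]
    perturbation_names: list[str]
    doses: np.ndarray
    covariate_schemas: dict[str, list[str]]
    covariates: pd.DataFrame
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.doses = np.asarray(self.doses, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        self.perturbation_names = list(self.perturbation_names)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, g = self.X.shape
        if len(self.gene_names) != g:
            raise ValidationError(f"{len(self.gene_names)} gene names for {g} genes")
        if self.doses.shape != (n, len(self.perturbation_names)):
            raise ValidationError(
                f"dose matrix {self.doses.shape} inconsistent with "
                f"N={n}, M={len(self.perturbation_names)}"
            )
        if np.any(self.doses < 0):
            raise ValidationError("doses must be >= 0")
        if list(self.covariates.columns) != list(self.covariate_schemas):
            raise SchemaError(
                f"covariate columns {list(self.covariates.columns)} do not match "
                f"schema {list(self.covariate_schemas)}"
            )
        if len(self.covariates) != n:
            raise ValidationError("covariate table row count differs from X")
        for key, levels in self.covariate_schemas.items():
            bad = set(self.covariates[key].astype(str)) - set(levels)
            if bad:
                raise ValidationError(f"invalid levels {sorted(bad)} for covariate {key!r}")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape != (n,):
                raise ValidationError("split vector length differs from X")
            bad = set(self.split) - {"train", "test", "ood"}
            if bad:
                raise ValidationError(f"invalid split labels {sorted(bad)}")

    # -- derived views ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def condition_ids(self) -> np.ndarray:
        # cached: the container is treated as immutable after construction
        cached = getattr(self, "_condition_ids", None)
        if cached is None:
            cov = self.covariates.astype(str).to_numpy()
            cached = np.array(
                [
                    condition_id(self.doses[i], list(cov[i]), self.perturbation_names)
                    for i in range(self.n_cells)
                ],
                dtype=object,
            )
            object.__setattr__(self, "_condition_ids", cached)
        return cached

    @property
    def applied(self) -> np.ndarray:
        """(N, M) boolean indicator of applied perturbations."""
        return self.doses > 0

    def covariate_indices(self, key: str) -> np.ndarray:
        levels = self.covariate_schemas[key]
        lookup = {lvl: i for i, lvl in enumerate(levels)}
        return np.array([lookup[v] for v in self.covariates[key].astype(str)], dtype=np.int64)

    def subset(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        return replace(
            self,
            X=self.X[mask],
            doses=self.doses[mask],
            covariates=self.covariates.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
            split=None if self.split is None else self.split[mask],
        )

    def cells_of(self, cid: str) -> np.ndarray:
        return np.flatnonzero(self.condition_ids == cid)


@dataclass(frozen=True)
class SplitPlan:
    """Condition-level holdout plan: full conditions go to OOD, the rest of the
    cells are partitioned per-condition into train/test reproducibly."""

    ood_conditions: frozenset = frozenset()
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError("test_fraction must lie in (0, 1)")
        object.__setattr__(self, "ood_conditions", frozenset(self.ood_conditions))


def make_split(ds: ExpressionDataset, plan: SplitPlan) -> ExpressionDataset:
    """Assign train/test/ood labels; cells of OOD conditions never reach train/test."""
    cids = ds.condition_ids
    present = set(cids)
    unknown = sorted(set(plan.ood_conditions) - present)
    if unknown:
        raise ValidationError(f"OOD conditions not present in dataset: {unknown}")
    split = np.array(["train"] * ds.n_cells, dtype=object)
    rng = np.random.default_rng(plan.seed)
    for cid in sorted(present):
        idx = np.flatnonzero(cids == cid)
        if cid in plan.ood_conditions:
            split[idx] = "ood"
            continue
        n_test = int(round(plan.test_fraction * len(idx)))
        test_idx = rng.choice(idx, size=n_test, replace=False)
        split[test_idx] = "test"
    return replace(ds, split=split)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_expression(
    raw_counts: np.ndarray,
    n_hvg: int,
    *,
    gene_names: list[str] | None = None,
    perturbation_names: list[str] | None = None,
    doses: np.ndarray | None = None,
    covariate_schemas: dict[str, list[str]] | None = None,
    covariates: pd.DataFrame | None = None,
    n_bins: int = 20,
) -> ExpressionDataset:
    """Normalize, log-transform and select highly variable genes.

    Cells are library-size scaled to the median per-cell total count, then
    log(x+1) transformed.  Genes are ranked by normalized dispersion
    (variance/mean of the normalized counts, z-scored within ``n_bins``
    equal-frequency mean bins), ties broken by gene index, and the top
    ``n_hvg`` are retained in dispersion-rank order.
    """
    counts = np.asarray(raw_counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValidationError("raw counts must be nonnegative")
    n, g = counts.shape
    if n_hvg > g:
        raise ValidationError(f"n_hvg={n_hvg} exceeds gene count G={g}")
    totals = counts.sum(axis=1)
    zero_cells = np.flatnonzero(totals == 0)
    if zero_cells.size:
        raise ValidationError(f"cell(s) with zero total counts: {zero_cells.tolist()}")
    target = float(np.median(totals))
    norm = counts * (target / totals)[:, None]

    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1) if n > 1 else np.zeros(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # z-score dispersion within equal-frequency mean bins
    order_by_mean = np.argsort(mean, kind="stable")
    bin_ids = np.empty(g, dtype=np.int64)
    bin_ids[order_by_mean] = np.minimum((np.arange(g) * n_bins) // g, n_bins - 1)
    norm_disp = np.zeros(g)
    for b in range(n_bins):
        in_bin = bin_ids == b
        if not in_bin.any():
            continue
        mu, sd = disp[in_bin].mean(), disp[in_bin].std()
        norm_disp[in_bin] = (disp[in_bin] - mu) / sd if sd > 0 else 0.0
    rank = np.lexsort((np.arange(g), -norm_disp))  # dispersion desc, ties by index
    keep = rank[:n_hvg]

    if gene_names is None:
        gene_names = [f"gene{i}" for i in range(g)]
    if perturbation_names is None:
        perturbation_names = []
    if doses is None:
        doses = np.zeros((n, len(perturbation_names)))
    if covariate_schemas is None:
        covariate_schemas = {}
    if covariates is None:
        covariates = pd.DataFrame(index=range(n))
    return ExpressionDataset(
        X=np.log1p(norm[:, keep]),
        gene_names=[gene_names[i] for i in keep],
        perturbation_names=perturbation_names,
        doses=doses,
        covariate_schemas=covariate_schemas,
        covariates=covariates.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# I/O: HDF5 annotated matrix (h5ad) and MatrixMarket + TSV
# ---------------------------------------------------------------------------

_PERT_COL, _DOSE_COL, _SPLIT_COL = "perturbation", "dose", "split"


def _obs_table(ds: ExpressionDataset) -> pd.DataFrame:
    perts, doses = [], []
    for i in range(ds.n_cells):
        row = ds.doses[i]
        applied = sorted(
            (ds.perturbation_names[j], row[j]) for j in np.flatnonzero(row > 0)
        )
        if applied:
            perts.append(DELIM.join(n for n, _ in applied))
            doses.append(DELIM.join(_format_dose(d) for _, d in applied))
        else:
            perts.append(CONTROL_TOKEN)
            doses.append("0")
    obs = pd.DataFrame({_PERT_COL: perts, _DOSE_COL: doses})
    for key in ds.covariate_schemas:
        obs[key] = ds.covariates[key].astype(str).to_numpy()
    if ds.split is not None:
        obs[_SPLIT_COL] = ds.split.astype(str)
    obs.index = obs.index.map(str)
    return obs


def _sidecar(ds: ExpressionDataset) -> dict:
    return {
        "perturbation_column": _PERT_COL,
        "dose_column": _DOSE_COL,
        "covariate_columns": list(ds.covariate_schemas),
        "covariate_levels": {k: list(v) for k, v in ds.covariate_schemas.items()},
        "perturbation_names": list(ds.perturbation_names),
        "delimiter": DELIM,
        "control_token": CONTROL_TOKEN,
    }


def _doses_from_obs(obs: pd.DataFrame, cfg: dict) -> np.ndarray:
    names = list(cfg["perturbation_names"])
    delim = cfg.get("delimiter", DELIM)
    ctrl = cfg.get("control_token", CONTROL_TOKEN)
    doses = np.zeros((len(obs), len(names)))
    for i, (pert, dose) in enumerate(
        zip(obs[cfg["perturbation_column"]], obs[cfg["dose_column"]])
    ):
        if str(pert) == ctrl:
            continue
        pnames = str(pert).split(delim)
        dvals = [float(v) for v in str(dose).split(delim)]
        if len(pnames) != len(dvals):
            raise ValidationError(f"row {i}: {pert!r} vs dose string {dose!r}")
        for p, d in zip(pnames, dvals):
            if p not in names:
                raise SchemaError(f"row {i}: unknown perturbation {p!r}")
            if d < 0:
                raise ValidationError(f"row {i}: negative dose {d} for {p!r}")
            if d == 0:
                raise ValidationError(f"row {i}: zero dose for listed perturbation {p!r}")
            doses[i, names.index(p)] = d
    return doses


def _dataset_from_parts(X, gene_names, obs: pd.DataFrame, cfg: dict) -> ExpressionDataset:
    for col in [cfg["perturbation_column"], cfg["dose_column"], *cfg["covariate_columns"]]:
        if col not in obs.columns:
            raise SchemaError(f"missing annotation column {col!r}")
    schemas = {k: [str(x) for x in v] for k, v in cfg["covariate_levels"].items()}
    covariates = obs[cfg["covariate_columns"]].astype(str).reset_index(drop=True)
    split = obs[_SPLIT_COL].to_numpy(dtype=object) if _SPLIT_COL in obs.columns else None
    return ExpressionDataset(
        X=np.asarray(X, dtype=np.float64),
        gene_names=list(gene_names),
        perturbation_names=list(cfg["perturbation_names"]),
        doses=_doses_from_obs(obs, cfg),
        covariate_schemas=schemas,
        covariates=covariates,
        split=split,
    )


def write_dataset(ds: ExpressionDataset, path, dialect: str = "h5ad") -> None:
    """Serialize to an annotated HDF5 matrix or an MTX + TSV directory."""
    import pathlib

    path = pathlib.Path(path)
    obs = _obs_table(ds)
    cfg = _sidecar(ds)
    if dialect == "h5ad":
        import anndata as ad

        var = pd.DataFrame(index=pd.Index(ds.gene_names, name="gene"))
        adata = ad.AnnData(X=ds.X.copy(), obs=obs, var=var)
        adata.uns["cpax"] = json.dumps(cfg)
        adata.write_h5ad(path)
    elif dialect == "mtx":
        from scipy import io as spio
        from scipy import sparse

        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(ds.X))
        obs.to_csv(path / "obs.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": ds.gene_names}).to_csv(path / "var.tsv", sep="\t", index=False)
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_dataset(path, dialect: str = "h5ad", config: dict | None = None) -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset` (or compatible files).

    ``config`` may override the sidecar/embedded column-naming configuration.
    """
    import pathlib

    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        cfg = config or json.loads(adata.uns["cpax"])
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return _dataset_from_parts(X, list(adata.var_names), adata.obs.reset_index(drop=True), cfg)
    if dialect == "mtx":
        from scipy import io as spio

        X = np.asarray(spio.mmread(str(path / "matrix.mtx")).todense())
        obs = pd.read_csv(path / "obs.tsv", sep="\t", dtype=str)
        var = pd.read_csv(path / "var.tsv", sep="\t", dtype=str)
        if config is None:
            with open(path / "config.yaml") as fh:
                config = yaml.safe_load(fh)
        return _dataset_from_parts(X, list(var["gene"]), obs, config)
    raise ValueError(f"unknown dialect {dialect!r}")
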