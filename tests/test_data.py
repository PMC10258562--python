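"""Container invariants, condition keys, preprocessing, splits and I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpax.data import (
    ExpressionDataset,
    SchemaError,
    SplitPlan,
    ValidationError,
    condition_id,
    make_split,
    parse_condition_id,
    preprocess_expression,
    read_dataset,
    write_dataset,
)
from conftest import tiny_dataset

PERTS = ["A", "B", "C"]


class TestConditionKeys:
    def test_combination_order_is_canonical(self):
        cov = {"cell_line": "l0"}
        a = condition_id(np.array([1.0, 2.0, 0.0]), cov, PERTS)
        assert a == "A+B@1.0+2.0|l0"
        # same condition regardless of how the dose vector was built
        assert condition_id(np.array([1.0, 2.0, 0.0]), cov, ["A", "B", "C"]) == a

    def test_control_key(self):
        assert condition_id(np.zeros(3), ["l0"], PERTS) == "ctrl@0|l0"

    @given(
        doses=st.lists(
            st.one_of(st.just(0.0), st.floats(1e-3, 1e3, allow_nan=False)),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_key_roundtrips_dose_vector_exactly(self, doses):
        doses = np.asarray(doses)
        cid = condition_id(doses, {"cv": "x"}, PERTS)
        back, cov = parse_condition_id(cid, PERTS, ["cv"])
        assert np.array_equal(back, doses)
        assert cov == {"cv": "x"}

    def test_unknown_perturbation_rejected(self):
        with pytest.raises(SchemaError):
            parse_condition_id("Z@1.0|x", PERTS, ["cv"])


class TestValidation:
    def test_negative_dose_rejected(self, tiny_ds):
        with pytest.raises(ValidationError, match="doses"):
            ExpressionDataset(
                X=tiny_ds.X,
                gene_names=tiny_ds.gene_names,
                perturbation_names=tiny_ds.perturbation_names,
                doses=tiny_ds.doses - 1.0,
                covariate_schemas=tiny_ds.covariate_schemas,
                covariates=tiny_ds.covariates,
            )

    def test_dimension_mismatch_rejected(self, tiny_ds):
        with pytest.raises(ValidationError):
            ExpressionDataset(
                X=tiny_ds.X,
                gene_names=tiny_ds.gene_names[:-1],
                perturbation_names=tiny_ds.perturbation_names,
                doses=tiny_ds.doses,
                covariate_schemas=tiny_ds.covariate_schemas,
                covariates=tiny_ds.covariates,
            )

    def test_invalid_covariate_level_rejected(self, tiny_ds):
        bad = tiny_ds.covariates.copy()
        bad.iloc[0, 0] = "not-a-level"
        with pytest.raises(ValidationError, match="level"):
            ExpressionDataset(
                X=tiny_ds.X,
                gene_names=tiny_ds.gene_names,
                perturbation_names=tiny_ds.perturbation_names,
                doses=tiny_ds.doses,
                covariate_schemas=tiny_ds.covariate_schemas,
                covariates=bad,
            )


class TestPreprocess:
    def test_hand_example_median_normalize_then_log1p(self):
        # cell (2,0,2): total 4 equals the median total, so normalization is
        # the identity and log1p gives (log 3, 0, log 3)
        counts = np.array([[2, 0, 2], [1, 2, 1], [0, 1, 3], [4, 0, 0]], dtype=float)
        ds = preprocess_expression(counts, n_hvg=3)
        assert np.median(counts.sum(axis=1)) == 4.0
        row = ds.X[0]
        by_name = dict(zip(ds.gene_names, row))
        assert by_name["gene0"] == pytest.approx(np.log(3.0))
        assert by_name["gene1"] == 0.0
        assert by_name["gene2"] == pytest.approx(np.log(3.0))

    def test_zeros_preserved_and_duplicates_identical(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(30, 20)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        counts[5] = counts[4]
        ds = preprocess_expression(counts, n_hvg=20, gene_names=[f"g{i}" for i in range(20)])
        kept = [int(g[1:]) for g in ds.gene_names]
        assert sorted(kept) == list(range(20))  # n_hvg = G keeps all genes
        assert np.array_equal(ds.X == 0, counts[:, kept] == 0)
        assert np.array_equal(ds.X[4], ds.X[5])

    def test_top_hvg_selection_is_nested(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(50, 30)).astype(float)
        counts[:, :5] *= rng.integers(1, 8, size=(50, 5))  # overdispersed genes
        g10 = preprocess_expression(counts, n_hvg=10).gene_names
        g20 = preprocess_expression(counts, n_hvg=20).gene_names
        assert set(g10) <= set(g20)

    def test_matches_scanpy_normalization(self):
        """Independent route: scanpy's median-target normalize_total + log1p."""
        import scanpy as sc
        import anndata as ad

        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(40, 25)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        ours = preprocess_expression(counts, n_hvg=25)
        order = np.argsort([int(g[4:]) for g in ours.gene_names])
        adata = ad.AnnData(X=counts.copy())
        sc.pp.normalize_total(adata)
        sc.pp.log1p(adata)
        np.testing.assert_allclose(ours.X[:, order], adata.X, rtol=1e-10)

    def test_errors(self):
        with pytest.raises(ValidationError, match="n_hvg"):
            preprocess_expression(np.ones((3, 4)), n_hvg=5)
        with pytest.raises(ValidationError, match="zero total"):
            preprocess_expression(np.array([[1.0, 1.0], [0.0, 0.0]]), n_hvg=2)
        with pytest.raises(ValidationError, match="nonnegative"):
            preprocess_expression(np.array([[1.0, -1.0]]), n_hvg=2)


class TestSplit:
    def test_ood_conditions_fully_held_out(self):
        ds, _ = tiny_dataset(3)
        cids = ds.condition_ids
        pair_cid = next(c for c in set(cids) if c.startswith("A+B@"))
        split_ds = make_split(ds, SplitPlan(ood_conditions={pair_cid}, seed=1))
        assert set(split_ds.split[cids == pair_cid]) == {"ood"}
        assert "ood" not in split_ds.split[cids != pair_cid]

    def test_seed_reproducible_and_empty_plan(self):
        ds, _ = tiny_dataset(3)
        a = make_split(ds, SplitPlan(seed=7)).split
        b = make_split(ds, SplitPlan(seed=7)).split
        assert np.array_equal(a, b)
        assert set(a) == {"train", "test"}

    def test_unknown_ood_condition_listed_in_error(self):
        ds, _ = tiny_dataset(3)
        with pytest.raises(ValidationError, match="no-such-condition"):
            make_split(ds, SplitPlan(ood_conditions={"no-such-condition"}))


class TestIO:
    @pytest.mark.parametrize("dialect", ["h5ad", "mtx"])
    def test_write_read_roundtrip(self, tmp_path, dialect):
        ds, _ = tiny_dataset(4, n_cells=10)
        path = tmp_path / ("ds.h5ad" if dialect == "h5ad" else "ds_mtx")
        write_dataset(ds, path, dialect=dialect)
        back = read_dataset(path, dialect=dialect)
        np.testing.assert_allclose(back.X, ds.X, atol=1e-12)
        assert back.gene_names == ds.gene_names
        assert back.perturbation_names == ds.perturbation_names
        np.testing.assert_array_equal(back.doses, ds.doses)
        assert np.array_equal(back.condition_ids, ds.condition_ids)
        assert np.array_equal(back.split, ds.split)

    def test_negative_dose_in_file_rejected(self, tmp_path):
        ds, _ = tiny_dataset(4, n_cells=5)
        write_dataset(ds, tmp_path / "ds_mtx", dialect="mtx")
        obs = pd.read_csv(tmp_path / "ds_mtx" / "obs.tsv", sep="\t", dtype=str)
        applied = obs["perturbation"] != "ctrl"
        obs.loc[applied, "dose"] = obs.loc[applied, "dose"].str.replace(r"^", "-", regex=True)
        obs.to_csv(tmp_path / "ds_mtx" / "obs.tsv", sep="\t", index=False)
        with pytest.raises(ValidationError, match="negative dose"):
            read_dataset(tmp_path / "ds_mtx", dialect="mtx")

    def test_missing_annotation_column_is_schema_error(self, tmp_path):
        ds, _ = tiny_dataset(4, n_cells=5)
        write_dataset(ds, tmp_path / "ds_mtx", dialect="mtx")
        obs = pd.read_csv(tmp_path / "ds_mtx" / "obs.tsv", sep="\t", dtype=str)
        obs.drop(columns=["dose"]).to_csv(tmp_path / "ds_mtx" / "obs.tsv", sep="\t", index=False)
        with pytest.raises(SchemaError):
            read_dataset(tmp_path / "ds_mtx", dialect="mtx")
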