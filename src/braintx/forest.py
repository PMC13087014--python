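"""Random-forest regression of regional atrophy on the gene panel, with
out-of-bag permutation importance and surrogate-null significance.

The forest is built as an explicit bagging loop over scikit-learn regression
trees so that the bootstrap, the out-of-bag (OOB) sets and the permutation
importance are fully controlled and seeded: importance for a predictor is
the mean over trees of the increase in that tree's OOB MSE when the
predictor's OOB values are permuted (the classic increase-in-MSE measure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .atlas import RegionMap
from .expression import ExpressionMatrix
from .surrogates import SurrogateEnsemble, empirical_pvalue


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; ``mtry`` defaults to floor(n_predictors / 3)."""

    ntree: int = 500
    mtry: int | None = None
    nodesize: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")

    def resolved_mtry(self, n_predictors: int) -> int:
        mtry = self.mtry if self.mtry is not None else n_predictors // 3
        mtry = max(1, mtry)
        if mtry > n_predictors:
            raise ValueError(f"mtry={mtry} exceeds predictor count {n_predictors}")
        return mtry


@dataclass
class ForestResult:
    oob_mse: float
    pct_var: float  # 100 * (1 - oob_mse / population variance of y)
    r2: float  # same quantity with the sample-variance (n-1) denominator
    importance: pd.DataFrame  # gene, inc_mse, inc_mse_pct [, p_spatial]
    config: ForestConfig
    p_spatial_global: float = float("nan")
    n_null: int = 0
    null_seed: int | None = None


def fit_forest(
    expression: ExpressionMatrix,
    atrophy: RegionMap,
    config: ForestConfig | None = None,
    compute_importance: bool = True,
) -> ForestResult:
    """Bagged regression trees with OOB error and permutation importance.

    ``compute_importance=False`` skips the per-tree permutation pass (used by
    large calibration runs that only need the global fit); importances are
    then reported as NaN.
    """
    config = config or ForestConfig()
    if expression.atlas != atrophy.atlas:
        raise ValueError("expression and atrophy must share an atlas")
    X = expression.values
    y = atrophy.values
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 regions")
    if config.nodesize >= n:
        raise ValueError("nodesize leaves no room for splitting")
    mtry = config.resolved_mtry(p)

    ss = np.random.SeedSequence(config.seed)
    tree_seeds = ss.spawn(config.ntree)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    imp_sum = np.zeros(p)
    imp_trees = 0
    for t_idx in range(config.ntree):
        rng = np.random.default_rng(tree_seeds[t_idx])
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=config.nodesize,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        if not compute_importance:
            oob_sum[oob] += tree.predict(X[oob])
            oob_count[oob] += 1
            continue
        # one batched predict covers the OOB set and all p permuted variants
        Xo = X[oob]
        m = oob.size
        blocks = [Xo]
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            blocks.append(Xp)
        preds = tree.predict(np.vstack(blocks)).reshape(p + 1, m)
        oob_sum[oob] += preds[0]
        oob_count[oob] += 1
        mses = np.mean((y[oob][None, :] - preds) ** 2, axis=1)
        imp_sum += mses[1:] - mses[0]
        imp_trees += 1

    seen = oob_count > 0
    if not seen.all():
        # with very few trees some regions may never be OOB; exclude them
        missing = int((~seen).sum())
        import warnings

        warnings.warn(f"{missing} regions had no OOB predictions; excluded from MSE")
    oob_pred = np.where(seen, oob_sum / np.maximum(oob_count, 1), np.nan)
    oob_mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2))
    var_pop = float(np.var(y))  # population (divide-by-n) convention
    var_samp = float(np.var(y, ddof=1))
    pct_var = 100.0 * (1.0 - oob_mse / var_pop)
    r2 = 1.0 - oob_mse / var_samp
    inc = imp_sum / imp_trees if imp_trees else np.full(p, np.nan)
    importance = pd.DataFrame(
        {
            "gene": list(expression.genes),
            "inc_mse": inc,
            "inc_mse_pct": 100.0 * inc / oob_mse if oob_mse > 0 else np.nan,
        }
    )
    return ForestResult(
        oob_mse=oob_mse, pct_var=pct_var, r2=r2, importance=importance, config=config
    )


def forest_null(
    expression: ExpressionMatrix,
    atrophy: RegionMap,
    ensembles: Mapping[str, SurrogateEnsemble],
    n_null: int = 1000,
    seed: int = 0,
    config: ForestConfig | None = None,
    surrogate_outcome: bool = False,
    compute_importance: bool = True,
) -> dict[str, np.ndarray]:
    """Null distributions of global fit and importances.

    Each iteration replaces every gene's map with an independently drawn
    cached surrogate of that gene (default), or — with
    ``surrogate_outcome=True`` — keeps the predictors and is retained for
    sensitivity analyses where the caller supplies an atrophy ensemble under
    the key ``"__atrophy__"``.  Tree seeds are re-derived per iteration from
    the master seed.
    """
    config = config or ForestConfig()
    genes = expression.genes
    for g in genes if not surrogate_outcome else []:
        ens = ensembles.get(g)
        if ens is None:
            raise ValueError(f"no surrogate ensemble cached for gene {g}")
        if ens.n_surrogates < n_null:
            raise ValueError(
                f"gene {g}: cache holds {ens.n_surrogates} surrogates, "
                f"need >= {n_null}"
            )
    if surrogate_outcome and "__atrophy__" not in ensembles:
        raise ValueError("surrogate_outcome mode needs an '__atrophy__' ensemble")

    rng = np.random.default_rng(seed)
    iter_seeds = np.random.SeedSequence(seed).generate_state(n_null)
    pct_var = np.empty(n_null)
    r2 = np.empty(n_null)
    imps = np.empty((n_null, len(genes)))
    for i in range(n_null):
        iconfig = ForestConfig(
            ntree=config.ntree,
            mtry=config.mtry,
            nodesize=config.nodesize,
            seed=int(iter_seeds[i]),
        )
        if surrogate_outcome:
            ens = ensembles["__atrophy__"]
            y_null = ens.surrogates[rng.integers(ens.n_surrogates)]
            res = fit_forest(
                expression, RegionMap(expression.atlas, y_null), iconfig,
                compute_importance=compute_importance,
            )
        else:
            Xn = np.column_stack(
                [
                    ensembles[g].surrogates[rng.integers(ensembles[g].n_surrogates)]
                    for g in genes
                ]
            )
            # surrogate values may leave [0,1] in non-resample mode; rescale defensively
            Xn = np.clip(Xn, 0.0, 1.0)
            res = fit_forest(
                ExpressionMatrix(expression.atlas, genes, Xn), atrophy, iconfig,
                compute_importance=compute_importance,
            )
        pct_var[i] = res.pct_var
        r2[i] = res.r2
        imps[i] = res.importance["inc_mse"].to_numpy()
    return {"pct_var": pct_var, "r2": r2, "importance": imps, "seed": np.array([seed])}


def forest_significance(
    empirical: ForestResult, nulls: Mapping[str, np.ndarray]
) -> ForestResult:
    """Attach one-sided (greater) add-one empirical p-values for the global
    fit and each gene's importance."""
    null_imp = np.asarray(nulls["importance"], dtype=float)
    if null_imp.ndim != 2 or null_imp.shape[1] != len(empirical.importance):
        raise ValueError("null importance array does not match the gene panel")
    n_null = null_imp.shape[0]
    if n_null < 1:
        raise ValueError("need at least one null fit")
    p_global = empirical_pvalue(
        empirical.pct_var, nulls["pct_var"], sided="greater"
    )
    imp = empirical.importance.copy()
    imp["p_spatial"] = [
        empirical_pvalue(obs, null_imp[:, j], sided="greater")
        for j, obs in enumerate(imp["inc_mse"])
    ]
    seed_arr = nulls.get("seed")
    return ForestResult(
        oob_mse=empirical.oob_mse,
        pct_var=empirical.pct_var,
        r2=empirical.r2,
        importance=imp,
        config=empirical.config,
        p_spatial_global=p_global,
        n_null=n_null,
        null_seed=int(seed_arr[0]) if seed_arr is not None else None,
    )
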