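"""Per-gene linear gene-atrophy regression with spatial-null p-values and
FDR control across the gene panel."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import RegionMap
from .expression import ExpressionMatrix
from .surrogates import SurrogateEnsemble, empirical_pvalue, generate_surrogates


class RegressionFit(NamedTuple):
    beta: float
    se: float
    t: float
    df: int
    r2: float


@dataclass
class AssociationResult:
    gene: str
    beta: float
    se: float
    t: float
    df: int
    r2: float
    p_spatial: float
    p_bh: float = float("nan")
    significant: bool = False
    n_surrogates: int = 0


def fit_gene_regression(
    atrophy: RegionMap | np.ndarray, gene_map: RegionMap | np.ndarray
) -> RegressionFit:
    """Simple OLS of regional atrophy on regional expression (with
    intercept); df = n - 2.

    The sign convention follows directly: higher expression in more atrophic
    (more negative w-score) regions yields beta < 0.
    """
    y = atrophy.values if isinstance(atrophy, RegionMap) else np.asarray(atrophy, float)
    x = gene_map.values if isinstance(gene_map, RegionMap) else np.asarray(gene_map, float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 regions")
    if x.size != n:
        raise ValueError("atrophy and gene map must have matching regions")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    beta = sxy / sxx
    resid = y - (ybar + beta * (x - xbar))
    df = n - 2
    s2 = (resid**2).sum() / df
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore"):
        t = beta / se if se > 0 else np.sign(beta) * np.inf
    syy = ((y - ybar) ** 2).sum()
    r2 = 0.0 if syy == 0 else 1.0 - (resid**2).sum() / syy
    return RegressionFit(float(beta), float(se), float(t), int(df), float(r2))


def batch_regression_t(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """t-statistics of simple OLS of ``y`` on each row of ``X``.

    Vectorized via the correlation identity t = r * sqrt(df / (1 - r^2));
    used to score surrogate ensembles cheaply.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    df = n - 2
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yc**2).sum())
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (xnorm * ynorm)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt(df / (1.0 - r**2))


def spatial_association_test(
    atrophy: RegionMap,
    gene_map: RegionMap,
    ensemble: SurrogateEnsemble,
    sided: str = "two",
) -> tuple[float, np.ndarray]:
    """Spatial p-value of the gene-atrophy regression.

    The regression is refitted with each surrogate of the gene map in place
    of the empirical map; the empirical t is then referred to the null t
    distribution with the add-one empirical p-value.
    """
    if not np.allclose(ensemble.source_values, gene_map.values):
        raise ValueError("ensemble was not generated from this gene map")
    fit = fit_gene_regression(atrophy, gene_map)
    null_t = batch_regression_t(atrophy.values, ensemble.surrogates)
    return empirical_pvalue(fit.t, null_t, sided=sided), null_t


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns (reject flags, adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def run_association_suite(
    atrophy: RegionMap,
    expression: ExpressionMatrix,
    n_surrogates: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
    sided: str = "two",
    ensembles: Mapping[str, SurrogateEnsemble] | None = None,
) -> tuple[pd.DataFrame, dict[str, SurrogateEnsemble]]:
    """Per-gene regression + spatial p across the panel, then BH FDR.

    Surrogate ensembles are generated once per gene (seeded independently
    from the master seed) and returned so the forest stage can reuse them.
    """
    genes = expression.genes
    if len(genes) < 1:
        raise ValueError("empty gene panel")
    cache: dict[str, SurrogateEnsemble] = dict(ensembles or {})
    child_seeds = np.random.SeedSequence(seed).generate_state(len(genes))
    results = []
    for g, gseed in zip(genes, child_seeds):
        gmap = RegionMap(expression.atlas, expression.gene_map(g), name=g)
        ens = cache.get(g)
        if ens is None or ens.n_surrogates < n_surrogates:
            ens = generate_surrogates(
                gmap, n_surrogates, seed=int(gseed), source_id=g
            )
            cache[g] = ens
        fit = fit_gene_regression(atrophy, gmap)
        p_spatial, _ = spatial_association_test(atrophy, gmap, ens, sided=sided)
        results.append(
            AssociationResult(
                gene=g,
                beta=fit.beta,
                se=fit.se,
                t=fit.t,
                df=fit.df,
                r2=fit.r2,
                p_spatial=p_spatial,
                n_surrogates=ens.n_surrogates,
            )
        )
    reject, p_adj = bh_fdr([r.p_spatial for r in results], q=q)
    for r, rej, pa in zip(results, reject, p_adj):
        r.p_bh = float(pa)
        r.significant = bool(rej)
    table = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "r2": [r.r2 for r in results],
            "p_spatial": [r.p_spatial for r in results],
            "p_bh": [r.p_bh for r in results],
            "significant": [r.significant for r in results],
            "n_surrogates": [r.n_surrogates for r in results],
        }
    )
    return table, cache
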