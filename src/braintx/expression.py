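"""Donor microarray processing into a normative region-by-gene matrix.

The chain mirrors a standard normative-expression workflow: intensity-based
probe filtering against background, one-probe-per-gene selection by
cross-donor consistency (differential stability), assignment of tissue
samples to parcels within a distance tolerance, nearest-sample interpolation
of empty parcels, scaled robust sigmoid normalization, and donor averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .atlas import RegionAtlas

logger = logging.getLogger(__name__)

#: consistent-SD scaling constant for the IQR (IQR of a normal is 1.35 SD)
IQR_TO_SD = 1.35

#: assignment tolerance in mm (inclusive)
DEFAULT_ASSIGNMENT_TOLERANCE = 2.0


@dataclass
class DonorSampleSet:
    """Raw microarray samples for a single donor.

    ``intensities`` and ``background`` are ``(n_probes, n_samples)`` arrays
    aligned with ``probe_ids``; ``probe_map`` maps probe id to gene symbol.
    """

    donor_id: str
    sample_coords: np.ndarray  # (n_samples, 3) mm
    probe_ids: tuple[str, ...]
    intensities: np.ndarray  # (n_probes, n_samples)
    background: np.ndarray  # (n_probes, n_samples)
    probe_map: dict[str, str]

    def __post_init__(self) -> None:
        self.sample_coords = np.asarray(self.sample_coords, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.probe_ids = tuple(self.probe_ids)
        n_probes = len(self.probe_ids)
        n_samples = self.sample_coords.shape[0]
        if self.sample_coords.ndim != 2 or self.sample_coords.shape[1] != 3:
            raise ValueError("sample_coords must be (n_samples, 3)")
        if not np.all(np.isfinite(self.sample_coords)):
            raise ValueError("sample coordinates must be finite")
        if self.intensities.shape != (n_probes, n_samples):
            raise ValueError("intensities shape must be (n_probes, n_samples)")
        if self.background.shape != (n_probes, n_samples):
            raise ValueError("background shape must be (n_probes, n_samples)")
        missing = [p for p in self.probe_ids if p not in self.probe_map]
        if missing:
            raise ValueError(f"probes missing from probe_map: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return self.sample_coords.shape[0]

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(
                f"probe {probe_id!r} absent from donor {self.donor_id}"
            ) from None


@dataclass
class ExpressionMatrix:
    """Normative region-by-gene expression, unit-interval values."""

    atlas: RegionAtlas
    genes: tuple[str, ...]
    values: np.ndarray  # (n_regions, n_genes)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.atlas.n_regions, len(self.genes)):
            raise ValueError(
                f"values must be ({self.atlas.n_regions}, {len(self.genes)}), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing cells)")
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ValueError("expression values must lie in [0, 1]")

    def gene_map(self, gene: str) -> np.ndarray:
        try:
            j = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.atlas.region_ids), columns=list(self.genes)
        )

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.genes.index(g) for g in genes]
        return ExpressionMatrix(self.atlas, tuple(genes), self.values[:, idx])


# ---------------------------------------------------------------------------
# probe filtering and selection
# ---------------------------------------------------------------------------

def filter_probes_by_intensity(
    donors: Sequence[DonorSampleSet],
) -> tuple[list[str], pd.Series]:
    """Discard probes below background in at least half of all samples.

    Samples are pooled across donors; a probe survives iff the fraction of
    samples with intensity strictly below its background value is < 0.5
    (i.e. probes at or above the 50% failure mark are discarded).

    Returns
    -------
    retained, fractions
        List of retained probe ids and the per-probe below-background
        fraction over the pooled samples.
    """
    if len(donors) < 1:
        raise ValueError("need at least one donor")
    probes = donors[0].probe_ids
    if len(probes) < 1:
        raise ValueError("need at least one probe")
    for d in donors[1:]:
        if d.probe_ids != probes:
            missing = set(probes).symmetric_difference(d.probe_ids)
            raise ValueError(
                f"probe sets differ across donors (donor {d.donor_id}): "
                f"{sorted(missing)[:5]}"
            )
    below = np.concatenate(
        [(d.intensities < d.background).astype(float) for d in donors], axis=1
    )
    fractions = pd.Series(below.mean(axis=1), index=list(probes))
    retained = [p for p in probes if fractions[p] < 0.5]
    return retained, fractions


def _donor_region_profile(
    donor: DonorSampleSet,
    atlas: RegionAtlas,
    probe_idx: int,
    assignments: np.ndarray,
) -> np.ndarray:
    """Region-averaged intensity profile of one probe (NaN where no sample)."""
    prof = np.full(atlas.n_regions, np.nan)
    vals = donor.intensities[probe_idx]
    for r in range(atlas.n_regions):
        mask = assignments == r
        if mask.any():
            prof[r] = vals[mask].mean()
    return prof


def select_probe_per_gene(
    donors: Sequence[DonorSampleSet],
    retained_probes: Iterable[str],
    atlas: RegionAtlas,
    tolerance: float = DEFAULT_ASSIGNMENT_TOLERANCE,
) -> dict[str, tuple[str, float]]:
    """Pick the most consistent probe per gene (differential stability).

    Each candidate probe is scored by the mean pairwise Spearman correlation
    of its region-averaged profile between donor pairs (regions observed in
    both donors).  Genes whose only retained probe has no competitor get that
    probe with a NaN score; genes with no retained probe are dropped with a
    warning.

    Returns a mapping gene -> (probe_id, score).
    """
    retained = list(retained_probes)
    if not retained:
        raise ValueError("no retained probes")
    probe_map = donors[0].probe_map
    genes: dict[str, list[str]] = {}
    for p in retained:
        genes.setdefault(probe_map[p], []).append(p)

    assignments = [assign_samples_to_regions(d, atlas, tolerance) for d in donors]
    profiles: dict[str, list[np.ndarray]] = {}
    for p in retained:
        profs = []
        for d, asn in zip(donors, assignments):
            profs.append(_donor_region_profile(d, atlas, d.probe_index(p), asn))
        profiles[p] = profs

    selected: dict[str, tuple[str, float]] = {}
    for gene, plist in genes.items():
        if len(plist) == 1:
            selected[gene] = (plist[0], float("nan"))
            continue
        if len(donors) < 2:
            raise ValueError("consistency scoring requires at least 2 donors")
        best_probe, best_score = None, -np.inf
        for p in plist:
            profs = profiles[p]
            corrs = []
            for i in range(len(profs)):
                for j in range(i + 1, len(profs)):
                    both = np.isfinite(profs[i]) & np.isfinite(profs[j])
                    if both.sum() < 3:
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rho = spearmanr(profs[i][both], profs[j][both]).statistic
                    if np.isfinite(rho):
                        corrs.append(rho)
            score = float(np.mean(corrs)) if corrs else -np.inf
            if score > best_score:
                best_probe, best_score = p, score
        selected[gene] = (best_probe, best_score)

    all_genes = set(probe_map.values())
    for gene in sorted(all_genes - set(selected)):
        warnings.warn(
            f"gene {gene} has no retained probes and was dropped", UserWarning
        )
    return selected


# ---------------------------------------------------------------------------
# sample-to-region assignment and interpolation
# ---------------------------------------------------------------------------

def assign_samples_to_regions(
    donor: DonorSampleSet,
    atlas: RegionAtlas,
    tolerance: float = DEFAULT_ASSIGNMENT_TOLERANCE,
) -> np.ndarray:
    """Nearest-centroid assignment within ``tolerance`` mm (inclusive).

    Returns an integer array of region indices, with -1 for unassigned
    samples.  Ties go to the lowest region index.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    diffs = donor.sample_coords[:, None, :] - atlas.centroids[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    nearest = np.argmin(dists, axis=1)  # argmin takes the lowest index on ties
    mind = dists[np.arange(len(nearest)), nearest]
    out = np.where(mind <= tolerance, nearest, -1)
    return out.astype(int)


def donor_region_matrix(
    donor: DonorSampleSet,
    atlas: RegionAtlas,
    probe_per_gene: Mapping[str, str],
    tolerance: float = DEFAULT_ASSIGNMENT_TOLERANCE,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Average assigned samples per region for each gene's selected probe.

    Returns the partial region-by-gene matrix (NaN where no sample landed),
    plus the per-sample gene-expression matrix and the assignment vector,
    which downstream interpolation reuses.
    """
    genes = list(probe_per_gene)
    probe_rows = [donor.probe_index(probe_per_gene[g]) for g in genes]
    sample_expr = donor.intensities[probe_rows].T  # (n_samples, n_genes)
    assignments = assign_samples_to_regions(donor, atlas, tolerance)
    mat = np.full((atlas.n_regions, len(genes)), np.nan)
    for r in range(atlas.n_regions):
        mask = assignments == r
        if mask.any():
            mat[r] = sample_expr[mask].mean(axis=0)
    frame = pd.DataFrame(mat, index=list(atlas.region_ids), columns=genes)
    return frame, sample_expr, assignments


def interpolate_empty_regions(
    partial: pd.DataFrame,
    sample_coords: np.ndarray,
    sample_values: np.ndarray,
    atlas: RegionAtlas,
    donor_id: str = "?",
) -> pd.DataFrame:
    """Fill empty regions with the nearest tissue sample's expression.

    Nearest is centroid-to-sample Euclidean distance over all of the donor's
    samples.  Raises if the donor contributed no samples at all.
    """
    sample_coords = np.asarray(sample_coords, dtype=float)
    sample_values = np.asarray(sample_values, dtype=float)
    if sample_coords.shape[0] == 0:
        raise ValueError(f"donor {donor_id} has no samples to interpolate from")
    out = partial.copy()
    empty = out.isna().any(axis=1).to_numpy()
    if not empty.any():
        return out
    for r in np.flatnonzero(empty):
        d = np.linalg.norm(sample_coords - atlas.centroids[r], axis=1)
        out.iloc[r] = sample_values[np.argmin(d)]
    return out


# ---------------------------------------------------------------------------
# normalization and aggregation
# ---------------------------------------------------------------------------

def _srs_slice(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid of a 1-D slice, mapped to [0, 1].

    Slices with a zero IQR fall back to rank-based scaling; slices with
    fewer than two distinct values are returned unchanged (nothing to scale).
    """
    distinct = np.unique(x)
    if distinct.size < 2:
        return x.copy()
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])  # linear-interpolation quartiles
    iqr = q75 - q25
    if iqr == 0:
        logger.info("zero IQR slice: falling back to rank-based scaling")
        ranks = rankdata(x)
        return (ranks - 1) / (len(x) - 1)
    y = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / IQR_TO_SD)))
    lo, hi = y.min(), y.max()
    return (y - lo) / (hi - lo)


def normalize_srs(matrix: np.ndarray | pd.DataFrame, axis: int = 0) -> np.ndarray | pd.DataFrame:
    """Scaled robust sigmoid normalization along ``axis``.

    ``axis=0`` normalizes each column over rows; ``axis=1`` each row over
    columns.  Output lies in [0, 1] except for degenerate (constant or
    single-element) slices, which pass through unchanged.
    """
    frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if frame else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    out = np.apply_along_axis(_srs_slice, axis, X)
    if frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def normalize_donor_matrix(matrix: pd.DataFrame, cross_gene: bool = True) -> pd.DataFrame:
    """Apply the two-step normalization to a complete region-by-gene matrix:
    first across genes within each region, then across regions within each
    gene."""
    out = matrix
    if cross_gene:
        out = normalize_srs(out, axis=1)
    return normalize_srs(out, axis=0)


def aggregate_donors(donor_matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean across donors, per cell."""
    if len(donor_matrices) == 0:
        raise ValueError("no donor matrices")
    first = donor_matrices[0]
    for m in donor_matrices[1:]:
        if m.shape != first.shape or list(m.index) != list(first.index) or list(
            m.columns
        ) != list(first.columns):
            raise ValueError("donor matrices must share region and gene sets")
    stacked = np.stack([m.to_numpy(dtype=float) for m in donor_matrices])
    return pd.DataFrame(stacked.mean(axis=0), index=first.index, columns=first.columns)


def gene_correlation_matrix(expression: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlations between gene expression profiles.

    Constant genes produce NaN rows/columns and a warning.
    """
    if expression.atlas.n_regions < 3:
        raise ValueError("need at least 3 regions for correlations")
    X = expression.values
    sds = X.std(axis=0)
    constant = sds == 0
    if constant.any():
        bad = [g for g, c in zip(expression.genes, constant) if c]
        warnings.warn(f"constant gene columns, correlations undefined: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=list(expression.genes), columns=list(expression.genes))


# ---------------------------------------------------------------------------
# end-to-end chain
# ---------------------------------------------------------------------------

def process_donors(
    donors: Sequence[DonorSampleSet],
    atlas: RegionAtlas,
    tolerance: float = DEFAULT_ASSIGNMENT_TOLERANCE,
    cross_gene_norm: bool = True,
    genes: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Full processing chain from donor sample sets to an ExpressionMatrix.

    filter probes -> select one probe per gene -> assign samples -> average
    per region per donor -> interpolate empty regions -> normalize (across
    genes, then across regions) -> average across donors.
    """
    retained, _ = filter_probes_by_intensity(donors)
    if not retained:
        raise ValueError("all probes were discarded by the intensity filter")
    if len(donors) >= 2:
        selection = select_probe_per_gene(donors, retained, atlas, tolerance)
    else:
        # single donor: no consistency scoring possible; keep first retained probe
        selection = {}
        for p in retained:
            selection.setdefault(donors[0].probe_map[p], (p, float("nan")))
    probe_per_gene = {g: pr for g, (pr, _) in sorted(selection.items())}
    if genes is not None:
        missing = [g for g in genes if g not in probe_per_gene]
        if missing:
            raise ValueError(f"genes with no surviving probe: {missing}")
        probe_per_gene = {g: probe_per_gene[g] for g in genes}

    donor_mats = []
    for d in donors:
        partial, sample_expr, assignments = donor_region_matrix(
            d, atlas, probe_per_gene, tolerance
        )
        if (assignments >= 0).sum() == 0:
            raise ValueError(f"donor {d.donor_id} has no assigned samples")
        filled = interpolate_empty_regions(
            partial, d.sample_coords, sample_expr, atlas, d.donor_id
        )
        donor_mats.append(normalize_donor_matrix(filled, cross_gene=cross_gene_norm))
    combined = aggregate_donors(donor_mats)
    values = np.clip(combined.to_numpy(dtype=float), 0.0, 1.0)
    return ExpressionMatrix(atlas, tuple(combined.columns), values)
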