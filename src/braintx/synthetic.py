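"""Synthetic inputs: atlas geometry, spatially autocorrelated maps, donor
microarray sample sets, and control/patient cohorts with known ground truth.

Every generator is a pure function of its arguments and a seed, so fixtures
and parameter-recovery experiments are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, RegionMap
from .expression import DonorSampleSet, ExpressionMatrix

# geometry of the default lobe clusters (mm)
CORTICAL_SHELL_RADIUS = 70.0
SUBCORTICAL_RADIUS = 25.0
CEREBELLAR_CENTRE = np.array([-20.0, -60.0, -40.0])
CEREBELLAR_SPREAD = 14.0
BRAINSTEM_CENTRE = np.array([0.0, -30.0, -45.0])
BRAINSTEM_SPREAD = 6.0

# default cohort demographics
AGE_MEAN, AGE_SD = 69.0, 8.6
TIV_MEAN, TIV_SD = 1450.0, 130.0
FEMALE_FRACTION = 0.3


@dataclass(frozen=True)
class GroundTruth:
    """Parameters that generated a simulated cohort.

    ``effect_coefficients`` are signed per-gene atrophy effects in units of
    w-score per unit of (normalized) expression; the injected volume shift is
    ``effect * expression * noise_sd`` so recovered w-score slopes are
    directly comparable to the coefficients.
    """

    effect_coefficients: dict[str, float]
    noise_sd: float
    spatial_length_scale: float
    seed: int
    spatial_noise_sd: float = 0.1  # patient-level SA noise, w-score units

    def to_json(self) -> str:
        return json.dumps(
            {
                "effect_coefficients": self.effect_coefficients,
                "noise_sd": self.noise_sd,
                "spatial_length_scale": self.spatial_length_scale,
                "spatial_noise_sd": self.spatial_noise_sd,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            effect_coefficients=dict(d["effect_coefficients"]),
            noise_sd=float(d["noise_sd"]),
            spatial_length_scale=float(d["spatial_length_scale"]),
            seed=int(d["seed"]),
            spatial_noise_sd=float(d.get("spatial_noise_sd", 0.1)),
        )


@dataclass
class SubjectTable:
    """Per-subject covariates and regional grey-matter volumes.

    ``covariates`` is indexed by subject id with columns ``group`` (control /
    patient), ``age`` (years), ``sex`` (F/M) and ``tiv`` (ml); ``volumes``
    shares the index and has one column per atlas region (ml).
    """

    covariates: pd.DataFrame
    volumes: pd.DataFrame
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        required = {"group", "age", "sex", "tiv"}
        missing = required - set(self.covariates.columns)
        if missing:
            raise ValueError(f"covariates missing columns: {sorted(missing)}")
        if not self.covariates.index.equals(self.volumes.index):
            raise ValueError("covariates and volumes must share subject index")
        if list(self.volumes.columns) != list(self.atlas.region_ids):
            raise ValueError("volume columns must match atlas region ids in order")
        bad_group = set(self.covariates["group"]) - {"control", "patient"}
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(self.covariates["sex"]) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
        if self.covariates[["age", "tiv"]].isna().any().any():
            raise ValueError("missing covariates")
        if not (self.volumes.to_numpy() > 0).all():
            raise ValueError("volumes must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def _subset(self, group: str) -> "SubjectTable":
        mask = self.covariates["group"] == group
        return SubjectTable(
            self.covariates.loc[mask].copy(),
            self.volumes.loc[mask].copy(),
            self.atlas,
        )

    def controls(self) -> "SubjectTable":
        return self._subset("control")

    def patients(self) -> "SubjectTable":
        return self._subset("patient")

    def select(self, subject_ids: Sequence[str]) -> "SubjectTable":
        ids = list(subject_ids)
        missing = [s for s in ids if s not in self.covariates.index]
        if missing:
            raise KeyError(f"unknown subject ids: {missing[:5]}")
        return SubjectTable(
            self.covariates.loc[ids].copy(), self.volumes.loc[ids].copy(), self.atlas
        )


@dataclass(frozen=True)
class CovariateModel:
    """Linear volume model used by the cohort simulator.

    Scalar coefficients are broadcast over regions; per-region arrays are
    accepted too.  Units: baseline ml, tiv coefficient ml/ml, age ml/year,
    sex (F=1 indicator) ml.
    """

    baseline: float | np.ndarray = 10.0
    beta_tiv: float | np.ndarray = 0.004
    beta_age: float | np.ndarray = -0.02
    beta_sex: float | np.ndarray = 0.15

    def per_region(self, n_regions: int) -> tuple[np.ndarray, ...]:
        out = []
        for v in (self.baseline, self.beta_tiv, self.beta_age, self.beta_sex):
            arr = np.broadcast_to(np.asarray(v, dtype=float), (n_regions,))
            out.append(np.array(arr))
        return tuple(out)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def _shell_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Points on the upper half of a sphere of the given radius."""
    pts = rng.standard_normal((n, 3))
    pts[:, 2] = np.abs(pts[:, 2])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts * radius


def make_atlas(
    n_cortical: int,
    n_subcortical: int,
    n_cerebellar: int,
    n_brainstem: int,
    seed: int = 0,
) -> RegionAtlas:
    """Build a synthetic parcellation with lobe-specific spatial clusters.

    Cortical centroids sit on a hemispheric shell, subcortical ones in a deep
    central ball, cerebellar ones in a posterior-inferior cluster and
    brainstem ones along the inferior midline.  Deterministic per seed.
    """
    counts = (n_cortical, n_subcortical, n_cerebellar, n_brainstem)
    if any(c < 0 for c in counts):
        raise ValueError("region counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("atlas must contain at least one region")
    rng = np.random.default_rng(seed)

    centroids, lobes, ids, labels = [], [], [], []
    if n_cortical:
        centroids.append(_shell_points(rng, n_cortical, CORTICAL_SHELL_RADIUS))
        lobes += ["cortical"] * n_cortical
        ids += [f"CTX{i + 1:02d}" for i in range(n_cortical)]
        labels += [f"cortical region {i + 1}" for i in range(n_cortical)]
    if n_subcortical:
        u = rng.standard_normal((n_subcortical, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = SUBCORTICAL_RADIUS * rng.uniform(0.3, 1.0, n_subcortical) ** (1 / 3)
        centroids.append(u * r[:, None])
        lobes += ["subcortical"] * n_subcortical
        ids += [f"SUB{i + 1:02d}" for i in range(n_subcortical)]
        labels += [f"subcortical region {i + 1}" for i in range(n_subcortical)]
    if n_cerebellar:
        centroids.append(
            CEREBELLAR_CENTRE + rng.standard_normal((n_cerebellar, 3)) * CEREBELLAR_SPREAD
        )
        lobes += ["cerebellar"] * n_cerebellar
        ids += [f"CBL{i + 1:02d}" for i in range(n_cerebellar)]
        labels += [f"cerebellar region {i + 1}" for i in range(n_cerebellar)]
    if n_brainstem:
        offsets = rng.standard_normal((n_brainstem, 3)) * BRAINSTEM_SPREAD
        offsets[:, 0] *= 0.2  # keep close to the midline
        centroids.append(BRAINSTEM_CENTRE + offsets)
        lobes += ["brainstem"] * n_brainstem
        ids += [f"BST{i + 1:02d}" for i in range(n_brainstem)]
        labels += [f"brainstem region {i + 1}" for i in range(n_brainstem)]

    return RegionAtlas(
        tuple(ids), tuple(labels), tuple(lobes), np.vstack(centroids)
    )


def default_atlas(seed: int = 0) -> RegionAtlas:
    """The default 58-region parcellation (41 cortical, 6 subcortical,
    9 cerebellar, 2 brainstem)."""
    return make_atlas(41, 6, 9, 2, seed=seed)


# ---------------------------------------------------------------------------
# spatially autocorrelated fields
# ---------------------------------------------------------------------------

def _sa_cholesky(atlas: RegionAtlas, length_scale: float) -> np.ndarray:
    if not np.isfinite(length_scale):
        raise ValueError("length_scale must be finite")
    if length_scale < 0:
        raise ValueError("length_scale must be >= 0")
    n = atlas.n_regions
    if length_scale == 0:
        return np.eye(n)
    cov = np.exp(-atlas.distance_matrix / length_scale)
    # tiny jitter keeps the factorization stable for near-duplicate centroids
    return np.linalg.cholesky(cov + 1e-10 * np.eye(n))


def simulate_sa_map(
    atlas: RegionAtlas, length_scale: float, seed: int = 0
) -> RegionMap:
    """Zero-mean unit-variance Gaussian field with exponential covariance
    ``exp(-d / length_scale)`` between regions at distance ``d``."""
    L = _sa_cholesky(atlas, length_scale)
    rng = np.random.default_rng(seed)
    return RegionMap(atlas, L @ rng.standard_normal(atlas.n_regions), name="sa_map")


def simulate_expression(
    atlas: RegionAtlas,
    genes: Sequence[str],
    length_scale: float = 40.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Spatially autocorrelated expression maps, min-max scaled to [0, 1]
    per gene."""
    genes = tuple(genes)
    if not genes:
        raise ValueError("gene list must not be empty")
    L = _sa_cholesky(atlas, length_scale)
    rng = np.random.default_rng(seed)
    fields = L @ rng.standard_normal((atlas.n_regions, len(genes)))
    lo, hi = fields.min(axis=0), fields.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return ExpressionMatrix(atlas, genes, (fields - lo) / span)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    atlas: RegionAtlas,
    expression: ExpressionMatrix,
    truth: GroundTruth,
    n_controls: int,
    n_patients: int,
    covariate_model: CovariateModel | None = None,
) -> tuple[SubjectTable, GroundTruth]:
    """Simulate controls and patients with a gene-linked atrophy effect.

    Control volumes follow the linear covariate model plus i.i.d. Gaussian
    noise of SD ``truth.noise_sd``.  Patient volumes are additionally shifted
    by ``sum_g effect_g * expression_g(region) * noise_sd`` plus a spatially
    autocorrelated disturbance, so the injected effects are expressed in
    residual-SD (w-score) units.
    """
    if expression.atlas != atlas:
        raise ValueError("expression regions do not match atlas")
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 subjects per group")
    effects = truth.effect_coefficients
    unknown = set(effects) - set(expression.genes)
    if unknown:
        raise ValueError(f"effect genes absent from expression matrix: {sorted(unknown)}")
    if len(effects) != len(expression.genes):
        raise ValueError(
            f"effect vector length {len(effects)} != gene count {len(expression.genes)}"
        )
    cm = covariate_model or CovariateModel()
    baseline, b_tiv, b_age, b_sex = cm.per_region(atlas.n_regions)

    rng = np.random.default_rng(truth.seed)
    n = n_controls + n_patients
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), 40.0, 95.0)
    tiv = np.clip(rng.normal(TIV_MEAN, TIV_SD, n), 1000.0, 2000.0)
    sex_f = (rng.random(n) < FEMALE_FRACTION).astype(float)
    group = np.array(["control"] * n_controls + ["patient"] * n_patients)

    expected = (
        baseline[None, :]
        + tiv[:, None] * b_tiv[None, :]
        + age[:, None] * b_age[None, :]
        + sex_f[:, None] * b_sex[None, :]
    )
    vols = expected + rng.normal(0.0, truth.noise_sd, (n, atlas.n_regions))

    shift = np.zeros(atlas.n_regions)
    for gene, eff in effects.items():
        shift += eff * expression.gene_map(gene)
    patient_rows = slice(n_controls, n)
    vols[patient_rows] += shift[None, :] * truth.noise_sd
    if truth.spatial_noise_sd > 0:
        L = _sa_cholesky(atlas, truth.spatial_length_scale)
        sa = (L @ rng.standard_normal((atlas.n_regions, n_patients))).T
        vols[patient_rows] += truth.spatial_noise_sd * truth.noise_sd * sa
    vols = np.maximum(vols, 1e-3)  # volumes must stay positive

    ids = [f"C{i + 1:04d}" for i in range(n_controls)] + [
        f"P{i + 1:04d}" for i in range(n_patients)
    ]
    covariates = pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": np.where(sex_f == 1.0, "F", "M"),
            "tiv": tiv,
        },
        index=pd.Index(ids, name="subject_id"),
    )
    volumes = pd.DataFrame(
        vols, index=covariates.index, columns=list(atlas.region_ids)
    )
    return SubjectTable(covariates, volumes, atlas), truth


# ---------------------------------------------------------------------------
# donors
# ---------------------------------------------------------------------------

def simulate_donors(
    atlas: RegionAtlas,
    n_donors: int,
    genes: Sequence[str],
    probes_per_gene: int = 2,
    background_sd: float = 0.1,
    seed: int = 0,
    noise_sd: float = 0.1,
    weak_probe_fraction: float = 0.0,
    coverage: float = 0.85,
    n_far_samples: int = 3,
    jitter_sd: float = 0.8,
    signal_length_scale: float = 40.0,
) -> list[DonorSampleSet]:
    """Generate multi-donor microarray sample sets over the atlas.

    A shared spatially autocorrelated signal per gene drives all donors (so
    probe selection has a consistent pattern to find).  Each donor covers a
    random subset of regions (fraction ``coverage``) with samples jittered
    around centroids, plus ``n_far_samples`` samples placed > 2 mm from every
    centroid to exercise interpolation.  A fraction ``weak_probe_fraction``
    of probes is generated below background to exercise intensity filtering.
    """
    if n_donors < 1:
        raise ValueError("need at least one donor")
    if probes_per_gene < 1:
        raise ValueError("need at least one probe per gene")
    genes = tuple(genes)
    if not genes:
        raise ValueError("gene list must not be empty")

    rng = np.random.default_rng(seed)
    n_regions = atlas.n_regions

    # region-level true signal per gene, positive intensity scale
    L = _sa_cholesky(atlas, signal_length_scale)
    signal = 8.0 + 1.5 * (L @ rng.standard_normal((n_regions, len(genes))))

    probe_ids, probe_map, probe_offsets, weak = [], {}, [], []
    for g in genes:
        for k in range(probes_per_gene):
            pid = f"{g}_p{k + 1}"
            probe_ids.append(pid)
            probe_map[pid] = g
            probe_offsets.append(rng.normal(0.0, 0.3))
            weak.append(rng.random() < weak_probe_fraction)
    probe_offsets = np.array(probe_offsets)
    weak = np.array(weak)
    background_base = 4.0

    donors = []
    for d in range(n_donors):
        covered = np.flatnonzero(rng.random(n_regions) < coverage)
        if covered.size == 0:
            covered = np.array([int(rng.integers(n_regions))])
        coords = atlas.centroids[covered] + rng.normal(
            0.0, jitter_sd, (covered.size, 3)
        )
        sample_regions = list(covered)
        if n_far_samples > 0:
            far = []
            while len(far) < n_far_samples:
                r = int(rng.integers(n_regions))
                offset = rng.normal(0.0, 1.0, 3)
                offset *= (5.0 + 3.0 * rng.random()) / np.linalg.norm(offset)
                pt = atlas.centroids[r] + offset
                if np.min(np.linalg.norm(atlas.centroids - pt, axis=1)) > 2.0:
                    far.append((pt, r))
            coords = np.vstack([coords] + [p for p, _ in far])
            sample_regions += [r for _, r in far]
        n_samples = coords.shape[0]

        gene_idx = np.array([genes.index(probe_map[p]) for p in probe_ids])
        truth_vals = signal[np.array(sample_regions)][:, gene_idx].T
        intens = (
            truth_vals
            + probe_offsets[:, None]
            + rng.normal(0.0, noise_sd, (len(probe_ids), n_samples))
        )
        bg = background_base + rng.normal(0.0, background_sd, intens.shape)
        # weak probes sit reliably below their background value
        intens[weak] = bg[weak] - 0.5 + rng.normal(
            0.0, noise_sd, (int(weak.sum()), n_samples)
        )
        donors.append(
            DonorSampleSet(
                donor_id=f"D{d + 1:02d}",
                sample_coords=coords,
                probe_ids=tuple(probe_ids),
                intensities=intens,
                background=bg,
                probe_map=dict(probe_map),
            )
        )
    return donors
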