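"""Summary statistics over vascular networks.

The per-sample feature vector condenses a traced network into interpretable
numbers: rPVV (vessel volume fraction), RM10 (supply-homogeneity range),
moments of segment length, diameter and straightness, the circular spread of
orientations, and the areas of highest-density regions of the 2D kernel
density estimate of diameter versus straightness (KDE_50(D/S), KDE_90(D/S)).
Small KDE_50(D/S) areas indicate a hierarchical network — few calibers, each
well represented, with little straightness spread — whereas chaotic networks
smear probability mass over wide diameter/straightness ranges.

Feature tables feed a standardized PCA for organ/tumor discrimination and
two-group comparisons with an equality-of-variance screen (pooled t-test,
Welch variant when the screen rejects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .distances import DistanceField, compute_rm10
from .segmentation import VesselMask
from .tracing import circular_sd

__all__ = [
    "KDEArea",
    "kde_area",
    "kde50_area",
    "SampleResult",
    "assemble_feature_table",
    "PCAResult",
    "run_pca",
    "GroupComparison",
    "group_compare",
    "miles_correction",
]


# ---------------------------------------------------------------------------
# 2D KDE highest-density-region areas
# ---------------------------------------------------------------------------


@dataclass
class KDEArea:
    pair: tuple[str, str]
    mass_level: float
    area: float
    bandwidths: tuple[float, float]
    grid_shape: tuple[int, int]
    threshold: float
    method: str


def kde_area(
    x: np.ndarray,
    y: np.ndarray,
    mass_level: float = 0.5,
    grid_size: int = 256,
    pad_bandwidths: float = 3.0,
    threshold_method: str = "sample_quantile",
    pair: tuple[str, str] = ("x", "y"),
) -> KDEArea:
    """Area of the highest-density region holding ``mass_level`` probability.

    A Gaussian product-kernel density with per-axis Scott bandwidths
    (``σ_i · n^(-1/6)``) is evaluated on a regular ``grid_size²`` grid padded
    by ``pad_bandwidths`` bandwidths beyond the data range.  The density
    threshold is then chosen by one of two methods:

    ``sample_quantile`` (default)
        The ``(1 − mass_level)`` quantile of the density evaluated *at the
        data points* (Hyndman's highest-density-region estimator).  The
        region then covers ``mass_level`` of the underlying distribution,
        which keeps the area estimate free of the kernel-smoothing inflation
        (for a bivariate normal the 50% area converges to ``2π ln2 σₓσᵧ``).

    ``grid_mass``
        Sort grid densities, accumulate KDE mass until ``mass_level`` is
        reached.  Simpler, but measures the smoothed density's own HDR and
        therefore runs ≈ ``n^(-1/3)`` large for Gaussian data.

    The area is the summed cell area where density ≥ threshold, in product
    units of the pair (e.g. µm × dimensionless for diameter/straightness).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D arrays")
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 points for a stable KDE area, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in KDE input")
    if not 0 < mass_level < 1:
        raise ValueError("mass_level must lie in (0, 1)")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError(
            "degenerate point cloud: zero variance along one axis, KDE area undefined"
        )
    r = np.corrcoef(x, y)[0, 1]
    if abs(r) > 1 - 1e-12:
        raise ValueError("degenerate point cloud: exactly collinear points")

    hx = sx * n ** (-1.0 / 6.0)
    hy = sy * n ** (-1.0 / 6.0)
    gx = np.linspace(x.min() - pad_bandwidths * hx, x.max() + pad_bandwidths * hx, grid_size)
    gy = np.linspace(y.min() - pad_bandwidths * hy, y.max() + pad_bandwidths * hy, grid_size)
    norm = 1.0 / (n * 2.0 * np.pi * hx * hy)
    ax = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    by = np.exp(-0.5 * ((y[:, None] - gy[None, :]) / hy) ** 2)
    density = norm * (ax @ by)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])

    if threshold_method == "sample_quantile":
        fx = np.exp(-0.5 * ((x[:, None] - x[None, :]) / hx) ** 2)
        fy = np.exp(-0.5 * ((y[:, None] - y[None, :]) / hy) ** 2)
        f_at_points = norm * (fx * fy).sum(axis=1)
        thr = float(np.quantile(f_at_points, 1.0 - mass_level))
    elif threshold_method == "grid_mass":
        flat = np.sort(density.ravel())[::-1]
        cum = np.cumsum(flat) * cell
        k = int(np.searchsorted(cum, mass_level))
        thr = float(flat[min(k, flat.size - 1)])
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    area = float(cell * np.count_nonzero(density >= thr))
    return KDEArea(
        pair=pair,
        mass_level=mass_level,
        area=area,
        bandwidths=(float(hx), float(hy)),
        grid_shape=(grid_size, grid_size),
        threshold=thr,
        method=threshold_method,
    )


def kde50_area(x: np.ndarray, y: np.ndarray, mass_level: float = 0.5, **kw) -> KDEArea:
    """Convenience wrapper for the 50% (or given level) KDE area of a pair."""
    return kde_area(x, y, mass_level=mass_level, **kw)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


@dataclass
class SampleResult:
    """Everything measured on one sample, ready for feature assembly."""

    name: str
    group: str
    segments: pd.DataFrame          # segment table (rim-cut rows still flagged)
    distance_field: DistanceField | None = None
    mask: VesselMask | None = None
    extra: dict = field(default_factory=dict)


FEATURE_COLUMNS = [
    "rpvv", "rm10", "length_mean", "length_sd", "diameter_mean", "diameter_sd",
    "straightness_mean", "straightness_sd", "orientation_circ_sd",
    "kde50_ds_area", "kde90_ds_area", "distance_mean", "distance_max",
    "segment_density", "filament_count",
]


def assemble_feature_table(
    samples: Sequence[SampleResult],
    kde_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One feature row per sample; rows with unmeasurable features are dropped.

    Boundary-touching segments are excluded from all morphometric statistics.
    ``segment_density`` is segments per 10⁶ µm³ of imaged tissue.
    """
    rows = []
    for s in samples:
        seg = s.segments
        if "touches_boundary" in seg:
            seg = seg[~seg["touches_boundary"]]
        row: dict[str, float | str] = {"sample": s.name, "group": s.group}
        try:
            if len(seg) < 2:
                raise ValueError("too few interior segments")
            row["length_mean"] = seg["length"].mean()
            row["length_sd"] = seg["length"].std(ddof=1)
            row["diameter_mean"] = seg["mean_diameter"].mean()
            row["diameter_sd"] = seg["mean_diameter"].std(ddof=1)
            row["straightness_mean"] = seg["straightness"].mean()
            row["straightness_sd"] = seg["straightness"].std(ddof=1)
            row["orientation_circ_sd"] = circular_sd(seg["orientation_xy"].to_numpy())
            kw = dict(pair=("mean_diameter", "straightness"))
            kw.update(kde_kwargs or {})
            d = seg["mean_diameter"].to_numpy()
            st = seg["straightness"].to_numpy()
            try:
                row["kde50_ds_area"] = kde_area(d, st, mass_level=0.5, **kw).area
                row["kde90_ds_area"] = kde_area(d, st, mass_level=0.9, **kw).area
            except ValueError as err:
                # degenerate D/S cloud (e.g. perfectly constant straightness)
                warnings.warn(f"sample {s.name!r}: KDE area unavailable ({err})", stacklevel=2)
                row["kde50_ds_area"] = np.nan
                row["kde90_ds_area"] = np.nan
            row["filament_count"] = float(seg["filament_id"].nunique())
            if s.distance_field is not None:
                rm = compute_rm10(s.distance_field)
                row["rm10"] = rm.rm10
                row["distance_mean"] = s.distance_field.mean
                row["distance_max"] = s.distance_field.max
            if s.mask is not None:
                row["rpvv"] = s.mask.rpvv
                vol_um3 = s.mask.mask.voxels.size * s.mask.mask.voxel_volume
                row["segment_density"] = 1e6 * len(seg) / vol_um3
            row.update({k: v for k, v in s.extra.items() if np.isscalar(v)})
        except ValueError as err:
            warnings.warn(f"dropping sample {s.name!r}: {err}", stacklevel=2)
            continue
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("sample")
    return df


# ---------------------------------------------------------------------------
# PCA and group comparison
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples × components
    loadings: pd.DataFrame          # features × components
    explained_variance_ratio: np.ndarray
    ranked_variables: list[str]     # by loading norm in the PC1–PC2 plane
    groups: pd.Series | None = None


def run_pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Standardized PCA of a feature table.

    Features are z-scored, constant columns dropped (with a warning), and
    variables ranked by the Euclidean norm of their loading vector in the
    PC1–PC2 plane — the arrows a biplot would draw longest.
    """
    groups = table["group"] if "group" in table else None
    feats = table.drop(columns=[c for c in ("group",) if c in table])
    feats = feats.select_dtypes(include=[np.number]).dropna(axis=1, how="all")
    incomplete = feats.index[feats.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"dropping incomplete sample(s): {list(incomplete)}", stacklevel=2)
        feats = feats.dropna(axis=0)
        groups = groups.drop(index=incomplete) if groups is not None else None
    if len(feats) < 3:
        raise ValueError(f"PCA needs at least 3 samples, got {len(feats)}")
    keep = feats.columns[feats.std(ddof=0) > 0]
    if len(keep) < len(feats.columns):
        warnings.warn(
            f"dropping constant feature(s): {sorted(set(feats.columns) - set(keep))}",
            stacklevel=2,
        )
    feats = feats[keep]
    if feats.shape[1] < 2:
        raise ValueError("PCA needs at least 2 non-constant features")
    z = (feats - feats.mean()) / feats.std(ddof=0)
    n_comp = min(n_components or min(z.shape), min(z.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores_df = pd.DataFrame(scores, index=feats.index, columns=comp_names)
    loadings = pd.DataFrame(pca.components_.T, index=feats.columns, columns=comp_names)
    plane = loadings[comp_names[: min(2, n_comp)]]
    ranked = plane.pow(2).sum(axis=1).pow(0.5).sort_values(ascending=False).index.tolist()
    return PCAResult(
        scores=scores_df,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        ranked_variables=ranked,
        groups=groups,
    )


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    variant: str                    # "student" or "welch"
    variance_test_pvalue: float
    flag: str | None = None


def group_compare(a: np.ndarray, b: np.ndarray, alpha_variance: float = 0.05) -> GroupComparison:
    """Two-sided two-sample t-test with an equality-of-variance screen.

    An F-test on the sample variances (two-sided, α = ``alpha_variance``)
    decides between the classical pooled-variance t-test and the Welch
    variant; the choice is reported so results stay auditable.  Two groups
    with zero variance and equal means return p = 1 by convention (flagged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, "student", 1.0, flag="zero variance, equal means")
        return GroupComparison(np.inf, 0.0, "student", 1.0, flag="zero variance, unequal means")
    if va == 0 or vb == 0:
        f_p = 0.0
    else:
        f = va / vb
        cdf = sps.f.cdf(f, a.size - 1, b.size - 1)
        f_p = float(2 * min(cdf, 1 - cdf))
    equal_var = f_p >= alpha_variance
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        variant="student" if equal_var else "welch",
        variance_test_pvalue=f_p,
    )


# ---------------------------------------------------------------------------
# Miles-assay utility
# ---------------------------------------------------------------------------


def miles_correction(a620, a740):
    """Hemoglobin correction for Evans-Blue absorbance readings.

    ``A620(corrected) = A620 − (1.426 · A740 + 0.030)``: the 740 nm reading
    tracks co-extracted hemoglobin, whose bleed-through at 620 nm is removed
    before concentrations are read off a standard curve.
    """
    a620 = np.asarray(a620, dtype=float)
    a740 = np.asarray(a740, dtype=float)
    if np.any(a620 < 0) or np.any(a740 < 0):
        raise ValueError("absorbances must be non-negative")
    out = a620 - (1.426 * a740 + 0.030)
    return float(out) if out.ndim == 0 else out
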