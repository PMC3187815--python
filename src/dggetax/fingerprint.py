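"""DGGE fingerprint ordination.

A community fingerprint is a lanes x bands intensity matrix exported
after cross-gel band matching (band calling itself is upstream of this
package).  The workflow here:

1. normalize each lane's total band intensity to 100, so lanes are
   comparable relative-abundance profiles;
2. covariance PCA on the band-centered matrix (no unit-variance scaling:
   band intensities keep their meaning);
3. 90% confidence ellipses per sample group (uranium-rich vs control),
   built from the group score covariance scaled by the chi-square(2 df)
   quantile, i.e. population-coverage ellipses that enclose individual
   samples rather than standard errors of the mean;
4. selection of the n bands with the greatest signed loadings on a chosen
   axis — the candidate group-discriminant bands to excise and sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA

GROUP_URANIUM = "uranium"
GROUP_CONTROL = "control"


@dataclass
class BandTable:
    """Lanes x bands intensity matrix with per-lane group labels.

    ``intensities`` rows are lanes, columns are band ids; 0 means the
    band is absent from that lane.  ``groups`` maps lane id to its group
    label.  ``metadata`` optionally carries site/year/replicate columns.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.intensities
        if df.empty:
            raise ValueError("band table is empty")
        if df.columns.duplicated().any():
            raise ValueError("band ids must be unique")
        if df.index.duplicated().any():
            raise ValueError("lane ids must be unique")
        if (df.values < 0).any():
            raise ValueError("band intensities must be non-negative")
        zero = df.sum(axis=1) == 0
        if zero.any():
            lanes = list(df.index[zero])
            raise ValueError(f"all-zero lane(s): {lanes}")
        if not df.index.equals(self.groups.index):
            self.groups = self.groups.reindex(df.index)
            if self.groups.isna().any():
                raise ValueError("every lane needs a group label")

    @property
    def lane_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def band_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def group_lanes(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class PCAResult:
    """Scores (lanes x components), loadings (bands x components,
    orthonormal columns) and per-component variance fractions in percent
    (summing to 100 over all retained components)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ConfidenceEllipse:
    """Population-coverage ellipse of one group's 2-D scores."""

    group: str
    center: np.ndarray
    semi_axes: np.ndarray       # descending
    orientation: np.ndarray     # 2x2, columns = axis directions
    coverage: float
    degenerate: bool = False    # minor axis collapsed (points near a line)

    @property
    def angle_deg(self) -> float:
        """Angle of the major axis against the first score axis, degrees."""
        v = self.orientation[:, 0]
        return float(np.degrees(np.arctan2(v[1], v[0])))

    def mahalanobis_radius(self) -> float:
        return float(np.sqrt(stats.chi2.ppf(self.coverage, df=2)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which 2-D points fall inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        # back-rotate into the ellipse frame and compare to unit circle
        local = pts @ self.orientation
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (local / self.semi_axes) ** 2
        return r2.sum(axis=1) <= 1.0


def normalize_lanes(t: BandTable, total: float = 100.0) -> BandTable:
    """Scale every lane so its band intensities sum to ``total`` (default
    100); zeros are preserved.  Idempotent on already-normalized tables."""
    sums = t.intensities.sum(axis=1)
    if (sums <= 0).any():
        lanes = list(sums.index[sums <= 0])
        raise ValueError(f"cannot normalize all-zero lane(s): {lanes}")
    scaled = t.intensities.div(sums, axis=0) * total
    return BandTable(
        intensities=scaled,
        groups=t.groups.copy(),
        metadata=None if t.metadata is None else t.metadata.copy(),
    )


def pca(
    t: BandTable,
    presence_absence: bool = False,
    correlation: bool = False,
) -> PCAResult:
    """Covariance PCA of the band table (column-centered per band).

    ``presence_absence`` replaces intensities by 0/1 before the analysis;
    ``correlation`` additionally scales each band to unit variance
    (correlation PCA).  Component signs are fixed so the largest-magnitude
    loading of each component is positive, making output deterministic.
    """
    X = t.intensities.to_numpy(dtype=float)
    n_lanes, n_bands = X.shape
    if n_lanes < 3:
        raise ValueError("PCA needs at least 3 lanes")
    if n_bands < 2:
        raise ValueError("PCA needs at least 2 bands")
    if presence_absence:
        X = (X > 0).astype(float)
    if correlation:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X.copy()
        X[:, keep] = X[:, keep] / sd[keep]
    centered = X - X.mean(axis=0)
    total_var = centered.var(axis=0, ddof=1).sum()
    if total_var <= 0:
        raise ValueError("band table has zero variance (rank 0); PCA undefined")
    model = _SKPCA(n_components=min(n_lanes, n_bands), svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # bands x components
    var_frac = model.explained_variance_ratio_ * 100.0
    # drop numerically-null trailing components so fractions describe the
    # achievable rank; they still sum to 100
    keep = model.explained_variance_ > max(1e-12 * total_var, 1e-30)
    keep[0] = True
    scores = scores[:, keep]
    loadings = loadings[:, keep]
    var_frac = var_frac[keep]
    var_frac = var_frac / var_frac.sum() * 100.0
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[idx, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    comp_ids = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=t.intensities.index, columns=comp_ids),
        loadings=pd.DataFrame(loadings, index=t.intensities.columns, columns=comp_ids),
        variance_fraction=var_frac,
    )


def confidence_ellipse(
    scores: np.ndarray | pd.DataFrame,
    coverage: float = 0.90,
    group: str = "",
) -> ConfidenceEllipse:
    """Coverage ellipse of a group's 2-D scores.

    Semi-axes are sqrt(eigenvalue * chi2.ppf(coverage, 2)) of the sample
    covariance: under a bivariate Gaussian the ellipse contains the stated
    fraction of the population.  Needs >= 3 points; collinear points give
    a degenerate (flagged) minor axis.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("confidence ellipse needs at least 3 points")
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = stats.chi2.ppf(coverage, df=2)
    rel_tol = 1e-12 * max(eigvals[0], 1.0)
    degenerate = bool(eigvals[1] <= rel_tol)
    semi = np.sqrt(np.clip(eigvals, 0.0, None) * scale)
    return ConfidenceEllipse(
        group=group,
        center=center,
        semi_axes=semi,
        orientation=eigvecs,
        coverage=coverage,
        degenerate=degenerate,
    )


def group_ellipses(
    result: PCAResult,
    groups: pd.Series,
    coverage: float = 0.90,
    axes: tuple[int, int] = (1, 2),
) -> dict[str, ConfidenceEllipse]:
    """One ellipse per group on the chosen pair of component axes; groups
    with fewer than 3 lanes are skipped."""
    cols = [f"PC{axes[0]}", f"PC{axes[1]}"]
    out: dict[str, ConfidenceEllipse] = {}
    for g in pd.unique(groups):
        lanes = groups.index[groups == g]
        pts = result.scores.loc[lanes, cols].to_numpy()
        if pts.shape[0] < 3:
            continue
        out[str(g)] = confidence_ellipse(pts, coverage=coverage, group=str(g))
    return out


def select_discriminant_bands(p: PCAResult, axis: int = 1, n: int = 6) -> list[str]:
    """The ``n`` bands with the greatest signed loadings on component
    ``axis`` (1-based), descending; ties broken by band id."""
    if not (1 <= axis <= p.n_components):
        raise ValueError(f"axis {axis} out of range 1..{p.n_components}")
    if n > p.loadings.shape[0]:
        raise ValueError(
            f"asked for {n} bands but table has only {p.loadings.shape[0]}"
        )
    col = p.loadings[f"PC{axis}"]
    order = sorted(col.index, key=lambda b: (-col[b], b))
    return list(order[:n])


class LaneNormalizer(BaseEstimator, TransformerMixin):
    """Scale each lane's total intensity to a fixed sum (default 100)."""

    def __init__(self, total: float = 100.0):
        self.total = total

    def fit(self, X: BandTable, y=None):
        return self

    def transform(self, X: BandTable) -> BandTable:
        return normalize_lanes(X, total=self.total)


class BandTablePCA(BaseEstimator, TransformerMixin):
    """Covariance PCA of a (normalized) band table.

    Fitted attributes: ``scores_``, ``loadings_``, ``variance_fraction_``,
    ``result_`` (the full :class:`PCAResult`) and ``ellipses_`` (per-group
    coverage ellipses on PC1/PC2).
    """

    def __init__(
        self,
        presence_absence: bool = False,
        correlation: bool = False,
        coverage: float = 0.90,
    ):
        self.presence_absence = presence_absence
        self.correlation = correlation
        self.coverage = coverage

    def fit(self, X: BandTable, y=None):
        result = pca(
            X, presence_absence=self.presence_absence, correlation=self.correlation
        )
        self.result_ = result
        self.scores_ = result.scores
        self.loadings_ = result.loadings
        self.variance_fraction_ = result.variance_fraction
        self.mean_ = X.intensities.mean(axis=0)
        self.ellipses_ = group_ellipses(result, X.groups, coverage=self.coverage)
        return self

    def transform(self, X: BandTable) -> pd.DataFrame:
        """Project lanes onto the fitted components (raw-intensity PCA only)."""
        if not hasattr(self, "result_"):
            raise ValueError("not fitted")
        if self.presence_absence or self.correlation:
            raise NotImplementedError(
                "out-of-sample projection is defined for raw-intensity PCA only"
            )
        return (X.intensities - self.mean_) @ self.loadings_

    def discriminant_bands(self, axis: int = 1, n: int = 6) -> list[str]:
        if not hasattr(self, "result_"):
            raise ValueError("not fitted")
        return select_discriminant_bands(self.result_, axis=axis, n=n)


def plot_scores(
    result: PCAResult,
    groups: pd.Series,
    ellipses: dict[str, ConfidenceEllipse] | None = None,
    path: str | None = None,
):
    """Scatter of PC1/PC2 scores with optional group ellipses (vector
    output when ``path`` ends in .svg/.pdf)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    fig, ax = plt.subplots(figsize=(6, 5))
    palette = {GROUP_URANIUM: "tab:red", GROUP_CONTROL: "tab:blue"}
    for g in pd.unique(groups):
        lanes = groups.index[groups == g]
        pts = result.scores.loc[lanes, ["PC1", "PC2"]]
        ax.scatter(pts["PC1"], pts["PC2"], label=str(g),
                   color=palette.get(str(g)), s=40)
        for lane in lanes:
            ax.annotate(lane, result.scores.loc[lane, ["PC1", "PC2"]],
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    for g, ell in (ellipses or {}).items():
        patch = MplEllipse(
            xy=ell.center,
            width=2 * ell.semi_axes[0],
            height=2 * ell.semi_axes[1],
            angle=ell.angle_deg,
            facecolor="none",
            edgecolor=palette.get(g, "grey"),
            linestyle="--",
        )
        ax.add_patch(patch)
    ax.set_xlabel(f"PC1 ({result.variance_fraction[0]:.1f}%)")
    if result.n_components > 1:
        ax.set_ylabel(f"PC2 ({result.variance_fraction[1]:.1f}%)")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
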