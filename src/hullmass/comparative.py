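"""Comparative analyses: COM normalisation, stylopodial masses,
allometric regression (OLS and Brownian PGLS), ancestral states, and
phylomorphospace coordinates.

Centre-of-mass positions are non-dimensionalised two ways: relative to
the glenoacetabular (GA) distance (0 = acetabulum, 1 = glenoid), which
references the COM to the proximal limb joints, and relative to total
body mass to the one-third power, which references it to overall body
scale.  Allometries are fitted on log10-transformed data by ordinary
least squares and by phylogenetic generalised least squares with
residual covariance proportional to Brownian shared path lengths
(sigma^2 estimated by maximum likelihood; no additional branch-length
transformation).  Ancestral states are maximum-likelihood Brownian
reconstructions, computed in closed form as the GLS conditional
expectation at internal nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .mass_model import BodyMassProps
from .skeleton_io import DV_EPSILON, SkeletonManifest
from .trees import PhyloTree

__all__ = [
    "ComRecord",
    "StylopodialModel",
    "RegressionResult",
    "ComparativeError",
    "normalize_com",
    "stylopodial_mass",
    "spearman_rho",
    "fit_allometry",
    "ancestral_states",
    "phylomorphospace",
    "aicc",
]


class ComparativeError(ValueError):
    """Raised for degenerate normalisations or singular fits."""


@dataclass
class ComRecord:
    """Normalised centre-of-mass coordinates for one taxon.

    ``com_ap_ga``/``com_dv_ga`` are GA-relative (dimensionless, 0 at the
    acetabulum, 1 at the glenoid); ``com_ap_m13``/``com_dv_m13`` are in
    m kg^(-1/3).  ``dv_degenerate`` marks taxa whose glenoid sits at
    acetabular height, for which the DV-GA coordinate is meaningless and
    stored as NaN.
    """

    taxon: str
    com_ap_ga: float
    com_dv_ga: float
    com_ap_m13: float
    com_dv_m13: float
    total_mass: float
    dv_degenerate: bool = False


def normalize_com(body: BodyMassProps, manifest: SkeletonManifest) -> ComRecord:
    """Non-dimensionalise a whole-body COM against GA distance and mass^(1/3).

    The GA-relative coordinates use signed displacements so that the
    value is exactly 0 at the acetabulum and exactly 1 at the glenoid.
    """
    ap = float(manifest.glenoid[0] - manifest.acetabulum[0])
    dv = float(manifest.glenoid[2] - manifest.acetabulum[2])
    if ap == 0.0:
        raise ComparativeError(
            f"{body.taxon}: anteroposterior GA distance is zero; cannot normalise"
        )
    com = body.com - manifest.acetabulum
    m13 = body.total_mass ** (1.0 / 3.0)
    dv_degenerate = abs(dv) < DV_EPSILON
    return ComRecord(
        taxon=body.taxon,
        com_ap_ga=float(com[0]) / ap,
        com_dv_ga=(float(com[2]) / dv) if not dv_degenerate else float("nan"),
        com_ap_m13=float(com[0]) / m13,
        com_dv_m13=float(com[2]) / m13,
        total_mass=body.total_mass,
        dv_degenerate=dv_degenerate,
    )


@dataclass(frozen=True)
class StylopodialModel:
    """Log-linear limb-circumference body-mass estimator.

    ``mass = 10**(intercept + slope * log10(C))`` with ``C`` the femoral
    shaft circumference (bipeds) or summed humeral+femoral circumference
    (quadrupeds), in mm.  Coefficients are not bundled: supply the
    published regression coefficients of your chosen equation.
    """

    name: str  # bipedal | quadrupedal
    slope: float
    intercept: float
    mppe: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ComparativeError("stylopodial slope must be > 0")
        if self.mppe < 0:
            raise ComparativeError("mppe must be >= 0")


def stylopodial_mass(
    circumference_mm: float, model: StylopodialModel | None
) -> tuple[float, float, float]:
    """Body mass (kg) point estimate and mPPE bounds from circumference.

    Returns ``(mass, lower, upper)`` with bounds ``mass * (1 -/+ mppe)``.
    """
    if model is None:
        raise ComparativeError(
            "no stylopodial coefficients supplied; provide a StylopodialModel "
            "populated from the published limb-scaling equations"
        )
    if circumference_mm <= 0:
        raise ComparativeError("circumference must be > 0")
    mass = float(10.0 ** (model.intercept + model.slope * np.log10(circumference_mm)))
    return mass, mass * (1.0 - model.mppe), mass * (1.0 + model.mppe)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Ties receive mid-ranks.  A constant input vector leaves the rank
    correlation undefined: NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ComparativeError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    """A fitted bivariate allometry (OLS or PGLS).

    ``k`` counts estimated parameters (two coefficients plus the
    residual variance) for information criteria.  The allometry verdict
    compares the 95% slope CI with the caller-supplied isometric
    expectation (e.g. 1/3 for a linear dimension against mass).
    """

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    adj_r2: float
    loglik: float
    aicc: float
    n: int
    method: str
    sigma2: float
    slope_se: float
    verdict: str | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ComparativeError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _brownian_cov(tree: PhyloTree, taxa: list[str] | None, n: int) -> np.ndarray:
    C = tree.tip_covariance()
    if taxa is not None:
        order = tree.reorder(list(taxa))
        C = C[np.ix_(order, order)]
    if C.shape[0] != n:
        raise ComparativeError(
            f"tree has {C.shape[0]} tips but data has {n}; pass taxa= to align"
        )
    return C


def fit_allometry(
    y: np.ndarray,
    x: np.ndarray,
    tree: PhyloTree | None = None,
    method: str = "ols",
    taxa: list[str] | None = None,
    iso_slope: float | None = None,
) -> RegressionResult:
    """Fit ``y = intercept + slope * x`` by OLS or Brownian PGLS.

    For PGLS the residual covariance is ``sigma^2 * C`` with ``C`` the
    tree's shared-path-length matrix; ``taxa`` aligns the data rows to
    tip labels (defaults to the tree's own tip order).  ``sigma^2`` is
    the maximum-likelihood estimate; slope confidence intervals are
    t-based at 95% with ``n - 2`` degrees of freedom.

    On a star phylogeny (C proportional to the identity) PGLS reproduces
    OLS coefficients exactly.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3 or len(x) != n:
        raise ComparativeError("need equal-length x, y with n >= 3")
    method = method.lower()
    if method == "pgls":
        if tree is None:
            raise ComparativeError("PGLS requires a tree")
        C = _brownian_cov(tree, taxa, n)
    elif method == "ols":
        C = np.eye(n)
    else:
        raise ComparativeError(f"method must be 'ols' or 'pgls', got {method!r}")

    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ComparativeError(f"singular Brownian covariance: {exc}") from exc
    X = np.column_stack([np.ones(n), x])
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise ComparativeError("singular design matrix (constant predictor?)")
    beta, rss_arr, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)

    sigma2_ml = rss / n
    sigma2_unbiased = rss / (n - 2)
    cov_beta = sigma2_unbiased * np.linalg.inv(XtX)
    slope_se = float(np.sqrt(cov_beta[1, 1]))
    tcrit = stats.t.ppf(0.975, df=n - 2)
    slope = float(beta[1])
    ci = (slope - tcrit * slope_se, slope + tcrit * slope_se)

    # GLS-mean-centred total sum of squares for the (pseudo) R^2
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    sign, logdet = np.linalg.slogdet(C)
    if sigma2_ml > 0:
        loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
    else:  # perfect fit: report +inf likelihood is useless; use a large finite proxy
        loglik = float("inf")
    k = 3  # intercept, slope, sigma^2
    aicc_val = aicc(loglik, k, n) if np.isfinite(loglik) else float("-inf")

    verdict = None
    if iso_slope is not None:
        if ci[0] <= iso_slope <= ci[1]:
            verdict = "isometry-within-CI"
        else:
            verdict = "positive" if slope > iso_slope else "negative"

    return RegressionResult(
        slope=slope,
        intercept=float(beta[0]),
        slope_ci=ci,
        adj_r2=float(adj_r2),
        loglik=float(loglik),
        aicc=aicc_val,
        n=n,
        method=method,
        sigma2=float(sigma2_ml),
        slope_se=slope_se,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# ancestral states & phylomorphospace


def ancestral_states(
    tree: PhyloTree,
    tip_values: np.ndarray | dict[str, float],
    taxa: list[str] | None = None,
) -> pd.Series:
    """Maximum-likelihood Brownian ancestral states at internal nodes.

    Computed as the GLS conditional expectation: with root state
    ``mu = (1' C^-1 1)^-1 1' C^-1 y`` (the GLS mean) and ``A`` the
    internal-node/tip shared-path matrix, the reconstruction is
    ``mu + A C^-1 (y - mu)``.  The root state is exactly the GLS mean.

    Zero-length terminal branches would make ``C`` singular; they are
    replaced by a small epsilon (with a warning).

    Returns a Series indexed by internal-node label, in the tree's
    preorder (root first).
    """
    if isinstance(tip_values, dict):
        y = np.array([tip_values[t] for t in tree.taxa], dtype=float)
    else:
        y = np.asarray(tip_values, dtype=float)
        if taxa is not None:
            order = tree.reorder(list(taxa))
            full = np.empty(tree.n_tips)
            full[order] = y
            y = full
    if len(y) != tree.n_tips:
        raise ComparativeError("tip_values length must equal the number of tips")
    if not np.all(np.isfinite(y)):
        raise ComparativeError("tip values must be complete and finite")

    C = tree.tip_covariance().copy()
    term = tree.terminal_branch_lengths()
    if np.any(term <= 0):
        eps = 1e-8 * max(1.0, float(C.max()))
        warnings.warn(
            "zero-length terminal branches replaced by epsilon for reconstruction",
            stacklevel=2,
        )
        idx = np.where(term <= 0)[0]
        C[idx, idx] += eps

    Cinv_y = np.linalg.solve(C, y)
    Cinv_1 = np.linalg.solve(C, np.ones_like(y))
    mu = float(np.ones_like(y) @ Cinv_y) / float(np.ones_like(y) @ Cinv_1)
    A = tree.internal_tip_covariance()
    est = mu + A @ np.linalg.solve(C, y - mu)
    return pd.Series(est, index=tree.internal_labels, name="ancestral_state")


def phylomorphospace(
    tree: PhyloTree,
    trait_x: np.ndarray | dict[str, float],
    trait_y: np.ndarray | dict[str, float],
    taxa: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Node coordinates and edge list for a phylomorphospace plot.

    Tip coordinates are the observed traits; internal-node coordinates
    are the Brownian ancestral reconstructions of each trait.  Edges
    follow the tree topology (parent label, child label).
    """
    anc_x = ancestral_states(tree, trait_x, taxa)
    anc_y = ancestral_states(tree, trait_y, taxa)

    def tipvec(trait) -> np.ndarray:
        if isinstance(trait, dict):
            return np.array([trait[t] for t in tree.taxa], dtype=float)
        v = np.asarray(trait, dtype=float)
        if taxa is not None:
            order = tree.reorder(list(taxa))
            full = np.empty(tree.n_tips)
            full[order] = v
            return full
        return v

    tx, ty = tipvec(trait_x), tipvec(trait_y)
    rows = []
    tip_pos = {t: i for i, t in enumerate(tree.taxa)}
    for label in tree.node_labels:
        if label in tip_pos:
            i = tip_pos[label]
            rows.append({"node": label, "x": tx[i], "y": ty[i], "is_tip": True})
        else:
            rows.append(
                {"node": label, "x": anc_x[label], "y": anc_y[label], "is_tip": False}
            )
    return pd.DataFrame(rows).set_index("node"), tree.edges()


def plot_phylomorphospace(coords: pd.DataFrame, edges: list[tuple[str, str]], path=None):
    """Scatter the phylomorphospace with tree edges (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for parent, child in edges:
        ax.plot(
            [coords.loc[parent, "x"], coords.loc[child, "x"]],
            [coords.loc[parent, "y"], coords.loc[child, "y"]],
            color="0.7",
            lw=0.8,
            zorder=1,
        )
    tips = coords[coords["is_tip"]]
    internals = coords[~coords["is_tip"]]
    ax.scatter(tips["x"], tips["y"], s=25, zorder=2, label="tips")
    ax.scatter(internals["x"], internals["y"], s=8, color="k", zorder=2, label="ancestors")
    ax.set_xlabel("trait x")
    ax.set_ylabel("trait y")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
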