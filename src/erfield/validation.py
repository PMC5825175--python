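"""Cross-validated prediction diagnostics and baseline models.

Model accuracy is assessed on held-out data: predictions are sorted and
grouped into 200-stimulus bins, the observed bin means are compared to the
predicted means by a coefficient of determination, and a best-case R²
(the value an exact model would achieve under Poisson spiking variability)
is estimated by simulation.  The variance-vs-mean check tests the Poisson
assumption directly.  Two subspace baselines are provided: STC1 (projection
onto the first STC component with a double-sided sigmoid) and STC2
(projection onto the two most significant components with a 2-D lowess
response surface).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from scipy.special import expit

from .stimulus_gen import DesignMatrix
from .subspace_id import STCResult, compute_stc
from .synthetic_rgc import SpikeResponse

logger = logging.getLogger("erfield")


# ---------------------------------------------------------------------------
# Folds and binned curves
# ---------------------------------------------------------------------------

def crossval_split(
    n_rows: int,
    k: int = 5,
    seed: int | None = None,
    method: str = "contiguous",
) -> list[np.ndarray]:
    """Partition row indices into k validation folds.

    Contiguous blocks by default: overlapping stimulus windows make adjacent
    rows dependent, and interleaved random splits would leak that dependence
    across the train/validation boundary.  ``method="random"`` shuffles
    (seeded) before splitting.
    """
    if k < 2:
        raise ValueError("need at least 2 folds for held-out validation")
    if n_rows < k:
        raise ValueError(f"{n_rows} rows cannot form {k} folds")
    idx = np.arange(n_rows)
    if method == "random":
        np.random.default_rng(seed).shuffle(idx)
    elif method != "contiguous":
        raise ValueError(f"unknown method {method!r}")
    return [np.sort(part) for part in np.array_split(idx, k)]


def binned_prediction_curve(
    preds: np.ndarray,
    counts: np.ndarray,
    bin_size: int = 200,
) -> np.ndarray:
    """Bin observed counts into 200-stimulus groups ordered by prediction.

    Rows are sorted by predicted rate (stable sort, so ties keep time order)
    and grouped into contiguous bins; the final partial bin is dropped.
    Returns columns (pred_mean, obs_mean, obs_se, obs_var, n).
    """
    preds = np.asarray(preds, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if preds.size != counts.size:
        raise ValueError("preds and counts must have equal length")
    if preds.size < bin_size:
        raise ValueError(f"need at least {bin_size} rows ({preds.size} given)")
    order = np.argsort(preds, kind="stable")
    n_bins = preds.size // bin_size
    p = preds[order][: n_bins * bin_size].reshape(n_bins, bin_size)
    r = counts[order][: n_bins * bin_size].reshape(n_bins, bin_size)
    obs_var = r.var(axis=1, ddof=1)
    return np.column_stack([
        p.mean(axis=1), r.mean(axis=1),
        np.sqrt(obs_var / bin_size), obs_var,
        np.full(n_bins, bin_size),
    ])


def coefficient_of_determination(binned: np.ndarray) -> float:
    """R² of observed bin means against predicted bin means.

    1 - SS_res / SS_tot with residuals (obs_mean - pred_mean); can be
    negative when the prediction is worse than the observed grand mean.
    Zero variance in the observed means -> NaN (flagged).
    """
    binned = np.asarray(binned)
    if binned.shape[0] < 2:
        raise ValueError("need at least 2 bins")
    pred, obs = binned[:, 0], binned[:, 1]
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        warnings.warn("observed bin means have zero variance; R² undefined")
        return float("nan")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def best_case_r2(
    preds: np.ndarray,
    bin_size: int = 200,
    n_sims: int = 20,
    seed: int | None = 0,
) -> float:
    """Poisson-simulated ceiling on the binned R².

    For each simulation, counts are drawn Poisson with mean equal to the
    prediction, binned identically, and the R² of simulated bin means
    against the predictions is computed; the mean over simulations is the
    best-case value an exact model could reach.
    """
    preds = np.asarray(preds, dtype=float)
    if not np.any(preds > 0):
        raise ValueError("all predictions are zero")
    if np.ptp(preds) == 0:
        warnings.warn("constant predictions have no spread; best-case R² "
                      "is undefined")
        return float("nan")
    rng = np.random.default_rng(seed)
    r2s = []
    for _ in range(n_sims):
        sim = rng.poisson(preds)
        binned = binned_prediction_curve(preds, sim, bin_size=bin_size)
        r2s.append(coefficient_of_determination(binned))
    return float(np.nanmean(r2s))


def prediction_errors(binned: np.ndarray) -> tuple[float, float]:
    """(avg_error_spikes, pct_error): mean |pred - obs_mean| per bin, and
    that as a percentage of the maximum predicted response."""
    binned = np.asarray(binned)
    avg_err = float(np.abs(binned[:, 0] - binned[:, 1]).mean())
    max_resp = float(binned[:, 0].max())
    return avg_err, 100.0 * avg_err / max_resp if max_resp > 0 else float("nan")


def variance_mean_check(binned: np.ndarray, max_pred: float | None = None):
    """Normalized variance-vs-mean points and their through-origin slope.

    For a Poisson process the per-bin count variance equals the mean, so the
    points (pred_mean/max, obs_var/max) lie on the identity and the slope of
    a through-origin regression is 1.
    """
    binned = np.asarray(binned)
    if binned.shape[0] < 2:
        raise ValueError("need at least 2 bins")
    if max_pred is None:
        max_pred = binned[:, 0].max()
    x = binned[:, 0] / max_pred
    y = binned[:, 3] / max_pred
    slope = float((x @ y) / (x @ x)) if np.any(x != 0) else 0.0
    return np.column_stack([x, y]), slope


# ---------------------------------------------------------------------------
# Baseline models
# ---------------------------------------------------------------------------

def _double_sigmoid(x, r0, ap, bp, cp, am, bm, cm):
    """Two independent saturating arms sharing the response floor at x = 0.

    N(x) = r0 + a+ [s(b+(x-c+)) - s(-b+ c+)] for x >= 0 and the mirrored
    expression for x < 0, continuous at 0 and monotone on each half-axis.
    """
    pos = r0 + ap * (expit(bp * (x - cp)) - expit(-bp * cp))
    neg = r0 + am * (expit(bm * (-x - cm)) - expit(-bm * cm))
    return np.where(x >= 0, pos, neg)


@dataclass
class STC1Model:
    component: np.ndarray
    params: tuple
    binned_curve: np.ndarray

    def predict(self, rows: np.ndarray) -> np.ndarray:
        proj = np.asarray(rows) @ self.component
        return np.maximum(_double_sigmoid(proj, *self.params), 0.0)


def fit_stc1_baseline(
    design: DesignMatrix,
    resp: SpikeResponse,
    stc: STCResult | None = None,
    bin_size: int = 200,
) -> STC1Model:
    """1-D baseline: project onto the first (largest-eigenvalue) STC
    component and fit a double-sided sigmoid to 200-binned response means."""
    if stc is None:
        stc = compute_stc(design, resp)
    comp = stc.eigenvectors[:, 0]
    proj = design.rows @ comp
    counts = np.asarray(resp.counts, dtype=float)
    order = np.argsort(proj, kind="stable")
    n_bins = proj.size // bin_size
    if n_bins < 2:
        raise ValueError("too few samples to bin the projection")
    pb = proj[order][: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    rb = counts[order][: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    span = max(pb.max() - pb.min(), 1e-9)
    p0 = [max(rb.min(), 1e-3),
          max(rb.max() - rb.min(), 1e-3), 8.0 / span, span / 4,
          max(rb.max() - rb.min(), 1e-3), 8.0 / span, span / 4]
    lb = [0.0] + [1e-9, 1e-9, -np.inf] * 2
    ub = [np.inf] * 7
    try:
        popt, _ = curve_fit(_double_sigmoid, pb, rb, p0=p0, bounds=(lb, ub),
                            maxfev=20000)
    except RuntimeError:
        warnings.warn("double-sided sigmoid fit did not converge")
        popt = p0
    binned = np.column_stack([pb, rb])
    return STC1Model(component=comp, params=tuple(popt), binned_curve=binned)


def lowess_surface_2d(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    span: float = 0.05,
    grid_size: int = 50,
):
    """Locally weighted linear regression surface with tricube weights.

    For each node of a ``grid_size`` x ``grid_size`` grid over the data
    range, the nearest ``span`` fraction of samples is fit with a
    tricube-weighted plane; the surface is the fitted value at the node.
    Returns (grid_x, grid_y, surface).
    """
    pts = np.column_stack([x, y])
    n = pts.shape[0]
    k = max(int(round(span * n)), 10)
    tree = cKDTree(pts)
    gx = np.linspace(x.min(), x.max(), grid_size)
    gy = np.linspace(y.min(), y.max(), grid_size)
    nodes = np.array([[xi, yi] for yi in gy for xi in gx])
    dists, idx = tree.query(nodes, k=k, workers=1)
    surface = np.empty(nodes.shape[0])
    for m in range(nodes.shape[0]):
        d = dists[m]
        dmax = d[-1] if d[-1] > 0 else 1.0
        w = (1.0 - (d / dmax) ** 3) ** 3
        sel = idx[m]
        A = np.column_stack([np.ones(k), pts[sel, 0] - nodes[m, 0],
                             pts[sel, 1] - nodes[m, 1]])
        Aw = A * w[:, None]
        coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ z[sel], rcond=None)
        surface[m] = coef[0]
    return gx, gy, surface.reshape(grid_size, grid_size)


@dataclass
class STC2Model:
    components: np.ndarray            # (D, 2)
    grid_x: np.ndarray
    grid_y: np.ndarray
    surface: np.ndarray
    _interp: RegularGridInterpolator = field(default=None, repr=False)

    def __post_init__(self):
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.grid_x, self.grid_y), self.surface.T,
                bounds_error=False, fill_value=None)

    def predict(self, rows: np.ndarray) -> np.ndarray:
        proj = np.asarray(rows) @ self.components
        # clamp extrapolation to the fitted range
        proj = np.column_stack([
            np.clip(proj[:, 0], self.grid_x[0], self.grid_x[-1]),
            np.clip(proj[:, 1], self.grid_y[0], self.grid_y[-1]),
        ])
        return np.maximum(self._interp(proj), 0.0)


def fit_stc2_baseline(
    design: DesignMatrix,
    resp: SpikeResponse,
    stc: STCResult | None = None,
    span: float = 0.05,
    grid_size: int = 50,
) -> STC2Model:
    """2-D baseline: lowess response surface over the projections onto the
    two components whose eigenvalues depart most from the bulk (usually the
    first and last)."""
    if stc is None:
        stc = compute_stc(design, resp)
    lam = stc.eigenvalues
    centre = np.median(lam)
    picks = np.argsort(-np.abs(lam - centre))[:2]
    if stc.null_lo is not None and stc.n_significant >= 2:
        sig = np.concatenate([stc.significant_exc, stc.significant_sup])
        dep = np.where(lam[sig] > centre, lam[sig] - stc.null_hi[sig],
                       stc.null_lo[sig] - lam[sig])
        picks = sig[np.argsort(-dep)[:2]]
    V = stc.eigenvectors[:, np.sort(picks)]
    proj = design.rows @ V
    counts = np.asarray(resp.counts, dtype=float)
    gx, gy, surf = lowess_surface_2d(proj[:, 0], proj[:, 1], counts,
                                     span=span, grid_size=grid_size)
    return STC2Model(components=V, grid_x=gx, grid_y=gy, surface=surf)


# ---------------------------------------------------------------------------
# Cross-validated report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    folds: list[np.ndarray]
    binned: np.ndarray                  # from the last fold (diagnostic)
    r2: float
    r2_best_case: float
    avg_error_spikes: float
    pct_error: float
    variance_slope: float
    per_fold: dict = field(default_factory=dict)


def validate_model(
    fit_fn,
    predict_fn,
    design: DesignMatrix,
    resp: SpikeResponse,
    k: int = 5,
    bin_size: int = 200,
    seed: int | None = 0,
    n_best_case_sims: int = 10,
) -> ValidationReport:
    """k-fold cross-validated diagnostics for any model.

    ``fit_fn(design_train, resp_train) -> model`` and
    ``predict_fn(model, rows) -> rates``; contiguous folds; reported metrics
    are means over the folds, per-fold values retained.
    """
    counts = np.asarray(resp.counts)
    folds = crossval_split(design.rows.shape[0], k=k)
    per_fold = {"r2": [], "r2_best_case": [], "avg_error": [],
                "pct_error": [], "variance_slope": []}
    binned = None
    rng = np.random.default_rng(seed)
    for val_idx in folds:
        mask = np.ones(design.rows.shape[0], dtype=bool)
        mask[val_idx] = False
        d_train = DesignMatrix(
            rows=design.rows[mask], L=design.L,
            n_electrodes=design.n_electrodes, window_ms=design.window_ms,
            frequency_hz=design.frequency_hz)
        model = fit_fn(d_train, SpikeResponse(counts=counts[mask]))
        preds = np.asarray(predict_fn(model, design.rows[val_idx]))
        binned = binned_prediction_curve(preds, counts[val_idx],
                                         bin_size=bin_size)
        per_fold["r2"].append(coefficient_of_determination(binned))
        per_fold["r2_best_case"].append(best_case_r2(
            preds, bin_size=bin_size, n_sims=n_best_case_sims,
            seed=int(rng.integers(2 ** 31))))
        err, pct = prediction_errors(binned)
        per_fold["avg_error"].append(err)
        per_fold["pct_error"].append(pct)
        per_fold["variance_slope"].append(variance_mean_check(binned)[1])
    return ValidationReport(
        folds=folds, binned=binned,
        r2=float(np.nanmean(per_fold["r2"])),
        r2_best_case=float(np.nanmean(per_fold["r2_best_case"])),
        avg_error_spikes=float(np.mean(per_fold["avg_error"])),
        pct_error=float(np.nanmean(per_fold["pct_error"])),
        variance_slope=float(np.mean(per_fold["variance_slope"])),
        per_fold=per_fold)
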