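"""Generalized Quadratic Model (GQM) estimation by Poisson maximum likelihood.

The model maps a stimulus-history vector S onto an expected spike count via a
quadratic generator signal and a sigmoid output nonlinearity::

    g(S) = v0 . S  +  sum_i  w_i (v_i . S)^2        (w_i = +1 exc, -1 sup)
    E(S) = a / (1 + exp(-b (g(S) - c)))

and the parameters maximize the Poisson log-likelihood
``L = sum_t R(t) log E(S_t) - E(S_t)`` (the constant log R! term is omitted).

Fitting alternates quasi-Newton ascent on the filter block (v0 and all v_i,
analytic gradients) with a refit of the sigmoid (a, b, c), warm-started from
the STA/STC subspace.  Fitted components are canonicalized: the quadratic
kernel M = sum_i w_i v_i v_i^T is eigendecomposed and the components replaced
by its eigenvectors scaled to sqrt(|eigenvalue|), which leaves g(S) unchanged
for every stimulus.

Internally the stimulus is standardized by its global SD so the optimization
is well-conditioned; all filters in the returned model are on the raw
stimulus scale (uA).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.special import expit, log_expit

from .stimulus_gen import DesignMatrix
from .subspace_id import STCResult, compute_stc
from .synthetic_rgc import SpikeResponse

logger = logging.getLogger("erfield")


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class GQMModel:
    v0: np.ndarray
    components: list[tuple[np.ndarray, int]]       # (v_i, w_i), w_i = ±1
    sigmoid: tuple[float, float, float]            # (a, b, c)
    sig_mask: np.ndarray | None = None             # (1 + N, D) bool; row 0 = v0
    fit_meta: dict = field(default_factory=dict)

    @property
    def n_exc(self) -> int:
        return sum(1 for _, w in self.components if w > 0)

    @property
    def n_sup(self) -> int:
        return sum(1 for _, w in self.components if w < 0)

    @property
    def dim(self) -> int:
        return self.v0.size

    def component_matrix(self) -> np.ndarray:
        if not self.components:
            return np.zeros((self.dim, 0))
        return np.stack([v for v, _ in self.components], axis=1)

    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components], dtype=float)


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float
    binned_curve: np.ndarray        # columns: g_mean, resp_mean, resp_se, n
    logexp_params: tuple[float, float, float] | None = None
    flat: bool = False

    def __call__(self, g: np.ndarray) -> np.ndarray:
        return self.a * expit(self.b * (np.asarray(g, dtype=float) - self.c))


# ---------------------------------------------------------------------------
# Forward model and likelihood
# ---------------------------------------------------------------------------

def generator_signal(model: GQMModel, S: np.ndarray) -> np.ndarray | float:
    """g(S) = v0.S + sum_i w_i (v_i.S)^2 for one stimulus row or a matrix."""
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != model.dim:
        raise ValueError(f"stimulus has {S.shape[-1]} entries but the model "
                         f"filters have {model.dim}")
    g = S @ model.v0
    for v, w in model.components:
        g = g + w * (S @ v) ** 2
    return g


def expected_response(model: GQMModel, S: np.ndarray) -> np.ndarray | float:
    """Expected spikes per bin: a * sigmoid(b (g(S) - c))."""
    a, b, c = model.sigmoid
    return a * expit(b * (generator_signal(model, S) - c))


def poisson_log_likelihood(rates: np.ndarray, counts: np.ndarray) -> float:
    """Sum of R log E - E.  Returns -inf if any rate is 0 where counts > 0."""
    rates = np.asarray(rates, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if rates.shape != counts.shape:
        raise ValueError("rates and counts must have the same shape")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    spk = counts > 0
    if np.any(rates[spk] == 0):
        return -math.inf
    return float(counts[spk] @ np.log(rates[spk]) - rates.sum())


# ---------------------------------------------------------------------------
# Internal likelihood machinery (standardized stimulus scale)
# ---------------------------------------------------------------------------

def _pack(v0: np.ndarray, comps: np.ndarray) -> np.ndarray:
    return np.concatenate([v0, comps.ravel()])


def _unpack(theta: np.ndarray, dim: int, n_comp: int):
    v0 = theta[:dim]
    comps = theta[dim:].reshape(n_comp, dim)
    return v0, comps


def _filter_negll_grad(theta, Z, R, weights, sigmoid, ridge=0.0):
    """Penalized -LL and gradient w.r.t. the filter block, sigmoid fixed.

    ``ridge`` adds -0.5 * ridge * ||theta||^2 to the log-likelihood (on the
    standardized stimulus scale); see ``fit_gqm``.
    """
    a, b, c = sigmoid
    dim = Z.shape[1]
    n_comp = len(weights)
    v0, comps = _unpack(theta, dim, n_comp)
    P = Z @ comps.T if n_comp else np.empty((Z.shape[0], 0))
    g = Z @ v0
    if n_comp:
        g = g + (P ** 2) @ weights
    z = b * (g - c)
    sig = expit(z)
    E = a * sig
    # LL = sum R (log a + log sigmoid(z)) - E   (stable for large |z|)
    ll = R @ (math.log(a) + log_expit(z)) - E.sum()
    q = (R - E) * (b * (1.0 - sig))            # dLL/dg
    grad_v0 = Z.T @ q
    if n_comp:
        grad_c = 2.0 * (Z.T @ (q[:, None] * P)) * weights[None, :]
        grad = _pack(grad_v0, grad_c.T)
    else:
        grad = grad_v0
    if ridge:
        ll = ll - 0.5 * ridge * float(theta @ theta)
        grad = grad - ridge * theta
    return -ll, -grad


def _sigmoid_negll_grad(params, g, R):
    """-LL and gradient w.r.t. (a, b, c), generator values fixed."""
    a, b, c = params
    z = b * (g - c)
    sig = expit(z)
    E = a * sig
    ll = R @ (math.log(a) + log_expit(z)) - E.sum()
    resid = R - E
    da = R.sum() / a - sig.sum()
    db = resid @ ((1.0 - sig) * (g - c))
    dc = -b * (resid * (1.0 - sig)).sum()
    return -ll, -np.array([da, db, dc])


def _loglik(Z, R, v0, comps, weights, sigmoid, ridge=0.0):
    a, b, c = sigmoid
    g = Z @ v0
    if len(weights):
        g = g + ((Z @ comps.T) ** 2) @ weights
    z = b * (g - c)
    ll = float(R @ (math.log(a) + log_expit(z)) - a * expit(z).sum())
    if ridge:
        ll -= 0.5 * ridge * (float(v0 @ v0) + float((comps ** 2).sum()))
    return ll


#: upper bound on the sigmoid gain, on the scale where std(g) = 1.  The
#: model has a scale redundancy (g, b, c) -> (g/s, b s, c/s); fits are kept
#: on the normalized scale, where an unbounded gain would let the sigmoid
#: degenerate into a step function that memorizes individual response bins.
MAX_SIGMOID_GAIN = 20.0


def _refit_sigmoid(g, R, sigmoid):
    x0 = np.asarray(sigmoid, dtype=float)
    x0[1] = min(x0[1], MAX_SIGMOID_GAIN)
    res = minimize(
        _sigmoid_negll_grad, x0=x0,
        args=(g, R), jac=True, method="L-BFGS-B",
        bounds=[(1e-8, None), (1e-8, MAX_SIGMOID_GAIN), (None, None)],
        options={"maxiter": 100})
    return tuple(res.x)


def _normalize_generator_scale(v0, comps, weights, sigmoid, g):
    """Fix the scale redundancy by rescaling filters so std(g) = 1.

    (v0, v_i) -> (v0/s, v_i/sqrt(s)) with (b, c) -> (b s, c/s) leaves the
    expected response unchanged for every stimulus.  Only applied when the
    generator scale has grown (s > 1): shrinking filters also shrinks the
    ridge penalty, so the penalized objective cannot decrease here.
    """
    s = float(np.std(g))
    if not np.isfinite(s) or s <= 1.0:
        return v0, comps, sigmoid, g
    a, b, c = sigmoid
    return (v0 / s, comps / math.sqrt(s), (a, b * s, c / s), g / s)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _initial_parameters(Z, R, scale, n_exc, n_sup, init, rng):
    dim = Z.shape[1]
    n_comp = n_exc + n_sup
    weights = np.array([1.0] * n_exc + [-1.0] * n_sup)
    if init is not None:
        sta = init.sta * scale                     # raw -> standardized scale
        nrm = np.linalg.norm(sta)
        v0 = 0.1 * sta / nrm if nrm > 0 else np.zeros(dim)
        eigvals_z = init.eigenvalues / scale ** 2  # null level ~ 1
        comps = []
        for k in range(n_exc):
            amp = math.sqrt(max(abs(eigvals_z[k] - 1.0), 0.05))
            comps.append(init.eigenvectors[:, k] * min(amp, 2.0))
        for k in range(n_sup):
            amp = math.sqrt(max(abs(eigvals_z[-1 - k] - 1.0), 0.05))
            comps.append(init.eigenvectors[:, -1 - k] * min(amp, 2.0))
        comps = np.array(comps) if comps else np.empty((0, dim))
    else:
        v0 = 0.05 * rng.standard_normal(dim) / math.sqrt(dim)
        comps = 0.2 * rng.standard_normal((n_comp, dim)) / math.sqrt(dim)
    return v0, comps, weights


def fit_gqm(
    design: DesignMatrix,
    resp: SpikeResponse,
    n_exc: int,
    n_sup: int,
    init: STCResult | None = None,
    seed: int | None = 0,
    max_outer: int = 200,
    tol: float = 1e-6,
    filter_maxiter: int = 60,
    max_rows: int | None = None,
    canonicalize: bool = True,
    ridge: float = 1.0,
) -> GQMModel:
    """Maximum-likelihood GQM fit, initialized from STA/STC.

    Alternates an L-BFGS pass over the filter block (sigmoid fixed) with a
    refit of the sigmoid (filters fixed) until the relative log-likelihood
    change falls below ``tol`` or ``max_outer`` outer iterations.  The
    (penalized) log-likelihood is non-decreasing across blocks.
    ``max_rows`` fits on an evenly strided row subsample (used by order
    selection).  Deterministic given the seed.

    ``ridge`` is a small L2 penalty on the filter coefficients (standardized
    stimulus scale).  Together with the bounded sigmoid gain it removes a
    degeneracy of the unpenalized likelihood, which can otherwise drive the
    sigmoid toward a step function with unbounded filters that memorize
    individual response bins; at the default it is orders of magnitude below
    the likelihood curvature of genuine components (negligible bias).
    """
    rows = design.rows
    counts = np.asarray(resp.counts, dtype=float)
    if max_rows is not None and rows.shape[0] > max_rows:
        idx = np.linspace(0, rows.shape[0] - 1, max_rows).astype(int)
        rows = rows[idx]
        counts = counts[idx]
    scale = rows.std()
    if scale == 0:
        raise ValueError("stimulus has zero variance")
    Z = rows / scale
    R = counts
    rng = np.random.default_rng(seed)
    if init is None and n_exc + n_sup > 0:
        try:
            init = compute_stc(DesignMatrix(
                rows=rows, L=design.L, n_electrodes=design.n_electrodes,
                window_ms=design.window_ms, frequency_hz=design.frequency_hz),
                SpikeResponse(counts=counts))
        except ValueError:
            init = None

    v0, comps, weights = _initial_parameters(Z, R, scale, n_exc, n_sup,
                                             init, rng)
    # initial sigmoid from the initial generator values, on the normalized
    # generator scale (std(g) = 1)
    g = Z @ v0 + (((Z @ comps.T) ** 2) @ weights if len(weights) else 0.0)
    a0 = max(float(R.mean() + 2.0 * R.std()), 0.1)
    v0, comps, _, g = _normalize_generator_scale(
        v0, comps, weights, (a0, 1.0, 0.0), g)
    sigmoid = _refit_sigmoid(g, R, (a0, 1.0, float(g.mean())))

    ll = _loglik(Z, R, v0, comps, weights, sigmoid, ridge)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        theta0 = _pack(v0, comps)
        res = minimize(_filter_negll_grad, theta0,
                       args=(Z, R, weights, sigmoid, ridge), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": filter_maxiter})
        if -res.fun >= ll:
            v0, comps = _unpack(res.x, Z.shape[1], len(weights))
            ll = -res.fun
        g = Z @ v0 + (((Z @ comps.T) ** 2) @ weights if len(weights) else 0.0)
        v0, comps, sigmoid, g = _normalize_generator_scale(
            v0, comps, weights, sigmoid, g)
        ll = _loglik(Z, R, v0, comps, weights, sigmoid, ridge)
        new_sigmoid = _refit_sigmoid(g, R, sigmoid)
        new_ll = _loglik(Z, R, v0, comps, weights, new_sigmoid, ridge)
        if new_ll >= ll:
            sigmoid = new_sigmoid
            ll = new_ll
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (1.0 + abs(trace[-2])):
            converged = True
            break
    if not converged:
        logger.warning("GQM fit did not converge in %d outer iterations",
                       max_outer)

    # standardized filters satisfy  v_tilde . (S/scale) = (v_tilde/scale) . S,
    # so dividing by the scale returns filters on the raw uA stimulus scale
    model = GQMModel(
        v0=v0 / scale,
        components=[(comps[k] / scale, int(weights[k])) for k in range(len(weights))],
        sigmoid=sigmoid,
        fit_meta={"loglik": ll, "seed": seed, "iterations": n_iter,
                  "converged": converged, "ll_trace": np.asarray(trace),
                  "stim_scale": scale, "n_rows": rows.shape[0],
                  "ridge": ridge},
    )
    if canonicalize and model.components:
        model = canonicalize_components(model)
    return model


def canonicalize_components(model: GQMModel, tol: float = 1e-10) -> GQMModel:
    """Rotate the quadratic components to the eigenbasis of their kernel.

    Forms M = sum_i w_i v_i v_i^T, eigendecomposes it, and replaces the
    components by eigenvectors scaled to sqrt(|lambda|) with w = sign(lambda)
    (excitatory first, by descending eigenvalue, then suppressive by
    descending magnitude).  The generator signal is unchanged for every
    stimulus; parallel components collapse onto one eigenvector with the
    combined eigenvalue.
    """
    if not model.components:
        return model
    V = model.component_matrix()
    w = model.weights()
    M = (V * w) @ V.T
    eigvals, eigvecs = np.linalg.eigh(M)
    keep = np.abs(eigvals) > tol * max(np.abs(eigvals).max(), 1.0)
    eigvals = eigvals[keep]
    eigvecs = eigvecs[:, keep]
    order = np.concatenate([
        np.nonzero(eigvals > 0)[0][np.argsort(-eigvals[eigvals > 0])],
        np.nonzero(eigvals < 0)[0][np.argsort(eigvals[eigvals < 0])],
    ])
    comps = []
    for k in order:
        vec = eigvecs[:, k]
        peak = np.argmax(np.abs(vec))
        if vec[peak] < 0:
            vec = -vec
        comps.append((vec * math.sqrt(abs(eigvals[k])),
                      1 if eigvals[k] > 0 else -1))
    out = GQMModel(v0=model.v0, components=comps, sigmoid=model.sigmoid,
                   sig_mask=model.sig_mask, fit_meta=dict(model.fit_meta))
    out.fit_meta["kernel_eigenvalues"] = eigvals[order]
    return out


# ---------------------------------------------------------------------------
# Binned sigmoid diagnostic fit
# ---------------------------------------------------------------------------

def _sigmoid_fn(g, a, b, c):
    return a * expit(b * (g - c))


def _logexp_fn(g, alpha, beta, gamma):
    return alpha * np.logaddexp(0.0, beta * (g - gamma))


def fit_sigmoid_nonlinearity(
    g_values: np.ndarray,
    counts: np.ndarray,
    bin_size: int = 200,
) -> SigmoidFit:
    """Least-squares sigmoid fit to 200-stimulus binned response means.

    Responses are sorted by generator value, grouped into contiguous bins of
    ``bin_size`` (the final partial bin is dropped), and Eq-style sigmoid and
    log-exponential curves are fitted to the bin means.  Flat data (constant
    counts) yields a flagged flat fit with ``a`` at the constant level.
    """
    g_values = np.asarray(g_values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if g_values.size < 2 * bin_size:
        raise ValueError(f"need at least {2 * bin_size} samples "
                         f"({g_values.size} given)")
    order = np.argsort(g_values, kind="stable")
    n_bins = g_values.size // bin_size
    gs = g_values[order][: n_bins * bin_size].reshape(n_bins, bin_size)
    rs = counts[order][: n_bins * bin_size].reshape(n_bins, bin_size)
    g_mean = gs.mean(axis=1)
    r_mean = rs.mean(axis=1)
    r_se = rs.std(axis=1, ddof=1) / math.sqrt(bin_size)
    binned = np.column_stack([g_mean, r_mean, r_se,
                              np.full(n_bins, bin_size)])

    if np.allclose(r_mean, r_mean[0]):
        return SigmoidFit(a=float(r_mean[0]), b=0.0, c=float(g_mean.mean()),
                          binned_curve=binned, flat=True)

    span = max(g_mean.max() - g_mean.min(), 1e-9)
    p0 = [max(r_mean.max(), 1e-3), 4.0 / span, float(np.median(g_mean))]
    try:
        popt, _ = curve_fit(_sigmoid_fn, g_mean, r_mean, p0=p0,
                            bounds=([1e-9, 1e-9, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError:
        warnings.warn("sigmoid fit did not converge; returning initial guess")
        popt = p0
    logexp = None
    try:
        lp, _ = curve_fit(_logexp_fn, g_mean, r_mean,
                          p0=[max(r_mean.max() / 2, 1e-3), 4.0 / span,
                              float(np.median(g_mean))],
                          maxfev=20000)
        logexp = tuple(float(x) for x in lp)
    except RuntimeError:
        pass
    return SigmoidFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                      binned_curve=binned, logexp_params=logexp)


# ---------------------------------------------------------------------------
# Model-order selection
# ---------------------------------------------------------------------------

def select_model_order(
    design: DesignMatrix,
    resp: SpikeResponse,
    max_exc: int = 3,
    max_sup: int = 3,
    seed: int | None = 0,
    tol: float = 0.01,
    n_folds: int = 2,
    bin_size: int = 200,
    max_rows: int | None = None,
    stc: STCResult | None = None,
    return_scores: bool = False,
):
    """Grid search over (n_exc, n_sup) scored by held-out binned R².

    The grid expands outward from (0, 0) (a linear LN fit) by total
    component count: level t evaluates every order with n_exc + n_sup = t
    within the maxima.  Expansion stops once two consecutive levels fail to
    improve the best score seen so far by at least ``tol`` (the one-level
    lookahead guards against stopping on a plateau step just before a real
    component); the argmax over everything evaluated is returned (exact
    ties broken toward fewer components).  Superfluous components overfit
    and *lower* held-out R², so a linear cell falls back to a small order
    and pure noise to (0, 0), while a component whose genuine contribution
    is below ``tol`` (typical for weak suppression) is still selected when
    it is the argmax.
    """
    from .validation import binned_prediction_curve, coefficient_of_determination, crossval_split

    counts = np.asarray(resp.counts)
    folds = crossval_split(design.rows.shape[0], k=n_folds)
    if stc is None:
        stc = compute_stc(design, resp)
    scores: dict[tuple[int, int], float] = {}

    def score(order: tuple[int, int]) -> float:
        if order in scores:
            return scores[order]
        e, s = order
        r2s = []
        for val_idx in folds:
            train_mask = np.ones(design.rows.shape[0], dtype=bool)
            train_mask[val_idx] = False
            d_train = DesignMatrix(
                rows=design.rows[train_mask], L=design.L,
                n_electrodes=design.n_electrodes,
                window_ms=design.window_ms, frequency_hz=design.frequency_hz)
            r_train = SpikeResponse(counts=counts[train_mask])
            model = fit_gqm(d_train, r_train, e, s, init=stc, seed=seed,
                            max_outer=50, tol=1e-6, filter_maxiter=60,
                            max_rows=max_rows)
            preds = expected_response(model, design.rows[val_idx])
            try:
                binned = binned_prediction_curve(preds, counts[val_idx],
                                                 bin_size=bin_size)
                r2s.append(coefficient_of_determination(binned))
            except ValueError:
                r2s.append(-np.inf)
        scores[order] = float(np.mean(r2s))
        return scores[order]

    best_so_far = score((0, 0))
    stalled = 0
    for level in range(1, max_exc + max_sup + 1):
        level_orders = [(e, level - e) for e in range(level + 1)
                        if e <= max_exc and level - e <= max_sup]
        if not level_orders:
            break
        level_best = max(score(o) for o in level_orders)
        stalled = stalled + 1 if level_best - best_so_far < tol else 0
        best_so_far = max(best_so_far, level_best)
        if stalled >= 2:
            break
    # argmax over everything evaluated; exact ties favour fewer components
    winner = max(scores.items(),
                 key=lambda kv: (kv[1], -(kv[0][0] + kv[0][1])))[0]
    if return_scores:
        return winner, scores
    return winner


def subspace_principal_cosines(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cosines of the principal angles between the column spans of A and B.

    The quadratic generator is invariant to rotations of components within a
    degenerate eigen-subspace of the kernel, so recovery of planted
    components is judged subspace-to-subspace: all cosines near 1 means the
    fitted components span the planted ones.
    """
    Qa, _ = np.linalg.qr(np.atleast_2d(A))
    Qb, _ = np.linalg.qr(np.atleast_2d(B))
    return np.linalg.svd(Qa.T @ Qb, compute_uv=False)


# ---------------------------------------------------------------------------
# Bootstrap electrode significance
# ---------------------------------------------------------------------------

def _batched_shift_refit(Z, shifted_R, inits, weights, sigmoid,
                         n_iter=150, lr=0.05, chunk_mb=200.0, ridge=0.0):
    """Refit the filter block for every time-shifted response in parallel.

    Full-batch Adam ascent on the Poisson log-likelihood, each shift
    starting from its own STA/STC initialization (``inits``: (B, 1+N, D)),
    sigmoid held fixed.  All shifts share the stimulus matrix so each
    iteration is two matrix products per chunk of shifts.  Returns
    (B, 1+N, D) filter samples on the standardized scale.
    """
    a, b, c = sigmoid
    n, dim = Z.shape
    B = shifted_R.shape[0]
    n_vec = 1 + len(weights)
    wcol = np.concatenate([[0.0], weights])       # 0 marks the v0 slot
    per_boot_mb = n * n_vec * 8 / 1e6 * 3
    chunk = max(1, int(chunk_mb / max(per_boot_mb, 1e-9)))
    out = np.empty((B, n_vec, dim))
    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        nb = stop - start
        Rb = shifted_R[start:stop].T                      # (n, nb)
        V = inits[start:stop].reshape(nb * n_vec, dim).T.copy()
        W = np.tile(wcol, nb)                             # (nb * n_vec,)
        is_v0 = W == 0.0
        m = np.zeros_like(V)
        vadam = np.zeros_like(V)
        for t in range(1, n_iter + 1):
            P = Z @ V                                     # (n, nb*n_vec)
            Pq = P.reshape(n, nb, n_vec)
            g = Pq[:, :, 0] + np.einsum("nbk,bk->nb", Pq[:, :, 1:] ** 2,
                                        np.tile(weights, (nb, 1)))
            sig = expit(b * (g - c))
            E = a * sig
            q = (Rb - E) * (b * (1.0 - sig))              # (n, nb)
            Q = np.repeat(q, n_vec, axis=1)
            Q = Q * np.where(is_v0, 1.0, 2.0 * W)[None, :]
            Q[:, ~is_v0] *= P[:, ~is_v0]
            G = Z.T @ Q - ridge * V                       # gradient of LL
            lr_t = lr * (0.5 * (1 + math.cos(math.pi * t / n_iter)) * 0.9 + 0.1)
            m = 0.9 * m + 0.1 * G
            vadam = 0.999 * vadam + 0.001 * G ** 2
            mhat = m / (1 - 0.9 ** t)
            vhat = vadam / (1 - 0.999 ** t)
            V = V + lr_t * mhat / (np.sqrt(vhat) + 1e-8)
        out[start:stop] = V.T.reshape(nb, n_vec, dim)
    return out


def electrode_significance(
    model: GQMModel,
    design: DesignMatrix,
    resp: SpikeResponse,
    n_boot: int = 1000,
    threshold_sd: float = 2.0,
    seed: int | None = 0,
    method: str = "batched",
    n_iter: int = 150,
) -> np.ndarray:
    """Bootstrap significance mask for every (filter, lag, electrode).

    The estimation procedure is repeated against ``n_boot`` circularly
    time-shifted response vectors: each replicate re-initializes from the
    shifted data's own STA/STC (so the init-selection step of the pipeline
    is included in the null) and refits the filter block with the sigmoid
    held fixed at the fitted values.  This gives a null distribution for
    every coefficient of v0 and of each component; coefficients of the
    fitted model whose magnitude exceeds ``threshold_sd`` times the null SD
    are flagged significant.  Stimulus columns with zero variance are
    unidentifiable and always masked insignificant.  Sets ``model.sig_mask``
    and returns it.
    """
    if n_boot < 50:
        warnings.warn(f"n_boot={n_boot} gives an unstable null SD")
    rows = design.rows
    counts = np.asarray(resp.counts, dtype=float)
    scale = model.fit_meta.get("stim_scale", rows.std())
    Z = rows / scale
    rng = np.random.default_rng(seed)
    n = rows.shape[0]
    offsets = rng.integers(design.L, n - design.L, size=n_boot)
    shifted = np.stack([np.roll(counts, int(o)) for o in offsets])

    weights = model.weights()
    n_exc = int((weights > 0).sum())
    n_sup = int((weights < 0).sum())
    ridge = model.fit_meta.get("ridge", 0.0)

    # per-replicate STA/STC initialization from the shifted responses
    rng_init = np.random.default_rng(seed)
    inits = np.empty((n_boot, 1 + len(weights), Z.shape[1]))
    for kbt in range(n_boot):
        stc_k = compute_stc(design, SpikeResponse(counts=shifted[kbt]))
        v0k, compsk, _ = _initial_parameters(Z, shifted[kbt], scale,
                                             n_exc, n_sup, stc_k, rng_init)
        inits[kbt, 0] = v0k
        if len(weights):
            inits[kbt, 1:] = compsk

    if method == "batched":
        samples = _batched_shift_refit(Z, shifted, inits, weights,
                                       model.sigmoid, n_iter=n_iter,
                                       ridge=ridge)
    elif method == "scipy":
        samples = np.empty((n_boot, 1 + len(weights), Z.shape[1]))
        for kbt in range(n_boot):
            res = minimize(_filter_negll_grad,
                           _pack(inits[kbt, 0], inits[kbt, 1:]),
                           args=(Z, shifted[kbt], weights, model.sigmoid,
                                 ridge),
                           jac=True, method="L-BFGS-B",
                           options={"maxiter": 200})
            v0b, compsb = _unpack(res.x, Z.shape[1], len(weights))
            samples[kbt, 0] = v0b
            samples[kbt, 1:] = compsb
    else:
        raise ValueError(f"unknown method {method!r}")

    null_sd = samples.std(axis=0) / scale          # back to raw scale
    true_coefs = np.concatenate(
        [[model.v0], [v for v, _ in model.components]], axis=0) \
        if model.components else model.v0[None, :]
    mask = np.abs(true_coefs) > threshold_sd * null_sd
    dead = rows.std(axis=0) == 0
    if dead.any():
        logger.warning("%d zero-variance stimulus columns masked "
                       "insignificant", int(dead.sum()))
        mask[:, dead] = False
    model.sig_mask = mask
    model.fit_meta["null_sd"] = null_sd
    model.fit_meta["sig_threshold_sd"] = threshold_sd
    return mask


# ---------------------------------------------------------------------------
# Constant-response contours
# ---------------------------------------------------------------------------

def response_contour(model: GQMModel, i: int, j: int, level: float) -> dict:
    """Conic coefficients of the constant-response surface in a 2-D slice.

    In the plane of (canonicalized, orthogonal) components i and j with
    coordinates x = v_i . S and y = v_j . S, the generator restricted to the
    plane is g'(x, y) = k_z + k_x x + k_y y + w_i x^2 + w_j y^2, and the
    contour at expected rate ``level`` solves g' = c - ln(a/level - 1)/b.
    Excitatory-excitatory pairs give ellipses; excitatory-suppressive pairs
    give hyperbolae.
    """
    if i == j:
        raise ValueError("component indices must differ")
    a, b, c = model.sigmoid
    if not (0 < level < a):
        raise ValueError(f"level must lie in (0, {a})")
    vi, wi = model.components[i]
    vj, wj = model.components[j]
    ni2 = float(vi @ vi)
    nj2 = float(vj @ vj)
    if abs(vi @ vj) > 1e-8 * math.sqrt(ni2 * nj2):
        raise ValueError("components are not orthogonal; canonicalize first")
    g_level = c - math.log(a / level - 1.0) / b
    return {
        "k_z": 0.0,
        "k_x": float(model.v0 @ vi) / ni2,
        "k_y": float(model.v0 @ vj) / nj2,
        "w_i": float(wi),
        "w_j": float(wj),
        "g_level": g_level,
        "level": level,
        "kind": "ellipse" if wi == wj else "hyperbola",
    }


def contour_points(contour: dict, x_range: tuple[float, float],
                   n: int = 200) -> np.ndarray:
    """Sample (x, y) points on the contour by solving the conic for y."""
    kz, kx, ky = contour["k_z"], contour["k_x"], contour["k_y"]
    wi, wj, gl = contour["w_i"], contour["w_j"], contour["g_level"]
    xs = np.linspace(*x_range, n)
    pts = []
    for x in xs:
        # wj y^2 + ky y + (kz + kx x + wi x^2 - gl) = 0
        const = kz + kx * x + wi * x ** 2 - gl
        disc = ky ** 2 - 4.0 * wj * const
        if disc < 0:
            continue
        for sgn in (-1.0, 1.0):
            y = (-ky + sgn * math.sqrt(disc)) / (2.0 * wj)
            pts.append((x, y))
    return np.asarray(pts)


def plane_stimulus(model: GQMModel, i: int, j: int,
                   x: float, y: float) -> np.ndarray:
    """Stimulus in the (v_i, v_j) plane with projections (x, y)."""
    vi, _ = model.components[i]
    vj, _ = model.components[j]
    return x * vi / (vi @ vi) + y * vj / (vj @ vj)
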