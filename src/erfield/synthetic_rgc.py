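"""Synthetic ground-truth retinal ganglion cells.

Every downstream stage (subspace identification, GQM fitting, validation) is
exercised against cells with known excitatory/suppressive filter components
and a known sigmoid output nonlinearity, spiking as an inhomogeneous Poisson
process.  A "direct" mode emulates the synaptic-blockade condition, in which
the generator collapses to (at most) a one-dimensional quadratic plus a
dominant linear component.

Component scaling: for a white stimulus with per-entry SD s, a filter v gives
projections v.S with SD s * ||v||.  Components are therefore scaled so their
stimulus projections have a target SD in generator units (defaults chosen so
a 2-excitatory / 1-suppressive cell with the default sigmoid produces about
0.5 spikes per bin, i.e. ~30,000 spikes over a 60,000-pulse run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus_gen import DesignMatrix, truncated_gaussian_sd

#: per-entry SD of the default white-noise stimulus (sigma=150 uA truncated
#: at ±300 uA)
DEFAULT_STIM_SD = truncated_gaussian_sd(150.0, 300.0)

DEFAULT_SIGMOID = (3.0, 2.0, 1.0)        # (a, b, c): ~3 spikes/bin ceiling
DEFAULT_QUAD_PROJ_SD = 0.35              # projection SD per quadratic component
DEFAULT_LIN_PROJ_SD = 0.25               # projection SD of v0 (network mode)
#: direct activation responds to both pulse polarities (quadratic-dominated)
#: with a moderate polarity preference carried by the aligned linear term
DIRECT_LIN_PROJ_SD = 0.25


@dataclass
class SyntheticGroundTruth:
    """Planted GQM cell: linear filter, signed quadratic components, sigmoid."""

    v0: np.ndarray
    components: list[tuple[np.ndarray, int]]     # (v_i, w_i) with w_i = ±1
    sigmoid: tuple[float, float, float]          # (a, b, c)
    seed: int | None
    mode: str = "network"
    L: int = 1
    n_electrodes: int = 1
    sig_electrodes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_exc(self) -> int:
        return sum(1 for _, w in self.components if w > 0)

    @property
    def n_sup(self) -> int:
        return sum(1 for _, w in self.components if w < 0)

    def component_matrix(self) -> np.ndarray:
        """Components as columns (D x N)."""
        if not self.components:
            return np.zeros((self.v0.size, 0))
        return np.stack([v for v, _ in self.components], axis=1)


def _structured_filter(
    rng: np.random.Generator,
    L: int,
    n_electrodes: int,
    lag: int,
    background_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially compact filter: 2-4 strong electrodes in one lag frame.

    Background entries are small Gaussian noise (SD = 5% of the peak) so
    significance testing has a true-negative set.  Returns the flat filter
    and the flat indices of the planted (significant) entries.
    """
    filt = rng.normal(0.0, background_sd, size=(L, n_electrodes))
    n_sig = int(rng.integers(2, 5))
    n_sig = min(n_sig, n_electrodes)
    elecs = rng.choice(n_electrodes, size=n_sig, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_sig)
    amps = rng.uniform(0.6, 1.0, size=n_sig)
    filt[lag, elecs] = signs * amps
    flat = filt.ravel()
    return flat, lag * n_electrodes + elecs


def make_ground_truth(
    n_exc: int,
    n_sup: int,
    L: int,
    n_electrodes: int,
    sigmoid: tuple[float, float, float] = DEFAULT_SIGMOID,
    seed: int | None = None,
    mode: str = "network",
    stim_sd: float = DEFAULT_STIM_SD,
    quad_proj_sd: float = DEFAULT_QUAD_PROJ_SD,
    lin_proj_sd: float | None = None,
    orthogonalize: bool = True,
    uniform_polarity_first: bool = True,
) -> SyntheticGroundTruth:
    """Plant a ground-truth cell.

    Excitatory components sit at lag 0, suppressive components at lags >= 1
    (cycling if there are more suppressive components than earlier lags).
    Components are Gram-Schmidt orthogonalized in order, then scaled so each
    stimulus projection has SD ``quad_proj_sd``.  ``mode="direct"`` emulates
    synaptic blockade: at most one excitatory quadratic component, no
    suppression, and a dominant linear component.

    ``uniform_polarity_first`` forces the first excitatory component's planted
    electrodes to share one sign (the configuration used for polarity-
    preference statistics).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n_exc < 0 or n_sup < 0:
        raise ValueError("component counts must be non-negative")
    if mode not in ("network", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "direct":
        if n_exc > 1 or n_sup > 0:
            raise ValueError("direct mode allows at most one excitatory "
                             "quadratic component and no suppressive ones")
        if lin_proj_sd is None:
            lin_proj_sd = DIRECT_LIN_PROJ_SD
    if lin_proj_sd is None:
        lin_proj_sd = DEFAULT_LIN_PROJ_SD
    dim = L * n_electrodes
    if n_exc + n_sup > dim:
        raise ValueError(f"{n_exc + n_sup} components exceed the "
                         f"{dim}-dimensional stimulus space")

    rng = np.random.default_rng(seed)
    raw: list[np.ndarray] = []
    sig_idx: list[np.ndarray] = []
    weights: list[int] = []
    for i in range(n_exc):
        flat, idx = _structured_filter(rng, L, n_electrodes, lag=0)
        if i == 0 and uniform_polarity_first:
            flat[idx] = np.abs(flat[idx])
        raw.append(flat)
        sig_idx.append(idx)
        weights.append(+1)
    for i in range(n_sup):
        lag = 1 + i % max(1, L - 1) if L > 1 else 0
        flat, idx = _structured_filter(rng, L, n_electrodes, lag=lag)
        raw.append(flat)
        sig_idx.append(idx)
        weights.append(-1)

    # orthogonalize in order, preserving the planted structure as closely as
    # possible, then scale for the target projection SD
    comps: list[tuple[np.ndarray, int]] = []
    basis: list[np.ndarray] = []
    for flat, w in zip(raw, weights):
        v = flat.astype(float)
        if orthogonalize:
            for u in basis:
                v = v - (u @ v) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError("degenerate component during orthogonalization")
        u = v / nrm
        basis.append(u)
        comps.append((u * (quad_proj_sd / stim_sd), w))

    if mode == "direct" and comps:
        # direct activation is one-dimensional: the cell responds to a single
        # stimulus projection, so the linear term shares the quadratic
        # component's direction (g reduces to alpha*p + kappa^2*p^2 in the
        # projection p) and the subspace stays rank 1
        u = comps[0][0] / np.linalg.norm(comps[0][0])
        v0 = u * (lin_proj_sd / stim_sd)
        v0_idx = sig_idx[0]
    else:
        # linear filter: compact, lag 0; not orthogonalized against the
        # quadratic span (real cells' v0 largely lies inside that subspace)
        v0_flat, v0_idx = _structured_filter(rng, L, n_electrodes, lag=0)
        v0 = v0_flat / np.linalg.norm(v0_flat) * (lin_proj_sd / stim_sd)

    return SyntheticGroundTruth(
        v0=v0, components=comps, sigmoid=tuple(float(x) for x in sigmoid),
        seed=seed, mode=mode, L=L, n_electrodes=n_electrodes,
        sig_electrodes=sig_idx + [v0_idx],
    )


@dataclass(frozen=True)
class SpikeResponse:
    """Per-bin spike counts aligned to design-matrix rows."""

    counts: np.ndarray

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())


def generator_values(gt: SyntheticGroundTruth, rows: np.ndarray) -> np.ndarray:
    """Ground-truth generator signal g(S) = v0.S + sum_i w_i (v_i.S)^2."""
    g = rows @ gt.v0
    for v, w in gt.components:
        g = g + w * (rows @ v) ** 2
    return g


def expected_rates(gt: SyntheticGroundTruth, rows: np.ndarray) -> np.ndarray:
    a, b, c = gt.sigmoid
    g = generator_values(gt, rows)
    return a / (1.0 + np.exp(-b * (g - c)))


def simulate_responses(
    gt: SyntheticGroundTruth,
    design: DesignMatrix,
    seed: int | None = None,
    dead_time_ms: float = 0.0,
) -> SpikeResponse:
    """Draw Poisson spike counts from the planted cell's rate function.

    ``dead_time_ms`` removes an un-counted window at the start of each
    inter-pulse bin (emulating artefact-blanking dead time in a recording)
    by scaling the rate with the remaining bin fraction; the default is no
    dead time, since blanking is a recording artefact, not a property of the
    cell.
    """
    rows = design.rows
    if rows.shape[1] != gt.v0.size:
        raise ValueError(
            f"design has {rows.shape[1]} columns but the cell's filters have "
            f"{gt.v0.size} entries")
    rates = expected_rates(gt, rows)
    if dead_time_ms:
        interval_ms = 1000.0 / design.frequency_hz
        if not 0 <= dead_time_ms < interval_ms:
            raise ValueError("dead_time_ms must lie within the inter-pulse "
                             "interval")
        rates = rates * (1.0 - dead_time_ms / interval_ms)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates)
    return SpikeResponse(counts=counts.astype(np.int64))
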