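"""Post-fit characterization of electrical receptive fields.

Summaries derived from a fitted GQM: the integration time (latest stimulus
lag at which any electrode is significant, per excitatory/suppressive class),
the ERF size (amplitude-weighted mean distance of significant electrodes
from the recording site), the polarity preference (normalized saturation
rates for anodic-first vs cathodic-first stimulation along a component), and
the reconstruction of the linear filter v0 from the quadratic subspace
(u0 = V V^T v0 with cosine similarity ||u0|| / ||v0||).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gqm_fit import GQMModel
from .stimulus_gen import DesignMatrix, ElectrodeArray
from .synthetic_rgc import SpikeResponse

logger = logging.getLogger("erfield")


@dataclass
class ERFSummary:
    integration_time_exc_ms: float
    integration_time_sup_ms: float
    erf_sizes_mm: list[float]
    polarity: tuple[float, float] | None       # (anodic_sat, cathodic_sat)
    similarity: float | None
    b_weights: np.ndarray | None
    flags: list[str]


def integration_time(
    sig_mask: np.ndarray,
    weights: np.ndarray,
    frequency_hz: float,
    n_electrodes: int,
) -> tuple[float, float]:
    """Latest significant stimulus lag per component class, in ms.

    ``sig_mask`` is the (1 + N, L*n_electrodes) bootstrap mask (row 0 = v0,
    excluded here); ``weights`` the N component signs.  A class with no
    significant entries reports 0 ms (logged).
    """
    comp_mask = np.asarray(sig_mask)[1:]
    weights = np.asarray(weights)
    out = []
    for cls in (+1, -1):
        rows = comp_mask[weights == cls]
        if rows.size == 0 or not rows.any():
            logger.info("no significant entries for class %+d; integration "
                        "time reported as 0", cls)
            out.append(0.0)
            continue
        lag_any = rows.reshape(rows.shape[0], -1, n_electrodes).any(axis=(0, 2))
        latest = np.nonzero(lag_any)[0].max()
        out.append(latest * 1000.0 / frequency_hz)
    return out[0], out[1]


def erf_size(
    component: np.ndarray,
    sig_mask: np.ndarray,
    array: ElectrodeArray,
) -> float:
    """Amplitude-weighted mean distance (mm) of significant electrodes from
    the recording location.

    An electrode is significant if any of its lags is; its weight is the
    largest absolute fitted amplitude across lags.  Invariant to global
    rescaling of the component.  No significant electrodes -> NaN (flagged).
    """
    comp = np.asarray(component).reshape(-1, array.n_electrodes)
    mask = np.asarray(sig_mask).reshape(-1, array.n_electrodes)
    elec_sig = mask.any(axis=0)
    if not elec_sig.any():
        logger.warning("no significant electrodes; ERF size undefined")
        return float("nan")
    amps = np.abs(comp).max(axis=0)[elec_sig]
    dists = array.distances_to_recording()[elec_sig]
    return float((amps * dists).sum() / amps.sum())


def polarity_preference(
    component: np.ndarray,
    design: DesignMatrix,
    resp: SpikeResponse,
    sig_mask: np.ndarray | None = None,
    bin_size: int = 200,
) -> tuple[float, float]:
    """Normalized saturation rates for anodic (+) and cathodic (−) stimulation.

    Stimuli are projected onto the (unit-normalized) component and binned in
    groups of ``bin_size`` along the projection; the maximum mean response on
    the positive and on the negative half-axis are each divided by the global
    maximum, so max(anodic, cathodic) = 1.

    The statistic is only meaningful for components whose significant
    electrodes share one polarity; mixed-sign components raise ValueError.
    """
    comp = np.asarray(component, dtype=float)
    if sig_mask is not None:
        sig = comp[np.asarray(sig_mask, dtype=bool)]
        if sig.size and not (np.all(sig > 0) or np.all(sig < 0)):
            raise ValueError("component has mixed-polarity significant "
                             "electrodes; polarity preference not applicable")
        if sig.size and np.all(sig < 0):
            comp = -comp        # orient so planted polarity maps to +
    proj = design.rows @ (comp / np.linalg.norm(comp))
    counts = np.asarray(resp.counts, dtype=float)
    order = np.argsort(proj, kind="stable")
    n_bins = proj.size // bin_size
    if n_bins < 4:
        raise ValueError("too few samples for polarity binning")
    pb = proj[order][: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    rb = counts[order][: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    pos = rb[pb > 0]
    neg = rb[pb < 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("too few samples on one projection half-axis")
    peak = rb.max()
    if peak <= 0:
        raise ValueError("no responses in any bin")
    return float(pos.max() / peak), float(neg.max() / peak)


def linear_component_similarity(
    v0: np.ndarray,
    components: np.ndarray,
    atol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project v0 onto the span of orthonormal quadratic components.

    Returns (b, u0, similarity) with b = V^T v0, u0 = V b, and
    similarity = cos(angle(v0, u0)) = ||u0|| / ||v0||.  Columns of
    ``components`` are normalized here; they must be mutually orthogonal.
    """
    v0 = np.asarray(v0, dtype=float)
    V = np.asarray(components, dtype=float)
    if V.ndim != 2:
        raise ValueError("components must be a (D, N) matrix of columns")
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm component column")
    V = V / norms
    gram = V.T @ V
    if not np.allclose(gram, np.eye(V.shape[1]), atol=1e-6):
        raise ValueError("components are not mutually orthogonal")
    nv0 = np.linalg.norm(v0)
    if nv0 < atol:
        raise ValueError("v0 has (near-)zero norm; similarity undefined")
    b = V.T @ v0
    u0 = V @ b
    similarity = float(np.linalg.norm(u0) / nv0)
    return b, u0, similarity


def summarize_erf(
    model: GQMModel,
    design: DesignMatrix,
    resp: SpikeResponse,
    array: ElectrodeArray,
) -> ERFSummary:
    """Assemble the per-cell ERF summary from a fitted, masked model."""
    flags: list[str] = []
    if model.sig_mask is None:
        raise ValueError("run electrode_significance before summarizing")
    weights = model.weights()
    t_exc, t_sup = integration_time(model.sig_mask, weights,
                                    design.frequency_hz, design.n_electrodes)
    sizes = []
    for k, (v, _) in enumerate(model.components):
        sizes.append(erf_size(v, model.sig_mask[k + 1], array))
    polarity = None
    for k, (v, w) in enumerate(model.components):
        if w < 0:
            continue
        try:
            polarity = polarity_preference(v, design, resp,
                                           sig_mask=model.sig_mask[k + 1])
            break
        except ValueError:
            continue
    if polarity is None:
        flags.append("no uniform-polarity excitatory component")
    b = u0 = None
    similarity = None
    if model.components:
        try:
            b, u0, similarity = linear_component_similarity(
                model.v0, model.component_matrix())
        except ValueError as exc:
            flags.append(str(exc))
    return ERFSummary(
        integration_time_exc_ms=t_exc, integration_time_sup_ms=t_sup,
        erf_sizes_mm=sizes, polarity=polarity, similarity=similarity,
        b_weights=b, flags=flags)
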