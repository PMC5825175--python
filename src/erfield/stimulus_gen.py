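"""Electrical stimulus generation.

Multi-electrode arrays deliver biphasic current pulses simultaneously on all
electrodes; each pulse is abstracted to one signed amplitude per electrode
(positive = anodic-first).  This module generates the array geometry, Gaussian
white-noise pulse trains (rejection-resampled at the stimulator limit),
structured image stimuli (spots, lines, gratings), and the windowed design
matrix that relates stimulus history to per-pulse spike counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

logger = logging.getLogger("erfield")

IMAGE_SIZE = 500          # pixels per side
PIXEL_PITCH_MM = 0.01     # 10 um per pixel
IMAGE_MAX_UA = 250.0      # scaling target for structured images
STRUCTURED_MODES = ("spots", "lines", "static_grating", "moving_grating")


# ---------------------------------------------------------------------------
# Electrode arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeArray:
    """Hexagonal stimulating-electrode layout.

    positions are (x, y) centre coordinates in mm, array centred at the
    origin; ``recording_loc`` is the extracellular recording site.
    """

    positions: np.ndarray          # (n, 2) mm
    diameter_um: float
    recording_loc: tuple[float, float] = (0.0, 0.0)
    pitch_mm: float = 1.0

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    def distances_to_recording(self) -> np.ndarray:
        rec = np.asarray(self.recording_loc, dtype=float)
        return np.linalg.norm(self.positions - rec, axis=1)


def _centered_hex_rings(n: int, pitch: float) -> np.ndarray | None:
    """Ring layout for centered hexagonal counts 1, 7, 19, 37, ..."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n:
        # walk the 6 edges of ring `ring`
        corners = [
            (pitch * ring * math.cos(math.pi / 3 * k),
             pitch * ring * math.sin(math.pi / 3 * k))
            for k in range(6)
        ]
        for k in range(6):
            x0, y0 = corners[k]
            x1, y1 = corners[(k + 1) % 6]
            for s in range(ring):
                t = s / ring
                pts.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
        ring += 1
    if len(pts) != n:
        return None
    return np.asarray(pts)


def _staggered_grid(n: int, pitch: float) -> np.ndarray:
    """Compact staggered hexagonal grid, rows offset by pitch/2."""
    dy = pitch * math.sqrt(3) / 2
    best = None
    for n_cols in range(1, n + 1):
        n_rows = math.ceil(n / n_cols)
        if n_rows * n_cols - n >= n_cols:
            continue
        width = (n_cols - 1 + 0.5) * pitch if n_rows > 1 else (n_cols - 1) * pitch
        height = (n_rows - 1) * dy
        score = abs(width - height)
        if best is None or score < best[0]:
            best = (score, n_rows, n_cols)
    _, n_rows, n_cols = best
    pts = []
    for r in range(n_rows):
        xoff = 0.5 * pitch if r % 2 else 0.0
        for c in range(n_cols):
            pts.append((c * pitch + xoff, r * dy))
    pts = np.asarray(pts[:n])
    return pts - pts.mean(axis=0)


def make_electrode_array(
    n_electrodes: int,
    pitch_mm: float = 1.0,
    diameter_um: float = 400.0,
    recording_loc: tuple[float, float] = (0.0, 0.0),
) -> ElectrodeArray:
    """Build a hexagonal-lattice array centred at the origin.

    Centered-hexagonal counts (1, 7, 19, ...) are laid out as concentric
    rings; other counts as a compact staggered near-square grid (for the
    20-electrode array at 1 mm pitch this spans ~3.5 x 3.5 mm).
    """
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    if pitch_mm <= 0:
        raise ValueError("pitch_mm must be positive")
    pts = _centered_hex_rings(n_electrodes, pitch_mm)
    if pts is None:
        pts = _staggered_grid(n_electrodes, pitch_mm)
    pts = pts - pts.mean(axis=0) if n_electrodes > 1 else np.zeros((1, 2))
    return ElectrodeArray(
        positions=pts, diameter_um=diameter_um,
        recording_loc=tuple(recording_loc), pitch_mm=pitch_mm,
    )


# ---------------------------------------------------------------------------
# White-noise pulse trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusTrain:
    """Per-pulse current amplitudes (uA) for every electrode.

    Positive amplitudes are anodic-first pulses, negative cathodic-first.
    """

    amplitudes: np.ndarray        # (n_pulses, n_electrodes) uA
    frequency_hz: float
    seed: int | None = None

    @property
    def n_pulses(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.amplitudes.shape[1]


def truncated_gaussian_sd(sigma: float, limit: float) -> float:
    """Closed-form SD of N(0, sigma^2) truncated to [-limit, limit]."""
    a = limit / sigma
    z = 2.0 * norm.cdf(a) - 1.0
    return sigma * math.sqrt(1.0 - 2.0 * a * norm.pdf(a) / z)


def sample_white_noise_train(
    n_pulses: int,
    n_electrodes: int,
    sigma_ua: float = 150.0,
    limit_ua: float = 300.0,
    frequency_hz: float = 20.0,
    seed: int | None = None,
) -> StimulusTrain:
    """Gaussian white-noise amplitudes, rejection-resampled beyond the limit.

    Amplitudes beyond ±limit_ua are discarded and redrawn (not clipped), so
    the marginal distribution is the truncated Gaussian.
    """
    if sigma_ua <= 0:
        raise ValueError("sigma_ua must be positive")
    if limit_ua <= 0:
        raise ValueError("limit_ua must be positive")
    if limit_ua < sigma_ua / 100.0:
        logger.warning(
            "limit_ua=%g is degenerate relative to sigma_ua=%g; "
            "the truncated distribution is nearly uniform", limit_ua, sigma_ua)
    rng = np.random.default_rng(seed)
    amps = rng.normal(0.0, sigma_ua, size=(n_pulses, n_electrodes))
    bad = np.abs(amps) > limit_ua
    while bad.any():
        amps[bad] = rng.normal(0.0, sigma_ua, size=int(bad.sum()))
        bad = np.abs(amps) > limit_ua
    return StimulusTrain(amplitudes=amps, frequency_hz=frequency_hz, seed=seed)


# ---------------------------------------------------------------------------
# Structured image stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusImage:
    """A 500 x 500 current-amplitude image; each pixel spans 10 um."""

    pixels: np.ndarray
    mode: str
    pixel_pitch_um: float = 10.0


def scale_image(pixels: np.ndarray, max_ua: float = IMAGE_MAX_UA) -> np.ndarray:
    """Scale so the largest-|amplitude| pixel is exactly ±max_ua (idempotent)."""
    peak = np.abs(pixels).max()
    if peak == 0 or abs(peak - max_ua) <= 1e-9 * max_ua:
        return pixels
    return pixels * (max_ua / peak)


def _draw_spot(img: np.ndarray, rng: np.random.Generator, sign: float) -> None:
    # spot diameter up to 1.5 mm (150 px) prior to blurring
    radius = rng.uniform(0.1, 0.75) / PIXEL_PITCH_MM   # px
    cy, cx = rng.uniform(0, IMAGE_SIZE, size=2)
    yy, xx = np.ogrid[:IMAGE_SIZE, :IMAGE_SIZE]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = sign


def _draw_line(img: np.ndarray, rng: np.random.Generator, sign: float) -> None:
    # length >= 1 mm (100 px), at most the image size; 1 px thick pre-blur
    length = rng.uniform(1.0, 5.0) / PIXEL_PITCH_MM
    theta = math.radians(rng.integers(0, 180))
    cy, cx = rng.uniform(0, IMAGE_SIZE, size=2)
    t = np.arange(-length / 2, length / 2, 0.5)
    ys = np.rint(cy + t * math.sin(theta)).astype(int)
    xs = np.rint(cx + t * math.cos(theta)).astype(int)
    ok = (ys >= 0) & (ys < IMAGE_SIZE) & (xs >= 0) & (xs < IMAGE_SIZE)
    img[ys[ok], xs[ok]] = sign


def _grating(sf_cyc_mm: float, theta_deg: float, phase: float) -> np.ndarray:
    idx = (np.arange(IMAGE_SIZE) - (IMAGE_SIZE - 1) / 2) * PIXEL_PITCH_MM
    xx, yy = np.meshgrid(idx, idx)
    th = math.radians(theta_deg)
    proj = xx * math.cos(th) + yy * math.sin(th)
    return np.sin(2 * math.pi * sf_cyc_mm * proj + phase)


def render_structured_image(
    mode: str,
    rng: np.random.Generator,
    blur_sigma_px: float = 10.0,
    sf_range_cyc_mm: tuple[float, float] = (0.05, 0.5),
    pulse_rate_hz: float = 30.0,
    mixed_polarity: bool = True,
) -> StimulusImage | list[StimulusImage]:
    """Render one structured stimulus image (or a frame sequence).

    Spots and lines: up to 4 features at uniform-random locations, each with
    random polarity, Gaussian-blurred (default SD 100 um).  Gratings: random
    orientation (0-180 deg in 1 deg steps) and spatial frequency below the
    0.5 cyc/mm Nyquist limit of the 1 mm electrode pitch.  Moving gratings
    drift at up to 2 Hz (0.1 Hz steps) for 300 ms, one frame per pulse.
    Static modes are scaled so max |pixel| = 250 uA; moving gratings are
    scaled over the whole frame set.
    """
    if mode not in STRUCTURED_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {STRUCTURED_MODES}")

    if mode in ("spots", "lines"):
        img = np.zeros((IMAGE_SIZE, IMAGE_SIZE))
        n_feat = int(rng.integers(1, 5))
        for _ in range(n_feat):
            sign = float(rng.choice([-1.0, 1.0])) if mixed_polarity else 1.0
            if mode == "spots":
                _draw_spot(img, rng, sign)
            else:
                _draw_line(img, rng, sign)
        img = ndimage.gaussian_filter(img, blur_sigma_px)
        return StimulusImage(pixels=scale_image(img), mode=mode)

    sf = rng.uniform(*sf_range_cyc_mm)
    theta = float(rng.integers(0, 180))
    phase = rng.uniform(0, 2 * math.pi)
    if mode == "static_grating":
        img = _grating(sf, theta, phase)
        return StimulusImage(pixels=scale_image(img), mode=mode)

    # moving grating: drift along the wave direction, 300 ms of frames
    tf = 0.1 * int(rng.integers(1, 21))      # 0.1 .. 2.0 Hz
    n_frames = round(0.3 * pulse_rate_hz)
    frames = [
        _grating(sf, theta, phase - 2 * math.pi * tf * k / pulse_rate_hz)
        for k in range(n_frames)
    ]
    peak = max(np.abs(f).max() for f in frames)
    frames = [f * (IMAGE_MAX_UA / peak) for f in frames]
    return [StimulusImage(pixels=f, mode=mode) for f in frames]


def image_to_pulse_amplitudes(image: StimulusImage, array: ElectrodeArray) -> np.ndarray:
    """Read the pixel value at each electrode centre (nearest pixel).

    The array centre is aligned to the image centre: electrode (x, y) in mm
    maps to pixel (row, col) = round(249.5 + y/0.01), round(249.5 + x/0.01)
    with the image origin at the top-left.
    """
    centre = (IMAGE_SIZE - 1) / 2
    amps = np.empty(array.n_electrodes)
    for i, (x, y) in enumerate(array.positions):
        row = int(np.round(centre + y / PIXEL_PITCH_MM))
        col = int(np.round(centre + x / PIXEL_PITCH_MM))
        if not (0 <= row < IMAGE_SIZE and 0 <= col < IMAGE_SIZE):
            raise ValueError(
                f"electrode {i} at ({x:.3f}, {y:.3f}) mm falls outside the "
                f"{IMAGE_SIZE}x{IMAGE_SIZE} image")
        amps[i] = image.pixels[row, col]
    return amps


def structured_train(
    array: ElectrodeArray,
    duration_s: float,
    rng: np.random.Generator,
    pulse_rate_hz: float = 30.0,
    hold_ms: float = 180.0,
    modes: tuple[str, ...] = STRUCTURED_MODES,
    **render_kw,
) -> StimulusTrain:
    """Pulse train sampled from a random sequence of structured images.

    Static images (spots / lines / static gratings) are held for ``hold_ms``;
    moving gratings emit one frame per pulse.  This reproduces the structure
    (and inter-electrode correlation) of image-based stimulation.  ``modes``
    restricts the image modes drawn (all four by default).
    """
    n_pulses = int(round(duration_s * pulse_rate_hz))
    hold_pulses = max(1, int(round(hold_ms * pulse_rate_hz / 1000.0)))
    rows: list[np.ndarray] = []
    while len(rows) < n_pulses:
        mode = modes[int(rng.integers(0, len(modes)))]
        out = render_structured_image(mode, rng, pulse_rate_hz=pulse_rate_hz,
                                      **render_kw)
        if isinstance(out, list):
            rows.extend(image_to_pulse_amplitudes(f, array) for f in out)
        else:
            amp = image_to_pulse_amplitudes(out, array)
            rows.extend([amp] * hold_pulses)
    amps = np.asarray(rows[:n_pulses])
    return StimulusTrain(amplitudes=amps, frequency_hz=pulse_rate_hz)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """Stimulus-history design matrix.

    Row t concatenates the pulse vectors at lags 0..L-1 (lag 0 = the pulse
    immediately preceding the response bin), lag-major / electrode-minor.
    Rows exist only for pulses with a full history, so the first L-1 pulses
    are dropped.
    """

    rows: np.ndarray               # (n_responses, L * n_electrodes)
    L: int
    n_electrodes: int
    window_ms: float
    frequency_hz: float
    lag_times_ms: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.lag_times_ms is None:
            object.__setattr__(
                self, "lag_times_ms",
                -1000.0 / self.frequency_hz * np.arange(self.L))

    @property
    def n_responses(self) -> int:
        return self.rows.shape[0]

    def unstack(self, vector: np.ndarray) -> np.ndarray:
        """Reshape a flat filter to (L, n_electrodes)."""
        return np.asarray(vector).reshape(self.L, self.n_electrodes)


def build_design_matrix(train: StimulusTrain, window_ms: float = 300.0) -> DesignMatrix:
    """Window the pulse train into stimulus-history rows S_t.

    L = round(window_ms * f / 1000); the window must cover at least one
    inter-pulse interval.
    """
    f = train.frequency_hz
    if window_ms < 1000.0 / f:
        raise ValueError(
            f"window_ms={window_ms} is shorter than one inter-pulse interval "
            f"({1000.0 / f:.1f} ms at {f} Hz)")
    L = round(window_ms * f / 1000.0)
    amps = train.amplitudes
    n = amps.shape[0]
    if n < L:
        raise ValueError(f"train has {n} pulses but the window needs {L}")
    blocks = [amps[L - 1 - lag: n - lag] for lag in range(L)]
    rows = np.ascontiguousarray(np.hstack(blocks))
    return DesignMatrix(rows=rows, L=L, n_electrodes=train.n_electrodes,
                        window_ms=window_ms, frequency_hz=f)
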