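"""Ground-truth-known synthetic widefield movies.

Real recordings from the home-cage rig are not redistributable, so every
downstream stage (registration, ΔF/F₀ preprocessing, connectivity mapping,
evoked statistics) is validated against movies generated here, where every
injected quantity — region-pair correlations, evoked peak amplitudes and
latencies, rigid motion, photobleaching, focus artifacts — is known
exactly.

Generative model, per pixel and frame::

    F(x, t) = B(x) * bleach(t) * m(t) * (1 + g(t) + s_r(t) + e_r(t)) + n(x, t)

where ``B`` is the baseline fluorescence image, ``bleach`` a single
exponential, ``m`` a multiplicative focus/motion artifact shared by the
whole frame, ``g`` a band-limited global component common to the brain
window, ``s_r`` the band-limited latent trace of the cortical region
containing the pixel (zero elsewhere), ``e_r`` region-specific evoked
transients, and ``n`` white sensor noise.  Frames are then rigidly
translated by per-frame integer shifts.  An off-window correction-ROI
patch carries only ``B * bleach * m`` plus noise — no neural signal.

Region latents are Gaussian noise band-limited to the analysis band
(0.3-3 Hz) and correlated to user-specified targets through a Cholesky
mixing of independent sources, so expected pairwise Pearson r equals the
target exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .session_io import FrameStack, MaskSet

__all__ = [
    "RigGeometry",
    "EvokedEvent",
    "GroundTruth",
    "SyntheticMovie",
    "InvalidGeometryError",
    "pixel_pitch",
    "mm_to_px",
    "default_scene",
    "make_settling_motion",
    "generate_movie",
    "generate_gfp_control",
    "bandlimited_noise",
    "evoked_kernel",
    "DEFAULT_REGION_COORDS_MM",
]


class InvalidGeometryError(ValueError):
    """Rig geometry with non-positive or out-of-frame fields."""


# ---------------------------------------------------------------------------
# rig geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigGeometry:
    """Camera/optics geometry of the imaging rig.

    The production rig images a bilateral ~10.5-10.75 mm field of view at
    256 x 256 binned pixels and 30 Hz; smaller frames are used in tests
    purely for speed (pixel pitch scales accordingly).
    """

    fov_mm: float = 10.75
    frame_px: int = 256
    frame_rate_hz: float = 30.0
    bregma_px: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.fov_mm <= 0 or self.frame_rate_hz <= 0:
            raise InvalidGeometryError("fov_mm and frame_rate_hz must be positive")
        if self.frame_px < 16:
            raise InvalidGeometryError("frame_px must be >= 16")
        r, c = self.bregma_px
        if not (0 <= r < self.frame_px and 0 <= c < self.frame_px):
            raise InvalidGeometryError("bregma_px outside the frame")


def pixel_pitch(geom: RigGeometry) -> float:
    """Pixel size in micrometres (fov_mm * 1000 / frame_px)."""
    if not isinstance(geom, RigGeometry):
        geom = RigGeometry(*geom)
    return geom.fov_mm * 1000.0 / geom.frame_px


def mm_to_px(geom: RigGeometry, ap_mm: float, ml_mm: float) -> tuple[int, int]:
    """Bregma-relative (anterior-posterior, medio-lateral) mm to (row, col).

    Anterior is the -row direction; positive ML is to the right (+col).
    """
    pitch_mm = pixel_pitch(geom) / 1000.0
    r = int(round(geom.bregma_px[0] - ap_mm / pitch_mm))
    c = int(round(geom.bregma_px[1] + ml_mm / pitch_mm))
    return r, c


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvokedEvent:
    """One injected evoked transient.

    ``peak_fraction`` is the ΔF/F₀ peak (e.g. 0.049 for 4.9 %);
    ``latency_s`` the time from event to peak; ``decay_s`` the decay time
    constant of the indicator (GCaMP6s-like by default).
    """

    time_s: float
    region: str
    peak_fraction: float
    latency_s: float = 0.5
    decay_s: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_fraction < 0:
            raise ValueError("peak_fraction must be >= 0")
        if self.latency_s <= 0 or self.decay_s <= 0:
            raise ValueError("latency_s and decay_s must be positive")


@dataclass
class GroundTruth:
    """Everything the generator injects, hence everything recoverable.

    ``region_masks`` are disjoint labelled pixel sets; ``mixing`` maps
    region-name pairs to target Pearson correlations (unspecified pairs are
    uncorrelated; homotopic pairs of the default scene are set to 0.8).
    Amplitudes are ΔF/F₀ standard deviations (dimensionless fractions);
    ``noise_sd`` is in raw counts.
    """

    region_masks: dict
    mixing: dict = field(default_factory=dict)
    region_amp: float = 0.02
    global_amplitude: float = 0.01
    evoked: list = field(default_factory=list)
    motion: np.ndarray | None = None        # (T, 2) integer (dy, dx) or None
    bleach_tau_s: float = 600.0
    noise_sd: float = 50.0
    baseline: float = 10000.0
    baseline_outside: float = 2000.0
    roi_baseline: float = 6000.0
    focus_amplitude: float = 0.0            # sd of multiplicative focus artifact
    band_hz: tuple[float, float] = (0.3, 3.0)

    def validate(self, frame_shape: tuple[int, int]) -> None:
        occupied = np.zeros(frame_shape, dtype=bool)
        for name, mask in self.region_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != frame_shape:
                raise InvalidGeometryError(
                    f"region {name} mask shape {mask.shape} != frame {frame_shape}")
            if np.any(mask & occupied):
                raise ValueError(f"region {name} overlaps another region")
            occupied |= mask
        for pair, rho in self.mixing.items():
            if abs(rho) > 1:
                raise ValueError(f"correlation target {pair} -> {rho} exceeds |1|")
        for ev in self.evoked:
            if ev.region not in self.region_masks:
                raise ValueError(f"evoked event names unknown region {ev.region}")
        if self.motion is not None and not np.all(np.isfinite(self.motion)):
            raise ValueError("motion shifts must be finite")


@dataclass
class SyntheticMovie:
    """A generated movie together with its realized ground truth.

    ``region_traces`` are the realized latent ΔF/F₀ traces (region name ->
    length-T array), the oracle for recovery tests; ``global_trace``,
    ``focus_trace``, ``bleach`` and ``motion`` likewise.
    """

    stack: FrameStack
    truth: GroundTruth
    geom: RigGeometry
    masks: MaskSet
    region_traces: dict
    global_trace: np.ndarray
    focus_trace: np.ndarray
    bleach: np.ndarray
    motion: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def bandlimited_noise(n_traces: int, n_frames: int, fs: float,
                      band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (zero-phase)."""
    white = rng.standard_normal((n_traces, n_frames))
    sos = signal.butter(4, band, btype="band", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def evoked_kernel(t: np.ndarray, latency_s: float, decay_s: float) -> np.ndarray:
    """Stylized calcium transient with unit peak exactly at ``latency_s``.

    The indicator impulse response ``exp(-t / decay_s)`` convolved with a
    boxcar of stimulus-driven spiking lasting ``latency_s``: fluorescence
    ramps up while the burst lasts, peaks at burst offset, then decays
    with the indicator time constant.  The peak is a genuine kink, as in
    measured transients, so time-to-peak is well defined.
    """
    if latency_s <= 0 or decay_s <= 0:
        raise ValueError("latency_s and decay_s must be positive")
    tt = np.asarray(t, dtype=np.float64)
    rise = (1.0 - np.exp(-np.clip(tt, 0, None) / decay_s)) \
        / (1.0 - math.exp(-latency_s / decay_s))
    fall = np.exp(-(tt - latency_s) / decay_s)
    k = np.where(tt < latency_s, rise, fall)
    k[tt < 0] = 0.0
    return k


def make_settling_motion(n_frames: int, fs: float, settle_s: float = 1.0,
                         amp_px: int = 3, seed: int = 0,
                         drift: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Per-frame integer shifts with a mechanical-settling transient.

    The first ``settle_s`` seconds carry random shifts up to ``amp_px``
    (the head bar settling after solenoid engagement); afterwards the
    frame sits at the constant inter-session ``drift``.
    """
    rng = np.random.default_rng(seed)
    motion = np.zeros((n_frames, 2), dtype=int)
    n_settle = min(n_frames, int(round(settle_s * fs)))
    motion[:n_settle] = rng.integers(-amp_px, amp_px + 1, size=(n_settle, 2))
    motion[n_settle:] = drift
    return motion


#: schematic bregma-relative centres (AP mm, |ML| mm) of the cortical
#: regions resolvable through the bilateral window; mirrored per hemisphere
DEFAULT_REGION_COORDS_MM = {
    "V1": (-3.5, 2.5),
    "BC": (-1.5, 3.3),
    "HL": (-0.5, 1.7),
    "M1": (1.0, 1.7),
    "M2": (2.2, 0.9),
    "RS": (-2.5, 0.6),
    "AC": (0.3, 0.8),
}


def default_scene(geom: RigGeometry | None = None,
                  region_radius_mm: float = 0.5,
                  homotopic_r: float = 0.8,
                  extra_mixing: dict | None = None,
                  **truth_kwargs) -> tuple[GroundTruth, MaskSet]:
    """Build the default bilateral scene: window, correction ROI, 14 regions.

    Each named region appears once per hemisphere (``V1-L``/``V1-R`` etc.)
    as a disk of ``region_radius_mm``; homotopic pairs get correlation
    ``homotopic_r``; ``extra_mixing`` adds further pair targets (e.g.
    ipsilateral HL-M1 coupling).  The correction ROI sits in the frame
    corner, outside the circular transcranial window.
    """
    geom = geom or RigGeometry()
    n = geom.frame_px
    pitch_mm = pixel_pitch(geom) / 1000.0
    yy, xx = np.mgrid[:n, :n]
    br, bc = geom.bregma_px
    window = ((yy - br) ** 2 + (xx - bc) ** 2) <= (0.45 * n) ** 2

    roi = np.zeros((n, n), dtype=bool)
    k = max(3, n // 12)
    roi[1:1 + k, 1:1 + k] = True
    roi &= ~window
    masks = MaskSet(window, roi, geom.bregma_px)

    radius_px = max(2.0, region_radius_mm / pitch_mm)
    region_masks: dict[str, np.ndarray] = {}
    for name, (ap, ml) in DEFAULT_REGION_COORDS_MM.items():
        for side, sign in (("L", -1.0), ("R", 1.0)):
            r, c = mm_to_px(geom, ap, sign * ml)
            disk = ((yy - r) ** 2 + (xx - c) ** 2) <= radius_px ** 2
            disk &= window
            if not disk.any():
                raise InvalidGeometryError(
                    f"region {name}-{side} falls outside the window")
            region_masks[f"{name}-{side}"] = disk
    # enforce disjointness (clip later regions where disks touch)
    occupied = np.zeros((n, n), dtype=bool)
    for name in region_masks:
        region_masks[name] = region_masks[name] & ~occupied
        occupied |= region_masks[name]

    mixing = {(f"{name}-L", f"{name}-R"): homotopic_r
              for name in DEFAULT_REGION_COORDS_MM}
    if extra_mixing:
        mixing.update(extra_mixing)
    truth = GroundTruth(region_masks=region_masks, mixing=mixing, **truth_kwargs)
    truth.validate((n, n))
    return truth, masks


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _correlation_matrix(names: list[str], mixing: dict) -> np.ndarray:
    m = np.eye(len(names))
    index = {n: i for i, n in enumerate(names)}
    for (a, b), rho in mixing.items():
        if a in index and b in index:
            m[index[a], index[b]] = m[index[b], index[a]] = rho
    return m


def _correlated_latents(names: list[str], mixing: dict, n_frames: int,
                        fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Band-limited unit-variance latents with target pairwise correlations."""
    corr = _correlation_matrix(names, mixing)
    # tiny ridge guards semi-definite targets against round-off
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(names)))
    sources = bandlimited_noise(len(names), n_frames, fs, band, rng)
    latents = chol @ sources
    sd = latents.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return latents / sd


def _translate(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with replicate padding at the entering edge."""
    out = frame
    if dy:
        out = np.roll(out, dy, axis=0)
        if dy > 0:
            out[:dy] = out[dy]
        else:
            out[dy:] = out[dy - 1]
    if dx:
        out = np.roll(out, dx, axis=1)
        if dx > 0:
            out[:, :dx] = out[:, dx:dx + 1]
        else:
            out[:, dx:] = out[:, dx - 1:dx]
    return out


def generate_movie(truth: GroundTruth, geom: RigGeometry, duration_s: float,
                   seed: int, masks: MaskSet | None = None,
                   dtype=np.float32) -> SyntheticMovie:
    """Render the generative model into a movie; bit-identical per seed.

    ``masks`` defaults to the geometry's default scene layout when the
    ground truth came from :func:`default_scene`; pass the matching MaskSet
    explicitly otherwise.  ``dtype`` float32 keeps the conservation
    identity exact; uint8/uint16 quantize for the raw-format I/O path.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    n = geom.frame_px
    truth.validate((n, n))
    if masks is None:
        _, masks = default_scene(geom)
    fs = geom.frame_rate_hz
    n_frames = int(round(duration_s * fs))
    t = np.arange(n_frames) / fs
    rng = np.random.default_rng(seed)

    names = list(truth.region_masks)
    if names and truth.region_amp > 0:
        latents = _correlated_latents(names, truth.mixing, n_frames, fs,
                                      truth.band_hz, rng) * truth.region_amp
    else:
        # burn identical draws so noise realizations match amp=0 runs
        latents = np.zeros((len(names), n_frames))
        if names:
            _ = _correlated_latents(names, truth.mixing, n_frames, fs,
                                    truth.band_hz, rng)

    global_trace = (bandlimited_noise(1, n_frames, fs, truth.band_hz, rng)[0]
                    * truth.global_amplitude)

    evoked_traces = {name: np.zeros(n_frames) for name in names}
    for ev in truth.evoked:
        kern = evoked_kernel(t - ev.time_s, ev.latency_s, ev.decay_s)
        evoked_traces[ev.region] = evoked_traces[ev.region] \
            + ev.peak_fraction * kern

    region_traces = {name: latents[i] + evoked_traces[name]
                     for i, name in enumerate(names)}

    if truth.focus_amplitude > 0:
        focus = 1.0 + bandlimited_noise(1, n_frames, fs, (0.05, 1.0), rng)[0] \
            * truth.focus_amplitude
    else:
        focus = np.ones(n_frames)
    bleach = np.exp(-t / truth.bleach_tau_s)

    baseline_img = np.full((n, n), truth.baseline_outside, dtype=np.float64)
    baseline_img[masks.window_mask] = truth.baseline
    baseline_img[masks.correction_roi] = truth.roi_baseline

    motion = (np.zeros((n_frames, 2), dtype=int) if truth.motion is None
              else np.asarray(truth.motion, dtype=int))
    if motion.shape != (n_frames, 2):
        raise ValueError(f"motion must have shape ({n_frames}, 2)")

    window = masks.window_mask
    neural = np.zeros((n_frames, n, n))
    neural[:, window] = global_trace[:, None]
    for name in names:
        neural[:, truth.region_masks[name]] += region_traces[name][:, None]
    movie = baseline_img[None] * (1.0 + neural) * (bleach * focus)[:, None, None]
    del neural
    for i in np.nonzero(motion.any(axis=1))[0]:
        movie[i] = _translate(movie[i].copy(),
                              int(motion[i, 0]), int(motion[i, 1]))
    if truth.noise_sd > 0:
        movie += rng.normal(0.0, truth.noise_sd, size=movie.shape)

    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        movie = np.clip(np.rint(movie), info.min, info.max)
    stack = FrameStack(movie.astype(dtype), frame_rate_hz=fs, source="synthetic")
    return SyntheticMovie(stack=stack, truth=truth, geom=geom, masks=masks,
                          region_traces=region_traces,
                          global_trace=global_trace, focus_trace=focus,
                          bleach=bleach, motion=motion, seed=seed)


def generate_gfp_control(truth: GroundTruth, geom: RigGeometry,
                         duration_s: float, seed: int,
                         masks: MaskSet | None = None,
                         dtype=np.float32) -> SyntheticMovie:
    """No-indicator control: same model with all neural amplitudes zeroed.

    Mirrors recordings from GFP-expressing mice, which carry the global,
    motion, bleaching and noise processes but no calcium-dependent regional
    or evoked signal.
    """
    null = GroundTruth(**{**truth.__dict__, "region_amp": 0.0, "evoked": []})
    return generate_movie(null, geom, duration_s, seed, masks=masks, dtype=dtype)
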