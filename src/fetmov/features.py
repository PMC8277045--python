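"""Time-frequency features: magnitude spectrograms, RGB rendering, NNMF.

Each 200-sample realization becomes a fixed 64 x 26 magnitude spectrogram
V (frequency rows x time columns): Hann window of length 126, hop 3,
one-sided FFT of length 126 (64 bins), with the input zero-padded to 201
samples so exactly 26 frames fit.  This is the unique simple configuration
producing the 64 x 26 classifier input without resampling.

V is non-negative, which makes it a valid input for non-negative matrix
factorization V ~= W H with W (64 x r) holding spectral basis vectors and
H (r x 26) their time activations ("abundance").  The factorization uses
the classical multiplicative updates for the Frobenius objective
||V - WH||_F^2, whose objective is non-increasing at every step; it serves
as a data-reduction stage before classification (variants feed W or H to
the classifier instead of the full V).

For the classifier, matrices are rendered as small RGB images: log
compression (log1p), per-image min-max normalization, then a fixed
256-entry monotone-luminance colour lookup table.  The table is generated
from a closed-form ramp so images are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Realization, WINDOW_LEN

__all__ = [
    "SPEC_SHAPE",
    "STFT_WINDOW",
    "STFT_HOP",
    "MagnitudeSpectrogram",
    "SpectrogramImage",
    "NNMFResult",
    "stft_magnitude",
    "render_rgb",
    "nnmf_factorize",
    "colour_lookup_table",
]

STFT_WINDOW = 126
STFT_HOP = 3
STFT_PADDED_LEN = 201
N_FREQ_BINS = STFT_WINDOW // 2 + 1          # 64
N_FRAMES = (STFT_PADDED_LEN - STFT_WINDOW) // STFT_HOP + 1  # 26
SPEC_SHAPE = (N_FREQ_BINS, N_FRAMES)


@dataclass
class MagnitudeSpectrogram:
    """Non-negative 64 x 26 magnitude matrix with bin/frame coordinates."""

    V: np.ndarray
    freq_hz: np.ndarray
    frame_idx: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.V.shape != SPEC_SHAPE:
            raise ValueError(f"spectrogram must be {SPEC_SHAPE}, got {self.V.shape}")
        if np.any(self.V < 0):
            raise ValueError("magnitude spectrogram must be non-negative")


@dataclass
class SpectrogramImage:
    """64 x 26 x 3 RGB rendering with all channels in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("channels must lie in [0, 1]")


@dataclass
class NNMFResult:
    """Factors of V ~= W H plus the convergence record."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    recon_error: float          # Frobenius norm of V - WH at the last iterate
    n_iter: int
    objective_trace: np.ndarray  # ||V - WH||_F^2 after each update sweep


def _hann_periodic(m: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(m) / m)


def stft_magnitude(realization: Realization | np.ndarray,
                   fs: float = 280.0) -> MagnitudeSpectrogram:
    """Magnitude spectrogram of one 200-sample realization.

    The realization is zero-padded by one sample to length 201; frames of
    length 126 start every 3 samples (26 frames); each frame is multiplied
    by a periodic Hann window and transformed with a one-sided FFT of
    length 126, keeping the 64 non-negative-frequency magnitude bins.
    """
    x = realization.samples if isinstance(realization, Realization) else np.asarray(
        realization, dtype=np.float64
    )
    if x.shape != (WINDOW_LEN,):
        raise ValueError(f"expected {WINDOW_LEN}-sample input, got {x.shape}")
    padded = np.zeros(STFT_PADDED_LEN)
    padded[:WINDOW_LEN] = x
    starts = np.arange(N_FRAMES) * STFT_HOP
    frames = np.stack([padded[s : s + STFT_WINDOW] for s in starts])
    win = _hann_periodic(STFT_WINDOW)
    V = np.abs(np.fft.rfft(frames * win, n=STFT_WINDOW, axis=1)).T  # 64 x 26
    freq_hz = np.fft.rfftfreq(STFT_WINDOW, d=1.0 / fs)
    return MagnitudeSpectrogram(V=V, freq_hz=freq_hz, frame_idx=starts)


def colour_lookup_table() -> np.ndarray:
    """The package's fixed 256 x 3 monotone-luminance colour table.

    A dark-blue to yellow ramp defined in closed form: R = t, G = t^0.8,
    B = 0.35 + 0.3t (t = i/255).  Luminance 0.2126R + 0.7152G + 0.0722B is
    strictly increasing in t, so brighter pixels always mean larger
    magnitudes.
    """
    t = np.arange(256) / 255.0
    lut = np.stack([t, t**0.8, 0.35 + 0.3 * t], axis=1)
    return np.clip(lut, 0.0, 1.0)


_LUT = colour_lookup_table()


RENDER_DYNAMIC_RANGE = 1000.0  # ~60 dB kept by the log compression


def render_matrix_rgb(mat: np.ndarray) -> SpectrogramImage:
    """Render a non-negative matrix: normalize -> log compress -> colour LUT.

    The matrix is first scaled to peak 1 (making the rendering exactly
    invariant to positive rescaling of the input), then log-compressed as
    log1p(1000 * x) / log1p(1000) to keep ~60 dB of dynamic range, then
    mapped through the fixed monotone colour table.
    """
    mat = np.asarray(mat, dtype=np.float64)
    if np.any(mat < 0):
        raise ValueError("matrix must be non-negative")
    peak = mat.max()
    if peak > 0 and mat.min() < peak:
        norm = np.log1p(RENDER_DYNAMIC_RANGE * (mat / peak))
        norm /= np.log1p(RENDER_DYNAMIC_RANGE)
    else:  # constant matrix -> all pixels map to the lowest LUT entry
        norm = np.zeros_like(mat)
    idx = np.minimum((norm * 255.0).round().astype(np.intp), 255)
    return SpectrogramImage(pixels=_LUT[idx])


def render_rgb(spec: MagnitudeSpectrogram) -> SpectrogramImage:
    """RGB image of a magnitude spectrogram (see :func:`render_matrix_rgb`)."""
    return render_matrix_rgb(spec.V)


def nnmf_factorize(
    spec: MagnitudeSpectrogram | np.ndarray,
    rank: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> NNMFResult:
    """Non-negative matrix factorization V ~= WH by multiplicative updates.

    Minimizes ||V - WH||_F^2 from a seeded non-negative random start.
    Iteration stops when the relative objective decrease falls below
    ``tol`` or after ``max_iter`` sweeps; the objective after every sweep
    is recorded and is non-increasing.
    """
    V = spec.V if isinstance(spec, MagnitudeSpectrogram) else np.asarray(
        spec, dtype=np.float64
    )
    if np.any(V < 0):
        raise ValueError("NNMF input must be non-negative")
    m, n = V.shape
    if not (1 <= rank <= min(m, n)):
        raise ValueError(f"rank must lie in [1, {min(m, n)}], got {rank}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / rank)
    W = scale * rng.random((m, rank))
    H = scale * rng.random((rank, n))
    eps = 1e-12
    trace = []
    prev = np.linalg.norm(V - W @ H) ** 2
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        obj = float(np.linalg.norm(V - W @ H) ** 2)
        trace.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            prev = obj
            break
        prev = obj
    return NNMFResult(
        W=W,
        H=H,
        rank=rank,
        recon_error=float(np.linalg.norm(V - W @ H)),
        n_iter=n_iter,
        objective_trace=np.asarray(trace),
    )
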