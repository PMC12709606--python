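"""B-mode and short-lag spatial coherence (SLSC) image formation.

B-mode maps each pixel to the envelope of the delay-and-sum (DAS) beam
sum, i.e. to echo *amplitude*. SLSC instead maps each pixel to the sum
of normalized inter-element correlations over the first ``M`` lags of
the receive aperture, i.e. to echo *spatial coherence*:

    R_hat(m) = 1/(N-m) * sum_i  <s_i, s_{i+m}> / sqrt(<s_i, s_i><s_{i+m}, s_{i+m}>)
    SLSC(pixel) = sum_{m=1..M} R_hat(m)

with the inner products taken over a short axial kernel centred at the
pixel. Diffuse scattering decorrelates across the aperture (triangular
van Cittert-Zernike decay), fluid filled with incoherent clutter
decorrelates much faster, so coherent tissue appears bright and fluid
dark regardless of echo amplitude. Negative coherence values are
truncated to zero after the lag sum, and the image is kept on the full
linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import imageio.v3 as iio
import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .acquisition import ChannelData
from .geometry import ArrayGeometry

__all__ = [
    "SLSCParams",
    "UltrasoundImage",
    "AlignedChannelData",
    "apply_receive_delays",
    "das_bmode",
    "log_compress",
    "spatial_coherence",
    "slsc_image",
    "save_image_h5",
    "load_image_h5",
    "save_image_png",
]

#: Axial decimation from the RF sampling grid to image pixels.
DEFAULT_DECIMATION = 4


@dataclass(frozen=True)
class SLSCParams:
    """Parameters of the short-lag coherence sum.

    ``M`` is the short-lag cutoff (7 by default, 10% of a 64-element
    receive aperture). ``kernel_samples`` is the axial correlation
    kernel length in RF samples; ``None`` selects one wavelength of
    round-trip depth (``2 * sampling_freq / center_freq`` samples).
    ``truncate_negative`` zeroes negative values after the lag sum;
    ``per_lag_truncate`` instead truncates each R_hat(m) before summing.
    ``normalize_by_M`` rescales pixel values from [0, M] to [0, 1].
    """

    M: int = 7
    kernel_samples: int | None = None
    truncate_negative: bool = True
    normalize_by_M: bool = False
    per_lag_truncate: bool = False

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.kernel_samples is not None and self.kernel_samples < 1:
            raise ValueError("kernel_samples must be >= 1")

    def resolve_kernel(self, geometry: ArrayGeometry) -> int:
        if self.kernel_samples is not None:
            return self.kernel_samples
        return max(1, int(round(2.0 * geometry.sampling_freq / geometry.center_freq)))


@dataclass(frozen=True)
class UltrasoundImage:
    """Pixel grid of B-mode or SLSC values.

    ``values`` is an ``(n_axial, n_lateral)`` array with depth
    increasing along axis 0. ``kind`` is one of ``bmode_linear``,
    ``bmode_log`` or ``slsc``.
    """

    values: np.ndarray
    kind: str
    axial_spacing: float
    lateral_spacing: float
    depth_offset: float
    dynamic_range_db: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (axial, lateral)")
        if self.kind not in ("bmode_linear", "bmode_log", "slsc"):
            raise ValueError(f"unknown image kind {self.kind!r}")
        if self.kind == "bmode_linear" and v.size and v.min() < -1e-9:
            raise ValueError("bmode_linear image values must be non-negative")
        object.__setattr__(self, "values", v)

    def pixel_depths(self) -> np.ndarray:
        return self.depth_offset + np.arange(self.values.shape[0]) * self.axial_spacing


@dataclass(frozen=True)
class AlignedChannelData:
    """Dynamic-receive-focused aperture signals.

    ``data`` has shape ``(n_lines, n_elements, n_depths)``: for every
    scan line and axial depth, the per-element signals after removal of
    the geometric round-trip delay, so that an on-axis echo from that
    depth appears at lag zero in every element.
    """

    data: np.ndarray
    depths: np.ndarray
    line_positions: np.ndarray
    geometry: ArrayGeometry

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]


def apply_receive_delays(
    channel_data: ChannelData,
    depth_range: tuple[float, float],
) -> AlignedChannelData:
    """Dynamic receive focusing of the channel data onto a pixel grid.

    The axial grid spans ``depth_range`` at the RF-rate depth increment
    ``c / (2 * fs)``. For element ``i`` at lateral offset ``u_i`` from
    the beam axis, the signal contributing to depth ``z`` is read at
    time ``(z + sqrt(u_i^2 + z^2)) / c`` with linear interpolation
    between RF samples; times outside the record yield zeros.
    """
    geom = channel_data.geometry
    c = geom.sound_speed
    fs = geom.sampling_freq
    z0, z1 = depth_range
    if z0 <= 0:
        raise ValueError("pixel depths must be positive")
    dz = geom.rf_sample_depth()
    depths = np.arange(z0, z1, dz)
    if depths.size == 0:
        raise ValueError("empty depth range")

    offsets = geom.element_offsets()
    # Delay (in fractional samples) per element per depth; identical for
    # every line because the aperture translates with the beam.
    t = (depths[None, :] + np.sqrt(offsets[:, None] ** 2 + depths[None, :] ** 2)) / c
    sample_pos = t * fs

    n_time = channel_data.n_time
    if sample_pos.max() > n_time - 1:
        warnings.warn(
            "some pixels lie beyond the recorded time window; their samples are zero",
            stacklevel=2,
        )

    grid = np.arange(n_time, dtype=float)
    out = np.zeros((channel_data.n_lines, geom.n_elements, depths.size))
    for k in range(channel_data.n_lines):
        rf = channel_data.samples[k]
        for i in range(geom.n_elements):
            out[k, i] = np.interp(sample_pos[i], grid, rf[i], left=0.0, right=0.0)
    return AlignedChannelData(
        data=out,
        depths=depths,
        line_positions=channel_data.line_positions,
        geometry=geom,
    )


def _pixel_index(n_depths: int, decimation: int) -> np.ndarray:
    return np.arange(0, n_depths, decimation)


def das_bmode(
    aligned: AlignedChannelData,
    decimation: int = DEFAULT_DECIMATION,
) -> UltrasoundImage:
    """Delay-and-sum B-mode image (linear envelope, uniform apodization).

    The aligned element signals are summed across the aperture, the
    envelope is taken as the magnitude of the axial analytic signal, and
    the result is decimated onto the image pixel grid.
    """
    beam_sum = aligned.data.sum(axis=1)  # (n_lines, n_depths)
    env = np.abs(hilbert(beam_sum, axis=1))
    idx = _pixel_index(aligned.depths.size, decimation)
    values = env[:, idx].T  # (axial, lateral)
    lat = _lateral_spacing(aligned.line_positions)
    return UltrasoundImage(
        values=values,
        kind="bmode_linear",
        axial_spacing=decimation * aligned.geometry.rf_sample_depth(),
        lateral_spacing=lat,
        depth_offset=float(aligned.depths[0]),
    )


def _lateral_spacing(line_positions: np.ndarray) -> float:
    if line_positions.size < 2:
        return 0.0
    diffs = np.diff(line_positions)
    if not np.allclose(diffs, diffs[0]):
        raise ValueError("image formation requires uniformly spaced scan lines")
    return float(diffs[0])


def log_compress(image: UltrasoundImage, dynamic_range_db: float = 60.0) -> UltrasoundImage:
    """Log-compress a linear B-mode image for display.

    The maximum maps to 0 dB and values are clipped at
    ``-dynamic_range_db``.
    """
    if image.kind != "bmode_linear":
        raise ValueError("log_compress expects a bmode_linear image")
    vmax = image.values.max()
    if vmax <= 0:
        raise ValueError("cannot log-compress an all-zero image")
    floor = vmax * 10.0 ** (-dynamic_range_db / 20.0)
    db = 20.0 * np.log10(np.maximum(image.values, floor) / vmax)
    return UltrasoundImage(
        values=db,
        kind="bmode_log",
        axial_spacing=image.axial_spacing,
        lateral_spacing=image.lateral_spacing,
        depth_offset=image.depth_offset,
        dynamic_range_db=dynamic_range_db,
    )


def _coherence_line(signals: np.ndarray, m: int, kernel: int) -> np.ndarray:
    """R_hat(m) along one line; ``signals`` is (n_elements, n_t)."""
    n_el = signals.shape[0]
    energy = uniform_filter1d(signals**2, size=kernel, axis=1, mode="constant") * kernel
    num = np.zeros(signals.shape[1])
    count = np.zeros(signals.shape[1])
    for i in range(n_el - m):
        cross = (
            uniform_filter1d(signals[i] * signals[i + m], size=kernel, mode="constant") * kernel
        )
        denom = energy[i] * energy[i + m]
        valid = denom > 0
        r = np.zeros_like(cross)
        r[valid] = cross[valid] / np.sqrt(denom[valid])
        num += r
        count += valid
    out = np.zeros_like(num)
    nz = count > 0
    out[nz] = num[nz] / count[nz]
    return np.clip(out, -1.0, 1.0)


def spatial_coherence(signals: np.ndarray, m: int, kernel_samples: int) -> np.ndarray:
    """Normalized spatial correlation at lag ``m``.

    Parameters
    ----------
    signals:
        Aligned aperture signals, shape ``(n_elements, n_t)``. With
        ``n_t == kernel_samples`` this evaluates a single pixel.
    m:
        Element lag, ``1 <= m <= n_elements - 1``.
    kernel_samples:
        Axial kernel length (centred moving window).

    Returns
    -------
    ndarray of R_hat(m) per time sample, in [-1, 1]. Element pairs with
    a zero-energy member are skipped and the averaging denominator
    reduced; if every pair is degenerate the value is 0.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be (n_elements, n_t)")
    n_el = signals.shape[0]
    if not 1 <= m <= n_el - 1:
        raise ValueError(f"lag m must satisfy 1 <= m <= {n_el - 1}, got {m}")
    return _coherence_line(signals, m, kernel_samples)


def slsc_image(
    aligned: AlignedChannelData,
    params: SLSCParams = SLSCParams(),
    decimation: int = DEFAULT_DECIMATION,
) -> UltrasoundImage:
    """Short-lag spatial coherence image: pixel = sum_{m<=M} R_hat(m)."""
    n_el = aligned.geometry.n_elements
    if params.M >= n_el:
        raise ValueError(f"M ({params.M}) must be < n_elements ({n_el})")
    kernel = params.resolve_kernel(aligned.geometry)
    idx = _pixel_index(aligned.depths.size, decimation)
    values = np.zeros((idx.size, aligned.n_lines))
    for k in range(aligned.n_lines):
        total = np.zeros(aligned.depths.size)
        for m in range(1, params.M + 1):
            r = _coherence_line(aligned.data[k], m, kernel)
            if params.per_lag_truncate:
                r = np.maximum(r, 0.0)
            total += r
        values[:, k] = total[idx]
    if params.truncate_negative:
        values = np.maximum(values, 0.0)
    if params.normalize_by_M:
        values = values / params.M
    return UltrasoundImage(
        values=values,
        kind="slsc",
        axial_spacing=decimation * aligned.geometry.rf_sample_depth(),
        lateral_spacing=_lateral_spacing(aligned.line_positions),
        depth_offset=float(aligned.depths[0]),
    )


def save_image_h5(image: UltrasoundImage, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=image.values)
        f.attrs["kind"] = image.kind
        f.attrs["axial_spacing"] = image.axial_spacing
        f.attrs["lateral_spacing"] = image.lateral_spacing
        f.attrs["depth_offset"] = image.depth_offset
        if image.dynamic_range_db is not None:
            f.attrs["dynamic_range_db"] = image.dynamic_range_db


def load_image_h5(path) -> UltrasoundImage:
    with h5py.File(path, "r") as f:
        dr = f.attrs.get("dynamic_range_db")
        return UltrasoundImage(
            values=f["values"][()],
            kind=str(f.attrs["kind"]),
            axial_spacing=float(f.attrs["axial_spacing"]),
            lateral_spacing=float(f.attrs["lateral_spacing"]),
            depth_offset=float(f.attrs["depth_offset"]),
            dynamic_range_db=None if dr is None else float(dr),
        )


def save_image_png(image: UltrasoundImage, path, dynamic_range_db: float = 60.0) -> None:
    """8-bit PNG export: log-compressed B-mode, or SLSC on [0, 1]."""
    if image.kind == "bmode_linear":
        image = log_compress(image, dynamic_range_db)
    if image.kind == "bmode_log":
        dr = image.dynamic_range_db or dynamic_range_db
        scaled = (image.values + dr) / dr
    else:  # slsc
        top = image.values.max()
        scaled = image.values / top if top > 0 else image.values
    arr = np.clip(scaled * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
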