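"""Focused RF channel-data simulation for linear-array imaging.

The model is single-scattering and attenuation-free. For each scan line
the transmit beam is an idealized diffraction-limited focused beam: its
arrival time at a scatterer is the on-axis depth divided by the sound
speed, and its lateral amplitude profile is the far-field pattern of the
uniform transmit aperture, ``sinc(D * dx / (lambda * z))`` (constant
f-number). Each receive element then records a Gaussian-windowed tone at
the centre frequency, delayed by the transmit path plus its own
geometric receive path and weighted by spherical spreading ``1/r``.

This is deliberately simpler than a full acoustic field simulation, but
it preserves the two properties that matter for coherence imaging: the
round-trip delays are geometrically exact (so dynamic receive focusing
aligns echoes correctly), and diffuse scattering produces the triangular
van Cittert-Zernike decay of spatial coherence across the receive
aperture.

Acoustic clutter is injected per lesion directly into the channel
signals as band-limited noise that is a mixture of an element-correlated
(shared) component and an element-independent component, gated to the
time samples whose round-trip depth falls inside the lesion. Purely
independent noise would be fully incoherent and make coherence imaging
trivially perfect; the shared component is what lets clutter partially
survive in coherence images, as it does in vivo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit
from scipy.signal import fftconvolve

from .geometry import ArrayGeometry
from .phantom import Phantom

__all__ = [
    "ChannelData",
    "simulate_channel_data",
    "save_channel_data",
    "load_channel_data",
]

_PULSE_OVERSAMPLE = 16


@dataclass(frozen=True)
class ChannelData:
    """Focused per-line RF receive signals.

    ``samples`` has shape ``(n_lines, n_elements, n_time)``; sample ``n``
    of every trace corresponds to absolute time ``n / sampling_freq``
    after transmit. ``line_positions`` are the lateral beam origins in
    metres; the active aperture is centred on each line.
    """

    samples: np.ndarray
    line_positions: np.ndarray
    geometry: ArrayGeometry
    rng_seed: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        lp = np.asarray(self.line_positions, dtype=float)
        if s.ndim != 3:
            raise ValueError("samples must have shape (n_lines, n_elements, n_time)")
        if s.shape[0] != lp.size:
            raise ValueError("one line position per scan line required")
        if s.shape[1] != self.geometry.n_elements:
            raise ValueError("samples second axis must match geometry.n_elements")
        if not np.all(np.isfinite(s)):
            raise ValueError("channel data must be finite")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "line_positions", lp)

    @property
    def n_lines(self) -> int:
        return self.samples.shape[0]

    @property
    def n_time(self) -> int:
        return self.samples.shape[2]


def _pulse_table(pulse_cycles: float, geometry: ArrayGeometry) -> tuple[np.ndarray, int, float]:
    """Tabulated Gaussian-windowed tone for fast deposition.

    Returns ``(table, half_width_samples, half_width_seconds)``; the
    table spans ``+-half_width_seconds`` at ``_PULSE_OVERSAMPLE`` times
    the RF rate. The envelope FWHM equals ``pulse_cycles`` periods of
    the centre frequency.
    """
    f0 = geometry.center_freq
    fs = geometry.sampling_freq
    sigma = pulse_cycles / (2.355 * f0)
    half_w = int(math.ceil(3.0 * sigma * fs))
    t_half = half_w / fs
    n_tab = 2 * half_w * _PULSE_OVERSAMPLE + 1
    t = np.linspace(-t_half, t_half, n_tab)
    tab = np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(2.0 * np.pi * f0 * t)
    return tab, half_w, t_half


@njit(cache=True, fastmath=True)
def _deposit_line(rf, xs, zs, amps, elem_x, c, fs, tab, t_half, half_w):  # pragma: no cover
    os_rate = (tab.size - 1) / (2.0 * t_half)
    n_time = rf.shape[1]
    for s in range(xs.size):
        a = amps[s]
        if a == 0.0:
            continue
        z = zs[s]
        t_tx = z / c
        for i in range(elem_x.size):
            dx = xs[s] - elem_x[i]
            d = math.sqrt(dx * dx + z * z)
            t0 = t_tx + d / c
            ai = a / d
            n_center = t0 * fs
            n0 = int(math.ceil(n_center)) - half_w
            n1 = int(math.floor(n_center)) + half_w
            if n0 < 0:
                n0 = 0
            if n1 >= n_time:
                n1 = n_time - 1
            for n in range(n0, n1 + 1):
                dt = n / fs - t0
                j = int((dt + t_half) * os_rate + 0.5)
                if j < 0:
                    j = 0
                elif j >= tab.size:
                    j = tab.size - 1
                rf[i, n] += ai * tab[j]


def _bandpass_noise(rng: np.random.Generator, shape: tuple[int, ...], kernel: np.ndarray) -> np.ndarray:
    """White Gaussian noise filtered to the pulse band, unit variance."""
    pad = kernel.size
    padded = list(shape)
    padded[-1] += 2 * pad
    x = rng.standard_normal(tuple(padded))
    y = fftconvolve(x, kernel.reshape((1,) * (len(shape) - 1) + (-1,)), mode="same", axes=-1)
    return y[..., pad:-pad]


def simulate_channel_data(
    phantom: Phantom,
    geometry: ArrayGeometry,
    line_positions: np.ndarray,
    pulse_cycles: float = 2.0,
    seed: int = 0,
    correlated_fraction: float = 0.5,
    n_sidelobes: float = 4.0,
) -> ChannelData:
    """Simulate focused RF channel data for every scan line.

    Parameters
    ----------
    phantom:
        Scatterer cloud with lesion specifications.
    geometry:
        Array geometry; the active aperture translates with each line.
    line_positions:
        Lateral beam origins in metres, within the phantom extent.
    pulse_cycles:
        Envelope FWHM of the transmit pulse in periods of the centre
        frequency.
    seed:
        Seed for the clutter noise draws. The scatterer contribution is
        fully deterministic given the phantom.
    correlated_fraction:
        Fraction (by variance) of the injected clutter that is shared
        across elements; the remainder is element-independent.
    n_sidelobes:
        Lateral truncation of the transmit beam in sinc lobes. Scatterers
        beyond this off-axis distance contribute negligibly and are
        skipped for speed.

    Notes
    -----
    Clutter amplitude is expressed relative to the RMS of the clean
    (scatterer-only) channel signals over the insonified time gate, so
    ``clutter_level=1`` injects noise as strong as the average background
    speckle channel signal.
    """
    line_positions = np.atleast_1d(np.asarray(line_positions, dtype=float))
    (x0, x1), (z0, z1) = phantom.extent
    if line_positions.min() < x0 or line_positions.max() > x1:
        raise ValueError("line positions must lie within the phantom lateral extent")
    if not (0.0 <= correlated_fraction <= 1.0):
        raise ValueError("correlated_fraction must be in [0, 1]")
    if phantom.n_scatterers and phantom.positions[:, 1].min() <= 0:
        raise ValueError("scatterers must lie in front of the array (axial > 0)")

    c = geometry.sound_speed
    fs = geometry.sampling_freq
    lam = geometry.wavelength
    aperture = geometry.aperture_width
    offsets = geometry.element_offsets()

    tab, half_w, t_half = _pulse_table(pulse_cycles, geometry)

    # Time record long enough for the farthest scatterer seen by the
    # farthest element of any line.
    dx_max = max(abs(x0 - line_positions.min()), abs(x1 - line_positions.max())) + aperture / 2.0
    t_max = (z1 + math.hypot(dx_max, z1)) / c + 2.0 * t_half
    n_time = int(math.ceil(t_max * fs)) + 1

    n_lines = line_positions.size
    rf = np.zeros((n_lines, geometry.n_elements, n_time))

    xs = np.ascontiguousarray(phantom.positions[:, 0]) if phantom.n_scatterers else np.empty(0)
    zs = np.ascontiguousarray(phantom.positions[:, 1]) if phantom.n_scatterers else np.empty(0)
    amps = np.ascontiguousarray(phantom.amplitudes)

    for k, xl in enumerate(line_positions):
        if phantom.n_scatterers == 0:
            continue
        dx = xs - xl
        # Idealized focused transmit beam: sinc lateral field profile,
        # truncated beyond n_sidelobes lobes.
        u = aperture * dx / (lam * zs)
        keep = np.abs(u) <= n_sidelobes
        if not np.any(keep):
            continue
        a_eff = amps[keep] * np.sinc(u[keep])
        _deposit_line(
            rf[k],
            np.ascontiguousarray(xs[keep]),
            np.ascontiguousarray(zs[keep]),
            np.ascontiguousarray(a_eff),
            xl + offsets,
            c,
            fs,
            tab,
            t_half,
            half_w,
        )

    # Reference amplitude for clutter scaling: RMS of the clean signals
    # over the insonified round-trip time gate.
    n_lo = int((2.0 * z0 / c) * fs)
    n_hi = min(n_time, int(math.ceil((2.0 * z1 / c) * fs)) + 2 * half_w)
    gate = rf[:, :, n_lo:n_hi]
    sigma_ref = float(np.sqrt(np.mean(gate**2))) if gate.size else 0.0
    if sigma_ref == 0.0:
        sigma_ref = 1.0

    cluttered = [les for les in phantom.lesions if les.clutter_level > 0]
    if cluttered:
        rng = np.random.default_rng(seed)
        kernel = _pulse_table(pulse_cycles, geometry)[0][:: _PULSE_OVERSAMPLE].copy()
        kernel /= math.sqrt(float(np.sum(kernel**2)))  # unit noise gain
        f_sh = math.sqrt(correlated_fraction)
        f_ind = math.sqrt(1.0 - correlated_fraction)
        for k, xl in enumerate(line_positions):
            for les in cluttered:
                dxl = xl - les.center[0]
                if abs(dxl) > les.radius:
                    continue
                half_chord = math.sqrt(les.radius**2 - dxl**2)
                # Gate: samples whose round-trip depth c*t/2 is inside the lesion.
                g0 = max(0, int(math.floor((2.0 * (les.center[1] - half_chord) / c) * fs)))
                g1 = min(n_time, int(math.ceil((2.0 * (les.center[1] + half_chord) / c) * fs)))
                if g1 <= g0:
                    continue
                length = g1 - g0
                shared = _bandpass_noise(rng, (length,), kernel)
                indep = _bandpass_noise(rng, (geometry.n_elements, length), kernel)
                noise = les.clutter_level * sigma_ref * (f_sh * shared[None, :] + f_ind * indep)
                rf[k][:, g0:g1] += noise

    return ChannelData(samples=rf, line_positions=line_positions, geometry=geometry, rng_seed=seed)


def save_channel_data(cd: ChannelData, path) -> None:
    """Write channel data to HDF5 (datasets ``/lines/<k>/rf``)."""
    with h5py.File(path, "w") as f:
        lines = f.create_group("lines")
        for k in range(cd.n_lines):
            lines.create_dataset(f"{k}/rf", data=cd.samples[k])
        f.create_dataset("line_positions", data=cd.line_positions)
        f.attrs["rng_seed"] = cd.rng_seed
        for name in (
            "n_elements",
            "pitch",
            "center_freq",
            "sampling_freq",
            "sound_speed",
            "transmit_focus_depth",
        ):
            f.attrs[name] = getattr(cd.geometry, name)


def load_channel_data(path) -> ChannelData:
    """Read channel data written by :func:`save_channel_data`."""
    with h5py.File(path, "r") as f:
        geometry = ArrayGeometry(
            n_elements=int(f.attrs["n_elements"]),
            pitch=float(f.attrs["pitch"]),
            center_freq=float(f.attrs["center_freq"]),
            sampling_freq=float(f.attrs["sampling_freq"]),
            sound_speed=float(f.attrs["sound_speed"]),
            transmit_focus_depth=float(f.attrs["transmit_focus_depth"]),
        )
        line_positions = f["line_positions"][()]
        keys = sorted(f["lines"].keys(), key=int)
        samples = np.stack([f["lines"][k]["rf"][()] for k in keys])
        return ChannelData(
            samples=samples,
            line_positions=line_positions,
            geometry=geometry,
            rng_seed=int(f.attrs["rng_seed"]),
        )
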