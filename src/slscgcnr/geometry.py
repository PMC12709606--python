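"""Linear-array acquisition geometry.

All distances are in metres, frequencies in Hz, times in seconds. The
default values describe a 64-element active receive aperture of a
high-frequency linear probe of the class used for breast imaging
(0.3 mm pitch, 8 MHz centre frequency, 40 MHz RF sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArrayGeometry"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Receive-aperture geometry of a linear transducer array.

    Parameters
    ----------
    n_elements:
        Number of active receive elements ``N``.
    pitch:
        Element centre-to-centre spacing in metres.
    center_freq:
        Transmit centre frequency in Hz.
    sampling_freq:
        RF sampling rate in Hz; must exceed the Nyquist rate of the
        centre frequency.
    sound_speed:
        Assumed homogeneous speed of sound in m/s.
    transmit_focus_depth:
        Axial depth of the fixed per-line transmit focus in metres.
    """

    n_elements: int = 64
    pitch: float = 0.3e-3
    center_freq: float = 8e6
    sampling_freq: float = 40e6
    sound_speed: float = 1540.0
    transmit_focus_depth: float = 20e-3

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if self.sampling_freq <= 2.0 * self.center_freq:
            raise ValueError("sampling_freq must exceed 2 * center_freq")
        if self.transmit_focus_depth <= 0:
            raise ValueError("transmit_focus_depth must be positive")

    @property
    def wavelength(self) -> float:
        """Acoustic wavelength at the centre frequency, metres."""
        return self.sound_speed / self.center_freq

    @property
    def aperture_width(self) -> float:
        """Active aperture width ``N * pitch``, metres."""
        return self.n_elements * self.pitch

    def element_offsets(self) -> np.ndarray:
        """Lateral element positions relative to the aperture centre."""
        idx = np.arange(self.n_elements, dtype=float)
        return (idx - (self.n_elements - 1) / 2.0) * self.pitch

    def rf_sample_depth(self) -> float:
        """Depth increment per RF sample for round-trip propagation."""
        return self.sound_speed / (2.0 * self.sampling_freq)
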