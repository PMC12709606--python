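"""Point-scatterer phantoms with circular fluid or solid lesions.

A phantom is a cloud of sub-resolution scatterers whose interference
produces fully developed speckle once beamformed. Lesions are circular
regions that rescale scatterer amplitudes: a fluid lesion (echogenicity
0) is anechoic, a solid lesion keeps tissue-like scattering at reduced
amplitude. Acoustic clutter, which is what makes complicated cysts mimic
hypoechoic solid masses, is injected later at the channel-data level and
is parameterised here per lesion via ``clutter_level``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LesionSpec", "Phantom", "make_phantom", "MIN_LESION_DEPTH"]

#: Shallow masses closer than this to the transducer face cannot be
#: focused properly and are excluded from coherence imaging.
MIN_LESION_DEPTH = 5e-3


@dataclass(frozen=True)
class LesionSpec:
    """One circular lesion inside a phantom.

    Parameters
    ----------
    center:
        ``(lateral, axial)`` centre position in metres.
    radius:
        Lesion radius in metres.
    content:
        ``"fluid"`` or ``"solid"``.
    echogenicity:
        Scatterer-amplitude scale relative to the background
        (0 for anechoic fluid, a value in (0, 1] for solid tissue).
    clutter_level:
        Amplitude of partially element-correlated noise injected into
        the channel data inside the lesion, relative to the RMS of the
        background speckle channel signals.
    """

    center: tuple[float, float]
    radius: float
    content: str = "fluid"
    echogenicity: float = 0.0
    clutter_level: float = 0.0

    def __post_init__(self) -> None:
        if self.content not in ("fluid", "solid"):
            raise ValueError(f"content must be 'fluid' or 'solid', got {self.content!r}")
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")
        if self.echogenicity < 0:
            raise ValueError("echogenicity must be >= 0")
        if self.clutter_level < 0:
            raise ValueError("clutter_level must be >= 0")
        if self.center[1] < MIN_LESION_DEPTH:
            raise ValueError(
                f"lesion axial centre {self.center[1] * 1e3:.1f} mm is shallower than "
                f"{MIN_LESION_DEPTH * 1e3:.0f} mm; superficial masses cannot be focused"
            )

    def contains(self, lateral: np.ndarray, axial: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the lesion."""
        dx = np.asarray(lateral) - self.center[0]
        dz = np.asarray(axial) - self.center[1]
        return dx * dx + dz * dz <= self.radius * self.radius


@dataclass(frozen=True)
class Phantom:
    """Scatterer cloud with optional lesions.

    ``positions`` is an ``(n, 2)`` array of ``(lateral, axial)``
    coordinates in metres; ``amplitudes`` the matching real scattering
    amplitudes. ``extent`` is ``((x_min, x_max), (z_min, z_max))``.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    lesions: tuple[LesionSpec, ...]
    extent: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if amp.shape != (pos.shape[0],):
            raise ValueError("amplitudes must match positions")
        (x0, x1), (z0, z1) = self.extent
        if pos.size:
            if pos[:, 0].min() < x0 or pos[:, 0].max() > x1:
                raise ValueError("scatterer lateral position outside extent")
            if pos[:, 1].min() < z0 or pos[:, 1].max() > z1:
                raise ValueError("scatterer axial position outside extent")
            if pos[:, 1].min() <= 0:
                raise ValueError("scatterer axial positions must be > 0 (in front of the array)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]


def make_phantom(
    extent: tuple[tuple[float, float], tuple[float, float]],
    scatterer_density: float,
    lesions: list[LesionSpec] | tuple[LesionSpec, ...] = (),
    seed: int = 0,
) -> Phantom:
    """Draw a random speckle phantom.

    Parameters
    ----------
    extent:
        ``((x_min, x_max), (z_min, z_max))`` bounds in metres;
        ``z_min`` must be positive.
    scatterer_density:
        Expected scatterer count per square metre (e.g. ``5e6`` for
        5 scatterers per mm^2). The realised count is the rounded
        product of density and area.
    lesions:
        Lesion specifications; each must lie fully inside the extent.
    seed:
        RNG seed; the phantom is a pure function of its arguments.
    """
    (x0, x1), (z0, z1) = extent
    if x1 <= x0 or z1 <= z0:
        raise ValueError("extent bounds must be increasing")
    if z0 <= 0:
        raise ValueError("axial extent must start in front of the array (z_min > 0)")
    if scatterer_density <= 0:
        raise ValueError("scatterer_density must be positive")
    for k, lesion in enumerate(lesions):
        cx, cz = lesion.center
        r = lesion.radius
        if not (x0 <= cx - r and cx + r <= x1 and z0 <= cz - r and cz + r <= z1):
            raise ValueError(
                f"lesion {k} ({lesion.content}, centre {cx * 1e3:.1f}, {cz * 1e3:.1f} mm, "
                f"radius {r * 1e3:.1f} mm) does not fit inside the phantom extent"
            )

    area = (x1 - x0) * (z1 - z0)
    n = int(round(scatterer_density * area))
    rng = np.random.default_rng(seed)
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(x0, x1, n)
    pos[:, 1] = rng.uniform(z0, z1, n)
    amp = rng.standard_normal(n)
    for lesion in lesions:
        inside = lesion.contains(pos[:, 0], pos[:, 1])
        amp[inside] *= lesion.echogenicity
    return Phantom(positions=pos, amplitudes=amp, lesions=tuple(lesions), extent=extent)
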