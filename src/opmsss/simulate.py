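"""Synthetic triaxial helmet arrays, dipole sources and recordings.

The generator emulates the study conditions used throughout the package:
a 64-slot triaxial magnetometer helmet (192 channels) on a spherical cap,
internal sources drawn in a thin shell 5-50 mm from the shell centre
(toy stand-in for brain sources), and external interference sources drawn
2-3 m away.  Sources drive sinusoids at distinct integer frequencies, and
white Gaussian sensor noise of 30 fT (one standard deviation per sample)
is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Sequence

import numpy as np

from .exceptions import SingularPointError
from .sss_basis import SensorArray

__all__ = [
    "MU0_OVER_4PI",
    "DipoleSource",
    "Recording",
    "make_helmet_array",
    "sample_shell_dipoles",
    "dipole_field",
    "simulate_recording",
    "white_noise_vectors",
]

MU0_OVER_4PI = 1e-7  # T m / (A m^2)

#: Shell centre shared by the source shells and the helmet centre of mass (m).
SHELL_CENTRE = np.array([0.0, 0.0, 0.02])

#: Radial bounds of the internal (brain-side) and external source shells (m).
INTERNAL_SHELL = (0.005, 0.05)
EXTERNAL_SHELL = (2.0, 3.0)

#: Default dipole moment magnitudes (A m^2): weak internal, strong distal
#: interference.
INTERNAL_MOMENT = 10e-9
EXTERNAL_MOMENT = 10e-3

#: Minimum sensor distance from the internal shell surface (m), used to
#: calibrate the helmet radius.
SENSOR_STANDOFF = 0.0215


@dataclass(frozen=True)
class DipoleSource:
    """Point magnetic dipole driven sinusoidally."""

    position: np.ndarray  # (3,) metres
    moment: np.ndarray  # (3,) A m^2
    frequency: int  # Hz, in [1, 100]
    kind: Literal["internal", "external"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float).reshape(3))
        if not 1 <= self.frequency <= 100:
            raise ValueError(f"frequency must be an integer in [1, 100], got {self.frequency}")
        if self.kind not in ("internal", "external"):
            raise ValueError(f"kind must be 'internal' or 'external', got {self.kind!r}")


@dataclass
class Recording:
    """Channels x samples field matrix in tesla, with optional ground truth.

    When ground truths are present, ``data`` equals
    ``ground_truth_in + ground_truth_out + noise`` exactly by construction.
    """

    data: np.ndarray  # (N, T) tesla
    fs: float  # Hz
    ground_truth_in: np.ndarray | None = None
    ground_truth_out: np.ndarray | None = None
    labels: List[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def data_fT(self) -> np.ndarray:
        """Convenience view of the data in femtotesla."""
        return self.data * 1e15

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _fibonacci_cap(n: int, half_angle: float, phase: float) -> np.ndarray:
    """Quasi-uniform unit vectors on a spherical cap of the given half-angle
    about +z (Fibonacci lattice; ``phase`` rotates the lattice azimuthally)."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    i = np.arange(n)
    # equal-area spacing in cos(theta) from the pole down to the cap edge
    ct = 1.0 - (1.0 - math.cos(half_angle)) * (i + 0.5) / n
    st = np.sqrt(1.0 - ct**2)
    az = golden * i + phase
    return np.stack([st * np.cos(az), st * np.sin(az), ct], axis=1)


def make_helmet_array(
    n_sensors: int = 64,
    radius: float | None = None,
    coverage: float = math.radians(100.0),
    seed: int | None = 0,
) -> SensorArray:
    """Synthetic triaxial helmet: ``n_sensors`` slots, 3 channels each.

    Sensors sit on a spherical cap (half-angle ``coverage``) and each
    contributes a radial channel plus two tangential channels, so the
    default array has 192 channels.  The whole array is translated so the
    centre of mass of the sensor positions is the shell centre
    (0, 0, 0.02) m.  When ``radius`` is None it is calibrated so the
    closest sensor lies ``SENSOR_STANDOFF`` (21.5 mm) outside the internal
    source shell surface.  The default coverage half-angle (100 degrees) is
    calibrated so the array reproduces the ~60 degree mean principal angle
    between the internal and external basis subspaces that characterises
    whole-head triaxial helmets; together with the standoff calibration
    this pins the geometry to the two published diagnostics available for
    such arrays.

    ``seed`` only rotates the Fibonacci lattice azimuthally; geometry is
    otherwise deterministic.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors for a sensible helmet")
    phase = 0.0
    if seed is not None:
        phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * math.pi))
    unit = _fibonacci_cap(n_sensors, coverage, phase)
    com_unit = unit.mean(axis=0)
    # distance of each lattice point from the lattice centre of mass, per
    # unit sphere radius; calibrate the radius so the nearest sensor ends up
    # INTERNAL_SHELL[1] + SENSOR_STANDOFF from the shell centre (== the
    # centre of mass after translation).
    min_frac = np.linalg.norm(unit - com_unit, axis=1).min()
    if radius is None:
        radius = (INTERNAL_SHELL[1] + SENSOR_STANDOFF) / min_frac
    positions_sensor = unit * radius
    com = positions_sensor.mean(axis=0)
    positions_sensor = positions_sensor - com + SHELL_CENTRE

    # per-sensor orthonormal triad: radial (outward from the cap's sphere
    # centre) + two tangentials
    radial = unit
    ref = np.where(np.abs(radial[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    t1 = np.cross(ref, radial)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(radial, t1)

    positions = np.repeat(positions_sensor, 3, axis=0)
    orientations = np.empty((3 * n_sensors, 3))
    orientations[0::3] = radial
    orientations[1::3] = t1
    orientations[2::3] = t2
    labels = [f"s{i:02d}_{ax}" for i in range(n_sensors) for ax in ("rad", "t1", "t2")]
    return SensorArray(positions, orientations, labels)


def _distinct_frequencies(n: int, rng: np.random.Generator) -> np.ndarray:
    if n > 100:
        raise ValueError(f"cannot assign {n} distinct integer frequencies in [1, 100]")
    return rng.choice(np.arange(1, 101), size=n, replace=False)


def sample_shell_dipoles(
    n: int,
    r_min: float,
    r_max: float,
    centre=SHELL_CENTRE,
    moment_magnitude: float = INTERNAL_MOMENT,
    kind: Literal["internal", "external"] = "internal",
    seed: int | None = None,
    frequencies: Sequence[int] | None = None,
) -> List[DipoleSource]:
    """Dipoles uniform in the volume of a spherical shell, with uniformly
    random moment directions of fixed magnitude and distinct integer drive
    frequencies in [1, 100] Hz (unless ``frequencies`` is given)."""
    if not 0 <= r_min < r_max:
        raise ValueError("need 0 <= r_min < r_max")
    rng = np.random.default_rng(seed)
    # uniform-in-volume radius: CDF ~ r^3 between the shell bounds
    u = rng.uniform(size=n)
    radii = (r_min**3 + u * (r_max**3 - r_min**3)) ** (1.0 / 3.0)
    directions = rng.standard_normal((n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    moments = rng.standard_normal((n, 3))
    moments /= np.linalg.norm(moments, axis=1, keepdims=True)
    if frequencies is None:
        frequencies = _distinct_frequencies(n, rng)
    elif len(frequencies) != n:
        raise ValueError("frequencies must have one entry per dipole")
    centre = np.asarray(centre, dtype=float)
    return [
        DipoleSource(
            position=centre + radii[i] * directions[i],
            moment=moment_magnitude * moments[i],
            frequency=int(frequencies[i]),
            kind=kind,
        )
        for i in range(n)
    ]


def dipole_field(source: DipoleSource, points) -> np.ndarray:
    """Magnetic field of a point dipole, ``B = (mu0/4pi)[3 r_hat (m.r_hat) - m]/r^3``.

    ``points`` is (K, 3) or (3,) in metres; the result is in tesla with the
    matching shape.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d = pts - source.position
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise SingularPointError("field requested at the dipole position")
    r_hat = d / r[:, None]
    m_dot = r_hat @ source.moment
    b = MU0_OVER_4PI * (3.0 * m_dot[:, None] * r_hat - source.moment) / r[:, None] ** 3
    return b[0] if single else b


def simulate_recording(
    array: SensorArray,
    sources: Iterable[DipoleSource],
    duration: float = 1.0,
    fs: float = 1200.0,
    noise_sd: float = 30e-15,
    seed: int | None = None,
) -> Recording:
    """Multichannel recording of sinusoidally driven dipoles plus sensor noise.

    Each source contributes ``sin(2 pi f t)`` times its static projection on
    the channels; internal and external contributions are accumulated
    separately as ground truth, then i.i.d. Gaussian noise of standard
    deviation ``noise_sd`` (tesla) is added per channel per sample.
    """
    n = array.n_channels
    t = np.arange(int(round(duration * fs))) / fs
    truth = {"internal": np.zeros((n, t.size)), "external": np.zeros((n, t.size))}
    for src in sources:
        proj = np.einsum(
            "ij,ij->i", dipole_field(src, array.positions), array.orientations
        )
        truth[src.kind] += proj[:, None] * np.sin(2.0 * math.pi * src.frequency * t)[None, :]
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=noise_sd, size=(n, t.size)) if noise_sd > 0 else np.zeros((n, t.size))
    data = truth["internal"] + truth["external"] + noise
    return Recording(
        data=data,
        fs=fs,
        ground_truth_in=truth["internal"],
        ground_truth_out=truth["external"],
        labels=list(array.labels),
    )


def white_noise_vectors(array: SensorArray, n_vectors: int, seed: int | None = None) -> np.ndarray:
    """I.i.d. standard-normal signal vectors (N x n_vectors) on the array,
    used by the reconstruction-noise experiment; unit variance is all that
    matters because the noise-amplification ratio is scale free."""
    if n_vectors < 1:
        raise ValueError("need at least one vector")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((array.n_channels, n_vectors))
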