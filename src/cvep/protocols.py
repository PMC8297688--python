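"""Applied-current protocols: spherical baseline impulses mimicking the
physiological atrial activation sequence, a cubic high-frequency
pulmonary-vein-style trigger, and S1-S2 pinwheel protocols for
vulnerable-window experiments.

Amplitudes are expressed in 1/s on the normalized potential (span 100 mV),
so 200 1/s corresponds to 20 mV/ms on the physical membrane.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

#: mV of membrane potential per unit normalized potential
V_SPAN_MV = 100.0

#: printed protocol constants
AMPLITUDE_PER_S = 200.0
DURATION_MS = 5.0
BASELINE_FREQ_HZ = 1.82
TRIGGER_FREQ_HZ = 8.26
BASELINE_RADIUS_MM = 6.0
BASELINE_RADIUS_PAROX_MM = 7.0
TRIGGER_SIDE_MM = 6.0
BASELINE_DELAYS_MS = (0.0, 10.0, 20.0)


@dataclass(frozen=True)
class Impulse:
    """One periodic stimulus: spherical, cubic, or slab (planar) support.

    size is the sphere radius, the cube side, or the slab thickness along x,
    all in mm.  frequency None (or 0) means a single pulse at ``delay``.
    """

    shape: str                  # "sphere" | "cube" | "slab"
    center: tuple               # mm; for "slab": (x0, 0, 0) half-space start
    size: float                 # mm
    amplitude: float = AMPLITUDE_PER_S   # 1/s on normalized potential
    duration: float = DURATION_MS        # ms
    frequency: float | None = None       # Hz
    delay: float = 0.0                   # ms
    n_pulses: int | None = None          # None = unlimited

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("impulse size must be positive")
        if self.amplitude <= 0:
            raise ValueError("impulse amplitude must be positive")
        if self.frequency and self.duration >= 1000.0 / self.frequency:
            raise ValueError("duration must be shorter than the period")

    def support_mask(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        c = np.asarray(self.center, dtype=float)
        if self.shape == "sphere":
            return np.linalg.norm(p - c, axis=1) <= self.size
        if self.shape == "cube":
            return np.max(np.abs(p - c), axis=1) <= self.size / 2.0
        if self.shape == "slab":
            return np.abs(p[:, 0] - c[0]) <= self.size / 2.0
        raise ValueError(f"unknown impulse shape {self.shape!r}")

    def active(self, t: float) -> bool:
        """Is the impulse delivering current at time t (ms)?"""
        tau = t - self.delay
        if tau < 0:
            return False
        if not self.frequency:
            return tau <= self.duration
        period = 1000.0 / self.frequency
        k = int(np.floor(tau / period))
        if self.n_pulses is not None and k >= self.n_pulses:
            return False
        return (tau - k * period) <= self.duration

    @property
    def amplitude_mv_per_ms(self) -> float:
        return self.amplitude * V_SPAN_MV / 1000.0


@dataclass
class Protocol:
    """Ordered impulse list; applied currents superpose."""

    impulses: list
    name: str = "custom"

    def applied_current(self, points: np.ndarray, t: float) -> np.ndarray:
        """Per-point applied current (1/s, normalized-potential units)."""
        p = np.atleast_2d(points)
        out = np.zeros(len(p))
        for imp in self.impulses:
            if imp.active(t):
                out[imp.support_mask(p)] += imp.amplitude
        return out

    def validate_support(self, points: np.ndarray) -> None:
        lo = points.min(axis=0) - 1e-9
        hi = points.max(axis=0) + 1e-9
        for imp in self.impulses:
            c = np.asarray(imp.center, dtype=float)
            if imp.shape == "slab":
                if not (lo[0] <= c[0] <= hi[0]):
                    raise ValueError(f"slab impulse at x={c[0]} outside mesh")
            elif np.any(c < lo) or np.any(c > hi):
                raise ValueError(f"impulse center {tuple(c)} outside mesh")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name,
                       "impulses": [asdict(i) for i in self.impulses]}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path) -> "Protocol":
        with open(path) as fh:
            d = json.load(fh)
        return cls([Impulse(**{**i, "center": tuple(i["center"])})
                    for i in d["impulses"]], name=d.get("name", "custom"))


def applied_current(points: np.ndarray, t: float, protocol: Protocol):
    return protocol.applied_current(points, t)


def default_landmarks(mesh) -> list:
    """Baseline-impulse sites on a synthetic sheet: three points along the
    y=0 edge spaced 1.5 cm, playing the roles of the interatrial
    conduction bundles (Bachmann-bundle, fossa-ovalis, coronary-sinus
    analogs)."""
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    x0 = lo[0] + 0.15 * (hi[0] - lo[0])
    pts = []
    for k in range(3):
        x = min(x0 + 15.0 * k, hi[0])
        pts.append((x, lo[1], lo[2]))
    return pts


def default_trigger_site(mesh) -> tuple:
    """Trigger point in the corner opposite the baseline edge, mimicking
    pulmonary-vein remoteness."""
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    return (hi[0] - 0.08 * (hi[0] - lo[0]),
            hi[1] - 0.08 * (hi[1] - lo[1]), lo[2])


def baseline_preset(landmarks=None, mesh=None, paroxysmal: bool = False,
                    frequency: float = BASELINE_FREQ_HZ) -> Protocol:
    """Three delayed spherical impulses at the physiological frequency.

    Radius 6 mm (7 mm for the paroxysmal variant), amplitude 200 1/s,
    duration 5 ms, delays 0/10/20 ms recurring every cycle.
    """
    if landmarks is None:
        if mesh is None:
            raise ValueError("provide landmarks or a mesh for defaults")
        landmarks = default_landmarks(mesh)
    if len(landmarks) != 3:
        raise ValueError("baseline preset needs exactly 3 landmark points")
    radius = BASELINE_RADIUS_PAROX_MM if paroxysmal else BASELINE_RADIUS_MM
    imps = [Impulse("sphere", tuple(p), radius, AMPLITUDE_PER_S, DURATION_MS,
                    frequency, delay)
            for p, delay in zip(landmarks, BASELINE_DELAYS_MS)]
    return Protocol(imps, name="baseline-paroxysmal" if paroxysmal else "baseline")


def trigger_preset(x_t, frequency: float = TRIGGER_FREQ_HZ,
                   onset: float = 0.0) -> Protocol:
    """Cubic high-frequency ectopic trigger (side 6 mm, 8.26 Hz)."""
    imp = Impulse("cube", tuple(x_t), TRIGGER_SIDE_MM, AMPLITUDE_PER_S,
                  DURATION_MS, frequency, onset)
    return Protocol([imp], name="trigger")


def combined_preset(mesh, paroxysmal: bool = False,
                    trigger_site=None) -> Protocol:
    """Baseline plus trigger on a synthetic sheet (defaults for both)."""
    base = baseline_preset(mesh=mesh, paroxysmal=paroxysmal)
    trig = trigger_preset(trigger_site or default_trigger_site(mesh))
    return Protocol(base.impulses + trig.impulses, name="baseline+trigger")


def s1s2_preset(s1_center, s2_center, coupling_intervals,
                s1_shape: str = "slab", s1_size: float = 2.0,
                s2_shape: str = "sphere", s2_size: float = 5.0,
                amplitude: float = AMPLITUDE_PER_S,
                duration: float = DURATION_MS) -> list:
    """One Protocol instance per S1-S2 coupling interval (ms).

    S1 is a single planar (slab) or spherical stimulus at t=0; S2 fires once
    at each coupling interval.  A zero coupling interval is degenerate and
    rejected.
    """
    cis = list(coupling_intervals)
    if any(ci <= 0 for ci in cis):
        raise ValueError("coupling intervals must be positive (CI=0 would "
                         "coincide with S1)")
    if sorted(cis) != cis:
        raise ValueError("coupling intervals must be sorted ascending")
    protos = []
    for ci in cis:
        s1 = Impulse(s1_shape, tuple(s1_center), s1_size, amplitude, duration,
                     None, 0.0, n_pulses=1)
        s2 = Impulse(s2_shape, tuple(s2_center), s2_size, amplitude, duration,
                     None, float(ci), n_pulses=1)
        protos.append(Protocol([s1, s2], name=f"s1s2-ci{ci:g}"))
    return protos
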