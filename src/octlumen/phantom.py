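"""Synthetic IVOCT pullback phantoms with exact ground truth.

Clinical FD-OCT pullbacks are not redistributable, so every pipeline stage is
exercised on parametric phantoms that emulate the three segmentation
challenges of real frames: (a) irregular, non-circular lumens (smooth
harmonic perturbations, plus a deep angular notch standing in for a
bifurcation opening), (b) a guide-wire reflection with a dark radial shadow
whose angular position drifts smoothly along the pullback, and (c) thin
blood-artifact blobs inside the lumen, under multiplicative speckle noise.

Phantoms are generated natively in polar space, where the ground-truth
boundary r(θ) is exact by construction; Cartesian versions are derived by the
inverse transform.  What the phantoms deliberately do NOT model: physically
realistic OCT speckle statistics, depth attenuation, catheter eccentricity
distortion, or stent struts.

Every frame's randomness is seeded as (spec.seed, frame_index), so a fixed
spec yields byte-identical pullbacks regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .guidewire import Interval
from .metrics import contour_to_mask
from .polar import PolarFrame


@dataclass(frozen=True)
class Harmonic:
    """One sinusoidal boundary perturbation: amplitude·sin(k·θ + phase)."""

    k: int
    amplitude: float  # rows
    phase: float = 0.0


@dataclass(frozen=True)
class Notch:
    """Bifurcation surrogate: a raised-cosine radial dip over an angular window."""

    center_col: int
    width_cols: int
    depth_rows: float
    frame_range: tuple[int, int] | None = None  # [first, last] inclusive; None = all


@dataclass(frozen=True)
class GuideWire:
    """A bright wire reflection inside the lumen, with a dark shadow beyond.

    The wire lies between the catheter and the vessel wall, so its reflection
    blocks the radial view: everything at larger radius in those A-lines —
    including the wall band — is attenuated.  This is what makes the shadow
    columns genuinely unsegmentable rather than merely dark.
    """

    start_col: int = 40
    drift: float = 0.5           # columns per frame
    width: int = 20              # shadowed columns
    wire_radius_rows: int = 60   # radial position of the wire reflection
    attenuation: float = 0.12    # multiplicative, on rows beyond the reflection
    reflection_brightness: float = 1.0
    reflection_rows: int = 4


@dataclass(frozen=True)
class Artifacts:
    """Thin bright blood-artifact blobs inside the lumen."""

    count: int = 3
    thickness_rows: int = 3
    length_cols: int = 15
    contrast: float = 0.35


@dataclass(frozen=True)
class Stenosis:
    """Smooth radius narrowing centred on one frame (scale < 1 at the centre)."""

    frame: int
    scale: float = 0.6
    extent_frames: float = 4.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of a synthetic pullback.

    Default geometry mimics an FD-OCT polar frame: 384 radial samples at
    10 µm/row, 360 A-lines, lumen radius ≈ 1.5 mm (150 rows), a ~0.25 mm
    bright wall band, dark lumen and dimmer tissue beyond the wall.
    """

    n_frames: int = 50
    n_radii: int = 384
    n_angles: int = 360
    r0: float = 150.0
    harmonics: tuple[Harmonic, ...] = ()
    notch: Notch | None = None
    wall_thickness: int = 25
    lumen_level: float = 0.05
    wall_level: float = 0.9
    background_level: float = 0.15
    catheter_rows: int = 30
    sheath_level: float = 0.55
    guidewire: GuideWire | None = None
    artifacts: Artifacts | None = None
    speckle_sigma: float = 0.0
    stenosis: Stenosis | None = None
    pixel_spacing: float = 0.01  # mm per row/pixel
    seed: int = 0

    def __post_init__(self) -> None:
        reach = self.r0 + sum(abs(h.amplitude) for h in self.harmonics) \
            + self.wall_thickness
        if reach >= self.n_radii:
            raise ValueError("boundary + wall exceeds the radial extent")
        if self.guidewire is not None and not (0 <= self.guidewire.attenuation < 1):
            raise ValueError("guide-wire attenuation must be in [0, 1)")
        if not (0 <= self.lumen_level <= 1 and 0 <= self.wall_level <= 1):
            raise ValueError("intensity levels must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Exact per-frame truth: boundary radii, guide-wire interval, lumen masks."""

    radii: np.ndarray                    # (n_frames, n_angles), real-valued
    intervals: list[Interval | None]
    shape: tuple[int, int]               # (n_radii, n_angles)
    pixel_spacing: float

    def lumen_mask(self, f: int) -> np.ndarray:
        return contour_to_mask(self.radii[f], self.shape)


def _stenosis_scale(spec: PhantomSpec, f: int) -> float:
    st = spec.stenosis
    if st is None:
        return 1.0
    depth = 1.0 - st.scale
    return 1.0 - depth * float(np.exp(-((f - st.frame) ** 2)
                                      / (2.0 * st.extent_frames ** 2)))


def boundary_radii(spec: PhantomSpec, f: int) -> np.ndarray:
    """Exact ground-truth boundary r(θ) for frame f, in rows."""
    j = np.arange(spec.n_angles)
    theta = 2.0 * np.pi * j / spec.n_angles
    r = np.full(spec.n_angles, spec.r0 * _stenosis_scale(spec, f))
    for h in spec.harmonics:
        r = r + h.amplitude * np.sin(h.k * theta + h.phase)
    nt = spec.notch
    if nt is not None:
        active = nt.frame_range is None or nt.frame_range[0] <= f <= nt.frame_range[1]
        if active:
            d = (j - nt.center_col + spec.n_angles / 2) % spec.n_angles \
                - spec.n_angles / 2
            inside = np.abs(d) <= nt.width_cols / 2
            profile = 0.5 * (1.0 + np.cos(2.0 * np.pi * d / nt.width_cols))
            r = r - np.where(inside, nt.depth_rows * profile, 0.0)
    return r


def guidewire_interval(spec: PhantomSpec, f: int) -> Interval | None:
    gw = spec.guidewire
    if gw is None:
        return None
    center = (gw.start_col + gw.drift * f) % spec.n_angles
    start = int(np.round(center - gw.width / 2)) % spec.n_angles
    return Interval(start, (start + gw.width - 1) % spec.n_angles, spec.n_angles)


def generate_frame(spec: PhantomSpec, f: int,
                   rng: np.random.Generator | None = None
                   ) -> tuple[PolarFrame, np.ndarray, Interval | None]:
    """One polar frame plus its exact boundary radii and guide-wire interval."""
    if not (0 <= f < spec.n_frames):
        raise ValueError("frame index out of range")
    if rng is None:
        rng = np.random.default_rng([spec.seed, f])
    r = boundary_radii(spec, f)
    rows = np.arange(spec.n_radii, dtype=float)[:, None]
    # lumen → wall with a 2-row linear ramp centred on r (the ground-truth
    # boundary is the transition midpoint), tissue background beyond the wall
    ramp = np.clip((rows - r[None, :]) / 2.0 + 0.5, 0.0, 1.0)
    img = spec.lumen_level + ramp * (spec.wall_level - spec.lumen_level)
    beyond = rows >= (r[None, :] + spec.wall_thickness)
    img = np.where(beyond, spec.background_level, img)
    # catheter sheath: a thin bright ring well inside the lumen
    sheath_lo = max(spec.catheter_rows - 8, 0)
    img[sheath_lo:max(spec.catheter_rows - 4, sheath_lo + 1), :] = spec.sheath_level

    interval = guidewire_interval(spec, f)
    if interval is not None:
        gw = spec.guidewire
        cols = interval.columns()
        lo = min(gw.wire_radius_rows, spec.n_radii - 1)
        hi = min(lo + gw.reflection_rows, spec.n_radii)
        img[lo:hi, cols] = gw.reflection_brightness
        img[hi:, cols] *= gw.attenuation

    if spec.artifacts is not None and spec.artifacts.count > 0:
        art = spec.artifacts
        lo_row = spec.catheter_rows + 15
        for _ in range(art.count):
            c0 = int(rng.integers(0, spec.n_angles))
            hi_row = int(r.min()) - 15 - art.thickness_rows
            if hi_row <= lo_row:
                continue
            rr0 = int(rng.integers(lo_row, hi_row))
            cc = (c0 + np.arange(art.length_cols)) % spec.n_angles
            img[rr0:rr0 + art.thickness_rows, cc] += art.contrast

    if spec.speckle_sigma > 0:
        img = img * (1.0 + rng.normal(0.0, spec.speckle_sigma, img.shape))
    img = np.clip(img, 0.0, 1.0)
    return PolarFrame(img, radial_step=spec.pixel_spacing), r, interval


def generate_pullback(spec: PhantomSpec) -> tuple[list[PolarFrame], GroundTruth]:
    """All frames of the pullback plus the exact ground truth."""
    frames: list[PolarFrame] = []
    radii = np.empty((spec.n_frames, spec.n_angles))
    intervals: list[Interval | None] = []
    for f in range(spec.n_frames):
        frame, r, interval = generate_frame(spec, f)
        frames.append(frame)
        radii[f] = r
        intervals.append(interval)
    truth = GroundTruth(radii=radii, intervals=intervals,
                        shape=(spec.n_radii, spec.n_angles),
                        pixel_spacing=spec.pixel_spacing)
    return frames, truth


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable form of a spec (inverse of :func:`spec_from_dict`)."""
    import dataclasses

    d = dataclasses.asdict(spec)
    d["harmonics"] = [list(dataclasses.astuple(h)) for h in spec.harmonics]
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    """Build a spec from a plain dict (e.g. parsed JSON); unknown keys rejected."""
    import dataclasses

    d = dict(d)
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
    if "harmonics" in d:
        d["harmonics"] = tuple(
            h if isinstance(h, Harmonic) else Harmonic(*h) for h in d["harmonics"])
    for key, cls in (("notch", Notch), ("guidewire", GuideWire),
                     ("artifacts", Artifacts), ("stenosis", Stenosis)):
        v = d.get(key)
        if isinstance(v, dict):
            if key == "notch" and v.get("frame_range") is not None:
                v = dict(v, frame_range=tuple(v["frame_range"]))
            d[key] = cls(**v)
    return PhantomSpec(**d)


# --- the standard fixture scenarios (challenges individually switchable) ----

def baseline(seed: int = 0, n_frames: int = 10, **kw) -> PhantomSpec:
    """Clean circular lumen: no harmonics, wire, artifacts or noise."""
    return PhantomSpec(n_frames=n_frames, seed=seed, **kw)


def irregular(seed: int = 1, n_frames: int = 10, **kw) -> PhantomSpec:
    """Smoothly irregular lumen from three boundary harmonics."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, 3)
    return PhantomSpec(
        n_frames=n_frames, seed=seed,
        harmonics=(Harmonic(2, 15.0, phases[0]), Harmonic(3, 8.0, phases[1]),
                   Harmonic(5, 4.0, phases[2])), **kw)


def bifurcation(seed: int = 2, n_frames: int = 10, **kw) -> PhantomSpec:
    """A deep angular notch: the boundary radius jumps between adjacent A-lines."""
    rng = np.random.default_rng(seed)
    return PhantomSpec(
        n_frames=n_frames, seed=seed,
        harmonics=(Harmonic(2, 10.0, rng.uniform(0, 2 * np.pi)),),
        notch=Notch(center_col=int(rng.integers(60, 300)), width_cols=40,
                    depth_rows=60.0), **kw)


def guidewire_only(seed: int = 3, n_frames: int = 50, **kw) -> PhantomSpec:
    """Drifting guide-wire shadow over an otherwise smooth lumen."""
    rng = np.random.default_rng(seed)
    return PhantomSpec(
        n_frames=n_frames, seed=seed,
        harmonics=(Harmonic(2, 10.0, rng.uniform(0, 2 * np.pi)),),
        guidewire=GuideWire(start_col=int(rng.integers(0, 360)), drift=0.5),
        **kw)


def artifact_heavy(seed: int = 4, n_frames: int = 10, **kw) -> PhantomSpec:
    """Blood-artifact blobs and speckle inside a mildly irregular lumen."""
    rng = np.random.default_rng(seed)
    return PhantomSpec(
        n_frames=n_frames, seed=seed,
        harmonics=(Harmonic(2, 10.0, rng.uniform(0, 2 * np.pi)),),
        artifacts=Artifacts(count=4), speckle_sigma=0.08, **kw)


def full_combined(seed: int = 5, n_frames: int = 20, **kw) -> PhantomSpec:
    """All three challenges at once: irregular lumen + notch + wire + artifacts.

    The notch is placed on the far side of the wire track: the gap fit can
    only interpolate smooth structure across the shadow, so a bifurcation
    hidden entirely behind the wire is unrecoverable by construction (a
    documented limitation of the divide-and-conquer strategy, not a test
    subject).
    """
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, 2)
    wire_start = int(rng.integers(0, 360))
    return PhantomSpec(
        n_frames=n_frames, seed=seed,
        harmonics=(Harmonic(2, 12.0, phases[0]), Harmonic(3, 6.0, phases[1])),
        notch=Notch(center_col=(wire_start + 180) % 360, width_cols=40,
                    depth_rows=50.0),
        guidewire=GuideWire(start_col=wire_start, drift=0.5),
        artifacts=Artifacts(count=3), speckle_sigma=0.08, **kw)
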