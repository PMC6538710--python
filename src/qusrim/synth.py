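"""Synthetic RF scenes, reference phantoms, and lesion cohorts.

Scenes are built envelope-first: envelope amplitudes are drawn from a
Nakagami law whose shape parameter varies by region (background, elliptical
lesion interior, surrounding rim band), then a band-limited carrier with a
random phase per resolution cell is imposed so that standard analytic-signal
demodulation recovers the envelope statistics. This gives exact
distributional control of the ground truth, which is what downstream
estimators are tested against.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .preprocess import RFFrame, read_rf_h5, write_rf_h5

__all__ = [
    "SceneSpec",
    "CohortSpec",
    "SpeckleScene",
    "Plane",
    "Lesion",
    "Cohort",
    "sample_nakagami_envelope",
    "make_speckle_rf",
    "make_reference_phantom",
    "make_cohort",
    "ellipse_polygon",
    "region_label_map",
    "example_scene_spec",
    "example_cohort_spec",
    "write_cohort",
    "read_cohort",
]

BACKGROUND, INTERIOR, RIM = 0, 1, 2


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth description of one synthetic RF scene.

    ``lesion_ellipse`` is ``(center_mm, semi_axes_mm, rotation_deg)`` with
    ``center_mm=(x, z)`` and ``semi_axes_mm=(a_x, b_z)``; ``None`` means a
    uniform background-only scene. Shape parameters are per region; mean
    power (omega) scales are ``(background, interior, rim)``.
    """

    grid_shape: tuple[int, int] = (1560, 510)
    sample_spacing_mm: float = 0.01925
    line_pitch_mm: float = 0.0745
    background_nak: float = 1.0
    lesion_ellipse: tuple | None = None
    interior_nak: float = 1.0
    rim_nak: float = 1.0
    rim_width_mm: float = 5.0
    mean_power: tuple[float, float, float] = (1.0, 1.0, 1.0)
    carrier_freq_hz: float = 7.2e6
    cell_samples: int = 3
    sound_speed_mps: float = 1540.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_spacing_mm <= 0 or self.line_pitch_mm <= 0:
            raise ValueError("spacings must be positive")
        for nak in (self.background_nak, self.interior_nak, self.rim_nak):
            if nak <= 0:
                raise ValueError("Nakagami shape parameters must be positive")
        if any(p <= 0 for p in self.mean_power):
            raise ValueError("mean power scales must be positive")
        if self.rim_width_mm < 0:
            raise ValueError("rim width must be non-negative")
        if self.cell_samples < 1:
            raise ValueError("cell_samples must be >= 1")
        if len(self.grid_shape) != 2 or self.grid_shape[0] < 1 or self.grid_shape[1] < 2:
            raise ValueError("grid_shape must be (axial >= 1, lines >= 2)")
        if self.carrier_freq_hz <= 0 or self.carrier_freq_hz >= self.fs_hz / 2:
            raise ValueError("carrier frequency must lie in (0, fs/2)")
        if self.lesion_ellipse is not None:
            center, semi, _rot = self.lesion_ellipse
            extent_z = (self.grid_shape[0] - 1) * self.sample_spacing_mm
            extent_x = (self.grid_shape[1] - 1) * self.line_pitch_mm
            margin = max(semi) + self.rim_width_mm
            cx, cz = center
            if (
                cx - margin < 0
                or cz - margin < 0
                or cx + margin > extent_x
                or cz + margin > extent_z
            ):
                raise ValueError("lesion ellipse plus rim does not fit inside the grid")

    @property
    def fs_hz(self) -> float:
        return self.sound_speed_mps * 1e3 / (2.0 * self.sample_spacing_mm)


@dataclass(frozen=True)
class CohortSpec:
    """A two-class cohort of synthetic lesions, two scan planes each."""

    n_benign: int
    n_malignant: int
    benign_scene: SceneSpec
    malignant_scene: SceneSpec
    planes_per_lesion: int = 2
    per_lesion_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("class counts must be >= 1")
        if self.planes_per_lesion != 2:
            raise ValueError("planes_per_lesion is fixed at 2")
        if not 0 <= self.per_lesion_jitter < 1:
            raise ValueError("per_lesion_jitter must be in [0, 1)")
        if self.benign_scene.lesion_ellipse is None or self.malignant_scene.lesion_ellipse is None:
            raise ValueError("cohort scene templates must define a lesion ellipse")


@dataclass(frozen=True)
class SpeckleScene:
    """A synthesized frame plus its ground truth."""

    frame: RFFrame
    labels: np.ndarray  # region label per RF sample: 0 bg, 1 interior, 2 rim
    spec: SceneSpec


@dataclass(frozen=True)
class Plane:
    frame: RFFrame
    contour_mm: np.ndarray  # closed (n+1, 2) polygon, columns [x_mm, z_mm]
    spec: SceneSpec


@dataclass(frozen=True)
class Lesion:
    lesion_id: str
    label: str  # 'benign' | 'malignant'
    planes: tuple[Plane, ...]
    truth: dict


@dataclass(frozen=True)
class Cohort:
    lesions: tuple[Lesion, ...]
    spec: CohortSpec


def sample_nakagami_envelope(
    n: int, nak: float, omega: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. Nakagami(``nak``, ``omega``) envelope amplitudes.

    The amplitude squared is Gamma(shape=nak, scale=omega/nak), so the
    empirical second moment converges to ``omega``.
    """
    if nak <= 0:
        raise ValueError("shape parameter must be positive")
    if omega <= 0:
        raise ValueError("mean power must be positive")
    if n < 1:
        raise ValueError("sample count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intensity = rng.gamma(shape=nak, scale=omega / nak, size=int(n))
    return np.sqrt(intensity)


def region_label_map(
    spec: SceneSpec,
    shape: tuple[int, int] | None = None,
    spacing_mm: tuple[float, float] | None = None,
) -> np.ndarray:
    """Region labels (0 background, 1 interior, 2 rim) on a sample grid.

    Defaults to the spec's RF grid; pass ``shape``/``spacing_mm`` to rate the
    same geometry on another (e.g. isotropic pixel) grid.
    """
    if shape is None:
        shape = spec.grid_shape
    if spacing_mm is None:
        spacing_mm = (spec.sample_spacing_mm, spec.line_pitch_mm)
    labels = np.zeros(shape, dtype=np.uint8)
    if spec.lesion_ellipse is None:
        return labels
    (cx, cz), (a, b), rot_deg = spec.lesion_ellipse
    dz, dx = spacing_mm
    z = np.arange(shape[0])[:, None] * dz
    x = np.arange(shape[1])[None, :] * dx
    theta = np.deg2rad(rot_deg)
    u = (x - cx) * np.cos(theta) + (z - cz) * np.sin(theta)
    v = -(x - cx) * np.sin(theta) + (z - cz) * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    labels[inside] = INTERIOR
    if spec.rim_width_mm > 0:
        dist = distance_transform_edt(~inside, sampling=(dz, dx))
        labels[(dist > 0) & (dist <= spec.rim_width_mm)] = RIM
    return labels


def _draw_rf(
    nak_map: np.ndarray,
    omega_map: np.ndarray,
    spec_like,
    rng: np.random.Generator,
    gain: np.ndarray | None = None,
) -> np.ndarray:
    """Envelope-first RF synthesis shared by scenes and phantoms.

    Envelope and carrier phase are drawn once per resolution cell
    (``cell_samples`` axial samples by one line) and held constant inside the
    cell, which keeps the signal band mostly above DC so that Hilbert
    demodulation recovers the imposed amplitudes.
    """
    n_ax, n_lines = nak_map.shape
    cell = int(spec_like.cell_samples)
    n_cells = -(-n_ax // cell)
    rows = np.minimum(np.arange(n_cells) * cell, n_ax - 1)
    nak_c = nak_map[rows, :]
    omega_c = omega_map[rows, :]
    env_c = np.sqrt(rng.gamma(shape=nak_c, scale=omega_c / nak_c))
    phase_c = rng.uniform(0.0, 2.0 * np.pi, size=env_c.shape)
    env = np.repeat(env_c, cell, axis=0)[:n_ax, :]
    phase = np.repeat(phase_c, cell, axis=0)[:n_ax, :]
    if gain is not None:
        env = env * gain[:, None]
    t = np.arange(n_ax) / spec_like.fs_hz
    carrier = np.cos(2.0 * np.pi * spec_like.carrier_freq_hz * t[:, None] + phase)
    return env * carrier


def make_speckle_rf(spec: SceneSpec) -> SpeckleScene:
    """Synthesize an RF frame for a scene and return it with ground truth."""
    if spec.grid_shape[1] < 2:
        raise ValueError("scene needs at least 2 scan lines")
    labels = region_label_map(spec)
    naks = np.array([spec.background_nak, spec.interior_nak, spec.rim_nak])
    omegas = np.asarray(spec.mean_power, dtype=float)
    rng = np.random.default_rng(spec.seed)
    rf = _draw_rf(naks[labels], omegas[labels], spec, rng)
    frame = RFFrame(
        samples=rf,
        fs_hz=spec.fs_hz,
        line_pitch_mm=spec.line_pitch_mm,
        sound_speed_mps=spec.sound_speed_mps,
    )
    return SpeckleScene(frame=frame, labels=labels, spec=spec)


def make_reference_phantom(
    grid_shape: tuple[int, int],
    nak: float = 1.0,
    depth_gain: float | Sequence[float] | Callable[[np.ndarray], np.ndarray] = 1.0,
    seed: int = 0,
    *,
    sample_spacing_mm: float = 0.01925,
    line_pitch_mm: float = 0.0745,
    omega: float = 1.0,
    carrier_freq_hz: float = 7.2e6,
    cell_samples: int = 3,
    sound_speed_mps: float = 1540.0,
) -> RFFrame:
    """Homogeneous speckle frame with an imposed depth-dependent gain.

    ``depth_gain`` may be a scalar, a per-sample array, or a callable of
    depth in mm; it must be strictly positive everywhere.
    """
    spec = SceneSpec(
        grid_shape=tuple(grid_shape),
        sample_spacing_mm=sample_spacing_mm,
        line_pitch_mm=line_pitch_mm,
        background_nak=nak,
        mean_power=(omega, omega, omega),
        carrier_freq_hz=carrier_freq_hz,
        cell_samples=cell_samples,
        sound_speed_mps=sound_speed_mps,
        seed=seed,
    )
    n_ax = spec.grid_shape[0]
    z_mm = np.arange(n_ax) * sample_spacing_mm
    if callable(depth_gain):
        gain = np.asarray(depth_gain(z_mm), dtype=float)
    else:
        gain = np.broadcast_to(np.asarray(depth_gain, dtype=float), (n_ax,)).copy()
    if gain.shape != (n_ax,):
        raise ValueError("depth gain must broadcast to one value per axial sample")
    if np.any(gain <= 0):
        raise ValueError("depth gain must be strictly positive")
    rng = np.random.default_rng(seed)
    nak_map = np.full(spec.grid_shape, nak, dtype=float)
    omega_map = np.full(spec.grid_shape, omega, dtype=float)
    rf = _draw_rf(nak_map, omega_map, spec, rng, gain=gain)
    return RFFrame(
        samples=rf,
        fs_hz=spec.fs_hz,
        line_pitch_mm=line_pitch_mm,
        sound_speed_mps=sound_speed_mps,
    )


def ellipse_polygon(
    center_mm: tuple[float, float],
    semi_axes_mm: tuple[float, float],
    rotation_deg: float = 0.0,
    n_vertices: int = 64,
) -> np.ndarray:
    """Closed polygon (n+1 rows of [x_mm, z_mm]) tracing an ellipse."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a, b = semi_axes_mm
    phi = np.deg2rad(rotation_deg)
    u = a * np.cos(t)
    v = b * np.sin(t)
    x = center_mm[0] + u * np.cos(phi) - v * np.sin(phi)
    z = center_mm[1] + u * np.sin(phi) + v * np.cos(phi)
    poly = np.column_stack([x, z])
    return np.vstack([poly, poly[:1]])


def _jitter(rng: np.random.Generator, amount: float) -> float:
    return 1.0 + rng.uniform(-amount, amount)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate a reproducible synthetic lesion cohort.

    Each lesion gets its own jittered geometry and per-region shape
    parameters (shared by both planes; the second plane swaps the ellipse
    semi-axes, emulating orthogonal scan planes) and a contour polygon
    tracing the true ellipse of each plane.
    """
    rng = np.random.default_rng(spec.seed)
    lesions: list[Lesion] = []
    templates = [("benign", spec.benign_scene)] * spec.n_benign + [
        ("malignant", spec.malignant_scene)
    ] * spec.n_malignant
    j = spec.per_lesion_jitter
    for idx, (label, template) in enumerate(templates):
        (cx, cz), (a, b), rot = template.lesion_ellipse
        semi = (a * _jitter(rng, j), b * _jitter(rng, j))
        naks = {
            "background_nak": template.background_nak * _jitter(rng, j),
            "interior_nak": template.interior_nak * _jitter(rng, j),
            "rim_nak": template.rim_nak * _jitter(rng, j),
        }
        planes = []
        for p in range(spec.planes_per_lesion):
            axes = semi if p == 0 else (semi[1], semi[0])
            plane_spec = replace(
                template,
                lesion_ellipse=((cx, cz), axes, rot),
                seed=int(rng.integers(0, 2**31 - 1)),
                **naks,
            )
            scene = make_speckle_rf(plane_spec)
            contour = ellipse_polygon((cx, cz), axes, rot)
            planes.append(Plane(frame=scene.frame, contour_mm=contour, spec=plane_spec))
        lesions.append(
            Lesion(
                lesion_id=f"lesion_{idx:03d}",
                label=label,
                planes=tuple(planes),
                truth={"semi_axes_mm": semi, **naks},
            )
        )
    return Cohort(lesions=tuple(lesions), spec=spec)


def example_scene_spec(
    *,
    effect: str = "none",
    rim_nak: float = 1.6,
    interior_nak: float = 0.6,
    coarse: bool = True,
    seed: int = 0,
) -> SceneSpec:
    """A ready-made scene: small elliptical lesion centred in the frame.

    ``effect`` selects where the shape parameter deviates from the
    background: ``'rim'``, ``'interior'``, or ``'none'``. The coarse variant
    trades resolution for speed and is what the test-scale cohorts use.
    """
    if effect not in ("none", "rim", "interior"):
        raise ValueError(f"unknown effect {effect!r}")
    base = dict(
        background_nak=1.0,
        interior_nak=1.0,
        rim_nak=1.0,
        lesion_ellipse=((10.0, 10.0), (3.0, 2.5), 0.0),
        rim_width_mm=5.0,
        seed=seed,
    )
    if effect == "rim":
        base["rim_nak"] = rim_nak
    elif effect == "interior":
        base["interior_nak"] = interior_nak
    if coarse:
        return SceneSpec(
            grid_shape=(520, 81),
            sample_spacing_mm=0.0385,
            line_pitch_mm=0.25,
            **base,
        )
    return SceneSpec(**base)


def example_cohort_spec(
    n_benign: int = 59,
    n_malignant: int = 57,
    *,
    effect: str = "rim",
    seed: int = 0,
    per_lesion_jitter: float = 0.1,
) -> CohortSpec:
    """A two-class cohort whose class difference sits in the chosen region."""
    benign = example_scene_spec(effect="none")
    malignant = example_scene_spec(effect=effect)
    return CohortSpec(
        n_benign=n_benign,
        n_malignant=n_malignant,
        benign_scene=benign,
        malignant_scene=malignant,
        per_lesion_jitter=per_lesion_jitter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort I/O: RF frames to HDF5, contours to JSON, labels to CSV


def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for lesion in cohort.lesions:
        for p, plane in enumerate(lesion.planes):
            stem = f"{lesion.lesion_id}_plane{p}"
            write_rf_h5(outdir / f"{stem}.h5", plane.frame)
            contour = {
                "lesion_id": lesion.lesion_id,
                "plane": p,
                "vertices_mm": plane.contour_mm.tolist(),
            }
            (outdir / f"{stem}.contour.json").write_text(json.dumps(contour))
        rows.append((lesion.lesion_id, lesion.label))
    with open(outdir / "labels.csv", "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["lesion_id", "label"])
        writer.writerows(rows)


def read_cohort(indir) -> list[dict]:
    """Read a written cohort back as a list of per-lesion dicts.

    Each dict has ``lesion_id``, ``label``, and ``planes``: a list of
    ``(RFFrame, contour ndarray)`` pairs. Ground truth is not round-tripped.
    """
    indir = Path(indir)
    with open(indir / "labels.csv", newline="") as f:
        labels = {row["lesion_id"]: row["label"] for row in csv.DictReader(f)}
    out = []
    for lesion_id in sorted(labels):
        planes = []
        for p in range(2):
            stem = indir / f"{lesion_id}_plane{p}"
            frame = read_rf_h5(f"{stem}.h5")
            contour = np.asarray(
                json.loads((indir / f"{lesion_id}_plane{p}.contour.json").read_text())[
                    "vertices_mm"
                ]
            )
            planes.append((frame, contour))
        out.append({"lesion_id": lesion_id, "label": labels[lesion_id], "planes": planes})
    return out
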