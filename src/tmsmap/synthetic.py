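"""Synthetic TMS motor-mapping cohorts with known ground truth.

Real motor-mapping data (stimulation-locked EMG, neuro-navigated coil
positions, FreeSurfer surfaces) are not redistributable, so this module
generates the whole experiment from scratch: cortical patch / hemisphere
meshes with analytic sphere registrations, per-muscle Gaussian
excitability fields on a "precentral" band, pseudo-random coil schedules
(3 intensities x 120 pulses x 2 repetitions = 720 per subject), and
stimulation-locked EMG sweeps at 2 kHz with injected biphasic MEPs over
Gaussian baseline noise.

Everything is seeded and every ground-truth quantity (field centres,
mask-restricted centroids, analytic disc overlaps) is recorded, so each
downstream stage — MEP detection, masking, warping, interpolation,
centroid/area/overlap metrics, group statistics — can be tested for
parameter recovery without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .emg import EMGTrace
from .surface import StimulationEvent, TriSurface

__all__ = [
    "HAND_MUSCLES",
    "FOREARM_MUSCLES",
    "MUSCLES",
    "GroundTruthField",
    "ExperimentDesign",
    "InvalidDesignError",
    "design_experiment",
    "make_flat_patch_mesh",
    "make_hemisphere_mesh",
    "sample_field_amplitude",
    "synth_emg",
    "default_fields",
    "disc_iou",
    "SubjectData",
    "Cohort",
    "make_cohort",
]

# Canonical muscle set: four intrinsic hand and four forearm muscles.
HAND_MUSCLES = ("FDI", "ADM", "FPB", "APB")
FOREARM_MUSCLES = ("EDC", "FDS", "ECR", "FCR")
MUSCLES = HAND_MUSCLES + FOREARM_MUSCLES

# The three stimulation intensities: 105% of the resting motor threshold
# of FDI, EDC and FCR respectively.
DEFAULT_CONDITIONS = ("105%-RMT-FDI", "105%-RMT-EDC", "105%-RMT-FCR")
# Relative excitability scaling per condition (higher effective intensity
# for the FCR-referenced threshold, which produces larger overlaps).
DEFAULT_CONDITION_SCALE = {
    "105%-RMT-FDI": 1.0,
    "105%-RMT-EDC": 1.15,
    "105%-RMT-FCR": 1.3,
}

M1_LABEL = "precentral L"


class InvalidDesignError(ValueError):
    pass


@dataclass
class GroundTruthField:
    """An isotropic Gaussian excitability field for one muscle.

    The noiseless MEP amplitude at a stimulation point p is
    ``peak_amplitude * exp(-||p - center||^2 / (2 sigma^2))``.
    """

    muscle_label: str
    center: np.ndarray  # 3-vector, mm
    sigma: float  # mm
    peak_amplitude: float  # uV

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")

    def noiseless(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = np.sum((pts - self.center) ** 2, axis=1)
        return self.peak_amplitude * np.exp(-d2 / (2.0 * self.sigma**2))


@dataclass
class ExperimentDesign:
    """Stimulation bookkeeping: intensities x pulses-per-block x repetitions."""

    n_intensities: int = 3
    stims_per_block: int = 120
    n_repetitions: int = 2
    inter_stimulus_s: float = 5.0
    grid_extent_mm: float = 50.0

    def __post_init__(self) -> None:
        if min(self.n_intensities, self.stims_per_block, self.n_repetitions) < 1:
            raise InvalidDesignError("all design counts must be >= 1")
        if self.inter_stimulus_s <= 0:
            raise InvalidDesignError("inter_stimulus_s must be positive")
        if self.grid_extent_mm <= 0:
            raise InvalidDesignError("grid_extent_mm must be positive")

    @property
    def total_stimulations(self) -> int:
        return self.n_intensities * self.stims_per_block * self.n_repetitions


def design_experiment(
    design: ExperimentDesign,
    seed: int,
    hotspot: np.ndarray | tuple = (0.0, 0.0, 0.0),
    conditions: tuple[str, ...] | None = None,
) -> list[StimulationEvent]:
    """Generate the full pseudo-random stimulation schedule for one subject.

    Coil positions are uniform over a ``grid_extent_mm`` square centred
    on the hotspot (in the hotspot's tangent x-y plane); blocks run
    repetition-major then intensity, pulses ``inter_stimulus_s`` apart.
    Identical arguments and seed give a byte-identical schedule.
    """
    if conditions is None:
        conditions = (
            DEFAULT_CONDITIONS
            if design.n_intensities == len(DEFAULT_CONDITIONS)
            else tuple(f"cond{i + 1}" for i in range(design.n_intensities))
        )
    if len(conditions) != design.n_intensities:
        raise InvalidDesignError("one condition label per intensity required")
    hotspot = np.asarray(hotspot, dtype=float)
    rng = np.random.default_rng(seed)
    half = design.grid_extent_mm / 2.0
    total = design.total_stimulations
    offsets = rng.uniform(-half, half, size=(total, 2))
    events: list[StimulationEvent] = []
    k = 0
    for _rep in range(design.n_repetitions):
        for cond in conditions:
            for _ in range(design.stims_per_block):
                pos = hotspot + np.array([offsets[k, 0], offsets[k, 1], 0.0])
                events.append(
                    StimulationEvent(
                        event_id=k,
                        time_s=k * design.inter_stimulus_s,
                        coil_position=pos,
                        coil_orientation=np.array([0.0, 1.0, 0.0]),
                        intensity_condition=cond,
                    )
                )
                k += 1
    return events


# -- meshes ---------------------------------------------------------------


def _flat_patch_sphere(xy: np.ndarray, max_angle_rad: float = math.pi / 3) -> np.ndarray:
    """Azimuthal-equidistant embedding of a planar patch on the unit sphere.

    Plane radii map linearly to polar angles (up to ``max_angle_rad`` at
    the patch's outermost vertex), so great-circle distance is
    proportional to planar distance along radial directions and the
    registration is analytic and deterministic.
    """
    r = np.linalg.norm(xy, axis=1)
    rmax = r.max()
    scale = max_angle_rad / rmax if rmax > 0 else 0.0
    rho = r * scale
    phi = np.arctan2(xy[:, 1], xy[:, 0])
    return np.column_stack(
        [np.sin(rho) * np.cos(phi), np.sin(rho) * np.sin(phi), np.cos(rho)]
    )


def make_flat_patch_mesh(
    nx: int,
    ny: int,
    spacing_mm: float,
    label: str = M1_LABEL,
    m1_band_mm: float | None = None,
) -> TriSurface:
    """Regular planar triangle grid centred on the origin (z = 0).

    ``nx * ny`` vertices, ``2 (nx-1)(ny-1)`` triangles, zero curvature.
    With ``m1_band_mm`` set, vertices with ``|x| <= m1_band_mm`` are
    labelled ``"precentral L"`` and the rest ``"other"``, emulating a
    precentral-gyrus band so that M1 masking is exercised; otherwise all
    vertices carry ``label``.
    """
    if nx < 2 or ny < 2:
        raise ValueError("grid needs nx, ny >= 2")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing_mm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing_mm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    faces = np.asarray(faces, dtype=np.int64)
    if m1_band_mm is not None:
        labels = np.where(np.abs(verts[:, 0]) <= m1_band_mm, M1_LABEL, "other")
    else:
        labels = np.full(nx * ny, label, dtype=object)
    sphere = _flat_patch_sphere(verts[:, :2])
    return TriSurface(verts, faces, np.zeros(nx * ny), np.asarray(labels), sphere)


def make_hemisphere_mesh(
    n_subdiv: int, radius_mm: float, label: str = M1_LABEL
) -> TriSurface:
    """Icosphere-style triangulation of the upper (z >= 0) hemisphere.

    An icosphere is sliced exactly at the equatorial plane and every
    vertex (including the cut-line vertices the slice introduces) is
    pushed radially onto the sphere of radius ``radius_mm``, so the
    summed triangle area stays close to the analytic ``2 pi r^2``.
    Curvature is the analytic ``1/radius``; the sphere registration is
    the radial projection.
    """
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=n_subdiv, radius=radius_mm)
    cap = trimesh.intersections.slice_mesh_plane(
        ico, plane_normal=(0.0, 0.0, 1.0), plane_origin=(0.0, 0.0, 0.0)
    )
    cap.merge_vertices()  # the slice duplicates cut-line vertices per face
    verts = np.asarray(cap.vertices, dtype=float)
    faces = np.asarray(cap.faces, dtype=np.int64)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius_mm
    # renormalisation can degenerate slice slivers; drop them and reindex
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    faces = faces[areas > 1e-12 * radius_mm**2]
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = verts[used]
    faces = remap[faces]
    sphere = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    n = len(verts)
    return TriSurface(
        verts,
        faces,
        np.full(n, 1.0 / radius_mm),
        np.full(n, label, dtype=object),
        sphere,
    )


# -- fields and EMG --------------------------------------------------------


def sample_field_amplitude(
    field: GroundTruthField,
    point: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Noiseless Gaussian field value at ``point`` plus Gaussian noise, clipped at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    value = float(field.noiseless(np.asarray(point, dtype=float))[0])
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        value += rng.normal(0.0, noise_sd)
    return max(value, 0.0)


def synth_emg(
    mep_amplitude: float,
    latency_ms: float = 20.0,
    baseline_sd: float = 5.0,
    rate_hz: float = 2000.0,
    pre_ms: float = 250.0,
    post_ms: float = 100.0,
    seed: int | np.random.Generator | None = None,
    wavelet_freq_hz: float = 150.0,
    wavelet_tau_ms: float = 3.0,
) -> EMGTrace:
    """Stimulation-locked EMG sweep with an injected biphasic MEP.

    The trace spans [-pre_ms, post_ms] around the stimulus at ``rate_hz``.
    Baseline activity is white Gaussian noise of SD ``baseline_sd``; when
    ``mep_amplitude > 0`` a Gabor-like biphasic wavelet (one positive and
    one negative lobe) is centred at ``latency_ms``, scaled so that its
    sampled peak-to-peak amplitude equals ``mep_amplitude`` exactly.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n = int(round((pre_ms + post_ms) / 1000.0 * rate_hz))
    if n < 2:
        raise ValueError("trace would have fewer than 2 samples")
    t0 = -pre_ms / 1000.0
    t = t0 + np.arange(n) / rate_hz
    if mep_amplitude > 0 and not (t[0] <= latency_ms / 1000.0 <= t[-1]):
        raise ValueError("latency lies outside the trace")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = rng.normal(0.0, baseline_sd, size=n) if baseline_sd > 0 else np.zeros(n)
    if mep_amplitude > 0:
        dt = t - latency_ms / 1000.0
        tau = wavelet_tau_ms / 1000.0
        w = np.sin(2.0 * math.pi * wavelet_freq_hz * dt) * np.exp(-(dt**2) / (2 * tau**2))
        p2p = w.max() - w.min()
        if p2p > 0:
            samples = samples + w * (mep_amplitude / p2p)
    return EMGTrace(samples, rate_hz, t0)


# -- cohort ----------------------------------------------------------------


def default_fields(
    sigma_mm: float = 5.0, band_x_mm: float = 0.0
) -> dict[str, GroundTruthField]:
    """Canonical eight-muscle field layout on the precentral band.

    Hand representations sit lateral (positive y), forearm medial
    (negative y), with synergistic muscles adjacent — mirroring the
    somatotopy the mapping experiment probes. Peaks are a few hundred uV,
    typical of just-above-threshold stimulation.
    """
    layout = {
        # hand (lateral): thumb-side synergists FDI/APB/FPB adjacent and
        # lateral to the little-finger muscle ADM
        "FDI": (12.0, 600.0),
        "APB": (9.0, 500.0),
        "FPB": (6.0, 450.0),
        "ADM": (2.0, 400.0),
        # forearm (medial): synergist pairs EDC-ECR and FDS-FCR adjacent
        "EDC": (-5.0, 500.0),
        "ECR": (-8.0, 450.0),
        "FDS": (-13.0, 420.0),
        "FCR": (-16.0, 400.0),
    }
    return {
        m: GroundTruthField(m, np.array([band_x_mm, y, 0.0]), sigma_mm, peak)
        for m, (y, peak) in layout.items()
    }


def disc_iou(c1: np.ndarray, r1: float, c2: np.ndarray, r2: float) -> float:
    """Analytic intersection-over-union of two discs in a common plane."""
    d = float(np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)))
    a1, a2 = math.pi * r1**2, math.pi * r2**2
    if d >= r1 + r2:
        inter = 0.0
    elif d <= abs(r1 - r2):
        inter = min(a1, a2)
    else:
        alpha = math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
        beta = math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
        inter = (
            r1**2 * (alpha - math.sin(2 * alpha) / 2)
            + r2**2 * (beta - math.sin(2 * beta) / 2)
        )
    union = a1 + a2 - inter
    return inter / union if union > 0 else float("nan")


@dataclass
class SubjectData:
    """One synthetic participant: mesh, fields, schedule and amplitudes."""

    subject_id: str
    mesh: TriSurface
    fields: dict[str, GroundTruthField]
    events: list[StimulationEvent]
    # (n_events, n_muscles) clean per-pulse MEP amplitude (uV), noise and
    # condition scaling applied; this is what gets injected into the EMG.
    amplitudes: np.ndarray


@dataclass
class Cohort:
    """A full synthetic cohort with recorded ground truth.

    EMG traces are synthesised lazily and deterministically from
    ``(seed, subject, event, muscle)`` — a 20-subject default cohort has
    115,200 traces (~0.6 GB at 2 kHz), far too much to hold at once and
    never needed at once, since the pipeline streams per subject/muscle.
    """

    template: TriSurface
    subjects: list[SubjectData]
    design: ExperimentDesign
    muscles: tuple[str, ...]
    conditions: tuple[str, ...]
    condition_scale: dict[str, float]
    seed: int
    emg_rate_hz: float = 2000.0
    emg_latency_ms: float = 20.0
    emg_baseline_sd_uv: float = 5.0
    emg_pre_ms: float = 250.0
    emg_post_ms: float = 100.0
    ground_truth: dict = dc_field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return sum(len(s.events) for s in self.subjects)

    @property
    def n_traces(self) -> int:
        return self.n_events * len(self.muscles)

    def muscle_index(self, muscle: str) -> int:
        return self.muscles.index(muscle)

    def emg_trace(self, subject_idx: int, event_idx: int, muscle: str) -> EMGTrace:
        """Deterministically regenerate one stimulation-locked EMG sweep."""
        mi = self.muscle_index(muscle)
        amp = float(self.subjects[subject_idx].amplitudes[event_idx, mi])
        rng = np.random.default_rng([self.seed, 7001, subject_idx, event_idx, mi])
        return synth_emg(
            amp,
            latency_ms=self.emg_latency_ms,
            baseline_sd=self.emg_baseline_sd_uv,
            rate_hz=self.emg_rate_hz,
            pre_ms=self.emg_pre_ms,
            post_ms=self.emg_post_ms,
            seed=rng,
        )


def _masked_field_centroid(
    surface: TriSurface,
    field: GroundTruthField,
    region: str = M1_LABEL,
    floor_uv: float = 0.0,
) -> np.ndarray:
    """MEP-weighted centroid of the noiseless field over the masked vertices.

    ``floor_uv`` restricts the support to vertices whose field value
    reaches the MEP detection floor — the estimand of the map pipeline,
    which only ever sees MEP-positive stimulations.
    """
    keep = surface.atlas_labels == region
    v = surface.vertices[keep]
    w = field.noiseless(v)
    if floor_uv > 0:
        above = w >= floor_uv
        v, w = v[above], w[above]
    return (w[:, None] * v).sum(axis=0) / w.sum()


def make_cohort(
    n_subjects: int = 20,
    fields: dict[str, GroundTruthField] | None = None,
    jitter_mm: float = 2.0,
    seed: int = 0,
    design: ExperimentDesign | None = None,
    template: TriSurface | None = None,
    condition_scale: dict[str, float] | None = None,
    amplitude_noise_sd_uv: float = 20.0,
    mesh_noise_mm: float = 0.3,
    disc_radius_sigmas: float = 2.0,
    detection_floor_uv: float = 100.0,
) -> Cohort:
    """Generate a cohort of subjects with recorded ground truth.

    Per subject: a copy of the template patch with out-of-plane vertex
    noise (SD ``mesh_noise_mm``; the sphere registration stays the
    template's, as a surface registration would align anatomy), muscle
    fields whose centres are jittered tangentially (Gaussian, SD
    ``jitter_mm``), a full stimulation schedule and per-pulse amplitudes
    for every muscle. Recorded ground truth: jittered field parameters,
    mask-restricted noiseless-field centroids over the vertices whose
    field value reaches ``detection_floor_uv`` (the default 100 uV is
    twenty times the default 5 uV EMG baseline SD; the map pipeline only
    ever sees MEP-positive pulses, so this is its estimand), and
    analytic disc overlaps at ``disc_radius_sigmas * sigma`` per muscle
    pair.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if fields is None:
        fields = default_fields()
    if design is None:
        design = ExperimentDesign()
    if template is None:
        template = make_flat_patch_mesh(40, 40, 1.5, m1_band_mm=10.0)
    muscles = tuple(fields.keys())
    conditions = (
        DEFAULT_CONDITIONS
        if design.n_intensities == len(DEFAULT_CONDITIONS)
        else tuple(f"cond{i + 1}" for i in range(design.n_intensities))
    )
    if condition_scale is None:
        condition_scale = (
            dict(DEFAULT_CONDITION_SCALE)
            if conditions == DEFAULT_CONDITIONS
            else {c: 1.0 for c in conditions}
        )
    root = np.random.default_rng(seed)
    subjects: list[SubjectData] = []
    gt_fields: dict[str, dict] = {}
    centroid_rows = []
    overlap_rows = []
    for s in range(n_subjects):
        sid = f"sub{s + 1:02d}"
        rng = np.random.default_rng([seed, 101, s])
        verts = template.vertices.copy()
        if mesh_noise_mm > 0:
            verts[:, 2] += rng.normal(0.0, mesh_noise_mm, size=len(verts))
        mesh = TriSurface(
            verts,
            template.faces.copy(),
            template.curvature.copy(),
            template.atlas_labels.copy(),
            template.sphere.copy() if template.sphere is not None else None,
        )
        subj_fields: dict[str, GroundTruthField] = {}
        for m in muscles:
            f = fields[m]
            jitter = rng.normal(0.0, jitter_mm, size=2) if jitter_mm > 0 else np.zeros(2)
            center = f.center + np.array([jitter[0], jitter[1], 0.0])
            subj_fields[m] = GroundTruthField(m, center, f.sigma, f.peak_amplitude)
        events = design_experiment(design, seed=int(root.integers(2**31)), conditions=conditions)
        positions = np.array([ev.coil_position for ev in events])
        scales = np.array([condition_scale[ev.intensity_condition] for ev in events])
        amp = np.empty((len(events), len(muscles)))
        for mi, m in enumerate(muscles):
            clean = subj_fields[m].noiseless(positions) * scales
            if amplitude_noise_sd_uv > 0:
                clean = clean + rng.normal(0.0, amplitude_noise_sd_uv, size=len(events))
            amp[:, mi] = np.clip(clean, 0.0, None)
        subjects.append(SubjectData(sid, mesh, subj_fields, events, amp))
        gt_fields[sid] = {
            m: {
                "center": subj_fields[m].center.tolist(),
                "sigma": subj_fields[m].sigma,
                "peak_amplitude": subj_fields[m].peak_amplitude,
            }
            for m in muscles
        }
        for m in muscles:
            for cond in conditions:
                # the detectable support scales with the condition's
                # excitability scaling, so the estimand is per condition
                c = _masked_field_centroid(
                    template,
                    subj_fields[m],
                    floor_uv=detection_floor_uv / condition_scale[cond],
                )
                centroid_rows.append(
                    {
                        "subject": sid,
                        "muscle": m,
                        "intensity_condition": cond,
                        "cx": c[0],
                        "cy": c[1],
                        "cz": c[2],
                    }
                )
        for i in range(len(muscles)):
            for j in range(i + 1, len(muscles)):
                fi, fj = subj_fields[muscles[i]], subj_fields[muscles[j]]
                overlap_rows.append(
                    {
                        "subject": sid,
                        "muscle_k": muscles[i],
                        "muscle_l": muscles[j],
                        "disc_iou": disc_iou(
                            fi.center,
                            disc_radius_sigmas * fi.sigma,
                            fj.center,
                            disc_radius_sigmas * fj.sigma,
                        ),
                    }
                )
    ground_truth = {
        "fields": gt_fields,
        "masked_centroids": pd.DataFrame(centroid_rows),
        "disc_overlaps": pd.DataFrame(overlap_rows),
        "disc_radius_sigmas": disc_radius_sigmas,
    }
    return Cohort(
        template=template,
        subjects=subjects,
        design=design,
        muscles=muscles,
        conditions=conditions,
        condition_scale=condition_scale,
        seed=seed,
        ground_truth=ground_truth,
    )
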