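"""End-to-end orchestration: simulate -> detect -> map -> metrics -> stats.

Each stage is a plain function over the library modules so the numbered
analysis scripts, the tests and the acceptance script all drive the same
code. ``run_pipeline`` chains them, optionally writing every table (and
a manifest echoing the configuration) to an output directory; identical
configuration and seed give identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emg as emg_mod
from . import mapping, stats, surface, synthetic

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "detect_cohort", "build_maps", "compute_metrics", "compute_overlaps", "group_statistics"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs; echoed into the manifest."""

    seed: int = 0
    n_subjects: int = 20
    n_intensities: int = 3
    stims_per_block: int = 120
    n_repetitions: int = 2
    inter_stimulus_s: float = 5.0
    grid_extent_mm: float = 50.0
    # synthetic cohort
    field_sigma_mm: float = 5.0
    jitter_mm: float = 2.0
    amplitude_noise_sd_uv: float = 20.0
    mesh_noise_mm: float = 0.3
    patch_nx: int = 40
    patch_ny: int = 40
    patch_spacing_mm: float = 1.5
    m1_band_mm: float = 10.0
    # EMG / detection
    highpass_hz: float = 30.0
    filter_order: int = 2
    response_window_ms: tuple[float, float] = (15.0, 50.0)
    baseline_window_ms: float = 200.0
    # mapping
    radius_mm: float = 5.0
    lambda_curv: float = 1.0
    overlap_mode: str = "geometric"
    m1_mask: bool = True
    region: str = "precentral L"
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "response_window_ms" in raw:
            raw["response_window_ms"] = tuple(raw["response_window_ms"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["response_window_ms"] = list(d["response_window_ms"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: synthetic.Cohort
    mep_table: pd.DataFrame
    maps: dict  # (subject_id, condition, muscle) -> ExcitabilityMap
    metrics: pd.DataFrame
    overlaps: pd.DataFrame
    anova_tables: dict
    posthoc_tables: dict
    counters: dict
    manifest: dict = field(default_factory=dict)


# -- stage 1: simulate ----------------------------------------------------


def simulate_cohort(cfg: RunConfig) -> synthetic.Cohort:
    design = synthetic.ExperimentDesign(
        n_intensities=cfg.n_intensities,
        stims_per_block=cfg.stims_per_block,
        n_repetitions=cfg.n_repetitions,
        inter_stimulus_s=cfg.inter_stimulus_s,
        grid_extent_mm=cfg.grid_extent_mm,
    )
    template = synthetic.make_flat_patch_mesh(
        cfg.patch_nx, cfg.patch_ny, cfg.patch_spacing_mm, m1_band_mm=cfg.m1_band_mm
    )
    return synthetic.make_cohort(
        n_subjects=cfg.n_subjects,
        fields=synthetic.default_fields(sigma_mm=cfg.field_sigma_mm),
        jitter_mm=cfg.jitter_mm,
        seed=cfg.seed,
        design=design,
        template=template,
        amplitude_noise_sd_uv=cfg.amplitude_noise_sd_uv,
        mesh_noise_mm=cfg.mesh_noise_mm,
    )


# -- stage 2: EMG -> MEP table --------------------------------------------


def detect_cohort(cohort: synthetic.Cohort, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Filter every trace and classify it, one row per pulse x muscle.

    Columns: subject, event_id, muscle, intensity_condition, p2p_uv,
    baseline_sd_uv, is_mep, reason.
    """
    cfg = cfg or RunConfig()
    from scipy import signal as ssig

    b, a = ssig.butter(cfg.filter_order, cfg.highpass_hz, btype="highpass", fs=cohort.emg_rate_hz)
    padlen = 3 * max(len(a), len(b))
    rows = []
    for si, subj in enumerate(cohort.subjects):
        conds = [ev.intensity_condition for ev in subj.events]
        for muscle in cohort.muscles:
            raw = np.stack(
                [cohort.emg_trace(si, ei, muscle).samples for ei in range(len(subj.events))]
            )
            filtered = ssig.filtfilt(b, a, raw, axis=1, padlen=padlen)
            t0 = -cohort.emg_pre_ms / 1000.0
            for ei in range(len(subj.events)):
                trace = emg_mod.EMGTrace(filtered[ei], cohort.emg_rate_hz, t0)
                res = emg_mod.detect_mep(
                    trace,
                    response_window_ms=cfg.response_window_ms,
                    baseline_window_ms=cfg.baseline_window_ms,
                )
                rows.append(
                    {
                        "subject": subj.subject_id,
                        "event_id": subj.events[ei].event_id,
                        "muscle": muscle,
                        "intensity_condition": conds[ei],
                        "p2p_uv": res.p2p_uv,
                        "baseline_sd_uv": res.baseline_sd_uv,
                        "is_mep": res.is_mep,
                        "reason": res.reason,
                    }
                )
    return pd.DataFrame(rows)


# -- stage 3: project / mask / warp / interpolate -------------------------


def build_maps(
    cohort: synthetic.Cohort,
    mep_table: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> tuple[dict, dict]:
    """Per subject x condition x muscle excitability maps on the template.

    MEP-positive pulses are projected to the nearest subject vertex,
    masked to the M1 region on the subject surface (order fixed: mask
    before warping), warped to the template via the sphere registration,
    then interpolated to an MEP-weighted vertex map. Returns
    ``(maps, counters)``; muscle x condition cells whose masked MEP set
    is empty are absent from ``maps``.
    """
    cfg = cfg or RunConfig()
    template = cohort.template
    maps: dict = {}
    counters = {"stims_in_mask": 0, "stims_out_of_mask": 0, "mep_positive": 0, "empty_cells": 0}
    for si, subj in enumerate(cohort.subjects):
        positions = np.array([ev.coil_position for ev in subj.events])
        # nearest subject vertex per event (ties -> lowest index)
        d2 = (
            np.sum(positions**2, axis=1)[:, None]
            - 2 * positions @ subj.mesh.vertices.T
            + np.sum(subj.mesh.vertices**2, axis=1)[None, :]
        )
        stim_vertices = np.argmin(d2, axis=1)
        in_mask = (
            subj.mesh.atlas_labels[stim_vertices] == cfg.region
            if cfg.m1_mask
            else np.ones(len(stim_vertices), dtype=bool)
        )
        counters["stims_in_mask"] += int(in_mask.sum())
        counters["stims_out_of_mask"] += int((~in_mask).sum())
        sub_meps = mep_table[mep_table.subject == subj.subject_id]
        for cond in cohort.conditions:
            cond_events = np.array([ev.intensity_condition == cond for ev in subj.events])
            for muscle in cohort.muscles:
                mrows = sub_meps[(sub_meps.muscle == muscle) & sub_meps.is_mep]
                positive = np.zeros(len(subj.events), dtype=bool)
                positive[mrows.event_id.to_numpy()] = True
                amp_by_event = np.zeros(len(subj.events))
                amp_by_event[mrows.event_id.to_numpy()] = mrows.p2p_uv.to_numpy()
                keep = cond_events & in_mask & positive
                counters["mep_positive"] += int((cond_events & positive).sum())
                if not keep.any():
                    counters["empty_cells"] += 1
                    continue
                tmpl_vertices, amps = surface.warp_events(
                    stim_vertices[keep],
                    amp_by_event[keep],
                    subj.mesh,
                    template,
                    lambda_curv=cfg.lambda_curv,
                )
                emap = mapping.interpolate_to_vertices(
                    tmpl_vertices,
                    amps,
                    template,
                    radius_mm=cfg.radius_mm,
                    muscle_label=muscle,
                    intensity_condition=cond,
                )
                maps[(subj.subject_id, cond, muscle)] = emap
    return maps, counters


# -- stage 4: metrics and overlaps ----------------------------------------


def compute_metrics(maps: dict) -> pd.DataFrame:
    rows = []
    for (sid, cond, muscle), emap in maps.items():
        c = mapping.centroid(emap)
        rows.append(
            {
                "subject": sid,
                "intensity_condition": cond,
                "muscle": muscle,
                "Cx": c[0],
                "Cy": c[1],
                "Cz": c[2],
                "W_size": mapping.area_size(emap),
                "n_vertices": len(emap),
            }
        )
    return pd.DataFrame(rows)


def compute_overlaps(maps: dict, mode: str = "geometric") -> pd.DataFrame:
    """28-row overlap table per subject x condition, with group/synergy labels."""
    pairs = mapping.pair_grouping()
    keys = pd.DataFrame(
        [(s, c, m) for (s, c, m) in maps.keys()],
        columns=["subject", "cond", "muscle"],
    )
    rows = []
    for (sid, cond), _ in keys.groupby(["subject", "cond"]):
        for rec in pairs.itertuples(index=False):
            mk = maps.get((sid, cond, rec.muscle_k))
            ml = maps.get((sid, cond, rec.muscle_l))
            o = (
                mapping.overlap(mk, ml, mode=mode)
                if mk is not None and ml is not None
                else np.nan
            )
            rows.append(
                {
                    "subject": sid,
                    "intensity_condition": cond,
                    "muscle_k": rec.muscle_k,
                    "muscle_l": rec.muscle_l,
                    "pair_group": rec.pair_group,
                    "synergistic": rec.synergistic,
                    "overlap": o,
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


# -- stage 5: group statistics ---------------------------------------------


def group_statistics(
    metrics_table: pd.DataFrame, overlap_table: pd.DataFrame
) -> tuple[dict, dict]:
    """RM-ANOVAs mirroring the study design.

    Muscle x Intensity on each centroid component and on the area size;
    Muscle-Group x Intensity on the pair overlaps (averaged within group
    per subject x condition); Bonferroni post-hocs for the overlap
    factors.
    """
    anova_tables: dict = {}
    posthoc_tables: dict = {}
    for dv in ["Cx", "Cy", "Cz", "W_size"]:
        anova_tables[dv] = stats.rm_anova_2way(
            metrics_table.rename(columns={dv: "value"}),
            dv="value",
            subject="subject",
            factors=("muscle", "intensity_condition"),
        )
    ov = overlap_table.dropna(subset=["overlap"]).copy()
    grouped = ov.groupby(
        ["subject", "pair_group", "intensity_condition"], as_index=False
    )["overlap"].mean()
    anova_tables["overlap"] = stats.rm_anova_2way(
        grouped,
        dv="overlap",
        subject="subject",
        factors=("pair_group", "intensity_condition"),
    )
    for eff in ["pair_group", "intensity_condition"]:
        posthoc_tables[f"overlap_{eff}"] = stats.bonferroni_posthoc(
            grouped, eff, dv="overlap", subject="subject",
            factors=("pair_group", "intensity_condition"),
        )
    return anova_tables, posthoc_tables


# -- orchestration ----------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage on a synthetic cohort; optionally write outputs."""
    cohort = simulate_cohort(cfg)
    mep_table = detect_cohort(cohort, cfg)
    maps, counters = build_maps(cohort, mep_table, cfg)
    metrics_table = compute_metrics(maps)
    overlap_table = compute_overlaps(maps, mode=cfg.overlap_mode)
    anova_tables, posthoc_tables = group_statistics(metrics_table, overlap_table)
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_subjects": cfg.n_subjects,
        "n_events": cohort.n_events,
        "n_traces": cohort.n_traces,
        "counters": counters,
    }
    result = PipelineResult(
        cohort, mep_table, maps, metrics_table, overlap_table,
        anova_tables, posthoc_tables, counters, manifest,
    )
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        mep_table.to_csv(out / "mep_table.csv", index=False)
        metrics_table.to_csv(out / "metrics.csv", index=False)
        overlap_table.to_csv(out / "overlaps.csv", index=False)
        for name, tab in anova_tables.items():
            tab.to_csv(out / f"anova_{name}.csv")
        for name, tab in posthoc_tables.items():
            tab.to_csv(out / f"posthoc_{name}.csv", index=False)
        manifest_out = dict(manifest)
        manifest_out["config"]["response_window_ms"] = list(
            manifest_out["config"]["response_window_ms"]
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest_out, fh, indent=2, default=str)
        cfg.to_yaml(out / "config.yaml")
    return result
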