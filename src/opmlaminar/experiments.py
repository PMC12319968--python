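"""Sweep orchestration: repeat laminar inference across simulated sources
and condition grids (SNR, sensor density, measurement axes, scalp offsets,
co-registration error, patch-size congruence, brain noise, generative-model
mismatch) and summarise classification accuracy and bias.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import geometry as geo
from .forward import HeadConductor, leadfield_for_surface
from .laminar import LayerModel, roi_decision, whole_brain_decision
from .simulate import SnrSpec, add_brain_noise, add_noise, gaussian_patch, simulate_signal

__all__ = ["SweepConfig", "run_sweep", "summarize", "derive_seed"]

CONDITION_COLUMNS = [
    "noise_db",
    "spacing_mm",
    "n_axes",
    "offset_mm",
    "fiducial_sd_mm",
    "sim_fwhm_mm",
    "rec_fwhm_mm",
]


def derive_seed(*parts) -> int:
    """Stable sub-seed from a master seed and a condition tuple.

    CRC32 of the joined string representation, masked below 2^31, so adding
    a condition never changes the draws of the others.
    """
    key = "|".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class SweepConfig:
    """Full factorial simulation sweep over array and noise conditions.

    ``noise_db`` is interpreted per ``noise_mode``: single-trial SNR levels
    (default) or fixed-magnitude levels with ``reference_amplitude`` (fT).
    ``patch_fwhm_pairs`` holds (simulated, reconstructed) patch sizes, so
    congruent and incongruent designs are grid cells.  ``generative_model``
    "AGM" simulates from a perturbed geometry (jittered sensors, resampled
    cortical layers) while reconstruction keeps the original model.
    """

    noise_db: list = field(default_factory=lambda: [-5.0])
    noise_mode: str = "per_trial_snr"
    reference_amplitude: float | None = None
    spacing_mm: list = field(default_factory=lambda: [35.0])
    n_axes: list = field(default_factory=lambda: [1])
    offset_mm: list = field(default_factory=lambda: [6.5])
    fiducial_sd_mm: list = field(default_factory=lambda: [0.0])
    patch_fwhm_pairs: list = field(default_factory=lambda: [(5.0, 5.0)])
    brain_noise_n_sources: int = 0
    brain_noise_relative_strength: float = 0.4
    generative_model: str = "GM"
    n_sources: int = 60
    methods: list = field(default_factory=lambda: ["EBB", "MSP"])
    analyses: list = field(default_factory=lambda: ["whole_brain", "roi"])
    n_trials: int = 200
    fs: float = 200.0
    amplitude_nam: float = 10.0
    freq_hz: float = 20.0
    waveform: str = "sine"
    white_radius_mm: float = 70.0
    pial_radius_mm: float = 72.0
    scalp_radius_mm: float = 85.0
    subdivisions: int = 4
    bump_amplitude_mm: float = 0.0
    msp_n_patch_centres: int = 256
    msp_include_true_vertex: bool = True
    n_spatial_modes: int = 274
    n_temporal_modes: int = 4
    master_seed: int = 0

    def validate(self) -> None:
        for name in ("noise_db", "spacing_mm", "n_axes", "offset_mm",
                     "fiducial_sd_mm", "patch_fwhm_pairs", "methods", "analyses"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be a non-empty list")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.noise_mode not in ("per_trial_snr", "fixed_magnitude"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.noise_mode == "fixed_magnitude" and self.reference_amplitude is None:
            raise ValueError("fixed_magnitude mode needs reference_amplitude")
        if self.generative_model not in ("GM", "AGM"):
            raise ValueError("generative_model must be GM or AGM")
        for m in self.methods:
            if m.upper() not in ("EBB", "MSP", "IID", "COH"):
                raise ValueError(f"unknown method {m!r}")
        for a in self.analyses:
            if a not in ("whole_brain", "roi"):
                raise ValueError(f"unknown analysis {a!r}")

    def conditions(self) -> list[tuple]:
        return list(
            itertools.product(
                self.noise_db,
                self.spacing_mm,
                self.n_axes,
                self.offset_mm,
                self.fiducial_sd_mm,
                [tuple(p) for p in self.patch_fwhm_pairs],
            )
        )

    def expected_rows(self) -> int:
        return (
            len(self.conditions())
            * 2
            * self.n_sources
            * len(self.analyses)
            * len(self.methods)
        )

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_array(scalp, spacing, n_axes, offset, seed):
    array = geo.pack_sensors(scalp, spacing, seed=seed)
    array = geo.build_channel_axes(array, n_axes)
    return geo.offset_sensors(array, scalp, offset)


def _conductor_for(space, sim_space, array, sim_array) -> HeadConductor:
    r_src = max(
        np.linalg.norm(space.pial.vertices, axis=1).max(),
        np.linalg.norm(sim_space.pial.vertices, axis=1).max(),
    )
    r_sens = min(
        np.linalg.norm(array.positions, axis=1).min(),
        np.linalg.norm(sim_array.positions, axis=1).min(),
    )
    if r_sens <= r_src:
        raise ValueError("sensors not outside the source space")
    return HeadConductor(np.zeros(3), 0.5 * (r_src + r_sens))


def run_sweep(config: SweepConfig, cache_dir=None, progress: bool = False) -> pd.DataFrame:
    """Run every condition cell of the sweep and return the decision table.

    One row per condition x surface x source x analysis x method.  Failures
    of individual cells are recorded in the ``error`` column and never abort
    the sweep.  With ``cache_dir``, completed condition cells are stored as
    TSV and skipped on re-runs with the same configuration.
    """
    config.validate()
    cfg_hash = config.content_hash()
    if cache_dir is not None:
        from pathlib import Path

        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)

    space, scalp = geo.make_head_geometry(
        config.white_radius_mm,
        config.pial_radius_mm,
        config.scalp_radius_mm,
        config.subdivisions,
        config.bump_amplitude_mm,
        seed=derive_seed(config.master_seed, "geometry"),
    )

    all_rows: list[dict] = []
    geometry_cache: dict = {}

    for cond in config.conditions():
        noise_db, spacing, n_axes, offset, fid_sd, (sim_fwhm, rec_fwhm) = cond
        cond_dict = dict(zip(CONDITION_COLUMNS, (noise_db, spacing, n_axes, offset, fid_sd, sim_fwhm, rec_fwhm)))
        cell_tag = hashlib.sha1(
            f"{cfg_hash}|{cond}".encode()
        ).hexdigest()[:16]
        if cache_dir is not None:
            cell_file = cache_dir / f"cell_{cell_tag}.tsv"
            if cell_file.exists():
                cached = pd.read_csv(cell_file, sep="\t")
                cached["error"] = cached["error"].fillna("")
                cached["decision"] = cached["decision"].fillna("")
                all_rows.extend(cached.to_dict("records"))
                continue
        rows = _run_cell(
            config, space, scalp, geometry_cache, cond_dict,
            noise_db, spacing, n_axes, offset, fid_sd, sim_fwhm, rec_fwhm,
        )
        if cache_dir is not None:
            tmp = cache_dir / f"cell_{cell_tag}.tsv.tmp"
            pd.DataFrame(rows).to_csv(tmp, sep="\t", index=False)
            tmp.replace(cache_dir / f"cell_{cell_tag}.tsv")
        if progress:
            done = sum(1 for r in rows if not r["error"])
            print(f"condition {cond}: {done}/{len(rows)} decisions")
        all_rows.extend(rows)

    df = pd.DataFrame(all_rows)
    return df.sort_values(
        CONDITION_COLUMNS + ["true_surface", "source_index", "analysis", "method"]
    ).reset_index(drop=True)


def _run_cell(
    config, space, scalp, geometry_cache, cond_dict,
    noise_db, spacing, n_axes, offset, fid_sd, sim_fwhm, rec_fwhm,
) -> list[dict]:
    master = config.master_seed
    geo_key = (spacing, n_axes, offset)
    if geo_key not in geometry_cache:
        array = _build_array(
            scalp, spacing, n_axes, offset, seed=derive_seed(master, "pack", spacing)
        )
        if config.generative_model == "AGM":
            sim_space, sim_array = geo.make_alternative_geometry(
                space, array, sensor_jitter_sd_mm=1.0,
                seed=derive_seed(master, "agm", spacing, n_axes, offset),
            )
        else:
            sim_space, sim_array = space, array
        conductor = _conductor_for(space, sim_space, array, sim_array)
        lf_rec = {
            "pial": leadfield_for_surface(space.pial, array, conductor, "pial"),
            "white": leadfield_for_surface(space.white, array, conductor, "white"),
        }
        same_model = sim_space is space and sim_array is array
        lf_sim = lf_rec if same_model else {
            "pial": leadfield_for_surface(sim_space.pial, sim_array, conductor, "pial"),
            "white": leadfield_for_surface(sim_space.white, sim_array, conductor, "white"),
        }
        lf_mid = (
            leadfield_for_surface(sim_space.mid, sim_array, conductor, "mid")
            if config.brain_noise_n_sources > 0
            else None
        )
        geometry_cache[geo_key] = (array, sim_space, sim_array, conductor, lf_rec, lf_sim, lf_mid)
    array, sim_space, sim_array, conductor, lf_rec, lf_sim, lf_mid = geometry_cache[geo_key]

    src_seed = derive_seed(master, "sources", spacing, n_axes, offset, config.generative_model)
    rng_src = np.random.default_rng(src_seed)
    source_vertices = {
        surf: rng_src.choice(
            getattr(sim_space, surf).n_vertices, size=config.n_sources, replace=False
        )
        for surf in ("pial", "white")
    }

    rows: list[dict] = []
    for surf in ("pial", "white"):
        sim_mesh = getattr(sim_space, surf)
        for s_idx, vertex in enumerate(source_vertices[surf]):
            vertex = int(vertex)
            cell_seed = derive_seed(
                master, "trial", noise_db, spacing, n_axes, offset,
                fid_sd, sim_fwhm, rec_fwhm, surf, s_idx,
            )
            try:
                dataset, rec_models = _simulate_and_models(
                    config, space, sim_space, array, conductor, sim_mesh, surf,
                    vertex, lf_sim, lf_rec, lf_mid, noise_db, fid_sd, sim_fwhm,
                    cell_seed,
                )
            except Exception as exc:  # pragma: no cover - defensive
                for method in config.methods:
                    for analysis in config.analyses:
                        rows.append(
                            dict(cond_dict, true_surface=surf, source_index=s_idx,
                                 source_vertex=vertex, analysis=analysis,
                                 method=method.upper(), metric=np.nan,
                                 decision="", significant=False, correct=False,
                                 seed=cell_seed, error=str(exc))
                        )
                continue
            include = None
            if (
                config.msp_include_true_vertex
                and config.generative_model == "GM"
            ):
                include = {surf: [vertex]}
            for method in config.methods:
                for analysis in config.analyses:
                    row = dict(cond_dict, true_surface=surf, source_index=s_idx,
                               source_vertex=vertex, analysis=analysis,
                               method=method.upper(), metric=np.nan, decision="",
                               significant=False, correct=False,
                               seed=cell_seed, error="")
                    try:
                        kwargs = dict(
                            method=method,
                            patch_fwhm_mm=rec_fwhm,
                            n_patch_centres=config.msp_n_patch_centres,
                            include_vertices=include,
                            n_spatial_modes=config.n_spatial_modes,
                            n_temporal_modes=config.n_temporal_modes,
                            msp_seed=derive_seed(cell_seed, "msp"),
                            ground_truth_surface=surf,
                        )
                        if analysis == "whole_brain":
                            dec = whole_brain_decision(
                                dataset, rec_models["pial"], rec_models["white"], **kwargs
                            )
                        else:
                            dec = roi_decision(
                                dataset, rec_models["pial"], rec_models["white"], **kwargs
                            )
                        row.update(
                            metric=dec.metric,
                            decision=dec.inferred_surface,
                            significant=dec.significant,
                            correct=bool(dec.correct),
                        )
                    except Exception as exc:
                        row["error"] = str(exc)
                    rows.append(row)
    return rows


def _simulate_and_models(
    config, space, sim_space, array, conductor, sim_mesh, surf, vertex,
    lf_sim, lf_rec, lf_mid, noise_db, fid_sd, sim_fwhm, cell_seed,
):
    patch = gaussian_patch(sim_mesh, vertex, sim_fwhm)
    dataset = simulate_signal(
        patch,
        lf_sim[surf],
        amplitude_nam=config.amplitude_nam,
        freq_hz=config.freq_hz,
        fs=config.fs,
        n_trials=config.n_trials,
        waveform=config.waveform,
        seed=derive_seed(cell_seed, "waveform"),
    )
    if config.brain_noise_n_sources > 0:
        dataset = add_brain_noise(
            dataset,
            lf_mid,
            mid_mesh=sim_space.mid,
            n_sources=config.brain_noise_n_sources,
            relative_strength=config.brain_noise_relative_strength,
            fwhm_mm=sim_fwhm,
            seed=derive_seed(cell_seed, "brain_noise"),
        )
    spec = SnrSpec(
        mode=config.noise_mode,
        value_db=noise_db,
        reference_amplitude=config.reference_amplitude,
    )
    dataset = add_noise(dataset, spec, seed=derive_seed(cell_seed, "noise"))

    if fid_sd > 0:
        pert_array, _ = geo.perturb_fiducials(
            array, fid_sd, seed=derive_seed(cell_seed, "fiducials")
        )
        lf_pial = leadfield_for_surface(space.pial, pert_array, conductor, "pial")
        lf_white = leadfield_for_surface(space.white, pert_array, conductor, "white")
    else:
        lf_pial, lf_white = lf_rec["pial"], lf_rec["white"]
    rec_models = {
        "pial": LayerModel(space.pial, lf_pial, "pial"),
        "white": LayerModel(space.white, lf_white, "white"),
    }
    return dataset, rec_models


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition percent correct / percent pial / percent significant
    with binomial standard errors."""
    if table.empty:
        raise ValueError("empty experiment table")
    ok = table[table["error"].fillna("") == ""] if "error" in table else table
    group_cols = [c for c in CONDITION_COLUMNS if c in ok.columns] + ["analysis", "method"]

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        p_c = g["correct"].mean()
        p_p = (g["decision"] == "pial").mean()
        p_s = g["significant"].mean()
        return pd.Series(
            dict(
                n=n,
                pct_correct=100.0 * p_c,
                pct_pial=100.0 * p_p,
                pct_significant=100.0 * p_s,
                se_correct=100.0 * np.sqrt(p_c * (1 - p_c) / n),
                se_pial=100.0 * np.sqrt(p_p * (1 - p_p) / n),
            )
        )

    out = ok.groupby(group_cols, dropna=False).apply(_agg, include_groups=False)
    return out.reset_index()
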