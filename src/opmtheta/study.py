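"""End-to-end synthetic study: paired wearable-OPM / cryogenic-SQUID
sessions for a cohort, four OPM processing variants (triaxial/radial ×
with/without homogeneous field correction), beamformer imaging, SNR tables,
slope fits and fingerprinting.

Defaults match the full study conditions (cohort 14, 1200 Hz, full trial counts,
4 mm grid); reduced configurations for quick runs are provided by
:func:`StudyConfig.reduced`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import localise as loc
from . import nulling, preprocess, spectral, stats, synth
from .forward import HeadModel, LeadFieldGrid, build_leadfield_grid

__all__ = ["StudyConfig", "StudyReport", "run_study", "run_nulling_study"]

VARIANTS = ("triaxial_hfc", "triaxial_nohfc", "radial_hfc", "radial_nohfc")


@dataclass
class StudyConfig:
    cohort_size: int = 14
    master_seed: int = 0
    fs: float = 1200.0
    n_trials: int = 25
    on_s: float = 20.0
    off_s: float = 20.0
    opm_sites: int = 58
    squid_sites: int = 275
    grid_spacing: float = 0.004
    variants: tuple = VARIANTS
    fingerprint_iterations: int = 100_000
    theta_band: tuple = (4.0, 8.0)
    contrast_on: tuple = (5.0, 20.0)
    contrast_off: tuple = (24.0, 39.0)
    task_window: tuple = (0.0, 20.0)
    rest_window: tuple = (20.0, 40.0)

    @classmethod
    def reduced(cls, **overrides) -> "StudyConfig":
        """Small configuration for quick, deterministic runs."""
        base = dict(
            cohort_size=6,
            fs=240.0,
            n_trials=6,
            on_s=10.0,
            off_s=10.0,
            grid_spacing=0.008,
            fingerprint_iterations=20_000,
        )
        base.update(overrides)
        cfg = cls(**base)
        scale = cfg.on_s / 20.0
        return replace(
            cfg,
            contrast_on=(5.0 * scale, 20.0 * scale),
            contrast_off=(24.0 * scale, 39.0 * scale),
            task_window=(0.0, 20.0 * scale),
            rest_window=(20.0 * scale, 40.0 * scale),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        for k in ("variants", "theta_band", "contrast_on", "contrast_off", "task_window", "rest_window"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def subset_grid(grid: LeadFieldGrid, channel_idx, system_tag) -> LeadFieldGrid:
    """Restrict a lead-field grid to a channel subset (e.g. radial-only)."""
    return LeadFieldGrid(
        grid.voxel_centres, grid.leadfields[:, channel_idx, :], grid.spacing, grid.head, system_tag
    )


def _radial_indices(array) -> np.ndarray:
    normals = array.site_positions / np.linalg.norm(array.site_positions, axis=1, keepdims=True)
    cosines = np.abs(np.einsum("sai,si->sa", array.site_triads, normals))
    best = cosines.argmax(axis=1)
    return np.arange(array.n_sites) * array.n_axes + best


def analyse_theta_session(
    recording,
    grid: LeadFieldGrid,
    cfg: StudyConfig,
    use_hfc: bool,
    empty_recording=None,
    array=None,
):
    """Theta-band beamformer analysis of one session.

    Band-pass to theta, optional homogeneous field correction, whole-session
    covariance with 2 % Tikhonov regularisation, LCMV weights per voxel,
    pseudo-T contrast between task and rest windows, peak search in the
    frontal mask, virtual electrode, Hilbert envelope and SNR.
    """
    array = array if array is not None else recording.array
    rec = preprocess.bandpass(
        recording, preprocess.FilterSpec(cfg.theta_band[0], cfg.theta_band[1])
    )
    projector = None
    data = rec.data
    if use_hfc:
        projector = preprocess.hfc_projector(array)
        data = projector @ data
        rec = rec.copy_with(data)
    trials = preprocess.segment_trials(rec, cfg.on_s + cfg.off_s)
    trials, report = preprocess.reject_bad_trials(trials)

    C = loc.compute_covariance(trials)
    C_reg = loc.regularise(C, 0.02)
    weights = loc.compute_weights_grid(grid, C_reg, projector=projector)
    C_on = loc.compute_covariance(trials, cfg.contrast_on)
    C_off = loc.compute_covariance(trials, cfg.contrast_off)
    image = loc.pseudo_t_image(weights, C_on, C_off, (cfg.contrast_on, cfg.contrast_off))
    peak = loc.find_peak(
        image, loc.region_mask(grid.voxel_centres, "frontal", grid.head.source_radius_max)
    )
    w = weights.weights[peak]
    ve_trials = np.einsum("c,tcs->ts", w, trials.data)
    sd = ve_trials.std()
    if sd > 0:
        ve_trials = ve_trials / sd
    env = spectral.hilbert_envelope(
        ve_trials, rec.fs, off_window=cfg.contrast_off
    )
    snr = spectral.snr_nback(env, cfg.task_window, cfg.rest_window)
    inst = spectral.instantaneous_snr(env, cfg.rest_window)
    out = dict(
        image=image,
        peak_voxel=peak,
        peak_position=grid.voxel_centres[peak],
        snr=snr,
        envelope=env,
        instantaneous_snr=inst,
        rejection=report,
        weights_peak=w,
    )
    if empty_recording is not None:
        filt = preprocess.bandpass(
            empty_recording, preprocess.FilterSpec(cfg.theta_band[0], cfg.theta_band[1])
        )
        ed = projector @ filt.data if projector is not None else filt.data
        ve = loc.project_empty_room(w, filt.copy_with(ed))
        out["empty_room_asd"] = spectral.welch_asd(
            ve.timecourse / (sd if sd > 0 else 1.0), rec.fs, segment=cfg.on_s, overlap=cfg.on_s / 2
        )
    return out


@dataclass
class StudyReport:
    config: StudyConfig
    snr_table: pd.DataFrame
    slopes: dict
    fingerprint: stats.FingerprintResult
    group_slopes: dict
    peak_positions: pd.DataFrame
    failures: list = field(default_factory=list)

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.snr_table.to_csv(out / "snr_table.tsv", sep="\t", index=False)
        self.peak_positions.to_csv(out / "peak_positions.tsv", sep="\t", index=False)
        with open(out / "slopes.json", "w") as fh:
            json.dump(
                {k: json.loads(v.to_json()) for k, v in self.slopes.items()},
                fh,
                indent=1,
            )
        self.fingerprint.to_json(out / "fingerprint.json")
        pd.DataFrame(self.fingerprint.matrix).to_csv(
            out / "fingerprint_matrix.tsv", sep="\t", index=False, header=False
        )
        with open(out / "group_slopes.json", "w") as fh:
            json.dump(self.group_slopes, fh, indent=1)
        with open(out / "provenance.json", "w") as fh:
            json.dump(dict(config=asdict(self.config), failures=self.failures), fh, indent=1, default=str)


def run_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Simulate the cohort, run every processing variant, and compare systems."""
    head = HeadModel()
    opm_array = synth.build_array("opm_triaxial", n_sites=config.opm_sites)
    squid_array = synth.build_array("squid_radial", n_sites=config.squid_sites)
    opm_grid = build_leadfield_grid(head, opm_array, config.grid_spacing)
    squid_grid = build_leadfield_grid(head, squid_array, config.grid_spacing)
    rad_idx = _radial_indices(opm_array)
    radial_array, _ = preprocess.select_radial(opm_array)
    radial_grid = subset_grid(opm_grid, rad_idx, radial_array.system_tag)

    cohort = synth.gen_cohort(
        n_subjects=config.cohort_size,
        task="nback",
        master_seed=config.master_seed,
        fs=config.fs,
        n_trials=config.n_trials,
        on=config.on_s,
        off=config.off_s,
    )

    rows, peaks, failures = [], [], []
    images = {"opm": [], "squid": []}
    inst_acc = {}
    for subj in cohort:
        sid = subj["subject"]
        try:
            rec_opm, empty_opm = synth.simulate_session(
                subj["sessions"]["opm"], head, opm_array
            )
            rec_squid, _ = synth.simulate_session(subj["sessions"]["squid"], head, squid_array)
            for variant in config.variants:
                radial = variant.startswith("radial")
                use_hfc = variant.endswith("_hfc")
                if radial:
                    sub_array, sub_data = preprocess.select_radial(opm_array, rec_opm.data)
                    rec_v = synth.Recording(sub_data, rec_opm.fs, rec_opm.events, sub_array)
                    res = analyse_theta_session(rec_v, radial_grid, config, use_hfc)
                else:
                    res = analyse_theta_session(
                        rec_opm, opm_grid, config, use_hfc, empty_recording=empty_opm
                    )
                rows.append(
                    dict(subject=sid, system="opm", variant=variant, snr=res["snr"])
                )
                peaks.append(
                    dict(
                        subject=sid,
                        system="opm",
                        variant=variant,
                        x=res["peak_position"][0],
                        y=res["peak_position"][1],
                        z=res["peak_position"][2],
                        true_x=subj["position"][0],
                        true_y=subj["position"][1],
                        true_z=subj["position"][2],
                    )
                )
                if variant == "triaxial_hfc":
                    images["opm"].append(res["image"])
                inst_acc.setdefault(("opm", variant), []).append(res["instantaneous_snr"])
                time_axis = res["envelope"].time
            res_sq = analyse_theta_session(rec_squid, squid_grid, config, use_hfc=False)
            rows.append(dict(subject=sid, system="squid", variant="radial", snr=res_sq["snr"]))
            peaks.append(
                dict(
                    subject=sid,
                    system="squid",
                    variant="radial",
                    x=res_sq["peak_position"][0],
                    y=res_sq["peak_position"][1],
                    z=res_sq["peak_position"][2],
                    true_x=subj["position"][0],
                    true_y=subj["position"][1],
                    true_z=subj["position"][2],
                )
            )
            images["squid"].append(res_sq["image"])
            inst_acc.setdefault(("squid", "radial"), []).append(res_sq["instantaneous_snr"])
        except Exception as err:  # pragma: no cover - partial-failure path
            failures.append(dict(subject=sid, error=repr(err)))

    snr_table = pd.DataFrame(rows)
    squid_snr = (
        snr_table[snr_table.system == "squid"].sort_values("subject")["snr"].to_numpy()
    )
    slopes = {}
    for variant in config.variants:
        sel = snr_table[(snr_table.system == "opm") & (snr_table.variant == variant)]
        opm_snr = sel.sort_values("subject")["snr"].to_numpy()
        if len(opm_snr) == len(squid_snr) and len(opm_snr) >= 3:
            slopes[variant] = stats.snr_slope_fit(squid_snr, opm_snr)

    fp = stats.fingerprint_matrix(images["opm"], images["squid"])
    fp.p_value = stats.monte_carlo_within_between(
        fp.matrix,
        n_iter=config.fingerprint_iterations,
        seed=synth.subject_seed(config.master_seed, 0, "fingerprint"),
    )
    fp.n_iterations = config.fingerprint_iterations

    sq_mean = np.mean(inst_acc[("squid", "radial")], axis=0)
    group_slopes = {}
    for variant in config.variants:
        opm_mean = np.mean(inst_acc[("opm", variant)], axis=0)
        group_slopes[variant] = stats.group_slope(
            opm_mean, sq_mean, time_axis, config.task_window, config.rest_window
        )

    return StudyReport(
        config,
        snr_table,
        slopes,
        fp,
        group_slopes,
        pd.DataFrame(peaks),
        failures,
    )


def run_nulling_study(
    n_seeds: int = 100,
    n_iterations: int = 2,
    start_magnitude_nT: float = 0.9,
    master_seed: int = 0,
    threshold_pT: float = 300.0,
    **overrides,
):
    """Monte-Carlo of the iterative nulling procedure.

    Returns ``(per-seed DataFrame, summary dict)``: per seed and iteration the
    fitted and residual field magnitudes, and overall the median final
    residual and the fraction of seeds below ``threshold_pT``.
    """
    rows = []
    for k in range(n_seeds):
        seed = synth.subject_seed(master_seed, k, "nulling")
        rng = np.random.default_rng(seed)
        start = nulling.random_start_field(rng, magnitude_nT=start_magnitude_nT)
        log = nulling.run_nulling(
            start, n_iterations=n_iterations, seed=int(rng.integers(2**31 - 1)), **overrides
        )
        for e in log.entries:
            rows.append(
                dict(
                    seed_index=k,
                    iteration=e["iteration"],
                    before_nT=start_magnitude_nT if e["iteration"] == 1 else None,
                    residual_pT=e["residual_magnitude_nT"] * 1e3,
                    residual_gradient_nT_per_m=e["residual_gradient_nT_per_m"],
                )
            )
    df = pd.DataFrame(rows)
    final = df[df.iteration == n_iterations]["residual_pT"]
    summary = dict(
        n_seeds=n_seeds,
        n_iterations=n_iterations,
        start_magnitude_nT=start_magnitude_nT,
        median_final_residual_pT=float(final.median()),
        fraction_below_threshold=float((final < threshold_pT).mean()),
        threshold_pT=threshold_pT,
    )
    return df, summary
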