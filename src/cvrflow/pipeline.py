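"""Subject- and cohort-level orchestration.

``analyze_subject`` composes the stages — edema-excluded GM extraction,
wavelet de-noising, CO2 resampling and bulk alignment, exponential-HRF tau
fitting, inflow-voxel selection, skew-normal peak fitting, and the lag
analyses — on in-memory containers. ``run_subject`` wraps it with file I/O
and config validation; ``cohort_stats``/``run_cohort`` aggregate subject
reports into the group regressions and the paired pre/post comparison.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cvio
from .containers import BoldSeries, MaskVolume, PhysioTrace
from .errors import ConfigurationError, FitFailureError
from .inflow import (
    DEFAULT_INFLOW_WINDOW,
    average_voxel_trace,
    fit_inflow_peak,
    select_inflow_voxels,
)
from .preprocess import (
    bulk_align,
    denoise_wavelet,
    dilate_mask,
    extract_regional_mean,
    resample_trace,
    temporal_derivative,
)
from .simulate import RespiratoryProtocol, epoch_volume_range, inflow_fit_window
from .stats import GroupRecord, edema_fraction, paired_change_test, regress, shifted_crosscorr
from .tau import DEFAULT_TAU_WINDOW, fit_tau

logger = logging.getLogger("cvrflow")

__all__ = [
    "AnalysisOptions",
    "PipelineConfig",
    "analyze_subject",
    "run_subject",
    "cohort_stats",
    "run_cohort",
    "inflow_peak_ratio",
]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis parameters with the defaults used throughout.

    Windows are volume-index pairs (inclusive). ``inflow_window=None``
    derives the window from the protocol (block end to the midpoint toward
    the ramp peak) when a protocol is available, else falls back to the
    static default. ``inflow_threshold`` is the peak-over-baseline-noise
    ratio above which a dataset counts as showing inflow signal.
    """

    tau_window: tuple[int, int] = DEFAULT_TAU_WINDOW
    tau_grid_max: float = 120.0
    tau_grid_step: float = 0.5
    include_drift: bool = False
    inflow_window: tuple[int, int] | None = None
    denoise_family: str = "sym4"
    denoise_level: int = 2
    edema_dilation: int = 1
    dilation_connectivity: int = 6
    n_bottom_slices: int = 2
    k_voxels: int = 5
    bulk_max_lag: int = 50  # volumes
    lag_max_s: float = 30.0
    inflow_threshold: float = 3.0
    baseline_window: tuple[int, int] = (10, 150)

    def tau_grid(self) -> np.ndarray:
        return np.arange(self.tau_grid_step, self.tau_grid_max + 1e-9,
                         self.tau_grid_step)


def inflow_peak_ratio(
    trace: np.ndarray,
    search_window: tuple[int, int],
    baseline_window: tuple[int, int],
    noise_trace: np.ndarray | None = None,
) -> float:
    """Peak excursion in a window relative to baseline measurement noise.

    The peak is the maximum of ``trace`` over the search window above the
    median baseline level (a constant level — extrapolating a trend fit far
    beyond the baseline window would inject spurious excursions). The noise
    scale is the SD of the linearly detrended baseline segment of
    ``noise_trace`` — normally the raw, un-denoised trace, since smoothing
    would understate the measurement noise; it defaults to ``trace``.
    """
    t = np.arange(trace.size, dtype=float)
    b0, b1 = baseline_window
    s0, s1 = search_window
    noise = trace if noise_trace is None else np.asarray(noise_trace, float)
    coef = np.polyfit(t[b0 : b1 + 1], noise[b0 : b1 + 1], 1)
    resid_sd = float(np.std(noise[b0 : b1 + 1] - np.polyval(coef, t[b0 : b1 + 1])))
    level = float(np.median(trace[b0 : b1 + 1]))
    excursion = float(np.max(trace[s0 : s1 + 1]) - level)
    if resid_sd == 0:
        return math.inf if excursion > 0 else 0.0
    return excursion / resid_sd


def analyze_subject(
    bold: BoldSeries,
    masks: MaskVolume,
    co2: PhysioTrace,
    o2: PhysioTrace | None = None,
    options: AnalysisOptions | None = None,
    protocol: RespiratoryProtocol | None = None,
    subject_id: str = "subject",
    timepoint: str = "pre",
    seed: int = 0,
) -> dict:
    """Run the full single-subject analysis on in-memory data.

    Returns a JSON-serializable report with the bulk alignment, tau fit,
    inflow peak fit, lag analyses and edema fraction.
    """
    opts = options or AnalysisOptions()
    n, tr = bold.n_volumes, bold.tr
    for name, (w0, w1) in (("tau_window", opts.tau_window),
                           ("baseline_window", opts.baseline_window)):
        if not (0 <= w0 < w1 < n):
            raise ConfigurationError(f"{name} {(w0, w1)} outside {n} volumes")

    # --- regional signals -------------------------------------------------
    masks_d = dilate_mask(masks, "edema", opts.edema_dilation,
                          connectivity=opts.dilation_connectivity)
    gm = extract_regional_mean(bold, masks_d, "gm", exclude="edema")
    gm_dn = denoise_wavelet(gm, opts.denoise_family, opts.denoise_level)
    wb = extract_regional_mean(bold, masks_d, "brain")
    wb_dn = denoise_wavelet(wb, opts.denoise_family, opts.denoise_level)

    # --- CO2 alignment and tau fit ---------------------------------------
    co2_rs = resample_trace(co2, tr, n)
    co2_aligned, bulk_lag = bulk_align(wb_dn, co2_rs, opts.bulk_max_lag)
    tau_res = fit_tau(gm_dn, co2_aligned, tr, window=opts.tau_window,
                      tau_grid=opts.tau_grid(), include_drift=opts.include_drift)

    # --- inflow window ----------------------------------------------------
    if opts.inflow_window is not None:
        inflow_win = opts.inflow_window
    elif protocol is not None:
        inflow_win = inflow_fit_window(protocol)
    else:
        inflow_win = DEFAULT_INFLOW_WINDOW
    if not (0 <= inflow_win[0] < inflow_win[1] < n):
        raise ConfigurationError(f"inflow window {inflow_win} outside {n} volumes")

    # --- inflow selection, presence, peak fit ----------------------------
    voxels, inflow_trace = select_inflow_voxels(
        bold,
        n_bottom_slices=opts.n_bottom_slices,
        contrast_window=inflow_win,
        k_voxels=opts.k_voxels,
    )
    inflow_raw = average_voxel_trace(bold, voxels)
    ratio = inflow_peak_ratio(inflow_trace, inflow_win, opts.baseline_window,
                              noise_trace=inflow_raw)
    inflow_present = bool(ratio > opts.inflow_threshold)
    inflow_block: dict = {
        "present": inflow_present,
        "peak_to_noise_ratio": ratio,
        "window": list(inflow_win),
        "n_voxels": len(voxels),
    }
    if inflow_present:
        try:
            peak = fit_inflow_peak(inflow_trace, tr, window=inflow_win)
            inflow_block.update(
                amplitude=peak.amplitude, xi=peak.xi, omega=peak.omega,
                alpha=peak.alpha, baseline_intercept=peak.a,
                baseline_slope=peak.b, hwhm_right=peak.hwhm_right, rss=peak.rss,
            )
        except FitFailureError as exc:  # pragma: no cover - diagnostic path
            logger.warning("inflow peak fit failed: %s", exc)
            inflow_block["fit_error"] = str(exc)
            inflow_present = False
            inflow_block["present"] = False

    # --- lag analyses -----------------------------------------------------
    d_gm = temporal_derivative(gm_dn, tr)
    d_co2 = temporal_derivative(co2_aligned, tr)
    lags = {}
    if inflow_present:
        # inflow follows CBV decreases: compare against the negated derivatives
        lag_cbv = shifted_crosscorr(-d_gm, inflow_trace, tr, opts.lag_max_s)
        lag_co2 = shifted_crosscorr(-d_co2, inflow_trace, tr, opts.lag_max_s)
        lags = {
            "inflow_vs_cbv": {"lag_s": lag_cbv.lag, "r_max": lag_cbv.r_max},
            "inflow_vs_co2": {"lag_s": lag_co2.lag, "r_max": lag_co2.r_max},
        }

    report = {
        "subject_id": subject_id,
        "timepoint": timepoint,
        "seed": seed,
        "n_volumes": n,
        "tr": tr,
        "bulk_alignment": {"lag_volumes": int(bulk_lag),
                           "lag_s": float(bulk_lag * tr)},
        "tau_fit": {
            "tau_s": tau_res.tau,
            "beta0": tau_res.beta0,
            "cvr_amplitude_per_mmhg": tau_res.beta1,
            "rss": tau_res.rss,
            "window": list(tau_res.window),
        },
        "inflow": inflow_block,
        "lags": lags,
        "edema_fraction": edema_fraction(masks),
        "options": dataclasses.asdict(opts),
    }
    return report


@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline configuration (YAML round-trippable)."""

    bold_path: str
    mask_dir: str
    co2_path: str
    out_dir: str
    o2_path: str | None = None
    tr_override: float | None = None
    subject_id: str = "subject"
    timepoint: str = "pre"
    seed: int = 0
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        opts_raw = raw.pop("options", {}) or {}
        for key in ("tau_window", "inflow_window", "baseline_window"):
            if opts_raw.get(key) is not None:
                opts_raw[key] = tuple(opts_raw[key])
        return cls(options=AnalysisOptions(**opts_raw), **raw)

    def to_yaml(self, path: str | Path) -> Path:
        data = dataclasses.asdict(self)
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def run_subject(config: PipelineConfig) -> dict:
    """Load a subject's files, validate, analyze, and write outputs.

    Writes ``report.json`` plus CSV exports of the de-noised GM trace, the
    aligned CO2 regressor and the inflow trace under ``out_dir``.
    """
    for name in ("bold_path", "mask_dir", "co2_path"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise ConfigurationError(f"{name} does not exist: {p}")
    bold = cvio.load_bold(config.bold_path, tr_override=config.tr_override)
    masks = cvio.load_masks(config.mask_dir)
    if masks.shape != bold.data.shape[:3]:
        raise ConfigurationError(
            f"mask grid {masks.shape} does not match BOLD grid {bold.data.shape[:3]}"
        )
    co2 = cvio.load_trace(config.co2_path, gas="CO2")
    o2 = cvio.load_trace(config.o2_path, gas="O2") if config.o2_path else None
    n = bold.n_volumes
    for name, win in (("tau_window", config.options.tau_window),
                      ("inflow_window", config.options.inflow_window)):
        if win is not None and win[1] >= n:
            raise ConfigurationError(f"{name} {tuple(win)} beyond {n} volumes")

    logger.info("analyzing %s (%s): %d volumes, tr=%.3f s",
                config.subject_id, config.timepoint, n, bold.tr)
    report = analyze_subject(
        bold, masks, co2, o2=o2, options=config.options,
        subject_id=config.subject_id, timepoint=config.timepoint,
        seed=config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cvio.save_report(report, out / "report.json")

    # trace exports for recomputation outside imaging I/O
    opts = config.options
    masks_d = dilate_mask(masks, "edema", opts.edema_dilation,
                          connectivity=opts.dilation_connectivity)
    gm_dn = denoise_wavelet(
        extract_regional_mean(bold, masks_d, "gm", exclude="edema"),
        opts.denoise_family, opts.denoise_level,
    )
    co2_aligned, _ = bulk_align(
        denoise_wavelet(extract_regional_mean(bold, masks_d, "brain"),
                        opts.denoise_family, opts.denoise_level),
        resample_trace(co2, bold.tr, n),
        opts.bulk_max_lag,
    )
    win = tuple(report["inflow"]["window"])
    _, inflow_trace = select_inflow_voxels(
        bold, n_bottom_slices=opts.n_bottom_slices, contrast_window=win,
        k_voxels=opts.k_voxels,
    )
    pd.DataFrame(
        {
            "time_s": np.arange(n) * bold.tr,
            "gm_denoised": gm_dn,
            "co2_aligned_mmhg": co2_aligned,
            "inflow": inflow_trace,
        }
    ).to_csv(out / "traces.csv", index=False)
    return report


def _records_from_reports(reports: list[dict]) -> list[GroupRecord]:
    records = []
    for rep in reports:
        inflow = rep.get("inflow", {})
        records.append(
            GroupRecord(
                dataset_id=rep["subject_id"],
                timepoint=rep["timepoint"],
                tau=float(rep["tau_fit"]["tau_s"]),
                edema_fraction=float(rep["edema_fraction"]),
                hwhm_right=float(inflow.get("hwhm_right", float("nan"))),
                inflow_present=bool(inflow.get("present", False)),
            )
        )
    return records


def cohort_stats(records: list[GroupRecord]) -> dict:
    """Group-level statistics over dataset summary records.

    Regressions of tau on edema load (all datasets) and of tau on inflow
    HWHM (datasets with inflow signal only), plus the paired pre/post tau
    test for subjects measured twice. Analyses with insufficient data are
    listed under ``omissions`` instead of failing.
    """
    report: dict = {"n_datasets": len(records), "omissions": []}
    rows = [dataclasses.asdict(r) for r in records]
    report["table"] = rows

    taus = np.array([r.tau for r in records])
    edema = np.array([r.edema_fraction for r in records])
    if len(records) >= 3:
        res = regress(edema, taus)
        report["tau_vs_edema"] = dataclasses.asdict(res)
    else:
        report["omissions"].append("tau_vs_edema: fewer than 3 datasets")

    with_inflow = [r for r in records if r.inflow_present
                   and np.isfinite(r.hwhm_right)]
    report["n_inflow_datasets"] = len(with_inflow)
    if len(with_inflow) >= 3:
        res = regress(
            np.array([r.hwhm_right for r in with_inflow]),
            np.array([r.tau for r in with_inflow]),
        )
        report["tau_vs_hwhm"] = dataclasses.asdict(res)
    else:
        report["omissions"].append("tau_vs_hwhm: fewer than 3 inflow datasets")

    by_id: dict[str, dict[str, float]] = {}
    for r in records:
        by_id.setdefault(r.dataset_id, {})[r.timepoint] = r.tau
    pre, post = [], []
    for tps in by_id.values():
        if "pre" in tps and "post" in tps:
            pre.append(tps["pre"])
            post.append(tps["post"])
    if len(pre) >= 2:
        t, p = paired_change_test(np.array(pre), np.array(post))
        report["paired_tau_change"] = {"t": t, "p_value": p, "n_pairs": len(pre)}
    else:
        report["omissions"].append("paired_tau_change: fewer than 2 pairs")
    return report


def run_cohort(report_paths: list[str | Path], out_dir: str | Path | None = None) -> dict:
    """Aggregate per-subject report JSONs into the group report.

    Every number in the group report is recomputable from the per-subject
    reports alone.
    """
    reports = [cvio.load_report(p) for p in report_paths]
    records = _records_from_reports(reports)
    group = cohort_stats(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cvio.save_report(group, out / "cohort.json")
        pd.DataFrame(group["table"]).to_csv(out / "cohort.csv", index=False)
    return group
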