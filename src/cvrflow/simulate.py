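"""Synthetic gas-challenge experiments.

Generates respiratory protocols (hypercapnic block, hypercapnic ramp,
hyperoxic block, interleaved baselines), idealized end-tidal gas traces,
forward-modelled BOLD responses (CO2 convolved with an exponential
hemodynamic response function), CSF inflow traces driven by the rectified
negative BOLD derivative (the time-of-flight mechanism: only inflow of
fresh spins raises the signal), and mask volumes with a controllable edema
load — so every downstream stage is testable against known ground truth.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import BoldSeries, MaskVolume, PhysioTrace

__all__ = [
    "Epoch",
    "RespiratoryProtocol",
    "ForwardModelParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "build_default_protocol",
    "render_traces",
    "simulate_bold",
    "simulate_csf_inflow",
    "simulate_masks",
    "simulate_dataset",
    "simulate_cohort",
    "epoch_time_range",
    "epoch_volume_range",
    "inflow_fit_window",
]

EPOCH_KINDS = ("baseline", "hypercapnic_block", "hypercapnic_ramp", "hyperoxic_block")


@dataclass(frozen=True)
class Epoch:
    """One gas-challenge epoch.

    ``co2_delta`` is the CO2 target relative to baseline (mmHg); it must be
    zero for baseline and hyperoxic epochs. ``o2_target`` is an absolute O2
    target in mmHg and is set only for hyperoxic epochs.
    """

    kind: str
    duration: float  # s
    co2_delta: float = 0.0
    o2_target: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("epoch duration must be strictly positive")
        if self.kind in ("baseline", "hyperoxic_block") and self.co2_delta != 0:
            raise ValueError(f"{self.kind} epoch must have co2_delta = 0")
        if (self.o2_target is not None) != (self.kind == "hyperoxic_block"):
            raise ValueError("o2_target is set exactly for hyperoxic epochs")


@dataclass(frozen=True)
class RespiratoryProtocol:
    """Ordered gas-challenge epochs plus scan timing.

    The scan may outlast the listed epochs (trailing time is at baseline)
    and trailing epochs may be truncated by the scan end; the protocol must
    cover at least one volume.
    """

    epochs: tuple[Epoch, ...]
    co2_baseline: float = 40.0  # mmHg
    o2_baseline: float = 110.0  # mmHg
    tr: float = 1.05  # s
    n_volumes: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if not (self.tr > 0 and self.n_volumes >= 1):
            raise ValueError("tr must be positive and n_volumes >= 1")
        if not (self.co2_baseline > 0 and self.o2_baseline > 0):
            raise ValueError("gas baselines must be positive (mmHg)")
        if self.epochs[0].duration < self.tr:
            # protocol must cover >= 1 volume
            total = sum(e.duration for e in self.epochs)
            if total < self.tr:
                raise ValueError("protocol covers less than one volume")

    @property
    def scan_duration(self) -> float:
        """Total scan time in seconds (``tr * n_volumes``)."""
        return self.tr * self.n_volumes

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def epoch_bounds(self) -> list[tuple[float, float]]:
        """(start, end) time in seconds of each epoch, in order."""
        starts = np.concatenate([[0.0], np.cumsum([e.duration for e in self.epochs])])
        return [(float(starts[i]), float(starts[i + 1])) for i in range(len(self.epochs))]


def build_default_protocol(
    lead_baseline: float = 172.5,
    co2_baseline: float = 40.0,
    o2_baseline: float = 110.0,
    tr: float = 1.05,
    n_volumes: int = 1000,
) -> RespiratoryProtocol:
    """The default paradigm: block, ramp and hyperoxia with 120-s baselines.

    Baseline, then a 90-s hypercapnic block (+10 mmHg), a 120-s baseline, a
    120-s hypercapnic ramp rising to +12 mmHg, a 120-s baseline, a 180-s
    hyperoxic block targeting 680 mmHg, and a closing 120-s baseline. The
    default 172.5-s lead places the end of the hypercapnic block at volume
    250 (262.5 s at TR = 1.05 s), the start of the tau analysis window.
    """
    epochs = (
        Epoch("baseline", lead_baseline),
        Epoch("hypercapnic_block", 90.0, co2_delta=10.0),
        Epoch("baseline", 120.0),
        Epoch("hypercapnic_ramp", 120.0, co2_delta=12.0),
        Epoch("baseline", 120.0),
        Epoch("hyperoxic_block", 180.0, o2_target=680.0),
        Epoch("baseline", 120.0),
    )
    return RespiratoryProtocol(
        epochs=epochs,
        co2_baseline=co2_baseline,
        o2_baseline=o2_baseline,
        tr=tr,
        n_volumes=n_volumes,
    )


def epoch_time_range(
    protocol: RespiratoryProtocol, kind: str, occurrence: int = 0
) -> tuple[float, float]:
    """Start/end time (s) of the n-th epoch of the given kind."""
    found = [
        bounds
        for e, bounds in zip(protocol.epochs, protocol.epoch_bounds())
        if e.kind == kind
    ]
    if occurrence >= len(found):
        raise ValueError(f"protocol has no occurrence {occurrence} of {kind!r}")
    return found[occurrence]


def epoch_volume_range(
    protocol: RespiratoryProtocol, kind: str, occurrence: int = 0
) -> tuple[int, int]:
    """Volume-index range (inclusive) spanned by an epoch, clipped to scan."""
    t0, t1 = epoch_time_range(protocol, kind, occurrence)
    v0 = int(np.ceil(t0 / protocol.tr))
    v1 = int(np.floor(t1 / protocol.tr))
    v0 = max(0, min(v0, protocol.n_volumes - 1))
    v1 = max(0, min(v1, protocol.n_volumes - 1))
    return v0, v1


def inflow_fit_window(protocol: RespiratoryProtocol) -> tuple[int, int]:
    """Inflow fit window from the protocol geometry.

    Starts at the end of the hypercapnic block and ends at the midpoint
    between the block end and the peak of the hypercapnic ramp, so the
    entire tail of the block-offset inflow peak is included while the
    ramp-offset peak stays out.
    """
    _, block_end = epoch_time_range(protocol, "hypercapnic_block")
    _, ramp_end = epoch_time_range(protocol, "hypercapnic_ramp")
    v_start = int(round(block_end / protocol.tr))
    v_mid = int(round(0.5 * (block_end + ramp_end) / protocol.tr))
    v_start = min(v_start, protocol.n_volumes - 2)
    v_mid = min(v_mid, protocol.n_volumes - 1)
    return v_start, v_mid


def _trapezoid_profile(t: np.ndarray, t0: float, t1: float, tt: float) -> np.ndarray:
    """Plateau profile in [0, 1]: rise over [t0, t0+tt], hold to the epoch
    end t1, then return to zero over [t1, t1+tt].

    The return transition lies just after the epoch, so the stimulus starts
    decaying exactly at the epoch end — where CSF inflow is expected to
    begin. With tt = 0 the profile is an exact rectangle on [t0, t1).
    """
    tt = min(tt, 0.5 * (t1 - t0))
    if tt <= 0:
        return ((t >= t0) & (t < t1)).astype(float)
    up = np.clip((t - t0) / tt, 0.0, 1.0)
    down = np.clip((t1 + tt - t) / tt, 0.0, 1.0)
    return np.minimum(up, down)


def _ramp_profile(t: np.ndarray, t0: float, t1: float, tt: float) -> np.ndarray:
    """Linear rise from 0 to 1 over [t0, t1], returning to zero over
    [t1, t1+tt] after the epoch. The epoch midpoint is exactly 0.5."""
    rise = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    if tt > 0:
        fall = np.clip((t1 + tt - t) / tt, 0.0, 1.0)
    else:
        fall = (t < t1).astype(float)
    return np.where(t < t0, 0.0, np.minimum(rise, fall))


def render_traces(
    protocol: RespiratoryProtocol, dt: float = 0.1, transition_time: float = 10.0
) -> tuple[PhysioTrace, PhysioTrace]:
    """Render idealized end-tidal CO2 and O2 traces for a protocol.

    Block epochs are plateaus reached via linear transitions of length
    ``transition_time`` (contained within the epoch); the ramp epoch rises
    linearly from baseline to its maximum delta; values equal baseline
    outside epochs. With ``transition_time = 0`` the profiles are exact
    rectangles/triangles. Prospective end-tidal targeting is idealized:
    breath-to-breath variability is not modelled here.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if transition_time < 0:
        raise ValueError("transition_time must be >= 0")
    total = max(sum(e.duration for e in protocol.epochs), protocol.scan_duration)
    t = np.arange(0.0, total + 0.5 * dt, dt)
    co2 = np.full(t.size, protocol.co2_baseline)
    o2 = np.full(t.size, protocol.o2_baseline)
    for epoch, (t0, t1) in zip(protocol.epochs, protocol.epoch_bounds()):
        if epoch.kind == "hypercapnic_block":
            co2 += epoch.co2_delta * _trapezoid_profile(t, t0, t1, transition_time)
        elif epoch.kind == "hypercapnic_ramp":
            co2 += epoch.co2_delta * _ramp_profile(t, t0, t1, transition_time)
        elif epoch.kind == "hyperoxic_block":
            delta = epoch.o2_target - protocol.o2_baseline
            o2 += delta * _trapezoid_profile(t, t0, t1, transition_time)
    return (
        PhysioTrace(times=t, values=co2, gas="CO2"),
        PhysioTrace(times=t, values=o2, gas="O2"),
    )


@dataclass(frozen=True)
class ForwardModelParams:
    """Ground-truth parameters of the forward model.

    ``tau_true`` is the exponential HRF time constant (s); ``cvr_amplitude``
    the BOLD change per mmHg CO2; ``o2_amplitude`` the direct (saturation)
    BOLD change per mmHg O2 — zero by default because brief hyperoxia is not
    vasoactive and the validation analyses assume no O2-driven CBV change;
    ``inflow_gain`` converts the rectified negative BOLD derivative (signal/s)
    into inflow signal; ``inflow_skew`` stretches the right side of the
    inflow peak (> -1); ``inflow_delay_s`` is the transit delay of inflow
    behind the CBV change; ``noise_sd`` is additive Gaussian noise.
    """

    tau_true: float = 10.0
    cvr_amplitude: float = 2.0
    o2_amplitude: float = 0.0
    inflow_gain: float = 30.0
    inflow_skew: float = 1.0
    inflow_delay_s: float = 1.26
    noise_sd: float = 2.0
    seed: int = 0
    signal_baseline: float = 1000.0
    inflow_baseline: float = 100.0

    def __post_init__(self) -> None:
        if not self.tau_true > 0:
            raise ValueError("tau_true must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.inflow_skew <= -1:
            raise ValueError("inflow_skew must be > -1")
        if self.inflow_delay_s < 0:
            raise ValueError("inflow_delay_s must be >= 0")


def simulate_bold(
    co2: PhysioTrace,
    params: ForwardModelParams,
    protocol: RespiratoryProtocol,
    o2: PhysioTrace | None = None,
) -> BoldSeries:
    """Forward-model a regional BOLD trace from gas traces.

    ``s(t) = s0 + cvr_amplitude * (dCO2 (*) h_tau)(t)
    [+ o2_amplitude * (dO2 (*) h_tau)(t)] + noise`` sampled at the volume
    times, where ``h_tau`` is the unit-sum exponential kernel and ``dCO2``
    the CO2 excursion from baseline. Noise is i.i.d. Gaussian with the given
    seed; a fixed seed gives bit-identical output.
    """
    from .preprocess import resample_trace
    from .tau import convolve_exponential

    n, tr = protocol.n_volumes, protocol.tr
    dco2 = resample_trace(co2, tr, n) - protocol.co2_baseline
    signal = params.signal_baseline + params.cvr_amplitude * convolve_exponential(
        dco2, params.tau_true, tr
    )
    if o2 is not None and params.o2_amplitude != 0.0:
        do2 = resample_trace(o2, tr, n) - protocol.o2_baseline
        signal = signal + params.o2_amplitude * convolve_exponential(
            do2, params.tau_true, tr
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        signal = signal + rng.normal(0.0, params.noise_sd, n)
    return BoldSeries(data=signal, tr=tr)


def _warp_right_side(t: np.ndarray, y: np.ndarray, skew: float) -> np.ndarray:
    """Stretch the right side of every peak by a factor (1 + skew).

    Each connected positive region of the rectified derivative is warped
    independently about its own maximum, so both the block-offset and the
    ramp-offset inflow events acquire the same right-sided skew. The stretch
    is limited to the gap before the next region.
    """
    if skew == 0 or not np.any(y > 0):
        return y.copy()
    out = y.copy()
    flags = np.concatenate([[0], (y > 0).astype(np.int8), [0]])
    edges = np.flatnonzero(np.diff(flags))
    starts, ends = edges[::2], edges[1::2]  # regions [start, end)
    for k, (i0, i1) in enumerate(zip(starts, ends)):
        ip = i0 + int(np.argmax(y[i0:i1]))
        tp = t[ip]
        stop = starts[k + 1] if k + 1 < starts.size else t.size
        sel = slice(ip, stop)
        tq = tp + (t[sel] - tp) / (1.0 + skew)
        out[sel] = np.interp(tq, t, y)
    return out


def simulate_csf_inflow(
    bold: BoldSeries, params: ForwardModelParams
) -> BoldSeries:
    """Time-of-flight CSF inflow trace from a regional BOLD series.

    Inflow responds only to CBV decreases: the negative temporal derivative
    of the (noise-free) BOLD input is rectified at zero, the right side of
    the dominant peak is stretched by the skewness factor, the trace is
    shifted by the transit delay, scaled by ``inflow_gain`` and offset by
    the inflow baseline, and Gaussian noise is added. A constant BOLD input
    therefore yields baseline plus noise only, and a monotonically
    increasing BOLD input yields no rectified response at all.
    """
    from .preprocess import temporal_derivative

    if not bold.is_regional:
        raise ValueError("inflow simulation requires a regional (1D) BoldSeries")
    t = bold.times
    rect = np.maximum(0.0, -temporal_derivative(bold.data, bold.tr))
    shaped = _warp_right_side(t, rect, params.inflow_skew)
    if params.inflow_delay_s > 0:
        shaped = np.interp(t - params.inflow_delay_s, t, shaped, left=shaped[0])
    signal = params.inflow_baseline + params.inflow_gain * shaped
    if params.noise_sd > 0:
        rng = np.random.default_rng([params.seed, 1])
        signal = signal + rng.normal(0.0, params.noise_sd, signal.size)
    return BoldSeries(data=signal, tr=bold.tr)


def simulate_masks(
    shape: tuple[int, int, int],
    edema_fraction_target: float,
    seed: int,
    voxel_dims: tuple[float, float, float] = (2.3, 2.3, 2.5),
) -> MaskVolume:
    """Brain ellipsoid with GM/WM/CSF shells and a connected edema blob.

    The brain is an axis-aligned ellipsoid; CSF occupies the innermost
    normalized radius (< 0.25, a ventricle stand-in), WM the middle shell
    (< 0.6) and GM the outer shell. Edema is grown by seeded breadth-first
    search over 6-connected brain voxels until its voxel count is
    ``round(target * n_brain)``, so the achieved fraction is within one
    voxel of the target.
    """
    if not (0 <= edema_fraction_target < 1):
        raise ValueError("edema_fraction_target must be in [0, 1)")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 3 for s in shape):
        raise ValueError("shape must be three dims of at least 3 voxels")
    center = (np.array(shape) - 1) / 2.0
    radii = 0.45 * np.array(shape)
    grid = np.indices(shape).astype(float)
    r2 = sum(((grid[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    brain = r2 <= 1.0
    r = np.sqrt(r2)
    csf = brain & (r < 0.25)
    wm = brain & (r >= 0.25) & (r < 0.6)
    gm = brain & (r >= 0.6)
    n_brain = int(brain.sum())
    if n_brain == 0:
        raise ValueError("degenerate shape: empty brain mask")
    n_edema = int(round(edema_fraction_target * n_brain))
    edema = np.zeros(shape, dtype=bool)
    if n_edema > 0:
        rng = np.random.default_rng(seed)
        brain_idx = np.argwhere(brain)
        start = tuple(brain_idx[rng.integers(brain_idx.shape[0])])
        queue = deque([start])
        seen = {start}
        grown = 0
        while queue and grown < n_edema:
            v = queue.popleft()
            edema[v] = True
            grown += 1
            for ax in range(3):
                for d in (-1, 1):
                    w = list(v)
                    w[ax] += d
                    w = tuple(w)
                    if (
                        w not in seen
                        and 0 <= w[ax] < shape[ax]
                        and brain[w]
                    ):
                        seen.add(w)
                        queue.append(w)
    return MaskVolume(
        brain=brain, gm=gm, wm=wm, csf=csf, edema=edema, voxel_dims=voxel_dims
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded alongside a synthetic dataset."""

    params: ForwardModelParams
    edema_fraction: float
    hwhm_right: float  # s, from the noiseless inflow trace
    inflow_peak_time: float  # s


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete synthetic subject: 4D BOLD, masks, gas traces, truth."""

    bold: BoldSeries
    masks: MaskVolume
    co2: PhysioTrace
    o2: PhysioTrace
    truth: SyntheticTruth
    protocol: RespiratoryProtocol


def _numeric_hwhm_right(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Right HWHM and peak time of a sampled unimodal peak (interpolated)."""
    i = int(np.argmax(y))
    t_peak, peak = float(t[i]), float(y[i])
    half = 0.5 * peak
    for j in range(i + 1, y.size):
        if y[j] <= half:
            # linear interpolation of the crossing
            frac = (y[j - 1] - half) / max(y[j - 1] - y[j], 1e-300)
            t_half = t[j - 1] + frac * (t[j] - t[j - 1])
            return float(t_half - t_peak), t_peak
    return float(t[-1] - t_peak), t_peak


def simulate_dataset(
    protocol: RespiratoryProtocol | None = None,
    params: ForwardModelParams | None = None,
    shape: tuple[int, int, int] = (16, 16, 8),
    edema_fraction: float = 0.05,
    n_inflow_voxels: int = 5,
    transition_time: float = 10.0,
) -> SyntheticDataset:
    """Generate a full synthetic subject on a small voxel grid.

    GM/WM voxels carry the CO2-driven BOLD response (WM at half amplitude);
    ``n_inflow_voxels`` voxels near the centre of each of the two bottom
    slices carry the CSF inflow trace; everything gets i.i.d. Gaussian
    noise. The recorded truth includes the right HWHM measured on the
    noiseless inflow trace.
    """
    protocol = protocol or build_default_protocol()
    params = params or ForwardModelParams()
    co2, o2 = render_traces(protocol, transition_time=transition_time)
    masks = simulate_masks(shape, edema_fraction, seed=params.seed)
    clean = replace(params, noise_sd=0.0)
    bold_clean = simulate_bold(co2, clean, protocol, o2=o2)
    # inflow is driven by the CO2-mediated CBV change only
    cbv_source = (
        bold_clean
        if params.o2_amplitude == 0.0
        else simulate_bold(co2, replace(clean, o2_amplitude=0.0), protocol)
    )
    inflow_clean = simulate_csf_inflow(cbv_source, clean)

    n, tr = protocol.n_volumes, protocol.tr
    rng = np.random.default_rng([params.seed, 2])
    data = np.zeros(shape + (n,), dtype=float)
    gm_resp = bold_clean.data
    wm_resp = params.signal_baseline + 0.5 * (gm_resp - params.signal_baseline)
    csf_flat = np.full(n, params.inflow_baseline)
    data[masks.gm] = gm_resp
    data[masks.wm] = wm_resp
    data[masks.csf] = csf_flat
    # inflow voxels in the bottom two slices, clustered at the slice centre
    ci, cj = shape[0] // 2, shape[1] // 2
    offsets = [(0, 0), (1, 0), (0, 1), (-1, 0), (0, -1), (1, 1), (-1, -1),
               (1, -1), (-1, 1)]
    for s in range(min(2, shape[2])):
        for di, dj in offsets[:n_inflow_voxels]:
            data[ci + di, cj + dj, s] = inflow_clean.data
    if params.noise_sd > 0:
        data += rng.normal(0.0, params.noise_sd, data.shape)
    bold = BoldSeries(data=data, tr=tr, slice_axis=2)

    # ground-truth peak width: the block-offset inflow event, measured on the
    # noiseless trace within the protocol-derived fit window
    baseline_free = inflow_clean.data - params.inflow_baseline
    w0, w1 = inflow_fit_window(protocol)
    hwhm, t_peak = _numeric_hwhm_right(
        np.arange(w0, w1 + 1) * tr, baseline_free[w0 : w1 + 1]
    )
    truth = SyntheticTruth(
        params=params,
        edema_fraction=float(masks.edema.sum() / masks.brain.sum()),
        hwhm_right=hwhm,
        inflow_peak_time=t_peak,
    )
    return SyntheticDataset(
        bold=bold, masks=masks, co2=co2, o2=o2, truth=truth, protocol=protocol
    )


@dataclass(frozen=True)
class CohortSubject:
    """Regional-level synthetic subject for cohort statistics."""

    subject_id: str
    timepoint: str  # "pre" or "post"
    bold: BoldSeries
    edema_fraction: float
    tau_true: float


def simulate_cohort(
    n_subjects: int = 20,
    seed: int = 0,
    protocol: RespiratoryProtocol | None = None,
    tau_intercept: float = 10.0,
    tau_edema_slope: float = 60.0,
    tau_noise_sd: float = 5.0,
    edema_range: tuple[float, float] = (0.0, 0.4),
    noise_sd: float = 2.0,
    cvr_amplitude: float = 2.0,
    paired: bool = False,
    transition_time: float = 10.0,
) -> tuple[list[CohortSubject], PhysioTrace]:
    """Simulate a cohort with an edema-dependent vascular time constant.

    Each subject's edema fraction is uniform over ``edema_range`` and its
    true tau is ``tau_intercept + tau_edema_slope * edema + noise`` (floored
    at 1 s): brains with more edema respond more slowly. With
    ``paired=True`` every subject gets a pre and a post dataset whose tau
    difference tracks its edema change. Returns the subjects and the shared
    CO2 trace.
    """
    protocol = protocol or build_default_protocol()
    co2, _ = render_traces(protocol, transition_time=transition_time)
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []

    def make(sid: str, timepoint: str, edema: float, idx: int) -> CohortSubject:
        tau = max(1.0, tau_intercept + tau_edema_slope * edema
                  + rng.normal(0.0, tau_noise_sd))
        params = ForwardModelParams(
            tau_true=tau,
            cvr_amplitude=cvr_amplitude,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        bold = simulate_bold(co2, params, protocol)
        return CohortSubject(sid, timepoint, bold, edema, tau)

    for i in range(n_subjects):
        sid = f"sub-{i:03d}"
        edema_pre = float(rng.uniform(*edema_range))
        subjects.append(make(sid, "pre", edema_pre, i))
        if paired:
            edema_post = float(
                np.clip(edema_pre + rng.normal(0.0, 0.1), *edema_range)
            )
            subjects.append(make(sid, "post", edema_post, i))
    return subjects, co2
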