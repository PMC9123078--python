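"""Per-response tuning metrics for one neuron at one degree of polarization.

A *response* is one stimulus epoch containing at least one clockwise and
one counterclockwise 360-degree polarizer rotation. Spikes fired during
the rotations are assigned to the polarizer orientation at their spike
time (mod 180, the axial AoP period) and pooled into 10-degree bins.
From the binned response the stage derives:

* significance of AoP modulation (circular-linear correlation of bin
  counts with the doubled bin angles, p < alpha),
* the preferred AoP Phi_max and mean resultant length r (axial mean of
  the per-spike angles),
* the response amplitude A = sum_i |n_i - n_bar| over the 18 bins,
  computed per single rotation and averaged across the epoch's
  rotations (n_bar is rotation-scoped by definition),
* firing rates at Phi_max and Phi_min = Phi_max + 90 from a bimodal
  von Mises fit to the binned rates,
* background activity in the 5 s before lights-on (1 s bins; median and
  2.5th/97.5th percentiles) and rates normalized to it,
* a no-stimulus control: the same rotation trajectory applied as a sham
  to a stimulus-free window, yielding the null directedness r of
  background spiking.

No latency correction is applied when assigning spikes to angles;
pooling CW and CCW rotations partially cancels the lag bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import (
    AxialSample,
    CircResult,
    DegenerateInputError,
    VonMisesFit,
    axial_mean,
    circ_linear_corr,
    fit_bimodal_von_mises,
    rate_at,
)
from .types import AnalysisConfig, CellType, PolarizerRotation, Recording, StimulusEpoch

__all__ = [
    "BinnedResponse",
    "BackgroundActivity",
    "TuningResult",
    "ProtocolError",
    "bin_response",
    "response_amplitude",
    "amplitude_from_counts",
    "background_activity",
    "analyze_response",
    "normalized_extremes",
    "no_stimulus_control",
    "no_stimulus_metrics",
]


class ProtocolError(ValueError):
    """The epoch does not meet the analysis protocol (e.g. one direction only)."""


@dataclass
class BinnedResponse:
    """Spike counts per AoP bin, pooled over the epoch's rotations."""

    counts: np.ndarray
    exposure: np.ndarray
    bin_edges: np.ndarray
    per_rotation_counts: list = field(default_factory=list)
    rotations_used: int = 0
    spike_angles: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.exposure

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_centers_doubled(self) -> np.ndarray:
        return np.mod(2.0 * self.bin_centers, 360.0)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bar(self) -> float:
        return self.n_total / self.counts.size


@dataclass
class BackgroundActivity:
    """Summary of pre-stimulus firing (1 s bins over the 5 s before lights-on)."""

    median: float
    p2_5: float
    p97_5: float
    n_bins: int
    truncated: bool = False
    missing: bool = False


@dataclass
class TuningResult:
    """All per-response metrics for one neuron at one DoP."""

    neuron_id: str
    cell_type: CellType
    dop: float
    n_spikes: int
    phi_max: float
    phi_min: float
    r: float
    r_cl: float
    p: float
    significant: bool
    A: float
    rate_phi_max: float
    rate_phi_min: float
    mean_rate: float
    background: BackgroundActivity
    fit: VonMisesFit
    binned: BinnedResponse
    flags: list = field(default_factory=list)


def bin_response(
    rec: Recording, epoch: StimulusEpoch, cfg: AnalysisConfig | None = None
) -> BinnedResponse:
    """Assign rotation-window spikes to AoP bins and accumulate dwell times."""
    cfg = cfg or AnalysisConfig()
    if not epoch.has_both_directions():
        raise ProtocolError(
            f"epoch {epoch.label!r}: needs >=1 CW and >=1 CCW rotation"
        )
    nb = cfg.n_bins
    edges = np.arange(nb + 1) * cfg.bin_width
    counts = np.zeros(nb)
    exposure = np.zeros(nb)
    per_rot = []
    angles_all = []
    for rot in epoch.rotations:
        spikes = rec.spike_train.spike_times
        inside = spikes[(spikes >= rot.t_start) & (spikes < rot.t_end)]
        aop = np.mod(rot.angle_at(inside), cfg.aop_period)
        idx = np.minimum((aop // cfg.bin_width).astype(int), nb - 1)
        c = np.bincount(idx, minlength=nb).astype(float)
        counts += c
        per_rot.append(c)
        angles_all.append(aop)
        exposure += _rotation_exposure(rot, cfg)
    return BinnedResponse(
        counts=counts,
        exposure=exposure,
        bin_edges=edges,
        per_rotation_counts=per_rot,
        rotations_used=len(epoch.rotations),
        spike_angles=np.concatenate(angles_all) if angles_all else np.empty(0),
    )


def _rotation_exposure(rot: PolarizerRotation, cfg: AnalysisConfig) -> np.ndarray:
    """Dwell time (s) of the AoP in each bin during one constant-speed sweep."""
    nb = cfg.n_bins
    period = cfg.aop_period
    w = cfg.bin_width
    full_cycles = int(rot.sweep // period)
    expo = np.full(nb, full_cycles * w / rot.speed)
    rem = rot.sweep - full_cycles * period
    if rem > 1e-12:
        s0 = rot.start_angle % period
        # the partial arc covers [s0, s0+rem) upward for CW, downward for CCW
        lo = s0 if rot.direction.value == "CW" else (s0 - rem) % period
        for i in range(nb):
            expo[i] += _wrapped_overlap(lo, rem, i * w, w, period) / rot.speed
    return expo


def _wrapped_overlap(arc_lo: float, arc_len: float, bin_lo: float, bin_w: float,
                     period: float) -> float:
    """Length of the overlap between an arc [arc_lo, arc_lo+arc_len) wrapped
    mod ``period`` and the bin [bin_lo, bin_lo+bin_w)."""
    total = 0.0
    # split the arc at the wrap point
    first = min(arc_len, period - arc_lo)
    for lo, ln in ((arc_lo, first), (0.0, arc_len - first)):
        if ln <= 0:
            continue
        total += max(0.0, min(lo + ln, bin_lo + bin_w) - max(lo, bin_lo))
    return total


def amplitude_from_counts(counts) -> float:
    """A = sum_i |n_i - n_bar| for one rotation's bin counts."""
    c = np.asarray(counts, dtype=float)
    return float(np.abs(c - c.mean()).sum())


def response_amplitude(binned: BinnedResponse) -> float:
    """Response amplitude A, computed per rotation and averaged across the
    epoch's rotations (n_bar is the rotation's spike count over 18 bins)."""
    if binned.per_rotation_counts:
        return float(np.mean([amplitude_from_counts(c)
                              for c in binned.per_rotation_counts]))
    return amplitude_from_counts(binned.counts)


def background_activity(
    rec: Recording, epoch: StimulusEpoch, cfg: AnalysisConfig | None = None
) -> BackgroundActivity:
    """Median and 2.5/97.5 percentiles of 1 s-binned rates before lights-on."""
    cfg = cfg or AnalysisConfig()
    gap = min(rec.pre_epoch_gap(epoch), cfg.ba_window)
    n_bins = int(gap // cfg.ba_bin)
    full = int(cfg.ba_window // cfg.ba_bin)
    if n_bins == 0:
        return BackgroundActivity(
            median=float("nan"), p2_5=float("nan"), p97_5=float("nan"),
            n_bins=0, truncated=True, missing=True,
        )
    edges = epoch.t_on - np.arange(n_bins, -1, -1) * cfg.ba_bin
    counts, _ = np.histogram(rec.spike_train.spike_times, bins=edges)
    rates = counts / cfg.ba_bin
    p2_5, med, p97_5 = np.percentile(rates, [2.5, 50.0, 97.5])
    return BackgroundActivity(
        median=float(med), p2_5=float(p2_5), p97_5=float(p97_5),
        n_bins=n_bins, truncated=n_bins < full,
    )


def analyze_response(
    rec: Recording,
    epoch: StimulusEpoch,
    cfg: AnalysisConfig | None = None,
    fit_curve: bool = True,
) -> TuningResult:
    """Assemble the full TuningResult for one (neuron, epoch) response."""
    cfg = cfg or AnalysisConfig()
    binned = bin_response(rec, epoch, cfg)
    flags: list[str] = []

    if binned.n_total > 0:
        circ = axial_mean(AxialSample.from_angles(binned.spike_angles))
        if not circ.phi_max_defined:
            flags.append("phi_max_undefined")
    else:
        circ = CircResult(phi_max=float("nan"), r=0.0, n=0, phi_max_defined=False)
        flags.append("no_spikes")

    p = float("nan")
    r_cl = float("nan")
    significant = False
    if binned.n_total < cfg.min_spikes:
        flags.append("untestable")
    else:
        try:
            r_cl, p = circ_linear_corr(
                binned.counts,
                binned.bin_centers_doubled,
                method=cfg.p_method,
                n_perm=cfg.n_perm,
                seed=cfg.rng_seed,
            )
            significant = p < cfg.alpha
        except DegenerateInputError:
            flags.append("degenerate_counts")

    A = response_amplitude(binned)

    fit = None
    rate_max = rate_min = float("nan")
    if fit_curve:
        fit = fit_bimodal_von_mises(binned)
        if not fit.converged:
            flags.append("fit_failed")
    if fit is not None and fit.converged and circ.phi_max_defined:
        rate_max = rate_at(fit, circ.phi_max)
        rate_min = rate_at(fit, circ.phi_max + 90.0)
    elif circ.phi_max_defined and binned.n_total:
        # raw-bin fallback, flagged
        nb = binned.counts.size
        i_max = min(int(circ.phi_max // cfg.bin_width), nb - 1)
        i_min = int((circ.phi_max + 90.0) % cfg.aop_period // cfg.bin_width) % nb
        rates = binned.rates
        rate_max, rate_min = float(rates[i_max]), float(rates[i_min])
        if fit_curve:
            flags.append("raw_rate_fallback")

    rot_time = sum(r.duration for r in epoch.rotations)
    mean_rate = binned.n_total / rot_time if rot_time > 0 else float("nan")

    ba = background_activity(rec, epoch, cfg)
    if ba.missing:
        flags.append("missing_background")
    elif ba.truncated:
        flags.append("truncated_background")

    phi_max = circ.phi_max
    return TuningResult(
        neuron_id=rec.spike_train.neuron_id,
        cell_type=rec.spike_train.cell_type,
        dop=epoch.dop,
        n_spikes=binned.n_total,
        phi_max=phi_max,
        phi_min=float(np.mod(phi_max + 90.0, 180.0)),
        r=circ.r,
        r_cl=r_cl,
        p=p,
        significant=significant,
        A=A,
        rate_phi_max=rate_max,
        rate_phi_min=rate_min,
        mean_rate=mean_rate,
        background=ba,
        fit=fit if fit is not None else VonMisesFit(0, 0, 0, float("nan"),
                                                    float("nan"), False, False),
        binned=binned,
        flags=flags,
    )


def normalized_extremes(tr: TuningResult) -> tuple[float | None, float | None]:
    """Rates at Phi_max/Phi_min as fractions of the background median.

    Returns (None, None), with no infinities, when the background median
    is zero or missing.
    """
    ba = tr.background
    if ba.missing or not np.isfinite(ba.median) or ba.median == 0.0:
        if "undefined_normalization" not in tr.flags:
            tr.flags.append("undefined_normalization")
        return None, None
    return tr.rate_phi_max / ba.median, tr.rate_phi_min / ba.median


def _sham_epoch(rec: Recording, epoch: StimulusEpoch, cfg: AnalysisConfig):
    """The epoch's rotation trajectory shifted back in time so that it ends
    where the background window begins; None when no stimulus-free window
    of sufficient length exists."""
    if not epoch.rotations:
        return None
    span_start = epoch.rotations[0].t_start
    span_end = epoch.rotations[-1].t_end
    span = span_end - span_start
    shift = (epoch.t_on - cfg.ba_window) - span_end
    if span_start + shift < 0 or rec.pre_epoch_gap(epoch) < cfg.ba_window + span:
        return None
    rotations = [
        PolarizerRotation(
            t_start=rot.t_start + shift,
            direction=rot.direction,
            start_angle=rot.start_angle,
            speed=rot.speed,
            sweep=rot.sweep,
        )
        for rot in epoch.rotations
    ]
    return StimulusEpoch(
        t_on=span_start + shift,
        t_off=span_end + shift + 1e-9,
        dop=epoch.dop,
        rotations=rotations,
        label=f"{epoch.label}-sham",
    )


def no_stimulus_metrics(
    rec: Recording, epoch: StimulusEpoch, cfg: AnalysisConfig | None = None
) -> dict | None:
    """Sham-rotation control metrics (r, A, mean rate) of background spiking.

    Spikes in a stimulus-free window preceding the epoch's background
    window are assigned the polarizer angles they would have seen had the
    epoch's rotations happened there, and the same response metrics are
    computed. Returns None (caller logs) when no free window of
    sufficient length exists or it contains no spikes.
    """
    cfg = cfg or AnalysisConfig()
    sham = _sham_epoch(rec, epoch, cfg)
    if sham is None:
        return None
    binned = bin_response(rec, sham, cfg)
    if binned.n_total == 0:
        return None
    circ = axial_mean(AxialSample.from_angles(binned.spike_angles))
    rot_time = sum(r.duration for r in sham.rotations)
    return {
        "r": circ.r,
        "A": response_amplitude(binned),
        "mean_rate": binned.n_total / rot_time,
        "n": binned.n_total,
    }


def no_stimulus_control(
    rec: Recording, epoch: StimulusEpoch, cfg: AnalysisConfig | None = None
) -> CircResult | None:
    """Null directedness of background spiking under a sham rotation.

    The epoch's rotation trajectory is applied as a sham to a
    stimulus-free window and the axial mean resultant length r is
    computed exactly as for a real response. Returns None (caller logs)
    when no suitable window exists or it contains no spikes.
    """
    cfg = cfg or AnalysisConfig()
    sham = _sham_epoch(rec, epoch, cfg)
    if sham is None:
        return None
    binned = bin_response(rec, sham, cfg)
    if binned.n_total == 0:
        return None
    return axial_mean(AxialSample.from_angles(binned.spike_angles))
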