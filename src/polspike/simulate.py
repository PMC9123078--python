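"""Inhomogeneous-Poisson simulator for polarization-stimulus recordings.

The firing-rate model combines, for a neuron with baseline rate B
(spikes/s), preferred AoP phi_max_true and degree of polarization d of
the current stimulus epoch:

* sinusoidal axial tuning  M(d) * cos(2 * (theta(t) - phi_max_true)),
  where theta(t) is the commanded polarizer angle and M(d) is either
  linear in d (M = m0 * d) or linear in log10(d) clipped at zero
  (M = max(0, a0 + a1 * log10 d));
* a tonic light response  T(d) = tau0 * (1 - d), strongest for
  near-unpolarized light and vanishing at full polarization;
* signed exponential transients at stimulus onset and offset
  (phasic excitation/inhibition and post-stimulus rebounds);
* an overall clip to [0, rate_ceiling].

Spikes are drawn by thinning a homogeneous Poisson process at
rate_ceiling. Between the rotations of an epoch the polarizer holds its
last angle (the physical device does not jump); before the first
rotation it sits at that rotation's start angle. With ``dra_occluded``
set, every stimulus-driven term is zero and only the baseline remains —
mimicking occlusion of the dorsal rim area, the eye region that feeds
the polarization pathway.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .types import (
    CellType,
    Direction,
    PolarizerRotation,
    Recording,
    SpikeTrain,
    StimulusEpoch,
    ValidationError,
)

__all__ = [
    "NeuronModel",
    "ProtocolSpec",
    "rate_function",
    "simulate_recording",
    "make_celltype_preset",
    "simulate_cohort",
    "PRESET_VARIANTS",
    "DEFAULT_DOP_LADDER",
]

DEFAULT_DOP_LADDER = (0.99, 0.35, 0.1, 0.05, 0.002)


@dataclass
class NeuronModel:
    """Parameters of one simulated AoP-sensitive neuron."""

    baseline: float = 20.0
    phi_max_true: float = 60.0
    amp_law: str = "linear"  # "linear": M(d)=m0*d; "log": M(d)=max(0, a0+a1*log10 d)
    amp_params: tuple = (12.0,)
    tonic_gain: float = 0.0  # tau0; T(d) = tau0 * (1 - d)
    on_transient: tuple = (0.0, 1.0)  # (signed amplitude sp/s, tau s)
    off_transient: tuple = (0.0, 5.0)
    dra_occluded: bool = False
    rate_ceiling: float = 200.0
    dead_time: float | None = None  # refractory period in s (typically 0.002); None disables it

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValidationError("baseline: must be non-negative")
        if self.rate_ceiling < self.baseline:
            raise ValidationError("rate_ceiling: must be >= baseline")
        if not 0.0 <= self.phi_max_true < 180.0:
            self.phi_max_true = float(np.mod(self.phi_max_true, 180.0))
        if self.amp_law not in ("linear", "log"):
            raise ValidationError("amp_law: must be 'linear' or 'log'")

    def amplitude(self, dop: float) -> float:
        """Tuning-modulation amplitude M(d) in spikes/s; always >= 0."""
        if self.dra_occluded:
            return 0.0
        if self.amp_law == "linear":
            (m0,) = self.amp_params
            return max(0.0, m0 * dop)
        a0, a1 = self.amp_params
        if dop <= 0:
            return 0.0
        return max(0.0, a0 + a1 * np.log10(dop))

    def tonic(self, dop: float) -> float:
        if self.dra_occluded:
            return 0.0
        return self.tonic_gain * (1.0 - dop)


@dataclass
class ProtocolSpec:
    """Stimulus schedule: one epoch per ladder DoP, each with >=1 CW + >=1 CCW
    360-degree rotation, separated by gaps long enough for rebounds to decay
    and a clean 5 s background window to exist."""

    dop_ladder: tuple = DEFAULT_DOP_LADDER
    rotations_per_epoch: tuple = (Direction.CW, Direction.CCW)
    speed: float = 40.0
    inter_epoch_gap: float = 30.0
    lead_in: float = 30.0  # long enough for a sham-control window before epoch 1
    start_angle: float = 0.0
    epoch_pad: float = 0.5  # light on this long before the first / after the last sweep

    def __post_init__(self) -> None:
        if self.inter_epoch_gap < 25.0:
            raise ValidationError(
                "inter_epoch_gap: must be >= 25 s (20 s rebound + 5 s background)"
            )

    def build_epochs(self) -> list[StimulusEpoch]:
        epochs = []
        t = self.lead_in
        sweep_dur = 360.0 / self.speed
        for dop in self.dop_ladder:
            t_on = t
            rot_t = t_on + self.epoch_pad
            rotations = []
            angle = self.start_angle
            for direction in self.rotations_per_epoch:
                rot = PolarizerRotation(
                    t_start=rot_t,
                    direction=Direction.coerce(direction),
                    start_angle=angle,
                    speed=self.speed,
                )
                rotations.append(rot)
                angle = rot.end_angle
                rot_t = rot.t_end
            t_off = rot_t + self.epoch_pad
            epochs.append(
                StimulusEpoch(t_on=t_on, t_off=t_off, dop=dop, rotations=rotations,
                              label=f"dop{dop:g}")
            )
            t = t_off + self.inter_epoch_gap
        return epochs

    @property
    def session_duration(self) -> float:
        eps = self.build_epochs()
        return (eps[-1].t_off if eps else self.lead_in) + self.inter_epoch_gap


def _held_angle(epoch: StimulusEpoch, t: np.ndarray) -> np.ndarray:
    """Polarizer angle during an epoch: sweeping during rotations, held
    at the last reached angle between/after them, at the first start
    angle before the first rotation."""
    if not epoch.rotations:
        return np.zeros_like(t)
    angle = np.full_like(t, epoch.rotations[0].start_angle)
    for rot in epoch.rotations:
        inside = (t >= rot.t_start) & (t <= rot.t_end)
        angle[inside] = rot.angle_at(t[inside])
        after = t > rot.t_end
        angle[after] = rot.end_angle
    return angle


def rate_function(model: NeuronModel, epochs: list[StimulusEpoch], t) -> np.ndarray:
    """Instantaneous firing rate lambda(t) in spikes/s (vectorized, total)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam = np.full_like(t, model.baseline)
    for epoch in epochs:
        inside = (t >= epoch.t_on) & (t < epoch.t_off)
        if np.any(inside):
            theta = _held_angle(epoch, t[inside])
            tuned = model.amplitude(epoch.dop) * np.cos(
                2.0 * np.deg2rad(theta - model.phi_max_true)
            )
            lam[inside] += model.tonic(epoch.dop) + tuned
        if not model.dra_occluded:
            a_on, tau_on = model.on_transient
            if a_on != 0.0:
                dt = t - epoch.t_on
                m = dt >= 0
                lam[m] += a_on * np.exp(-dt[m] / tau_on)
            a_off, tau_off = model.off_transient
            if a_off != 0.0:
                dt = t - epoch.t_off
                m = dt >= 0
                lam[m] += a_off * np.exp(-dt[m] / tau_off)
    return np.clip(lam, 0.0, model.rate_ceiling)


def simulate_recording(
    model: NeuronModel,
    protocol: ProtocolSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    neuron_id: str = "sim",
    cell_type: CellType | str = CellType.OTHER,
) -> Recording:
    """Draw one Recording from the inhomogeneous Poisson rate model.

    Uses thinning against ``rate_ceiling``: candidate spikes are drawn
    homogeneously at the ceiling rate and kept with probability
    lambda(t)/ceiling. Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    epochs = protocol.build_epochs()
    duration = protocol.session_duration

    ceiling = model.rate_ceiling
    peak = _sup_rate(model, epochs)
    if ceiling < peak - 1e-9:
        raise ValidationError(
            f"rate_ceiling ({ceiling}) is below the supremum of the rate "
            f"function ({peak:.3f})"
        )

    n_cand = rng.poisson(ceiling * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    if cand.size:
        lam = rate_function(model, epochs, cand)
        keep = rng.uniform(0.0, 1.0, size=cand.size) < lam / ceiling
        times = cand[keep]
    else:
        times = cand
    if model.dead_time:
        times = _apply_dead_time(times, model.dead_time)
    times = np.unique(times)  # strict monotonicity for the container

    train = SpikeTrain(
        neuron_id=neuron_id,
        cell_type=CellType.coerce(cell_type),
        spike_times=times,
        session_duration=duration,
    )
    meta = {
        "synthetic": True,
        "model": asdict(model),
        "protocol": {
            "dop_ladder": list(protocol.dop_ladder),
            "rotations_per_epoch": [Direction.coerce(d).value
                                    for d in protocol.rotations_per_epoch],
            "speed": protocol.speed,
            "inter_epoch_gap": protocol.inter_epoch_gap,
        },
    }
    return Recording(spike_train=train, epochs=epochs, metadata=meta)


def _sup_rate(model: NeuronModel, epochs: list[StimulusEpoch]) -> float:
    """Upper bound on lambda before clipping (transients assumed additive)."""
    peak = model.baseline
    a_on, _ = model.on_transient
    a_off, _ = model.off_transient
    trans = (0.0 if model.dra_occluded else max(a_on, 0.0) + max(a_off, 0.0))
    for epoch in epochs:
        peak = max(
            peak,
            model.baseline + model.tonic(epoch.dop) + model.amplitude(epoch.dop) + trans,
        )
    return peak


def _apply_dead_time(times: np.ndarray, dead_time: float) -> np.ndarray:
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= dead_time:
            kept.append(t)
            last = t
    return np.asarray(kept)


# --- cell-type presets -----------------------------------------------------
#
# Variants encode the qualitative response classes seen under
# near-unpolarized light (DoP = 0.002): tonic excitation or inhibition
# during the stimulus with an opposite-signed rebound at lights off,
# phasic onset transients in CL1a cells, and cells with no tonic change.
# Magnitudes are package defaults (ranges below); the source recordings
# report signs and prevalence, not per-cell magnitudes.

PRESET_VARIANTS: dict[str, dict[str, tuple[str, ...]]] = {
    "TL2": {"variants": ("inhibited-low-DoP", "excited-low-DoP", "no-change")},
    "TL3": {"variants": ("inhibited-low-DoP", "no-change")},
    "CL1a": {"variants": ("phasic-onset", "excited-low-DoP", "phasic-onset-excitation")},
    "TB1": {"variants": ("excited-rebound", "inhibited-rebound", "offset-excitation",
                         "no-rebound", "no-change")},
    "CPU1": {"variants": ("inhibited-rebound", "offset-excitation", "no-change")},
    "CPU2": {"variants": ("excited-offset-inhibition", "inhibited-rebound", "no-change")},
}

# amplitude-vs-DoP law per cell type: linear for TL2/CPU2, logarithmic
# for the rest; log parameters chosen so M vanishes at DoP = 0.002.
_LOG_A1 = 4.5
_LOG_A0 = _LOG_A1 * -np.log10(0.002)  # ~12.15 sp/s at DoP = 1


def _base_model(cell_type: str, rng: np.random.Generator) -> NeuronModel:
    baseline = float(rng.uniform(12.0, 25.0))
    phi = float(rng.uniform(0.0, 180.0))
    if cell_type in ("TL2", "CPU2"):
        law, params = "linear", (float(rng.uniform(10.0, 15.0)),)
    else:
        scale = float(rng.uniform(0.85, 1.15))
        law, params = "log", (_LOG_A0 * scale, _LOG_A1 * scale)
    return NeuronModel(
        baseline=baseline,
        phi_max_true=phi,
        amp_law=law,
        amp_params=params,
        rate_ceiling=80.0,
    )


def make_celltype_preset(
    cell_type: CellType | str,
    variant: str,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> NeuronModel:
    """Build a NeuronModel whose tonic/transient signs match a named
    response class for the given cell type; magnitudes drawn from the
    documented default ranges, reproducibly from ``seed``."""
    ct = CellType.coerce(cell_type).value
    if ct not in PRESET_VARIANTS or variant not in PRESET_VARIANTS[ct]["variants"]:
        known = PRESET_VARIANTS.get(ct, {}).get("variants", ())
        raise ValidationError(
            f"unknown preset variant {variant!r} for {ct}; known: {list(known)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = _base_model(ct, rng)

    def u(lo, hi):
        return float(rng.uniform(lo, hi))

    if variant == "inhibited-low-DoP":
        # tonic inhibition under unpolarized light, rebound excitation at off
        model = replace(model, tonic_gain=-u(5, 9), off_transient=(u(5, 10), u(3, 8)))
    elif variant == "excited-low-DoP":
        model = replace(model, tonic_gain=u(5, 9), off_transient=(-u(5, 10), u(3, 8)))
    elif variant == "phasic-onset":
        # phasic inhibition at lights on giving way to elevated activity,
        # rebound inhibition at lights off
        model = replace(
            model,
            tonic_gain=u(3, 6),
            on_transient=(-u(8, 15), u(0.5, 1.5)),
            off_transient=(-u(5, 10), u(1, 3)),
        )
    elif variant == "phasic-onset-excitation":
        model = replace(model, tonic_gain=u(2, 5), on_transient=(u(8, 15), u(0.5, 1.5)))
    elif variant == "excited-rebound":
        model = replace(model, tonic_gain=u(2, 4), off_transient=(-u(3, 6), u(2, 5)))
    elif variant == "inhibited-rebound":
        model = replace(model, tonic_gain=-u(2, 4), off_transient=(u(3, 6), u(2, 5)))
    elif variant == "offset-excitation":
        model = replace(model, off_transient=(u(5, 10), u(2, 5)))
    elif variant == "no-rebound":
        model = replace(model, tonic_gain=u(2, 4))
    elif variant == "excited-offset-inhibition":
        model = replace(model, tonic_gain=u(2, 4), off_transient=(-u(3, 6), u(2, 5)))
    elif variant == "no-change":
        model = replace(model, tonic_gain=0.0, on_transient=(0.0, 1.0),
                        off_transient=(0.0, 5.0))
    return model


# default cohort composition: modal variant per cell type, sized like a
# typical intracellular study of this system
DEFAULT_COHORT: tuple[tuple[str, str, int], ...] = (
    ("TL2", "inhibited-low-DoP", 5),
    ("TL2", "excited-low-DoP", 2),
    ("TL2", "no-change", 1),
    ("TL3", "inhibited-low-DoP", 1),
    ("TL3", "no-change", 4),
    ("CL1a", "phasic-onset", 10),
    ("CL1a", "excited-low-DoP", 3),
    ("CL1a", "phasic-onset-excitation", 1),
    ("TB1", "excited-rebound", 2),
    ("TB1", "inhibited-rebound", 2),
    ("TB1", "offset-excitation", 3),
    ("TB1", "no-rebound", 2),
    ("TB1", "no-change", 1),
    ("CPU1", "inhibited-rebound", 2),
    ("CPU1", "offset-excitation", 2),
    ("CPU1", "no-change", 4),
    ("CPU2", "excited-offset-inhibition", 1),
    ("CPU2", "inhibited-rebound", 2),
    ("CPU2", "no-change", 1),
)


def simulate_cohort(
    seed: int,
    composition=DEFAULT_COHORT,
    protocol: ProtocolSpec | None = None,
) -> list[Recording]:
    """Simulate a population of neurons, one Recording each.

    The master seed is expanded into independent per-neuron substreams
    with ``numpy.random.SeedSequence.spawn``, so adding a neuron to the
    composition never perturbs the draws of the others.
    """
    protocol = protocol or ProtocolSpec()
    recs = []
    ss = np.random.SeedSequence(seed)
    idx = 0
    for cell_type, variant, count in composition:
        for k in range(count):
            sub = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(idx,))
            model_rng, spike_rng = [np.random.default_rng(s) for s in sub.spawn(2)]
            model = make_celltype_preset(cell_type, variant, model_rng)
            rec = simulate_recording(
                model,
                protocol,
                spike_rng,
                neuron_id=f"{cell_type}-{variant}-{k}",
                cell_type=cell_type,
            )
            rec.metadata["variant"] = variant
            recs.append(rec)
            idx += 1
    return recs
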