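"""Reduced stochastic firing-rate model of the CBGT circuit.

The circuit comprises ten cell types — cortex (Cx), cortical interneurons
(CxI), fast-spiking interneurons (FSI), direct- and indirect-pathway spiny
projection neurons (dSPN, iSPN), prototypic and arkypallidal external
pallidum (GPeP, GPeA), subthalamic nucleus (STN), internal pallidum (GPi)
and thalamus (Th).  Eight of them are duplicated into left/right action
channels; CxI and FSI are shared, giving 18 population streams.

Each stream follows a rectified-linear rate equation driven by
Ornstein--Uhlenbeck noise,

    tau_p dr_p/dt = -r_p + [sum_q w_{q->p} r_q + I_p]_+ + xi_p(t),

integrated by Euler--Maruyama at 1 ms.  A trial starts with a baseline
segment, after which an identical constant stimulus is applied to both
cortical channels; the first thalamic stream to reach 30 Hz selects the
corresponding action.  Trial-level reinforcement learning follows a
reward-prediction-error rule acting on the corticostriatal weights:
positive dopamine signals potentiate Cx->dSPN and depress Cx->iSPN in
proportion to each channel's striatal eligibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NumericalInstabilityError, ParameterError

__all__ = [
    "CELL_TYPES",
    "CHANNELIZED_TYPES",
    "SHARED_TYPES",
    "STREAMS",
    "STREAM_NAMES",
    "PopulationStream",
    "NetworkConfig",
    "LearningState",
    "SessionPlan",
    "TrialRecord",
    "default_config",
    "sample_network",
    "simulate_trial",
    "reward_prediction_error",
    "apply_plasticity",
    "run_session",
    "stream_index",
]

CELL_TYPES = ("Cx", "CxI", "FSI", "dSPN", "iSPN", "GPeP", "GPeA", "STN", "GPi", "Th")
CHANNELIZED_TYPES = ("Cx", "dSPN", "iSPN", "GPeP", "GPeA", "STN", "GPi", "Th")
SHARED_TYPES = ("CxI", "FSI")


@dataclass(frozen=True)
class PopulationStream:
    """One population time series: a cell type in one action channel."""

    cell_type: str
    channel: str  # "L", "R", or "shared"

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ParameterError(f"unknown cell type {self.cell_type!r}")
        if self.cell_type in SHARED_TYPES:
            if self.channel != "shared":
                raise ParameterError(f"{self.cell_type} must be channel='shared'")
        elif self.channel not in ("L", "R"):
            raise ParameterError(f"{self.cell_type} must be channel 'L' or 'R'")

    @property
    def name(self) -> str:
        if self.channel == "shared":
            return self.cell_type
        return f"{self.cell_type}-{self.channel}"


def _build_streams() -> tuple[PopulationStream, ...]:
    streams = []
    for ct in CHANNELIZED_TYPES:
        for ch in ("L", "R"):
            streams.append(PopulationStream(ct, ch))
    for ct in SHARED_TYPES:
        streams.append(PopulationStream(ct, "shared"))
    return tuple(streams)


#: The 18 population streams in canonical order: the 8 channelized types as
#: (L, R) pairs, then the shared CxI and FSI.
STREAMS: tuple[PopulationStream, ...] = _build_streams()
STREAM_NAMES: tuple[str, ...] = tuple(s.name for s in STREAMS)
_STREAM_INDEX = {s.name: i for i, s in enumerate(STREAMS)}

N_STREAMS = 18

# Sign constraints of the pathway diagram: +1 excitatory, -1 inhibitory.
EDGE_SIGNS: dict[tuple[str, str], int] = {
    ("Cx", "dSPN"): +1,
    ("Cx", "iSPN"): +1,
    ("Cx", "Th"): +1,
    ("Cx", "CxI"): +1,
    ("Cx", "FSI"): +1,
    ("Th", "Cx"): +1,
    ("STN", "GPi"): +1,
    ("STN", "GPeP"): +1,
    ("dSPN", "GPi"): -1,
    ("iSPN", "GPeP"): -1,
    ("GPeP", "STN"): -1,
    ("GPeP", "GPi"): -1,
    ("GPeP", "GPeA"): -1,
    ("GPeA", "dSPN"): -1,
    ("GPeA", "iSPN"): -1,
    ("FSI", "dSPN"): -1,
    ("FSI", "iSPN"): -1,
    ("CxI", "Cx"): -1,
    ("GPi", "Th"): -1,
}


def stream_index(name: str) -> int:
    """Index of a stream (e.g. ``"Th-L"``, ``"FSI"``) in the canonical order."""
    return _STREAM_INDEX[name]


@dataclass
class NetworkConfig:
    """Parameters of the rate network and of the trial protocol.

    ``weights`` is keyed by (presynaptic type, postsynaptic type); the
    channel structure is implied — channelized pairs connect within a
    channel, shared interneurons project to and collect from both channels.
    The corticostriatal entries serve as the pre-learning initial values of
    the plastic per-channel weights.
    """

    weights: dict[tuple[str, str], float]
    baseline_hz: dict[str, float]
    tau_ms: dict[str, float]
    noise_sigma_hz: float = 2.0
    noise_tau_ms: float = 5.0
    stim_hz: float = 15.0
    #: constant hyperpolarising bias subtracted from the SPN input drive;
    #: keeps striatum rectified silent at baseline so the winner-take-all
    #: loop only engages once the cortical stimulus arrives
    spn_offset_hz: float = 3.0
    threshold_hz: float = 30.0
    max_duration_ms: float = 1000.0
    baseline_ms: float = 100.0
    dt_ms: float = 1.0
    # plasticity
    eta: float = 0.10
    alpha_v: float = 0.3
    #: clip bounds of the plastic corticostriatal weights; saturating the
    #: rewarded channel early shifts late learning toward suppression of
    #: the unrewarded channel
    w_dspn_bounds: tuple[float, float] = (1.0, 2.0)
    w_ispn_bounds: tuple[float, float] = (1.0, 1.45)
    #: exponent sharpening the normalised dSPN eligibility trace
    eligibility_sharpness: float = 3.0
    # consolidation-time distribution (ms)
    consolidation_mean_ms: float = 250.0
    consolidation_sd_ms: float = 1.5

    def __post_init__(self) -> None:
        for edge, w in self.weights.items():
            sign = EDGE_SIGNS.get(edge)
            if sign is None:
                raise ParameterError(f"edge {edge} is not in the pathway diagram")
            if w != 0 and np.sign(w) != sign:
                raise ParameterError(
                    f"edge {edge} must be {'excitatory' if sign > 0 else 'inhibitory'}"
                )

    def copy(self) -> "NetworkConfig":
        return replace(
            self,
            weights=dict(self.weights),
            baseline_hz=dict(self.baseline_hz),
            tau_ms=dict(self.tau_ms),
        )


@dataclass
class LearningState:
    """Value estimate and the plastic corticostriatal weights."""

    value_estimate: float = 0.0
    w_cx_dspn: dict[str, float] = field(default_factory=dict)  # per channel
    w_cx_ispn: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: NetworkConfig) -> "LearningState":
        wd = config.weights[("Cx", "dSPN")]
        wi = config.weights[("Cx", "iSPN")]
        return cls(0.0, {"L": wd, "R": wd}, {"L": wi, "R": wi})

    def copy(self) -> "LearningState":
        return LearningState(
            self.value_estimate, dict(self.w_cx_dspn), dict(self.w_cx_ispn)
        )


@dataclass
class SessionPlan:
    """A pre / training / post session under a reward rule."""

    n_train: int
    n_pre: int = 50
    n_post: int = 50
    reward_rule: dict[str, float] = field(
        default_factory=lambda: {"L": 1.0, "R": 0.0}
    )
    seed: int = 0


@dataclass
class TrialRecord:
    """One simulated trial.

    ``rates`` covers the baseline segment plus the decision period sampled
    at ``dt_ms``; ``onset_index`` marks the cue-onset sample.  ``decision_time``
    is measured from cue onset and is ``nan`` when no thalamic stream
    reached threshold (choice ``"none"``).
    """

    trial_index: int
    rates: np.ndarray  # [time, 18]
    choice: str  # "L" | "R" | "none"
    decision_time: float  # ms
    consolidation_time: float  # ms
    learning_stage: int
    onset_index: int
    dt_ms: float
    block: str = ""  # "pre" | "train" | "post" (optional tag)

    @property
    def decided(self) -> bool:
        return self.choice in ("L", "R")

    @property
    def decision_rates(self) -> np.ndarray:
        """Rates from cue onset to the decision (or trial end)."""
        return self.rates[self.onset_index:]


def default_config() -> NetworkConfig:
    """The shipped reference configuration.

    Calibrated so that, pre-learning, choices are unbiased with mean
    decision time near 130 ms, and 30 training trials of deterministic
    left reward raise P(choose L) to about 0.9 while the mean decision
    time falls to about 100 ms.
    """
    weights = {
        ("Cx", "dSPN"): 1.80,
        ("Cx", "iSPN"): 1.20,
        ("Cx", "Th"): 0.60,
        ("Cx", "CxI"): 0.60,
        ("Cx", "FSI"): 0.60,
        ("Th", "Cx"): 0.45,
        ("STN", "GPi"): 0.40,
        ("STN", "GPeP"): 0.30,
        ("dSPN", "GPi"): -1.50,
        ("iSPN", "GPeP"): -0.80,
        ("GPeP", "STN"): -0.40,
        ("GPeP", "GPi"): -0.30,
        ("GPeP", "GPeA"): -0.50,
        ("GPeA", "dSPN"): -0.30,
        ("GPeA", "iSPN"): -0.30,
        ("FSI", "dSPN"): -0.70,
        ("FSI", "iSPN"): -0.70,
        ("CxI", "Cx"): -0.70,
        ("GPi", "Th"): -1.00,
    }
    baseline_hz = {
        "Cx": 5.0,
        "CxI": 5.0,
        "FSI": 10.0,
        "dSPN": 0.0,
        "iSPN": 0.0,
        "GPeP": 40.0,
        "GPeA": 10.0,
        "STN": 15.0,
        "GPi": 30.0,
        "Th": 8.0,
    }
    tau_ms = {
        "Cx": 12.0,
        "CxI": 8.0,
        "FSI": 8.0,
        "dSPN": 15.0,
        "iSPN": 15.0,
        "GPeP": 10.0,
        "GPeA": 15.0,
        "STN": 10.0,
        "GPi": 10.0,
        "Th": 12.0,
    }
    return NetworkConfig(
        weights=weights,
        baseline_hz=baseline_hz,
        tau_ms=tau_ms,
        noise_sigma_hz=2.5,
        stim_hz=12.8,
    )


# ---------------------------------------------------------------------------
# matrix assembly


def _weight_matrix(config: NetworkConfig, learning: LearningState | None) -> np.ndarray:
    """Expand type-level weights into the 18x18 stream matrix W[post, pre]."""
    W = np.zeros((N_STREAMS, N_STREAMS))
    wd = learning.w_cx_dspn if learning is not None else None
    wi = learning.w_cx_ispn if learning is not None else None
    for (pre_t, post_t), w in config.weights.items():
        pre_shared = pre_t in SHARED_TYPES
        post_shared = post_t in SHARED_TYPES
        for ch in ("L", "R"):
            if pre_t == "Cx" and post_t == "dSPN" and wd is not None:
                w_eff = wd[ch]
            elif pre_t == "Cx" and post_t == "iSPN" and wi is not None:
                w_eff = wi[ch]
            else:
                w_eff = w
            pre = pre_t if pre_shared else f"{pre_t}-{ch}"
            post = post_t if post_shared else f"{post_t}-{ch}"
            W[_STREAM_INDEX[post], _STREAM_INDEX[pre]] = w_eff
            if pre_shared and post_shared:  # no such edge in the diagram
                break
    return W


def _baseline_vector(config: NetworkConfig) -> np.ndarray:
    return np.array([config.baseline_hz[s.cell_type] for s in STREAMS])


def _external_input(config: NetworkConfig, W: np.ndarray) -> np.ndarray:
    """Constant input making the baseline targets a noise-free fixed point.

    SPN rows additionally receive the negative ``spn_offset_hz`` bias, so
    with baseline targets of zero their drive rests below the rectification
    threshold.
    """
    r0 = _baseline_vector(config)
    I = r0 - W @ r0
    for ch in ("L", "R"):
        for ct in ("dSPN", "iSPN"):
            I[_STREAM_INDEX[f"{ct}-{ch}"]] -= config.spn_offset_hz
    return I


# ---------------------------------------------------------------------------
# operations


def sample_network(
    base_config: NetworkConfig, jitter_scale: float, seed: int
) -> NetworkConfig:
    """Draw a network instance by jittering every connection weight.

    Each type-level weight is multiplied by an independent factor uniform
    on [1 - jitter_scale, 1 + jitter_scale].  Because weights are stored at
    the type level the left and right counterparts of every edge receive
    the same factor, so pre-learning channel symmetry is preserved exactly.
    """
    if not 0.0 <= jitter_scale <= 0.5:
        raise ParameterError("jitter_scale must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    cfg = base_config.copy()
    # sorted for draw-order determinism independent of dict insertion order
    for edge in sorted(cfg.weights):
        factor = rng.uniform(1.0 - jitter_scale, 1.0 + jitter_scale)
        cfg.weights[edge] = cfg.weights[edge] * factor
    return cfg


def simulate_trial(
    config: NetworkConfig,
    learning: LearningState | None = None,
    seed: int | np.random.Generator = 0,
    trial_index: int = 0,
    learning_stage: int = 0,
    store_rates: bool = True,
) -> TrialRecord:
    """Integrate one trial and record the outcome.

    The network starts at its baseline fixed point, runs ``baseline_ms``
    without stimulus, then receives the cortical stimulus in both channels
    until either thalamic stream crosses ``threshold_hz`` (the selected
    action) or ``max_duration_ms`` elapses (choice ``"none"``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if learning is None:
        learning = LearningState.from_config(config)
    dt = config.dt_ms
    W = _weight_matrix(config, learning)
    I_ext = _external_input(config, W)
    tau = np.array([config.tau_ms[s.cell_type] for s in STREAMS])
    n_base = int(round(config.baseline_ms / dt))
    n_max = n_base + int(round(config.max_duration_ms / dt))

    stim = np.zeros(N_STREAMS)
    stim[_STREAM_INDEX["Cx-L"]] = config.stim_hz
    stim[_STREAM_INDEX["Cx-R"]] = config.stim_hz

    i_thL = _STREAM_INDEX["Th-L"]
    i_thR = _STREAM_INDEX["Th-R"]

    # OU noise: xi' = -xi/tau_n + sigma*sqrt(2/tau_n)*dW
    tau_n = config.noise_tau_ms
    sig = config.noise_sigma_hz
    ou_decay = 1.0 - dt / tau_n
    ou_scale = sig * np.sqrt(2.0 * dt / tau_n)
    normals = rng.standard_normal((n_max + 1, N_STREAMS))

    r = _baseline_vector(config).astype(float)
    xi = np.zeros(N_STREAMS)
    rates = np.empty((n_max + 1, N_STREAMS)) if store_rates else None
    if store_rates:
        rates[0] = r

    dt_over_tau = dt / tau
    choice = "none"
    decision_time = float("nan")
    n_end = n_max
    for step in range(1, n_max + 1):
        drive = W @ r + I_ext
        if step > n_base:
            drive = drive + stim
        xi = ou_decay * xi + ou_scale * normals[step]
        r = r + dt_over_tau * (-r + np.maximum(drive, 0.0) + xi)
        np.maximum(r, 0.0, out=r)
        if store_rates:
            rates[step] = r
        if step > n_base:
            th_l, th_r = r[i_thL], r[i_thR]
            if th_l >= config.threshold_hz or th_r >= config.threshold_hz:
                choice = "L" if th_l >= th_r else "R"
                decision_time = (step - n_base) * dt
                n_end = step
                break
    if not np.all(np.isfinite(r)):
        bad = STREAM_NAMES[int(np.argmax(~np.isfinite(r)))]
        raise NumericalInstabilityError(f"non-finite rate in stream {bad}")

    consolidation = float(
        rng.normal(config.consolidation_mean_ms, config.consolidation_sd_ms)
    )
    return TrialRecord(
        trial_index=trial_index,
        rates=rates[: n_end + 1] if store_rates else np.empty((0, N_STREAMS)),
        choice=choice,
        decision_time=decision_time,
        consolidation_time=consolidation,
        learning_stage=learning_stage,
        onset_index=n_base,
        dt_ms=dt,
    )


def reward_prediction_error(reward: float, learning: LearningState,
                            alpha_v: float = 0.1) -> float:
    """Dopaminergic learning signal: received minus expected reward.

    Returns delta = reward - V and updates the value estimate in place,
    V <- V + alpha_v * delta.
    """
    delta = float(reward) - learning.value_estimate
    learning.value_estimate += alpha_v * delta
    return delta


def apply_plasticity(
    learning: LearningState,
    delta: float,
    eligibility: dict[str, float],
    eta: float,
    dspn_bounds: tuple[float, float] = (1.0, 2.0),
    ispn_bounds: tuple[float, float] = (1.0, 1.45),
) -> LearningState:
    """Dopamine-modulated corticostriatal update (in place).

    Positive dopamine potentiates Cx->dSPN and depresses Cx->iSPN in each
    channel in proportion to that channel's eligibility; negative dopamine
    reverses both signs.  Each projection is clipped to its configured
    bounds.
    """
    for ch in ("L", "R"):
        e = eligibility.get(ch, 0.0)
        if e < 0:
            raise ParameterError("eligibility must be non-negative")
        learning.w_cx_dspn[ch] = float(
            np.clip(learning.w_cx_dspn[ch] + eta * delta * e, *dspn_bounds)
        )
        learning.w_cx_ispn[ch] = float(
            np.clip(learning.w_cx_ispn[ch] - eta * delta * e, *ispn_bounds)
        )
    return learning


def _eligibility(trial: TrialRecord, sharpness: float = 3.0) -> dict[str, float]:
    """Per-channel striatal eligibility trace.

    The trial-mean dSPN rate of each channel, raised to ``sharpness`` and
    normalised across channels.  dSPN rates carry the channel asymmetry at
    decision time (iSPN rates are nearly symmetric and would dilute the
    trace); the exponent makes the trace winner-dominated, approximating
    credit assignment to the channel whose activity produced the choice.
    """
    seg = trial.decision_rates
    if seg.size == 0:
        return {"L": 0.5, "R": 0.5}
    e = {
        ch: float(seg[:, _STREAM_INDEX[f"dSPN-{ch}"]].mean()) ** sharpness
        for ch in ("L", "R")
    }
    total = e["L"] + e["R"]
    if total <= 0:
        return {"L": 0.5, "R": 0.5}
    return {ch: v / total for ch, v in e.items()}


def run_session(
    config: NetworkConfig,
    plan: SessionPlan,
    store_rates: bool = True,
) -> list[TrialRecord]:
    """Run a full pre / training / post session.

    Plasticity acts only during the training block; the value estimate and
    corticostriatal weights carry forward across training trials and are
    frozen for the post block.  Fully reproducible from ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    learning = LearningState.from_config(config)
    records: list[TrialRecord] = []
    idx = 0

    for _ in range(plan.n_pre):
        rec = simulate_trial(config, learning, rng, idx, 0, store_rates)
        rec.block = "pre"
        records.append(rec)
        idx += 1

    for j in range(plan.n_train):
        # rates are always needed within training for the eligibility trace
        rec = simulate_trial(config, learning, rng, idx, j, True)
        rec.block = "train"
        if rec.decided:
            p_reward = plan.reward_rule.get(rec.choice, 0.0)
            reward = 1.0 if rng.random() < p_reward else 0.0
            delta = reward_prediction_error(reward, learning, config.alpha_v)
            apply_plasticity(
                learning,
                delta,
                _eligibility(rec, config.eligibility_sharpness),
                config.eta,
                config.w_dspn_bounds,
                config.w_ispn_bounds,
            )
        if not store_rates:
            rec.rates = np.empty((0, N_STREAMS))
        records.append(rec)
        idx += 1

    for _ in range(plan.n_post):
        rec = simulate_trial(config, learning, rng, idx, plan.n_train, store_rates)
        rec.block = "post"
        records.append(rec)
        idx += 1

    n_none = sum(1 for r in records if not r.decided)
    if n_none:
        warnings.warn(
            f"{n_none}/{len(records)} trials ended without a decision",
            stacklevel=2,
        )
    return records
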