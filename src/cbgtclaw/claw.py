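"""CLAW — Circuit Logic Assessed via Walks.

Discretises population firing-rate time series into binary network states,
estimates the empirical state-transition chain, partitions states into six
functional zones (launching, deliberation, left/right commitment, deep
deliberation, reversal), and classifies per-trial decision trajectories.

The state space is built from N=10 populations — dSPN, iSPN, GPi, GPeP and
Th in each action channel — binarised per 10 ms bin against thresholds
derived from the pooled firing-rate histogram of each stream.  A state is
the base-2 encoding of the 10 bits in a declared stream order.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import entropy

from .errors import ConfigurationError, MissingDataError, ParameterError
from .synth import TrialRecord, stream_index

__all__ = [
    "DEFAULT_STATE_STREAMS",
    "BinarizationScheme",
    "StateSequence",
    "ClawModel",
    "bin_rates",
    "compute_thresholds",
    "encode_state",
    "decode_state",
    "state_sequence",
    "transition_matrix",
    "extract_claw",
    "assign_zones",
    "classify_trajectory",
    "state_statistics",
    "zone_statistics",
    "compare_claws",
    "zone_transition_table",
]

#: Declared bit order, most-significant first.
DEFAULT_STATE_STREAMS: tuple[str, ...] = (
    "dSPN-L", "iSPN-L", "GPi-L", "GPeP-L", "Th-L",
    "dSPN-R", "iSPN-R", "GPi-R", "GPeP-R", "Th-R",
)
N_BITS = 10
N_STATES = 2 ** N_BITS

ZONES = ("I", "II", "III", "IV", "V", "VI")


@dataclass
class BinarizationScheme:
    """Bin width and per-stream binarisation thresholds (Hz)."""

    bin_width_ms: float = 10.0
    thresholds: dict[str, float] = field(default_factory=dict)
    degenerate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, thr in self.thresholds.items():
            if not np.isfinite(thr):
                raise ParameterError(f"threshold for {name} must be finite")


@dataclass
class StateSequence:
    """A trial as a run-length-collapsed walk through network states."""

    states: list[int]
    dwells: list[int]  # bins spent in each state

    @property
    def n_bins(self) -> int:
        return int(sum(self.dwells))

    def expand(self) -> np.ndarray:
        return np.repeat(self.states, self.dwells)


# ---------------------------------------------------------------------------
# binning and binarisation


def bin_rates(rates: np.ndarray, bin_width_ms: float, dt_ms: float = 1.0) -> np.ndarray:
    """Average a [time x stream] rate matrix into fixed-width bins.

    A trailing partial bin is dropped.
    """
    per_bin = bin_width_ms / dt_ms
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ParameterError("bin width must be a multiple of the time step")
    per_bin = int(round(per_bin))
    n_bins = rates.shape[0] // per_bin
    if n_bins == 0:
        return np.empty((0, rates.shape[1]))
    trimmed = rates[: n_bins * per_bin]
    return trimmed.reshape(n_bins, per_bin, rates.shape[1]).mean(axis=1)


def _antimode(samples: np.ndarray) -> float | None:
    """Minimum-density antimode between the two largest histogram modes.

    Returns None when the Freedman--Diaconis histogram is effectively
    unimodal: fewer than two local maxima, or a between-mode dip shallower
    than half the smaller mode (noise wrinkles on one bump otherwise pass
    as separate modes).
    """
    counts, edges = np.histogram(samples, bins="fd")
    if len(counts) < 5:
        return None
    # moving-average smoothing removes sampling wrinkles that would
    # otherwise read as separate modes on one bump
    w = max(3, len(counts) // 20) | 1
    kernel = np.ones(w) / w
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    maxima = argrelextrema(padded, np.greater)[0] - 1
    if len(maxima) < 2:
        return None
    top2 = maxima[np.argsort(smooth[maxima])[-2:]]
    lo, hi = sorted(top2)
    if hi - lo < max(3, w):  # modes must be separated in value
        return None
    between = smooth[lo + 1: hi]
    dip = between.min()
    if dip > 0.8 * min(smooth[lo], smooth[hi]):
        return None
    k = lo + 1 + int(np.argmin(between))
    return float(0.5 * (edges[k] + edges[k + 1]))


def compute_thresholds(
    samples: dict[str, np.ndarray],
    bin_width_ms: float = 10.0,
    min_samples: int = 1000,
) -> BinarizationScheme:
    """Derive per-stream binarisation thresholds from pooled rate samples.

    The threshold sits at the minimum-density antimode between the two
    largest modes of the pooled histogram; unimodal streams fall back to
    median + 2*MAD.  Deterministic given the samples.
    """
    scheme = BinarizationScheme(bin_width_ms=bin_width_ms)
    for name, x in samples.items():
        x = np.asarray(x, dtype=float).ravel()
        if x.size == 0:
            raise MissingDataError(f"no samples for stream {name}")
        if x.size < min_samples:
            warnings.warn(
                f"stream {name}: only {x.size} samples (<{min_samples})",
                stacklevel=2,
            )
        if np.ptp(x) == 0:
            scheme.thresholds[name] = float(x[0])
            scheme.degenerate.add(name)
            continue
        thr = _antimode(x)
        if thr is None:
            # quantile fallback, oriented toward the stream's informative
            # deviation: engagement (right skew) or suppression (left skew)
            med = float(np.median(x))
            mad = float(np.median(np.abs(x - med)))
            sign = 1.0 if float(np.mean(x)) >= med else -1.0
            thr = med + sign * 2.0 * mad
        scheme.thresholds[name] = thr
    return scheme


# ---------------------------------------------------------------------------
# state encoding


def encode_state(bits: np.ndarray | list[int]) -> int:
    """Base-2 encoding of the bit vector (most-significant bit first)."""
    bits = np.asarray(bits)
    if bits.shape != (N_BITS,):
        raise ParameterError(f"expected {N_BITS} bits, got shape {bits.shape}")
    k = 0
    for b in bits:
        k = (k << 1) | int(b)
    return k


def decode_state(k: int) -> np.ndarray:
    """Inverse of :func:`encode_state`."""
    if not 0 <= k < N_STATES:
        raise ParameterError(f"state index {k} outside [0, {N_STATES - 1}]")
    return np.array([(k >> (N_BITS - 1 - j)) & 1 for j in range(N_BITS)])


def _bit(k: int, stream: str, streams: tuple[str, ...] = DEFAULT_STATE_STREAMS) -> int:
    j = streams.index(stream)
    return (k >> (N_BITS - 1 - j)) & 1


def binarize(
    binned: np.ndarray,
    scheme: BinarizationScheme,
    streams: tuple[str, ...] = DEFAULT_STATE_STREAMS,
    stream_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Binarise binned rates for the state-defining streams.

    ``binned`` is [bin x 18] in the canonical stream order unless
    ``stream_names`` gives another order.
    """
    cols = []
    for s in streams:
        idx = stream_names.index(s) if stream_names is not None else stream_index(s)
        cols.append(binned[:, idx] > scheme.thresholds[s])
    return np.stack(cols, axis=1).astype(np.uint8)


def state_sequence(binary: np.ndarray) -> StateSequence:
    """Collapse a [bin x N] binary matrix into a run-length state walk."""
    if binary.shape[0] == 0:
        return StateSequence([], [])
    weights = 1 << np.arange(N_BITS - 1, -1, -1)
    codes = binary @ weights
    states, dwells = [], []
    for k in codes:
        if states and states[-1] == k:
            dwells[-1] += 1
        else:
            states.append(int(k))
            dwells.append(1)
    return StateSequence(states, dwells)


# ---------------------------------------------------------------------------
# transition chain


def transition_matrix(sequences: list[StateSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical transition probabilities pooled over trials.

    Self-transitions (dwell loops) are included.  Returns ``(P, counts)``
    where P[i, j] = P(next=j | current=i) on visited rows (all-zero on
    unvisited rows) and ``counts`` are raw transition counts.
    """
    if not sequences:
        raise MissingDataError("no state sequences provided")
    counts = np.zeros((N_STATES, N_STATES))
    for seq in sequences:
        for s, d in zip(seq.states, seq.dwells):
            if d > 1:
                counts[s, s] += d - 1
        for a, b in zip(seq.states[:-1], seq.states[1:]):
            counts[a, b] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row > 0, counts / np.where(row > 0, row, 1.0), 0.0)
    return P, counts


def visit_counts(sequences: list[StateSequence]) -> np.ndarray:
    """Number of trials visiting each state."""
    v = np.zeros(N_STATES, dtype=int)
    for seq in sequences:
        for s in set(seq.states):
            v[s] += 1
    return v


def extract_claw(
    P: np.ndarray,
    counts: np.ndarray,
    visits: np.ndarray,
    min_edge_prob: float = 0.01,
    min_visits: int = 20,
) -> nx.DiGraph:
    """High-probability transition subgraph (the CLAW diagram)."""
    if not 0 < min_edge_prob <= 1:
        raise ParameterError("min_edge_prob must be in (0, 1]")
    if min_visits < 1:
        raise ParameterError("min_visits must be >= 1")
    g = nx.DiGraph()
    keep = np.flatnonzero(visits >= min_visits)
    for s in keep:
        g.add_node(int(s), visits=int(visits[s]))
    for s in keep:
        for t in keep:
            if P[s, t] >= min_edge_prob and counts[s, t] > 0:
                g.add_edge(int(s), int(t), prob=float(P[s, t]), count=float(counts[s, t]))
    return g


# ---------------------------------------------------------------------------
# zones


def _dominant(k: int, ch: str, streams: tuple[str, ...]) -> bool:
    opp = "R" if ch == "L" else "L"
    return (
        _bit(k, f"dSPN-{ch}", streams) == 1
        and _bit(k, f"GPi-{ch}", streams) == 0
        and _bit(k, f"Th-{ch}", streams) == 1
        and _bit(k, f"dSPN-{opp}", streams) == 0
    )


def _reversal(k: int, streams: tuple[str, ...]) -> bool:
    """Commitment in one channel carrying the disinhibition trace of prior
    commitment in the other: the opposite channel's GPi is still off and
    its thalamus still elevated although its dSPN has turned off."""
    for ch, opp in (("L", "R"), ("R", "L")):
        if (
            _dominant(k, ch, streams)
            and _bit(k, f"GPi-{opp}", streams) == 0
            and _bit(k, f"Th-{opp}", streams) == 1
        ):
            return True
    return False


def assign_zones(
    graph: nx.DiGraph,
    baseline_state: int,
    streams: tuple[str, ...] = DEFAULT_STATE_STREAMS,
    user_map: dict[int, str] | None = None,
) -> dict[int, str]:
    """Partition CLAW states into the six functional zones.

    Rule-based classifier, applied in order of precedence:

    I    the pre-stimulus baseline state;
    VI   reversal: committed pattern in one channel while the opposite
         channel — its dSPN now off — still carries the disinhibition trace
         of an earlier commitment (GPi off, thalamus elevated);
    III  left-committed: dSPN-L on, GPi-L off, Th-L on, dSPN-R off;
    IV   right-committed (mirror image);
    V    deep deliberation: member of a directed cycle of length >= 3 among
         the remaining states, not entered directly from baseline;
    II   remaining states with bilateral iSPN engagement or without
         channel dominance;
    any state matching no rule is labelled "other".

    A user-supplied ``user_map`` overrides the classifier verbatim.
    """
    if user_map is not None:
        return dict(user_map)
    if baseline_state not in graph:
        raise ConfigurationError(
            f"baseline state {baseline_state} not present in the CLAW graph"
        )
    zones: dict[int, str] = {baseline_state: "I"}
    nodes = [n for n in graph.nodes if n != baseline_state]

    for k in nodes:
        if _reversal(k, streams):
            zones[k] = "VI"
        elif _dominant(k, "L", streams):
            zones[k] = "III"
        elif _dominant(k, "R", streams):
            zones[k] = "IV"

    remaining = [k for k in nodes if k not in zones]
    sub = graph.subgraph(remaining)
    from_baseline = set(graph.successors(baseline_state))
    # states on directed cycles of length >= 3: members of a strongly
    # connected component that is larger than a mutual 2-cycle
    cycle_states: set[int] = set()
    for comp in nx.strongly_connected_components(sub):
        if len(comp) >= 3:
            cycle_states.update(comp)
    for k in cycle_states:
        if k not in from_baseline:
            zones[k] = "V"

    for k in remaining:
        if k in zones:
            continue
        bilateral_ispn = (
            _bit(k, "iSPN-L", streams) == 1 and _bit(k, "iSPN-R", streams) == 1
        )
        left_dom = _bit(k, "dSPN-L", streams) == 1 and _bit(k, "dSPN-R", streams) == 0
        right_dom = _bit(k, "dSPN-R", streams) == 1 and _bit(k, "dSPN-L", streams) == 0
        if bilateral_ispn or not (left_dom or right_dom):
            zones[k] = "II"
        else:
            zones[k] = "other"
    return zones


def zone_path(seq: StateSequence, zones: dict[int, str]) -> list[str]:
    """Project a state walk onto zones, collapsing repeats."""
    path: list[str] = []
    for s in seq.states:
        z = zones.get(s, "other")
        if not path or path[-1] != z:
            path.append(z)
    return path


def classify_trajectory(path: list[str]) -> str:
    """Assign a decision-trajectory class to a zone path.

    A: purely deliberative; B: deliberation then commitment; C: direct
    commitment; D: commitment followed by reversal.  Paths not starting in
    the launching zone are flagged "unclassified".
    """
    if not path or path[0] != "I":
        return "unclassified"
    committed_at = None
    saw_ii_before_commit = False
    label = "A"
    for i, z in enumerate(path):
        if z == "II" and committed_at is None:
            saw_ii_before_commit = True
        elif z in ("III", "IV"):
            if committed_at is None:
                committed_at = i
        elif z == "VI" and committed_at is not None:
            return "D"
    if committed_at is not None:
        label = "B" if saw_ii_before_commit else "C"
    return label


# ---------------------------------------------------------------------------
# statistics


def _kl_decision_times(dt_l: np.ndarray, dt_r: np.ndarray, eps: float = 1e-9) -> float:
    """KL(P_DT|L || P_DT|R) on a shared histogram grid, natural log."""
    if len(dt_l) == 0 or len(dt_r) == 0:
        return float("nan")
    pooled = np.concatenate([dt_l, dt_r])
    edges = np.histogram_bin_edges(pooled, bins=20)
    p, _ = np.histogram(dt_l, bins=edges)
    q, _ = np.histogram(dt_r, bins=edges)
    p = p.astype(float) + eps
    q = q.astype(float) + eps
    return float(entropy(p / p.sum(), q / q.sum()))


def _group_statistics(trials, groups) -> pd.DataFrame:
    rows = []
    for key, idx in groups.items():
        sel = [trials[i] for i in idx]
        dts = np.array([t.decision_time for t in sel])
        choices = np.array([t.choice for t in sel])
        dt_l, dt_r = dts[choices == "L"], dts[choices == "R"]
        rows.append(
            {
                "key": key,
                "n_trials": len(sel),
                "mean_dt_ms": float(dts.mean()),
                "p_left": float(np.mean(choices == "L")),
                "kl_lr_nats": _kl_decision_times(dt_l, dt_r),
            }
        )
    return pd.DataFrame(rows).set_index("key").sort_index()


def state_statistics(
    trials: list[TrialRecord], sequences: list[StateSequence]
) -> pd.DataFrame:
    """Per-state decision statistics over the trials visiting each state."""
    for t in trials:
        if not t.decided:
            raise MissingDataError("state statistics require decided trials")
    groups: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        for s in set(seq.states):
            groups.setdefault(s, []).append(i)
    return _group_statistics(trials, groups)


def zone_statistics(
    trials: list[TrialRecord],
    sequences: list[StateSequence],
    zones: dict[int, str],
) -> pd.DataFrame:
    """Per-zone decision statistics over the trials visiting each zone."""
    for t in trials:
        if not t.decided:
            raise MissingDataError("zone statistics require decided trials")
    groups: dict[str, list[int]] = {}
    for i, seq in enumerate(sequences):
        for z in {zones.get(s, "other") for s in seq.states}:
            groups.setdefault(z, []).append(i)
    return _group_statistics(trials, groups)


def zone_transition_table(
    sequences: list[StateSequence], zones: dict[int, str]
) -> pd.DataFrame:
    """Zone-to-zone transition probabilities (including dwell loops)."""
    labels = list(ZONES) + ["other"]
    counts = pd.DataFrame(0.0, index=labels, columns=labels)
    for seq in sequences:
        zp = [zones.get(s, "other") for s in seq.expand()]
        for a, b in zip(zp[:-1], zp[1:]):
            counts.loc[a, b] += 1
    row = counts.sum(axis=1)
    probs = counts.div(row.where(row > 0, 1.0), axis=0)
    probs[row == 0] = 0.0
    return probs


def compare_claws(
    table_old: pd.DataFrame, table_new: pd.DataFrame, rel_threshold: float = 0.10
) -> pd.DataFrame:
    """Flag zone transitions whose relative probability change exceeds
    ``rel_threshold``.

    Transitions appearing from zero probability are flagged "new" rather
    than divided by zero.
    """
    if not table_old.index.equals(table_new.index):
        raise ParameterError("zone tables must share the same zone set")
    rows = []
    for a in table_old.index:
        for b in table_old.columns:
            p_old = float(table_old.loc[a, b])
            p_new = float(table_new.loc[a, b])
            if p_old == 0.0:
                if p_new > 0.0:
                    rows.append((a, b, p_old, p_new, np.inf, "new"))
                continue
            rel = (p_new - p_old) / p_old
            if abs(rel) > rel_threshold:
                direction = "increase" if rel > 0 else "decrease"
                rows.append((a, b, p_old, p_new, rel, direction))
    return pd.DataFrame(
        rows, columns=["from", "to", "p_old", "p_new", "rel_change", "direction"]
    )


# ---------------------------------------------------------------------------
# estimator


class ClawModel:
    """Fit the CLAW discretisation on a set of trials.

    Parameters
    ----------
    bin_width_ms : width of the discretisation bin (default 10 ms).
    min_edge_prob, min_visits : thresholds of the high-probability subgraph.
    state_streams : bit order of the state encoding, most-significant first.
    user_zone_map : optional explicit state->zone association overriding the
        rule-based classifier.

    Attributes (after :meth:`fit`)
    ------------------------------
    scheme_ : the binarisation thresholds.
    sequences_ : per-trial state walks (decision period, truncated at the
        decision bin).
    transition_matrix_, counts_, visits_ : the empirical chain.
    graph_ : the CLAW subgraph.
    baseline_state_ : modal pre-stimulus state.
    zones_ : state->zone association.
    """

    def __init__(
        self,
        bin_width_ms: float = 10.0,
        min_edge_prob: float = 0.01,
        min_visits: int = 20,
        state_streams: tuple[str, ...] = DEFAULT_STATE_STREAMS,
        user_zone_map: dict[int, str] | None = None,
    ):
        self.bin_width_ms = bin_width_ms
        self.min_edge_prob = min_edge_prob
        self.min_visits = min_visits
        self.state_streams = state_streams
        self.user_zone_map = user_zone_map

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bin_width_ms": self.bin_width_ms,
            "min_edge_prob": self.min_edge_prob,
            "min_visits": self.min_visits,
            "state_streams": self.state_streams,
            "user_zone_map": self.user_zone_map,
        }

    def set_params(self, **params) -> "ClawModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ParameterError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------

    def _binarize_trial(self, trial: TrialRecord, segment: str) -> np.ndarray:
        if segment == "decision":
            raw = trial.decision_rates
        else:
            raw = trial.rates[: trial.onset_index]
        binned = bin_rates(raw, self.bin_width_ms, trial.dt_ms)
        return binarize(binned, self.scheme_, self.state_streams)

    def _trial_sequence(self, trial: TrialRecord) -> StateSequence:
        """State walk of one trial: the modal pre-stimulus state followed by
        the decision-period states (bin flicker would otherwise randomise
        the departure point of the walk)."""
        seq = state_sequence(self._binarize_trial(trial, "decision"))
        pre = state_sequence(self._binarize_trial(trial, "baseline"))
        if pre.states:
            counts = Counter()
            for s, d in zip(pre.states, pre.dwells):
                counts[s] += d
            s0 = counts.most_common(1)[0][0]
            if seq.states and seq.states[0] == s0:
                seq.dwells[0] += 1
            else:
                seq.states.insert(0, s0)
                seq.dwells.insert(0, 1)
        return seq

    def fit(self, trials: list[TrialRecord]) -> "ClawModel":
        if not trials:
            raise MissingDataError("no trials to fit")
        pooled = {
            s: np.concatenate(
                [
                    bin_rates(t.rates, self.bin_width_ms, t.dt_ms)[:, stream_index(s)]
                    for t in trials
                ]
            )
            for s in self.state_streams
        }
        self.scheme_ = compute_thresholds(pooled, self.bin_width_ms)

        # modal pre-stimulus state across trials
        base_counter: Counter = Counter()
        for t in trials:
            b = self._binarize_trial(t, "baseline")
            for k in state_sequence(b).states:
                base_counter[k] += 1
        if not base_counter:
            raise ConfigurationError("trials contain no pre-stimulus bins")
        self.baseline_state_ = base_counter.most_common(1)[0][0]

        self.sequences_ = [self._trial_sequence(t) for t in trials]
        self.transition_matrix_, self.counts_ = transition_matrix(self.sequences_)
        self.visits_ = visit_counts(self.sequences_)
        self.graph_ = extract_claw(
            self.transition_matrix_,
            self.counts_,
            self.visits_,
            self.min_edge_prob,
            self.min_visits,
        )
        if self.baseline_state_ not in self.graph_:
            # baseline must anchor zone I even if rarely revisited
            self.graph_.add_node(
                self.baseline_state_, visits=int(self.visits_[self.baseline_state_])
            )
        self.zones_ = assign_zones(
            self.graph_, self.baseline_state_, self.state_streams, self.user_zone_map
        )
        if self.user_zone_map is None:
            # rare states below the visit threshold still occur in walks;
            # give them the pattern-based label (cycle rule needs the graph,
            # so none of them can be V)
            for seq in self.sequences_:
                for s in seq.states:
                    if s in self.zones_:
                        continue
                    self.zones_[s] = self._pattern_zone(s)
        return self

    def _pattern_zone(self, k: int) -> str:
        st = self.state_streams
        if k == self.baseline_state_:
            return "I"
        if _reversal(k, st):
            return "VI"
        if _dominant(k, "L", st):
            return "III"
        if _dominant(k, "R", st):
            return "IV"
        bilateral = _bit(k, "iSPN-L", st) and _bit(k, "iSPN-R", st)
        left_dom = _bit(k, "dSPN-L", st) and not _bit(k, "dSPN-R", st)
        right_dom = _bit(k, "dSPN-R", st) and not _bit(k, "dSPN-L", st)
        if bilateral or not (left_dom or right_dom):
            return "II"
        return "other"

    # -- application --------------------------------------------------------

    def transform(self, trials: list[TrialRecord]) -> list[list[str]]:
        """Zone paths of trials under the fitted scheme and zone map."""
        paths = []
        for t in trials:
            seq = self._trial_sequence(t)
            zmap = dict(self.zones_)
            if self.user_zone_map is None:
                for s in set(seq.states) - zmap.keys():
                    zmap[s] = self._pattern_zone(s)
            paths.append(zone_path(seq, zmap))
        return paths

    def fit_transform(self, trials: list[TrialRecord]) -> list[list[str]]:
        return self.fit(trials).transform(trials)

    def classify(self, trials: list[TrialRecord]) -> list[str]:
        """Trajectory classes (A-D) of trials."""
        return [classify_trajectory(p) for p in self.transform(trials)]

    def zone_table(self, trials: list[TrialRecord] | None = None) -> pd.DataFrame:
        """Zone-to-zone transition probabilities."""
        if trials is None:
            seqs = self.sequences_
        else:
            seqs = [self._trial_sequence(t) for t in trials]
        return zone_transition_table(seqs, self.zones_)

    def to_json(self) -> str:
        """Serialise the fitted zone map and thresholds."""
        return json.dumps(
            {
                "bin_width_ms": self.bin_width_ms,
                "state_streams": list(self.state_streams),
                "thresholds": self.scheme_.thresholds,
                "baseline_state": int(self.baseline_state_),
                "zones": {str(k): v for k, v in self.zones_.items()},
            },
            indent=2,
        )
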