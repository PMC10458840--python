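"""Seeded synthetic accelerometer studies with known ground truth.

The generator emulates a multi-cat bio-logging deployment: each cat wears
two 30 Hz triaxial accelerometers (collar and harness) for several days,
and one five-hour window on day 1 is behaviour-annotated from video.

Behaviour sequences come from a semi-Markov chain: bout durations are
gamma-distributed per behaviour (mean ``mean_dwell``, shape
``dwell_shape``, rounded up to whole seconds), and the successor
behaviour is drawn from a transition-weight matrix with zero diagonal.

Each behaviour has a statistical acceleration signature in the cat's
body frame (craniocaudal, dorsoventral, lateral): a static 1 g gravity
component along a posture-specific unit vector, a sinusoidal dynamic
component of amplitude ``dyn_amp`` at ``gait_freq`` on the craniocaudal
axis, and isotropic Gaussian noise. Device axes follow the mounting
conventions: collar X/Y/Z = lateral / dorsoventral / craniocaudal,
harness X/Y/Z = craniocaudal / dorsoventral / lateral.

Collar recordings carry two artefacts that harness recordings do not:
a slowly drifting rotation of the device about the neck axis
(Ornstein-Uhlenbeck angle, stationary sd ``collar_jitter_sd``) and a
damped "ringing" oscillation for a short time after every
active-to-inactive transition (the loose collar keeps swinging after
the cat stops). Values are clipped to the +/- 8 g device range.

A configurable fraction of annotated seconds is relabelled
"out of sight" / "other" to exercise downstream label filtering.
All operations are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ingestion import (
    AnnotationTrack,
    CATEGORIES,
    MOUNTS,
    RawTrace,
    normalise_label,
)

DAY_S = 86400


@dataclass(frozen=True)
class BehaviourSignature:
    """Statistical acceleration signature of one behaviour.

    ``gravity_dir`` is the body-frame posture orientation (craniocaudal,
    dorsoventral, lateral components), normalised to unit length.
    ``dyn_amp`` (g) and ``gait_freq`` (Hz) shape the periodic dynamic
    component; ``noise_sd`` (g) the isotropic sensor/tissue noise.
    ``mean_dwell`` (s) and ``dwell_shape`` parameterise the gamma bout
    length law; ``weight`` is the behaviour's relative rate of being
    entered, from which the default transition matrix is built.
    """

    label: str
    category: str
    gravity_dir: tuple[float, float, float]
    dyn_amp: float = 0.0
    gait_freq: float = 0.0
    noise_sd: float = 0.02
    mean_dwell: float = 30.0
    dwell_shape: float = 2.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", normalise_label(self.label))
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        g = np.asarray(self.gravity_dir, dtype=float)
        norm = float(np.linalg.norm(g))
        if norm == 0.0:
            raise ValueError("gravity_dir must be a nonzero vector")
        object.__setattr__(self, "gravity_dir", tuple(g / norm))
        if self.dyn_amp < 0 or self.noise_sd < 0:
            raise ValueError("dyn_amp and noise_sd must be nonnegative")
        if self.mean_dwell <= 0 or self.dwell_shape <= 0:
            raise ValueError("mean_dwell and dwell_shape must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def default_signatures() -> tuple[BehaviourSignature, ...]:
    """Signatures for the 18 behaviours observed in a cat-colony study.

    Postures (gravity directions) and gait parameters are statistical
    stand-ins chosen to be mutually separable while keeping field-
    realistic structure: inactive postures are near-static with distinct
    orientations, locomotion has gait-frequency periodicity, grooming-
    like maintenance behaviours are low-amplitude and deliberately
    similar to each other. Weights and dwell times are set so the
    stationary time budget is dominated by lying and sitting, as colony
    cats' days are.
    """
    S = BehaviourSignature
    return (
        # active
        S("climbing", "active", (0.55, 0.80, 0.10), 0.45, 2.2, 0.10, 8, weight=1.0),
        S("jumping horizontal", "active", (0.70, 0.70, 0.10), 0.90, 3.5, 0.15, 2, weight=0.5),
        S("jumping vertical", "active", (0.30, 0.95, 0.00), 1.00, 3.8, 0.15, 2, weight=0.5),
        S("fighting", "active", (0.10, 0.90, 0.40), 0.80, 4.0, 0.25, 5, weight=0.02),
        S("playing", "active", (0.20, 0.90, 0.30), 0.60, 3.0, 0.20, 10, weight=0.01),
        S("rubbing", "active", (0.10, 0.80, 0.60), 0.25, 1.5, 0.08, 8, weight=1.5),
        S("trotting", "active", (0.15, 1.00, 0.00), 0.55, 2.8, 0.08, 6, weight=2.0),
        S("walking", "active", (0.10, 1.00, 0.00), 0.30, 1.8, 0.06, 20, weight=9.0),
        # inactive
        S("lying", "inactive", (0.05, 0.35, 0.95), 0.00, 0.0, 0.020, 600, weight=5.0),
        S("sitting", "inactive", (0.65, 0.75, 0.00), 0.00, 0.0, 0.025, 300, weight=5.5),
        S("standing", "inactive", (0.00, 1.00, 0.08), 0.00, 0.0, 0.030, 60, weight=9.0),
        # maintenance
        S("digging", "maintenance", (0.35, 0.90, 0.20), 0.35, 2.5, 0.10, 10, weight=1.0),
        S("eating", "maintenance", (0.45, 0.90, -0.10), 0.12, 2.0, 0.05, 60, weight=4.5),
        S("grooming", "maintenance", (0.30, 0.60, 0.74), 0.18, 1.2, 0.07, 120, weight=4.0),
        S("littering", "maintenance", (0.55, 0.80, -0.25), 0.08, 0.8, 0.05, 40, weight=0.8),
        S("scratching", "maintenance", (0.25, 0.65, 0.70), 0.22, 1.4, 0.09, 8, weight=2.0),
        S("shaking", "maintenance", (0.00, 0.90, 0.30), 0.70, 5.0, 0.20, 3, weight=0.7),
        # other
        S("allogrooming", "other", (0.35, 0.62, 0.70), 0.15, 1.1, 0.07, 20, weight=1.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study design and nuisance parameters of the synthetic deployment."""

    signatures: tuple[BehaviourSignature, ...] = field(
        default_factory=default_signatures)
    transition_weights: Optional[np.ndarray] = None  # (n, n), zero diagonal
    sampling_rate: int = 30
    n_cats: int = 12
    n_days: int = 7
    #: (start, end) seconds within day 1; default 09:00-14:00.
    annotated_window: tuple[int, int] = (9 * 3600, 14 * 3600)
    #: stationary sd (radians) of the collar's rotational drift
    collar_jitter_sd: float = 0.25
    #: time constant (s) of the drift's mean reversion
    collar_drift_tau: float = 30.0
    #: time constant (s) of the post-transition collar ringing
    residual_decay: float = 0.5
    #: amplitude (g) and frequency (Hz) of the collar ringing
    residual_amp: float = 0.3
    residual_freq: float = 3.0
    #: fraction of annotated seconds relabelled out of sight / other
    unscorable_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("at least one behaviour signature is required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_cats < 0 or self.n_days < 1:
            raise ValueError("n_cats must be >= 0 and n_days >= 1")
        lo, hi = self.annotated_window
        if not (0 <= lo < hi <= DAY_S):
            raise ValueError("annotated window must lie within one day")
        labels = [s.label for s in self.signatures]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate behaviour labels in signatures")
        tw = self.transition_weights
        if tw is None:
            tw = default_transition_matrix(self.signatures)
        tw = np.asarray(tw, dtype=float)
        n = len(self.signatures)
        if tw.shape != (n, n):
            raise ValueError(f"transition_weights must be {n}x{n}")
        if (tw < 0).any() or np.diag(tw).any():
            raise ValueError("transition weights must be nonnegative with a "
                             "zero diagonal")
        if n > 1 and (tw.sum(axis=1) <= 0).any():
            raise ValueError("every transition row needs positive total weight")
        object.__setattr__(self, "transition_weights", tw)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.signatures)

    def signature(self, label: str) -> BehaviourSignature:
        label = normalise_label(label)
        for s in self.signatures:
            if s.label == label:
                return s
        raise KeyError(f"no signature for behaviour {label!r}")


def default_transition_matrix(
    signatures: Sequence[BehaviourSignature],
) -> np.ndarray:
    """Successor weights proportional to each behaviour's entry weight.

    The successor draw does not depend on the current behaviour (beyond
    excluding self-transitions), so the chain's stationary bout-type
    distribution is approximately proportional to the weights and the
    time occupancy to weight x mean dwell.
    """
    w = np.array([s.weight for s in signatures], dtype=float)
    tw = np.tile(w, (len(w), 1))
    np.fill_diagonal(tw, 0.0)
    return tw


# ---------------------------------------------------------------------------
# Label simulation

def _simulate_codes(config: SimConfig, duration_s: int,
                    rng: np.random.Generator) -> np.ndarray:
    n = len(config.signatures)
    out = np.empty(duration_s, dtype=np.int16)
    shapes = np.array([s.dwell_shape for s in config.signatures])
    scales = np.array([s.mean_dwell / s.dwell_shape for s in config.signatures])
    tw = config.transition_weights
    row_p = tw / tw.sum(axis=1, keepdims=True) if n > 1 else None

    start_w = np.array([s.weight * s.mean_dwell for s in config.signatures])
    current = int(rng.choice(n, p=start_w / start_w.sum()))
    t = 0
    while t < duration_s:
        dwell = int(np.ceil(rng.gamma(shapes[current], scales[current])))
        dwell = max(dwell, 1)
        end = min(t + dwell, duration_s)
        out[t:end] = current
        t = end
        if n > 1:
            current = int(rng.choice(n, p=row_p[current]))
    return out


def simulate_labels(config: SimConfig, duration_s: int,
                    seed: Optional[int] = None) -> np.ndarray:
    """One behaviour label per whole second from the semi-Markov chain."""
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    codes = _simulate_codes(config, duration_s, rng)
    labels = np.array(config.labels, dtype=object)
    return labels[codes]


# ---------------------------------------------------------------------------
# Trace synthesis

def _body_to_device(body: np.ndarray, mount: str) -> np.ndarray:
    """Map body-frame (cranio, dorso, lateral) samples to device X/Y/Z."""
    if mount == "collar":
        # X = lateral, Y = dorsoventral, Z = craniocaudal
        return body[:, [2, 1, 0]]
    if mount == "harness":
        # X = craniocaudal, Y = dorsoventral, Z = lateral
        return body
    raise ValueError(f"unknown mount {mount!r}; expected one of {MOUNTS}")


def synthesize_trace(
    labels: Sequence[str],
    config: SimConfig,
    mount: str,
    seed: Optional[int] = None,
    cat_id: str = "cat",
    start_second: int = 0,
) -> RawTrace:
    """Render a per-second label sequence into a 30 Hz triaxial trace."""
    if mount not in MOUNTS:
        raise ValueError(f"unknown mount {mount!r}; expected one of {MOUNTS}")
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("label sequence must be nonempty")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    index = {l: i for i, l in enumerate(config.labels)}
    try:
        codes_s = np.array([index[normalise_label(l)] for l in labels],
                           dtype=np.int16)
    except KeyError as exc:
        raise KeyError(f"no signature for behaviour {exc.args[0]!r}") from None

    sr = config.sampling_rate
    n_sec = codes_s.size
    n = n_sec * sr
    codes = np.repeat(codes_s, sr)
    t = start_second + np.arange(n) / sr

    grav = np.array([s.gravity_dir for s in config.signatures])
    amp = np.array([s.dyn_amp for s in config.signatures])
    freq = np.array([s.gait_freq for s in config.signatures])
    nsd = np.array([s.noise_sd for s in config.signatures])

    body = grav[codes].copy()  # 1 g static component
    body[:, 0] += amp[codes] * np.sin(2 * np.pi * freq[codes] * t)
    body += rng.normal(0.0, 1.0, size=(n, 3)) * nsd[codes][:, None]

    if mount == "collar":
        body = _apply_collar_artefacts(body, codes_s, config, rng)

    device = _body_to_device(body, mount)
    np.clip(device, -8.0, 8.0, out=device)
    return RawTrace(cat_id, mount, sr, device, start_second=start_second)


def _apply_collar_artefacts(body: np.ndarray, codes_s: np.ndarray,
                            config: SimConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Rotational drift about the neck axis plus post-stop ringing."""
    sr = config.sampling_rate
    n = body.shape[0]
    dt = 1.0 / sr
    # Ornstein-Uhlenbeck angle about the craniocaudal axis, exact AR(1)
    # discretisation with stationary sd collar_jitter_sd.
    phi = np.exp(-dt / config.collar_drift_tau)
    innov_sd = config.collar_jitter_sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    theta = np.empty(n)
    theta[0] = rng.normal(0.0, config.collar_jitter_sd)
    if n > 1:
        from scipy.signal import lfilter
        theta[1:] = lfilter([1.0], [1.0, -phi], eps[1:],
                            zi=[phi * theta[0]])[0]
    c, s = np.cos(theta), np.sin(theta)
    dorso = c * body[:, 1] - s * body[:, 2]
    lat = s * body[:, 1] + c * body[:, 2]
    body[:, 1], body[:, 2] = dorso, lat

    # damped ring after each active -> inactive transition
    sigs = config.signatures
    active = np.array([sigs[c].category == "active" for c in range(len(sigs))])
    inactive = np.array([sigs[c].category == "inactive"
                         for c in range(len(sigs))])
    trans = np.flatnonzero(active[codes_s[:-1]] & inactive[codes_s[1:]]) + 1
    ring_len = int(np.ceil(5 * config.residual_decay * sr))
    if ring_len and trans.size:
        tau = config.residual_decay
        tt = np.arange(ring_len) / sr
        template = (config.residual_amp * np.exp(-tt / tau)
                    * np.sin(2 * np.pi * config.residual_freq * tt))
        for sec in trans:
            i0 = sec * sr
            seg = min(ring_len, n - i0)
            phase = rng.uniform(0, 2 * np.pi)
            body[i0:i0 + seg, 1] += template[:seg] * np.cos(phase)
            body[i0:i0 + seg, 2] += template[:seg] * np.sin(phase)
    return body


# ---------------------------------------------------------------------------
# Whole-study generation

@dataclass
class CatRecord:
    """Ground truth and lazily synthesized traces for one cat."""

    cat_id: str
    config: SimConfig
    labels: np.ndarray  # one behaviour label per second, all days
    annotation: AnnotationTrack  # annotated window of day 1, with
    # unscorable seconds relabelled

    _cat_index: int = 0

    def true_labels(self, start_s: int = 0,
                    end_s: Optional[int] = None) -> np.ndarray:
        return self.labels[start_s:end_s]

    def _trace_seed(self, mount: str, day: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            (self.config.seed, 1, self._cat_index, MOUNTS.index(mount), day))

    def day_trace(self, mount: str, day: int) -> RawTrace:
        """Synthesize the full trace for one day (deterministic)."""
        if not 0 <= day < self.config.n_days:
            raise ValueError(f"day {day} outside the study ({self.config.n_days} days)")
        day_labels = self.labels[day * DAY_S:(day + 1) * DAY_S]
        rng = np.random.default_rng(self._trace_seed(mount, day))
        return synthesize_trace(day_labels, self.config, mount,
                                seed=rng.integers(2**31),
                                cat_id=self.cat_id,
                                start_second=day * DAY_S)

    def annotated_trace(self, mount: str) -> RawTrace:
        """Day-1 trace sliced to the annotated window."""
        lo, hi = self.config.annotated_window
        full = self.day_trace(mount, 0)
        sr = self.config.sampling_rate
        return RawTrace(self.cat_id, mount, sr,
                        full.samples[lo * sr:hi * sr], start_second=lo)


@dataclass
class StudyBundle:
    """A complete synthetic deployment: all cats, labels, annotations."""

    config: SimConfig
    cats: list[CatRecord]

    def __iter__(self):
        return iter(self.cats)

    def __len__(self) -> int:
        return len(self.cats)

    def occupancy(self) -> dict[str, float]:
        """Ground-truth time budget over all cats and days."""
        from collections import Counter
        counts: Counter = Counter()
        for cat in self.cats:
            counts.update(cat.labels.tolist())
        total = sum(counts.values())
        return {l: c / total for l, c in sorted(counts.items())}


def generate_study(config: SimConfig) -> StudyBundle:
    """Generate the full study: labels for every second of every cat, and
    an annotated track for the day-1 window with a seeded fraction of
    seconds relabelled "out of sight" (mostly) or "other"."""
    root = np.random.SeedSequence((config.seed, 0))
    cat_seeds = root.spawn(max(config.n_cats, 1))
    cats = []
    duration = config.n_days * DAY_S
    lo, hi = config.annotated_window
    for i in range(config.n_cats):
        rng = np.random.default_rng(cat_seeds[i])
        cat_id = f"cat{i + 1:02d}"
        labels = simulate_labels(config, duration, seed=int(rng.integers(2**31)))
        window = labels[lo:hi].copy()
        mask = rng.random(window.size) < config.unscorable_fraction
        kind = rng.random(window.size) < 0.9
        window[mask & kind] = "out of sight"
        window[mask & ~kind] = "other"
        annotation = AnnotationTrack(cat_id, np.arange(lo, hi), window)
        cats.append(CatRecord(cat_id, config, labels, annotation, _cat_index=i))
    return StudyBundle(config, cats)
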