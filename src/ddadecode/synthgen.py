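"""Synthetic multichannel trial sets with known, class-dependent delay dynamics.

Signals are produced by forward iteration of a discrete two-delay map

    u[n] = u[n-1] + b1*v1[n] + b2*v2[n] + b3*v1[n]**2 + eps[n],
    vk[n] = (u[n-tk] + u[n-1-tk]) / 2,

with ``eps ~ N(0, noise_sd**2)``.  The delayed terms are evaluated at the
trapezoidal midpoint so that, under the center-difference derivative used
by the fitting stage, the fitted delay is centered on the generating delay
(a plain Euler step would shift the effective delay by half a sample and
bias delay-recovery experiments toward t-1).  Classes differ (or, for null
sets, deliberately do not differ) in their delays ``(t1, t2)`` and map
coefficients ``(b1, b2, b3)``; channels are formed by applying a mixing
matrix to independent per-class sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import TrialSet

__all__ = [
    "ClassDynamics",
    "GeneratorSpec",
    "DivergenceError",
    "gen_signal",
    "gen_trialset",
    "gen_null_trialset",
    "gen_sinusoid",
    "null_spec",
    "two_class_spec",
]

#: |u| beyond this aborts a run as divergent.
AMPLITUDE_GUARD = 1e6
#: Divergent runs are resampled with a perturbed seed up to this many times.
RETRY_CAP = 10
#: Burn-in multiplier: 10 * max(t1, t2) samples are discarded.
BURNIN_FACTOR = 10
#: SD of the i.i.d. normal initial history.
HISTORY_SD = 0.1


class DivergenceError(RuntimeError):
    """The delay map exceeded the amplitude guard on every retry."""


@dataclass(frozen=True)
class ClassDynamics:
    """Map parameters for one class: delays in samples, dimensionless coefficients."""

    t1: int
    t2: int
    b1: float
    b2: float
    b3: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 < 1 or self.t2 < 1:
            raise ValueError("delays must be >= 1 sample")
        if self.t1 == self.t2:
            raise ValueError("t1 and t2 must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic trial-set experiment.

    ``dynamics`` maps each class label to its :class:`ClassDynamics`.
    ``mixing`` is an (n_channels, n_sources) matrix or ``None`` for the
    identity (channels are then independent realizations of the class
    dynamics).  With ``scramble_across_subjects`` the class-to-dynamics
    assignment is permuted independently per subject, so labels carry
    within-subject signal but no cross-subject signal.
    """

    n_subjects: int
    n_trials_per_class: int
    classes: tuple
    fs: float
    trial_len: float
    n_channels: int
    dynamics: dict = field(default_factory=dict)
    mixing: np.ndarray | None = None
    obs_noise_sd: float = 0.0
    scramble_across_subjects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if set(self.dynamics) != set(self.classes):
            raise ValueError("dynamics must define every class")
        n_samples = int(round(self.trial_len * self.fs))
        for dyn in self.dynamics.values():
            if n_samples <= BURNIN_FACTOR * max(dyn.t1, dyn.t2):
                raise ValueError("trial too short for the requested delays")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.ndim != 2 or m.shape[0] != self.n_channels:
                raise ValueError("mixing must be (n_channels, n_sources)")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len * self.fs))


def _iterate_map(dyn: ClassDynamics, length: int, rng: np.random.Generator) -> np.ndarray:
    tmax = max(dyn.t1, dyn.t2)
    hist = tmax + 1
    burnin = BURNIN_FACTOR * tmax
    total = burnin + length
    u = np.empty(total + hist)
    u[:hist] = rng.normal(0.0, HISTORY_SD, hist)
    eps = rng.normal(0.0, dyn.noise_sd, total) if dyn.noise_sd > 0 else np.zeros(total)
    for i in range(hist, hist + total):
        v1 = 0.5 * (u[i - dyn.t1] + u[i - 1 - dyn.t1])
        v2 = 0.5 * (u[i - dyn.t2] + u[i - 1 - dyn.t2])
        u[i] = u[i - 1] + dyn.b1 * v1 + dyn.b2 * v2 + dyn.b3 * v1 * v1 + eps[i - hist]
        if not np.isfinite(u[i]) or abs(u[i]) > AMPLITUDE_GUARD:
            return np.array([])  # divergence sentinel
    return u[hist + burnin:]


def gen_signal(spec: GeneratorSpec, class_label, length: int, seed) -> np.ndarray:
    """One univariate realization of a class's delay dynamics.

    Burn-in (10x the largest delay) is discarded.  Runs that exceed the
    amplitude guard are resampled with a perturbed seed up to a retry cap,
    after which :class:`DivergenceError` is raised.
    """
    dyn = spec.dynamics[class_label]
    if length <= max(dyn.t1, dyn.t2):
        raise ValueError("length must exceed the largest delay")
    base = list(np.atleast_1d(seed).astype(np.uint64))
    for attempt in range(RETRY_CAP + 1):
        rng = np.random.default_rng(base + [attempt])
        out = _iterate_map(dyn, length, rng)
        if out.size:
            return out
    raise DivergenceError(
        f"delay map for class {class_label!r} diverged on {RETRY_CAP + 1} attempts"
    )


def gen_sinusoid(freq: float, fs: float, length: int, amplitude: float = 1.0) -> np.ndarray:
    """Exact sinusoid ``amplitude * sin(2*pi*freq*n/fs)``; analytic fixture."""
    if not 0 < freq < fs / 2:
        raise ValueError("freq must satisfy 0 < freq < fs/2 (Nyquist)")
    n = np.arange(length)
    return amplitude * np.sin(2.0 * np.pi * freq * n / fs)


def _subject_dynamics(spec: GeneratorSpec, subj: int) -> dict:
    if not spec.scramble_across_subjects:
        return spec.dynamics
    rng = np.random.default_rng([spec.seed, 7919, subj])
    perm = rng.permutation(len(spec.classes))
    return {c: spec.dynamics[spec.classes[p]] for c, p in zip(spec.classes, perm)}


def gen_trialset(spec: GeneratorSpec) -> TrialSet:
    """Full labeled trial set: subjects x classes x trials.

    Each trial draws ``n_sources`` independent realizations of that class's
    dynamics and mixes them into channels; optional white observation noise
    is added per channel.  Identical spec and seed reproduce the set
    bit-for-bit.
    """
    mixing = spec.mixing
    if mixing is None:
        n_sources = spec.n_channels
    else:
        mixing = np.asarray(mixing, dtype=float)
        n_sources = mixing.shape[1]
    n_samples = spec.n_samples
    data, labels, subjects = [], [], []
    for subj in range(spec.n_subjects):
        dyn_map = _subject_dynamics(spec, subj)
        for ci, cls in enumerate(spec.classes):
            sub_spec = replace(spec, dynamics=dyn_map, scramble_across_subjects=False)
            for trial in range(spec.n_trials_per_class):
                sources = np.stack(
                    [
                        gen_signal(sub_spec, cls, n_samples, [spec.seed, subj, ci, trial, src])
                        for src in range(n_sources)
                    ]
                )
                chans = sources if mixing is None else mixing @ sources
                if spec.obs_noise_sd > 0:
                    rng = np.random.default_rng([spec.seed, 104729, subj, ci, trial])
                    chans = chans + rng.normal(0.0, spec.obs_noise_sd, chans.shape)
                data.append(chans)
                labels.append(cls)
                subjects.append(subj)
    return TrialSet(
        data=np.stack(data),
        fs=spec.fs,
        labels=np.asarray(labels),
        subjects=np.asarray(subjects),
        channel_names=[f"ch{i}" for i in range(spec.n_channels)],
    )


def gen_null_trialset(spec: GeneratorSpec) -> TrialSet:
    """Chance-level control: labels assigned but all classes share one dynamics.

    The shared parameterization is the one of the first class in
    ``spec.classes``; everything else matches :func:`gen_trialset`.
    """
    shared = spec.dynamics[spec.classes[0]]
    null = replace(
        spec,
        dynamics={c: shared for c in spec.classes},
        scramble_across_subjects=False,
    )
    return gen_trialset(null)


DEFAULT_DYNAMICS = ClassDynamics(t1=3, t2=7, b1=-0.1, b2=0.05, b3=0.0, noise_sd=1.0)


def null_spec(
    n_classes: int = 5,
    n_subjects: int = 10,
    n_trials_per_class: int = 20,
    fs: float = 256.0,
    trial_len: float = 2.0,
    n_channels: int = 3,
    seed: int = 0,
    dynamics: ClassDynamics = DEFAULT_DYNAMICS,
) -> GeneratorSpec:
    """Spec for a balanced null set: every class shares ``dynamics``."""
    classes = tuple(f"c{i}" for i in range(n_classes))
    return GeneratorSpec(
        n_subjects=n_subjects,
        n_trials_per_class=n_trials_per_class,
        classes=classes,
        fs=fs,
        trial_len=trial_len,
        n_channels=n_channels,
        dynamics={c: dynamics for c in classes},
        seed=seed,
    )


def two_class_spec(
    dyn_a: ClassDynamics,
    dyn_b: ClassDynamics,
    n_subjects: int = 1,
    n_trials_per_class: int = 10,
    fs: float = 256.0,
    trial_len: float = 2.0,
    n_channels: int = 3,
    seed: int = 0,
    scramble_across_subjects: bool = False,
) -> GeneratorSpec:
    """Spec for a two-class problem with explicit per-class dynamics."""
    return GeneratorSpec(
        n_subjects=n_subjects,
        n_trials_per_class=n_trials_per_class,
        classes=("a", "b"),
        fs=fs,
        trial_len=trial_len,
        n_channels=n_channels,
        dynamics={"a": dyn_a, "b": dyn_b},
        seed=seed,
        scramble_across_subjects=scramble_across_subjects,
    )
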