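"""Ground-truth-known synthetic EEG sessions and VAR fixtures.

The generator emulates a slow-propofol-induction study design: a resting
eyes-closed baseline, an infusion period during which behavioral response is
lost (LOBR), an unresponsive plateau, and emergence with recovery of response
(ROBR).  The multichannel signal is a state-switching vector autoregression:
directed coupling edges (predominantly lateral-frontal → medial) are active
while the subject is responsive and collapse abruptly at LOBR, recovering at
ROBR.  Narrowband stochastic oscillators (delta/alpha/beta), occasional
high-amplitude artifacts, and high-frequency "muscle" noise on outer
electrodes are added on top, so the directed information flow attributable to
the VAR edges is known exactly.

Because the generator is a fixture factory for every downstream stage, all
randomness flows from a single session seed: ``SeedSequence(seed)`` is spawned
into four child streams, consumed in a fixed order (VAR innovations, band
oscillators, artifacts, muscle noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.linalg import solve_discrete_lyapunov
from scipy.signal import butter, filtfilt, lfilter
from statsmodels.tsa.stattools import levinson_durbin

from .montage import Montage, standard_montage_31
from .recording import EventTimeline, Recording

__all__ = [
    "VARSpec",
    "SessionPlan",
    "SharedOscillator",
    "simulate_var",
    "analytic_spectral_gc",
    "time_domain_gc",
    "simulate_session",
    "default_session_plan",
    "shared_driver_plan",
    "DEFAULT_EDGES",
]

PHASE_LABELS = ("rest_eyes_closed", "induction", "unresponsive", "emergence", "responsive")

#: Default ground-truth directed edges: lateral frontal / prefrontal sources
#: driving medial and centro-parietal targets, mirroring the dominant
#: posteromedial direction of information flow reported for this paradigm.
DEFAULT_EDGES = (
    ("F7", "Cz"), ("F8", "Fz"),
    ("FC5", "CP1"), ("FC6", "CP2"),
    ("Fp1", "FC1"), ("Fp2", "FC2"),
    ("F7", "Pz"), ("F8", "POz"),
    ("FC5", "P3"), ("FC6", "P4"),
    ("Fp1", "C3"), ("Fp2", "C4"),
)

#: Weak directed background network active while responsive: left-to-right
#: interhemispheric edges between homologous electrodes plus an
#: anterior-to-posterior midline chain.  It gives most electrode pairs a
#: nonzero (direct or indirect) baseline information flow that collapses at
#: LOBR together with the strong edges, emulating the global character of the
#: observed connectivity loss.  The structure is feedforward (acyclic), so it
#: never destabilizes the VAR.
DEFAULT_WEAK_EDGES = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("T7", "T8"), ("CP5", "CP6"), ("P7", "P8"), ("O1", "O2"),
    ("AFz", "FCz"), ("Oz", "POz"),
)

#: Outer-ring electrodes that carry broadband EMG-like noise while the
#: subject is awake (muscle tone disappears under anesthesia).
DEFAULT_MUSCLE_CHANNELS = ("T7", "T8", "F7", "F8", "P7", "P8", "O1", "O2", "Fp1", "Fp2")

#: Narrowband oscillator centers (Hz) and half-power bandwidths (Hz); the
#: AR(2) pole radius at sampling rate fs is exp(-pi * bw / fs).
OSC_BANDS = {"delta": (1.0, 0.8), "alpha": (10.0, 2.4), "beta": (24.0, 6.6)}

#: Per-state oscillator amplitudes (SD relative to the unit-scale VAR signal).
#: Delta and alpha power increase during unresponsiveness; beta decreases.
DEFAULT_OSC_AMPS = {
    "responsive": {"delta": 0.35, "alpha": 0.45, "beta": 0.25},
    "unresponsive": {"delta": 0.50, "alpha": 0.60, "beta": 0.15},
}


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of a VAR(p): block top row A_1..A_p, shifted identity below."""
    p, m, _ = coeffs.shape
    comp = np.zeros((m * p, m * p))
    for k in range(p):
        comp[:m, k * m:(k + 1) * m] = coeffs[k]
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return comp


@dataclass(frozen=True)
class VARSpec:
    """A stable vector autoregression x_t = sum_k A_k x_{t-k} + e_t.

    ``coeffs`` stacks A_1..A_p as (p, m, m); ``noise_cov`` is the innovation
    covariance (µV² on the simulator's internal unit scale).  Stability
    (companion spectral radius < 1) and a symmetric positive-definite noise
    covariance are enforced at construction.
    """

    coeffs: np.ndarray        # (p, m, m)
    noise_cov: np.ndarray     # (m, m)
    sample_rate: float = 125.0

    def __post_init__(self):
        coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        noise_cov = np.asarray(self.noise_cov, dtype=float)
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", noise_cov)
        p, m, m2 = coeffs.shape
        if m != m2 or noise_cov.shape != (m, m):
            raise ValueError("coeffs must be (p, m, m) and noise_cov (m, m)")
        if not np.allclose(noise_cov, noise_cov.T):
            raise ValueError("noise covariance must be symmetric")
        if np.linalg.eigvalsh(noise_cov).min() <= 0:
            raise ValueError("noise covariance must be positive-definite")
        rho = self.spectral_radius
        if rho >= 1.0:
            raise ValueError(f"unstable VAR: companion spectral radius {rho:.4f} >= 1")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(companion_matrix(self.coeffs))).max())


@njit(cache=True)
def _switching_var_kernel(e, A0, dA, gain):  # pragma: no cover - numba
    n, m = e.shape
    p = A0.shape[0]
    x = np.zeros((n, m))
    for t in range(p, n):
        acc = e[t].copy()
        g = gain[t]
        for k in range(p):
            acc += A0[k] @ x[t - 1 - k]
            if g != 0.0:
                acc += g * (dA[k] @ x[t - 1 - k])
        x[t] = acc
    return x


def _run_var(coeffs_a: np.ndarray, coeffs_b: np.ndarray, gain: np.ndarray,
             noise_cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Simulate a VAR whose coefficients blend A_a -> A_b with gain(t) in [0, 1]."""
    n = gain.size
    m = coeffs_a.shape[1]
    chol = np.linalg.cholesky(noise_cov)
    e = rng.standard_normal((n, m)) @ chol.T
    dA = coeffs_b - coeffs_a
    return _switching_var_kernel(
        e, np.ascontiguousarray(coeffs_a), np.ascontiguousarray(dA),
        np.ascontiguousarray(gain, dtype=np.float64),
    ).T


def simulate_var(spec: VARSpec, n_samples: int, seed: int, burn_in: int = 500) -> np.ndarray:
    """Simulate ``n_samples`` from a stable VAR; seed-deterministic.

    Returns a (n_channels, n_samples) array.  A burn-in stretch is discarded
    so the output is (approximately) a stationary draw.
    """
    if n_samples < 10 * spec.order:
        raise ValueError("n_samples must be at least 10 * order")
    rng = np.random.default_rng(seed)
    gain = np.zeros(n_samples + burn_in)
    x = _run_var(spec.coeffs, spec.coeffs, gain, spec.noise_cov, rng)
    return x[:, burn_in:]


# ---------------------------------------------------------------------------
# Analytic spectral Granger causality (ground truth from the generating VAR)
# ---------------------------------------------------------------------------

def analytic_spectral_gc(spec: VARSpec, freqs) -> np.ndarray:
    """Ground-truth Geweke spectral GC of a 2-channel VAR.

    Computed directly from the true coefficients via the transfer function
    H(f) = (I - sum_k A_k e^{-2 pi i f k / fs})^-1.  Returns (n_freqs, 2):
    column 0 is GC(channel0 -> channel1), column 1 GC(channel1 -> channel0).
    """
    from .granger import geweke_spectrum  # shared decomposition

    if spec.n_channels != 2:
        raise ValueError("analytic spectral GC is defined for 2-channel specs")
    gc = geweke_spectrum(
        spec.coeffs[None], spec.noise_cov[None], np.asarray(freqs, float),
        spec.sample_rate,
    )
    return gc[0]


def var_autocovariances(spec: VARSpec, n_lags: int) -> list[np.ndarray]:
    """Gamma_k = Cov(x_t, x_{t-k}) for k = 0..n_lags, solved exactly.

    Gamma_0..Gamma_{p-1} come from the discrete Lyapunov equation of the
    companion form; higher lags from the Yule-Walker recursion.
    """
    p, m, _ = spec.coeffs.shape
    comp = companion_matrix(spec.coeffs)
    q = np.zeros_like(comp)
    q[:m, :m] = spec.noise_cov
    big = solve_discrete_lyapunov(comp, q)
    gammas = [big[:m, k * m:(k + 1) * m] for k in range(p)]
    for k in range(p, n_lags + 1):
        gammas.append(sum(spec.coeffs[j] @ gammas[k - 1 - j] for j in range(p)))
    return gammas[: n_lags + 1]


def time_domain_gc(spec: VARSpec, n_lags: int = 200) -> np.ndarray:
    """Total (time-domain) Granger causality of a 2-channel VAR, both directions.

    GC(y->x) = ln(reduced-model innovation variance / full-model innovation
    variance).  The reduced univariate model is recovered from the exact
    autocovariance sequence by a high-order Levinson-Durbin recursion; no
    simulation or frequency integration is involved, which makes this an
    independent cross-check for the spectral decomposition (whose average
    over frequency must match, by Geweke's integral identity).
    """
    if spec.n_channels != 2:
        raise ValueError("time-domain GC helper is defined for 2-channel specs")
    gammas = var_autocovariances(spec, n_lags)
    out = np.empty(2)
    for target in (0, 1):
        acov = np.array([g[target, target] for g in gammas])
        sigma_reduced = levinson_durbin(acov, nlags=n_lags, isacov=True)[0]
        out[1 - target] = math.log(sigma_reduced / spec.noise_cov[target, target])
    # out[0] = GC(0->1): target channel 1; out[1] = GC(1->0)
    return out


# ---------------------------------------------------------------------------
# Session plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharedOscillator:
    """A single narrowband source mixed into several channels with zero lag.

    Produces synchrony (coherence) between the receiving channels without any
    directed lagged coupling — the configuration in which functional and
    effective connectivity dissociate.
    """

    band: str
    channels: tuple[str, ...]
    amp_responsive: float
    amp_unresponsive: float


@dataclass(frozen=True)
class SessionPlan:
    """Everything needed to synthesize one subject's session deterministically."""

    montage: Montage
    phases: tuple[tuple[str, float], ...]
    infusion_start: float
    lobr: float
    robr: float
    coupling_awake: tuple[tuple[str, str, float], ...]
    coupling_unresponsive: tuple[tuple[str, str, float], ...]
    band_oscillators: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_OSC_AMPS.items()
    })
    shared_oscillators: tuple[SharedOscillator, ...] = ()
    artifact_rate: float = 0.5            # events / min
    muscle_noise_channels: tuple[str, ...] = DEFAULT_MUSCLE_CHANNELS
    muscle_noise_sd: float = 0.15         # relative to unit VAR scale
    sample_rate: float = 250.0            # native rate before decimation
    amplitude_uv: float = 12.0            # µV per unit of internal scale
    transition_ramp_s: float = 0.0        # 0 = abrupt switch within one segment
    ar_base: tuple[float, float, float] = (0.5, 0.05, -0.05)
    coupling_lag2_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        labels = [lab for lab, _ in self.phases]
        unknown = set(labels) - set(PHASE_LABELS)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        if not self.infusion_start < self.lobr < self.robr:
            raise ValueError("require infusion_start < lobr < robr")
        if self.robr > self.duration:
            raise ValueError("robr beyond session end")
        names = set(self.montage.names)
        for edges in (self.coupling_awake, self.coupling_unresponsive):
            for src, tgt, _ in edges:
                if src not in names or tgt not in names:
                    raise ValueError(f"coupling edge ({src}->{tgt}) not in montage")
        for osc in self.shared_oscillators:
            if osc.band not in OSC_BANDS:
                raise ValueError(f"unknown oscillator band {osc.band!r}")
            if not set(osc.channels) <= names:
                raise ValueError("shared oscillator channels not in montage")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.phases))

    def coeffs_for(self, edges) -> np.ndarray:
        """VAR(3) coefficient stack: diagonal base dynamics + directed edges."""
        m = len(self.montage)
        idx = {c: i for i, c in enumerate(self.montage.names)}
        coeffs = np.zeros((3, m, m))
        for k, b in enumerate(self.ar_base):
            coeffs[k] += b * np.eye(m)
        for src, tgt, w in edges:
            coeffs[0][idx[tgt], idx[src]] += w
            coeffs[1][idx[tgt], idx[src]] += self.coupling_lag2_fraction * w
        return coeffs

    def var_spec_for(self, edges) -> VARSpec:
        m = len(self.montage)
        return VARSpec(self.coeffs_for(edges), np.eye(m), self.sample_rate)

    def edges_for_phase(self, label: str) -> tuple[tuple[str, str, float], ...]:
        if label == "unresponsive":
            return self.coupling_unresponsive
        return self.coupling_awake


def default_session_plan(
    seed: int = 0,
    duration: str = "full",
    montage: Montage | None = None,
    coupling_weight: float = 0.45,
    weak_coupling_weight: float = 0.18,
    jitter_s: float = 30.0,
    **overrides,
) -> SessionPlan:
    """Default study-like plan, with per-seed jitter of the LOBR/ROBR times.

    ``duration='full'`` is a 2-h session mirroring the study design (10-min
    rest, 48-min ultraslow induction, plateau, emergence); ``'short'`` is a
    20-min session with the same structure, used for group-level simulation
    studies at tractable cost.
    """
    montage = montage or standard_montage_31()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E55]))
    if duration == "full":
        infusion, lobr0, robr0, total = 600.0, 1680.0, 5280.0, 7200.0
    elif duration == "short":
        infusion, lobr0, robr0, total = 120.0, 480.0, 840.0, 1200.0
    else:
        raise ValueError("duration must be 'full' or 'short'")
    lobr = lobr0 + rng.uniform(-jitter_s, jitter_s)
    robr = robr0 + rng.uniform(-jitter_s, jitter_s)
    emergence = (total - robr) / 2
    phases = (
        ("rest_eyes_closed", infusion),
        ("induction", lobr - infusion),
        ("unresponsive", robr - lobr),
        ("emergence", emergence),
        ("responsive", total - robr - emergence),
    )
    coupling = tuple((s, t, coupling_weight) for s, t in DEFAULT_EDGES
                     if coupling_weight > 0)
    weak = tuple((s, t, weak_coupling_weight) for s, t in DEFAULT_WEAK_EDGES
                 if weak_coupling_weight > 0)
    return SessionPlan(
        montage=montage,
        phases=phases,
        infusion_start=infusion,
        lobr=lobr,
        robr=robr,
        coupling_awake=coupling + weak,
        coupling_unresponsive=(),
        seed=seed,
        **overrides,
    )


def shared_driver_plan(seed: int = 0, duration: str = "short",
                       channels: tuple[str, str] = ("F7", "F8"),
                       amp_unresponsive: float = 0.6) -> SessionPlan:
    """Plan with no directed edges and a shared alpha source on two channels.

    During unresponsiveness the two receiving channels synchronize (alpha
    coherence rises) although no lagged information flows between them, so
    Granger causality stays near its small-sample bias floor.
    """
    plan = default_session_plan(seed=seed, duration=duration, coupling_weight=0.0)
    return replace(
        plan,
        coupling_awake=(),
        coupling_unresponsive=(),
        shared_oscillators=(
            SharedOscillator("alpha", tuple(channels), 0.0, amp_unresponsive),
        ),
        artifact_rate=0.0,
    )


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _unresponsive_gain(plan: SessionPlan, n: int) -> np.ndarray:
    """0 while responsive, 1 while unresponsive, linear ramp if configured."""
    fs = plan.sample_rate
    t = np.arange(n) / fs
    ramp = max(plan.transition_ramp_s, 1e-9)
    g_on = np.clip((t - plan.lobr) / ramp + 0.5, 0.0, 1.0)
    g_off = np.clip((t - plan.robr) / ramp + 0.5, 0.0, 1.0)
    return g_on - g_off


def _ar2_oscillator(n: int, f0: float, bw: float, fs: float,
                    rng: np.random.Generator, n_series: int = 1) -> np.ndarray:
    """Unit-SD damped stochastic oscillator(s): AR(2) with complex poles at f0."""
    r = math.exp(-math.pi * bw / fs)
    a1, a2 = 2 * r * math.cos(2 * math.pi * f0 / fs), -r * r
    e = rng.standard_normal((n_series, n))
    x = lfilter([1.0], [1.0, -a1, -a2], e, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def simulate_session(plan: SessionPlan) -> tuple[Recording, dict]:
    """Synthesize one session; returns the Recording and its ground truth.

    The ground-truth dict carries the directed edges active in each phase,
    the artifact injection times/channels, and the event times, so that
    downstream acceptance checks can score recovery of known structure.
    """
    fs = plan.sample_rate
    n = int(round(plan.duration * fs))
    m = len(plan.montage)
    idx = {c: i for i, c in enumerate(plan.montage.names)}
    children = np.random.SeedSequence(plan.seed).spawn(4)
    rng_var, rng_osc, rng_art, rng_mus = (np.random.default_rng(s) for s in children)

    a_awake = plan.coeffs_for(plan.coupling_awake)
    a_unresp = plan.coeffs_for(plan.coupling_unresponsive)
    # both regimes must individually be stable
    VARSpec(a_awake, np.eye(m), fs)
    VARSpec(a_unresp, np.eye(m), fs)
    gain = _unresponsive_gain(plan, n)
    x = _run_var(a_awake, a_unresp, gain, np.eye(m), rng_var)

    amps = plan.band_oscillators
    for band, (f0, bw) in OSC_BANDS.items():
        osc = _ar2_oscillator(n, f0, bw, fs, rng_osc, n_series=m)
        a_resp = amps["responsive"].get(band, 0.0)
        a_un = amps["unresponsive"].get(band, 0.0)
        x += (a_resp + gain * (a_un - a_resp)) * osc
    for sh in plan.shared_oscillators:
        f0, bw = OSC_BANDS[sh.band]
        osc = _ar2_oscillator(n, f0, bw, fs, rng_osc)[0]
        amp = sh.amp_responsive + gain * (sh.amp_unresponsive - sh.amp_responsive)
        for c in sh.channels:
            x[idx[c]] += amp * osc

    artifacts: list[tuple[float, str]] = []
    n_art = rng_art.poisson(plan.artifact_rate * plan.duration / 60.0)
    width = int(0.3 * fs)
    bump = np.sin(np.linspace(0.0, math.pi, width))
    for _ in range(n_art):
        t0 = rng_art.uniform(0, plan.duration - 0.5)
        ch = plan.montage.names[rng_art.integers(m)]
        amp_uv = rng_art.uniform(280.0, 400.0) * rng_art.choice([-1.0, 1.0])
        i0 = int(t0 * fs)
        x[idx[ch], i0:i0 + width] += (amp_uv / plan.amplitude_uv) * bump
        artifacts.append((t0, ch))

    if plan.muscle_noise_channels and plan.muscle_noise_sd > 0:
        b, a = butter(3, [20 / (fs / 2), 45 / (fs / 2)], btype="band")
        for c in plan.muscle_noise_channels:
            mn = filtfilt(b, a, rng_mus.standard_normal(n))
            mn /= mn.std()
            x[idx[c]] += plan.muscle_noise_sd * mn * (1.0 - gain)

    rest_end = plan.phases[0][1] if plan.phases[0][0] == "rest_eyes_closed" else 0.0
    events = EventTimeline(
        infusion_start=plan.infusion_start, lobr=plan.lobr, robr=plan.robr,
        eye_closed_intervals=((0.0, rest_end), (plan.lobr, plan.robr)),
    )
    rec = Recording(
        signal=plan.amplitude_uv * x, sample_rate=fs, montage=plan.montage,
        events=events, subject=f"sim{plan.seed:04d}",
    )
    truth = {
        "edges_by_phase": {
            label: [list(e) for e in plan.edges_for_phase(label)]
            for label, _ in plan.phases
        },
        "coupled_pairs": [[s, t] for s, t, _ in plan.coupling_awake],
        "events": events.to_dict(),
        "artifacts": artifacts,
        "seed": plan.seed,
    }
    return rec, truth
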