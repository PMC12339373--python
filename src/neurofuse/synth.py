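"""Synthetic multimodal cohorts with planted, recoverable structure.

Real paired fMRI/EEG clinical-trial data are access-restricted, so every
pipeline stage here is exercised on generated cohorts that emulate the
statistical structure the method relies on:

* a group-level connectivity template shared by all subjects;
* per-subject symmetric deviation fields (low-rank + noise) that are
  partially shared between the two modalities (cross-modal coupling ρ);
* extra deviation variance on a planted set of edges among a planted set
  of ROIs, with per-edge effect weights;
* a treatment-outcome label (ΔHAMD, baseline minus week 8) that is a
  linear function of the planted-edge deviations plus Gaussian noise.

Two generators are provided: one at the connectivity level (fast; used
for model/evaluation tests) and one at the time-series level (exercises
the full Pearson-FC and power-envelope-connectivity front end).

Ground truth (planted sets, per-edge weights, subject factors) is stored
alongside each cohort so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sosfiltfilt, butter

from .connectivity import (
    ConnectivityMatrix,
    RoiTimeSeries,
    CANONICAL_BANDS,
    normalize_connectivity,
)

__all__ = ["SynthConfig", "SynthCohort", "fast_config", "gen_connectivity_cohort", "gen_timeseries_cohort"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` scales the standardized planted-edge score in the
    outcome; ``noise_sd`` is the sd of the additive outcome noise, so at
    the defaults (1.0, 0.5) the best possible predictor explains
    1/(1+0.25) = 80% of outcome variance. ``cross_modal_coupling`` ρ
    mixes a shared subject factor into both modalities' deviations
    (ρ=1, zero deviation noise → identical deviation fields).
    """

    n_subjects: int = 120
    n_rois: int = 100
    t_fmri: int = 300
    t_eeg: int = 5000
    sampling_rate: float = 250.0
    planted_rois: tuple[int, ...] | None = None   # default: first 10 ROIs
    planted_edges: tuple[tuple[int, int], ...] | None = None
    effect_size: float = 1.0
    noise_sd: float = 0.5
    cross_modal_coupling: float = 0.7
    band: str = "alpha"
    seed: int = 0
    # deviation-field geometry
    dev_rank: int = 3
    dev_scale: float = 0.08
    dev_noise_sd: float = 0.03
    planted_sd: float = 0.12
    planted_idio: float = 0.3       # per-edge idiosyncratic jitter, fraction of planted_sd
    arm: str = "sertraline"
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.cross_modal_coupling <= 1.0):
            raise ValueError("cross_modal_coupling must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_rois is None:
            self.planted_rois = tuple(range(min(10, self.n_rois)))
        if any(r < 0 or r >= self.n_rois for r in self.planted_rois):
            raise ValueError("planted ROI index out of range")
        if self.planted_edges is None:
            # the planted signature is a subnetwork: every pair of planted ROIs
            rois = list(self.planted_rois)
            self.planted_edges = tuple(
                (rois[a], rois[b]) for a in range(len(rois)) for b in range(a + 1, len(rois))
            )
        for (i, j) in self.planted_edges:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois) or i == j:
                raise ValueError(f"infeasible planted edge ({i}, {j})")


def fast_config(**overrides) -> SynthConfig:
    """Desk-scale configuration: 20 ROIs, 120 subjects."""
    defaults = dict(n_rois=20, n_subjects=120, t_fmri=240, t_eeg=4000)
    defaults.update(overrides)
    return SynthConfig(**defaults)


@dataclass
class SynthCohort:
    """A generated cohort plus the ground truth needed for recovery tests."""

    config: SynthConfig
    subject_ids: list[str]
    outcomes: np.ndarray                      # ΔHAMD per subject
    hamd_baseline: np.ndarray
    hamd_week8: np.ndarray
    connectivity: dict[str, list[ConnectivityMatrix]] = field(default_factory=dict)
    timeseries: dict[str, list[RoiTimeSeries]] = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def edge_effect_matrix(self) -> np.ndarray:
        """N×N matrix of planted per-edge effect weights (0 elsewhere)."""
        n = self.config.n_rois
        m = np.zeros((n, n))
        for (i, j), w in zip(self.ground_truth["planted_edges"], self.ground_truth["edge_weights"]):
            m[i, j] = m[j, i] = w
        return m


def _group_template(rng: np.random.Generator, n: int) -> np.ndarray:
    """A plausible group-average correlation template (moderate off-diagonals)."""
    f = rng.normal(size=(n, max(3, n // 5)))
    cov = f @ f.T + n * np.eye(n) / 2.0
    d = np.sqrt(np.diag(cov))
    t = cov / np.outer(d, d)
    np.fill_diagonal(t, 1.0)
    return t


def _symmetric_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    e = rng.normal(size=(n, n))
    e = (e + e.T) / np.sqrt(2.0)
    np.fill_diagonal(e, 0.0)
    return e


def _edge_loadings(cfg: SynthConfig) -> np.ndarray:
    n_e = len(cfg.planted_edges)
    return np.linspace(0.5, 1.5, n_e) if n_e > 1 else np.ones(1)


def _deviation_fields(cfg: SynthConfig, rng: np.random.Generator):
    """Per-subject, per-modality symmetric deviation fields.

    The predictive signature is a subnetwork mode: a per-subject
    expression score modulates every planted edge coherently, with fixed
    per-edge loadings (the ground-truth effect sizes) plus idiosyncratic
    jitter. The score and the low-rank nuisance loadings each mix a
    shared subject factor (weight sqrt(ρ)) with modality-private factors
    (sqrt(1−ρ)). Returns (devs[mod][s] as N×N array, per-subject
    planted-edge deviations per modality).
    """
    n, S = cfg.n_rois, cfg.n_subjects
    rho = cfg.cross_modal_coupling
    n_e = len(cfg.planted_edges)
    v = rng.normal(size=(cfg.dev_rank, n))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    loadings = _edge_loadings(cfg)
    shared_load = rng.normal(size=(S, cfg.dev_rank))
    shared_mode = rng.normal(size=S)
    shared_idio = rng.normal(size=(S, n_e))
    devs = {"fmri": [], "eeg": []}
    planted_dev = {}
    for mod in ("fmri", "eeg"):
        priv_load = rng.normal(size=(S, cfg.dev_rank))
        priv_mode = rng.normal(size=S)
        priv_idio = rng.normal(size=(S, n_e))
        lam = np.sqrt(rho) * shared_load + np.sqrt(1 - rho) * priv_load
        mode = np.sqrt(rho) * shared_mode + np.sqrt(1 - rho) * priv_mode
        idio = np.sqrt(rho) * shared_idio + np.sqrt(1 - rho) * priv_idio
        planted_dev[mod] = cfg.planted_sd * (
            mode[:, None] * loadings[None, :] + cfg.planted_idio * idio
        )
        for s in range(S):
            d = cfg.dev_scale * np.einsum("k,ki,kj->ij", lam[s], v, v)
            d = d + cfg.dev_noise_sd * _symmetric_noise(rng, n)
            for e, (i, j) in enumerate(cfg.planted_edges):
                p = planted_dev[mod][s, e]
                d[i, j] += p
                d[j, i] += p
            np.fill_diagonal(d, 0.0)
            devs[mod].append(d)
    return devs, planted_dev


def _outcome(cfg: SynthConfig, rng: np.random.Generator, planted_dev: dict) -> tuple:
    weights = _edge_loadings(cfg)
    mean_dev = (planted_dev["fmri"] + planted_dev["eeg"]) / 2.0
    # unweighted sum over planted edges: y is linear in the planted-edge
    # deviations themselves; the per-edge loadings shape their variances
    score = mean_dev.sum(axis=1)
    sd = score.std()
    if sd > 0:
        score = (score - score.mean()) / sd
    y = cfg.effect_size * score + cfg.noise_sd * rng.normal(size=cfg.n_subjects)
    return y, weights, score


def _clinical_scores(cfg: SynthConfig, rng: np.random.Generator, y: np.ndarray):
    baseline = np.clip(np.round(18 + 3 * rng.normal(size=cfg.n_subjects)), 10, 34)
    # ΔHAMD on a clinical scale: ~4 HAMD points per unit of latent outcome
    delta = np.clip(np.round(6 + 4 * y), None, baseline)
    week8 = baseline - delta
    return baseline, week8, delta


def gen_connectivity_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a cohort directly at the connectivity level.

    Subject connectivity = group template + deviation field, clipped to
    valid correlation range, then passed through the same Fisher-z +
    edge z-scoring normalization chain as measured data.
    """
    rng = np.random.default_rng(cfg.seed)
    template = cfg.template if cfg.template is not None else _group_template(rng, cfg.n_rois)
    devs, planted_dev = _deviation_fields(cfg, rng)
    y, weights, score = _outcome(cfg, rng, planted_dev)
    baseline, week8, delta = _clinical_scores(cfg, rng, y)
    ids = [f"sub-{s:04d}" for s in range(cfg.n_subjects)]

    connectivity: dict[str, list[ConnectivityMatrix]] = {"fmri": [], "eeg": []}
    for mod in ("fmri", "eeg"):
        band = cfg.band if mod == "eeg" else None
        for s, sid in enumerate(ids):
            raw = np.clip(template + devs[mod][s], -0.97, 0.97)
            np.fill_diagonal(raw, 1.0)
            raw = (raw + raw.T) / 2.0
            c = ConnectivityMatrix(sid, mod, raw, ["raw_corr"], band)
            connectivity[mod].append(normalize_connectivity(c))

    gt = {
        "planted_rois": list(cfg.planted_rois),
        "planted_edges": [list(e) for e in cfg.planted_edges],
        "edge_weights": weights,
        "planted_score": score,
        "deviations": devs,
        "effect_size": cfg.effect_size,
        "noise_sd": cfg.noise_sd,
        "latent_outcome": y,
    }
    return SynthCohort(cfg, ids, delta, baseline, week8, connectivity=connectivity, ground_truth=gt)


def _nearest_pd(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() > floor:
        return m
    w = np.clip(w, floor, None)
    r = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def _ar1_series(rng, sigma: np.ndarray, t: int, a: float = 0.3) -> np.ndarray:
    """AR(1) Gaussian series with stationary cross-correlation ``sigma``."""
    n = sigma.shape[0]
    chol = np.linalg.cholesky(sigma)
    innov = rng.normal(size=(t + 50, n)) @ chol.T * np.sqrt(1 - a * a)
    x = np.zeros((t + 50, n))
    x[0] = rng.normal(size=n) @ chol.T
    for k in range(1, t + 50):
        x[k] = a * x[k - 1] + innov[k]
    return x[50:]


def _envelope_series(rng, sigma: np.ndarray, t: int, fs: float) -> np.ndarray:
    """Slow (<1 Hz) log-normal amplitude envelopes with target latent correlation."""
    n = sigma.shape[0]
    chol = np.linalg.cholesky(sigma)
    white = rng.normal(size=(t + 200, n)) @ chol.T
    sos = butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
    slow = sosfiltfilt(sos, white, axis=0)[100:-100]
    slow /= slow.std(axis=0, keepdims=True)
    return np.exp(0.5 * slow)


def gen_timeseries_cohort(cfg: SynthConfig, modalities: tuple[str, ...] = ("fmri", "eeg")) -> SynthCohort:
    """Generate a cohort at the raw time-series level.

    fMRI-like data are AR(1) Gaussian series whose stationary
    cross-correlation matches the subject's target connectivity. EEG-like
    data are band-limited oscillators (carrier frequency jittered within
    the configured band, independent phases) modulated by slow log-normal
    envelopes whose latent correlations follow the same target, so the
    measured power-envelope connectivity recovers the planted structure.
    """
    rng = np.random.default_rng(cfg.seed)
    template = cfg.template if cfg.template is not None else _group_template(rng, cfg.n_rois)
    devs, planted_dev = _deviation_fields(cfg, rng)
    y, weights, score = _outcome(cfg, rng, planted_dev)
    baseline, week8, delta = _clinical_scores(cfg, rng, y)
    ids = [f"sub-{s:04d}" for s in range(cfg.n_subjects)]
    band = CANONICAL_BANDS[cfg.band]

    ts: dict[str, list[RoiTimeSeries]] = {m: [] for m in modalities}
    targets: dict[str, list[np.ndarray]] = {m: [] for m in modalities}
    for mod in modalities:
        for s, sid in enumerate(ids):
            sig = np.clip(template + devs[mod][s], -0.97, 0.97)
            np.fill_diagonal(sig, 1.0)
            sig = _nearest_pd((sig + sig.T) / 2.0)
            targets[mod].append(sig)
            if mod == "fmri":
                data = _ar1_series(rng, sig, cfg.t_fmri)
                ts[mod].append(RoiTimeSeries(sid, "fmri", data))
            else:
                env = _envelope_series(rng, sig, cfg.t_eeg, cfg.sampling_rate)
                tt = np.arange(cfg.t_eeg) / cfg.sampling_rate
                freqs = rng.uniform(band.low_hz + 0.5, band.high_hz - 0.5, size=cfg.n_rois)
                phases = rng.uniform(0, 2 * np.pi, size=cfg.n_rois)
                carrier = np.cos(2 * np.pi * freqs[None, :] * tt[:, None] + phases[None, :])
                data = env * carrier + 0.02 * rng.normal(size=(cfg.t_eeg, cfg.n_rois))
                ts[mod].append(RoiTimeSeries(sid, "eeg", data, sampling_rate=cfg.sampling_rate))

    gt = {
        "planted_rois": list(cfg.planted_rois),
        "planted_edges": [list(e) for e in cfg.planted_edges],
        "edge_weights": weights,
        "planted_score": score,
        "deviations": devs,
        "target_connectivity": targets,
        "effect_size": cfg.effect_size,
        "noise_sd": cfg.noise_sd,
        "latent_outcome": y,
    }
    return SynthCohort(cfg, ids, delta, baseline, week8, timeseries=ts, ground_truth=gt)
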