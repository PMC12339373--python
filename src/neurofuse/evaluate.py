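"""Evaluation protocol: cross-validation, permutation tests, band
comparison, unimodal transfer, clinical-scale association and
treatment-preference stratification.

The central object is a 10-fold cross-validation stratified by outcome
quantile: models (and any data augmentation) are fit strictly inside
training folds, out-of-fold predictions are pooled, and performance is
reported as pooled R² = 1 − SSres/SStot together with the Pearson
correlation between predicted and observed HAMD17 change. Statistical
significance uses label-permutation nulls with the add-one estimator
p = (1 + #{perm ≥ obs}) / (1 + B).

Two model backends share the identical harness code path: the full
dual-GNN fusion model, and a ridge regression on vectorized edges (a
fast linear baseline used where many thousands of refits are needed,
e.g. when checking the permutation machinery itself).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cobe import augment_dataset
from .connectivity import upper_triangle
from .model import (
    FusionConfig,
    FusionDataset,
    FusionModelParams,
    build_graph,
    latent_pairs,
    predict,
    train_model,
)

__all__ = [
    "EvalConfig",
    "CvRunResult",
    "StratificationResult",
    "stratified_folds",
    "cross_validate",
    "permutation_test",
    "compare_bands",
    "TransferModel",
    "train_transfer_model",
    "transfer_predict",
    "associate_clinical",
    "compare_correlations",
    "stratify_patients",
    "chi_square_yates",
    "pooled_r2",
]


@dataclass
class EvalConfig:
    """Cross-validation harness settings."""

    model: FusionConfig = field(default_factory=FusionConfig)
    n_folds: int = 10
    augment: bool = True
    c_schedule: tuple[int, ...] = (1, 2)
    backend: str = "fusion"          # "fusion" | "ridge"
    ridge_alpha: float = 10.0


@dataclass
class CvRunResult:
    """One seed's cross-validation outcome."""

    seed: int
    fold_assignments: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    r2: float
    pearson_r: float
    pearson_p: float
    fold_models: list = field(default_factory=list)


@dataclass
class StratificationResult:
    predicted_sertraline: np.ndarray
    predicted_placebo: np.ndarray
    preferred: np.ndarray                    # "sertraline" | "placebo"
    responder: np.ndarray                    # bool
    tables: dict[str, np.ndarray]            # per actual arm: 2×2 counts
    chi2: dict[str, tuple[float, float]]     # per arm: (statistic, p)
    t_tests: dict[str, tuple[float, float]]  # per arm: (t, p)


def permutation_pvalue(null_stats: np.ndarray, observed: float) -> float:
    """Add-one permutation p-value: (1 + #{null ≥ observed}) / (1 + B)."""
    null_stats = np.asarray(null_stats)
    return float((1.0 + np.sum(null_stats >= observed)) / (1.0 + len(null_stats)))


logger = logging.getLogger("neurofuse")


def pooled_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Outcome-quantile-stratified fold assignment.

    Subjects are sorted by outcome, cut into consecutive quantile blocks
    of ``n_folds`` subjects, and fold labels are shuffled within each
    block, so every fold spans the outcome range.
    """
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError(f"{n} subjects is too few for {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        labels = rng.permutation(n_folds)[: len(block)]
        folds[block] = labels
    counts = np.bincount(folds, minlength=n_folds)
    if counts.min() < 2:
        raise ValueError("a fold has fewer than 2 subjects")
    return folds


# ---------------------------------------------------------------------------
# backends


def _augment_training_set(ds: FusionDataset, c_schedule) -> FusionDataset:
    """Append COBE-residual copies of every training subject (train only)."""
    xs = {m: [ds.batch[m]["x"][i] for i in range(len(ds))] for m in ("fmri", "eeg")}
    new = {m: {"x": [], "a": []} for m in ("fmri", "eeg")}
    labels = []
    ids = []
    for m in ("fmri", "eeg"):
        samples = augment_dataset(xs[m], ds.subject_ids, ds.labels, list(c_schedule), modality=m)
        for s in samples:
            g = build_graph(_as_conn(s.values, m, s.source_subject_id))
            new[m]["x"].append(g.node_features)
            new[m]["a"].append(g.adjacency)
    n_aug = len(new["fmri"]["x"])
    labels = [s.label for s in samples][:n_aug]  # schedules align across modalities
    ids = [f"{s.source_subject_id}+aug{s.augmentation_tag}" for s in samples][:n_aug]
    xf = np.concatenate([ds.batch["fmri"]["x"], np.stack(new["fmri"]["x"])])
    af = np.concatenate([ds.batch["fmri"]["a"], np.stack(new["fmri"]["a"])])
    xe = np.concatenate([ds.batch["eeg"]["x"], np.stack(new["eeg"]["x"])])
    ae = np.concatenate([ds.batch["eeg"]["a"], np.stack(new["eeg"]["a"])])
    lab = np.concatenate([ds.labels, labels])
    flags = np.concatenate([ds.is_augmented, np.ones(n_aug, dtype=bool)])
    return FusionDataset(xf, af, xe, ae, lab, ds.subject_ids + ids, flags)


def _as_conn(values, modality, subject_id):
    from .connectivity import ConnectivityMatrix

    return ConnectivityMatrix(subject_id, modality, values, ["raw_corr", "fisher_z", "zscore"])


def _edge_features(ds: FusionDataset) -> np.ndarray:
    feats = []
    for m in ("fmri", "eeg"):
        x = ds.batch[m]["x"]
        feats.append(np.stack([upper_triangle(x[i]) for i in range(len(ds))]))
    return np.concatenate(feats, axis=1)


def _fit_fold(train: FusionDataset, test: FusionDataset, cfg: EvalConfig, seed: int):
    """Fit one fold's model; returns (test predictions, model, train size)."""
    if cfg.backend == "fusion":
        if cfg.augment and cfg.c_schedule:
            train = _augment_training_set(train, cfg.c_schedule)
        params = train_model(train, cfg.model, seed=seed)
        return predict(params, test.subset(np.arange(len(test)))), params, len(train)
    if cfg.backend == "ridge":
        from sklearn.linear_model import Ridge

        model = Ridge(alpha=cfg.ridge_alpha)
        model.fit(_edge_features(train), train.labels)
        return model.predict(_edge_features(test)), model, len(train)
    raise ValueError(f"unknown backend {cfg.backend!r}")


# ---------------------------------------------------------------------------
# cross-validation and permutation testing


def cross_validate(
    dataset: FusionDataset,
    config: EvalConfig,
    seeds: list[int],
    keep_models: bool = False,
) -> list[CvRunResult]:
    """Independent CV runs, one per seed (fold split and init both reseeded)."""
    if len(dataset) < 20:
        raise ValueError("need at least 20 subjects")
    results = []
    for seed in seeds:
        folds = stratified_folds(dataset.labels, config.n_folds, seed)
        y_pred = np.empty(len(dataset))
        models = []
        for k in range(config.n_folds):
            test_idx = np.flatnonzero(folds == k)
            train_idx = np.flatnonzero(folds != k)
            fold_seed = (seed * 1009 + k) % (2**31 - 1)
            preds, model, n_train = _fit_fold(
                dataset.take(train_idx), dataset.take(test_idx), config, fold_seed
            )
            y_pred[test_idx] = preds
            fold_r2 = pooled_r2(dataset.labels[test_idx], preds)
            logger.info(
                "seed=%d fold=%d train_size=%d (augmented=%d) test_r2=%.4f",
                seed, k, n_train, n_train - len(train_idx), fold_r2,
            )
            if keep_models:
                models.append(model)
        r, p = stats.pearsonr(dataset.labels, y_pred)
        results.append(
            CvRunResult(seed, folds, dataset.labels.copy(), y_pred,
                        pooled_r2(dataset.labels, y_pred), float(r), float(p),
                        fold_models=models)
        )
    return results


def permutation_test(
    dataset: FusionDataset,
    config: EvalConfig,
    b: int = 1000,
    seed: int = 0,
    observed: CvRunResult | None = None,
    null_config: EvalConfig | None = None,
) -> tuple[float, pd.DataFrame, CvRunResult]:
    """Label-permutation test of the cross-validated correlation.

    Outcome labels are permuted before the full CV (so augmentation, if
    enabled, sees permuted labels); p = (1 + #{perm r ≥ observed r}) /
    (1 + B). Returns the p-value, a frame of null statistics (columns
    ``r`` and ``r2``) and the observed run. ``null_config`` may use a
    cheaper configuration (reduced epochs) for the permuted refits.
    """
    if b < 100:
        raise ValueError("need at least 100 permutations")
    if observed is None:
        observed = cross_validate(dataset, config, [seed])[0]
    ncfg = null_config or config
    rng = np.random.default_rng(seed)
    null_r = np.empty(b)
    null_r2 = np.empty(b)
    for i in range(b):
        perm = rng.permutation(len(dataset))
        permuted = FusionDataset(
            dataset.batch["fmri"]["x"], dataset.batch["fmri"]["a"],
            dataset.batch["eeg"]["x"], dataset.batch["eeg"]["a"],
            dataset.labels[perm], dataset.subject_ids, dataset.is_augmented,
        )
        run = cross_validate(permuted, ncfg, [int(rng.integers(2**31 - 1))])[0]
        null_r[i] = run.pearson_r
        null_r2[i] = run.r2
    null = pd.DataFrame({"r": null_r, "r2": null_r2})
    return permutation_pvalue(null_r, observed.pearson_r), null, observed


def compare_bands(
    results_per_band: dict[str, list[CvRunResult]], reference: str = "alpha"
) -> pd.DataFrame:
    """Paired t-tests of per-seed R² between the reference band and the rest.

    Benjamini–Hochberg correction across the comparisons. A degenerate
    zero-variance nonzero difference is reported as p = 0.
    """
    from statsmodels.stats.multitest import multipletests

    ref = np.array([r.r2 for r in results_per_band[reference]])
    rows = []
    for band, runs in results_per_band.items():
        if band == reference:
            continue
        other = np.array([r.r2 for r in runs])
        if len(other) != len(ref):
            raise ValueError(f"unequal run counts for {band} vs {reference}")
        diff = ref - other
        if np.allclose(diff.std(), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(diff.mean()), 0.0
        else:
            t, p = stats.ttest_rel(ref, other)
        rows.append({"band": band, "mean_diff": float(diff.mean()), "t": float(t), "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# multimodal -> unimodal transfer


@dataclass
class TransferModel:
    """Reduced MLP trained on single-modality latents.

    Input width is the latent dimension d and the hidden widths are half
    those of the fusion model's MLP head, so a patient with only one
    modality can be scored from that branch's latent alone.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray
    y_mean: float
    y_std: float


def train_transfer_model(
    fusion_params: FusionModelParams,
    train_dataset: FusionDataset,
    seed: int = 0,
    epochs: int = 300,
    lr: float = 1e-3,
) -> TransferModel:
    """Fit the reduced MLP on the union of fMRI and EEG training latents."""
    pairs = latent_pairs(fusion_params, train_dataset.subset(np.arange(len(train_dataset))))
    zf = np.stack([p.z_fmri for p in pairs])
    ze = np.stack([p.z_eeg for p in pairs])
    x = np.concatenate([zf, ze])
    y = np.concatenate([train_dataset.labels, train_dataset.labels])
    y_mean, y_std = float(y.mean()), float(y.std()) or 1.0
    y_n = (y - y_mean) / y_std

    h1, h2 = (max(1, h // 2) for h in fusion_params.config.mlp_hidden)
    d = x.shape[1]
    rng = np.random.default_rng(seed)
    glorot = lambda a, b: rng.normal(0, np.sqrt(2.0 / (a + b)), size=(a, b))
    w1, b1 = glorot(d, h1), np.zeros(h1)
    w2, b2 = glorot(h1, h2), np.zeros(h2)
    w3, b3 = glorot(h2, 1), np.zeros(1)
    arrays = [w1, b1, w2, b2, w3, b3]
    mom = [np.zeros_like(a) for a in arrays]
    vel = [np.zeros_like(a) for a in arrays]
    for t in range(1, epochs + 1):
        a1 = np.tanh(x @ w1 + b1)
        a2 = np.tanh(a1 @ w2 + b2)
        out = (a2 @ w3 + b3)[:, 0]
        dout = 2.0 * (out - y_n) / len(y_n)
        dw3 = a2.T @ dout[:, None]
        db3 = np.array([dout.sum()])
        da2 = dout[:, None] @ w3.T * (1 - a2**2)
        dw2, db2 = a1.T @ da2, da2.sum(axis=0)
        da1 = da2 @ w2.T * (1 - a1**2)
        dw1, db1 = x.T @ da1, da1.sum(axis=0)
        for i, g in enumerate([dw1, db1, dw2, db2, dw3, db3]):
            mom[i] = 0.9 * mom[i] + 0.1 * g
            vel[i] = 0.999 * vel[i] + 0.001 * g * g
            arrays[i] -= lr * (mom[i] / (1 - 0.9**t)) / (np.sqrt(vel[i] / (1 - 0.999**t)) + 1e-8)
    return TransferModel(w1, b1, w2, b2, w3, b3, y_mean, y_std)


def transfer_predict(
    model: TransferModel,
    fusion_params: FusionModelParams,
    test_dataset: FusionDataset,
    modality: str,
) -> np.ndarray:
    """Score test subjects from a single modality's latent branch."""
    if modality not in ("fmri", "eeg"):
        raise ValueError(f"unknown modality {modality!r}")
    pairs = latent_pairs(fusion_params, test_dataset.subset(np.arange(len(test_dataset))))
    z = np.stack([p.z_fmri if modality == "fmri" else p.z_eeg for p in pairs])
    a1 = np.tanh(z @ model.w1 + model.b1)
    a2 = np.tanh(a1 @ model.w2 + model.b2)
    return (a2 @ model.w3 + model.b3)[:, 0] * model.y_std + model.y_mean


# ---------------------------------------------------------------------------
# clinical-scale association


def associate_clinical(
    latents: np.ndarray,
    scales: dict[str, np.ndarray],
    n_folds: int = 10,
    seed: int = 0,
    max_features: int = 5,
) -> pd.DataFrame:
    """Cross-validated GAM prediction of clinical scales from latents.

    Latents are reduced to their top principal components (default 5) and
    a generalized additive model with per-feature B-spline smooths (5
    basis functions, second-order difference penalty) is fit on training
    folds; the out-of-fold Pearson r per scale is reported with BH-FDR
    corrected p-values across scales.
    """
    from statsmodels.gam.api import BSplines, GLMGam
    from statsmodels.stats.multitest import multipletests

    x = np.asarray(latents, dtype=float)
    x = x - x.mean(axis=0)
    if x.shape[1] > max_features:
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        x = x @ vt[:max_features].T
    n = x.shape[0]
    rows = []
    for name, yv in scales.items():
        y = np.asarray(yv, dtype=float)
        if y.std() == 0:
            raise ValueError(f"scale {name} is constant")
        folds = stratified_folds(y, n_folds, seed)
        pred = np.empty(n)
        # knots span the full covariate support so held-out points are
        # always inside the outermost knots
        pad = 1e-6 + 0.01 * (x.max(axis=0) - x.min(axis=0))
        knot_kwds = [
            {"lower_bound": lo - p, "upper_bound": hi + p}
            for lo, hi, p in zip(x.min(axis=0), x.max(axis=0), pad)
        ]
        for k in range(n_folds):
            tr = folds != k
            te = ~tr
            bs = BSplines(
                x[tr], df=[5] * x.shape[1], degree=[3] * x.shape[1], knot_kwds=knot_kwds
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gam = GLMGam(y[tr], smoother=bs, alpha=[1.0] * x.shape[1]).fit()
                pred[te] = gam.predict(exog_smooth=x[te])
        r, p = stats.pearsonr(y, pred)
        rows.append({"scale": name, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z-test for two independent correlations.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided p.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# stratification and chi-square


def chi_square_yates(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction for a 2×2 table.

    χ² = N·(max(|ad−bc|−N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2×2 table of nonnegative integer counts")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    if n < 1:
        raise ValueError("empty table")
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in contingency table")
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    chi2 = num / np.prod(margins)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratify_patients(
    dataset: FusionDataset,
    subjects: pd.DataFrame,
    sertraline_model: FusionModelParams,
    placebo_model: FusionModelParams,
) -> StratificationResult:
    """Assign every patient a preferred arm from both arm models' predictions.

    ``subjects`` must carry columns arm, hamd_baseline, hamd_week8
    aligned with the dataset order. Preferred arm is the one with the
    larger predicted improvement (ties go to sertraline). Within each
    actual arm, a 2×2 table of (preference aligned with assignment) ×
    (responder: observed reduction > 50% of baseline) is tested with the
    Yates-corrected chi-square, and the observed HAMD17 reduction rates
    of aligned vs non-aligned patients are compared with a pooled-
    variance two-sample t-test.
    """
    baseline = subjects["hamd_baseline"].to_numpy(dtype=float)
    week8 = subjects["hamd_week8"].to_numpy(dtype=float)
    if np.any(~np.isfinite(baseline)):
        raise ValueError("missing baseline HAMD17")
    arms = subjects["arm"].to_numpy()
    full = dataset.subset(np.arange(len(dataset)))
    pred_s = predict(sertraline_model, full)
    pred_p = predict(placebo_model, full)
    preferred = np.where(pred_s >= pred_p, "sertraline", "placebo")
    reduction = baseline - week8
    responder = reduction > 0.5 * baseline
    rate = reduction / baseline

    tables, chi2s, ts = {}, {}, {}
    for arm in ("sertraline", "placebo"):
        in_arm = arms == arm
        aligned = preferred[in_arm] == arm
        resp = responder[in_arm]
        table = np.array(
            [
                [np.sum(aligned & resp), np.sum(aligned & ~resp)],
                [np.sum(~aligned & resp), np.sum(~aligned & ~resp)],
            ]
        )
        tables[arm] = table
        try:
            chi2s[arm] = chi_square_yates(table)
        except ValueError:
            chi2s[arm] = (float("nan"), float("nan"))  # degenerate margin
        if aligned.all() or (~aligned).all():
            ts[arm] = (float("nan"), float("nan"))
        else:
            t, p = stats.ttest_ind(rate[in_arm][aligned], rate[in_arm][~aligned], equal_var=True)
            ts[arm] = (float(t), float(p))
    return StratificationResult(pred_s, pred_p, preferred, responder, tables, chi2s, ts)
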