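"""Post-hoc interpretability: ROI, edge and network-level importance.

ROI importance comes from the latent projection matrices: per fold and
modality, the projection columns are combined with the softmax
aggregation weights into a single ROI-length vector, taken in absolute
value, normalized to sum 1, and averaged over the cross-validation
folds. Edge importance is the fold-average of the symmetrized learned
edge-scaling matrix; entries are ranked by absolute value, with sign
retained (positive/negative connections). Both are rolled up to the
seven canonical functional networks of the parcellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FusionModelParams, MODALITIES

__all__ = [
    "Parcellation",
    "ImportanceReport",
    "NETWORK_NAMES",
    "roi_importance",
    "edge_importance",
    "top_k_edges",
    "network_rollup",
    "build_report",
]

NETWORK_NAMES = ("VN", "SMN", "DAN", "VAN", "LN", "FPCN", "DMN")


@dataclass
class Parcellation:
    """Mapping of contiguous 0-based ROI indices to labels and networks."""

    roi_labels: list[str]
    networks: list[str]

    def __post_init__(self) -> None:
        if len(self.roi_labels) != len(self.networks):
            raise ValueError("labels and networks must align")
        unknown = set(self.networks) - set(NETWORK_NAMES)
        if unknown:
            raise ValueError(f"unknown network name(s): {sorted(unknown)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def members(self, network: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.networks) == network)
        if idx.size == 0:
            raise ValueError(f"network {network} has no member ROIs")
        return idx


@dataclass
class ImportanceReport:
    roi_scores: dict[str, np.ndarray]              # per modality, sums to 1
    edge_scores: dict[str, np.ndarray]             # per modality, signed N×N
    network_roi_scores: dict[str, pd.Series] = field(default_factory=dict)
    network_edge_intensity: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def roi_importance(models: list[FusionModelParams]) -> dict[str, np.ndarray]:
    """Aggregation-weighted projection mass per ROI, fold-averaged.

    Per fold/modality: v_m = Σ_j α_j · W_m[:, j]; |v_m| normalized to
    sum 1; averaged over folds and renormalized.
    """
    if len(models) != 10:
        warnings.warn(f"expected 10 fold models, got {len(models)}", stacklevel=2)
    out = {}
    for mod in MODALITIES:
        acc = None
        for p in models:
            v = p.proj[mod] @ p.alpha
            v = np.abs(v)
            v = v / v.sum()
            acc = v if acc is None else acc + v
        acc /= len(models)
        out[mod] = acc / acc.sum()
    return out


def edge_importance(models: list[FusionModelParams], baseline: float = 1.0) -> dict[str, np.ndarray]:
    """Fold-mean of the symmetrized edge-scaling matrices, sign retained.

    ``baseline`` (the scaling matrices' initialization value, 1 by
    default) is subtracted so scores measure the learned deviation of
    each connection's weight in either direction; pass ``baseline=0`` to
    get the raw fold-mean matrices. Ranking uses |score|.
    """
    out = {}
    for mod in MODALITIES:
        mats = [
            (p.scale[mod] + p.scale[mod].T) / 2.0 - baseline for p in models
        ]
        m = np.mean(mats, axis=0)
        np.fill_diagonal(m, 0.0)
        out[mod] = m
    return out


def top_k_edges(edge_scores: np.ndarray, k: int = 20) -> list[tuple[int, int, float]]:
    """The k largest-|score| upper-triangle edges; ties all retained,
    deterministic (i, j) index order."""
    n = edge_scores.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = edge_scores[iu, ju]
    if len(vals) <= k:
        order = np.arange(len(vals))
    else:
        mags = np.abs(vals)
        cutoff = np.sort(mags)[::-1][k - 1]
        order = np.flatnonzero(mags >= cutoff)
    picked = sorted(zip(iu[order], ju[order], vals[order]), key=lambda t: (t[0], t[1]))
    return [(int(i), int(j), float(v)) for i, j, v in picked]


def network_rollup(
    roi_scores: np.ndarray, edge_scores: np.ndarray, parcellation: Parcellation
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Seven-network summaries of ROI and edge importance.

    Network ROI score = mean of member ROI scores. Network-pair edge
    intensity = mean |edge score| over member pairs (within-network pairs
    use the upper triangle only). The between-network summary for each
    network is the mean of its six off-diagonal intensities.
    """
    members = {net: parcellation.members(net) for net in NETWORK_NAMES}
    net_roi = pd.Series(
        {net: float(roi_scores[idx].mean()) for net, idx in members.items()}
    )
    intensity = pd.DataFrame(0.0, index=list(NETWORK_NAMES), columns=list(NETWORK_NAMES))
    absd = np.abs(edge_scores)
    for a, ia in members.items():
        for b, ib in members.items():
            if a == b:
                sub = absd[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                vals = sub[iu]
                intensity.loc[a, a] = float(vals.mean()) if vals.size else 0.0
            else:
                intensity.loc[a, b] = float(absd[np.ix_(ia, ib)].mean())
    between = pd.Series(
        {
            net: float(np.mean([intensity.loc[net, other] for other in NETWORK_NAMES if other != net]))
            for net in NETWORK_NAMES
        }
    )
    return net_roi, intensity, between


def build_report(
    models: list[FusionModelParams],
    parcellation: Parcellation | None = None,
    provenance: dict | None = None,
) -> ImportanceReport:
    """Full importance report for the fold models of one run."""
    roi = roi_importance(models)
    edges = edge_importance(models)
    report = ImportanceReport(roi, edges, provenance=provenance or {})
    if parcellation is not None:
        for mod in MODALITIES:
            net_roi, intensity, between = network_rollup(roi[mod], edges[mod], parcellation)
            report.network_roi_scores[mod] = net_roi
            report.network_edge_intensity[mod] = intensity
            report.provenance.setdefault("between_network", {})[mod] = between.to_dict()
    return report
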