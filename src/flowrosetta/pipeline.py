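"""End-to-end orchestration: events in, fitted models and report out.

`analyze_dataset` chains the full routine — optimal clustering, principal
axis alignment, outlier removal, windowed EM with BIC selection — and
`replicate_report` turns the resulting report back into a synthetic dataset
placed in the original sample geometry.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .generator import LabeledEvents, sample_cluster
from .model_fitting import ClusterModel, select_model
from .preprocessing import (
    ClusterTransform,
    RosettaConfig,
    find_optimal_clusters,
    outlier_window,
    remove_outliers,
    rotate_to_axis,
)
from .translation import (
    RosettaReport,
    model_to_report,
    report_to_generator_args,
)

__all__ = ["RosettaAnalysis", "analyze_dataset", "analyze_single_cluster", "replicate_report",
           "config_hash"]

logger = logging.getLogger(__name__)


@dataclass
class RosettaAnalysis:
    """Everything the routine derived from one dataset."""

    report: RosettaReport
    models: list[tuple[ClusterModel, ClusterTransform]]
    labels: np.ndarray
    n_clusters: int
    silhouette: float


def config_hash(cfg: RosettaConfig) -> str:
    payload = repr(sorted(asdict(cfg).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def analyze_single_cluster(
    points: np.ndarray,
    cfg: RosettaConfig,
    silhouette: float = float("nan"),
) -> tuple[ClusterModel, ClusterTransform, int]:
    """Align, trim and fit one cluster; returns (model, transform, n_original)."""
    rotated, transform = rotate_to_axis(points, cfg.angle_method, cfg.outer_percent)
    window = outlier_window(rotated, cfg.threshold_x, cfg.threshold_y)
    cleaned = remove_outliers(rotated, cfg.threshold_x, cfg.threshold_y)
    model = select_model(cleaned[:, 0], cleaned[:, 1], cfg, window=window,
                         rotation_deg=transform.rotation_deg, silhouette=silhouette)
    return model, transform, points.shape[0]


def analyze_dataset(
    events: LabeledEvents,
    cfg: RosettaConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> RosettaAnalysis:
    """Run the full routine on an event table."""
    cfg = cfg or RosettaConfig()
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    labels, k, sil = find_optimal_clusters(events, cfg, seed)
    models: list[tuple[ClusterModel, ClusterTransform]] = []
    counts: list[int] = []
    for cl in sorted(np.unique(labels[labels >= 0])):
        pts = events.values[labels == cl]
        model, transform, n_orig = analyze_single_cluster(pts, cfg, silhouette=sil)
        models.append((model, transform))
        counts.append(n_orig)
    report = model_to_report(models, events=counts,
                             seed=seed_int, config_hash=config_hash(cfg),
                             version=__version__)
    return RosettaAnalysis(report=report, models=models, labels=labels,
                           n_clusters=k, silhouette=sil)


def replicate_report(
    report: RosettaReport,
    seed: int | np.random.SeedSequence | None = 0,
    skew_divisor: float = 1.0,
) -> LabeledEvents:
    """Generate a synthetic dataset from a report (one cluster per row)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(report.clusters))
    parts = []
    for row, child in zip(report.clusters, children):
        args = report_to_generator_args(row, seed=child, skew_divisor=skew_divisor)
        parts.append(sample_cluster(args))
    values = np.vstack([p.values for p in parts])
    labels = np.concatenate([np.full(len(p), row.cluster_id, dtype=np.int64)
                             for p, row in zip(parts, report.clusters)])
    return LabeledEvents(values, labels)
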