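"""From fitted models to report rows and generator arguments.

This is the translation layer the pipeline is named for: it turns a fitted
`ClusterModel` (plus the recorded alignment transform) into the
human-readable per-cluster statistics table, and a report row back into
`GeneratorArgs` for the synthetic sampler.

Report semantics: means and SDs are the fitted mixture's aggregate *density*
moments (mixture-moment identities over components); Skew and Kurtosis are
the standardized skewness / excess kurtosis implied by the dominant-weight
component's shape parameter (all components are logged); means are
re-expressed in original pre-rotation coordinates through the inverse
transform; the rotation is the maximum-variance direction in the [270, 360)
or [0, 90] reporting convention.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, fields

import numpy as np

from .distributions import kurt_excess_kurtosis, skew_skewness
from .generator import ClusterMomentSpec, GeneratorArgs, args_from_moments
from .model_fitting import ClusterModel
from .preprocessing import ClusterTransform, apply_inverse, axis_to_rotation

__all__ = [
    "ClusterReportRow",
    "RosettaReport",
    "ReportParseError",
    "model_to_report_row",
    "model_to_report",
    "report_to_generator_args",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ("cluster_id", "events", "rotation_deg",
                  "x_mean", "x_sd", "x_skew", "x_bic",
                  "y_mean", "y_sd", "y_kurtosis", "y_bic",
                  "full_bic", "silhouette")


class ReportParseError(ValueError):
    """A report file is malformed; the message names the offending field."""


@dataclass(frozen=True)
class ClusterReportRow:
    """One cluster's derived statistics (one row of the report table)."""

    cluster_id: int
    events: int
    rotation_deg: float
    x_mean: float
    x_sd: float
    x_skew: float
    x_bic: float
    y_mean: float
    y_sd: float
    y_kurtosis: float
    y_bic: float
    full_bic: float
    silhouette: float

    def __post_init__(self) -> None:
        if self.events <= 0:
            raise ValueError("events must be > 0")
        if self.x_sd <= 0 or self.y_sd <= 0:
            raise ValueError("report SDs must be > 0")


@dataclass
class RosettaReport:
    """The per-cluster statistics table plus provenance metadata."""

    clusters: list[ClusterReportRow]
    seed: int | None = None
    config_hash: str | None = None
    version: str | None = None

    def row(self, cluster_id: int) -> ClusterReportRow:
        for r in self.clusters:
            if r.cluster_id == cluster_id:
                return r
        raise KeyError(f"no cluster {cluster_id} in report")


def model_to_report_row(model: ClusterModel, transform: ClusterTransform,
                        cluster_id: int = 0, events: int | None = None) -> ClusterReportRow:
    """Summarize one fitted cluster model into a report row.

    ``events`` defaults to the fitted point count; pass the original cluster
    size to report pre-trimming membership.
    """
    x_mean_a, x_sd = model.x_model.mixture_mean_sd()
    y_mean_a, y_sd = model.y_model.mixture_mean_sd()
    mean_orig = apply_inverse(np.array([[x_mean_a, y_mean_a]]), transform)[0]
    dom_x = model.x_model.dominant.shape
    dom_y = model.y_model.dominant.shape
    for dm in (model.x_model, model.y_model):
        if dm.n_components > 1:
            logger.info("%s-axis mixture components: %s", dm.axis,
                        [(round(c.weight, 4), c.shape) for c in dm.components])
    return ClusterReportRow(
        cluster_id=cluster_id,
        events=int(events if events is not None else model.n_events),
        rotation_deg=axis_to_rotation(model.rotation_deg),
        x_mean=float(mean_orig[0]), x_sd=float(x_sd),
        x_skew=skew_skewness(dom_x.alpha),  # type: ignore[arg-type]
        x_bic=model.x_model.bic,
        y_mean=float(mean_orig[1]), y_sd=float(y_sd),
        y_kurtosis=kurt_excess_kurtosis(dom_y.beta),  # type: ignore[arg-type]
        y_bic=model.y_model.bic,
        full_bic=model.full_bic,
        silhouette=model.silhouette,
    )


def model_to_report(models: list[tuple[ClusterModel, ClusterTransform]],
                    events: list[int] | None = None,
                    seed: int | None = None,
                    config_hash: str | None = None,
                    version: str | None = None) -> RosettaReport:
    """Assemble report rows for a list of fitted clusters."""
    rows = [model_to_report_row(m, t, cluster_id=i,
                                events=None if events is None else events[i])
            for i, (m, t) in enumerate(models)]
    return RosettaReport(rows, seed=seed, config_hash=config_hash, version=version)


def clamp_shape_moments(skew: float, kurtosis: float) -> tuple[float, float]:
    """Saturate shape moments to what the two families can represent.

    The skew family covers |skewness| < ~0.995 and the kurtosis family
    excess kurtosis in ~(-0.388, 0.600); values beyond (which arise when
    correcting heavily gate-truncated clusters) are clamped with a warning.
    """
    from .distributions import KURT_G2_RANGE, MAX_SKEWNESS
    s = max(min(skew, MAX_SKEWNESS - 1e-4), -(MAX_SKEWNESS - 1e-4))
    lo, hi = KURT_G2_RANGE
    k = max(min(kurtosis, hi - 1e-3), lo + 1e-3)
    if s != skew or k != kurtosis:
        logger.warning("shape moments saturated: skew %.4f -> %.4f, kurtosis %.4f -> %.4f",
                       skew, s, kurtosis, k)
    return s, k


def report_to_generator_args(row: ClusterReportRow,
                             seed: int | np.random.SeedSequence | None = None,
                             skew_divisor: float = 1.0) -> GeneratorArgs:
    """Compile one report row into sampler arguments.

    ``skew_divisor`` rescales the skewness before shape inversion.  The
    default 1.0 keeps analyze -> generate -> analyze loops
    moment-consistent with this package's own sampler.  Interop note: the
    original Julia/CluGen workflow divides the final X-dimension skew by pi
    and by 2 (net 2*pi) to compensate that generator's internal 2D-to-1D
    projection convention; pass ``skew_divisor=2*math.pi`` to reproduce that
    behaviour when exporting arguments to CluGen itself.
    """
    if skew_divisor <= 0:
        raise ValueError("skew_divisor must be > 0")
    spec = ClusterMomentSpec(
        events=row.events, rotation_deg=row.rotation_deg,
        x_mean=row.x_mean, x_sd=row.x_sd, x_skew=row.x_skew / skew_divisor,
        y_mean=row.y_mean, y_sd=row.y_sd, y_kurtosis=row.y_kurtosis)
    return args_from_moments(spec, seed=seed)


# ---------------------------------------------------------------------------
# report files: structured text + CSV mirror
# ---------------------------------------------------------------------------

_META_FIELDS = ("seed", "config_hash", "version")


def write_report(report: RosettaReport, path: str) -> None:
    """Write a report as structured text; a ``.csv`` mirror sits alongside.

    The text format is line-oriented ``key = value`` with one ``[cluster N]``
    section per cluster; the CSV mirror has one row per cluster with columns
    exactly ``REPORT_COLUMNS``.
    """
    lines = ["[rosetta-report]"]
    for name in _META_FIELDS:
        val = getattr(report, name)
        if val is not None:
            lines.append(f"{name} = {val}")
    for row in report.clusters:
        lines.append(f"[cluster {row.cluster_id}]")
        for col in REPORT_COLUMNS[1:]:
            lines.append(f"{col} = {getattr(row, col)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(_csv_path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REPORT_COLUMNS)
        for row in report.clusters:
            w.writerow([getattr(row, col) for col in REPORT_COLUMNS])


def _csv_path(path: str) -> str:
    return path + ".csv" if not path.endswith(".txt") else path[:-4] + ".csv"


def read_report(path: str) -> RosettaReport:
    """Parse a structured-text report; inverse of `write_report`."""
    meta: dict[str, str] = {}
    clusters: list[ClusterReportRow] = []
    current: dict[str, float] | None = None
    current_id: int | None = None

    def flush():
        if current is None:
            return
        missing = [c for c in REPORT_COLUMNS[1:] if c not in current]
        if missing:
            raise ReportParseError(
                f"cluster {current_id}: missing mandatory field '{missing[0]}'")
        clusters.append(ClusterReportRow(
            cluster_id=current_id,  # type: ignore[arg-type]
            events=int(current["events"]),
            **{c: float(current[c]) for c in REPORT_COLUMNS[2:]}))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line == "[rosetta-report]":
                continue
            if line.startswith("[cluster"):
                flush()
                try:
                    current_id = int(line.strip("[]").split()[1])
                except (IndexError, ValueError):
                    raise ReportParseError(f"line {lineno}: bad cluster header {line!r}")
                current = {}
                continue
            if "=" not in line:
                raise ReportParseError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            if current is None:
                if key not in _META_FIELDS:
                    raise ReportParseError(f"line {lineno}: unknown metadata field '{key}'")
                meta[key] = val
            else:
                if key not in REPORT_COLUMNS[1:]:
                    raise ReportParseError(f"line {lineno}: unknown field '{key}'")
                try:
                    current[key] = float(val)
                except ValueError:
                    raise ReportParseError(f"line {lineno}: field '{key}' is not numeric: {val!r}")
    flush()
    return RosettaReport(
        clusters,
        seed=int(meta["seed"]) if "seed" in meta else None,
        config_hash=meta.get("config_hash"),
        version=meta.get("version"))
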