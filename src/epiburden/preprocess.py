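"""Quality-control filters and the beta <-> M transformation.

Probe-level QC removes probes with any missing value, a detection p-value
above threshold in any sample, a low bead count in too many samples, or
membership in SNP-overlapping / multi-mapping blacklists.  Sample-level QC
removes samples that lost more than a tolerated fraction of probes.  The
detection-p and bead-count grids are optional because public beta matrices
often arrive already QC'd; when a grid is absent the corresponding rule is
skipped and recorded as such in the removal report.

The M-value transform is the logit on base 2: ``M = log2(beta / (1 - beta))``.
Betas are clipped away from {0, 1} by a small epsilon so M stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import BETA_SCALE, M_SCALE, MethylationMatrix, ScaleError

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Thresholds for probe- and sample-level quality control.

    Defaults follow common Illumina-array practice: detection p above 1%
    in any sample fails the probe; a bead count below 3 in at least 5% of
    samples fails the probe; a sample losing more than 10% of probes is
    dropped.
    """

    max_detection_p: float = 0.01
    min_bead_count: int = 3
    max_bead_fail_fraction: float = 0.05
    max_sample_probe_loss: float = 0.10
    snp_probe_list: frozenset = field(default_factory=frozenset)
    multihit_probe_list: frozenset = field(default_factory=frozenset)
    beta_clip_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_detection_p", "max_bead_fail_fraction", "max_sample_probe_loss"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0 < self.beta_clip_epsilon < 0.5:
            raise ValueError("beta_clip_epsilon must lie in (0, 0.5)")
        self.snp_probe_list = frozenset(self.snp_probe_list)
        self.multihit_probe_list = frozenset(self.multihit_probe_list)


def _check_grid(grid: pd.DataFrame | None, matrix: MethylationMatrix, what: str) -> None:
    if grid is None:
        return
    if not grid.index.equals(matrix.probes) or not grid.columns.equals(matrix.samples):
        raise ValueError(f"{what} grid does not align with the matrix (probes x samples)")


def filter_probes(
    matrix: MethylationMatrix,
    detection_p: pd.DataFrame | None = None,
    bead_counts: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove low-quality probes; return the filtered matrix and a report.

    A probe is removed if any of the following holds:

    * any sample has a missing value for it;
    * any sample's detection p exceeds ``max_detection_p`` (grid given);
    * its bead count is below ``min_bead_count`` in at least
      ``max_bead_fail_fraction`` of samples (grid given);
    * it appears on the SNP or multi-hit blacklist.

    The report lists per-criterion counts (criteria may overlap) and the
    unique total actually removed.
    """
    thresholds = thresholds or QCThresholds()
    _check_grid(detection_p, matrix, "detection-p")
    _check_grid(bead_counts, matrix, "bead-count")

    vals = matrix.values
    removed: dict[str, pd.Index] = {}
    removed["missing_value"] = vals.index[vals.isna().any(axis=1)]
    if detection_p is not None:
        removed["detection_p"] = vals.index[
            (detection_p > thresholds.max_detection_p).any(axis=1)
        ]
    else:
        log.info("no detection-p grid supplied; detection-p filter skipped")
    if bead_counts is not None:
        fail_frac = (bead_counts < thresholds.min_bead_count).mean(axis=1)
        removed["bead_count"] = vals.index[fail_frac >= thresholds.max_bead_fail_fraction]
    else:
        log.info("no bead-count grid supplied; bead-count filter skipped")
    removed["snp"] = vals.index[vals.index.isin(thresholds.snp_probe_list)]
    removed["multihit"] = vals.index[vals.index.isin(thresholds.multihit_probe_list)]

    drop = pd.Index([])
    for idx in removed.values():
        drop = drop.union(idx)

    rows = [{"criterion": k, "n_probes": len(v), "applied": True} for k, v in removed.items()]
    if detection_p is None:
        rows.append({"criterion": "detection_p", "n_probes": 0, "applied": False})
    if bead_counts is None:
        rows.append({"criterion": "bead_count", "n_probes": 0, "applied": False})
    rows.append({"criterion": "total_unique", "n_probes": len(drop), "applied": True})
    report = pd.DataFrame(rows)

    out = MethylationMatrix(vals.drop(index=drop), matrix.scale, dict(matrix.meta))
    return out, report


def filter_samples(
    matrix: MethylationMatrix,
    failed_probe_fraction: pd.Series,
    thresholds: QCThresholds | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove samples whose fraction of quality-failed probes exceeds threshold.

    The comparison is strictly greater-than: a sample at exactly the
    threshold is kept.
    """
    thresholds = thresholds or QCThresholds()
    frac = failed_probe_fraction.reindex(matrix.samples)
    if frac.isna().any():
        raise ValueError("failed_probe_fraction missing for some samples")
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("failed_probe_fraction values must lie in [0, 1]")
    drop = frac.index[frac > thresholds.max_sample_probe_loss]
    report = pd.DataFrame(
        {
            "criterion": ["sample_probe_loss"],
            "n_samples": [len(drop)],
            "threshold": [thresholds.max_sample_probe_loss],
        }
    )
    out = MethylationMatrix(matrix.values.drop(columns=drop), matrix.scale, dict(matrix.meta))
    return out, report


def beta_to_m(matrix: MethylationMatrix, epsilon: float = 1e-6) -> MethylationMatrix:
    """Transform beta values to M values: ``M = log2(beta / (1 - beta))``.

    Betas are clipped to ``[epsilon, 1 - epsilon]`` first so the transform
    stays finite at the boundaries.
    """
    if matrix.scale != BETA_SCALE:
        raise ScaleError("beta_to_m requires a beta-scale matrix")
    b = matrix.values.to_numpy(dtype=float)
    b = np.clip(b, epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    out = pd.DataFrame(m, index=matrix.probes, columns=matrix.samples)
    meta = dict(matrix.meta)
    meta["beta_clip_epsilon"] = epsilon
    return MethylationMatrix(out, M_SCALE, meta)


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse transform: ``beta = 2^M / (1 + 2^M)`` (logistic in base 2)."""
    if matrix.scale != M_SCALE:
        raise ScaleError("m_to_beta requires an M-scale matrix")
    m = matrix.values.to_numpy(dtype=float)
    # logistic via expit on natural scale for numerical stability
    from scipy.special import expit

    b = expit(m * np.log(2.0))
    eps = float(matrix.meta.get("beta_clip_epsilon", 1e-6))
    b = np.clip(b, eps, 1 - eps)
    out = pd.DataFrame(b, index=matrix.probes, columns=matrix.samples)
    return MethylationMatrix(out, BETA_SCALE, dict(matrix.meta))
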