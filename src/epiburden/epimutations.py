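"""Stochastic epimutation calling with interquartile-range fences.

For each CpG probe the cohort distribution of M-values defines Tukey-style
outer fences

    Lmin = Q1 - 3 * IQR        Lmax = Q3 + 3 * IQR

where Q1 and Q3 are the first and third quartiles over all samples of the
dataset (the tested sample included) and IQR = Q3 - Q1.  A probe value in a
sample strictly beyond a fence is a stochastic epimutation: hypermethylated
above Lmax, hypomethylated below Lmin.  The distance from the violated fence
is the deviation delta.  Deltas are then pooled genome-wide per direction
and each call receives an integer weight 1-4 according to which quartile of
the pooled delta distribution it falls in — larger deviations get larger
weights.

Each dataset is treated as an independent experiment: fences and delta
quartiles are computed within a dataset and never pooled across datasets.

Quantile convention: linear interpolation between order statistics at
positions ``p * (n - 1)`` (numpy's default).  The convention is recorded in
the output metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import M_SCALE, MethylationMatrix, ScaleError

log = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"
DIRECTIONS = (HYPER, HYPO)

QUANTILE_METHOD = "linear"
FENCE_MULTIPLIER = 3.0

CALL_COLUMNS = ["sample", "probe", "direction", "m_value", "delta", "rank"]


def compute_limits(
    matrix: MethylationMatrix,
    fence_multiplier: float = FENCE_MULTIPLIER,
    min_values: int = 4,
) -> pd.DataFrame:
    """Per-probe quartiles and outer fences from an M-scale matrix.

    Probes with fewer than ``min_values`` non-missing values are skipped
    with a warning.  Returns a DataFrame indexed by probe with columns
    ``q1, q3, iqr, lmin, lmax, n_values``.
    """
    if matrix.scale != M_SCALE:
        raise ScaleError("compute_limits requires an M-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    n_ok = np.sum(np.isfinite(vals), axis=1)
    keep = n_ok >= min_values
    if not keep.all():
        log.warning("%d probes skipped (< %d non-missing values)", (~keep).sum(), min_values)
    with np.errstate(invalid="ignore"):
        q1 = np.nanquantile(vals[keep], 0.25, axis=1, method=QUANTILE_METHOD)
        q3 = np.nanquantile(vals[keep], 0.75, axis=1, method=QUANTILE_METHOD)
    iqr = q3 - q1
    limits = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lmin": q1 - fence_multiplier * iqr,
            "lmax": q3 + fence_multiplier * iqr,
            "n_values": n_ok[keep],
        },
        index=matrix.probes[keep],
    )
    limits.attrs["quantile_method"] = QUANTILE_METHOD
    limits.attrs["fence_multiplier"] = fence_multiplier
    return limits


def call_epimutations(
    matrix: MethylationMatrix,
    limits: pd.DataFrame,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Call hyper/hypo epimutations for every (sample, probe) cell.

    A call requires the M-value to lie strictly beyond the fence (a value
    exactly at Lmin/Lmax is not epimutated; set ``inclusive=True`` for the
    closed-interval variant).  Values within the fences are simply not
    emitted.  Returns a long DataFrame with columns
    ``sample, probe, direction, m_value, delta, rank`` (rank unset / NaN —
    see :func:`rank_deltas`).
    """
    if matrix.scale != M_SCALE:
        raise ScaleError("call_epimutations requires an M-scale matrix")
    missing = matrix.probes.difference(limits.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} probes in the matrix have no computed limits "
            f"(e.g. {missing[0]!r})"
        )
    lim = limits.reindex(matrix.probes)
    vals = matrix.values.to_numpy(dtype=float)
    lmax = lim["lmax"].to_numpy()[:, None]
    lmin = lim["lmin"].to_numpy()[:, None]
    if inclusive:
        hyper = vals >= lmax
        hypo = vals <= lmin
    else:
        hyper = vals > lmax
        hypo = vals < lmin
    hyper &= np.isfinite(vals)
    hypo &= np.isfinite(vals)

    frames = []
    for mask, direction, fence in ((hyper, HYPER, lmax), (hypo, HYPO, lmin)):
        pi, si = np.nonzero(mask)
        if pi.size == 0:
            continue
        m = vals[pi, si]
        delta = np.abs(m - fence[pi, 0])
        frames.append(
            pd.DataFrame(
                {
                    "sample": matrix.samples[si],
                    "probe": matrix.probes[pi],
                    "direction": direction,
                    "m_value": m,
                    "delta": delta,
                    "rank": pd.array([pd.NA] * pi.size, dtype="Int64"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS).astype({"rank": "Int64"})
    calls = pd.concat(frames, ignore_index=True)
    return calls.sort_values(["sample", "probe", "direction"], ignore_index=True)


def rank_deltas(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign genome-wide quartile weights 1-4 to calls, per direction.

    Deltas are pooled over all (probe, sample) calls of the dataset within
    each direction; the pooled 25/50/75% quantiles (linear interpolation)
    split the calls into four weight classes:

        rank 1: delta <= q25        rank 2: q25 < delta <= q50
        rank 3: q50 < delta <= q75  rank 4: delta > q75

    Returns the calls with the ``rank`` column filled and a per-direction
    boundary table (``direction, q25, q50, q75, n_deltas``).
    """
    calls = calls.copy()
    bounds = []
    for direction in DIRECTIONS:
        mask = calls["direction"] == direction
        deltas = calls.loc[mask, "delta"].to_numpy(dtype=float)
        if deltas.size == 0:
            log.warning("no %smethylated calls; rank boundaries undefined", direction)
            continue
        q25, q50, q75 = np.quantile(deltas, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
        rank = 1 + (deltas > q25).astype(int) + (deltas > q50) + (deltas > q75)
        calls.loc[mask, "rank"] = rank
        bounds.append(
            {"direction": direction, "q25": q25, "q50": q50, "q75": q75, "n_deltas": deltas.size}
        )
    calls["rank"] = calls["rank"].astype("Int64")
    boundaries = pd.DataFrame(bounds, columns=["direction", "q25", "q50", "q75", "n_deltas"])
    boundaries.attrs["quantile_method"] = QUANTILE_METHOD
    return calls, boundaries


def call_and_rank(matrix: MethylationMatrix, **kwargs) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: limits -> calls -> ranked calls on one M-scale matrix."""
    limits = compute_limits(matrix)
    if len(limits) < matrix.n_probes:  # drop probes skipped for too few values
        matrix = MethylationMatrix(
            matrix.values.loc[limits.index], matrix.scale, dict(matrix.meta)
        )
    calls = call_epimutations(matrix, limits, **kwargs)
    ranked, boundaries = rank_deltas(calls)
    return ranked, limits, boundaries
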