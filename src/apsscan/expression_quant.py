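"""Relative-quantification arithmetic for qPCR, reporter and western-blot data.

Implements the 2^-ddCt method for qPCR, log2 UTR-reporter fold changes against
a UTR-less control construct, the background-subtracted plasmid-derived fold
change ``(full - control) / (cds - control)``, and phospho/total western band
ratios with per-lane minimum-profile background subtraction.

Replicate Ct values are averaged on the Ct scale before differencing (that is
geometric-mean behaviour on the expression scale).  Replicate fold changes are
summarised as the mean of per-replicate log2 folds, reported alongside every
replicate value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RelativeExpression",
    "QuantError",
    "ddct",
    "ddct_table",
    "reporter_fold_change",
    "plasmid_fold_change",
    "western_ratio",
    "phospho_fold_change",
]

DEFAULT_EFFICIENCY = 2.0


class QuantError(ValueError):
    """Raised on non-computable or invalid quantification inputs."""


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    efficiency: float


def _mean_ct(ct) -> float:
    arr = np.asarray(ct, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise QuantError("Ct values must be finite and non-empty")
    return float(arr.mean())


def ddct(
    ct_target_sample,
    ct_ref_sample,
    ct_target_control,
    ct_ref_control,
    efficiency: float = DEFAULT_EFFICIENCY,
    *,
    sample: str = "sample",
    gene: str = "target",
) -> RelativeExpression:
    """Relative expression of a target gene by the 2^-ddCt method.

    Each argument may be a scalar Ct or an array of replicate Cts (averaged on
    the Ct scale first).  ``fold = efficiency^-(dCt_sample - dCt_control)``
    with ``dCt = Ct_target - Ct_reference``; efficiency 2.0 is the canonical
    perfect-doubling assumption, overridable per primer pair.
    """
    if not (1.0 < efficiency <= 2.2):
        raise QuantError(f"amplification efficiency {efficiency} outside (1, 2.2]")
    d_sample = _mean_ct(ct_target_sample) - _mean_ct(ct_ref_sample)
    d_control = _mean_ct(ct_target_control) - _mean_ct(ct_ref_control)
    ddct_val = d_sample - d_control
    return RelativeExpression(
        sample=sample,
        gene=gene,
        delta_ct=d_sample,
        delta_delta_ct=ddct_val,
        fold_change=efficiency ** (-ddct_val),
        efficiency=efficiency,
    )


def ddct_table(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_sample: str,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Apply :func:`ddct` to a tidy Ct table.

    ``ct`` has columns (sample, condition, gene, replicate, ct).  Every sample
    must carry both the target and the reference gene; fold changes are
    relative to ``control_sample``.
    """
    required = {"sample", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise QuantError(f"Ct table missing columns: {sorted(missing)}")
    if ((ct["ct"] <= 0) | (ct["ct"] > 40)).any():
        raise QuantError("Ct values must lie in (0, 40]")

    def cts(sample: str, gene: str) -> np.ndarray:
        vals = ct.loc[(ct["sample"] == sample) & (ct["gene"] == gene), "ct"].to_numpy()
        if vals.size == 0:
            raise QuantError(f"sample {sample!r} has no Ct for gene {gene!r}")
        return vals

    ref_ctrl = cts(control_sample, reference)
    tgt_ctrl = cts(control_sample, target)
    rows = []
    for sample in ct["sample"].unique():
        rel = ddct(
            cts(sample, target), cts(sample, reference), tgt_ctrl, ref_ctrl,
            efficiency, sample=sample, gene=target,
        )
        rows.append(
            {"sample": sample, "gene": target, "delta_ct": rel.delta_ct,
             "delta_delta_ct": rel.delta_delta_ct, "fold_change": rel.fold_change}
        )
    return pd.DataFrame(rows)


def reporter_fold_change(
    utr_signal,
    control_signal,
    scale: str = "log2",
) -> dict:
    """Fold change of a UTR-reporter over the UTR-less control reporter.

    Replicates are paired positionally (same batch, same day).  Per-replicate
    ratios ``utr / control`` are reported, log2-transformed when
    ``scale="log2"``; the summary is their mean.
    """
    utr = np.asarray(utr_signal, dtype=float).ravel()
    ctrl = np.asarray(control_signal, dtype=float).ravel()
    if utr.shape != ctrl.shape:
        raise QuantError(f"unpaired replicates: {utr.size} UTR vs {ctrl.size} control")
    if np.any(ctrl <= 0):
        raise QuantError("control signal must be positive in every replicate")
    if np.any(utr < 0):
        raise QuantError("reporter signal must be non-negative")
    ratio = utr / ctrl
    if scale == "log2":
        values = np.log2(ratio)
    elif scale == "linear":
        values = ratio
    else:
        raise QuantError(f"unknown scale {scale!r} (use 'log2' or 'linear')")
    return {
        "scale": scale,
        "replicates": values.tolist(),
        "mean": float(values.mean()),
        "n": int(values.size),
    }


def plasmid_fold_change(full_measured, cds_measured, control_measured) -> dict:
    """Fold change of plasmid-derived expression: (full - ctrl) / (cds - ctrl).

    Cells transfected with the empty control plasmid express only the
    endogenous gene; subtracting that background isolates the plasmid-derived
    signal for the full-transcript and CDS-only constructs.  Replicates where
    the denominator's background-subtracted value is <= 0 are flagged
    non-computable rather than clipped, because silent clipping would bias the
    fold estimate.
    """
    full = np.asarray(full_measured, dtype=float).ravel()
    cds = np.asarray(cds_measured, dtype=float).ravel()
    ctrl = np.asarray(control_measured, dtype=float).ravel()
    if not (full.shape == cds.shape == ctrl.shape):
        raise QuantError("full, cds and control must have equal replicate counts")
    folds: list[float | None] = []
    for f, c, b in zip(full, cds, ctrl):
        denom = c - b
        if denom <= 0:
            folds.append(None)  # non-computable for this replicate
        else:
            folds.append((f - b) / denom)
    computable = [x for x in folds if x is not None]
    return {
        "replicates": folds,
        "n_non_computable": folds.count(None),
        "mean": float(np.mean(computable)) if computable else math.nan,
        "n": len(folds),
    }


def western_ratio(
    phospho_band,
    total_band,
    per_lane_background=None,
    *,
    control_lane: int = 0,
) -> np.ndarray:
    """Phospho/total band ratios, normalized so the control lane reads 1.0.

    Intensities are background subtracted per lane with the minimum-profile
    value before the ratio is taken.  A total band that vanishes after
    subtraction makes the ratio undefined and is fatal for that lane.
    """
    phospho = np.asarray(phospho_band, dtype=float).ravel()
    total = np.asarray(total_band, dtype=float).ravel()
    if phospho.shape != total.shape:
        raise QuantError("phospho and total lanes must match")
    if per_lane_background is not None:
        bg = np.asarray(per_lane_background, dtype=float).ravel()
        if bg.shape != phospho.shape:
            raise QuantError("background must be per lane")
        if np.any(bg > phospho) or np.any(bg > total):
            raise QuantError("background exceeds band signal in at least one lane")
        phospho = phospho - bg
        total = total - bg
    if np.any(total <= 0):
        bad = int(np.argmax(total <= 0))
        raise QuantError(f"total band in lane {bad} is zero after background subtraction")
    ratio = phospho / total
    if not (0 <= control_lane < ratio.size):
        raise QuantError(f"control lane {control_lane} outside [0, {ratio.size - 1}]")
    if ratio[control_lane] == 0:
        raise QuantError("control-lane ratio is zero; cannot normalize")
    return ratio / ratio[control_lane]


def phospho_fold_change(control_ratio: float, inhibitor_ratio: float) -> float:
    """Fold reduction of a phospho/total ratio: [Control] / [Inhibitor]."""
    if inhibitor_ratio <= 0:
        raise QuantError("inhibitor ratio must be positive")
    if control_ratio < 0:
        raise QuantError("control ratio must be non-negative")
    return control_ratio / inhibitor_ratio
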