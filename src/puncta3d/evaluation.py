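"""Precision/recall/F scoring of detected markers against reference annotations.

A detection is correct when it lies within a centered proximity box
(default 7x7x5: |dx|, |dy| <= 3, |dz| <= 2) of a reference center.
Matching is greedy one-to-one: the globally closest qualifying pair
(anisotropy-scaled Euclidean distance, ties by the detected marker's
(z, y, x)) is paired first, so a reference center can absorb only one
detection.  Percentages are reported to 2 decimals, half-up.

    precision = 100 * matched / detected
    recall    = 100 * matched / reference
    F         = 2 P R / (P + R)        (0 when P + R = 0)
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from puncta3d.core import MarkerSet

__all__ = ["match_markers", "precision_recall", "f_measure", "region_report", "round2"]


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as printed in detection tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def match_markers(
    detected: MarkerSet,
    reference: MarkerSet,
    box: tuple[int, int, int] = (7, 7, 5),
    z_scale: float = 1.0,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching; returns (detected_idx, reference_idx) pairs."""
    if any(b % 2 == 0 or b < 1 for b in box):
        raise ValueError(f"box dimensions must be odd: {box}")
    det = detected.coords().astype(float)
    ref = reference.coords().astype(float)
    if len(det) == 0 or len(ref) == 0:
        return []
    rx, ry, rz = (box[0] - 1) // 2, (box[1] - 1) // 2, (box[2] - 1) // 2
    cand = []
    for i in range(len(det)):
        dx = np.abs(ref[:, 0] - det[i, 0])
        dy = np.abs(ref[:, 1] - det[i, 1])
        dz = np.abs(ref[:, 2] - det[i, 2])
        ok = (dx <= rx) & (dy <= ry) & (dz <= rz)
        for j in np.nonzero(ok)[0]:
            dist = float(np.sqrt(dx[j] ** 2 + dy[j] ** 2 + (z_scale * dz[j]) ** 2))
            tie = (det[i, 2], det[i, 1], det[i, 0])  # detected (z, y, x)
            cand.append((dist, tie, i, int(j)))
    cand.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, _, i, j in cand:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return pairs


def precision_recall(n_matched: int, n_detected: int, n_reference: int) -> tuple[float, float]:
    """Percent precision and recall; 0 for empty denominators."""
    if min(n_matched, n_detected, n_reference) < 0:
        raise ValueError("counts must be nonnegative")
    p = 100.0 * n_matched / n_detected if n_detected else 0.0
    r = 100.0 * n_matched / n_reference if n_reference else 0.0
    return p, r


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of percent precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 100.0 and 0.0 <= r <= 100.0):
        raise ValueError("precision and recall must lie in [0, 100]")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass
class EvalReport:
    table: pd.DataFrame  # per-region rows + AVERAGE row, percentages to 2 d.p.

    @property
    def average(self) -> pd.Series:
        return self.table.iloc[-1]


def region_report(
    regions: Sequence[tuple[MarkerSet, MarkerSet]],
    box: tuple[int, int, int] = (7, 7, 5),
    z_scale: float = 1.0,
    region_ids: Sequence[str] | None = None,
) -> EvalReport:
    """Per-region P/R/F plus an AVERAGE row of unweighted per-region means."""
    if len(regions) == 0:
        raise ValueError("need at least one region")
    ids = list(region_ids) if region_ids is not None else [f"Region {i + 1}" for i in range(len(regions))]
    rows = []
    for rid, (det, ref) in zip(ids, regions):
        pairs = match_markers(det, ref, box=box, z_scale=z_scale)
        p, r = precision_recall(len(pairs), len(det), len(ref))
        rows.append({
            "region": rid,
            "n_reference": len(ref),
            "n_detected": len(det),
            "n_matched": len(pairs),
            "precision": round2(p),
            "recall": round2(r),
            "f_measure": round2(f_measure(p, r)),
        })
    df = pd.DataFrame(rows)
    avg = {
        "region": "AVERAGE",
        "n_reference": df["n_reference"].sum(),
        "n_detected": df["n_detected"].sum(),
        "n_matched": df["n_matched"].sum(),
        "precision": round2(df["precision"].mean()),
        "recall": round2(df["recall"].mean()),
        "f_measure": round2(df["f_measure"].mean()),
    }
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return EvalReport(table=df)
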