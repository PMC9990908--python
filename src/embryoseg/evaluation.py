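"""Dice scoring, island cleanup, volumetric phenotyping and group stats.

This is the quantitative surface of the pipeline: per-structure Dice
overlap between predicted and reference label maps, removal of small
disconnected "islands" of a label, organ volume as a percentage of
whole-body volume, and two-group Student's t comparison of those volume
fractions between a baseline and a mutant cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import LabelDictionary, LabelVolume

__all__ = [
    "DiceReport",
    "PhenotypeReport",
    "dice",
    "dice_report",
    "remove_islands",
    "volume_fraction",
    "group_ttest",
    "phenotype_compare",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _label_ids(labels: "LabelDictionary | Iterable[int]") -> list[int]:
    if isinstance(labels, LabelDictionary):
        return labels.ids
    return [int(i) for i in labels]


def dice(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of one label's binary masks.

    Two empty masks score 1.0: a structure correctly predicted absent.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ma = a.data == label
    mb = b.data == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(ma, mb).sum()) / (na + nb)


@dataclass
class DiceReport:
    """Per-label Dice scores with their mean and threshold bookkeeping."""

    per_label: dict[int, float]
    both_empty: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_label.values())))

    def n_above(self, threshold: float) -> int:
        """Number of labels whose Dice exceeds ``threshold``."""
        return sum(1 for v in self.per_label.values() if v > threshold)

    def to_frame(self, names: LabelDictionary | None = None) -> pd.DataFrame:
        rows = [
            {
                "label": lid,
                "name": names.name(lid) if names and lid in names else "",
                "dice": score,
                "both_empty": lid in self.both_empty,
            }
            for lid, score in self.per_label.items()
        ]
        return pd.DataFrame(rows)


def dice_report(
    pred: LabelVolume,
    ref: LabelVolume,
    labels: "LabelDictionary | Iterable[int]",
    exclude_absent: bool = False,
) -> DiceReport:
    """Dice per foreground label, plus the mean over evaluated labels.

    With ``exclude_absent`` labels empty in both volumes are dropped from
    the report instead of scoring the empty-empty convention of 1.0.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    per: dict[int, float] = {}
    both_empty: list[int] = []
    for lid in _label_ids(labels):
        if lid == 0:
            continue
        empty = not (pred.data == lid).any() and not (ref.data == lid).any()
        if empty:
            if exclude_absent:
                continue
            both_empty.append(lid)
        per[lid] = dice(pred, ref, lid)
    if not per:
        raise ValueError("no labels evaluated")
    return DiceReport(per, both_empty)


def remove_islands(
    seg: LabelVolume, mode: str = "keep_largest", min_size: int = 0
) -> LabelVolume:
    """Remove disconnected components ("islands") of each foreground label.

    Components are 26-connected.  ``keep_largest`` retains only the
    largest component per label (ties broken toward the component holding
    the lowest linear voxel index); ``min_size`` removes components with
    fewer than ``min_size`` voxels.  Removed voxels become background.
    """
    if mode not in ("keep_largest", "min_size"):
        raise ValueError("mode must be 'keep_largest' or 'min_size'")
    out = seg.data.copy()
    for lid in seg.ids():
        mask = seg.data == lid
        comps, n = ndimage.label(mask, structure=_CONN26)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=range(1, n + 1))
        if mode == "keep_largest":
            best = int(np.argmax(sizes)) + 1
            top = np.flatnonzero(sizes == sizes[best - 1]) + 1
            if len(top) > 1:
                flat = comps.reshape(-1)
                firsts = {
                    c: int(np.flatnonzero(flat == c)[0]) for c in top
                }
                best = min(firsts, key=firsts.get)
            out[mask & (comps != best)] = 0
        else:
            drop = np.flatnonzero(sizes < min_size) + 1
            if drop.size:
                out[mask & np.isin(comps, drop)] = 0
    return LabelVolume(out, seg.spacing.copy(), seg.origin.copy())


def volume_fraction(
    seg: LabelVolume, label: int, body_label: int | None = None
) -> float:
    """Volume of ``label`` as a percentage of whole-body volume.

    Whole-body volume defaults to the union of all foreground labels
    (atlas labels tile the body); pass ``body_label`` to use one explicit
    body-mask label as the denominator instead.
    """
    n_label = int((seg.data == label).sum())
    if body_label is None:
        n_body = int((seg.data != 0).sum())
    else:
        n_body = int((seg.data == body_label).sum())
    if n_body == 0:
        raise ValueError("whole-body volume is zero")
    return 100.0 * n_label / n_body


def group_ttest(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    Returns (t, p, significant) with significant ⇔ p < alpha.  Zero
    pooled variance with equal means gives (0, 1, False) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, False
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0, 0.0 < alpha
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), bool(p < alpha)


@dataclass
class PhenotypeReport:
    """Volume fractions per specimen and two-group test results per label."""

    fractions: pd.DataFrame   # columns: group, specimen, label, fraction_pct
    stats: pd.DataFrame       # columns: label, mean_a, mean_b, t, p, significant
    alpha: float

    def significant_labels(self) -> list[int]:
        return [int(r.label) for r in self.stats.itertuples() if r.significant]

    def to_csv(self, path: str | Path) -> None:
        self.stats.to_csv(path, index=False, float_format="%.6g")


def phenotype_compare(
    group_a: Sequence[LabelVolume],
    group_b: Sequence[LabelVolume],
    labels: "LabelDictionary | Iterable[int]",
    alpha: float = 0.05,
    body_label: int | None = None,
    holm: bool = False,
) -> PhenotypeReport:
    """Compare per-organ volume fractions between two cohorts.

    For every specimen and label the volume fraction (% of whole-body
    volume) is computed, then a per-label Student's t-test between the
    groups at threshold ``alpha``.  No multiple-testing correction is
    applied by default (per-label reporting); ``holm=True`` enables a
    Holm step-down correction of the significance calls.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ids = [lid for lid in _label_ids(labels) if lid != 0]
    rows = []
    for gname, group in (("A", group_a), ("B", group_b)):
        for si, seg in enumerate(group):
            for lid in ids:
                rows.append(
                    {
                        "group": gname,
                        "specimen": si,
                        "label": lid,
                        "fraction_pct": volume_fraction(seg, lid, body_label),
                    }
                )
    fractions = pd.DataFrame(rows)
    stat_rows = []
    for lid in ids:
        fa = fractions.query("group == 'A' and label == @lid")["fraction_pct"].to_numpy()
        fb = fractions.query("group == 'B' and label == @lid")["fraction_pct"].to_numpy()
        t, p, sig = group_ttest(fa, fb, alpha)
        stat_rows.append(
            {
                "label": lid,
                "mean_a": float(fa.mean()),
                "mean_b": float(fb.mean()),
                "t": t,
                "p": p,
                "significant": sig,
            }
        )
    st = pd.DataFrame(stat_rows)
    if holm:
        order = np.argsort(st["p"].to_numpy())
        m = len(st)
        sig = np.zeros(m, dtype=bool)
        for rank, idx in enumerate(order):
            if st["p"].iloc[idx] < alpha / (m - rank):
                sig[idx] = True
            else:
                break
        st["significant"] = sig
    return PhenotypeReport(fractions, st, alpha)
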