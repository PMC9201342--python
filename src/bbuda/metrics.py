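"""Region composition, Dice and Hausdorff metrics, and evaluation reports.

Regions follow the brain-tumor convention: class 1 is CoreT (necrotic /
non-enhancing core), class 2 EnhT (enhancing tumor), class 3 ED (peritumoral
edema), and WholeT is their union.

Two Hausdorff variants are provided because the two common definitions
disagree: ``average`` symmetrizes the two directed mean boundary distances,
``max`` is the classical maximum of directed maxima.  ``max`` is the default
in reports.  Distances are Euclidean on a pixel-centered (row, col) grid
scaled by ``spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

REGION_CLASSES = {"CoreT": (1,), "EnhT": (2,), "ED": (3,), "WholeT": (1, 2, 3)}
REPORT_REGIONS = ("WholeT", "EnhT", "CoreT")

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def compose_regions(label: np.ndarray) -> dict[str, np.ndarray]:
    """Binary masks for CoreT, EnhT, ED and their union WholeT."""
    label = np.asarray(label)
    return {
        name: np.isin(label, classes)
        for name, classes in REGION_CLASSES.items()
    }


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); both-empty -> 1, one-empty -> 0."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    a, b = int(pred.sum()), int(truth.sum())
    if a == 0 and b == 0:
        return 1.0
    if a == 0 or b == 0:
        return 0.0
    inter = int(np.logical_and(pred, truth).sum())
    return 2.0 * inter / (a + b)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of mask pixels with a background 4-neighbor.

    The image border counts as background, so regions touching the edge
    still have a boundary there.
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(
    pred: np.ndarray,
    truth: np.ndarray,
    variant: str = "max",
    spacing: float = 1.0,
) -> float:
    """Boundary Hausdorff distance between two masks.

    ``max``: max of the two directed maximum distances.  ``average``: mean
    of the two directed average distances.  Both masks empty -> 0.0; exactly
    one empty -> NaN (undefined sentinel).
    """
    if variant not in ("max", "average"):
        raise ValueError("variant must be 'max' or 'average'")
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    pa = boundary_pixels(pred)
    pb = boundary_pixels(truth)
    if len(pa) == 0 and len(pb) == 0:
        return 0.0
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    d = cdist(pa.astype(float), pb.astype(float)) * spacing
    a_to_b = d.min(axis=1)
    b_to_a = d.min(axis=0)
    if variant == "max":
        return float(max(a_to_b.max(), b_to_a.max()))
    return float((a_to_b.mean() + b_to_a.mean()) / 2.0)


@dataclass
class MetricsReport:
    """Per-region mean DSC/HD over an evaluation set, with per-case table."""

    per_case: pd.DataFrame
    spacing: float
    hd_variant: str

    @property
    def n_cases(self) -> int:
        return self.per_case["case"].nunique()

    def summary(self) -> dict:
        out = {}
        for region in REPORT_REGIONS:
            sub = self.per_case[self.per_case["region"] == region]
            hd_vals = sub["hd"].dropna()
            out[region] = {
                "dsc_mean": float(sub["dsc"].mean()),
                "hd_mean": float(hd_vals.mean()) if len(hd_vals) else float("nan"),
                "n_cases": int(len(sub)),
                "n_hd_excluded": int(sub["hd"].isna().sum()),
                "n_both_empty": int(sub["both_empty"].sum()),
            }
        return out

    def format_table(self, method: str = "") -> str:
        s = self.summary()
        head = (f"{'Method':<16}" +
                "".join(f"DSC[%] {r:<9}" for r in REPORT_REGIONS) +
                "".join(f"HD {r:<11}" for r in REPORT_REGIONS))
        row = f"{method:<16}"
        for r in REPORT_REGIONS:
            row += f"{100 * s[r]['dsc_mean']:<16.2f}"
        for r in REPORT_REGIONS:
            row += f"{s[r]['hd_mean']:<14.2f}"
        return head + "\n" + row

    def save(self, out_dir: str | Path, name: str = "metrics") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(out / f"{name}_per_case.csv", index=False)
        payload = {
            "spacing": self.spacing,
            "hd_variant": self.hd_variant,
            "summary": _nan_to_none(self.summary()),
        }
        (out / f"{name}_summary.json").write_text(json.dumps(payload, indent=2))


def _nan_to_none(obj):
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def evaluate_predictions(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    spacing: float = 1.0,
    hd_variant: str = "max",
) -> MetricsReport:
    """Per-case, per-region DSC and HD from hard label maps.

    Cases where a region is absent from both prediction and truth score
    DSC = 1 and are excluded from the HD mean (the exclusion is counted).
    """
    if len(pred_labels) != len(truth_labels):
        raise ValueError("prediction and truth case counts differ")
    if len(pred_labels) == 0:
        raise ValueError("empty evaluation set")
    rows = []
    for i, (pl, tl) in enumerate(zip(pred_labels, truth_labels)):
        pred_masks = compose_regions(pl)
        truth_masks = compose_regions(tl)
        for region in REGION_CLASSES:
            pm, tm = pred_masks[region], truth_masks[region]
            both_empty = not pm.any() and not tm.any()
            hd = float("nan") if both_empty else hausdorff(
                pm, tm, variant=hd_variant, spacing=spacing
            )
            rows.append({
                "case": i,
                "region": region,
                "dsc": dice(pm, tm),
                "hd": hd,
                "both_empty": both_empty,
            })
    return MetricsReport(pd.DataFrame(rows), spacing=spacing, hd_variant=hd_variant)


def evaluate(
    net,
    images: np.ndarray,
    labels: np.ndarray,
    spacing: float = 1.0,
    hd_variant: str = "max",
    batch_size: int = 8,
) -> MetricsReport:
    """Evaluate a network: hard-argmax predictions -> per-region DSC/HD."""
    from .backbones import predict_probs

    probs = predict_probs(net, images, batch_size=batch_size)
    pred_labels = probs.argmax(axis=1)
    return evaluate_predictions(pred_labels, labels, spacing=spacing,
                                hd_variant=hd_variant)


def mean_region_dsc(report: MetricsReport, region: str = "WholeT") -> float:
    sub = report.per_case[report.per_case["region"] == region]
    return float(sub["dsc"].mean())
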