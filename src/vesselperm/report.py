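"""Aggregation: run manifests, group summaries, blockade tables, area ratio."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import filters, measure

from ._morph import drop_small

from .leakage import THEORETICAL_BASELINE, blockade_percent

__all__ = ["RunManifest", "area_ratio", "summarize"]


@dataclass
class RunManifest:
    """Traceability record for one analysis run."""

    inputs: dict = field(default_factory=dict)  # path -> sha256
    config: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    software_version: str = ""

    def add_input(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "inputs": self.inputs,
                    "config": self.config,
                    "seeds": self.seeds,
                    "qc": self.qc,
                    "software_version": self.software_version,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def area_ratio(
    image: np.ndarray,
    min_object_size: int = 64,
    tissue_threshold: str | float = "multiotsu",
) -> float:
    """Endothelium / tailfin area ratio from a tracer still.

    Endothelium: largest connected component above the bright (Otsu)
    threshold, after small-object removal. Tailfin: all supra-background
    tissue. The default splits the histogram into background / tissue /
    vessel with a 3-class Otsu; the tissue definition is configurable
    (``"otsu"`` for a single threshold, or a numeric cutoff) since the
    original script's choice is not documented.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("empty image: no foreground to measure")

    if tissue_threshold == "multiotsu":
        # log scale keeps the dim tissue mode resolvable next to the bright
        # vessel mode under the fixed histogram binning
        log_img = np.log1p(img - img.min())
        try:
            lo, hi = filters.threshold_multiotsu(log_img, classes=3)
            t_low, t_high = np.expm1([lo, hi]) + img.min()
        except ValueError:  # fewer than 3 grey levels: single split
            t_low = t_high = filters.threshold_otsu(img)
    elif tissue_threshold == "otsu":
        t_low = t_high = filters.threshold_otsu(img)
    else:
        t_low = float(tissue_threshold)
        t_high = filters.threshold_otsu(img[img > t_low]) if (img > t_low).any() else t_low

    vessel_mask = img > t_high
    vessel_mask = drop_small(vessel_mask, min_object_size)
    if not vessel_mask.any():
        raise ValueError("no endothelial foreground after filtering")
    labels = measure.label(vessel_mask)
    sizes = np.bincount(labels.ravel())[1:]
    endothelium_area = int(sizes.max())

    tissue_area = int((img > t_low).sum())
    if tissue_area == 0:
        raise ValueError("no tissue foreground")
    return endothelium_area / tissue_area


def summarize(
    metrics: pd.DataFrame,
    group_column: str = "group",
    control_group: str | None = None,
    leakage_column: str = "iv_tot_norm",
    baseline: float = THEORETICAL_BASELINE,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-group descriptive summaries and (optionally) a blockade table.

    ``metrics`` is tidy: one row per scene/larva with a group label and
    numeric metric columns. SDs use the n-1 denominator; single-member
    groups report SD as missing. The blockade table compares each group's
    mean integrated leakage against ``control_group`` using the theoretical
    no-leakage baseline.
    """
    if metrics.empty:
        raise ValueError("no rows to summarize")
    numeric = metrics.select_dtypes(include=[np.number]).columns
    rows = []
    for group, sub in metrics.groupby(group_column, sort=False):
        row: dict = {"group": group, "n": len(sub)}
        for col in numeric:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)

    blockade = None
    if control_group is not None:
        if control_group not in set(metrics[group_column]):
            raise ValueError(f"control group {control_group!r} not present")
        control_mean = float(
            metrics.loc[metrics[group_column] == control_group, leakage_column].mean()
        )
        b_rows = []
        for group, sub in metrics.groupby(group_column, sort=False):
            if group == control_group:
                continue
            treated_mean = float(sub[leakage_column].mean())
            b_rows.append(
                {
                    "group": group,
                    "control": control_group,
                    "blockade_percent": blockade_percent(
                        treated_mean, control_mean, baseline=baseline
                    ),
                }
            )
        blockade = pd.DataFrame(b_rows)
    return summary, blockade
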