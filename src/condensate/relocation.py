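"""Site classification by intensity fold change and the relocation rate.

Genomic sites (0-based half-open intervals) carrying an activity mark at two
time points are classified by the pseudocounted ratio
``r = (t8 + pc) / (t0 + pc)`` into ``up`` (r > threshold), ``down``
(r < 1/threshold) and ``permanent`` (in between). A chromatin factor's
relocation rate is the ratio of its mean binding intensity at up sites to
that at down sites: values above 1 mean the factor follows the gained sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SiteClasses", "RelocationResult", "classify_sites", "relocation_rate"]

CLASS_LABELS = ("up", "permanent", "down")


@dataclass(frozen=True)
class SiteClasses:
    """Exhaustive, exclusive per-site labels plus the threshold used."""

    labels: pd.Series  # values in CLASS_LABELS, aligned with the site table
    fc_threshold: float


@dataclass(frozen=True)
class RelocationResult:
    factor: str
    mean_up: float
    mean_down: float
    rate: float


def classify_sites(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    *,
    pseudocount: float = 1.0,
    t0_column: str = "intensity_t0",
    t8_column: str = "intensity_t8",
) -> SiteClasses:
    """Label each site up/permanent/down by pseudocounted fold change."""
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    t0 = table[t0_column].to_numpy(dtype=float)
    t8 = table[t8_column].to_numpy(dtype=float)
    if np.any(t0 < 0) or np.any(t8 < 0) or not (np.isfinite(t0).all() and np.isfinite(t8).all()):
        raise ValueError("intensities must be finite and non-negative")
    ratio = (t8 + pseudocount) / (t0 + pseudocount)
    labels = np.select(
        [ratio > fc_threshold, ratio < 1.0 / fc_threshold], ["up", "down"], "permanent"
    )
    return SiteClasses(
        labels=pd.Series(labels, index=table.index, name="site_class"),
        fc_threshold=float(fc_threshold),
    )


def relocation_rate(
    table: pd.DataFrame, classes: SiteClasses, factor_column: str
) -> RelocationResult:
    """Mean factor intensity at up sites over that at down sites."""
    if factor_column not in table.columns:
        raise KeyError(f"factor column {factor_column!r} not in the site table")
    values = table[factor_column].to_numpy(dtype=float)
    labels = classes.labels.to_numpy()
    means = {}
    for cls in ("up", "down"):
        sel = labels == cls
        if not sel.any():
            raise ValueError(f"no sites in class {cls!r}; relocation rate undefined")
        means[cls] = float(values[sel].mean())
    if means["down"] == 0:
        raise ZeroDivisionError("mean intensity of down sites is 0; rate undefined")
    return RelocationResult(
        factor=factor_column,
        mean_up=means["up"],
        mean_down=means["down"],
        rate=means["up"] / means["down"],
    )
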