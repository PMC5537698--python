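"""ΔΔCt relative quantification and group/correlation statistics.

Quantifies DNA copy number or transcript abundance from qPCR cycle
thresholds: replicate Cts are averaged per (sample, assay); the target's
mean Ct is normalized against the mean of the reference assays (ΔCt);
each sample's ΔCt is then referenced to the mean ΔCt of the calibrator
group (ΔΔCt); the reported log2 ratio is −ΔΔCt, i.e. a one-cycle earlier
target crossing corresponds to a doubling, assuming 100% amplification
efficiency. For DNA, a log2 ratio of −1 against a diploid calibrator is a
single-copy (heterozygous) loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import fmean
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

GROUPS = ("tumour", "control")
CT_COLUMNS = ["sample", "group", "assay", "replicate", "ct"]


class CtTable:
    """Validated long-format qPCR table: one row per replicate well."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"Ct table is missing required column(s): {', '.join(missing)}")
        frame = frame[CT_COLUMNS].copy()
        ct = pd.to_numeric(frame["ct"], errors="coerce")
        bad = frame.index[ct.isna() | (ct <= 0)]
        if len(bad):
            raise ValueError(
                f"non-numeric or non-positive Ct value at row(s): "
                f"{', '.join(str(i) for i in bad[:10])}"
            )
        frame["ct"] = ct.astype(float)
        unknown = set(frame["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s) {sorted(unknown)}; expected {GROUPS}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def assays(self) -> list[str]:
        return sorted(self.frame["assay"].unique())

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct per (sample, group, assay)."""
        return (
            self.frame.groupby(["sample", "group", "assay"], as_index=False)["ct"]
            .mean()
        )


@dataclass(frozen=True)
class CopyNumberCall:
    """Per-sample relative quantity for one target assay."""

    sample_id: str
    group: str
    assay: str
    delta_ct: float
    log2_ratio: float


def delta_delta_ct(
    table: CtTable,
    target: str,
    references: Sequence[str],
    calibrator_group: Literal["tumour", "control"] = "control",
    reference_average: Literal["arithmetic", "geometric"] = "arithmetic",
) -> list[CopyNumberCall]:
    """Per-sample log2 ratio of a target assay by the ΔΔCt method.

    ΔCt(sample) = mean Ct(target) − mean over reference assays of their
    replicate-mean Ct; ΔΔCt = ΔCt(sample) − mean ΔCt over the calibrator
    group; log2_ratio = −ΔΔCt. Samples lacking the target or any reference
    assay are skipped with a warning (their normalization is undefined).

    ``reference_average`` sets how reference Cts are combined: "arithmetic"
    (default; on the Ct scale this already corresponds to the geometric
    mean of reference template quantities) or "geometric" (geometric mean
    of the Ct values themselves). With a single reference they coincide.
    """
    if not references:
        raise ValueError("at least one reference assay is required")
    if reference_average not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown reference_average {reference_average!r}")
    present = set(table.frame["assay"])
    missing = [a for a in [target, *references] if a not in present]
    if missing:
        raise ValueError(f"assay(s) not present in the Ct table: {', '.join(missing)}")

    means = table.mean_ct()
    wide = means.pivot_table(index=["sample", "group"], columns="assay", values="ct")

    delta: dict[tuple[str, str], float] = {}
    for (sample, group), row in wide.iterrows():
        needed = [target, *references]
        if any(pd.isna(row.get(a)) for a in needed):
            logger.warning("sample %s skipped: missing target or reference assay", sample)
            continue
        ref_cts = [row[a] for a in references]
        if reference_average == "geometric":
            ref = float(sps.gmean(ref_cts))
        else:
            ref = fmean(ref_cts)
        delta[(sample, group)] = row[target] - ref

    calib = [d for (_, g), d in delta.items() if g == calibrator_group]
    if not calib:
        raise ValueError(f"calibrator group {calibrator_group!r} has no usable samples")
    calib_mean = fmean(calib)

    return [
        CopyNumberCall(
            sample_id=sample,
            group=group,
            assay=target,
            delta_ct=d,
            log2_ratio=-(d - calib_mean),
        )
        for (sample, group), d in sorted(delta.items())
    ]


def group_compare(
    calls: Sequence[CopyNumberCall],
    groups: tuple[str, str] = ("tumour", "control"),
) -> dict:
    """Two-sided unpaired Student's t-test between two groups of calls."""
    a = [c.log2_ratio for c in calls if c.group == groups[0]]
    b = [c.log2_ratio for c in calls if c.group == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations for the t-test")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return {
        "groups": list(groups),
        "n": [len(a), len(b)],
        "mean_log2_ratio": [fmean(a), fmean(b)],
        "t": float(t),
        "p": float(p),
    }


def correlate(
    x: Sequence[float | None], y: Sequence[float | None]
) -> tuple[float | None, float | None]:
    """Pearson correlation with two-sided p; pairs with any null dropped.

    Returns (None, None) when fewer than 3 complete pairs remain or when
    either vector is constant (the coefficient is undefined there).
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    pairs = [
        (a, b) for a, b in zip(x, y)
        if a is not None and b is not None
        and math.isfinite(a) and math.isfinite(b)
    ]
    if len(pairs) < 3:
        raise ValueError("correlation requires >= 3 complete pairs")
    xa = np.array([p[0] for p in pairs])
    ya = np.array([p[1] for p in pairs])
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None, None
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)
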