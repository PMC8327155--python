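"""Read-depth gene copy-number estimation.

The diploid copy number of a duplicated gene (the motivating case is the
canine pancreatic amylase gene AMY2B) is estimated from the ratio of reads
mapping to the target region to reads mapping to target plus control
regions.  Ratios carry Wilson binomial confidence intervals, and are
converted to copy numbers by anchoring a calibration group of known copy
number (wolves, diploid CN = 2): the scaling factor maps the anchor group's
*mean* ratio onto the anchor copy number, so the anchor-group mean estimate
is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RegionCounts",
    "CopyNumberEstimate",
    "read_ratio",
    "ratio_confidence",
    "scale_to_copies",
    "estimate_copy_numbers",
    "read_region_counts",
    "write_region_counts",
]


@dataclass(frozen=True)
class RegionCounts:
    """Mapped read counts for one host: target gene region vs. control."""

    host_id: str
    group: str
    target_reads: int
    control_reads: int
    target_length: int = 1
    control_length: int = 1

    def __post_init__(self):
        if self.target_reads < 0 or self.control_reads < 0:
            raise ValueError(f"{self.host_id}: read counts must be >= 0")
        if self.target_length <= 0 or self.control_length <= 0:
            raise ValueError(f"{self.host_id}: region lengths must be > 0")


@dataclass(frozen=True)
class CopyNumberEstimate:
    host_id: str
    group: str
    ratio: float
    ratio_ci: tuple[float, float]
    copy_number: float
    copy_number_ci: tuple[float, float]


def read_ratio(counts: RegionCounts, length_correct: bool = False) -> float:
    """target / (target + control) read-count ratio.

    With ``length_correct=True`` the counts are first divided by their
    effective region lengths (useful when target and control lengths
    differ; off by default, matching the raw-ratio convention).
    """
    t, c = float(counts.target_reads), float(counts.control_reads)
    if length_correct:
        t /= counts.target_length
        c /= counts.control_length
    total = t + c
    if total == 0:
        raise ValueError(f"{counts.host_id}: no reads in target or control")
    return t / total


def ratio_confidence(counts: RegionCounts, level: float = 0.95,
                     ) -> tuple[float, float]:
    """Wilson score interval for the target read proportion."""
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    n = counts.target_reads + counts.control_reads
    if n == 0:
        raise ValueError(f"{counts.host_id}: no reads in target or control")
    lo, hi = proportion_confint(counts.target_reads, n,
                                alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def scale_to_copies(counts: list[RegionCounts], anchor_group: str = "wolf",
                    anchor_copy_number: float = 2.0, level: float = 0.95,
                    convention: str = "mean-ratio",
                    linearize: bool = True) -> list[CopyNumberEstimate]:
    """Convert read ratios to diploid copy numbers via an anchor group.

    With ``linearize=True`` (default) the ratio r = t/(t+c) is first mapped
    to the target:control odds r/(1-r), which is exactly proportional to
    copy number under Poisson read sampling (t ~ CN, c ~ 2, so
    t/c = CN x const); the scaling factor then converts odds to copies.
    ``linearize=False`` scales the raw ratio itself — the literal
    convention, adequate only while target reads are a small fraction of
    the total (it saturates at high copy number).

    ``convention="mean-ratio"`` (default): one factor
    s = anchor_CN / mean(anchor values); the anchor group's mean copy
    number then equals the anchor value exactly.
    ``convention="mean-factor"``: s = mean over anchor hosts of
    anchor_CN / value_h (the alternative reading of "mean scaling factor").
    Confidence intervals are transformed and scaled the same way; in the
    linearised mode the calibration uncertainty of the anchor factor
    (delta-method Poisson variance of the anchor mean odds) is additionally
    propagated into each host's copy-number interval on the log scale —
    without it the intervals undercover whenever the anchor group is small.
    """
    if convention not in ("mean-ratio", "mean-factor"):
        raise ValueError(f"unknown convention {convention!r}")
    anchors = [c for c in counts if c.group == anchor_group]
    if not anchors:
        raise ValueError(f"no hosts in anchor group {anchor_group!r}")

    def g(r):
        if not linearize:
            return r
        with np.errstate(divide="ignore"):
            return np.where(np.asarray(r) < 1, np.asarray(r) / (1 - np.asarray(r)),
                            np.inf)[()]

    ratios = {c.host_id: read_ratio(c) for c in counts}
    anchor_vals = np.array([g(ratios[c.host_id]) for c in anchors])
    if not np.isfinite(anchor_vals).all():
        raise ValueError("anchor host with ratio 1 (no control reads)")
    if convention == "mean-ratio":
        if anchor_vals.mean() == 0:
            raise ValueError("anchor-group mean ratio is zero")
        s = anchor_copy_number / anchor_vals.mean()
    else:
        if (anchor_vals == 0).any():
            raise ValueError("anchor host with zero ratio")
        s = float(np.mean(anchor_copy_number / anchor_vals))
    # relative variance of the anchor mean odds (delta method, Poisson
    # counts); zero when not linearising (literal mode scales CIs only)
    relvar_s = 0.0
    if linearize:
        terms = [1 / max(c.target_reads, 1) + 1 / max(c.control_reads, 1)
                 for c in anchors]
        relvar_s = float(np.sum(terms)) / len(anchors) ** 2
    z = norm.ppf(0.5 + level / 2)

    out = []
    for c in counts:
        lo, hi = ratio_confidence(c, level=level)
        cn = float(s * g(ratios[c.host_id]))
        cn_lo, cn_hi = float(s * g(lo)), float(s * g(hi))
        if linearize and relvar_s > 0 and cn_lo > 0 and np.isfinite(cn_hi):
            half = np.sqrt((np.log(cn_hi / cn_lo) / 2) ** 2
                           + (z * np.sqrt(relvar_s)) ** 2)
            mid = np.sqrt(cn_lo * cn_hi)
            cn_lo, cn_hi = float(mid * np.exp(-half)), float(mid * np.exp(half))
        out.append(CopyNumberEstimate(
            host_id=c.host_id, group=c.group, ratio=ratios[c.host_id],
            ratio_ci=(lo, hi), copy_number=cn,
            copy_number_ci=(cn_lo, cn_hi)))
    return out


def estimate_copy_numbers(counts: list[RegionCounts], **kwargs) -> pd.DataFrame:
    """Tabular convenience wrapper over :func:`scale_to_copies`."""
    ests = scale_to_copies(counts, **kwargs)
    return pd.DataFrame([{
        "host": e.host_id, "group": e.group, "ratio": e.ratio,
        "ratio_lo": e.ratio_ci[0], "ratio_hi": e.ratio_ci[1],
        "copy_number": e.copy_number,
        "cn_lo": e.copy_number_ci[0], "cn_hi": e.copy_number_ci[1],
    } for e in ests])


def write_region_counts(counts: list[RegionCounts], path) -> None:
    pd.DataFrame([c.__dict__ for c in counts]).to_csv(path, sep="\t",
                                                      index=False)


def read_region_counts(path) -> list[RegionCounts]:
    df = pd.read_csv(path, sep="\t")
    return [RegionCounts(host_id=str(r.host_id), group=str(r.group),
                         target_reads=int(r.target_reads),
                         control_reads=int(r.control_reads),
                         target_length=int(r.target_length),
                         control_length=int(r.control_length))
            for r in df.itertuples()]
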