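"""Cohort statistics: AD vs control comparison of lobe tortuosities.

Bundles a verbatim transcription of the published per-subject tau3d values
for the four brain lobes of 60 MIRIAD subjects (37 Alzheimer's disease, 23
control) and reproduces the group comparison: a Wilcoxon rank-sum
(Mann-Whitney) test per lobe, with midranks for ties, tie-corrected variance,
normal approximation and no continuity correction, plus medians and standard
deviations per diagnosis group.  The z statistic is signed so that positive
values mean the control group ranks higher.

The same tests are exposed for user-computed two-group tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("frontal", "occipital", "parietal", "temporal")

_TABLE1_SHA256 = "3c3ca5f672c5dd4adfb5c0a3d4532ee1eb381d4824b981242e1398bf1380ad87"


@dataclass
class RankSumResult:
    """Wilcoxon rank-sum outcome: z (positive = group B larger), two-sided p."""

    z: float
    p: float
    n_a: int
    n_b: int


@dataclass
class RegionSummary:
    region: str
    median_a: float
    std_a: float
    median_b: float
    std_b: float

    @property
    def rounded_medians(self) -> tuple[int, int]:
        return int(round(self.median_a)), int(round(self.median_b))


def load_table1() -> pd.DataFrame:
    """The bundled 60-subject lobe-tortuosity table, checksum-verified.

    Columns: id, diagnosis (AD/Control), frontal, occipital, parietal,
    temporal — following the published table's column headers verbatim.
    """
    ref = resources.files("tau3d").joinpath("data/miriad_table1.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(f"bundled cohort table is corrupted (sha256 {digest})")
    df = pd.read_csv(ref.open("r"))
    assert len(df) == 60 and set(df.diagnosis) == {"AD", "Control"}
    return df


def load_cohort(path: str | Path) -> pd.DataFrame:
    """A user-supplied cohort CSV with the same schema as the bundled table."""
    df = pd.read_csv(path)
    missing = {"diagnosis"}.difference(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    return df


def rank_sum_test(group_a, group_b) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) z and two-sided p.

    Midranks for ties, tie-corrected variance, normal approximation without
    continuity correction.  z > 0 means ``group_b`` is stochastically larger.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test needs two nonempty groups")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_b = ranks[n_a:].sum() - n_b * (n_b + 1) / 2.0
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all pooled values identical: no evidence either way
        return RankSumResult(z=0.0, p=1.0, n_a=n_a, n_b=n_b)
    z = (u_b - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(z=float(z), p=float(min(p, 1.0)), n_a=n_a, n_b=n_b)


def region_medians(table: pd.DataFrame, region: str) -> RegionSummary:
    """Median and sample (n-1) standard deviation per diagnosis group."""
    if region not in table.columns:
        raise KeyError(f"region {region!r} not in table")
    ad = table.loc[table.diagnosis == "AD", region].to_numpy(dtype=float)
    co = table.loc[table.diagnosis == "Control", region].to_numpy(dtype=float)
    if ad.size == 0 or co.size == 0:
        raise ValueError("cohort must contain both AD and Control subjects")

    def _std(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return RegionSummary(
        region=region,
        median_a=float(np.median(ad)),
        std_a=_std(ad),
        median_b=float(np.median(co)),
        std_b=_std(co),
    )


def cohort_report(table: pd.DataFrame, regions=REGIONS) -> pd.DataFrame:
    """Rank-sum z/p and group medians/stds for every region column.

    One row per region: z is positive when control values rank higher, the
    reported medians are both raw and integer-rounded (the publication's
    reporting style).
    """
    groups = set(table.diagnosis)
    if groups != {"AD", "Control"}:
        raise ValueError(f"cohort must contain exactly the groups AD and Control, got {sorted(groups)}")
    rows = []
    for region in regions:
        ad = table.loc[table.diagnosis == "AD", region].to_numpy(dtype=float)
        co = table.loc[table.diagnosis == "Control", region].to_numpy(dtype=float)
        rs = rank_sum_test(ad, co)
        ms = region_medians(table, region)
        rows.append({
            "region": region,
            "z": rs.z,
            "p": rs.p,
            "n_AD": rs.n_a,
            "n_Control": rs.n_b,
            "median_AD": ms.median_a,
            "median_AD_rounded": ms.rounded_medians[0],
            "std_AD": ms.std_a,
            "median_Control": ms.median_b,
            "median_Control_rounded": ms.rounded_medians[1],
            "std_Control": ms.std_b,
        })
    return pd.DataFrame(rows)
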