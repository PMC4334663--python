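"""Rank-correlation statistics linking dipole moments to myelin estimates.

The omnibus statistic is the sum of the 3 maps x 6 ROIs Spearman
correlations between per-hemisphere dipole moments and ROI myelin
estimates; its null distribution is obtained by permuting hemisphere
labels (equivalently, shuffling the moment column against the myelin
rows).  Per-map repeated-measures ANOVAs with Bonferroni-corrected
post-hoc paired t-tests compare myelination between ROIs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .reference import MAP_TYPES, ROI_LABELS


class StatsError(ValueError):
    pass


class DegenerateRanksError(StatsError):
    """A variable has zero rank variance, so Spearman's r is undefined."""


@dataclass
class HemisphereRecord:
    """One hemisphere: dipole-moment magnitude plus myelin per (map, ROI)."""

    hemisphere_id: str
    moment_nAm: float
    myelin: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.moment_nAm < 0:
            raise StatsError("dipole-moment magnitude must be non-negative")


def records_to_frame(records: list[HemisphereRecord]) -> pd.DataFrame:
    """Wide table: one row per hemisphere, columns ``<map>_<roi>``."""
    keys = sorted(records[0].myelin)
    for rec in records:
        if sorted(rec.myelin) != keys:
            raise StatsError("all records must share the same (map, ROI) keys")
    rows = []
    for rec in records:
        row = {"hemisphere_id": rec.hemisphere_id, "moment_nAm": rec.moment_nAm}
        row.update({f"{m}_{r}": v for (m, r), v in rec.myelin.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[HemisphereRecord]:
    recs = []
    value_cols = [c for c in frame.columns if c not in ("hemisphere_id", "moment_nAm")]
    for _, row in frame.iterrows():
        myelin = {}
        for col in value_cols:
            m, r = col.split("_", 1)
            myelin[(m, r)] = float(row[col])
        recs.append(
            HemisphereRecord(str(row["hemisphere_id"]), float(row["moment_nAm"]), myelin)
        )
    return recs


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StatsError("x and y must be equal-length 1-d arrays of length >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    for name, r in (("x", rx), ("y", ry)):
        if np.ptp(r) == 0:
            raise DegenerateRanksError(f"variable {name} has zero rank variance")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass
class CorrelationTable:
    """Spearman r per (map, ROI), with the common sample size n."""

    r: dict[tuple[str, str], float]
    n: int

    def to_frame(self, maps=MAP_TYPES, rois=ROI_LABELS) -> pd.DataFrame:
        maps = [m for m in maps if any(k[0] == m for k in self.r)]
        rois = [ro for ro in rois if any(k[1] == ro for k in self.r)]
        return pd.DataFrame(
            [[self.r[(m, ro)] for ro in rois] for m in maps], index=maps, columns=rois
        )


def correlation_table(
    records: list[HemisphereRecord],
    maps=MAP_TYPES,
    rois=ROI_LABELS,
    strict: bool = True,
) -> CorrelationTable:
    """One Spearman coefficient per (map, ROI) across hemispheres."""
    if len(records) < 3:
        raise StatsError("need at least 3 hemisphere records")
    moments = np.array([rec.moment_nAm for rec in records])
    table = {}
    for m in maps:
        for ro in rois:
            vals = np.array([rec.myelin[(m, ro)] for rec in records])
            try:
                table[(m, ro)] = spearman(moments, vals)
            except DegenerateRanksError:
                if strict:
                    raise
                warnings.warn(f"zero rank variance in ({m}, {ro}); setting r = 0")
                table[(m, ro)] = 0.0
    return CorrelationTable(r=table, n=len(records))


def summed_r(table: CorrelationTable) -> float:
    """Plain sum of all correlation-table entries (the omnibus statistic)."""
    return float(sum(table.r.values()))


@dataclass
class PermutationResult:
    observed_sum: float
    null_samples: np.ndarray
    p_one_tailed: float
    seed: int | None
    n_records: int
    exhaustive: bool = False


def _rank_z(values: np.ndarray) -> np.ndarray:
    """Centred, unit-norm midranks (so r = dot product of two such vectors)."""
    r = sps.rankdata(values)
    if np.ptp(r) == 0:
        raise DegenerateRanksError("zero rank variance")
    r = r - r.mean()
    return r / np.linalg.norm(r)


def permutation_test(
    records: list[HemisphereRecord],
    n_perm: int = 5000,
    seed: int | None = None,
    maps=MAP_TYPES,
    rois=ROI_LABELS,
    exhaustive: bool = False,
    strict: bool = True,
) -> PermutationResult:
    """Hemisphere-label permutation test of the summed-r statistic.

    Each permutation shuffles the moment column against the myelin rows
    and recomputes the summed statistic; the one-tailed (greater) p-value
    is ``(1 + #{null >= observed}) / (1 + n_perm)``.  With
    ``exhaustive=True`` all n! orderings are enumerated (n <= 8) and the
    p-value is the exact proportion ``#{null >= observed} / n!`` (the
    identity ordering is one of them).
    """
    n = len(records)
    if n < 4:
        raise StatsError("need at least 4 records to permute")
    if n_perm < 1:
        raise StatsError("n_perm must be >= 1")
    moments = np.array([rec.moment_nAm for rec in records])
    cols = []
    for m in maps:
        for ro in rois:
            vals = np.array([rec.myelin[(m, ro)] for rec in records])
            try:
                cols.append(_rank_z(vals))
            except DegenerateRanksError:
                if strict:
                    raise DegenerateRanksError(
                        f"zero rank variance in myelin cell ({m}, {ro})"
                    )
                warnings.warn(f"zero rank variance in ({m}, {ro}); cell contributes 0")
                cols.append(np.zeros(n))
    Z = np.column_stack(cols)  # n x cells
    zm = _rank_z(moments)
    observed = float(zm @ Z.sum(axis=1))

    if exhaustive:
        if n > 8:
            raise StatsError("exhaustive enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        null = (zm[perms] @ Z).sum(axis=1)
        p = float(np.mean(null >= observed - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        null = (zm[perms] @ Z).sum(axis=1)
        p = float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_perm))
    return PermutationResult(
        observed_sum=observed,
        null_samples=np.asarray(null, float),
        p_one_tailed=p,
        seed=seed,
        n_records=n,
        exhaustive=exhaustive,
    )


def _long_frame(records: list[HemisphereRecord], map_type: str, rois) -> pd.DataFrame:
    rows = []
    for rec in records:
        for ro in rois:
            if (map_type, ro) not in rec.myelin:
                raise StatsError(f"record {rec.hemisphere_id} missing ({map_type}, {ro})")
            rows.append(
                {"hemisphere": rec.hemisphere_id, "roi": ro, "value": rec.myelin[(map_type, ro)]}
            )
    return pd.DataFrame(rows)


def rm_anova_roi(
    records: list[HemisphereRecord], map_type: str, rois=ROI_LABELS, alpha: float = 0.05 / 3
):
    """One-way repeated-measures ANOVA with factor ROI for one map type.

    Classical within-subject decomposition: subjects (hemispheres) are
    blocks, F = MS_roi / MS_error with (k-1) and (k-1)(n-1) degrees of
    freedom.  No sphericity correction is applied.  Returns
    (F, p, significant-at-Bonferroni-alpha); if there is no between-ROI
    variance at all, F = 0 and p = 1.
    """
    if len(records) < 2:
        raise StatsError("need at least 2 hemispheres")
    wide = _long_frame(records, map_type, rois).pivot(
        index="hemisphere", columns="roi", values="value"
    )
    if wide.isna().any().any():
        raise StatsError("missing cells in the hemisphere x ROI table")
    Y = wide.to_numpy(float)
    n, k = Y.shape
    grand = Y.mean()
    ss_roi = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_roi - ss_subj
    df_roi, df_err = k - 1, (k - 1) * (n - 1)
    if ss_roi <= 1e-300:
        return 0.0, 1.0, False
    F = (ss_roi / df_roi) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_roi, df_err))
    return float(F), p, bool(p < alpha)


def posthoc_pairwise(
    records: list[HemisphereRecord], map_type: str, rois=ROI_LABELS, alpha: float = 0.05 / 15
) -> pd.DataFrame:
    """All pairwise two-sided paired t-tests between ROIs for one map type."""
    df = _long_frame(records, map_type, rois).pivot(
        index="hemisphere", columns="roi", values="value"
    )
    rows = []
    for a, b in itertools.combinations(rois, 2):
        t, p = sps.ttest_rel(df[a], df[b])
        rows.append(
            {"roi_a": a, "roi_b": b, "t": float(t), "p": float(p), "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)
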