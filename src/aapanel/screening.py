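"""Univariate screening: Mann–Whitney comparisons across timepoints and
serum–tissue Pearson correlations with 95% confidence ellipses.

The temporal screen compares each analyte's concentrations between pairs of
timepoints with the two-sided Mann–Whitney U test (rank-based, so it needs no
normality assumption — serum amino-acid concentrations are frequently
non-Gaussian).  Small layouts (n_a + n_b ≤ 12) use exact enumeration of all
group assignments, which stays correct under ties; larger ones use the normal
approximation with tie and continuity corrections.  By convention no
multiple-testing correction is applied at the default α = 0.05 screen
(an optional Benjamini–Hochberg flag is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ValidationError
from .panel import AnalytePanel

#: Largest pooled sample size handled by exact enumeration.
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class GroupComparison:
    """A two-sided Mann–Whitney comparison of one analyte between two groups."""

    analyte: str
    group_a: str
    group_b: str
    u_statistic: float  # U of group A
    p_value: float
    direction: int  # sign of median(B) - median(A)
    n_a: int
    n_b: int
    method: str = "asymptotic"
    significant: bool | None = None


def _u_statistic(values_a, values_b) -> float:
    pooled = np.concatenate([values_a, values_b])
    ranks = stats.rankdata(pooled)
    n_a = len(values_a)
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(
    values_a,
    values_b,
    analyte: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test of ``values_a`` vs ``values_b``.

    Exact enumeration over all C(n_a+n_b, n_a) group assignments when the
    pooled size is at most ``EXACT_ENUMERATION_LIMIT`` (two-sided p is the
    probability of a U at least as far from its null mean n_a·n_b/2 as the
    observed one); otherwise the normal approximation with tie and
    continuity corrections via :func:`scipy.stats.mannwhitneyu`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)

    if n_a + n_b <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        mu = n_a * n_b / 2.0
        obs_dev = abs(u_obs - mu)
        offset = n_a * (n_a + 1) / 2.0
        hits = total = 0
        for assignment in combinations(range(n_a + n_b), n_a):
            u = ranks[list(assignment)].sum() - offset
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "asymptotic"

    return GroupComparison(
        analyte=analyte,
        group_a=group_a,
        group_b=group_b,
        u_statistic=u_obs,
        p_value=min(p, 1.0),
        direction=int(np.sign(np.median(b) - np.median(a))),
        n_a=n_a,
        n_b=n_b,
        method=method,
    )


def temporal_screen(
    panel: AnalytePanel,
    timepoint_pairs,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[GroupComparison]:
    """Mann–Whitney screen of every analyte over the given timepoint pairs.

    Significance is flagged at ``alpha`` on raw p-values by default, i.e.
    without multiplicity correction (the screen is descriptive); pass
    ``bh_correct=True`` for Benjamini–Hochberg-adjusted flags.
    """
    results: list[GroupComparison] = []
    for tp_a, tp_b in timepoint_pairs:
        sub_a = panel.filter(timepoint=tp_a)
        sub_b = panel.filter(timepoint=tp_b)
        if sub_a.n_samples == 0:
            raise ValidationError(f"panel has no samples at timepoint {tp_a!r}")
        if sub_b.n_samples == 0:
            raise ValidationError(f"panel has no samples at timepoint {tp_b!r}")
        for name in panel.analyte_names:
            results.append(
                mann_whitney(
                    sub_a.data[name].to_numpy(float),
                    sub_b.data[name].to_numpy(float),
                    analyte=name,
                    group_a=tp_a,
                    group_b=tp_b,
                )
            )
    if results:
        pvals = np.array([r.p_value for r in results])
        if bh_correct:
            adjusted = stats.false_discovery_control(pvals, method="bh")
            for r, padj in zip(results, adjusted):
                r.significant = bool(padj < alpha)
        else:
            for r in results:
                r.significant = bool(r.p_value < alpha)
    return results


@dataclass
class EllipseSummary:
    """Pearson correlation and 95% confidence ellipse for one analyte/group.

    The ellipse is derived from the 2×2 sample covariance of (serum, tissue):
    semi-axis lengths are sqrt(eigenvalue × χ²₂(0.95)) and ``angle`` is the
    major-axis orientation in degrees counter-clockwise from the serum axis.
    """

    analyte: str
    group: str
    r: float
    p_value: float
    center: tuple[float, float]
    axes: tuple[float, float]  # (major, minor) semi-axis lengths
    angle: float
    n: int
    degenerate: bool = False


def serum_tissue_correlation(
    serum: AnalytePanel,
    tissue: AnalytePanel,
    group: str,
) -> list[EllipseSummary]:
    """Per-analyte serum–tissue Pearson r with 95% confidence ellipses.

    Panels are paired on ``sample_id``; ``group`` is ``"sham"`` (label 0) or
    ``"injured"`` (label 1).  Fewer than 3 pairs in the group is degenerate
    and raises :class:`ValidationError`.
    """
    if group not in ("sham", "injured"):
        raise ValidationError(f"group must be 'sham' or 'injured', got {group!r}")
    label = 0 if group == "sham" else 1
    s = serum.data.set_index("sample_id")
    t = tissue.data.set_index("sample_id")
    common = s.index.intersection(t.index)
    s = s.loc[common]
    t = t.loc[common]
    mask = s["label"].astype(int).to_numpy() == label
    if mask.sum() < 3:
        raise ValidationError(
            f"fewer than 3 paired samples in group {group!r}; correlation degenerate"
        )
    chi2_scale = stats.chi2.ppf(0.95, df=2)
    out: list[EllipseSummary] = []
    for name in serum.analyte_names:
        x = s.loc[mask, name].to_numpy(float)
        y = t.loc[mask, name].to_numpy(float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            r, p = math.nan, math.nan
        else:
            r, p = stats.pearsonr(x, y)
        cov = np.cov(np.vstack([x, y]), ddof=1)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        evals = np.clip(evals, 0.0, None)
        major = math.sqrt(evals[1] * chi2_scale)
        minor = math.sqrt(evals[0] * chi2_scale)
        v = evecs[:, 1]
        angle = math.degrees(math.atan2(v[1], v[0])) % 180.0
        out.append(
            EllipseSummary(
                analyte=name,
                group=group,
                r=float(r),
                p_value=float(p),
                center=(float(x.mean()), float(y.mean())),
                axes=(major, minor),
                angle=angle,
                n=int(mask.sum()),
                degenerate=bool(evals[0] <= 1e-12 * max(evals[1], 1.0)),
            )
        )
    return out
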