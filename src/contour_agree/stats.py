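"""Downstream statistics of a multi-reader delineation study.

Four procedures, each mirroring one report table of a classical
inter-observer agreement analysis:

* Spearman rank correlation between two reader-pairs' per-patient metric
  series, dichotomized at rho = 0.6 into strong vs weak;
* Friedman repeated-measures cross-comparison of sequences with
  Bonferroni-corrected pairwise Wilcoxon signed-rank post-hocs;
* intraclass correlation ICC(2,1) — two-way random effects, absolute
  agreement, single rater — on the patients x readers volume matrix,
  with an F-based 95% confidence interval;
* Bland-Altman comparison of per-patient volumes between two sources
  (bias and 1.96-SD limits of agreement).

Missing data policy: pairwise deletion for Spearman and Bland-Altman,
listwise (complete-block) deletion for Friedman and ICC, matching each
procedure's balanced-design requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Dichotomization threshold for Spearman rho: rho >= 0.6 counts as strong
#: (the boundary belongs to "strong to very strong").
STRONG_RHO = 0.6

#: Default significance level of the report flags.
DEFAULT_ALPHA = 0.001


class InsufficientDataError(ValueError):
    """Fewer complete observations than the procedure requires."""


# ---------------------------------------------------------------------------
# Spearman between reader pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanRow:
    pair_of_pairs: str           # e.g. "r1-r2 vs r1-r3"
    metric: str
    sequence: str
    n: int
    rho: float
    strength: str                # "strong" | "weak"


def spearman_between_pairs(
    series_a: Sequence[float],
    series_b: Sequence[float],
    *,
    label: str = "",
    metric: str = "",
    sequence: str = "",
) -> SpearmanRow:
    """Spearman rank correlation between two aligned per-patient series.

    NaN entries (missing records) are removed pairwise; ties receive
    average ranks. Requires at least three complete observations.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned on the same patients")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete patient observations, got {len(a)}"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InsufficientDataError(
            "rank correlation undefined for a constant series"
        )
    rho = float(sps.spearmanr(a, b).statistic)
    return SpearmanRow(
        pair_of_pairs=label,
        metric=metric,
        sequence=sequence,
        n=int(len(a)),
        rho=rho,
        strength="strong" if rho >= STRONG_RHO else "weak",
    )


def spearman_table(pair_metrics: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between every two reader pairs, per sequence and metric.

    ``pair_metrics`` is the long-form frame from
    :func:`contour_agree.agreement.records_to_frame`.
    """
    rows: list[dict] = []
    for sequence, seq_frame in pair_metrics.groupby("sequence", sort=False):
        pair_ids = sorted(seq_frame["pair_id"].unique())
        for metric, col in (("Overlap", "ov"), ("Dice", "dsc"), ("Jaccard", "jsc")):
            wide = seq_frame.pivot(index="patient_id", columns="pair_id", values=col)
            for pa, pb in combinations(pair_ids, 2):
                try:
                    row = spearman_between_pairs(
                        wide[pa].to_numpy(float),
                        wide[pb].to_numpy(float),
                        label=f"{pa} vs {pb}",
                        metric=metric,
                        sequence=sequence,
                    )
                except InsufficientDataError:
                    continue
                rows.append(
                    {
                        "sequence": row.sequence,
                        "pair_of_pairs": row.pair_of_pairs,
                        "metric": row.metric,
                        "n": row.n,
                        "rho": row.rho,
                        "strength": row.strength,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Friedman cross-comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FriedmanResult:
    metric: str
    sequences: tuple[str, ...]
    statistic: float
    p_value: float
    n_blocks: int
    #: rows of (sequence_a, sequence_b, mean difference a-b, adjusted p, significant)
    pairwise: pd.DataFrame = field(repr=False, default=None)


#: Largest number of nonzero paired differences for which the Wilcoxon
#: signed-rank p-value is computed exactly; beyond this the normal
#: approximation with continuity correction is used.
WILCOXON_EXACT_LIMIT = 25


def _wilcoxon_p(diff: np.ndarray) -> float:
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 1.0
    method = "exact" if len(nz) <= WILCOXON_EXACT_LIMIT else "approx"
    try:
        res = sps.wilcoxon(diff, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        return 1.0
    return float(res.pvalue)


def friedman_cross_comparison(
    blocks: pd.DataFrame,
    metric: str = "",
    alpha: float = DEFAULT_ALPHA,
    min_blocks: int = 6,
) -> FriedmanResult:
    """Friedman repeated-measures test across sequences, with post-hocs.

    ``blocks`` is a wide frame: one row per block (a patient/reader-pair
    observation), one column per sequence. Rows with any missing value are
    dropped (listwise deletion). The omnibus test is the Friedman
    chi-square on within-block ranks; pairwise post-hocs are Wilcoxon
    signed-rank tests with Bonferroni correction (raw p multiplied by the
    number of pairwise comparisons, capped at 1). The reported mean
    difference for (A, B) is the mean of within-block differences A - B.
    """
    complete = blocks.dropna(axis=0)
    n = len(complete)
    if n < min_blocks:
        raise InsufficientDataError(
            f"need >= {min_blocks} complete blocks, got {n}"
        )
    seqs = tuple(complete.columns)
    if len(seqs) < 2:
        raise InsufficientDataError("need >= 2 sequences to compare")

    cols = [complete[s].to_numpy(float) for s in seqs]
    if len(seqs) == 2:
        # Friedman needs k >= 3; for two groups the omnibus is the Wilcoxon test
        stat = np.nan
        p = _wilcoxon_p(cols[0] - cols[1])
    else:
        ranks = sps.rankdata(np.column_stack(cols), axis=1)
        if np.all(np.ptp(ranks, axis=1) == 0):
            stat, p = 0.0, 1.0  # every block fully tied: no rank variation
        else:
            stat, p = sps.friedmanchisquare(*cols)
            stat, p = float(stat), float(p)

    pairs = list(combinations(seqs, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = complete[a].to_numpy(float) - complete[b].to_numpy(float)
        adj = min(1.0, _wilcoxon_p(diff) * m)
        rows.append(
            {
                "sequence_a": a,
                "sequence_b": b,
                "mean_difference": float(diff.mean()),
                "p_adjusted": adj,
                "significant": adj < alpha,
            }
        )
    return FriedmanResult(
        metric=metric,
        sequences=seqs,
        statistic=stat,
        p_value=float(p),
        n_blocks=n,
        pairwise=pd.DataFrame(rows),
    )


def cross_comparison_table(
    pair_metrics: pd.DataFrame,
    sequences: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Friedman cross-comparison of sequences for each agreement metric.

    Blocks are (patient, reader pair) observations complete across all
    compared sequences. Returns the pairwise post-hoc rows of each metric
    plus the omnibus statistic and p-value.
    """
    rows: list[dict] = []
    for metric, col in (("Overlap", "ov"), ("Dice", "dsc"), ("Jaccard", "jsc")):
        wide = pair_metrics.pivot(
            index=["patient_id", "pair_id"], columns="sequence", values=col
        )
        if sequences is not None:
            cols = [s for s in sequences if s in wide.columns]
            wide = wide[cols]
        try:
            res = friedman_cross_comparison(wide, metric=metric, alpha=alpha)
        except InsufficientDataError:
            continue
        for _, r in res.pairwise.iterrows():
            rows.append(
                {
                    "metric": metric,
                    "sequence_a": r["sequence_a"],
                    "sequence_b": r["sequence_b"],
                    "mean_difference": r["mean_difference"],
                    "p_adjusted": r["p_adjusted"],
                    "significant": r["significant"],
                    "omnibus_statistic": res.statistic,
                    "omnibus_p": res.p_value,
                    "n_blocks": res.n_blocks,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    sequence: str
    n: int                       # complete-case patients
    k: int                       # readers
    estimate: float              # may be negative
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1) two-way random, absolute agreement"
    degenerate: bool = False


def icc_volumes(
    volumes: np.ndarray | pd.DataFrame,
    sequence: str = "",
    ci_level: float = 0.95,
) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``volumes`` is a patients x readers matrix; rows with any missing value
    are dropped. The moment estimator

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the patient, reader and residual mean squares, can be
    negative when the between-patient variance is below its noise floor.
    The confidence interval is the standard F-based (Satterthwaite)
    interval for this form.
    """
    mat = np.asarray(pd.DataFrame(volumes).dropna(axis=0), dtype=float)
    n, k = mat.shape
    if k < 2:
        raise InsufficientDataError("need >= 2 readers")
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete patients, got {n}")

    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((mat - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr <= 1e-30 and mse <= 1e-30):
        return ICCResult(sequence, n, k, float("nan"), float("nan"),
                         float("nan"), degenerate=True)
    icc = (msr - mse) / denom

    alpha = 1.0 - ci_level
    if mse <= 0:
        # perfect agreement: no residual variance, interval collapses
        return ICCResult(sequence, n, k, float(icc), float(icc), float(icc))

    # Satterthwaite degrees of freedom for the absolute-agreement interval
    fj = msc / mse
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd if vd > 0 else 1.0
    f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ub = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr
    )
    return ICCResult(
        sequence=sequence,
        n=n,
        k=k,
        estimate=float(icc),
        ci_low=float(min(lb, icc)),
        ci_high=float(max(ub, icc)),
    )


def icc_table(volumes: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-sequence ICC on the long-form volumes frame.

    ``volumes`` has columns patient_id, sequence, reader, volume_cc; NaN or
    absent rows are missing exams.
    """
    rows = []
    for sequence, g in volumes.groupby("sequence", sort=False):
        wide = g.pivot(index="patient_id", columns="reader", values="volume_cc")
        try:
            res = icc_volumes(wide, sequence=sequence, ci_level=ci_level)
        except InsufficientDataError:
            continue
        rows.append(
            {
                "sequence": sequence,
                "n": res.n,
                "k": res.k,
                "icc": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "model": res.model,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    source_a: str
    source_b: str
    n: int
    bias: float                  # mean of a - b
    loa_low: float               # bias - 1.96 sd
    loa_high: float              # bias + 1.96 sd
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)


def bland_altman(
    v1: Sequence[float],
    v2: Sequence[float],
    *,
    source_a: str = "A",
    source_b: str = "B",
) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired volume series.

    Points are ((v1+v2)/2, v1-v2); bias is the mean difference and the
    limits of agreement are bias +/- 1.96 SD of the differences (sample SD,
    n-1 denominator). Pairs with a missing member are dropped.
    """
    a = np.asarray(v1, float)
    b = np.asarray(v2, float)
    if a.shape != b.shape:
        raise ValueError("paired series must be aligned")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, got {len(a)}")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        source_a=source_a,
        source_b=source_b,
        n=int(len(a)),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        differences=diff,
    )


def bland_altman_table(
    volumes: pd.DataFrame,
    sequences: Sequence[str],
    source_rule: str = "patient_mean",
) -> pd.DataFrame:
    """Bland-Altman of per-patient volumes between every two sequences.

    ``source_rule`` selects what "the volume of a patient on a sequence"
    means: "patient_mean" (default) averages the readers' volumes per
    patient; "reader:<id>" uses a single reader's volumes.
    """
    if source_rule == "patient_mean":
        per_patient = (
            volumes.groupby(["patient_id", "sequence"])["volume_cc"]
            .mean()
            .reset_index()
        )
    elif source_rule.startswith("reader:"):
        rid = source_rule.split(":", 1)[1]
        per_patient = volumes[volumes["reader"] == rid][
            ["patient_id", "sequence", "volume_cc"]
        ]
    else:
        raise ValueError(f"unknown source_rule {source_rule!r}")
    wide = per_patient.pivot(index="patient_id", columns="sequence", values="volume_cc")
    rows = []
    for a, b in combinations([s for s in sequences if s in wide.columns], 2):
        try:
            res = bland_altman(
                wide[a].to_numpy(float), wide[b].to_numpy(float),
                source_a=a, source_b=b,
            )
        except InsufficientDataError:
            continue
        rows.append(
            {
                "sequence_a": a,
                "sequence_b": b,
                "n": res.n,
                "bias": res.bias,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
            }
        )
    return pd.DataFrame(rows)
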