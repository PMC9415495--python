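"""Pairwise spatial-agreement metrics and their per-sequence summaries.

Three classical set-overlap coefficients between two binary delineations
A and B:

    Dice    DSC = 2|A n B| / (|A| + |B|)
    Jaccard JSC = |A n B| / |A u B|
    Overlap OV  = |A n B| / min(|A|, |B|)

All three live in [0, 1]; 0 means no shared voxel and 1 perfect agreement.
They are ordered JSC <= DSC <= OV for every mask pair, and DSC and JSC are
tied by DSC = 2 JSC / (1 + JSC).

A comparison in which either mask is absent or empty is recorded as
MISSING rather than zero: in a multi-reader study a reader declining to
delineate a sequence is an absent observation, not a disagreement of zero
(and the overlap coefficient is undefined when a volume is empty). This is
what makes the valid-N vary across sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_masks import BinaryMask, StudyManifest

VALID = "VALID"
MISSING = "MISSING"


class UndefinedMetricError(ValueError):
    """Raised when a coefficient is requested for an empty operand."""


@dataclass(frozen=True)
class PairMetrics:
    """Agreement record for one (patient, sequence, unordered reader pair)."""

    patient_id: str
    sequence: str
    pair_id: str                 # e.g. "r1-r2"
    dsc: float | None
    jsc: float | None
    ov: float | None
    status: str                  # VALID | MISSING


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if not a.grid.same_grid(b.grid):
        raise ValueError("masks are not on the same grid")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    _check_pair(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard similarity coefficient |A n B| / |A u B|."""
    _check_pair(a, b)
    if a.is_empty and b.is_empty:
        raise UndefinedMetricError("Jaccard undefined for two empty masks")
    inter = int(np.count_nonzero(a.data & b.data))
    union = int(np.count_nonzero(a.data | b.data))
    return inter / union


def overlap(a: BinaryMask, b: BinaryMask) -> float:
    """Overlap coefficient |A n B| / min(|A|, |B|).

    Undefined when either mask is empty (the denominator vanishes).
    """
    _check_pair(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 or nb == 0:
        raise UndefinedMetricError("Overlap undefined when either mask is empty")
    inter = int(np.count_nonzero(a.data & b.data))
    return inter / min(na, nb)


def pair_id(reader_a: str, reader_b: str) -> str:
    """Canonical unordered pair label."""
    lo, hi = sorted([reader_a, reader_b])
    return f"{lo}-{hi}"


def all_pairs(
    manifest: StudyManifest,
    masks: Mapping[tuple[str, str, str], BinaryMask | None],
) -> list[PairMetrics]:
    """All-pairs agreement over every (patient, sequence, reader pair).

    ``masks`` maps (patient, sequence, reader) to the loaded mask, or None
    for a missing exam. A pair with an absent or empty operand yields a
    MISSING record with no metric values; with three readers and no
    missingness, a 30-patient study yields 90 records per sequence.
    """
    records: list[PairMetrics] = []
    readers = manifest.readers
    for sequence in manifest.sequences:
        for patient in manifest.patients:
            for ra, rb in combinations(readers, 2):
                ma = masks.get((patient, sequence, ra))
                mb = masks.get((patient, sequence, rb))
                pid = pair_id(ra, rb)
                if ma is None or mb is None or ma.is_empty or mb.is_empty:
                    records.append(
                        PairMetrics(patient, sequence, pid, None, None, None, MISSING)
                    )
                    continue
                records.append(
                    PairMetrics(
                        patient,
                        sequence,
                        pid,
                        dsc=dice(ma, mb),
                        jsc=jaccard(ma, mb),
                        ov=overlap(ma, mb),
                        status=VALID,
                    )
                )
    return records


def records_to_frame(records: Iterable[PairMetrics]) -> pd.DataFrame:
    """Long-form DataFrame of pair records (one row per patient/sequence/pair)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "sequence": r.sequence,
                "pair_id": r.pair_id,
                "dsc": r.dsc,
                "jsc": r.jsc,
                "ov": r.ov,
                "status": r.status,
            }
            for r in records
        ]
    )


_METRIC_COLUMNS = {"Overlap": "ov", "Dice": "dsc", "Jaccard": "jsc"}


def _summary_row(values: np.ndarray, ci_level: float) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    median = float(np.median(values))
    if n >= 2:
        sd = float(np.std(values, ddof=1))
        half = sps.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / np.sqrt(n)
    else:
        half = 0.0  # degenerate CI collapses onto the mean
    return {
        "n": n,
        "mean": mean,
        "median": median,
        "ci_low": mean - half,
        "ci_high": mean + half,
    }


def summarize(
    records: Iterable[PairMetrics],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-sequence summary of the agreement coefficients.

    Emits one row per (sequence, reader pair, metric) plus an "All" row per
    (sequence, metric) pooling the pairs, each with the count of valid
    records, mean, median and a two-sided t-interval for the mean (unclipped,
    so it may exceed 1 near perfect agreement). Groups with no valid record
    are omitted.
    """
    frame = records_to_frame(records)
    rows: list[dict] = []
    if frame.empty:
        return pd.DataFrame(
            columns=["sequence", "pair_id", "metric", "n", "mean", "median",
                     "ci_low", "ci_high"]
        )
    valid = frame[frame["status"] == VALID]
    for sequence, seq_frame in valid.groupby("sequence", sort=False):
        groups = [(pid, g) for pid, g in seq_frame.groupby("pair_id", sort=True)]
        groups.append(("All", seq_frame))
        for pid, g in groups:
            for metric, col in _METRIC_COLUMNS.items():
                values = g[col].dropna().to_numpy(float)
                if len(values) == 0:
                    continue
                rows.append(
                    {"sequence": sequence, "pair_id": pid, "metric": metric}
                    | _summary_row(values, ci_level)
                )
    return pd.DataFrame(rows)
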