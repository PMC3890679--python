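"""Leave-one-out species-identification estimators and threshold optimiser.

Three distance-based criteria, each scored by removing the focal specimen
from the reference library and asking whether its neighbours identify it:

* near neighbour — true iff the nearest remaining specimen (any tied
  nearest) is conspecific;
* best close match — the nearest specimen(s) within a distance threshold
  decide: all conspecific -> correct, all heterospecific -> incorrect,
  mixed -> ambiguous, nobody within the threshold -> no_id;
* threshold (BOLD-style) identification — as above but over ALL specimens
  within the cutoff (1% by convention), not just the nearest.

The optimiser scans a threshold grid and returns the value minimising
cumulative identification error (incorrect + no_id by default), the
standard way a per-locus threshold is calibrated before scoring.

Specimens that are the only representative of their species can never match
a conspecific; they are retained and necessarily score false / incorrect /
no_id, with their count reported so either convention can be reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import BarcodekitError, ReferenceLibrary
from .distances import DistanceMatrix

logger = logging.getLogger("barcodekit")

NN_VERDICTS = ("true", "false")
MATCH_VERDICTS = ("correct", "incorrect", "ambiguous", "no_id")

#: Default BOLD-style cutoff (1%).
DEFAULT_THRESHOLD = 0.01

#: Default optimiser grid: 0.1%..5% in 0.01% steps.
DEFAULT_GRID = np.round(np.arange(0.001, 0.05 + 1e-12, 0.0001), 6)


@dataclass(frozen=True)
class IdentificationOutcome:
    id: str
    method: str
    verdict: str
    nearest_id: str | None
    nearest_distance: float


@dataclass
class MethodResult:
    """Outcomes plus the percentage summary for one method."""

    method: str
    outcomes: list[IdentificationOutcome]
    summary: dict[str, float]
    n_excluded: int = 0
    n_singletons: int = 0

    def outcome_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": o.id,
                    "method": o.method,
                    "verdict": o.verdict,
                    "nearest_id": o.nearest_id,
                    "nearest_distance": o.nearest_distance,
                }
                for o in self.outcomes
            ]
        )


def _neighbour_arrays(
    m: DistanceMatrix, species_of: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Per-record (min conspecific, min heterospecific, min overall) leave-
    one-out distances; inf where no (non-MISSING) neighbour of a kind exists."""
    labels = m.labels
    sp = np.array([species_of[lab] for lab in labels])
    vals = m.values.copy()
    np.fill_diagonal(vals, np.nan)
    same = sp[:, None] == sp[None, :]
    con = np.where(same, vals, np.nan)
    het = np.where(~same, vals, np.nan)
    with np.errstate(all="ignore"):
        dmin_con = np.nanmin(np.where(np.isnan(con), np.inf, con), axis=1)
        dmin_het = np.nanmin(np.where(np.isnan(het), np.inf, het), axis=1)
    return dmin_con, dmin_het, np.minimum(dmin_con, dmin_het), labels


def _nearest_of(m: DistanceMatrix, i: int) -> tuple[str | None, float]:
    row = m.values[i].copy()
    row[i] = np.nan
    if np.all(np.isnan(row)):
        return None, np.nan
    j = int(np.nanargmin(row))
    return m.labels[j], float(row[j])


def _percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: 100.0 * v / total if total else np.nan for k, v in counts.items()}


def near_neighbour(m: DistanceMatrix, species_of: Mapping[str, str]) -> MethodResult:
    """True iff any tied nearest non-self neighbour is conspecific."""
    dmin_con, dmin_het, dmin, labels = _neighbour_arrays(m, species_of)
    outcomes, counts = [], {v: 0 for v in NN_VERDICTS}
    n_excluded = n_singletons = 0
    for i, lab in enumerate(labels):
        if not np.isfinite(dmin[i]):
            n_excluded += 1
            logger.warning("near_neighbour: %s has no usable distances; excluded", lab)
            continue
        if not np.isfinite(dmin_con[i]):
            n_singletons += 1
        verdict = "true" if dmin_con[i] == dmin[i] else "false"
        counts[verdict] += 1
        nid, nd = _nearest_of(m, i)
        outcomes.append(IdentificationOutcome(lab, "near_neighbour", verdict, nid, nd))
    return MethodResult(
        "near_neighbour", outcomes, _percentages(counts), n_excluded, n_singletons
    )


def best_close_match(
    m: DistanceMatrix, species_of: Mapping[str, str], threshold: float
) -> MethodResult:
    """Verdict from the tied nearest neighbour(s) within ``threshold``."""
    if threshold < 0:
        raise BarcodekitError("threshold must be non-negative")
    dmin_con, dmin_het, dmin, labels = _neighbour_arrays(m, species_of)
    outcomes, counts = [], {v: 0 for v in MATCH_VERDICTS}
    n_excluded = n_singletons = 0
    for i, lab in enumerate(labels):
        if not np.isfinite(dmin[i]):
            n_excluded += 1
            logger.warning("best_close_match: %s has no usable distances; excluded", lab)
            continue
        if not np.isfinite(dmin_con[i]):
            n_singletons += 1
        if dmin[i] > threshold:
            verdict = "no_id"
        else:
            con_at_min = dmin_con[i] == dmin[i]
            het_at_min = dmin_het[i] == dmin[i]
            verdict = (
                "ambiguous"
                if (con_at_min and het_at_min)
                else "correct" if con_at_min else "incorrect"
            )
        counts[verdict] += 1
        nid, nd = _nearest_of(m, i)
        outcomes.append(IdentificationOutcome(lab, "best_close_match", verdict, nid, nd))
    return MethodResult(
        "best_close_match", outcomes, _percentages(counts), n_excluded, n_singletons
    )


def threshold_id(
    m: DistanceMatrix, species_of: Mapping[str, str], threshold: float = DEFAULT_THRESHOLD
) -> MethodResult:
    """Verdict from ALL non-self neighbours within ``threshold``."""
    if threshold < 0:
        raise BarcodekitError("threshold must be non-negative")
    dmin_con, dmin_het, dmin, labels = _neighbour_arrays(m, species_of)
    outcomes, counts = [], {v: 0 for v in MATCH_VERDICTS}
    n_excluded = n_singletons = 0
    for i, lab in enumerate(labels):
        if not np.isfinite(dmin[i]):
            n_excluded += 1
            logger.warning("threshold_id: %s has no usable distances; excluded", lab)
            continue
        if not np.isfinite(dmin_con[i]):
            n_singletons += 1
        has_con = dmin_con[i] <= threshold
        has_het = dmin_het[i] <= threshold
        if not has_con and not has_het:
            verdict = "no_id"
        elif has_con and has_het:
            verdict = "ambiguous"
        else:
            verdict = "correct" if has_con else "incorrect"
        counts[verdict] += 1
        nid, nd = _nearest_of(m, i)
        outcomes.append(IdentificationOutcome(lab, "threshold_id", verdict, nid, nd))
    return MethodResult(
        "threshold_id", outcomes, _percentages(counts), n_excluded, n_singletons
    )


def optimize_threshold(
    m: DistanceMatrix,
    species_of: Mapping[str, str],
    grid: Sequence[float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the threshold minimising cumulative identification error.

    Per record, a candidate threshold t commits a false negative when the
    record's furthest conspecific lies beyond t (a conspecific pair the
    cutoff fails to unite) and a false positive when its nearest
    heterospecific lies within t (a wrong species the cutoff lets in) —
    the standard threshold-optimisation bookkeeping for barcode libraries.
    Cumulative error = false negatives + false positives; ties broken
    toward the smallest t.  Singletons have no conspecifics and cannot
    contribute false negatives.

    Returns (best threshold, full error-vs-threshold profile).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise BarcodekitError("optimize_threshold: empty grid")
    labels = m.labels
    sp = np.array([species_of[lab] for lab in labels])
    vals = m.values.copy()
    np.fill_diagonal(vals, np.nan)
    same = sp[:, None] == sp[None, :]
    con = np.where(same, vals, np.nan)
    het = np.where(~same, vals, np.nan)
    usable = ~np.all(np.isnan(vals), axis=1)
    with np.errstate(all="ignore"):
        max_con = np.nanmax(np.where(np.isnan(con), -np.inf, con), axis=1)[usable]
        min_het = np.nanmin(np.where(np.isnan(het), np.inf, het), axis=1)[usable]
    t = grid[None, :]
    fn = (max_con[:, None] > t).sum(axis=0)
    fp = (min_het[:, None] <= t).sum(axis=0)
    errors = fn + fp
    best = int(np.argmin(errors))  # argmin takes the first = smallest t on ties
    profile = pd.DataFrame(
        {
            "threshold": grid,
            "cumulative_error": errors,
            "false_negative": fn,
            "false_positive": fp,
        }
    )
    return float(grid[best]), profile


def efficacy_table(
    lib: ReferenceLibrary,
    m: DistanceMatrix,
    bcm_threshold: float,
    bold_threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Run all three estimators and tabulate percentage summaries.

    One row per (method, verdict) percentage for this library's locus;
    integer-rounded percentages alongside full precision.
    """
    results = [
        near_neighbour(m, lib.species_of()),
        threshold_id(m, lib.species_of(), bold_threshold),
        best_close_match(m, lib.species_of(), bcm_threshold),
    ]
    rows = []
    for res in results:
        for verdict, pct in res.summary.items():
            rows.append(
                {
                    "locus": lib.locus,
                    "method": res.method,
                    "verdict": verdict,
                    "pct": pct,
                    "pct_rounded": int(round(pct)) if np.isfinite(pct) else np.nan,
                    "n_singletons": res.n_singletons,
                }
            )
    return pd.DataFrame(rows)
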