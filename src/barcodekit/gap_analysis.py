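"""Barcode-gap analysis: intra- vs interspecific distance distributions.

A locus is a usable barcode when conspecific individuals are much closer to
one another than to other species.  This module partitions a pairwise
distance matrix into intraspecific and interspecific sets, compares the two
with a Wilcoxon rank-sum test, summarises the per-locus statistics
(sequence count, divergence ranges/means/medians, Tajima's K, optimised
threshold), and computes the per-individual barcode gap: for each specimen,
does its nearest heterospecific lie farther than its furthest conspecific?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BarcodekitError, ReferenceLibrary
from .distances import DistanceMatrix, build_distance_matrix, tajima_K

logger = logging.getLogger("barcodekit")


def _species_array(m: DistanceMatrix, species_of: Mapping[str, str]) -> np.ndarray:
    missing = [lab for lab in m.labels if lab not in species_of]
    if missing:
        raise BarcodekitError(f"no species label for matrix ids: {missing}")
    return np.array([species_of[lab] for lab in m.labels])


def partition_distances(
    m: DistanceMatrix, species_of: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Split non-MISSING unordered pairs into (intraspecific, interspecific)."""
    sp = _species_array(m, species_of)
    iu = np.triu_indices(len(m), k=1)
    vals = m.values[iu]
    same = sp[iu[0]] == sp[iu[1]]
    ok = ~np.isnan(vals)
    return vals[same & ok], vals[~same & ok]


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of two samples.

    Exact when both samples are small (min n <= 20) and tie-free, normal
    approximation with tie correction otherwise.  Returns (U, p).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BarcodekitError("wilcoxon_rank_sum: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GapSummary:
    """One locus row of the distance-summary table."""

    locus: str
    n_sequences: int
    alignment_length: int
    tajima_K: float
    inter_min: float
    inter_max: float
    inter_mean: float
    inter_median: float
    inter_sd: float
    intra_min: float
    intra_max: float
    intra_mean: float
    intra_median: float
    intra_sd: float
    wilcoxon_p: float
    optimized_threshold_pct: float
    n_singleton_species: int = 0

    def to_row(self) -> dict:
        return asdict(self)


def summarize_locus(
    lib: ReferenceLibrary,
    m: DistanceMatrix,
    optimized_threshold: float | None = None,
) -> GapSummary:
    """Aggregate per-locus distance statistics (summary-table shape).

    ``optimized_threshold`` is the fraction-scale threshold from the
    identification optimiser; reported as a percentage.  Libraries with a
    single species yield NaN interspecific fields rather than an error.
    """
    species_of = lib.species_of()
    intra, inter = partition_distances(m, species_of)
    counts = pd.Series([species_of[lab] for lab in m.labels]).value_counts()
    n_singletons = int((counts == 1).sum())

    def _stats(v: np.ndarray) -> tuple[float, float, float, float, float]:
        if v.size == 0:
            return (np.nan,) * 5
        return (
            float(v.min()),
            float(v.max()),
            float(v.mean()),
            float(np.median(v)),
            float(v.std(ddof=1)) if v.size > 1 else 0.0,
        )

    p_matrix = build_distance_matrix(lib, model="p")
    if intra.size and inter.size:
        _, p = wilcoxon_rank_sum(intra, inter)
    else:
        p = np.nan
    i_min, i_max, i_mean, i_median, i_sd = _stats(inter)
    a_min, a_max, a_mean, a_median, a_sd = _stats(intra)
    return GapSummary(
        locus=lib.locus,
        n_sequences=len(lib),
        alignment_length=lib.alignment_length,
        tajima_K=tajima_K(p_matrix),
        inter_min=i_min,
        inter_max=i_max,
        inter_mean=i_mean,
        inter_median=i_median,
        inter_sd=i_sd,
        intra_min=a_min,
        intra_max=a_max,
        intra_mean=a_mean,
        intra_median=a_median,
        intra_sd=a_sd,
        wilcoxon_p=p,
        optimized_threshold_pct=(
            np.nan if optimized_threshold is None else 100.0 * optimized_threshold
        ),
        n_singleton_species=n_singletons,
    )


@dataclass(frozen=True)
class IndividualGap:
    """Per-specimen barcode gap: nearest heterospecific vs furthest
    conspecific distance.  ``has_gap`` is None for singleton species."""

    id: str
    max_intra: float | None
    min_inter: float
    has_gap: bool | None


def individual_gaps(
    m: DistanceMatrix, species_of: Mapping[str, str]
) -> list[IndividualGap]:
    """Per-record barcode gap, sorted by max_intra (singletons last)."""
    sp = _species_array(m, species_of)
    out = []
    for i, lab in enumerate(m.labels):
        row = m.values[i].copy()
        row[i] = np.nan
        con = row[(sp == sp[i]) & ~np.isnan(row)]
        het = row[(sp != sp[i]) & ~np.isnan(row)]
        min_inter = float(het.min()) if het.size else np.nan
        if con.size == 0:
            out.append(IndividualGap(lab, None, min_inter, None))
        else:
            max_intra = float(con.max())
            out.append(IndividualGap(lab, max_intra, min_inter, min_inter > max_intra))
    return sorted(out, key=lambda g: (g.max_intra is None, g.max_intra))


def gaps_table(gaps: list[IndividualGap]) -> pd.DataFrame:
    """Lineplot-ready table (id, max_intra, min_inter, has_gap)."""
    return pd.DataFrame(
        [
            {
                "id": g.id,
                "max_intra": g.max_intra,
                "min_inter": g.min_inter,
                "has_gap": g.has_gap,
            }
            for g in gaps
        ],
        columns=["id", "max_intra", "min_inter", "has_gap"],
    )
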