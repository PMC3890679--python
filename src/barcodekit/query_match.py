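"""Percent-identity matching of degraded market queries to the library.

Stands in for a BLAST search against a barcode database: each query is
aligned semi-globally (Needleman-Wunsch with free end gaps, so a short
degraded fragment can sit anywhere inside a full-length reference) against
every reference, hits are ranked by percent identity, and the best hit is
adjudicated against the species expected from the sample's vernacular name.
Ranking is by percent identity — the statistic read as the headline number
in barcode identification ("the closer the hit is to 100%, the better");
no database-size E-value statistics apply to a local matcher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import Align

from .core_io import BarcodekitError, ReferenceLibrary, SequenceRecord, VernacularLookup

logger = logging.getLogger("barcodekit")

DEFAULT_MIN_IDENTITY = 90.0

MARKET_STATUSES = ("match", "mismatch", "unverifiable", "amplification_failed", "no_hit")

MARKET_COLUMNS = (
    "query_id",
    "vernacular",
    "expected_species",
    "best_hit_id",
    "best_hit_species",
    "percent_identity",
    "status",
    "conservation_status",
)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.internal_gap_score = -2
    a.end_gap_score = 0  # free end gaps: semi-global
    return a


def semiglobal_identity(
    query: SequenceRecord, ref: SequenceRecord
) -> tuple[float, int]:
    """Percent identity of the best free-end-gap alignment of two sequences.

    Gaps are stripped first (inputs may be alignment slices); identity is
    scored over aligned columns excluding the terminal overhangs, so an
    exact substring scores 100.  Returns (percent_identity, aligned_sites).
    """
    q = query.sequence.replace("-", "")
    r = ref.sequence.replace("-", "")
    if not q or not r:
        raise BarcodekitError(
            f"semiglobal_identity: empty sequence ({query.id!r} vs {ref.id!r})"
        )
    aln = _aligner().align(q, r)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lead = max(len(s1) - len(s1.lstrip("-")), len(s2) - len(s2.lstrip("-")))
    trail = max(len(s1) - len(s1.rstrip("-")), len(s2) - len(s2.rstrip("-")))
    end = len(s1) - trail
    cols = range(lead, end)
    matches = sum(1 for i in cols if s1[i] == s2[i] and s1[i] != "-")
    aligned_sites = end - lead
    if aligned_sites == 0:
        return 0.0, 0
    return 100.0 * matches / aligned_sites, aligned_sites


@dataclass(frozen=True)
class QueryHit:
    query_id: str
    hit_id: str
    hit_species: str
    percent_identity: float
    aligned_sites: int


def rank_hits(
    query: SequenceRecord,
    lib: ReferenceLibrary,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[QueryHit]:
    """Score the query against every reference; keep hits >= min_identity,
    sorted by identity desc, aligned sites desc, then hit id."""
    hits = []
    for ref in lib.reference_records():
        pid, sites = semiglobal_identity(query, ref)
        if pid >= min_identity:
            hits.append(QueryHit(query.id, ref.id, ref.species, pid, sites))
    return sorted(hits, key=lambda h: (-h.percent_identity, -h.aligned_sites, h.hit_id))


def adjudicate(
    query: SequenceRecord,
    hits: list[QueryHit],
    lookup: VernacularLookup,
) -> dict:
    """One market-report row: best hit vs the vernacular expectation.

    A query whose sequence is empty (or all gaps) is amplification_failed.
    A vernacular absent from the lookup, or documented with no scientific
    name, gives expected species "?" and status "unverifiable".
    """
    vern = query.vernacular or "?"
    expected = lookup.expected(vern) if query.vernacular else None
    expected_str = ";".join(sorted(expected)) if expected else "?"
    row = {
        "query_id": query.id,
        "vernacular": vern,
        "expected_species": expected_str,
        "best_hit_id": None,
        "best_hit_species": None,
        "percent_identity": np.nan,
        "status": None,
        "conservation_status": query.conservation_status,
    }
    if not query.sequence.replace("-", ""):
        row["status"] = "amplification_failed"
        return row
    if not hits:
        row["status"] = "no_hit"
        return row
    best = hits[0]
    row["best_hit_id"] = best.hit_id
    row["best_hit_species"] = best.hit_species
    row["percent_identity"] = best.percent_identity
    if not expected:
        row["status"] = "unverifiable"
    elif best.hit_species in expected:
        row["status"] = "match"
    else:
        row["status"] = "mismatch"
    return row


def market_report(
    queries: list[SequenceRecord],
    lib: ReferenceLibrary,
    lookup: VernacularLookup,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> pd.DataFrame:
    """Adjudicate every query; returns the market-report table."""
    rows = []
    for q in queries:
        hits = (
            rank_hits(q, lib, min_identity) if q.sequence.replace("-", "") else []
        )
        rows.append(adjudicate(q, hits, lookup))
    return pd.DataFrame(rows, columns=MARKET_COLUMNS)


def _is_threatened(status: object) -> bool:
    if not isinstance(status, str):
        return False
    return "vulnerable" in status.lower() or "(vu)" in status.lower()


def market_summary(report: pd.DataFrame) -> dict:
    """Counts and percentages over a market report.

    The match percentage uses ALL queries as the denominator, including
    amplification failures.  Threatened percentage counts Vulnerable-listed
    conservation statuses over all queries.
    """
    n = len(report)
    counts = {s: int((report["status"] == s).sum()) for s in MARKET_STATUSES} if n else {
        s: 0 for s in MARKET_STATUSES
    }
    n_failed = counts["amplification_failed"]
    n_threatened = (
        int(report["conservation_status"].map(_is_threatened).sum())
        if n and "conservation_status" in report
        else 0
    )
    return {
        "n_queries": n,
        "n_with_sequence": n - n_failed,
        "n_failed": n_failed,
        "n_match": counts["match"],
        "n_mismatch": counts["mismatch"],
        "n_unverifiable": counts["unverifiable"],
        "n_no_hit": counts["no_hit"],
        "match_pct": 100.0 * counts["match"] / n if n else 0.0,
        "match_pct_rounded": int(round(100.0 * counts["match"] / n)) if n else 0,
        "n_threatened": n_threatened,
        "threatened_pct": 100.0 * n_threatened / n if n else 0.0,
        "threatened_pct_rounded": int(round(100.0 * n_threatened / n)) if n else 0,
    }


def load_table3() -> pd.DataFrame:
    """Packaged muthi-market adjudication table (18 query samples).

    Transcribed bookkeeping of a published market survey: vernacular names,
    literature expectations, red-list status, BLAST similarity and verdict.
    Returned in market-report shape for :func:`market_summary`.
    """
    path = resources.files("barcodekit").joinpath("data/table3.tsv")
    with resources.as_file(path) as p:
        raw = pd.read_csv(p, sep="\t", dtype=str)
    status_map = {
        "True": "match",
        "False": "mismatch",
        "Amplification failed": "amplification_failed",
    }
    return pd.DataFrame(
        {
            "query_id": raw["row"],
            "vernacular": raw["market_name"],
            "expected_species": raw["expected_species"],
            "best_hit_id": None,
            "best_hit_species": None,
            "percent_identity": pd.to_numeric(raw["similarity_pct"], errors="coerce"),
            "status": raw["verdict"].map(status_map),
            "conservation_status": raw["iucn"],
        },
        columns=list(MARKET_COLUMNS),
    )
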