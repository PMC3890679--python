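"""Synthetic barcode libraries, degraded queries, and vernacular lookups.

Emulates the data structure of a medicinal-plant barcoding study: a
reference library of ~108 species (1-3 individuals each) whose
intraspecific divergence is far below the interspecific divergence, a set
of degraded market queries with known true species, and a vernacular-name
lookup containing deliberate mismatches.

Sequences evolve on a star phylogeny: one random root, one branch of
expected length ``inter_target/2`` substitutions/site to each species
ancestor, and a branch of ``intra_target/2`` to each individual, under a
Kimura two-parameter process with transition/transversion rate ratio
``kappa``.  Branch lengths are expected K2P distances, so realized
distances are directly comparable to the generator's targets.

Degradation emulates processed market material: a contiguous terminal
fraction of the alignment is truncated (replaced by gaps, preserving
alignment coordinates) and random positions are masked to N.  A query left
with fewer than 50 bases is marked amplification-failed, mirroring PCR
failure on badly preserved tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    UNKNOWN,
    BarcodekitError,
    ReferenceLibrary,
    SequenceRecord,
    VernacularLookup,
)

logger = logging.getLogger("barcodekit")

_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)

#: Minimum bases for a query to count as amplified.
MIN_AMPLICON = 50


@dataclass(frozen=True)
class Degradation:
    """Query-degradation settings (fractions in [0, 1])."""

    truncate_frac: float = 0.3
    n_mask_frac: float = 0.02
    mislabel_rate: float = 5 / 18

    def __post_init__(self) -> None:
        for name in ("truncate_frac", "n_mask_frac", "mislabel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BarcodekitError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic locus library."""

    n_species: int = 108
    individuals_per_species: int | tuple[int, int] = (1, 3)
    seq_length: int = 600
    inter_target: float = 0.10
    intra_target: float = 0.003
    kappa: float = 2.0
    seed: int = 0
    locus: str = "rbcLa"
    degradation: Degradation = field(default_factory=Degradation)

    def __post_init__(self) -> None:
        if not 0.0 <= self.intra_target < self.inter_target:
            raise BarcodekitError("require 0 <= intra_target < inter_target")
        if self.kappa <= 0:
            raise BarcodekitError("kappa must be positive")


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each-transversion) site probabilities after a
    branch of expected length d substitutions/site at ts/tv rate ratio kappa."""
    bt = d / (kappa + 2.0)  # beta * t
    at = kappa * bt  # alpha * t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    p_tv = 0.25 - 0.25 * np.exp(-4.0 * bt)  # each of the two transversions
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence (A=0 G=1 C=2 T=3) along one branch."""
    if d == 0.0:
        return seq.copy()
    p_same, p_ts, p_tv = _k2p_site_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[ts] ^= 1  # transition partner shares the purine/pyrimidine bit
    out[tv1] ^= 2
    out[tv2] ^= 3
    return out


def _decode(enc: np.ndarray) -> str:
    return _BASES[enc].tobytes().decode("ascii")


@dataclass
class TruthTable:
    """Ground truth for generated records and (later) queries."""

    records: pd.DataFrame
    queries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "query_id",
                "source_id",
                "true_species",
                "failed",
                "truncated_sites",
                "masked_sites",
                "vernacular",
                "mislabeled",
            ]
        )
    )


def species_structure(cfg: SyntheticConfig) -> list[tuple[str, int]]:
    """Deterministic (species name, n individuals) draw for a config."""
    rng = np.random.default_rng(cfg.seed)
    structure = []
    for s in range(cfg.n_species):
        name = f"Species_{s + 1:03d}"
        ips = cfg.individuals_per_species
        if isinstance(ips, int):
            k = ips
        else:
            k = int(rng.integers(ips[0], ips[1] + 1))
        structure.append((name, k))
    return structure


def generate_library(
    cfg: SyntheticConfig,
    structure: Sequence[tuple[str, int]] | None = None,
) -> tuple[ReferenceLibrary, TruthTable]:
    """Simulate a reference library; deterministic given cfg.seed.

    ``structure`` optionally fixes the (species, n individuals) layout so
    that several loci can be generated for the same specimen panel.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if structure is None:
        structure = species_structure(cfg)
    root = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)
    records, truth_rows = [], []
    for species, k in structure:
        ancestor = _evolve(root, cfg.inter_target / 2.0, cfg.kappa, rng)
        for ind in range(1, k + 1):
            seq = _evolve(ancestor, cfg.intra_target / 2.0, cfg.kappa, rng)
            rid = f"{species}_{ind}"
            records.append(
                SequenceRecord(
                    id=rid, species=species, locus=cfg.locus, sequence=_decode(seq)
                )
            )
            truth_rows.append({"id": rid, "species": species, "locus": cfg.locus})
    lib = ReferenceLibrary(locus=cfg.locus, records=tuple(records))
    return lib, TruthTable(records=pd.DataFrame(truth_rows))


def degrade_query(
    record: SequenceRecord, degradation: Degradation, seed: int, force_fail: bool = False
) -> tuple[SequenceRecord, dict]:
    """Degrade one reference record into an unknown-species query.

    Truncation removes a contiguous terminal fraction (5' or 3' end chosen
    at random) by gapping it out, keeping alignment coordinates; masking
    replaces random surviving positions with N.  Fewer than 50 surviving
    bases means amplification failure: the query carries no sequence.
    """
    rng = np.random.default_rng(seed)
    L = len(record)
    chars = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8).copy()
    truncate_frac = 1.0 if force_fail else degradation.truncate_frac
    n_trunc = int(round(truncate_frac * L))
    if n_trunc:
        if rng.random() < 0.5:
            chars[:n_trunc] = ord("-")
        else:
            chars[L - n_trunc :] = ord("-")
    alive = np.flatnonzero(chars != ord("-"))
    n_mask = int(round(degradation.n_mask_frac * alive.size))
    if n_mask:
        masked = rng.choice(alive, size=n_mask, replace=False)
        chars[masked] = ord("N")
    n_bases = int((chars != ord("-")).sum())
    failed = n_bases < MIN_AMPLICON
    seq = "-" * L if failed else chars.tobytes().decode("ascii")
    query = replace(
        record,
        id=f"Q_{record.id}",
        species=UNKNOWN,
        source="query",
        sequence=seq,
        vernacular=None,
    )
    info = {
        "query_id": query.id,
        "source_id": record.id,
        "true_species": record.species,
        "failed": failed,
        "truncated_sites": n_trunc,
        "masked_sites": 0 if failed else n_mask,
    }
    return query, info


def make_queries(
    lib: ReferenceLibrary,
    n_queries: int,
    degradation: Degradation,
    seed: int,
    n_failures: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw query sources from distinct species and degrade them.

    The first ``n_failures`` drawn queries are truncated past the 50-base
    amplification limit, mirroring PCR failures on the worst material.
    """
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[SequenceRecord]] = {}
    for r in lib.reference_records():
        by_species.setdefault(r.species, []).append(r)
    species_pool = sorted(by_species)
    if n_queries > len(species_pool):
        raise BarcodekitError("more queries requested than available species")
    chosen = rng.choice(len(species_pool), size=n_queries, replace=False)
    queries, rows = [], []
    for k, idx in enumerate(chosen):
        candidates = by_species[species_pool[idx]]
        source = candidates[int(rng.integers(0, len(candidates)))]
        q, info = degrade_query(
            source, degradation, seed=seed + 1000 + k, force_fail=k < n_failures
        )
        queries.append(q)
        rows.append(info)
    return queries, pd.DataFrame(rows)


def generate_lookup(
    query_truth: pd.DataFrame,
    species: Sequence[str],
    mislabel_rate: float,
    seed: int,
) -> tuple[VernacularLookup, list[str], pd.DataFrame]:
    """Invent one vernacular per species and assign names to queries.

    A ``round(mislabel_rate * n_queries)``-sized subset of queries receives
    the vernacular of a random *other* species — the deliberate mismatches
    a market survey encounters.  Returns (lookup, per-query vernaculars,
    updated truth table with `vernacular` and `mislabeled` columns).
    """
    rng = np.random.default_rng(seed)
    species = sorted(set(species))
    vern_of = {sp: f"vern-{i + 1:03d}" for i, sp in enumerate(species)}
    lookup = VernacularLookup()
    for sp, v in vern_of.items():
        lookup.add(v, [sp])
    n = len(query_truth)
    n_mislabel = int(round(mislabel_rate * n))
    # mislabel only amplifiable queries: a wrong name on a sample with no
    # sequence is unobservable downstream
    if "failed" in query_truth:
        candidates = np.flatnonzero(~query_truth["failed"].to_numpy(dtype=bool))
    else:
        candidates = np.arange(n)
    if n_mislabel > candidates.size:
        raise BarcodekitError("more mislabels requested than amplifiable queries")
    mislabeled_idx = set(
        rng.choice(candidates, size=n_mislabel, replace=False).tolist()
        if n_mislabel
        else []
    )
    vernaculars, flags = [], []
    for i, sp in enumerate(query_truth["true_species"]):
        if i in mislabeled_idx:
            others = [s for s in species if s != sp]
            sp_assigned = others[int(rng.integers(0, len(others)))]
            vernaculars.append(vern_of[sp_assigned])
            flags.append(True)
        else:
            vernaculars.append(vern_of[sp])
            flags.append(False)
    truth = query_truth.copy()
    truth["vernacular"] = vernaculars
    truth["mislabeled"] = flags
    return lookup, vernaculars, truth


def attach_vernaculars(
    queries: list[SequenceRecord], vernaculars: Sequence[str]
) -> list[SequenceRecord]:
    """Return query records annotated with their assigned vernacular names."""
    if len(queries) != len(vernaculars):
        raise BarcodekitError("one vernacular per query required")
    return [replace(q, vernacular=v) for q, v in zip(queries, vernaculars)]
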