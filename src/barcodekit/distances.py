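"""Pairwise genetic distances under the Kimura two-parameter model.

The K2P distance corrects the observed proportions of transitions (P) and
transversions (Q) for multiple hits:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Columns with a gap, an N, or any IUPAC ambiguity code in either sequence of
a pair are excluded (pairwise deletion), so degraded query sequences simply
contribute fewer comparable sites rather than biased distances.  Pairs with
fewer than ``min_overlap`` comparable sites, and pairs past the saturation
boundary of the logarithm, yield MISSING (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import BarcodekitError, ReferenceLibrary, SequenceRecord

#: Minimum comparable sites for a pair before its distance is MISSING.
DEFAULT_MIN_OVERLAP = 100

#: MISSING distance marker.
MISSING = float("nan")

# Encoding: A=0, G=1, C=2, T=3 -- purines and pyrimidines share the high
# bit, so a substitution is a transition iff (a >> 1) == (b >> 1).
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _base in enumerate("AGCT"):
    _ENC[ord(_base)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as uint8: A=0 G=1 C=2 T=3, anything else 255."""
    return _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseCounts:
    """Site-pattern counts for one aligned pair after pairwise deletion."""

    n_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if min(self.n_sites, self.transitions, self.transversions) < 0:
            raise BarcodekitError("site counts must be non-negative")
        if self.transitions + self.transversions > self.n_sites:
            raise BarcodekitError("differences cannot exceed comparable sites")


def count_site_patterns(a: SequenceRecord, b: SequenceRecord) -> PairwiseCounts:
    """Count comparable sites, transitions and transversions for a pair."""
    if len(a) != len(b):
        raise BarcodekitError(
            f"unequal aligned lengths: {a.id!r} ({len(a)}) vs {b.id!r} ({len(b)})"
        )
    ea, eb = encode(a.sequence), encode(b.sequence)
    valid = (ea < 4) & (eb < 4)
    diff = valid & (ea != eb)
    ts = diff & ((ea >> 1) == (eb >> 1))
    return PairwiseCounts(
        n_sites=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
    )


def k2p_distance(c: PairwiseCounts, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Kimura two-parameter distance, or MISSING below min_overlap / at
    saturation (1-2P-Q <= 0 or 1-2Q <= 0)."""
    if c.n_sites < min_overlap:
        return MISSING
    P = c.transitions / c.n_sites
    Q = c.transversions / c.n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return MISSING
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(c: PairwiseCounts, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Uncorrected proportion of differing comparable sites."""
    if c.n_sites < min_overlap:
        return MISSING
    return (c.transitions + c.transversions) / c.n_sites


class DistanceMatrix:
    """Square symmetric distance container with MISSING (NaN) semantics."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise BarcodekitError("distance matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(values), np.nan_to_num(values.T)):
            raise BarcodekitError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0.0):
            raise BarcodekitError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                raise BarcodekitError("distances must be non-negative")
        self.labels = list(labels)
        self.values = values
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self._index[pair[0]], self._index[pair[1]]
        return float(self.values[i, j])

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(len(self), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def is_complete(self) -> bool:
        return self.n_missing_pairs == 0

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle values, MISSING included."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(list(df.columns), df.to_numpy(dtype=float))


def _pair_distance_fn(model: str) -> Callable[[PairwiseCounts, int], float]:
    if model == "k2p":
        return k2p_distance
    if model == "p":
        return p_distance
    raise BarcodekitError(f"unknown distance model {model!r}")


def build_distance_matrix(
    lib: ReferenceLibrary,
    model: str = "k2p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs distance matrix over the library under ``model``.

    Vectorised over alignment columns; equivalent to applying
    ``k2p_distance(count_site_patterns(a, b))`` to every pair.
    """
    _pair_distance_fn(model)  # validate early
    enc = np.vstack([encode(r.sequence) for r in lib.records])
    return matrix_from_encoded(enc, lib.ids, model=model, min_overlap=min_overlap)


def matrix_from_encoded(
    enc: np.ndarray,
    labels: Sequence[str],
    model: str = "k2p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Distance matrix from pre-encoded sequences (see :func:`encode`).

    Exposed separately so bootstrap resampling can re-use one encoding.
    """
    n = enc.shape[0]
    valid = enc < 4
    hi = enc >> 1
    n_sites = np.zeros((n, n))
    ts = np.zeros((n, n))
    tv = np.zeros((n, n))
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        d = v & (enc[i] != enc[i + 1 :])
        t = d & (hi[i] == hi[i + 1 :])
        n_sites[i, i + 1 :] = v.sum(axis=1)
        ts[i, i + 1 :] = t.sum(axis=1)
        tv[i, i + 1 :] = d.sum(axis=1) - t.sum(axis=1)
    n_sites += n_sites.T
    ts += ts.T
    tv += tv.T
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / n_sites
        Q = tv / n_sites
        if model == "k2p":
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            vals = np.where(
                (w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan
            )
        else:
            vals = P + Q
    vals = np.where(n_sites >= min_overlap, vals, np.nan)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(labels), vals)


def tajima_K(m: DistanceMatrix) -> float:
    """Mean number of substitutions per nucleotide over all unordered pairs.

    Computed on a p-distance matrix (substitutions per site taken
    literally, uncorrected); MISSING pairs are skipped.
    """
    upper = m.upper_triangle()
    finite = upper[~np.isnan(upper)]
    if finite.size == 0:
        raise BarcodekitError("tajima_K: no non-MISSING pairwise distances")
    return float(finite.mean())
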