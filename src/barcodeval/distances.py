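"""Kimura two-parameter distances, group summaries, and the barcoding gap.

The K2P distance between two aligned sequences is computed over the columns
where both carry an unambiguous base (pairwise deletion).  With P and Q the
transition and transversion proportions over those columns,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

A pair is *invalid* (carries no distance) when fewer than ``min_overlap``
columns are comparable or either logarithm argument is non-positive
(saturation).  Invalid pairs are excluded from all summaries and their count
is reported rather than silently propagating NaN.

Group summaries follow barcoding conventions:

* mean interspecific distance — average over all valid between-species pairs;
* mean intraspecific distance — average over all valid within-species pairs,
  pooled across species;
* theta — per-species mean intraspecific distance, averaged across species;
* coalescence depth — per-species maximum intraspecific distance, averaged
  across species.

Standard errors are analytic over pairs (species means for theta/depth); an
approximation, since pairwise distances sharing a sample are not independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import AlignmentError, DistanceError, GapUndefinedError
from .io import LabeledAlignment, encode_sequence

DEFAULT_MIN_OVERLAP = 50
DEFAULT_BIN_WIDTH = 0.005


# ---------------------------------------------------------------------------
# pairwise K2P
# ---------------------------------------------------------------------------

def _k2p_from_counts(n: float, ts: float, tv: float, min_overlap: int):
    if n < min_overlap:
        return math.nan, False
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, False
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), True


def k2p_distance(
    seq1: str | np.ndarray,
    seq2: str | np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, bool]:
    """K2P distance and validity flag for one pair of aligned sequences.

    Accepts raw strings or int8-encoded arrays.  Columns where either
    sequence is a gap or an ambiguity code are ignored (pairwise deletion).
    """
    a = encode_sequence(seq1) if isinstance(seq1, str) else np.asarray(seq1)
    b = encode_sequence(seq2) if isinstance(seq2, str) else np.asarray(seq2)
    if a.shape != b.shape:
        raise AlignmentError(
            f"sequence length mismatch: {a.shape[0]} != {b.shape[0]}"
        )
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    diff = both & (a != b)
    # transitions are the unequal pairs with equal parity (A<->G, C<->T)
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(n, ts, tv, min_overlap)


def _pair_count_matrices(enc: np.ndarray):
    """Vectorised (n, ts, tv) matrices over all sequence pairs."""
    a = enc[:, None, :]
    b = enc[None, :, :]
    both = (a >= 0) & (b >= 0)
    diff = both & (a != b)
    ts = (diff & ((a & 1) == (b & 1))).sum(axis=2)
    tv = diff.sum(axis=2) - ts
    return both.sum(axis=2), ts, tv


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair validity flags."""

    sample_ids: list[str]
    d: np.ndarray
    valid: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.sample_ids)}

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index(self, sample_id: str) -> int:
        return self._index[sample_id]

    def get(self, a: str, b: str) -> tuple[float, bool]:
        i, j = self._index[a], self._index[b]
        return float(self.d[i, j]), bool(self.valid[i, j])

    def n_invalid_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int((~self.valid[iu]).sum())


def pairwise_matrix(
    aln: LabeledAlignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs K2P matrix; diagonal is 0/valid by definition."""
    if aln.n_samples < 2:
        raise DistanceError(
            f"{aln.marker_name}: need >= 2 samples for a distance matrix"
        )
    enc = aln.encoded()
    n_mat, ts_mat, tv_mat = _pair_count_matrices(enc)
    m = aln.n_samples
    d = np.zeros((m, m))
    valid = np.ones((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            dij, ok = _k2p_from_counts(
                n_mat[i, j], ts_mat[i, j], tv_mat[i, j], min_overlap
            )
            d[i, j] = d[j, i] = 0.0 if not ok else dij
            valid[i, j] = valid[j, i] = ok
    return DistanceMatrix(list(aln.sample_ids), d, valid, min_overlap)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def _pair_values(dm: DistanceMatrix, labels: Mapping[str, str], kind: str):
    """Valid pair distances of one kind: 'intra' or 'inter'."""
    vals, pairs = [], []
    ids = dm.sample_ids
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            if not dm.valid[i, j]:
                continue
            same = labels[ids[i]] == labels[ids[j]]
            if (kind == "intra") == same:
                vals.append(float(dm.d[i, j]))
                pairs.append((ids[i], ids[j]))
    return vals, pairs


def _mean_se(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, se


@dataclass
class GroupDistanceSummary:
    mean_inter: float
    se_inter: float
    mean_intra: float
    se_intra: float
    theta: float
    se_theta: float
    coalescence_depth: float
    se_depth: float
    n_inter_pairs: int
    n_intra_pairs: int
    n_invalid_pairs: int
    per_species_theta: dict[str, float] = field(default_factory=dict)
    per_species_depth: dict[str, float] = field(default_factory=dict)


def group_distance_summary(
    dm: DistanceMatrix, labels: Mapping[str, str]
) -> GroupDistanceSummary:
    """Inter/intra means, theta and coalescence depth with standard errors.

    Species with fewer than two samples (or no valid intraspecific pair)
    contribute nothing to the intraspecific metrics.
    """
    species = sorted({labels[sid] for sid in dm.sample_ids})
    if len(species) < 2:
        raise DistanceError("group summary needs >= 2 species")
    inter_vals, _ = _pair_values(dm, labels, "inter")
    if not inter_vals:
        raise DistanceError("no valid interspecific pair")
    intra_vals, intra_pairs = _pair_values(dm, labels, "intra")

    mean_inter, se_inter = _mean_se(inter_vals)
    if intra_vals:
        mean_intra, se_intra = _mean_se(intra_vals)
    else:
        mean_intra, se_intra = math.nan, math.nan

    sp_theta: dict[str, float] = {}
    sp_depth: dict[str, float] = {}
    for sp in species:
        vals = [
            v
            for v, (a, b) in zip(intra_vals, intra_pairs)
            if labels[a] == sp
        ]
        if vals:
            sp_theta[sp] = float(np.mean(vals))
            sp_depth[sp] = float(np.max(vals))
    if sp_theta:
        theta, se_theta = _mean_se(list(sp_theta.values()))
        depth, se_depth = _mean_se(list(sp_depth.values()))
    else:
        theta = se_theta = depth = se_depth = math.nan

    return GroupDistanceSummary(
        mean_inter=mean_inter,
        se_inter=se_inter,
        mean_intra=mean_intra,
        se_intra=se_intra,
        theta=theta,
        se_theta=se_theta,
        coalescence_depth=depth,
        se_depth=se_depth,
        n_inter_pairs=len(inter_vals),
        n_intra_pairs=len(intra_vals),
        n_invalid_pairs=dm.n_invalid_pairs(),
        per_species_theta=sp_theta,
        per_species_depth=sp_depth,
    )


# ---------------------------------------------------------------------------
# barcoding gap
# ---------------------------------------------------------------------------

@dataclass
class GapAssessment:
    intra_histogram: list[tuple[float, int]]
    inter_histogram: list[tuple[float, int]]
    max_intra: float
    min_inter: float
    gap_present: bool
    overlap_interval: tuple[float, float] | None
    bin_width: float


def _histogram(values, bin_width: float) -> list[tuple[float, int]]:
    """Left-closed bins [k*w, (k+1)*w) starting at 0."""
    idx = np.floor(np.asarray(values, dtype=float) / bin_width).astype(int)
    top = int(idx.max())
    counts = np.bincount(idx, minlength=top + 1)
    return [(round(k * bin_width, 10), int(c)) for k, c in enumerate(counts)]


def barcoding_gap(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> GapAssessment:
    """Histogram both distance classes and test min_inter > max_intra."""
    intra_vals, _ = _pair_values(dm, labels, "intra")
    inter_vals, _ = _pair_values(dm, labels, "inter")
    if not intra_vals:
        raise GapUndefinedError(
            "barcoding gap undefined: no valid intraspecific pairs "
            "(every species has a single sample or all pairs are invalid)"
        )
    if not inter_vals:
        raise GapUndefinedError(
            "barcoding gap undefined: no valid interspecific pairs"
        )
    max_intra = float(max(intra_vals))
    min_inter = float(min(inter_vals))
    gap = min_inter > max_intra
    return GapAssessment(
        intra_histogram=_histogram(intra_vals, bin_width),
        inter_histogram=_histogram(inter_vals, bin_width),
        max_intra=max_intra,
        min_inter=min_inter,
        gap_present=gap,
        overlap_interval=None if gap else (min_inter, max_intra),
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix; invalid pairs written as -1.0."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, sid in enumerate(dm.sample_ids):
            cells = [
                f"{dm.d[i, j]:.6f}" if dm.valid[i, j] else "-1.000000"
                for j in range(dm.n)
            ]
            fh.write(f"{sid:<10s} " + " ".join(cells) + "\n")
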