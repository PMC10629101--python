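"""Best-match identification against a local labeled reference library.

Queries are scored against every reference by global pairwise alignment
percent identity (match +1, mismatch -1, gap -2; end-gap columns are
excluded from the identity denominator).  The top hit set (exact identity ties, or within an
optional ``tie_margin``) determines the call at species and genus level:

* success   — every top hit belongs to the query's true taxon;
* error     — no top hit belongs to the true taxon;
* ambiguous — top hits mix the true taxon with others.

Calls are made only when the top identity reaches ``min_identity``.
Evaluation mode is leave-one-out over the library itself: each sequence is
queried against the remaining references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .errors import IdentificationError
from .io import LabeledAlignment

DEFAULT_MIN_IDENTITY = 97.0


@dataclass(frozen=True)
class Reference:
    ref_id: str
    species: str
    genus: str
    sequence: str


@dataclass(frozen=True)
class Hit:
    ref_id: str
    species: str
    genus: str
    identity: float


@dataclass
class IdentificationResult:
    query_id: str
    true_species: str
    true_genus: str
    best_hits: list[Hit]  # identity-descending; the tied top set
    species_call: str | None  # success | error | ambiguous; None below threshold
    genus_call: str | None
    passed_threshold: bool
    top_identity: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # end gaps are penalised like internal gaps (true global alignment, so a
    # short spurious overlap cannot win); they are excluded again from the
    # identity denominator when scoring
    return aligner


_ALIGNER = _make_aligner()


def _degap(seq: str) -> str:
    return seq.replace("-", "")


def percent_identity(
    query: str, reference: str, orient: bool = False
) -> float:
    """Percent identity over a global alignment, end-gap columns excluded.

    With ``orient=True`` the reverse complement of the query is also tried
    and the higher identity returned.
    """
    q = _degap(query.upper())
    r = _degap(reference.upper())
    if not q or not r:
        raise IdentificationError("empty sequence in identity computation")
    ident = _identity_one(q, r)
    if orient:
        rc = str(Seq(q).reverse_complement())
        ident = max(ident, _identity_one(rc, r))
    return ident


def _identity_one(q: str, r: str) -> float:
    aln = _ALIGNER.align(q, r)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ncols = len(s1)
    # trim end-gap runs (only one string can have a gap run at each end)
    start = 0
    while start < ncols and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    end = ncols
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    core = end - start
    if core <= 0:
        return 0.0
    matches = sum(
        1 for i in range(start, end) if s1[i] == s2[i] and s1[i] != "-"
    )
    return 100.0 * matches / core


def best_match_identify(
    query_id: str,
    sequence: str,
    true_species: str,
    true_genus: str,
    library: Sequence[Reference],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    tie_margin: float = 0.0,
    orient: bool = False,
) -> IdentificationResult:
    """Classify one query against the reference library."""
    if not library:
        raise IdentificationError("empty reference library")
    hits = [
        Hit(
            ref.ref_id,
            ref.species,
            ref.genus,
            percent_identity(sequence, ref.sequence, orient=orient),
        )
        for ref in library
    ]
    return _result_from_hits(
        query_id, true_species, true_genus, hits, min_identity, tie_margin
    )


def _result_from_hits(
    query_id, true_species, true_genus, hits, min_identity, tie_margin
) -> IdentificationResult:
    hits = sorted(hits, key=lambda h: (-h.identity, h.ref_id))
    top = hits[0].identity
    top_hits = [h for h in hits if h.identity >= top - tie_margin]
    passed = top >= min_identity

    def call(level: str) -> str:
        truth = true_species if level == "species" else true_genus
        labels = {
            (h.species if level == "species" else h.genus) for h in top_hits
        }
        if labels == {truth}:
            return "success"
        if truth in labels:
            return "ambiguous"
        return "error"

    return IdentificationResult(
        query_id=query_id,
        true_species=true_species,
        true_genus=true_genus,
        best_hits=top_hits,
        species_call=call("species") if passed else None,
        genus_call=call("genus") if passed else None,
        passed_threshold=passed,
        top_identity=top,
    )


# ---------------------------------------------------------------------------
# library-level evaluation
# ---------------------------------------------------------------------------

def library_from_alignment(aln: LabeledAlignment) -> list[Reference]:
    """Degapped references from an alignment's rows."""
    return [
        Reference(s.sample_id, s.species, s.genus, _degap(s.sequence))
        for s in aln.samples
    ]


def identity_matrix(
    library: Sequence[Reference], orient: bool = False
) -> np.ndarray:
    """Symmetric all-vs-all percent-identity matrix over the library."""
    n = len(library)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(
                library[i].sequence, library[j].sequence, orient=orient
            )
            m[i, j] = m[j, i] = ident
    return m


def loo_identify(
    library: Sequence[Reference],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    tie_margin: float = 0.0,
    orient: bool = False,
    exclude_conspecific: bool = False,
    _identity: np.ndarray | None = None,
) -> list[IdentificationResult]:
    """Leave-one-out best-match evaluation over the library.

    With ``exclude_conspecific=True`` each query is matched only against
    references of *other* species (degradation experiment).
    """
    if len(library) < 2:
        raise IdentificationError("library needs >= 2 references for LOO")
    ident = identity_matrix(library, orient=orient) if _identity is None else _identity
    results = []
    for i, query in enumerate(library):
        hits = [
            Hit(ref.ref_id, ref.species, ref.genus, float(ident[i, j]))
            for j, ref in enumerate(library)
            if j != i
            and not (exclude_conspecific and ref.species == query.species)
        ]
        if not hits:
            raise IdentificationError(
                f"no references left for query {query.ref_id!r}"
            )
        results.append(
            _result_from_hits(
                query.ref_id,
                query.species,
                query.genus,
                hits,
                min_identity,
                tie_margin,
            )
        )
    return results


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def _cell(x: int, n: int) -> str:
    if n == 0:
        return "0 (0/0)"
    if x == 0:
        return f"0 (0/{n})"
    pct = 100.0 * x / n
    pct_str = f"{pct:.0f}%" if float(pct).is_integer() else f"{pct:.1f}%"
    return f"{pct_str} ({x}/{n})"


def summarize_identification(
    results: Sequence[IdentificationResult],
) -> dict:
    """Success/error/ambiguous rates with ``x/n`` counts at both levels."""
    passed = [r for r in results if r.passed_threshold]
    if not passed:
        raise IdentificationError("no query passed the identity threshold")
    n = len(passed)
    out: dict = {"n": n, "n_below_threshold": len(results) - n}
    for level in ("species", "genus"):
        counts = {"success": 0, "error": 0, "ambiguous": 0}
        for r in passed:
            counts[getattr(r, f"{level}_call")] += 1
        for outcome, x in counts.items():
            out[f"{level}_{outcome}"] = x
            out[f"{level}_{outcome}_cell"] = _cell(x, n)
    return out
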