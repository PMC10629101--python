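"""Character-based species diagnosis: conjunctive rule induction and scoring.

A diagnostic rule is a conjunction of (1-based alignment column, nucleotide
state) clauses implying one species.  A rule is *pure* on a training set
when every sample of the target species satisfies all clauses and no sample
of the other species does.  Gaps and ambiguity codes never satisfy a clause.

Induction searches single columns first; when no single pure column covers a
class it searches conjunctions of up to ``max_clauses`` columns (exhaustive
for pairs, greedy set cover beyond).  Returned rules prefer fewest clauses,
then lowest positions.

Evaluation reports cc / wc / nc (correctly / wrongly / not classified)
percentages per species, by leave-one-out cross-validation (default) or by
resubstitution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import RuleError
from .io import CODE_BASE, LabeledAlignment, encode_sequence


@dataclass(frozen=True)
class DiagnosticRule:
    """Conjunction of (position, state) clauses implying ``target_species``."""

    target_species: str
    clauses: tuple[tuple[int, str], ...]  # 1-based positions, state in ACGT
    support: int  # training samples of the target species matched

    def matches(self, sequence: str | np.ndarray) -> bool:
        enc = (
            encode_sequence(sequence)
            if isinstance(sequence, str)
            else np.asarray(sequence)
        )
        for pos, state in self.clauses:
            if enc[pos - 1] != CODE_BASE.index(state):
                return False
        return True

    def formula(self) -> str:
        return " AND ".join(f"{pos} = {state}" for pos, state in self.clauses)


@dataclass(frozen=True)
class RuleEvaluation:
    cc: float  # percent correctly classified
    wc: float  # percent wrongly classified (wrong species or conflict)
    nc: float  # percent not classified
    n: int


class RuleCall(NamedTuple):
    status: str  # "classified" | "unclassified" | "conflict"
    species: str | None


UNCLASSIFIED = RuleCall("unclassified", None)
CONFLICT = RuleCall("conflict", None)


# ---------------------------------------------------------------------------
# induction
# ---------------------------------------------------------------------------

def _class_masks(aln: LabeledAlignment):
    species = aln.species_set
    if len(species) != 2:
        raise RuleError(
            f"rule induction supports exactly 2 species, got {len(species)}"
        )
    labels = np.asarray(aln.species_labels)
    return species, [labels == sp for sp in species]


def _candidate_clauses(enc: np.ndarray, mask: np.ndarray):
    """Columns where the target class is uniform and unambiguous.

    Returns (positions0, states, omatch) where omatch[r, k] tells whether
    non-target row r satisfies candidate clause k.
    """
    s_rows = enc[mask]
    o_rows = enc[~mask]
    uniform = (s_rows == s_rows[0]).all(axis=0) & (s_rows[0] >= 0)
    cols = np.where(uniform)[0]
    states = s_rows[0, cols]
    omatch = o_rows[:, cols] == states[None, :]
    return cols, states, omatch


def _induce_for_class(
    enc: np.ndarray, mask: np.ndarray, max_clauses: int
) -> tuple[tuple[int, str], ...] | None:
    cols, states, omatch = _candidate_clauses(enc, mask)
    if len(cols) == 0:
        return None
    viol = omatch.sum(axis=0)
    pure = np.where(viol == 0)[0]
    if len(pure) > 0:
        k = int(pure[0])  # cols ascending -> lowest position
        return ((int(cols[k]) + 1, CODE_BASE[states[k]]),)
    if max_clauses < 2:
        return None

    # clauses matching every non-target row can never help a conjunction
    useful = np.where(viol < omatch.shape[0])[0]
    if len(useful) < 2:
        return None
    m = omatch[:, useful]
    if max_clauses == 2 or len(useful) <= 2:
        overlap = m.T.astype(np.int32) @ m.astype(np.int32)
        for a in range(len(useful)):
            row = np.where(overlap[a, a + 1 :] == 0)[0]
            if len(row) > 0:
                b = a + 1 + int(row[0])
                ka, kb = useful[a], useful[b]
                return (
                    (int(cols[ka]) + 1, CODE_BASE[states[ka]]),
                    (int(cols[kb]) + 1, CODE_BASE[states[kb]]),
                )
        return None

    # greedy set cover of non-target exclusions for larger budgets
    remaining = np.ones(m.shape[0], dtype=bool)
    available = np.ones(m.shape[1], dtype=bool)
    chosen: list[int] = []
    for _ in range(max_clauses):
        scores = m[remaining].sum(axis=0).astype(float)
        scores[~available] = np.inf
        best = int(np.argmin(scores))  # ties -> lowest position
        chosen.append(best)
        available[best] = False
        remaining &= m[:, best]
        if not remaining.any():
            return tuple(
                (int(cols[useful[k]]) + 1, CODE_BASE[states[useful[k]]])
                for k in sorted(chosen)
            )
    return None


def induce_rules(
    aln: LabeledAlignment, max_clauses: int = 2
) -> list[DiagnosticRule]:
    """One minimal pure rule per species, when one exists.

    A class with no pure rule at the clause budget yields no entry (reported
    by the caller, not an error).
    """
    species, masks = _class_masks(aln)
    enc = aln.encoded()
    out = []
    for sp, mask in zip(species, masks):
        if mask.sum() == 0 or (~mask).sum() == 0:
            continue
        clauses = _induce_for_class(enc, mask, max_clauses)
        if clauses is not None:
            out.append(DiagnosticRule(sp, clauses, support=int(mask.sum())))
    return out


def single_site_diagnostics(
    aln: LabeledAlignment,
) -> dict[str, list[DiagnosticRule]]:
    """All pure single-column rules per species (alternative disjuncts)."""
    species, masks = _class_masks(aln)
    enc = aln.encoded()
    out: dict[str, list[DiagnosticRule]] = {}
    for sp, mask in zip(species, masks):
        cols, states, omatch = _candidate_clauses(enc, mask)
        pure = np.where(omatch.sum(axis=0) == 0)[0]
        out[sp] = [
            DiagnosticRule(
                sp,
                ((int(cols[k]) + 1, CODE_BASE[states[k]]),),
                support=int(mask.sum()),
            )
            for k in pure
        ]
    return out


# ---------------------------------------------------------------------------
# classification and evaluation
# ---------------------------------------------------------------------------

def classify_with_rules(
    sequence: str | np.ndarray, rules: Sequence[DiagnosticRule]
) -> RuleCall:
    """Apply rules to one sequence; conflicts across species count as wc."""
    matched = {r.target_species for r in rules if r.matches(sequence)}
    if not matched:
        return UNCLASSIFIED
    if len(matched) > 1:
        return CONFLICT
    return RuleCall("classified", next(iter(matched)))


def evaluate_rules(
    aln: LabeledAlignment,
    max_clauses: int = 2,
    scheme: str = "loo",
) -> dict[str, RuleEvaluation]:
    """cc/wc/nc percentages per species.

    ``loo`` re-induces rules with each sample held out and classifies the
    held-out sample; ``resubstitution`` induces once on the full alignment.
    When a hold-out leaves a class empty (single-sample class), no rules can
    be induced and the held-out sample counts as not classified.
    """
    species, _ = _class_masks(aln)
    calls: list[tuple[str, RuleCall]] = []
    if scheme == "resubstitution":
        rules = induce_rules(aln, max_clauses)
        for s in aln.samples:
            calls.append((s.species, classify_with_rules(s.sequence, rules)))
    elif scheme == "loo":
        for s in aln.samples:
            training = aln.drop(s.sample_id)
            if len(set(training.species_labels)) < 2:
                calls.append((s.species, UNCLASSIFIED))
                continue
            rules = induce_rules(training, max_clauses)
            calls.append((s.species, classify_with_rules(s.sequence, rules)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    out: dict[str, RuleEvaluation] = {}
    for sp in species:
        mine = [c for true_sp, c in calls if true_sp == sp]
        n = len(mine)
        cc = sum(c.status == "classified" and c.species == sp for c in mine)
        nc = sum(c.status == "unclassified" for c in mine)
        wc = n - cc - nc  # wrong species or conflict
        out[sp] = RuleEvaluation(
            cc=100.0 * cc / n, wc=100.0 * wc / n, nc=100.0 * nc / n, n=n
        )
    return out
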