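"""Per-marker sequence characteristics: site classes and GC content.

Site classification uses only unambiguous bases {A,C,G,T} per column:

* columns with fewer than two usable rows are uncounted;
* conserved  — exactly one state among the usable rows;
* variable   — two or more states;
* parsimony-informative — at least two states each present in >= 2 rows;
* singleton  — variable but not informative.

GC content is pooled over all unambiguous cells of the matrix (not averaged
per sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .io import LabeledAlignment


@dataclass(frozen=True)
class SiteStats:
    n_sequences: int
    aligned_length: int
    n_conserved: int
    n_variable: int
    n_informative: int
    n_singleton: int
    gc_ratio: float  # percent


def gc_ratio(aln: LabeledAlignment) -> float:
    """Pooled G+C percentage over unambiguous cells; gaps/ambiguity excluded."""
    enc = aln.encoded()
    usable = enc >= 0
    total = int(usable.sum())
    if total == 0:
        raise AlignmentError(
            f"{aln.marker_name}: no unambiguous bases, GC undefined"
        )
    gc = int(((enc == 1) | (enc == 2)).sum())  # C=1, G=2
    return 100.0 * gc / total


def classify_sites(aln: LabeledAlignment) -> SiteStats:
    """Count conserved / variable / informative / singleton columns."""
    if aln.n_samples < 2:
        raise AlignmentError(
            f"{aln.marker_name}: site classification needs >= 2 sequences"
        )
    enc = aln.encoded()
    counts = np.stack([(enc == s).sum(axis=0) for s in range(4)])  # 4 x L
    usable_n = counts.sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    scored = usable_n >= 2
    conserved = scored & (n_states == 1)
    variable = scored & (n_states >= 2)
    informative = variable & ((counts >= 2).sum(axis=0) >= 2)
    singleton = variable & ~informative
    return SiteStats(
        n_sequences=aln.n_samples,
        aligned_length=aln.length,
        n_conserved=int(conserved.sum()),
        n_variable=int(variable.sum()),
        n_informative=int(informative.sum()),
        n_singleton=int(singleton.sum()),
        gc_ratio=gc_ratio(aln),
    )
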