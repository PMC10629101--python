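"""Synthetic two-species, multi-marker datasets with known ground truth.

Sequences evolve under the Kimura two-parameter substitution process: an
ancestral sequence is drawn at a target GC content, the two species
ancestors diverge along a stem of expected length ``inter_divergence``
substitutions/site, and each sample evolves from its species ancestor along
a terminal branch of ``intra_divergence / 2`` (so two conspecific samples
are separated by ``intra_divergence`` in expectation, and two heterospecific
samples by ``inter + intra``).

Ground-truth bookkeeping is exact by design: planted diagnostic columns and
every column fixed between the species ancestors on the stem are recorded in
the :class:`SimulationTruth` and *excluded from terminal mutation* (no
homoplasy at species-separating columns).  The per-site rate on the
remaining columns is scaled up so expected pairwise distances still match
the nominal divergences.  Indels are not simulated; an optional gap
injection exercises pairwise-deletion code paths only.

All randomness flows from a single seed through per-marker substreams, so a
given (specs, seed) pair yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SimulationError
from .io import (
    CODE_BASE,
    LabeledAlignment,
    Sample,
    SampleInfo,
    decode_sequence,
    encode_sequence,
    write_metadata,
)


@dataclass(frozen=True)
class MarkerSpec:
    """Simulation regime for one marker."""

    name: str
    length: int
    inter_divergence: float  # expected subs/site between species ancestors
    intra_divergence: float  # expected subs/site between conspecific samples
    kappa: float = 2.0  # transition/transversion rate ratio
    n_diagnostic_sites: int = 0
    gc_target: float = 0.5
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.length <= 0:
            raise SimulationError(f"{self.name}: length must be positive")
        if self.inter_divergence < 0 or self.intra_divergence < 0:
            raise SimulationError(f"{self.name}: divergences must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError(f"{self.name}: missing_rate outside [0, 1)")
        if not 0 < self.gc_target < 1:
            raise SimulationError(f"{self.name}: gc_target outside (0, 1)")
        if self.n_diagnostic_sites > self.length:
            raise SimulationError(
                f"{self.name}: more diagnostic sites than columns"
            )
        if self.kappa <= 0:
            raise SimulationError(f"{self.name}: kappa must be positive")


@dataclass
class MarkerTruth:
    """Planted and emergent species-fixed columns for one marker."""

    marker: str
    planted_positions: list[int]  # 1-based
    planted_states: dict[int, tuple[str, str]]  # pos -> (state sp1, state sp2)
    fixed_positions: list[int]  # all species-separating columns, 1-based
    inter_divergence: float
    intra_divergence: float

    @property
    def expected_inter_distance(self) -> float:
        """Expected K2P distance between heterospecific samples."""
        return self.inter_divergence + self.intra_divergence


@dataclass
class SimulationTruth:
    species: tuple[str, str]
    assignments: dict[str, str]  # sample_id -> species
    markers: dict[str, MarkerTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# K2P site process
# ---------------------------------------------------------------------------

def _k2p_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """4x4 substitution probabilities after expected ``t`` subs/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta  # alpha + 2*beta == 1: t is expected substitutions
    e_tv = np.exp(-4.0 * beta * t)
    e_ts = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    p = np.full((4, 4), p_tv)
    for b in range(4):
        p[b, b] = p_same
        p[b, b ^ 2] = p_ts  # transition partner: A<->G, C<->T
    return p


def evolve_sequence(
    parent: str | np.ndarray,
    branch_length: float,
    kappa: float,
    rng: np.random.Generator,
    frozen: np.ndarray | None = None,
) -> str | np.ndarray:
    """Evolve a sequence along a branch of expected ``branch_length`` subs/site.

    ``frozen`` is an optional boolean mask (or index array) of columns that
    must not change.  String input yields string output.
    """
    as_str = isinstance(parent, str)
    codes = encode_sequence(parent) if as_str else np.asarray(parent)
    if branch_length < 0:
        raise SimulationError("branch_length must be >= 0")
    if branch_length == 0:
        child = codes.copy()
    else:
        p = _k2p_transition_matrix(branch_length, kappa)
        cum = p.cumsum(axis=1)
        r = rng.random(len(codes))
        child = (cum[codes] < r[:, None]).sum(axis=1).astype(np.int8)
    if frozen is not None:
        child[frozen] = codes[frozen]
    return decode_sequence(child) if as_str else child


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _simulate_marker(
    spec: MarkerSpec,
    sample_ids: list[str],
    species_of: dict[str, str],
    species: tuple[str, str],
    genus: str,
    rng: np.random.Generator,
    gap_rate: float,
):
    L = spec.length
    gc = spec.gc_target
    anc = rng.choice(
        4, size=L, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ).astype(np.int8)

    planted = np.sort(
        rng.choice(L, size=spec.n_diagnostic_sites, replace=False)
    )
    planted_states: dict[int, tuple[str, str]] = {}

    # stem: each species ancestor evolves half the interspecific divergence;
    # planted columns are excluded, so the rate elsewhere is scaled up to
    # keep the expected whole-sequence divergence at the nominal value.
    mutable = L - len(planted)
    stem_t = (
        spec.inter_divergence / 2.0 * L / mutable if mutable > 0 else 0.0
    )
    frozen_planted = np.zeros(L, dtype=bool)
    frozen_planted[planted] = True
    anc1 = evolve_sequence(anc, stem_t, spec.kappa, rng, frozen_planted)
    anc2 = evolve_sequence(anc, stem_t, spec.kappa, rng, frozen_planted)
    for pos in planted:
        s1, s2 = rng.choice(4, size=2, replace=False)
        anc1[pos], anc2[pos] = s1, s2
        planted_states[int(pos) + 1] = (CODE_BASE[s1], CODE_BASE[s2])

    # all species-separating columns are immune to terminal mutation so the
    # recorded truth is exact (no homoplasy at fixed differences)
    fixed_mask = (anc1 != anc2) | frozen_planted
    n_fixed = int(fixed_mask.sum())
    mutable_term = L - n_fixed
    term_t = (
        spec.intra_divergence / 2.0 * L / mutable_term
        if mutable_term > 0
        else 0.0
    )
    if mutable_term == 0 and spec.intra_divergence > 0:
        raise SimulationError(
            f"{spec.name}: no mutable columns left for intraspecific variation"
        )

    ancestors = {species[0]: anc1, species[1]: anc2}
    rows = []
    for sid in sample_ids:
        child = evolve_sequence(
            ancestors[species_of[sid]], term_t, spec.kappa, rng, fixed_mask
        )
        seq = decode_sequence(child)
        if gap_rate > 0.0:
            gaps = rng.random(L) < gap_rate
            seq = "".join(
                "-" if g else c for c, g in zip(seq, gaps)
            )
        rows.append(Sample(sid, species_of[sid], genus, seq))

    # per-marker sample dropout, keeping at least two samples per species
    if spec.missing_rate > 0.0:
        drop = rng.random(len(rows)) < spec.missing_rate
        for sp in species:
            idx = [k for k, s in enumerate(rows) if s.species == sp]
            kept = [k for k in idx if not drop[k]]
            for k in idx:
                if len(kept) >= 2:
                    break
                if drop[k]:
                    drop[k] = False
                    kept.append(k)
        rows = [s for k, s in enumerate(rows) if not drop[k]]

    truth = MarkerTruth(
        marker=spec.name,
        planted_positions=[int(p) + 1 for p in planted],
        planted_states=planted_states,
        fixed_positions=[int(p) + 1 for p in np.where(fixed_mask)[0]],
        inter_divergence=spec.inter_divergence,
        intra_divergence=spec.intra_divergence,
    )
    return LabeledAlignment(spec.name, rows), truth


def simulate_dataset(
    specs: Sequence[MarkerSpec],
    n_per_species: int | tuple[int, int] = 16,
    seed: int = 0,
    species_names: tuple[str, str] = ("species_one", "species_two"),
    genus: str = "genus_demo",
    gap_rate: float = 0.0,
) -> tuple[dict[str, LabeledAlignment], list[SampleInfo], SimulationTruth]:
    """Simulate aligned FASTA-ready data for every marker spec.

    Returns ``(alignments, metadata, truth)``; ``alignments`` maps marker
    name to a :class:`LabeledAlignment` over the non-missing samples.
    """
    if not specs:
        raise SimulationError("no marker specs given")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SimulationError("duplicate marker names")
    for spec in specs:
        spec.validate()
    if isinstance(n_per_species, int):
        n1 = n2 = n_per_species
    else:
        n1, n2 = n_per_species
    if min(n1, n2) < 2:
        raise SimulationError("need at least 2 samples per species")

    sp1, sp2 = species_names
    ids = [f"A{i + 1:02d}" for i in range(n1)] + [
        f"B{i + 1:02d}" for i in range(n2)
    ]
    species_of = {
        sid: (sp1 if sid.startswith("A") else sp2) for sid in ids
    }
    metadata = [
        SampleInfo(sid, species_of[sid], genus, "simulated") for sid in ids
    ]

    streams = np.random.SeedSequence(seed).spawn(len(specs))
    alignments: dict[str, LabeledAlignment] = {}
    truth = SimulationTruth(
        species=(sp1, sp2), assignments=dict(species_of)
    )
    for spec, stream in zip(specs, streams):
        rng = np.random.default_rng(stream)
        aln, mt = _simulate_marker(
            spec, ids, species_of, (sp1, sp2), genus, rng, gap_rate
        )
        alignments[spec.name] = aln
        truth.markers[spec.name] = mt
    return alignments, metadata, truth


# ---------------------------------------------------------------------------
# the demo preset
# ---------------------------------------------------------------------------

def paper_like_markers() -> list[MarkerSpec]:
    """Seven markers spanning the divergence regimes of a two-species study.

    One marker (``psbA_like``) sits in the clean-barcode regime: moderate
    fixed interspecific divergence, zero intraspecific variation, and a
    planted diagnostic column.  The others cover zero-variation, overlapping,
    and high-noise regimes.
    """
    return [
        MarkerSpec("its2_like", 558, 0.0067, 0.0054, kappa=2.0,
                   gc_target=0.64, missing_rate=0.03),
        MarkerSpec("rpoB_like", 510, 0.0, 0.0, gc_target=0.41,
                   missing_rate=0.05),
        MarkerSpec("matK_like", 866, 0.0021, 0.0012, gc_target=0.37,
                   missing_rate=0.55),
        MarkerSpec("psbA_like", 256, 0.028, 0.0, n_diagnostic_sites=1,
                   gc_target=0.28, missing_rate=0.13),
        MarkerSpec("trnLF_like", 409, 0.083, 0.065, gc_target=0.35,
                   missing_rate=0.6),
        MarkerSpec("trnL_intron_like", 519, 0.0005, 0.0005, gc_target=0.34,
                   missing_rate=0.2),
        MarkerSpec("ycf3_like", 690, 0.0154, 0.0161, gc_target=0.29,
                   missing_rate=0.6),
    ]


DEFAULT_COMBINATIONS = [
    ["trnLF_like", "its2_like"],
    ["trnLF_like", "psbA_like"],
    ["its2_like", "psbA_like"],
    ["trnLF_like", "its2_like", "psbA_like"],
]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(
    alignments: dict[str, LabeledAlignment],
    metadata: Sequence[SampleInfo],
    truth: SimulationTruth,
    outdir: str | Path,
) -> None:
    """Write per-marker FASTA, metadata TSV, and a truth TSV/JSON pair."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, aln in alignments.items():
        aln.write_fasta(outdir / f"{name}.fasta")
    write_metadata(metadata, outdir / "metadata.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("marker\tposition\tkind\tstate_species_one\tstate_species_two\n")
        for name in sorted(truth.markers):
            mt = truth.markers[name]
            planted = set(mt.planted_positions)
            for pos in mt.fixed_positions:
                kind = "planted" if pos in planted else "stem_fixed"
                s1, s2 = mt.planted_states.get(pos, ("", ""))
                fh.write(f"{name}\t{pos}\t{kind}\t{s1}\t{s2}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "species": list(truth.species),
                "assignments": truth.assignments,
                "markers": {
                    name: {
                        "planted_positions": mt.planted_positions,
                        "planted_states": {
                            str(k): list(v)
                            for k, v in mt.planted_states.items()
                        },
                        "fixed_positions": mt.fixed_positions,
                        "inter_divergence": mt.inter_divergence,
                        "intra_divergence": mt.intra_divergence,
                    }
                    for name, mt in sorted(truth.markers.items())
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
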