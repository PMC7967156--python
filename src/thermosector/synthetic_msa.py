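"""Synthetic labeled protein-family alignments with planted ground truth.

The generator emulates the statistical structure the pipeline is built
to detect, without modelling real evolution:

* *covarying sectors* — for each planted sector every sequence carries a
  latent categorical state; member columns show that state's consensus
  residue with a configurable weight, which induces positive pairwise
  substitution-event correlation across the sector;
* *thermal divergence* — at divergent sites thermophilic sequences are
  biased toward one consensus residue and mesophilic (and unknown)
  sequences toward another, so those columns both covary with each
  other and separate the two thermal classes in entropy-angle space;
* *lineage background* — every sequence belongs to one of a few flat
  "clades" whose consensus weakly tints all columns.  This reproduces
  the dominant phylogenetic eigenmode seen in real families, so that
  excluding mode 1 from sector analysis is meaningful on synthetic data
  too.  It is a flat mixture, not a tree simulation.

A gap-free reference row ``REF`` carrying the mesophilic-expected
consensus is included so projection is the identity; it is excluded
from all statistics, mirroring the role of the design target sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .alignment_io import (Alignment, LabelTable, MESOPHILIC, ReferenceMap,
                           THERMOPHILIC, UNKNOWN, project_to_reference)
from .alphabet import ALPHABET, GAP_INDEX, SYMBOL_INDEX

REFERENCE_ID = "REF"


@dataclass(frozen=True)
class SectorSpec:
    """One planted covarying position group."""

    members: tuple[int, ...]
    n_states: int = 3
    weight: float = 0.75
    #: thermal sectors use the thermal class itself as the latent state
    #: (thermophilic vs not), the structure the design method targets
    thermal: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError("sector weight must lie in (0, 1]")
        if self.thermal and self.n_states != 2:
            raise ValueError("a thermal sector has exactly 2 states")
        if self.n_states < 2:
            raise ValueError("a sector needs at least 2 latent states")


@dataclass(frozen=True)
class DivergentSite:
    """One position with planted thermophile/mesophile consensus split."""

    position: int
    thermo_aa: str
    meso_aa: str
    weight: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError("divergent-site weight must lie in (0, 1]")
        for aa in (self.thermo_aa, self.meso_aa):
            if aa not in SYMBOL_INDEX or aa == "-":
                raise ValueError(f"invalid consensus residue {aa!r}")


def _default_sectors() -> tuple[SectorSpec, ...]:
    return (
        # thermal sector: dispersed along the sequence, all members divergent
        SectorSpec(members=(5, 18, 27, 34, 52), n_states=2,
                   weight=0.7, thermal=True),
        # neutral sectors: latent-state driven, mostly contiguous
        SectorSpec(members=(6, 7, 8, 9, 10, 11, 13, 14, 15, 16)),
        SectorSpec(members=(41, 42, 43, 44, 45, 46, 48, 49)),
    )


def _default_divergent_sites() -> tuple[DivergentSite, ...]:
    # thermo/meso consensus pairs change side-chain character strongly, as
    # thermal-adaptation substitutions typically do (charged<->aromatic,
    # polar<->hydrophobic); weakly contrasting pairs would plant divergence
    # that the BLOSUM-scored correlation cannot see
    pairs = [(5, "W", "D"), (18, "F", "K"), (27, "C", "E"),
             (34, "W", "S"), (52, "F", "D")]
    return tuple(DivergentSite(p, t, m) for p, t, m in pairs)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic family.

    Defaults: 150 thermophilic + 150 mesophilic + 100 unknown sequences
    over 60 positions, one dispersed 8-site thermal sector whose members
    are all divergent (consensus weight 0.7), two neutral latent-state
    sectors, 5% gaps, and a weak two-clade lineage background.
    """

    n_thermo: int = 150
    n_meso: int = 150
    n_unknown: int = 100
    n_positions: int = 60
    sector_specs: tuple[SectorSpec, ...] = field(default_factory=_default_sectors)
    divergent_sites: tuple[DivergentSite, ...] = field(
        default_factory=_default_divergent_sites)
    background_concentration: float = 1.0
    gap_rate: float = 0.05
    n_clades: int = 2
    clade_weight: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        seen: set[int] = set()
        for spec in self.sector_specs:
            overlap = seen & set(spec.members)
            if overlap:
                raise ValueError(f"sectors overlap at positions {sorted(overlap)}")
            seen |= set(spec.members)
            if any(not 1 <= p <= self.n_positions for p in spec.members):
                raise ValueError("sector member outside 1..n_positions")
        div_pos = [d.position for d in self.divergent_sites]
        if len(set(div_pos)) != len(div_pos):
            raise ValueError("duplicate divergent sites")
        if any(not 1 <= p <= self.n_positions for p in div_pos):
            raise ValueError("divergent site outside 1..n_positions")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must lie in [0, 1)")
        if not 0 <= self.clade_weight < 1:
            raise ValueError("clade_weight must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    sector_members: dict[int, tuple[int, ...]]     # planted group id -> positions
    divergent_sites: dict[int, tuple[str, str]]    # position -> (thermo, meso)
    labels: dict[str, str]
    clade_of: dict[str, int]
    sector_state_of: dict[int, dict[str, int]]     # group id -> seq -> state

    @property
    def thermal_group(self) -> int | None:
        """Planted group containing the divergent sites, if any."""
        div = set(self.divergent_sites)
        for g, members in self.sector_members.items():
            if div & set(members):
                return g
        return None


def generate_family(config: GeneratorConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[Alignment, LabelTable, ReferenceMap, GroundTruth]:
    """Draw one labeled synthetic family; deterministic given (config, seed)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    c = config.n_positions
    m = config.n_thermo + config.n_meso + config.n_unknown

    ids = ([f"T{i:04d}" for i in range(config.n_thermo)]
           + [f"M{i:04d}" for i in range(config.n_meso)]
           + [f"U{i:04d}" for i in range(config.n_unknown)])
    labels = {**{i: THERMOPHILIC for i in ids[:config.n_thermo]},
              **{i: MESOPHILIC for i in
                 ids[config.n_thermo:config.n_thermo + config.n_meso]},
              **{i: UNKNOWN for i in ids[config.n_thermo + config.n_meso:]}}
    is_thermo = np.array([labels[i] == THERMOPHILIC for i in ids])

    # per-column background profiles over the 20 amino acids
    profiles = rng.dirichlet(
        np.full(20, config.background_concentration), size=c)
    # distinct consensus residues per clade at every column, so lineages
    # actually differ; weighted by the column profile
    clade_consensus = np.array(
        [rng.choice(20, p=profiles[j], size=config.n_clades, replace=False)
         for j in range(c)]).T
    clade_of = rng.integers(config.n_clades, size=m)

    sector_of_col: dict[int, int] = {}
    state_consensus: dict[int, np.ndarray] = {}
    states: dict[int, np.ndarray] = {}
    for g, spec in enumerate(config.sector_specs, start=1):
        for p in spec.members:
            sector_of_col[p] = g
        # distinct consensus per latent state at every member column —
        # coinciding states would carry no covariation signal there
        state_consensus[g] = np.array(
            [rng.choice(20, p=profiles[p - 1], size=spec.n_states,
                        replace=False)
             for p in spec.members]).T
        states[g] = (np.where(is_thermo, 0, 1) if spec.thermal
                     else rng.integers(spec.n_states, size=m))

    div_at = {d.position: d for d in config.divergent_sites}

    codes = np.empty((m, c), dtype=np.uint8)
    for j in range(c):
        p = j + 1
        col = rng.choice(20, p=profiles[j], size=m).astype(np.uint8)
        # lineage tint first; sector / divergence mechanisms override it
        u = rng.random(m)
        take = u < config.clade_weight
        col[take] = clade_consensus[clade_of[take], j]
        if p in sector_of_col:
            g = sector_of_col[p]
            spec = config.sector_specs[g - 1]
            midx = spec.members.index(p)
            u = rng.random(m)
            take = u < spec.weight
            col[take] = state_consensus[g][states[g][take], midx]
        if p in div_at:
            d = div_at[p]
            v = rng.random(m)
            take = v < d.weight
            col[take & is_thermo] = SYMBOL_INDEX[d.thermo_aa]
            col[take & ~is_thermo] = SYMBOL_INDEX[d.meso_aa]
        codes[:, j] = col

    gaps = rng.random((m, c)) < config.gap_rate
    codes[gaps] = GAP_INDEX

    # gap-free reference row: mesophilic-expected consensus
    ref_row = np.array([SYMBOL_INDEX[div_at[j + 1].meso_aa]
                        if (j + 1) in div_at
                        else int(np.argmax(profiles[j]))
                        for j in range(c)], dtype=np.uint8)
    codes = np.vstack([ref_row[None, :], codes])
    ids = [REFERENCE_ID] + ids
    labels = {REFERENCE_ID: UNKNOWN, **labels}

    aln = Alignment(ids, codes)
    aln, refmap = project_to_reference(aln, REFERENCE_ID)
    truth = GroundTruth(
        sector_members={g: spec.members
                        for g, spec in enumerate(config.sector_specs, start=1)},
        divergent_sites={d.position: (d.thermo_aa, d.meso_aa)
                         for d in config.divergent_sites},
        labels=dict(labels),
        clade_of={i: int(cl) for i, cl in zip(ids[1:], clade_of)},
        sector_state_of={g: {i: int(s) for i, s in zip(ids[1:], states[g])}
                         for g in states},
    )
    return aln, LabelTable(labels), refmap, truth


def truth_metrics(assignment, profiles, plan, truth: GroundTruth
                  ) -> dict[str, float]:
    """Score pipeline output against the planted truth.

    Reports the adjusted Rand index of the sector partition (background
    as its own class), the worst theta rank of a planted divergent
    site, whether all planted sites sit in the top m+2 theta ranks, and
    the fraction of planted sites whose first-choice proposal equals the
    planted thermophilic consensus.
    """
    positions = sorted(assignment.sector_of)
    if positions != sorted(profiles.positions):
        raise ValueError("assignment and profiles cover different positions")
    planted_of = {p: 0 for p in positions}
    for g, members in truth.sector_members.items():
        for p in members:
            if p not in planted_of:
                raise ValueError(f"planted position {p} outside the analysis")
            planted_of[p] = g
    pred = [0 if assignment.sector_of[p] == "background"
            else int(assignment.sector_of[p]) for p in positions]
    ari = adjusted_rand_score([planted_of[p] for p in positions], pred)

    order = sorted(positions,
                   key=lambda p: -profiles.theta[profiles.positions.index(p)])
    rank_of = {p: i + 1 for i, p in enumerate(order)}
    div = sorted(truth.divergent_sites)
    worst = max((rank_of[p] for p in div), default=0)
    m_sites = len(div)

    first_choice = {c.ref_position: c.mutation_string[-1]
                    for c in (plan.singles if plan else [])
                    if c.mutation_string}
    matches = sum(1 for p in div
                  if first_choice.get(p) == truth.divergent_sites[p][0])
    return {
        "ari": float(ari),
        "worst_divergent_rank": float(worst),
        "all_in_top_m_plus_2": float(worst <= m_sites + 2 and m_sites > 0),
        "consensus_match_fraction": (matches / m_sites) if m_sites else float("nan"),
    }


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "sector_members": {str(g): list(v)
                           for g, v in truth.sector_members.items()},
        "divergent_sites": {str(p): list(v)
                            for p, v in truth.divergent_sites.items()},
        "labels": truth.labels,
        "clade_of": truth.clade_of,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


__all__ = [
    "REFERENCE_ID", "SectorSpec", "DivergentSite", "GeneratorConfig",
    "GroundTruth", "generate_family", "truth_metrics", "write_truth_json",
]
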