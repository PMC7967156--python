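"""Stabilizing-mutation design from sector and divergence evidence.

The sector with the largest mean relative-entropy angle is taken as the
stability-related design target; its member positions with theta above a
threshold (default 0.5) become mutation sites.  At each site the
replacement candidates are the amino acids of the thermophilic profile
ranked by descending frequency (gap and the wild-type residue excluded);
when the thermophilic and mesophilic consensus coincide, that shared
consensus is demoted below the runner-up, since it offers no
thermophile-specific signal.  The full ranked list is always reported so
that an experimentally unfavourable first choice can be walked down to
the next candidate; double mutants combine the best single with each of
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import ReferenceMap
from .alphabet import AMINO_ACIDS, GAP_INDEX, SYMBOL_INDEX
from .profile_divergence import EntropyProfiles, mean_theta
from .sector_analysis import SectorAssignment, sector_contiguity

DEFAULT_THETA_THRESHOLD = 0.5

# fixed 5-class side-chain classification used for advisory annotation
SIDECHAIN_CLASS = {
    **{aa: "hydrophobic" for aa in "AVLIMFW"},
    **{aa: "polar" for aa in "STNQYC"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "GP"},
}


@dataclass(frozen=True)
class Replacement:
    aa: str
    thermo_freq: float
    meso_freq: float
    rule_note: str = ""

    @property
    def sidechain_class(self) -> str:
        return SIDECHAIN_CLASS[self.aa]


@dataclass
class MutationCandidate:
    """Ranked replacement proposals for one design site."""

    ref_position: int
    wild_type: str
    ranked_replacements: list[Replacement]
    theta: float

    @property
    def mutation_string(self) -> str | None:
        if not self.ranked_replacements:
            return None
        return f"{self.wild_type}{self.ref_position}{self.ranked_replacements[0].aa}"


@dataclass
class MutationPlan:
    target_sector: int
    site_threshold: float
    singles: list[MutationCandidate]
    doubles: list[tuple[str, str]] = field(default_factory=list)
    sector_report: dict[int, dict[str, float | None]] = field(default_factory=dict)

    @property
    def mutation_strings(self) -> list[str]:
        return [c.mutation_string for c in self.singles
                if c.mutation_string is not None]


def select_target_sector(assignment: SectorAssignment,
                         profiles: EntropyProfiles
                         ) -> tuple[int, dict[int, dict[str, float | None]]]:
    """Sector with the largest mean theta, plus an advisory report.

    The report lists mean theta and primary-sequence contiguity for
    every sector; contiguity is informational only.  A tie in the best
    mean theta (within 1e-12) is a hard error: the target drives the
    whole design and must be chosen deliberately.
    """
    sectors = assignment.sectors
    if not sectors:
        raise ValueError("no sectors to choose from")
    contiguity = sector_contiguity(assignment)
    means = {s: mean_theta(profiles, assignment.members(s)) for s in sectors}
    assignment.mean_theta_by_sector = means
    report = {s: {"mean_theta": means[s], "contiguity": contiguity[s],
                  "n_members": float(len(assignment.members(s)))}
              for s in sectors}
    best = max(sectors, key=lambda s: means[s])
    others = [means[s] for s in sectors if s != best]
    if others and abs(means[best] - max(others)) <= 1e-12:
        raise ValueError("mean-theta tie between sectors; choose the target "
                         "sector manually")
    return best, report


def select_mutation_sites(assignment: SectorAssignment,
                          profiles: EntropyProfiles, sector: int,
                          threshold: float = DEFAULT_THETA_THRESHOLD
                          ) -> list[int]:
    """Sector member positions with theta above threshold, theta-descending."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    members = assignment.members(sector)
    scored = [(profiles.theta_of(p), p) for p in members]
    chosen = [(t, p) for t, p in scored if t > threshold]
    chosen.sort(key=lambda tp: (-tp[0], tp[1]))
    return [p for _t, p in chosen]


def rank_replacements(position: int, profiles: EntropyProfiles,
                      wild_type: str) -> MutationCandidate:
    """Rank replacement amino acids at one site from the thermophilic profile.

    Candidates are the amino acids present in the thermophilic column,
    by descending thermophilic frequency (ties alphabetical), with gap
    and the wild type excluded.  If the thermophilic and mesophilic
    consensus amino acids coincide (and differ from the wild type), that
    shared consensus is demoted below the runner-up.
    """
    i = profiles.positions.index(position)
    ft = profiles.freqs_thermo[i]
    fm = profiles.freqs_meso[i]
    theta = float(profiles.theta[i])

    def top_aa(f: np.ndarray) -> str | None:
        masked = f.copy()
        masked[GAP_INDEX] = 0.0
        if masked.max() <= 0:
            return None
        order = sorted(AMINO_ACIDS, key=lambda a: (-masked[SYMBOL_INDEX[a]], a))
        return order[0]

    candidates = [a for a in AMINO_ACIDS
                  if ft[SYMBOL_INDEX[a]] > 0 and a != wild_type]
    candidates.sort(key=lambda a: (-ft[SYMBOL_INDEX[a]], a))

    notes: dict[str, str] = {}
    top_t, top_m = top_aa(ft), top_aa(fm)
    if (top_t is not None and top_t == top_m and top_t != wild_type
            and len(candidates) >= 2 and candidates[0] == top_t):
        candidates[0], candidates[1] = candidates[1], candidates[0]
        notes[top_t] = "shared-consensus demotion"

    ranked = [Replacement(a, float(ft[SYMBOL_INDEX[a]]),
                          float(fm[SYMBOL_INDEX[a]]), notes.get(a, ""))
              for a in candidates]
    return MutationCandidate(position, wild_type, ranked, theta)


def propose_single_mutants(sites: list[int], profiles: EntropyProfiles,
                           refmap: ReferenceMap) -> list[MutationCandidate]:
    """One ranked candidate list per selected site, in site order."""
    singles = []
    for p in sites:
        wt = refmap.ref_residues[p - 1]
        singles.append(rank_replacements(p, profiles, wt))
    return singles


def enumerate_double_mutants(singles: list[MutationCandidate],
                             anchor: str = "auto") -> list[tuple[str, str]]:
    """Pair the anchor mutation with every other single.

    ``anchor="auto"`` picks the single at the highest-theta site.  Fewer
    than two usable singles yields an empty list.
    """
    usable = [c for c in singles if c.mutation_string is not None]
    if len(usable) < 2:
        return []
    if anchor == "auto":
        anchor_cand = max(usable, key=lambda c: (c.theta, -c.ref_position))
        anchor = anchor_cand.mutation_string  # type: ignore[assignment]
    else:
        if anchor not in [c.mutation_string for c in usable]:
            raise ValueError(f"anchor {anchor!r} is not among the proposed "
                             "single mutations")
    return [(anchor, c.mutation_string) for c in usable
            if c.mutation_string != anchor]


def design_plan(assignment: SectorAssignment, profiles: EntropyProfiles,
                refmap: ReferenceMap,
                threshold: float = DEFAULT_THETA_THRESHOLD,
                anchor: str = "auto") -> MutationPlan:
    """Full design: target sector -> sites -> ranked singles -> doubles."""
    sector, report = select_target_sector(assignment, profiles)
    sites = select_mutation_sites(assignment, profiles, sector, threshold)
    singles = propose_single_mutants(sites, profiles, refmap)
    doubles = enumerate_double_mutants(singles, anchor) if len(singles) >= 2 else []
    return MutationPlan(sector, threshold, singles, doubles, report)


def write_singles_tsv(plan: MutationPlan, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_position\twild_type\ttheta\trank\tcandidate_aa\t"
                 "thermo_freq\tmeso_freq\tsidechain_class_change\trule_note\n")
        for cand in plan.singles:
            wt_class = SIDECHAIN_CLASS.get(cand.wild_type, "?")
            for rank, rep in enumerate(cand.ranked_replacements, start=1):
                change = ("yes" if rep.sidechain_class != wt_class else "no")
                fh.write(f"{cand.ref_position}\t{cand.wild_type}\t"
                         f"{cand.theta:.10g}\t{rank}\t{rep.aa}\t"
                         f"{rep.thermo_freq:.10g}\t{rep.meso_freq:.10g}\t"
                         f"{change}\t{rep.rule_note}\n")


def write_doubles_tsv(plan: MutationPlan, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor\tpartner\tcombined\n")
        for a, b in plan.doubles:
            fh.write(f"{a}\t{b}\t{a}/{b}\n")


def plan_summary(plan: MutationPlan) -> str:
    lines = [f"target sector: {plan.target_sector} "
             f"(theta threshold {plan.site_threshold:g})"]
    for s, rep in sorted(plan.sector_report.items()):
        cont = ("n/a" if rep["contiguity"] is None
                else f"{rep['contiguity']:.3g}")
        lines.append(f"  sector {s}: mean theta {rep['mean_theta']:.4f}, "
                     f"{int(rep['n_members'])} positions, "
                     f"median gap {cont}")
    lines.append("single mutants: " + (", ".join(plan.mutation_strings)
                                       or "(none)"))
    if plan.doubles:
        lines.append("double mutants: "
                     + ", ".join(f"{a}/{b}" for a, b in plan.doubles))
    return "\n".join(lines)


__all__ = [
    "DEFAULT_THETA_THRESHOLD", "SIDECHAIN_CLASS", "Replacement",
    "MutationCandidate", "MutationPlan", "select_target_sector",
    "select_mutation_sites", "rank_replacements", "propose_single_mutants",
    "enumerate_double_mutants", "design_plan",
    "write_singles_tsv", "write_doubles_tsv", "plan_summary",
]
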