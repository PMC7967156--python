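"""Model/Results interface tying the pipeline stages together.

:class:`ThermostabilityDesign` plays the role of a model object: it is
built from an alignment plus thermal-class labels and holds the method's
tunable constants (substitution scoring, selected eigenmodes, null
calibration, cluster count, theta threshold).  :meth:`fit` runs the full
analysis — projection, residue correlation, eigen-decomposition,
shuffling-null boundaries, sector clustering, entropy-angle profile and
mutation design — and returns a :class:`DesignResults` carrying every
intermediate, a ``summary()`` table, and writers/plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import alignment_io as aio
from .alignment_io import Alignment, LabelTable, ReferenceMap
from .coevolution import (CorrelationMatrix, EigenSystem, eigendecompose,
                          rca_matrix, write_correlation_tsv, write_eigen_tsv)
from .mutation_design import (MutationPlan, design_plan, plan_summary,
                              write_doubles_tsv, write_singles_tsv)
from .profile_divergence import (EntropyProfiles, mean_theta, theta_profile,
                                 write_theta_tsv)
from .sector_analysis import (NullBoundaries, SectorAssignment, cluster_sectors,
                              null_boundaries, select_significant_positions,
                              write_boundaries_tsv, write_sectors_tsv)
from .substitution import SubstitutionModel


class ThermostabilityDesign:
    """Primary-sequence thermostability design for one protein family.

    Parameters
    ----------
    alignment, labels, reference_id
        The family MSA, the thermal-class label table and the id of the
        design target sequence contained in the MSA.
    substitution
        Scoring rules for substitution events (BLOSUM50, gap −8, gap-gap 0).
    modes
        1-based eigenmodes used for sector analysis; mode 1 (phylogeny)
        is excluded by default.
    n_null_trials, null_sigma
        Column-shuffling trials and the Gaussian-boundary multiplier.
    k
        Number of sectors for k-means.
    theta_threshold
        Minimum entropy angle for a design site.
    exclude_reference
        Drop the target sequence from all statistics (it still defines
        the position numbering and the wild-type residues).
    """

    def __init__(self, alignment: Alignment, labels: LabelTable,
                 reference_id: str, *,
                 substitution: SubstitutionModel | None = None,
                 modes: tuple[int, ...] = (2, 3, 4),
                 n_null_trials: int = 10, null_sigma: float = 2.0,
                 k: int = 4, n_restarts: int = 100,
                 theta_threshold: float = 0.5, q_floor: float = 1e-4,
                 min_subset_size: int = aio.MIN_SUBSET_SIZE,
                 weight_modes: bool = False,
                 exclude_reference: bool = True,
                 anchor: str = "auto") -> None:
        self.alignment = alignment
        self.labels = labels
        self.reference_id = reference_id
        self.substitution = substitution or SubstitutionModel()
        self.modes = list(modes)
        self.n_null_trials = n_null_trials
        self.null_sigma = null_sigma
        self.k = k
        self.n_restarts = n_restarts
        self.theta_threshold = theta_threshold
        self.q_floor = q_floor
        self.min_subset_size = min_subset_size
        self.weight_modes = weight_modes
        self.exclude_reference = exclude_reference
        self.anchor = anchor

    @classmethod
    def from_files(cls, msa_path: str | Path, labels_path: str | Path,
                   reference_id: str, **kwargs) -> "ThermostabilityDesign":
        aln = aio.read_alignment(msa_path)
        labels = aio.attach_labels(aln, labels_path)
        return cls(aln, labels, reference_id, **kwargs)

    def fit(self, seed: int = 0) -> "DesignResults":
        projected, refmap = aio.project_to_reference(self.alignment,
                                                     self.reference_id)
        exclude = {self.reference_id} if self.exclude_reference else set()
        stat_rows = [i for i, sid in enumerate(projected.sequence_ids)
                     if sid not in exclude]
        stats_aln = projected.take_rows(
            stat_rows, [projected.sequence_ids[i] for i in stat_rows])
        positions = list(refmap.ref_positions)

        corr = rca_matrix(stats_aln, self.substitution)
        eig = eigendecompose(corr, self.modes)
        boundaries = null_boundaries(stats_aln, self.substitution, self.modes,
                                     self.n_null_trials, self.null_sigma,
                                     seed=seed)
        retained = select_significant_positions(eig, boundaries, corr,
                                                positions)
        try:
            sectors = cluster_sectors(eig, retained, self.k, seed=seed,
                                      n_restarts=self.n_restarts,
                                      all_positions=positions,
                                      weight_modes=self.weight_modes)
        except ValueError as exc:
            raise ValueError(f"cluster_sectors: {exc}") from exc
        profiles = theta_profile(projected, self.labels, refmap,
                                 q_floor=self.q_floor,
                                 min_subset_size=self.min_subset_size,
                                 exclude_ids=exclude)
        plan = design_plan(sectors, profiles, refmap,
                           threshold=self.theta_threshold, anchor=self.anchor)
        return DesignResults(model=self, seed=seed, refmap=refmap,
                             projected=projected, corr=corr, eig=eig,
                             boundaries=boundaries,
                             retained_positions=retained, sectors=sectors,
                             profiles=profiles, plan=plan)


@dataclass
class DesignResults:
    """Everything :meth:`ThermostabilityDesign.fit` computed."""

    model: ThermostabilityDesign
    seed: int
    refmap: ReferenceMap
    projected: Alignment
    corr: CorrelationMatrix
    eig: EigenSystem
    boundaries: NullBoundaries
    retained_positions: list[int]
    sectors: SectorAssignment
    profiles: EntropyProfiles
    plan: MutationPlan
    warnings: list[str] = field(default_factory=list)

    # -- reporting ----------------------------------------------------

    def summary(self) -> str:
        m = self.model
        n = self.refmap.n_positions
        top = ", ".join(f"l{i + 1}={v:.3f}"
                        for i, v in enumerate(self.eig.eigenvalues[:5]))
        lines = [
            "Thermostability design summary",
            "=" * 64,
            f"sequences: {self.projected.n_sequences} "
            f"(thermo {self.profiles.support_thermo}, "
            f"meso {self.profiles.support_meso}); positions: {n}",
            f"modes {m.modes}; null: {m.n_null_trials} trials, "
            f"{m.null_sigma:g} sigma; k={m.k}; "
            f"theta threshold {m.theta_threshold:g}; seed {self.seed}",
            f"leading eigenvalues: {top}",
            f"significant positions: {len(self.retained_positions)} / {n}",
            "-" * 64,
            plan_summary(self.plan),
        ]
        return "\n".join(lines)

    def diagnostics(self, position_subsets: dict[str, list[int]]
                    ) -> dict[str, dict[str, object]]:
        """Mean theta and sector composition for named position subsets."""
        report: dict[str, dict[str, object]] = {}
        universe = set(self.profiles.positions)
        for name, subset in position_subsets.items():
            unknown = [p for p in subset if p not in universe]
            if unknown:
                raise ValueError(f"subset {name!r}: unknown positions {unknown}")
            comp: dict[str, int] = {}
            for p in subset:
                s = str(self.sectors.sector_of[p])
                comp[s] = comp.get(s, 0) + 1
            report[name] = {"mean_theta": mean_theta(self.profiles, subset),
                            "n": len(subset), "sector_composition": comp}
        return report

    # -- persistence --------------------------------------------------

    def to_directory(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        positions = list(self.refmap.ref_positions)
        residues = {p: self.refmap.ref_residues[p - 1] for p in positions}
        write_correlation_tsv(self.corr, positions,
                              out / "correlation_matrix.tsv")
        write_eigen_tsv(self.eig, positions, out / "eigen_values.tsv",
                        out / "eigen_vectors.tsv")
        write_boundaries_tsv(self.boundaries, out / "null_boundaries.tsv")
        write_sectors_tsv(self.sectors, out / "sectors.tsv", residues)
        write_theta_tsv(self.profiles, out / "theta.tsv", residues)
        write_singles_tsv(self.plan, out / "mutation_plan_singles.tsv")
        write_doubles_tsv(self.plan, out / "mutation_plan_doubles.tsv")
        (out / "summary.txt").write_text(self.summary() + "\n")
        return out

    # -- plotting -----------------------------------------------------

    def plot_sectors(self, path: str | Path) -> None:
        """3-D scatter of positions in selected-mode space, colored by sector."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for s in [*self.sectors.sectors, "background"]:
            pts = np.array([self.sectors.coordinates[p]
                            for p, lab in self.sectors.sector_of.items()
                            if lab == s])
            if pts.size == 0:
                continue
            kw = ({"color": "0.7", "alpha": 0.5} if s == "background" else {})
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2],
                       label=f"sector {s}" if s != "background" else s, **kw)
        labels = [f"mode {m}" for m in self.model.modes[:3]]
        ax.set_xlabel(labels[0]); ax.set_ylabel(labels[1])
        if len(labels) > 2:
            ax.set_zlabel(labels[2])
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def plot_theta(self, path: str | Path) -> None:
        """Bar chart of theta per position, colored by sector."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3))
        cmap = plt.get_cmap("tab10")
        colors = ["0.75" if self.sectors.sector_of[p] == "background"
                  else cmap((int(self.sectors.sector_of[p]) - 1) % 10)
                  for p in self.profiles.positions]
        ax.bar(self.profiles.positions, self.profiles.theta, color=colors)
        ax.axhline(self.model.theta_threshold, ls="--", lw=0.8, color="k")
        ax.set_xlabel("reference position")
        ax.set_ylabel(r"$\theta$ (rad)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


__all__ = ["ThermostabilityDesign", "DesignResults"]
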