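"""End-to-end pipeline runner: config, manifest, artifact directory.

Thin orchestration over :class:`~thermosector.model.ThermostabilityDesign`:
read the MSA and labels, fit, write every stage's artifact plus a run
manifest (tool version, config echo, input checksums, stage timings).
The shipped defaults are the method's published constants: BLOSUM50 with
gap penalty −8 and gap-gap 0, modes 2–4, 10 shuffling trials at 2σ,
k = 4 sectors, theta threshold 0.5.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .model import DesignResults, ThermostabilityDesign
from .substitution import SubstitutionModel

logger = logging.getLogger("thermosector")


@dataclass
class PipelineConfig:
    """Flat, fully-serializable run configuration."""

    msa_path: str
    labels_path: str
    reference_id: str
    out_dir: str = "thermosector_out"
    gap_penalty: int = -8
    gap_gap_score: int = 0
    modes: tuple[int, ...] = (2, 3, 4)
    null_trials: int = 10
    null_sigma: float = 2.0
    k: int = 4
    n_restarts: int = 100
    theta_threshold: float = 0.5
    q_floor: float = 1e-4
    min_subset_size: int = 5
    weight_modes: bool = False
    exclude_reference: bool = True
    anchor: str = "auto"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key=value config file; explicit keyword overrides win."""
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            raw[key.strip()] = value.strip()
        kwargs: dict[str, object] = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}: unknown config key {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if key == "modes":
                kwargs[key] = tuple(int(x) for x in value.split(","))
            elif typ in ("int", int):
                kwargs[key] = int(value)
            elif typ in ("float", float):
                kwargs[key] = float(value)
            elif typ in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
        bad = [k for k in overrides if k not in cls.__dataclass_fields__]
        if bad:
            raise ValueError(f"unknown config key(s) {bad}")
        kwargs.update(overrides)
        return cls(**kwargs)  # type: ignore[arg-type]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_model(config: PipelineConfig) -> ThermostabilityDesign:
    sub = SubstitutionModel(gap_vs_residue=config.gap_penalty,
                            gap_vs_gap=config.gap_gap_score)
    return ThermostabilityDesign.from_files(
        config.msa_path, config.labels_path, config.reference_id,
        substitution=sub, modes=tuple(config.modes),
        n_null_trials=config.null_trials, null_sigma=config.null_sigma,
        k=config.k, n_restarts=config.n_restarts,
        theta_threshold=config.theta_threshold, q_floor=config.q_floor,
        min_subset_size=config.min_subset_size,
        weight_modes=config.weight_modes,
        exclude_reference=config.exclude_reference, anchor=config.anchor)


def run_pipeline(config: PipelineConfig) -> Path:
    """Fit the full design and write all artifacts; returns the out dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "tool": "thermosector",
        "version": __version__,
        "config": {**asdict(config), "modes": list(config.modes)},
        "inputs": {
            "msa_sha256": _sha256(config.msa_path),
            "labels_sha256": _sha256(config.labels_path),
        },
        "substitution": {"matrix": "BLOSUM50",
                         "gap_vs_residue": config.gap_penalty,
                         "gap_vs_gap": config.gap_gap_score},
        "status": "running",
        "timings_s": {},
        "warnings": [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    model = build_model(config)
    timings["read_inputs"] = round(time.perf_counter() - t0, 3)
    t0 = time.perf_counter()
    results = model.fit(seed=config.seed)
    timings["fit"] = round(time.perf_counter() - t0, 3)
    t0 = time.perf_counter()
    results.to_directory(out)
    timings["write_artifacts"] = round(time.perf_counter() - t0, 3)

    manifest["timings_s"] = timings
    manifest["status"] = "complete"
    manifest["n_positions"] = results.refmap.n_positions
    manifest["n_sequences"] = results.projected.n_sequences
    manifest["mutations"] = results.plan.mutation_strings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %s", out)
    return out


def run_diagnostics(results: DesignResults,
                    position_subsets: dict[str, list[int]]) -> str:
    """Format the subset diagnostic (mean theta, sector composition)."""
    report = results.diagnostics(position_subsets)
    lines = []
    for name, rep in report.items():
        comp = ", ".join(f"{k}:{v}" for k, v in
                         sorted(rep["sector_composition"].items()))
        lines.append(f"{name}: mean_theta={rep['mean_theta']:.4f} "
                     f"n={rep['n']} sectors[{comp}]")
    return "\n".join(lines)


__all__ = ["PipelineConfig", "build_model", "run_pipeline", "run_diagnostics"]
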