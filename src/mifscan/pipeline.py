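"""End-to-end orchestration: fields → compare → scan → cluster → report.

One :class:`RunConfig` (typically loaded from a YAML file) drives the whole
study shape: structures are loaded from PQR files or generated as a
synthetic cohort, per-protein fields are solved and written as OpenDX,
global similarity/distance matrices, the epogram, the ordered heatmap and
per-residue conservation profiles are emitted, and a JSON manifest records
parameters, seeds, a parameter hash and per-stage status. A rerun over a
completed output directory with an unchanged parameter hash is a no-op
(stages report "skipped").
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .cluster import build_epogram, color_profile, heatmap
from .compare import (
    ComparisonSpec,
    conservation_profile,
    pairwise_global,
    residue_scan,
)
from .electrostatics import SolventSpec, solve_lpbe
from .errors import ConfigError, MifScanError
from .grid import GridSpec, ScalarField
from .hydrophobics import HydrophobicParams, dry_field
from .structures import read_pqr, write_pqr
from .synthetic import CohortSpec, make_cohort

log = logging.getLogger("mifscan")

FIELD_KINDS = ("electrostatic", "hydrophobic")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    structures: list[str] | None = None
    cohort: CohortSpec | None = None
    field_kinds: tuple[str, ...] = ("electrostatic",)
    outdir: str = "mifscan_run"
    seed: int = 42
    grid_spacing: float = 1.0
    grid_shape: tuple[int, int, int] | None = None  # None → smallest with margin
    grid_margin: float = 10.0
    solvent: SolventSpec = dc_field(default_factory=SolventSpec)
    hydrophobic: HydrophobicParams = dc_field(default_factory=HydrophobicParams)
    comparison: ComparisonSpec = dc_field(default_factory=ComparisonSpec)
    linkage: str = "average"
    lpbe_tol: float = 1e-5
    lpbe_max_iter: int = 10000
    write_png: bool = True

    def __post_init__(self):
        if not self.field_kinds:
            raise ConfigError("at least one field kind is required")
        for k in self.field_kinds:
            if k not in FIELD_KINDS:
                raise ConfigError(f"unknown field kind {k!r}; choose from {FIELD_KINDS}")
        if (self.structures is None) == (self.cohort is None):
            raise ConfigError("provide exactly one of 'structures' or 'cohort'")
        if self.structures is not None:
            missing = [p for p in self.structures if not Path(p).exists()]
            if missing:
                raise ConfigError(f"structure files not found: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        for key, klass in (
            ("solvent", SolventSpec),
            ("hydrophobic", HydrophobicParams),
            ("comparison", ComparisonSpec),
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = klass(**kwargs[key])
        if "field_kinds" in kwargs:
            kwargs["field_kinds"] = tuple(kwargs["field_kinds"])
        if "grid_shape" in kwargs and kwargs["grid_shape"] is not None:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def parameter_hash(self) -> str:
        """Stable hash of everything that affects the physics or comparison."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        payload = {
            "structures": self.structures,
            "cohort": encode(self.cohort),
            "field_kinds": list(self.field_kinds),
            "seed": self.seed,
            "grid": [self.grid_spacing, encode(self.grid_shape), self.grid_margin],
            "solvent": encode(self.solvent),
            "hydrophobic": encode(self.hydrophobic),
            "comparison": encode(self.comparison),
            "linkage": self.linkage,
            "lpbe": [self.lpbe_tol, self.lpbe_max_iter],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _solve_fields(structures, grid, config, kind):
    fields = []
    for s in structures:
        if kind == "electrostatic":
            fields.append(
                solve_lpbe(
                    s,
                    grid,
                    config.solvent,
                    tol=config.lpbe_tol,
                    max_iter=config.lpbe_max_iter,
                )
            )
        else:
            # solve on the half-spacing nested grid, then take every other
            # node so masks are shared with the electrostatic grid
            fine = GridSpec(
                origin=grid.origin,
                spacing=grid.spacing / 2.0,
                shape=tuple(2 * (n - 1) + 1 for n in grid.shape),
            )
            fields.append(dry_field(s, fine, config.hydrophobic).downsample(2))
    return fields


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    phash = config.parameter_hash()

    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("parameter_hash") == phash and all(
            (outdir / p).exists() for p in old.get("outputs", [])
        ):
            log.info("outputs complete for parameter hash %s; skipping", phash[:12])
            old["stages"] = {k: "skipped" for k in old.get("stages", {})}
            log.removeHandler(fh)
            return old

    from . import __version__

    manifest = {
        "package": "mifscan",
        "version": __version__,
        "parameter_hash": phash,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "timings_s": {},
    }

    def record(path: Path):
        manifest["outputs"].append(str(path.relative_to(outdir)))

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception:
            manifest["stages"][name] = "failed"
            manifest_path.write_text(json.dumps(manifest, indent=2))
            log.exception("stage %s failed", name)
            log.removeHandler(fh)
            raise
        manifest["stages"][name] = "done"
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, manifest["timings_s"][name])
        return result

    # ---- structures
    def stage_structures():
        if config.cohort is not None:
            structures, groups = make_cohort(config.cohort)
            sdir = outdir / "structures"
            sdir.mkdir(exist_ok=True)
            for s in structures:
                p = sdir / f"{s.label}.pqr"
                write_pqr(s, p)
                record(p)
            lab = outdir / "labels.tsv"
            with open(lab, "w") as fhd:
                fhd.write("label\tgroup\n")
                for s, g in zip(structures, groups):
                    fhd.write(f"{s.label}\t{g}\n")
            record(lab)
        else:
            structures = [read_pqr(p) for p in config.structures]
        return structures

    structures = run_stage("structures", stage_structures)

    # ---- common grid over the whole cohort
    def stage_grid():
        import numpy as np

        coords = np.vstack([s.coords for s in structures])
        return GridSpec.auto(
            coords,
            spacing=config.grid_spacing,
            shape=config.grid_shape,
            margin=config.grid_margin,
        )

    grid = run_stage("grid", stage_grid)

    results = {}
    for kind in config.field_kinds:
        short = "ep" if kind == "electrostatic" else "hif"

        def stage_fields(kind=kind, short=short):
            fields = _solve_fields(structures, grid, config, kind)
            fdir = outdir / "fields"
            fdir.mkdir(exist_ok=True)
            for s, f in zip(structures, fields):
                p = fdir / f"{s.label}_{short}.dx"
                f.write_dx(p)
                record(p)
            return fields

        fields = run_stage(f"fields_{short}", stage_fields)

        def stage_compare(fields=fields, kind=kind, short=short):
            mat = pairwise_global(fields, structures, config.comparison)
            si_p = outdir / f"si_{short}.tsv"
            d_p = outdir / f"distance_{short}.tsv"
            mat.to_tsv(si_p)
            mat.to_tsv(d_p, as_distance=True)
            record(si_p)
            record(d_p)
            return mat

        mat = run_stage(f"compare_{short}", stage_compare)

        def stage_cluster(mat=mat, short=short):
            tree = build_epogram(mat, linkage=config.linkage)
            nwk = outdir / f"epogram_{short}.nwk"
            tree.write_newick(nwk)
            record(nwk)
            hm_tsv = outdir / f"heatmap_{short}.tsv"
            hm_png = outdir / f"heatmap_{short}.png" if config.write_png else None
            heatmap(mat, tree, tsv_path=hm_tsv, png_path=hm_png)
            record(hm_tsv)
            if hm_png is not None:
                record(hm_png)
            return tree

        tree = run_stage(f"cluster_{short}", stage_cluster)

        def stage_scan(fields=fields, kind=kind, short=short):
            scan = residue_scan(fields, structures, config.comparison)
            prof = conservation_profile(scan)
            prof_p = outdir / f"conservation_{short}.tsv"
            prof.to_tsv(prof_p)
            record(prof_p)
            colors_p = outdir / f"conservation_{short}_colors.tsv"
            color_profile(prof, tsv_path=colors_p)
            record(colors_p)
            return prof

        prof = run_stage(f"scan_{short}", stage_scan)
        results[kind] = {"matrix": mat, "epogram": tree, "profile": prof}

    manifest["grid"] = {
        "origin": list(grid.origin),
        "spacing": grid.spacing,
        "shape": list(grid.shape),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.removeHandler(fh)
    manifest["results"] = results  # in-memory only, not serialized
    return manifest
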