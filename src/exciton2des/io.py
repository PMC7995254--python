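"""Dataset container, fit-result persistence and the end-to-end pipeline.

A 2DES dataset is stored as a directory of one tab-separated matrix per
population time (rows: excitation axis w1 ascending, columns: emission axis
w3 ascending) plus a ``metadata.json`` sidecar carrying axes, t2 list,
units, seed and the generating recipe.  Maps are written with 9 significant
digits, so a write -> read -> write cycle is byte-identical.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .dasanalysis import (
    NoRelaxationSignatureError,
    count_exciton_states,
    estimate_relaxation_gap,
    find_extrema,
    infer_effective_dipole,
)
from .excitonics import (
    all_couplings,
    build_hamiltonian,
    diagonalize,
    parse_structure,
    write_coupling_table,
    write_hamiltonian,
)
from .globalfit import (
    DASComponent,
    FitConfig,
    GlobalFitResult,
    global_fit,
    select_components,
)
from .synthetic import Dataset2DES, fixture_recipes, generate_dataset

logger = logging.getLogger(__name__)

_FORMAT = "exciton2des-2des-v1"
_MAP_FMT = "%.9g"


class DatasetSchemaError(ValueError):
    """The on-disk dataset container violates the expected schema."""


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset2DES, path) -> Path:
    """Write a dataset to a directory container (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    map_files = []
    for k, t in enumerate(dataset.t2):
        fname = f"map_{k:04d}.tsv"
        header = (
            f"t2 = {t:.9g} fs\n"
            "rows: omega1 (excitation, cm^-1) ascending; "
            "cols: omega3 (emission, cm^-1) ascending"
        )
        np.savetxt(
            path / fname, dataset.maps[k], fmt=_MAP_FMT, delimiter="\t", header=header
        )
        map_files.append(fname)
    meta = {
        "format": _FORMAT,
        "units": {"omega1": "cm^-1", "omega3": "cm^-1", "t2": "fs", "signal": "arb."},
        "omega1": dataset.omega1.tolist(),
        "omega3": dataset.omega3.tolist(),
        "t2": dataset.t2.tolist(),
        "map_files": map_files,
        "metadata": dataset.metadata,
    }
    with open(path / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    return path


def read_dataset(path) -> Dataset2DES:
    """Read a dataset container written by :func:`write_dataset`."""
    path = Path(path)
    sidecar = path / "metadata.json"
    if not sidecar.is_file():
        raise DatasetSchemaError(f"missing metadata sidecar {sidecar}")
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("format", "omega1", "omega3", "t2", "map_files"):
        if key not in meta:
            raise DatasetSchemaError(f"metadata.json is missing field {key!r}")
    if meta["format"] != _FORMAT:
        raise DatasetSchemaError(f"unsupported container format {meta['format']!r}")
    t2 = np.asarray(meta["t2"], dtype=float)
    files = meta["map_files"]
    if len(files) != t2.size:
        raise DatasetSchemaError(
            f"t2 count ({t2.size}) does not match map file count ({len(files)})"
        )
    omega1 = np.asarray(meta["omega1"], dtype=float)
    omega3 = np.asarray(meta["omega3"], dtype=float)
    maps = np.empty((t2.size, omega1.size, omega3.size))
    for k, fname in enumerate(files):
        fpath = path / fname
        if not fpath.is_file():
            raise DatasetSchemaError(f"missing map file {fname}")
        m = np.loadtxt(fpath, delimiter="\t", ndmin=2)
        if m.shape != (omega1.size, omega3.size):
            raise DatasetSchemaError(
                f"map file {fname} has shape {m.shape}, expected "
                f"({omega1.size}, {omega3.size})"
            )
        maps[k] = m
    return Dataset2DES(
        omega1=omega1, omega3=omega3, t2=t2, maps=maps, metadata=meta.get("metadata", {})
    )


# ---------------------------------------------------------------------------
# Fit-result persistence
# ---------------------------------------------------------------------------

def write_fit_result(result: GlobalFitResult, path) -> Path:
    """Write DAS maps plus a structured-text fit report to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    das_files = []
    for k, comp in enumerate(result.components):
        fname = f"das_{k:02d}.tsv"
        header = (
            f"2D-DAS, tau = {comp.tau:.9g} fs\n"
            "rows: omega1 (cm^-1) ascending; cols: omega3 (cm^-1) ascending"
        )
        np.savetxt(path / fname, comp.amplitude_map, fmt=_MAP_FMT, delimiter="\t", header=header)
        das_files.append(fname)
    report = {
        "format": "exciton2des-fit-v1",
        "taus_fs": [c.tau for c in result.components],
        "das_files": das_files,
        "omega1": result.omega1.tolist(),
        "omega3": result.omega3.tolist(),
        "t2_used": result.t2_used.tolist(),
        "sum_squared_residual": result.sum_squared_residual,
        "n_points_used": result.n_points_used,
        "converged": result.converged,
        "tau_at_bound": result.tau_at_bound,
        "info_criteria": result.info_criteria,
    }
    with open(path / "fit_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")
    return path


def read_fit_result(path) -> GlobalFitResult:
    path = Path(path)
    report_file = path / "fit_report.json"
    if not report_file.is_file():
        raise DatasetSchemaError(f"missing fit report {report_file}")
    with open(report_file, encoding="utf-8") as fh:
        report = json.load(fh)
    omega1 = np.asarray(report["omega1"], dtype=float)
    omega3 = np.asarray(report["omega3"], dtype=float)
    components = []
    for tau, fname in zip(report["taus_fs"], report["das_files"]):
        amp = np.loadtxt(path / fname, delimiter="\t", ndmin=2)
        components.append(
            DASComponent(tau=tau, amplitude_map=amp, omega1=omega1, omega3=omega3)
        )
    return GlobalFitResult(
        components=components,
        omega1=omega1,
        omega3=omega3,
        t2_used=np.asarray(report["t2_used"], dtype=float),
        sum_squared_residual=report["sum_squared_residual"],
        n_points_used=report["n_points_used"],
        converged=report["converged"],
        tau_at_bound=report["tau_at_bound"],
        info_criteria=report.get("info_criteria"),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

KNOWN_COMPLEXES = ("Lv-a", "Lv-b", "Bo-a", "Bo-b")


@dataclass
class PipelineConfig:
    """End-to-end run: (optional) couplings -> simulate -> fit -> analyze."""

    complex_name: str = "Lv-a"
    structure_path: str | None = None
    mu_chl_a: float = 4.58  # Debye
    mu_chl_b: float = 3.83  # Debye
    recipe_overrides: dict = field(default_factory=dict)
    fit: FitConfig = field(default_factory=FitConfig)
    k_components: int | None = None  # fixed model size; None = select up to k_max
    k_max: int = 4
    analysis_min_prominence: float = 0.2
    mu_reference: float | None = None  # Debye, for effective-dipole inference
    gap_calculated: float | None = None  # cm^-1
    output_dir: str = "pipeline_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.complex_name not in KNOWN_COMPLEXES and self.complex_name != "custom":
            raise ValueError(
                f"complex_name must be one of {KNOWN_COMPLEXES} or 'custom'"
            )
        if not (self.mu_chl_a > 0 and self.mu_chl_b > 0):
            raise ValueError("dipole defaults must be positive")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_recipe(config: PipelineConfig):
    grid_kwargs = {
        k: config.recipe_overrides[k]
        for k in ("grid_step", "grid_margin", "t2_step", "t2_max")
        if k in config.recipe_overrides
    }
    recipes = fixture_recipes(**grid_kwargs)
    if config.complex_name == "custom":
        raise PipelineError(
            "complex_name 'custom' requires driving the library directly "
            "with your own SimulationRecipe"
        )
    recipe = recipes[config.complex_name]
    replacements = {
        k: config.recipe_overrides[k]
        for k in ("noise_sigma",)
        if k in config.recipe_overrides
    }
    replacements["seed"] = int(config.recipe_overrides.get("seed", config.seed))
    return dataclasses.replace(recipe, **replacements)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": f"exciton2des {__version__}",
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [],
        "files": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            if p.is_dir():
                for f in sorted(p.rglob("*")):
                    if f.is_file():
                        manifest["files"][str(f.relative_to(out))] = _sha256(f)
            else:
                manifest["files"][str(p.relative_to(out))] = _sha256(p)

    # -- couplings (optional) ----------------------------------------------
    if config.structure_path:
        try:
            species = {
                "CLA": (config.mu_chl_a, 14900.0),
                "CHL": (config.mu_chl_b, 15250.0),
            }
            chrom = parse_structure(config.structure_path, species_params=species)
            couplings = all_couplings(chrom)
            model = diagonalize(build_hamiltonian(chrom, couplings))
            cdir = out / "couplings"
            cdir.mkdir(exist_ok=True)
            write_coupling_table(couplings, cdir / "couplings.tsv")
            write_hamiltonian(model, cdir / "hamiltonian.tsv")
            with open(cdir / "exciton_energies.tsv", "w", encoding="utf-8") as fh:
                fh.write("# exciton energies, cm^-1 (ascending)\n")
                for e in model.exciton_energies:
                    fh.write(f"{e:.9g}\n")
            record("couplings", cdir)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage couplings: {exc}") from exc
    else:
        logger.info("no structure_path given; couplings stage skipped")
        manifest["stages"].append("couplings:skipped")

    # -- simulate ----------------------------------------------------------
    try:
        recipe = _build_recipe(config)
        dataset = generate_dataset(recipe)
        ddir = write_dataset(dataset, out / "dataset")
        record("simulate", ddir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate: {exc}") from exc

    # -- fit ---------------------------------------------------------------
    try:
        fit_cfg = dataclasses.replace(config.fit, seed=config.seed)
        if config.k_components is not None:
            fit_cfg = dataclasses.replace(fit_cfg, n_components=config.k_components)
            result = global_fit(dataset, fit_cfg)
            chosen_k = config.k_components
        else:
            selection = select_components(dataset, fit_cfg, config.k_max)
            result = selection.result
            chosen_k = selection.chosen_k
        fdir = write_fit_result(result, out / "fit")
        record("fit", fdir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage fit: {exc}") from exc

    # -- analyze -----------------------------------------------------------
    try:
        analysis: dict = {"chosen_k": chosen_k, "taus_fs": [c.tau for c in result.components]}
        fastest = result.components[0]
        states = count_exciton_states(
            fastest, min_prominence=config.analysis_min_prominence
        )
        analysis["n_states"] = states.n_states
        analysis["state_energies_cm1"] = states.energies
        analysis["connected_pairs"] = states.connected_pairs
        gap = None
        for comp in result.components:  # first component with a relaxation signature
            try:
                peaks = find_extrema(
                    comp, min_prominence=config.analysis_min_prominence
                )
                gap = estimate_relaxation_gap(peaks)
                break
            except NoRelaxationSignatureError:
                continue
        if gap is None:
            analysis["relaxation_gap_cm1"] = None
            analysis["note"] = "no relaxation signature in any component"
        else:
            analysis["relaxation_gap_cm1"] = gap.gap
            analysis["gap_donor_cm1"] = gap.donor_energy
            analysis["gap_acceptor_cm1"] = gap.acceptor_energy
            analysis["gap_component_tau_fs"] = gap.source_component_tau
            if config.mu_reference and config.gap_calculated:
                resc = infer_effective_dipole(
                    gap.gap, config.gap_calculated, config.mu_reference
                )
                analysis["mu_effective_debye"] = resc.mu_effective
        afile = out / "analysis.json"
        with open(afile, "w", encoding="utf-8") as fh:
            json.dump(analysis, fh, indent=1)
            fh.write("\n")
        record("analyze", afile)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage analyze: {exc}") from exc

    manifest["created"] = datetime.now(timezone.utc).isoformat()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Config file (INI: key-value with sections)
# ---------------------------------------------------------------------------

def default_config_text() -> str:
    """Default pipeline configuration as INI text."""
    return (
        "[pipeline]\n"
        "complex_name = Lv-a\n"
        "# structure_path = path/to/structure.pdb\n"
        "mu_chl_a = 4.58\n"
        "mu_chl_b = 3.83\n"
        "output_dir = pipeline_out\n"
        "seed = 0\n"
        "\n"
        "[recipe]\n"
        "# noise_sigma = 0.01\n"
        "# grid_step = 10\n"
        "# t2_max = 1000\n"
        "\n"
        "[fit]\n"
        "# k_components = 2\n"
        "k_max = 4\n"
        "t2_min = 15\n"
        "n_starts = 5\n"
        "\n"
        "[analysis]\n"
        "min_prominence = 0.2\n"
        "# mu_reference = 3.83\n"
        "# gap_calculated = 134\n"
    )


def load_config(path) -> PipelineConfig:
    """Parse an INI pipeline configuration file."""
    cp = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    pipe = cp["pipeline"] if cp.has_section("pipeline") else {}
    rec = cp["recipe"] if cp.has_section("recipe") else {}
    fit = cp["fit"] if cp.has_section("fit") else {}
    ana = cp["analysis"] if cp.has_section("analysis") else {}
    fit_cfg = FitConfig(
        t2_min=float(fit.get("t2_min", 15.0)),
        n_starts=int(fit.get("n_starts", 5)),
    )
    overrides = {
        k: float(rec[k])
        for k in ("noise_sigma", "grid_step", "grid_margin", "t2_step", "t2_max")
        if k in rec
    }
    if "seed" in rec:
        overrides["seed"] = int(rec["seed"])
    return PipelineConfig(
        complex_name=pipe.get("complex_name", "Lv-a"),
        structure_path=pipe.get("structure_path") or None,
        mu_chl_a=float(pipe.get("mu_chl_a", 4.58)),
        mu_chl_b=float(pipe.get("mu_chl_b", 3.83)),
        recipe_overrides=overrides,
        fit=fit_cfg,
        k_components=int(fit["k_components"]) if "k_components" in fit else None,
        k_max=int(fit.get("k_max", 4)),
        analysis_min_prominence=float(ana.get("min_prominence", 0.2)),
        mu_reference=float(ana["mu_reference"]) if "mu_reference" in ana else None,
        gap_calculated=float(ana["gap_calculated"]) if "gap_calculated" in ana else None,
        output_dir=pipe.get("output_dir", "pipeline_out"),
        seed=int(pipe.get("seed", 0)),
    )
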