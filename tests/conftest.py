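"""Shared fixtures: scaled-down recipes and synthetic structure files."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from exciton2des.synthetic import fixture_recipes


def small_chla_recipe(noise: float = 0.0, seed: int = 0, grid_step: float = 30.0):
    """The Lv-a recipe on a coarse frequency grid (fast to fit, same physics)."""
    recipe = fixture_recipes(grid_step=grid_step, grid_margin=250.0)["Lv-a"]
    return dataclasses.replace(recipe, noise_sigma=noise, seed=seed)


@pytest.fixture
def chla_recipe_noiseless():
    return small_chla_recipe(noise=0.0)


@pytest.fixture
def chla_recipe_noisy():
    return small_chla_recipe(noise=0.01, seed=3)


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element) -> str:
    x, y, z = xyz
    return (
        f"HETATM{serial:5d} {name:<4s} {resname:<3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_synthetic_chl_pdb(
    path,
    mg_positions,
    qy_directions=None,
    resname: str = "CLA",
    drop_atom: tuple[int, str] | None = None,
) -> None:
    """Write a minimal synthetic PDB of fake chlorophylls (Mg, NB, ND only).

    ``qy_directions`` default to +z for every residue; ``drop_atom=(i, name)``
    omits one atom from residue i to exercise validation paths.
    """
    mg_positions = np.asarray(mg_positions, dtype=float)
    n = len(mg_positions)
    if qy_directions is None:
        qy_directions = np.tile([0.0, 0.0, 1.0], (n, 1))
    qy_directions = np.asarray(qy_directions, dtype=float)
    lines = []
    serial = 1
    for i in range(n):
        mg = mg_positions[i]
        d = qy_directions[i] / np.linalg.norm(qy_directions[i])
        atoms = [("MG", mg, "MG"), ("NB", mg - d, "N"), ("ND", mg + d, "N")]
        for name, xyz, elem in atoms:
            if drop_atom == (i, name):
                continue
            lines.append(_pdb_atom(serial, name, resname, "A", 100 + i, xyz, elem))
            serial += 1
    lines.append("END\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)


@pytest.fixture
def two_dimer_pdb(tmp_path):
    """Four fake chlorophylls arranged as two well-separated close pairs."""
    path = tmp_path / "two_dimer.pdb"
    write_synthetic_chl_pdb(
        path,
        mg_positions=[[0, 0, 0], [9, 0, 0], [0, 25, 0], [9, 25, 0]],
    )
    return path
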