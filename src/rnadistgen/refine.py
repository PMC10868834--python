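"""Coarse-grained refinement protocol adapter.

The package never executes the external SimRNA force-field engine;
this module emits a reproducible, inspectable refinement protocol
(configuration file and run script with the clustering invocation) and
ranks the resulting cluster centers with the score model once the user
has run it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SIMRNA_CONFIG = """# config.dat
NUMBER_OF_ITERATIONS 2000000
TRA_WRITE_IN_EVERY_N_ITERATIONS 200000

INIT_TEMP 1.15
FINAL_TEMP 0.9

BONDS_WEIGHT 1.0
ANGLES_WEIGHT 1.0
TORS_ANGLES_WEIGHT 0.0
ETA_THETA_WEIGHT 0.40
"""

CLUSTER_ENERGY_CUT = 0.25
CLUSTER_RADII = (5.0, 10.0, 15.0, 20.0, 25.0)
N_CLUSTER_CENTERS = 5
N_REPETITION_RUNS = 1000


@dataclass
class RefinementPlan:
    input_pdbs: list
    config_text: str = SIMRNA_CONFIG
    cluster_args: tuple = (CLUSTER_ENERGY_CUT, CLUSTER_RADII)
    n_centers: int = N_CLUSTER_CENTERS
    repetitions: int = N_REPETITION_RUNS


def parse_config(text: str) -> dict[str, float]:
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split()
        out[key] = float(value)
    return out


def write_simrna_config(path) -> None:
    """Emit the refinement engine configuration (byte-stable)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(SIMRNA_CONFIG)


def write_refinement_script(ensemble_pdbs: list, workdir,
                            tag: str = "ensemble") -> str:
    """Emit a run script: per-structure simulation runs, trajectory
    concatenation, and the spectral clustering call."""
    from pathlib import Path

    if not ensemble_pdbs:
        raise ValueError("empty ensemble")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    write_simrna_config(workdir / "config.dat")
    radii = " ".join(f"{r:.1f}" for r in CLUSTER_RADII)
    lines = ["#!/bin/sh", "# refinement protocol (external engine required)", ""]
    for pdb in ensemble_pdbs:
        lines.append(f"./SimRNA {pdb} -c config.dat  "
                     f"# compute {N_REPETITION_RUNS} repetition runs")
    lines += [
        f"cat *.trafl > {tag}.trafl",
        f"./clustering {tag}.trafl {CLUSTER_ENERGY_CUT} {radii}",
        f"# -> {N_CLUSTER_CENTERS} cluster centers",
        "",
    ]
    script = workdir / "run.sh"
    with open(script, "w", newline="\n") as fh:
        fh.write("\n".join(lines))
    return str(script)


def rank_cluster_centers(center_maps: list, seq: str, score_net) -> list:
    """Rank re-encoded cluster centers with the score model (expects 5)."""
    import warnings

    from .score import rank_ensemble

    if len(center_maps) != N_CLUSTER_CENTERS:
        warnings.warn(f"expected {N_CLUSTER_CENTERS} cluster centers, "
                      f"got {len(center_maps)}; ranking what was given")
    return rank_ensemble(center_maps, seq, score_net)
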