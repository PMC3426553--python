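"""End-to-end pipeline: simulate -> call -> estimate -> screen, with a manifest.

The manifest records the echoed configuration, the seed, the package version
and a SHA-256 checksum of every output, and is itself deterministic given the
configuration and seed, so a run can be re-executed bit-identically.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ReferenceGene
from .io import write_fasta, write_mutation_tsv, write_plate_tsv, write_results_tsv
from .plates import PlateParams, screening_scenario
from .rates import MutationRateModel, dispersion_test
from .screening import call_hits
from .simulate import EvolutionConfig, SimulatedLibrary, per_clone_counts, simulate_library
from .spectrum import MutationSpectrum

DEFAULT_CONFIG: dict = {
    "reference_length": 783,
    "mutation_rate": 1.0e-4,
    "generations": 17,
    "population_size": 300,
    "g_to_a_fraction": 0.623,
    "recombination_switch_rate": 0.0,
    "heterozygous_virion_fraction": 0.0,
    "cis_lethal_mask": [],
    "n_sequenced": 40,
    "screen": {
        "n_clones": 24,
        "n_sensitizers": 2,
        "n_experiments": 3,
        "screening_conc_nM": 10.0,
        "noise_sd": 0.02,
    },
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_evolution_config(config: dict, seed: int) -> EvolutionConfig:
    spectrum = MutationSpectrum.g_to_a_biased(config.get("g_to_a_fraction", 0.623))
    return EvolutionConfig(
        mutation_rate=config["mutation_rate"],
        generations=config["generations"],
        population_size=config["population_size"],
        spectrum=spectrum,
        recombination_switch_rate=config.get("recombination_switch_rate", 0.0),
        heterozygous_virion_fraction=config.get("heterozygous_virion_fraction", 0.0),
        cis_lethal_mask=frozenset(config.get("cis_lethal_mask", [])),
        seed=seed,
    )


def run_pipeline(config: dict | None, outdir, *, seed: int) -> Path:
    """Run the full desk-scale experiment; returns the manifest path.

    Validates the configuration before writing anything; any stage failure
    propagates with partial outputs preserved on disk.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    screen_cfg = dict(DEFAULT_CONFIG["screen"])
    screen_cfg.update((config or {}).get("screen", {}))
    cfg["screen"] = screen_cfg

    ss = np.random.SeedSequence(seed)
    sub = [int(s) for s in ss.generate_state(3) % (2 ** 31)]
    evo_config = build_evolution_config(cfg, sub[0])  # validates before output

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    reference = ReferenceGene.random(cfg["reference_length"], seed=sub[1],
                                     name="reference")
    library: SimulatedLibrary = simulate_library(evo_config, reference)

    ref_path = outdir / "reference.fasta"
    write_fasta({reference.name: reference.sequence}, ref_path)
    clones_path = outdir / "clones.fasta"
    write_fasta({c.clone_id: c.sequence for c in library.clones}, clones_path)
    mut_path = outdir / "mutations.tsv"
    write_mutation_tsv(library.clones, mut_path)
    outputs += [ref_path, clones_path, mut_path]

    sequenced = library.clones[: cfg["n_sequenced"]]
    res = MutationRateModel.from_clones(sequenced, reference).fit()
    disp = dispersion_test(per_clone_counts(sequenced))
    rate_row = pd.DataFrame([{
        "generation": res.model.generation_label,
        "cycles": res.model.G,
        "n_sequenced_clones": res.model.C,
        "n_mutated_positions": res.model.M,
        "rate_per_nt_per_cycle": res.rate,
        "rate_ci_low": res.ci_low,
        "rate_ci_high": res.ci_high,
        "avg_mut_positions_per_clone": res.per_clone_mean,
        "dispersion_index": disp.index,
    }])
    rate_path = outdir / "rate_table.tsv"
    write_results_tsv(rate_row, rate_path)
    outputs.append(rate_path)

    plate, implanted = screening_scenario(
        seed=sub[2], n_clones=screen_cfg["n_clones"],
        n_sensitizers=screen_cfg["n_sensitizers"],
        n_experiments=screen_cfg["n_experiments"],
        params=PlateParams(noise_sd=screen_cfg["noise_sd"]),
    )
    plate_path = outdir / "plate.tsv"
    write_plate_tsv(plate, plate_path)
    hits = call_hits(plate, screening_conc=screen_cfg["screening_conc_nM"])
    hits["implanted_sensitizer"] = hits["clone_id"].isin(implanted)
    screen_path = outdir / "screen_results.tsv"
    write_results_tsv(hits, screen_path)
    outputs += [plate_path, screen_path]

    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    outputs.append(config_path)

    manifest = {
        "seed": seed,
        "package_version": __version__,
        "config": cfg,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
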