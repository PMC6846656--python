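"""End-to-end pipeline driver: simulate -> call -> spectrum -> clones -> report.

Each stage writes schema-validated TSVs plus a JSON run log recording
the package version, seed and thresholds, so any run can be reproduced
byte-for-byte from its log.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, caller, clones, replicates, schemas, simulate, spectrum



@dataclass
class CallerConfig:
    uid_length: int = 24
    min_family: int = 3
    min_qual: int = 30
    max_mismatch: int = 19
    consensus: float = 0.95

    def __post_init__(self) -> None:
        if not (self.uid_length >= 1 and self.min_family >= 1 and
                0 <= self.min_qual <= 93 and self.max_mismatch >= 0 and
                0 < self.consensus <= 1):
            raise ValueError("caller thresholds outside documented ranges")


@dataclass
class SimulationConfig:
    n_clones: int = 2000
    length: int = 203
    deamination: dict = field(default_factory=dict)   # DeaminationModel overrides
    sequencing: dict = field(default_factory=dict)    # SequencingModel overrides


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 1
    caller: CallerConfig = field(default_factory=CallerConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.caller = CallerConfig(**raw.get("caller", {}))
        cfg.simulation = SimulationConfig(**raw.get("simulation", {}))
        return cfg


def table1_manifest() -> pd.DataFrame:
    """The shipped per-experiment count manifest (replicate rate fixture)."""
    with resources.files("aidmds.data").joinpath("table1.tsv").open() as fh:
        return schemas.validate_frame(pd.read_csv(fh, sep="\t"), "manifest")


def _run_log(out_dir: Path, stage: str, seed: int | None, params: dict) -> None:
    log = {"package": "aidmds", "version": __version__, "stage": stage,
           "seed": seed, "params": params,
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    with open(out_dir / f"{stage}.log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns a dict of output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    # --- simulate ---------------------------------------------------
    ref = simulate.generate_reference(length=sim.length, seed=config.seed)
    model = simulate.DeaminationModel(**sim.deamination)
    seqmodel = simulate.SequencingModel(**sim.sequencing)
    clone_set = simulate.simulate_clone_mutations(ref, model, sim.n_clones, seed=config.seed + 1)
    r1, r2, truth_path = out / "reads_R1.fastq", out / "reads_R2.fastq", out / "truth.tsv"
    simulate.emit_read_families(clone_set, seqmodel, seed=config.seed + 2,
                                r1_path=r1, r2_path=r2, truth_path=truth_path)
    ref.to_fasta(out / "reference.fasta")
    _run_log(out, "simulate", config.seed,
             {"n_clones": sim.n_clones, "deamination": asdict(model), "sequencing": asdict(seqmodel)})

    # --- call (both strand libraries live in one R1/R2 pair; the
    #     caller drops reads of the other strand via the mismatch gate) -
    paths = {"reference": out / "reference.fasta", "truth": truth_path}
    cc = config.caller
    for strand in ("NTS", "TS"):
        res = caller.call_library(r1, r2, ref, strand,
                                  uid_length=cc.uid_length, min_qual=cc.min_qual,
                                  family_min=cc.min_family, max_mismatch=cc.max_mismatch,
                                  consensus=cc.consensus)
        tpath = out / f"mutations_{strand}.tsv"
        res.table.to_tsv(tpath)
        cpath = out / f"clone_calls_{strand}.tsv"
        res.clones.to_csv(cpath, sep="\t", index=False)
        _run_log(out, f"call_{strand}", config.seed, {**asdict(cc), "filter_log": res.log})
        paths[f"mutations_{strand}"] = tpath
        paths[f"clone_calls_{strand}"] = cpath

        # --- spectrum ----------------------------------------------
        spec = spectrum.per_site_spectrum(res.table, ref)
        spath = out / f"spectrum_{strand}.tsv"
        spec.to_tsv(spath)
        region = spectrum.region_distribution(spec)
        region.to_csv(out / f"regions_{strand}.tsv", sep="\t", index=False)
        paths[f"spectrum_{strand}"] = spath

        # --- clone statistics --------------------------------------
        coords = [ref.duplex_coord(strand, p) for p in ref.c_positions(strand)]
        calls = res.clones.copy()
        if len(calls):
            calls["coord"] = [ref.duplex_coord(strand, int(p)) for p in calls["pos"]]
            calls = calls[calls["alt"] == "T"]
        if len(calls):
            mat = clones.CloneMutationMatrix.from_calls(calls, coords, strand)
            hist = clones.mutations_per_clone(mat)
            hist.to_csv(out / f"clone_histogram_{strand}.tsv", sep="\t", index=False)
            try:
                fit, cd = clones.correlation_length_from_matrix(mat)
                cd.to_csv(out / f"correlation_{strand}.tsv", sep="\t", index=False)
                with open(out / f"fit_{strand}.json", "w") as fh:
                    json.dump(asdict(fit), fh, indent=2)
            except ValueError:
                pass  # too few multiply mutated clones for a correlation fit

    # --- report (replicate statistics on the shipped manifest) ------
    manifest = table1_manifest()
    summary = replicates.summarize_manifest(manifest)
    summary.to_csv(out / "replicate_summary.tsv", sep="\t", index=False)
    paths["replicate_summary"] = out / "replicate_summary.tsv"
    _run_log(out, "report", None, {"manifest": "shipped table1 fixture"})
    return {k: str(v) for k, v in paths.items()}
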