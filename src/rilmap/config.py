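"""Pipeline configuration: every stage parameter with its default, plus
YAML serialisation that round-trips unchanged."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class SimulationParams:
    """Study conditions of the emulated population.

    Defaults mirror the real population: 144 F11 lines, ~124k parental
    SNPs over the 12 rice chromosomes (~0.33 SNPs/kb), 7.75x mean
    resequencing depth, parental day-6 germination means 15.4 / 86.5 %.
    QTL effects default to the published eleven-QTL set used as relative
    weights.  ``genome_scale`` shrinks both physical and genetic lengths
    for quick demonstrations without changing the per-cM structure.
    """

    n_chrom: int = 12
    n_lines: int = 144
    n_generations: int = 11
    snp_density_per_kb: float = 0.343  # ~123.9k SNPs over the 361 Mb map span
    mean_depth: float = 7.75
    error_rate: float = 0.01
    residual_sd: float = 10.0
    parent_means: tuple[float, float] = (15.4, 86.5)
    genome_scale: float = 1.0
    trait: str = "germination_d6"


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with their defaults."""

    seed: int = 1
    out_dir: str = "results/pipeline"
    simulate: bool = True
    calls_vcf: str | None = None
    phenotypes_csv: str | None = None
    # bincall
    window_size: int = 20
    min_informative: int = 10
    min_run: int = 3
    grid_bp: int = 15_000
    # genmap
    map_function: str = "kosambi"
    ceiling_cm: float = 50.0
    # qtlscan
    step_cm: float = 1.0
    method: str = "cim"
    max_cov: int = 5
    exclusion_window_cm: float = 10.0
    n_perm: int = 1000
    alpha: float = 0.05
    drop: float = 1.5
    lod_ceiling: float = 50.0
    sim: SimulationParams = field(default_factory=SimulationParams)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["parent_means"] = list(self.sim.parent_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if "parent_means" in sim_d:
            sim_d["parent_means"] = tuple(sim_d["parent_means"])
        known = {f.name for f in fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=SimulationParams(**sim_d), **d)

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = path_or_text
        return cls.from_dict(yaml.safe_load(text))
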