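"""Structured simulation config: one YAML file drives every generator.

Schema (all sections optional unless a command needs them)::

    seed: 1
    genome:
      scale: 0.01            # study-shaped genome, scaled; or explicit:
      # chromosomes: [[chr1, 500000], [chr2, 300000]]
      # gc_content: 0.296
      # masked: {chr1: [[100, 200]]}
    divergence:
      high_rate: 0.033       # two-compartment profile (defaults shown), or
      low_rate: 0.002        # uniform: 0.01
      high_fraction: 0.446
    meiosis:
      co_rate: 0.0
      nco_rate: 0.0
      tract_length: {family: geometric, params: [1500]}
      obligate_co: false
    ma:
      mu: 1.2e-10
      n_lines: 30
      generations: 2037
      founder_zygosity: homozygous-haploid
      at_bias: 3.6
      ts_tv: 1.21
      loh_rate: 0.0
      loh_length: {family: geometric, params: [10000]}
    depths:
      mean_depth: 30
      error_rate: 0.0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .genome import DivergenceProfile, GenomeSpec, study_genome
from .simulate import LengthDistribution, MAParams, MeiosisParams


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def genome_from_config(cfg: dict) -> GenomeSpec:
    g = cfg.get("genome", {})
    seed = cfg.get("seed")
    if "chromosomes" in g:
        return GenomeSpec(
            chromosomes=tuple((c, int(l)) for c, l in g["chromosomes"]),
            gc_content=float(g.get("gc_content", 0.296)),
            masked_intervals={c: [tuple(iv) for iv in ivs]
                              for c, ivs in g.get("masked", {}).items()},
            seed=seed,
        )
    return study_genome(scale=float(g.get("scale", 1.0)), seed=seed)


def divergence_from_config(cfg: dict, genome: GenomeSpec) -> DivergenceProfile:
    d = cfg.get("divergence", {})
    if "uniform" in d:
        return DivergenceProfile.uniform(genome, float(d["uniform"]))
    return DivergenceProfile.two_rate(
        genome,
        high_rate=float(d.get("high_rate", 0.033)),
        low_rate=float(d.get("low_rate", 0.002)),
        high_fraction=float(d.get("high_fraction", 0.446)),
    )


def _length_dist(d: dict | None, default: LengthDistribution) -> LengthDistribution:
    if not d:
        return default
    return LengthDistribution(d["family"], tuple(float(p) for p in d["params"]))


def meiosis_from_config(cfg: dict) -> MeiosisParams:
    m = cfg.get("meiosis", {})
    return MeiosisParams(
        co_rate=float(m.get("co_rate", 0.0)),
        nco_rate=float(m.get("nco_rate", 0.0)),
        tract_length=_length_dist(m.get("tract_length"),
                                  LengthDistribution("geometric", (1500.0,))),
        obligate_co=bool(m.get("obligate_co", False)),
        seed=cfg.get("seed"),
    )


def ma_from_config(cfg: dict) -> MAParams:
    m = cfg.get("ma")
    if m is None:
        raise ValueError("config has no 'ma' section")
    return MAParams(
        mu=float(m["mu"]),
        n_lines=int(m["n_lines"]),
        generations=int(m["generations"]),
        founder_zygosity=m.get("founder_zygosity", "homozygous-haploid"),
        at_bias=float(m.get("at_bias", 3.6)),
        ts_tv=float(m.get("ts_tv", 1.21)),
        loh_rate=float(m.get("loh_rate", 0.0)),
        loh_length=_length_dist(m.get("loh_length"),
                                LengthDistribution("geometric", (10_000.0,))),
        seed=cfg.get("seed"),
    )


def depth_params(cfg: dict) -> tuple[float, float]:
    d = cfg.get("depths", {})
    return float(d.get("mean_depth", 30.0)), float(d.get("error_rate", 0.0))
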