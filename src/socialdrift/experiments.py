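"""Study orchestration: scenario presets, replicate batteries, result tables.

The 23 data-generating scenarios are registered as named presets: nine
social-group scenarios (three mating systems x 10/50/500 groups), twelve
coalescent scenarios (theta = 0.1..1 in steps of 0.1, 1.5, 2) and two
panmictic forward Wright-Fisher scenarios (2000 haploids; 1000 diploid
dioecious).  Analysis presets bundle a generator with a sampling scheme and
an inference battery (equilibrium test or LD-Ne).

Every replicate draws its own ``numpy.random.Generator`` seeded with
``base_seed + replicate_index``; the seed is written into the result table,
so any row can be regenerated in isolation and a rerun of a preset with the
same base seed reproduces every table bit for bit.

``scale_factor`` shrinks a preset for desk-scale work: replicate counts,
tick counts and forward generations are multiplied by it (with floors of 1
replicate, 1000 ticks, 100 generations); the per-locus count of conditional
equilibrium simulations is part of the published procedure and never
scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import social
from .coalescent import MsatConfig, simulate_msat_dataset
from .dataset import GenotypeDataset
from .heteq_test import DEFAULT_N_SIMS, aggregate_proportions, test_dataset
from .ldne import LDNeConfig, estimate_ne
from .sampling import SamplingScheme, SchemeKind, draw_sample
from .social import (
    MONOGAMY,
    POLYGYNANDRY,
    POLYGYNY,
    LifeHistory,
    MatingSystem,
    init_population,
    make_founder_pool,
)
from .wright_fisher import WFConfig, run_wf

__all__ = ["ScenarioPreset", "PRESETS", "list_presets", "run_scenario", "load_overrides"]

_MATING = {"monogamy": MONOGAMY, "polygynandry": POLYGYNANDRY, "polygyny": POLYGYNY}

# Default sampling for inference on social scenarios: 20 individuals from a
# pool of groups, mirroring the random-pool scheme (30-of-50 etc.).
_POOL_OF = {10: 10, 50: 30, 500: 100}


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully parameterized scenario plus its analysis battery.

    battery is one of ``none`` (generate only), ``demography`` (census/RS
    time series, genetics off), ``heteq`` (equilibrium test per replicate)
    or ``ldne`` (LD-Ne per replicate, 10 sample replicates each).
    """

    name: str
    generator: str  # 'social' | 'coalescent' | 'wf'
    n_replicates: int = 100
    battery: str = "none"
    # social
    n_groups: int = 50
    mating: str = "monogamy"
    n_ticks: int = 500_000
    life: LifeHistory = field(default_factory=LifeHistory)
    founder_theta: float = 20.0
    # coalescent / wf
    theta: float = 2.0
    n_genes: int = 40
    wf_ploidy: int = 2
    wf_n: int = 1000
    wf_init: str = "equilibrium"
    wf_generations: int | None = None
    # shared
    n_loci: int = 100
    # analysis
    sample_n: int = 20
    scheme_kind: SchemeKind = SchemeKind.RANDOM_POOL
    heq_sims: int = DEFAULT_N_SIMS
    alpha: float = 0.05
    ldne_sample_sizes: tuple[int, ...] = (20, 50, 100)
    ldne_loci: int = 20
    ldne_sample_reps: int = 10


def _build_presets() -> dict[str, ScenarioPreset]:
    p: dict[str, ScenarioPreset] = {}
    # -- the 23 data-generating scenarios --------------------------------
    for label in _MATING:
        for g in (10, 50, 500):
            p[f"social-{g}-{label}"] = ScenarioPreset(
                name=f"social-{g}-{label}", generator="social", n_groups=g, mating=label
            )
    thetas = [round(0.1 * i, 1) for i in range(1, 11)] + [1.5, 2.0]
    for th in thetas:
        name = f"ms-theta{th:g}"
        p[name] = ScenarioPreset(name=name, generator="coalescent", theta=th)
    p["wf-haploid-2000"] = ScenarioPreset(
        name="wf-haploid-2000", generator="wf", wf_ploidy=1, wf_n=2000
    )
    p["wf-diploid-1000"] = ScenarioPreset(
        name="wf-diploid-1000", generator="wf", wf_ploidy=2, wf_n=1000
    )
    # -- analysis presets --------------------------------------------------
    p["ms-theta2-bottlenecktest"] = replace(
        p["ms-theta2"], name="ms-theta2-bottlenecktest", battery="heteq"
    )
    for label in _MATING:
        base = p[f"social-50-{label}"]
        p[f"social-50-{label}-demography"] = replace(
            base, name=f"social-50-{label}-demography", battery="demography",
            n_ticks=5000, n_replicates=5,
        )
        p[f"social-50-{label}-bottlenecktest"] = replace(
            base, name=f"social-50-{label}-bottlenecktest", battery="heteq"
        )
        p[f"social-50-{label}-ldne"] = replace(
            base, name=f"social-50-{label}-ldne", battery="ldne",
        )
    p["wf-haploid-bottlenecktest"] = replace(
        p["wf-haploid-2000"], name="wf-haploid-bottlenecktest", battery="heteq"
    )
    p["wf-diploid-bottlenecktest"] = replace(
        p["wf-diploid-1000"], name="wf-diploid-bottlenecktest", battery="heteq"
    )
    # ideal-population parameter recovery for the LD method: theta = 0.5,
    # the middle of the study's low-to-moderate coalescent grid
    p["wf-ideal-ldne-recovery"] = ScenarioPreset(
        name="wf-ideal-ldne-recovery", generator="wf", battery="ldne",
        wf_ploidy=2, wf_n=50, n_loci=20, theta=0.5, wf_generations=120,
        n_replicates=200, ldne_sample_sizes=(50,), ldne_sample_reps=1,
    )
    return p


PRESETS = _build_presets()


def list_presets() -> list[str]:
    return sorted(PRESETS)


def load_overrides(preset: ScenarioPreset, path) -> ScenarioPreset:
    """Apply YAML key-value overrides (Table 1 / Table 2 fields, ticks,
    loci, replicate counts ...) to a preset."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    life_kw = cfg.pop("life", None)
    if life_kw:
        cfg["life"] = replace(preset.life, **life_kw)
    return replace(preset, **cfg)


def _scaled(preset: ScenarioPreset, scale: float) -> ScenarioPreset:
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale_factor must be in (0, 1]")
    if scale == 1.0:
        return preset
    return replace(
        preset,
        n_replicates=math.ceil(scale * preset.n_replicates),
        n_ticks=max(1000, math.ceil(scale * preset.n_ticks)),
        wf_generations=None
        if preset.wf_generations is None
        else max(100, math.ceil(scale * preset.wf_generations)),
    )


def _generate(preset: ScenarioPreset, rng: np.random.Generator, genetics: bool):
    """One replicate of the preset's generator.

    Returns (population_or_None, dataset_or_None, demography_record)."""
    if preset.generator == "social":
        mating = _MATING[preset.mating]
        pool = (
            make_founder_pool(preset.n_loci, rng, theta=preset.founder_theta)
            if genetics
            else None
        )
        pop = init_population(preset.n_groups, mating, preset.life, pool, rng)
        record_every = max(1, preset.n_ticks // 10)
        rec = social.run(pop, preset.n_ticks, record_every, rng)
        return pop, None, rec
    if preset.generator == "coalescent":
        ds = simulate_msat_dataset(
            MsatConfig(preset.theta, preset.n_loci, preset.n_genes), rng, ploidy=2
        )
        return None, ds, None
    if preset.generator == "wf":
        mu = preset.theta / (2.0 * preset.wf_ploidy * preset.wf_n)
        cfg = WFConfig(
            ploidy=preset.wf_ploidy,
            n_individuals=preset.wf_n,
            n_loci=preset.n_loci,
            mu=mu,
            init=preset.wf_init,
            n_generations=preset.wf_generations,
        )
        full = run_wf(cfg, rng)
        return None, full, None
    raise ValueError(f"unknown generator {preset.generator!r}")


def _sample_for_inference(
    preset: ScenarioPreset, pop, ds, rng: np.random.Generator, n: int, n_loci: int
) -> GenotypeDataset:
    """Sample n diploid individuals (2n genes) for an inference stage."""
    if pop is not None:
        scheme = SamplingScheme(
            kind=preset.scheme_kind,
            n_individuals=n,
            pool_size=_POOL_OF.get(preset.n_groups, preset.n_groups),
        )
        sample = draw_sample(pop, scheme, rng)
    else:
        if preset.generator == "wf" and preset.wf_ploidy == 1:
            # pair sampled gene copies into pseudo-diploids (40 genes = 20)
            idx = rng.choice(ds.n_individuals, size=2 * n, replace=False)
            genes = ds.genotypes[idx, :, 0].T  # (L, 2n)
            sample = GenotypeDataset.from_gene_matrix(genes, ploidy=2)
        elif preset.generator == "wf":
            idx = rng.choice(ds.n_individuals, size=n, replace=False)
            sample = ds.subset(individuals=idx)
        else:
            sample = ds  # coalescent datasets are generated at sample size
    if n_loci < sample.n_loci:
        sample = sample.subset(loci=np.arange(n_loci))
    return sample


def run_scenario(
    preset_or_name,
    scale_factor: float = 1.0,
    base_seed: int = 20_000,
    out_dir=None,
) -> pd.DataFrame:
    """Run one preset's replicate battery and return the result table.

    Deterministic given ``base_seed``: replicate r uses seed base_seed + r,
    recorded in its row.  With ``out_dir`` the per-replicate table and the
    aggregate table are also written as TSV files.
    """
    if isinstance(preset_or_name, str):
        try:
            preset = PRESETS[preset_or_name]
        except KeyError:
            raise KeyError(
                f"unknown preset {preset_or_name!r}; valid presets: "
                + ", ".join(list_presets())
            ) from None
    else:
        preset = preset_or_name
    preset = _scaled(preset, scale_factor)

    rows = []
    genetics = preset.battery != "demography"
    for r in range(preset.n_replicates):
        seed = base_seed + r
        rng = np.random.default_rng(seed)
        pop, ds, rec = _generate(preset, rng, genetics)
        base = {
            "scenario": preset.name,
            "replicate": r,
            "seed": seed,
        }
        if rec is not None:
            tail = rec.table.iloc[-1]
            base.update(
                census=int(tail.census_size),
                n_rs=int(tail.n_rs),
                mean_he=float(tail.mean_he),
                fst=float(tail.fst),
                extinct=rec.extinct,
            )
        if preset.battery in ("none", "demography"):
            rows.append(base)
            continue
        if preset.battery == "heteq":
            sample = _sample_for_inference(
                preset, pop, ds, rng, preset.sample_n, preset.n_loci
            )
            res = test_dataset(sample, rng, n_sims=preset.heq_sims, alpha=preset.alpha)
            rows.append(
                base
                | {
                    "p_excess": res.p_excess,
                    "p_deficit": res.p_deficit,
                    "n_informative": res.n_informative_loci,
                    "verdict": res.verdict,
                }
            )
            continue
        if preset.battery == "ldne":
            mating_model = (
                "monogamy"
                if preset.generator == "social" and preset.mating == "monogamy"
                else "random"
            )
            for s in preset.ldne_sample_sizes:
                for sr in range(preset.ldne_sample_reps):
                    sample = _sample_for_inference(
                        preset, pop, ds, rng, s, preset.ldne_loci
                    )
                    est = estimate_ne(sample, LDNeConfig(mating_model=mating_model))
                    rows.append(
                        base
                        | {
                            "sample_size": s,
                            "sample_replicate": sr,
                            "mean_r2": est.mean_r2,
                            "r2_drift": est.r2_drift,
                            "ne_point": est.ne_point,
                            "infinite": est.infinite,
                        }
                    )
            continue
        raise ValueError(f"unknown battery {preset.battery!r}")

    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{preset.name}.tsv", sep="\t", index=False)
        if "verdict" in table.columns:
            agg = aggregate_proportions(table["verdict"])
            agg.to_csv(out / f"{preset.name}-aggregate.tsv", sep="\t")
    return table
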