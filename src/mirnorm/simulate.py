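"""Synthetic serum qPCR studies and microarray-style intensity matrices with
exported ground truth.

The Cq generator follows the multiplicative error model qPCR assumes
(normal noise on the Cq scale, i.e. log2 of abundance):

``Cq_gj = base_g + effect_g(group_j) + load_j + latent_coef_g * b_j + eps_gj``

with per-sample global load shifts ``load_j ~ N(0, load_sigma^2)`` (pipetting
and RNA-input variation, shared by every endogenous gene of a sample),
gene-specific noise ``eps ~ N(0, sigma_g^2)``, and an optional per-sample
latent "bone status" ``b_j ~ N(0,1)`` coupling biomarker levels to the
simulated BMD outcome. Group effects are in cycles *added* to Cq, so a
positive effect means down-regulation. Hemolysis is modeled as a shift on the
red-blood-cell marker gene only (its Cq drops by a uniform draw), leaving all
other genes untouched; the spike-in control is drawn around a fixed Cq with
small technical noise, independent of load (it monitors isolation, not input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CqMatrix, IntensityMatrix, SampleAnnotation, write_annotation, write_cq_table

__all__ = [
    "GeneSpec", "SimulationConfig", "GroundTruth",
    "simulate_cq_study", "simulate_intensity_matrix",
    "preset_config", "reference_screen_config", "write_study", "PRESETS",
]


@dataclass
class GeneSpec:
    """One simulated miRNA: baseline Cq, noise SD and per-group Cq shifts."""

    name: str
    base_cq: float = 25.0
    sigma: float = 0.5                     # cycles
    group_effects: Mapping[str, float] = field(default_factory=dict)  # cycles
    is_reference: bool = False
    latent_coef: float = 0.0               # cycles per SD of the latent status

    def effect(self, group: str) -> float:
        return float(self.group_effects.get(group, 0.0))


@dataclass
class SimulationConfig:
    """Study design for the synthetic generators; ``seed`` is mandatory."""

    groups: Mapping[str, int]              # group -> n samples
    genes: Sequence[GeneSpec]
    seed: int
    load_sigma: float = 0.5                # cycles
    max_cycles: float = 40.0
    # QC genes
    include_qc_genes: bool = True
    marker23_name: str = "miR-23a-3p"
    marker451_name: str = "miR-451a"
    marker_base_cq: float = 24.0
    marker_gap: float = 5.0                # clean-sample hemolysis index, cycles
    marker_sigma: float = 0.3
    hemolysis_fraction: float = 0.0
    hemolysis_delta_range: tuple[float, float] = (3.0, 8.0)
    spikein_gene: str = "cel-miR-39"
    spikein_cq: float = 25.0
    spikein_sigma: float = 0.15
    # covariates / outcome
    with_covariates: bool = True
    age_by_group: Mapping[str, tuple[float, float]] | None = None   # (mean, sd) years
    weight_mean_sd: tuple[float, float] = (62.0, 10.0)              # kg
    height_mean_sd: tuple[float, float] = (158.0, 6.0)              # cm
    bmd_group_means: Mapping[str, float] | None = None              # g/cm^2
    bmd_sigma: float = 0.07
    bmd_latent_coef: float = 0.0           # g/cm^2 per SD of latent status
    # intensity-matrix settings
    n_null_genes: int = 200
    intensity_log2_sd: float = 0.3
    intensity_log2_mean_range: tuple[float, float] = (6.0, 14.0)
    intensity_de: Mapping[str, float] = field(default_factory=dict)  # name -> linear fold

    def __post_init__(self) -> None:
        if not (0.0 <= self.hemolysis_fraction <= 1.0):
            raise ValueError("hemolysis_fraction must be in [0, 1]")
        for spec in self.genes:
            if spec.sigma < 0:
                raise ValueError(f"negative sigma for gene {spec.name!r}")
            for g in spec.group_effects:
                if g not in self.groups:
                    raise ValueError(f"gene {spec.name!r} has effect for unknown group {g!r}")
        if self.load_sigma < 0 or self.marker_sigma < 0 or self.spikein_sigma < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class GroundTruth:
    """Everything a test needs to score recovery against the generator."""

    reference_genes: list[str]
    gene_sigmas: dict[str, float]
    gene_effects: dict[str, dict[str, float]]
    de_genes: dict[str, float]             # gene -> max |effect| (cycles or log2 fold)
    hemolysed_samples: list[str]
    covariate_coefficients: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "reference_genes": list(self.reference_genes),
            "gene_sigmas": dict(self.gene_sigmas),
            "gene_effects": {k: dict(v) for k, v in self.gene_effects.items()},
            "de_genes": dict(self.de_genes),
            "hemolysed_samples": list(self.hemolysed_samples),
            "covariate_coefficients": dict(self.covariate_coefficients),
            "seed": self.seed,
        }


def _sample_names(groups: Mapping[str, int]) -> tuple[list[str], list[str]]:
    names, labels = [], []
    for g, n in groups.items():
        for i in range(int(n)):
            names.append(f"{g}_{i + 1}")
            labels.append(g)
    return names, labels


def simulate_cq_study(config: SimulationConfig, seed: int | None = None
                      ) -> tuple[CqMatrix, SampleAnnotation, GroundTruth]:
    """Generate a Cq study (panel + QC genes), annotation and ground truth.

    The same (config, seed) always yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples, labels = _sample_names(config.groups)
    n = len(samples)
    load = rng.normal(0.0, config.load_sigma, n)
    latent = rng.normal(0.0, 1.0, n)

    rows: dict[str, np.ndarray] = {}
    for spec in config.genes:
        eff = np.array([spec.effect(g) for g in labels])
        eps = rng.normal(0.0, spec.sigma, n)
        rows[spec.name] = spec.base_cq + eff + load + spec.latent_coef * latent + eps

    hemolysed: list[str] = []
    if config.include_qc_genes:
        n_hem = int(round(config.hemolysis_fraction * n))
        hem_idx = rng.choice(n, size=n_hem, replace=False) if n_hem else np.array([], int)
        hemolysed = [samples[i] for i in sorted(hem_idx)]
        shift = np.zeros(n)
        if n_hem:
            shift[hem_idx] = rng.uniform(*config.hemolysis_delta_range, n_hem)
        rows[config.marker23_name] = (config.marker_base_cq + load
                                      + rng.normal(0, config.marker_sigma, n))
        rows[config.marker451_name] = (config.marker_base_cq - config.marker_gap + load
                                       + rng.normal(0, config.marker_sigma, n) - shift)
        rows[config.spikein_gene] = config.spikein_cq + rng.normal(0, config.spikein_sigma, n)

    values = pd.DataFrame(rows, index=samples).T
    values = values.clip(lower=0.5, upper=config.max_cycles)
    cq = CqMatrix(values, max_cycles=config.max_cycles)

    ann_frame = pd.DataFrame({"group": labels}, index=samples)
    cov_coefs: dict = {}
    outcome = None
    if config.with_covariates:
        ages = np.empty(n)
        for i, g in enumerate(labels):
            mu, sd = (config.age_by_group or {}).get(g, (60.0, 8.0))
            ages[i] = rng.normal(mu, sd)
        ann_frame["age"] = np.round(ages, 1)
        ann_frame["weight"] = np.round(rng.normal(*config.weight_mean_sd, n), 1)
        ann_frame["height"] = np.round(rng.normal(*config.height_mean_sd, n), 1)
        if config.bmd_group_means is not None:
            means = np.array([config.bmd_group_means.get(g, 1.0) for g in labels])
            bmd = means + config.bmd_latent_coef * latent + rng.normal(0, config.bmd_sigma, n)
            ann_frame["bmd"] = np.round(bmd, 4)
            outcome = "bmd"
            cov_coefs = {
                "bmd_group_means": dict(config.bmd_group_means),
                "bmd_latent_coef": config.bmd_latent_coef,
                "bmd_sigma": config.bmd_sigma,
                "latent_cq_coefs": {s.name: s.latent_coef for s in config.genes
                                    if s.latent_coef},
            }
    ann = SampleAnnotation(ann_frame, outcome=outcome)

    effects = {s.name: dict(s.group_effects) for s in config.genes}
    de = {name: max(abs(v) for v in eff.values())
          for name, eff in effects.items() if any(v != 0 for v in eff.values())}
    truth = GroundTruth(
        reference_genes=[s.name for s in config.genes if s.is_reference],
        gene_sigmas={s.name: s.sigma for s in config.genes},
        gene_effects=effects,
        de_genes=de,
        hemolysed_samples=hemolysed,
        covariate_coefficients=cov_coefs,
        seed=int(config.seed if seed is None else seed),
    )
    return cq, ann, truth


def simulate_intensity_matrix(config: SimulationConfig, seed: int | None = None
                              ) -> tuple[IntensityMatrix, SampleAnnotation, GroundTruth]:
    """Log-normal intensity matrix for a two-group microarray-style screen.

    Null genes share a common log2 noise SD; genes in ``config.intensity_de``
    get the configured linear fold (case/control) applied in the case group
    (the second group of ``config.groups``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    levels = list(config.groups)
    if len(levels) < 2:
        raise ValueError("intensity simulation needs two groups")
    control, case = levels[0], levels[1]
    two = {control: config.groups[control], case: config.groups[case]}
    samples, labels = _sample_names(two)
    is_case = np.array([g == case for g in labels])

    names = [f"gene_{i + 1:04d}" for i in range(config.n_null_genes)]
    names += list(config.intensity_de)
    lo, hi = config.intensity_log2_mean_range
    mu = rng.uniform(lo, hi, len(names))
    log2fold = np.zeros(len(names))
    for i, g in enumerate(config.intensity_de):
        log2fold[config.n_null_genes + i] = np.log2(config.intensity_de[g])

    noise = rng.normal(0.0, config.intensity_log2_sd, (len(names), len(samples)))
    log2x = mu[:, None] + noise + np.outer(log2fold, is_case.astype(float))
    values = pd.DataFrame(np.power(2.0, log2x), index=names, columns=samples)
    expr = IntensityMatrix(values)
    ann = SampleAnnotation(pd.DataFrame({"group": labels}, index=samples))
    truth = GroundTruth(
        reference_genes=[],
        gene_sigmas={n: config.intensity_log2_sd for n in names},
        gene_effects={g: {case: float(np.log2(f))} for g, f in config.intensity_de.items()},
        de_genes={g: abs(float(np.log2(f))) for g, f in config.intensity_de.items()},
        hemolysed_samples=[],
        covariate_coefficients={},
        seed=int(config.seed if seed is None else seed),
    )
    return expr, ann, truth


# ---------------------------------------------------------------------------
# canonical study designs

def reference_screen_config(seed: int, n_genes: int = 10, n_per_group: int = 12,
                            stable_sigma: float = 0.1, unstable_sigma: float = 0.5,
                            max_bias: float = 1.0, load_sigma: float = 0.5,
                            groups: tuple[str, str] = ("control", "case")
                            ) -> SimulationConfig:
    """Designed reference-gene recovery study: one stable gene (``stable_sigma``
    cycles, no group effect) among noisy/biased candidates (``unstable_sigma``
    cycles, case-group biases spanning ±``max_bias`` cycles)."""
    control, case = groups
    genes = [GeneSpec("miR-ref", base_cq=24.0, sigma=stable_sigma, is_reference=True)]
    biases = np.linspace(-max_bias, max_bias, n_genes - 1)
    for i, b in enumerate(biases):
        genes.append(GeneSpec(f"miR-u{i + 1:02d}", base_cq=22.0 + i * 0.8,
                              sigma=unstable_sigma,
                              group_effects={case: float(b)}))
    return SimulationConfig(groups={control: n_per_group, case: n_per_group},
                            genes=genes, seed=seed, load_sigma=load_sigma,
                            include_qc_genes=True, with_covariates=False)


def _candidate_panel(effects_group: str | None = None) -> list[GeneSpec]:
    """A serum panel echoing a typical rodent candidate screen: one designed
    stable reference plus moderately noisy candidates."""
    panel = [
        GeneSpec("miR-25-3p", 24.5, 0.12, is_reference=True),
        GeneSpec("miR-140-5p", 26.0, 0.28),
        GeneSpec("miR-342-5p", 25.0, 0.30),
        GeneSpec("miR-19b-3p", 22.5, 0.40),
        GeneSpec("miR-150-5p", 23.5, 0.45),
        GeneSpec("miR-199a-3p", 27.0, 0.55),
        GeneSpec("miR-133b-3p", 29.0, 0.50),
        GeneSpec("miR-3473", 30.5, 0.60),
        GeneSpec("let-7i-5p", 23.0, 0.45),
    ]
    return panel


def preset_config(name: str, seed: int) -> SimulationConfig:
    """Named study designs used for demos and end-to-end tests.

    * ``ovx_rat``: 2 groups (sham/OVX, n = 8 each), candidate panel plus four
      biomarkers down-regulated in OVX.
    * ``clinical``: 3 groups (normal/osteopenia/osteoporosis, n = 19/7/10),
      age/weight/height covariates and a BMD outcome coupled to the
      biomarkers through a latent bone-status variable.
    * ``bedrest_monkey``: 2 groups (control/bedrest, n = 9/6), three
      biomarkers down-regulated after bedrest.
    """
    if name == "ovx_rat":
        genes = _candidate_panel()
        genes += [
            GeneSpec("miR-30b-5p", 26.5, 0.5, {"OVX": 1.3}),
            GeneSpec("miR-103-3p", 25.5, 0.5, {"OVX": 1.2}),
            GeneSpec("miR-142-3p", 24.0, 0.5, {"OVX": 1.4}),
            GeneSpec("miR-328-3p", 28.0, 0.5, {"OVX": 1.1}),
        ]
        return SimulationConfig(
            groups={"sham": 8, "OVX": 8}, genes=genes, seed=seed,
            hemolysis_fraction=0.0, with_covariates=False)
    if name == "clinical":
        genes = _candidate_panel()
        genes += [
            GeneSpec("miR-30b-5p", 26.5, 0.5,
                     {"osteopenia": 1.0, "osteoporosis": 1.2}, latent_coef=0.4),
            GeneSpec("miR-103-3p", 25.5, 0.5,
                     {"osteopenia": 0.3, "osteoporosis": 1.2}, latent_coef=0.4),
            GeneSpec("miR-142-3p", 24.0, 0.5,
                     {"osteopenia": 0.2, "osteoporosis": 1.3}, latent_coef=0.4),
            GeneSpec("miR-328-3p", 28.0, 0.5,
                     {"osteopenia": 0.1, "osteoporosis": 1.5}, latent_coef=0.4),
        ]
        return SimulationConfig(
            groups={"normal": 19, "osteopenia": 7, "osteoporosis": 10},
            genes=genes, seed=seed, hemolysis_fraction=0.1,
            age_by_group={"normal": (51.9, 2.6), "osteopenia": (72.9, 7.7),
                          "osteoporosis": (77.4, 4.5)},
            bmd_group_means={"normal": 1.06, "osteopenia": 0.79,
                             "osteoporosis": 0.58},
            bmd_sigma=0.07, bmd_latent_coef=-0.04)
    if name == "bedrest_monkey":
        genes = _candidate_panel()
        genes += [
            GeneSpec("miR-30b-5p", 26.5, 0.5, {"bedrest": 1.2}),
            GeneSpec("miR-103-3p", 25.5, 0.5, {"bedrest": 0.9}),
            GeneSpec("miR-142-3p", 24.0, 0.5, {"bedrest": 1.3}),
            GeneSpec("miR-328-3p", 28.0, 0.5, {}),
        ]
        return SimulationConfig(
            groups={"control": 9, "bedrest": 6}, genes=genes, seed=seed,
            with_covariates=False)
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = ("ovx_rat", "clinical", "bedrest_monkey")


def write_study(out_dir: str | Path, cq: CqMatrix, ann: SampleAnnotation,
                truth: GroundTruth) -> dict[str, str]:
    """Write cq.tsv, annotation.tsv and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"cq": str(out / "cq.tsv"), "annotation": str(out / "annotation.tsv"),
             "truth": str(out / "truth.json")}
    write_cq_table(cq, paths["cq"])
    write_annotation(ann, paths["annotation"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
        fh.write("\n")
    return paths
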