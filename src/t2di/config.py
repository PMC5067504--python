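"""Simulation and pipeline configuration.

``SimConfig`` fixes every parameter of the synthetic study: the interactome
generator, the two-group expression cohort, the GWAS summary statistics with
block LD, the regulatory/eQTL annotations and the comorbidity layer.  The
defaults emulate a desk-scale version of a 10-case / 10-control discovery
cohort with a planted 30-gene disease module; see docs/methods.md for the
rationale behind each default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import InvalidConfigError


@dataclass
class SimConfig:
    """Parameters of the synthetic study with a planted disease module."""

    seed: int = 0
    # interactome
    n_genes: int = 1000
    attach_m: int = 3
    module_size: int = 30
    n_seeds: int = 10
    module_extra_edge_prob: float = 0.2
    # expression cohort
    n_cases: int = 10
    n_controls: int = 10
    base_mean: float = 100.0
    dispersion: float = 0.1
    lfc_effect: float = 2.0
    neighbor_effect_prob: float = 0.05
    latent_sd: float = 0.6
    # GWAS
    snps_per_gene_mean: float = 3.0
    ld_block_size: int = 5
    gwas_ncp: float = 5.0
    # annotations / eQTL
    annot_enrichment: float = 8.0
    cell_types: tuple[str, ...] = ("islet", "adipose", "lcl")
    annot_base_rate: float = 0.1
    # comorbidity
    n_comorbid_diseases: int = 20
    shared_gene_rate: float = 0.3

    def validate(self) -> "SimConfig":
        counts = {
            "n_genes": self.n_genes,
            "attach_m": self.attach_m,
            "module_size": self.module_size,
            "n_seeds": self.n_seeds,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "ld_block_size": self.ld_block_size,
            "n_comorbid_diseases": self.n_comorbid_diseases,
        }
        for name, value in counts.items():
            if not isinstance(value, int) or value < 1:
                raise InvalidConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if self.module_size > self.n_genes:
            raise InvalidConfigError(
                f"module_size ({self.module_size}) must not exceed n_genes ({self.n_genes})"
            )
        if self.n_seeds > self.module_size:
            raise InvalidConfigError(
                f"n_seeds ({self.n_seeds}) must not exceed module_size ({self.module_size})"
            )
        for name in ("neighbor_effect_prob", "shared_gene_rate", "module_extra_edge_prob", "annot_base_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("base_mean", "dispersion", "snps_per_gene_mean"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.annot_enrichment <= 0:
            raise InvalidConfigError(f"annot_enrichment must be > 0, got {self.annot_enrichment!r}")
        if self.latent_sd < 0:
            raise InvalidConfigError("latent_sd must be >= 0")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "cell_types" in d:
            d["cell_types"] = tuple(d["cell_types"])
        return cls(**d).validate()


@dataclass
class DiscoveryParams:
    """Knobs of the two module-discovery algorithms and the DE gate.

    The production values are the published tool settings (200 diffusion
    iterations; annealing 1.0 -> 0.01 over 10^6 steps, 5 modules, overlap
    0.1; adjusted p < 0.05 with |log2FC| > 0.75).  ``test_profile`` scales
    the stochastic-search effort down for fast runs and stamps reports as
    scaled-down.
    """

    diamond_iterations: int = 200
    sa_start_temp: float = 1.0
    sa_end_temp: float = 0.01
    sa_iterations: int = 1_000_000
    n_modules: int = 5
    overlap_threshold: float = 0.1
    calibration_samples: int = 2000
    dge_alpha: float = 0.05
    dge_lfc_threshold: float = 0.75
    mi_threshold: float = 1.0
    n_rand_topology: int = 10_000
    n_rand_mc: int = 1_000_000
    n_control_sets: int = 100
    scaled_down: bool = False

    @classmethod
    def test_profile(cls) -> "DiscoveryParams":
        return cls(
            sa_iterations=10_000,
            calibration_samples=500,
            n_rand_topology=1000,
            n_rand_mc=1000,
            scaled_down=True,
        )

    def to_dict(self) -> dict:
        return asdict(self)
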