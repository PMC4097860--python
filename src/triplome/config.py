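"""Simulation configuration.

All generator parameters live in one dataclass tree so that a single YAML
file (plus a seed) fully determines every synthetic dataset.  Defaults mirror
the study conditions the package is validated against: mean per-strand read
depth ~7.3, genome-wide methylation levels CG >> CHG >> CHH (0.55/0.09/0.02),
biased retention of the three sub-genome copies (0.50/0.35/0.30), a
half-tetrad mapping population of 49 plants, and a 0.5% unmethylated
spike-in whose only positive reads come from bisulfite non-conversion
(default rate 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

SUBGENOMES = ("LF", "MF1", "MF2")
CONTEXTS = ("CG", "CHG", "CHH")
TISSUES = ("leaf", "root", "flower", "pod")
GENE_PARTS = (
    "promoter",
    "five_prime_UTR",
    "exon",
    "intron",
    "three_prime_UTR",
    "downstream",
)


@dataclass
class ExpressionModel:
    """Additive-plus-interaction model on the ln(FPKM+1) scale.

    y_ij = mu + G_i + T_j + GT_ij + eps_ij, with an optional dominance shift
    ``lf_shift_delta`` added to the least-fractionated row.  ``interaction_mode``
    selects GT_ij = 0 (``none``), sigma_GT * G_i * T_j (``multiplicative``,
    the exact alternative the Tukey one-degree-of-freedom test targets), or
    free N(0, sigma_GT^2) draws (``free``).
    """

    mu: float = 1.5
    sigma_G: float = 0.5
    sigma_T: float = 0.5
    sigma_GT: float = 0.3
    sigma_eps: float = 0.2
    lf_shift_delta: float = 0.0
    interaction_mode: str = "none"

    def validate(self) -> None:
        for name in ("sigma_G", "sigma_T", "sigma_GT", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.interaction_mode not in ("none", "multiplicative", "free"):
            raise ValueError(
                f"unknown interaction_mode {self.interaction_mode!r}"
            )


@dataclass
class MeiosisConfig:
    """Half-tetrad mapping design: FDR unreduced gametes, Haldane map."""

    map_length_morgans: float = 2.0
    centromere_pos_bp: int | None = None  # None -> 40% of chromosome length
    n_progeny: int = 49
    n_markers: int = 50
    missing_rate: float = 0.0

    def resolved_centromere(self, chrom_length_bp: int) -> int:
        if self.centromere_pos_bp is None:
            return max(1, round(0.4 * chrom_length_bp))
        return self.centromere_pos_bp

    def validate(self, chrom_length_bp: int) -> None:
        if self.map_length_morgans < 0:
            raise ValueError("map_length_morgans must be >= 0")
        if not (0 <= self.resolved_centromere(chrom_length_bp) <= chrom_length_bp):
            raise ValueError(
                "centromere_pos_bp outside chromosome "
                f"(0..{chrom_length_bp})"
            )
        if self.n_progeny <= 0 or self.n_markers < 2:
            raise ValueError("need n_progeny >= 1 and n_markers >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 300_000
    gc_fraction: float = 0.37
    n_ancestral_genes: int = 1000
    retention_probs: tuple[float, float, float] = (0.50, 0.35, 0.30)
    true_meth_levels: dict = field(
        default_factory=lambda: {"CG": 0.55, "CHG": 0.09, "CHH": 0.02}
    )
    # optional per-gene-part overrides: {part: {context: level}}
    feature_meth_levels: dict = field(default_factory=dict)
    depth_lambda: float = 7.29
    nonconversion_e: float = 0.005
    lambda_length_bp: int = 48_502
    expr_model: ExpressionModel = field(default_factory=ExpressionModel)
    meiosis: MeiosisConfig = field(default_factory=MeiosisConfig)

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.n_ancestral_genes < 0:
            raise ValueError("n_ancestral_genes must be >= 0")
        if len(self.retention_probs) != 3:
            raise ValueError("retention_probs must have 3 entries (LF, MF1, MF2)")
        for p in self.retention_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError("retention probabilities must be in [0, 1]")
        for ctx, lvl in self.true_meth_levels.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if not (0.0 <= lvl <= 1.0):
                raise ValueError("methylation levels must be in [0, 1]")
        if self.depth_lambda <= 0:
            raise ValueError("depth_lambda must be positive")
        if not (0.0 <= self.nonconversion_e < 1.0):
            raise ValueError("nonconversion_e must be in [0, 1)")
        self.expr_model.validate()
        self.meiosis.validate(self.chrom_length_bp)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["retention_probs"] = list(self.retention_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "expr_model" in d and isinstance(d["expr_model"], dict):
            d["expr_model"] = ExpressionModel(**d["expr_model"])
        if "meiosis" in d and isinstance(d["meiosis"], dict):
            d["meiosis"] = MeiosisConfig(**d["meiosis"])
        if "retention_probs" in d:
            d["retention_probs"] = tuple(d["retention_probs"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
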