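"""Study design for the synthetic-study generator.

The default design mirrors the field layout the analysis assumes: three
habitat groups (a pre-installation baseline Y0, plots one year after
solar-facility installation Y1, and plots six years after installation
Y6), six plots per group, and 23 ecosystem functions in six categories —
primary production (PP), soil nutrient pool (SNP), carbon / nitrogen /
phosphorus cycling and oxidation–reduction (redox).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CATEGORIES: dict[str, int] = {"PP": 2, "SNP": 5, "C": 6, "N": 5, "P": 3, "redox": 2}

#: Per-group mean shift of every function on the z-scale.  Y1 one SD above
#: baseline (construction-phase pulse) and Y6 slightly higher again, so the
#: per-year installation effect greatly exceeds the per-year running effect.
DEFAULT_EFFECT_PROFILE: dict[str, float] = {"Y0": 0.0, "Y1": 1.0, "Y6": 1.25}

#: Standardized effects of the latent plot-level drivers on every function:
#: microbial activity (MA) and microbial indicator taxa (Indicator) are the
#: true drivers; diversity (Div) and the environment composite (Env) carry
#: only weak direct effects.
DEFAULT_DRIVER_EFFECTS: dict[str, float] = {"MA": 0.6, "Indicator": 0.6, "Div": 0.1, "Env": 0.1}

#: Env → driver paths of the latent driver system (standardized).  Kept
#: deliberately modest so the "true driver" role of MA and Indicator is not
#: blurred by their shared upstream environmental cause.
DEFAULT_DRIVER_DAG: dict[tuple[str, str], float] = {
    ("Env", "MA"): 0.3,
    ("Env", "Div"): 0.3,
    ("Env", "Indicator"): 0.3,
}


@dataclass
class StudyDesign:
    """Parameters of one synthetic study; all randomness flows from `seed`."""

    n_groups: int = 3
    group_labels: tuple[str, ...] = ("Y0", "Y1", "Y6")
    plots_per_group: int = 6
    n_functions: int = 23
    categories: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    n_taxa_pro: int = 300
    n_taxa_fun: int = 200
    n_taxa_plant: int = 24
    n_indicator_planted: int = 20
    effect_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE)
    )
    driver_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIVER_EFFECTS)
    )
    driver_function_loading: float = 0.8
    rho_cat: float = 0.5
    noise_sd: float = 1.0
    depth: int = 50_000
    enrichment: float = 8.0
    n_modules: int = 8
    module_loading: float = 0.7
    base_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels must match n_groups")
        if self.plots_per_group < 3:
            raise ValueError("plots_per_group must be >= 3")
        if sum(self.categories.values()) != self.n_functions:
            raise ValueError("category sizes must sum to n_functions")
        for name in ("n_functions", "n_taxa_pro", "n_taxa_fun", "n_taxa_plant", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_indicator_planted < 0:
            raise ValueError("n_indicator_planted must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.enrichment <= 1:
            raise ValueError("planted-indicator enrichment must exceed 1")
        if not 0 <= self.rho_cat < 1:
            raise ValueError("rho_cat must be in [0, 1)")
        missing = set(self.effect_profile) - set(self.group_labels)
        if missing:
            raise ValueError(f"effect_profile refers to unknown groups: {sorted(missing)}")

    @property
    def n_plots(self) -> int:
        return self.n_groups * self.plots_per_group

    def plot_ids(self) -> list[str]:
        return [
            f"{g}_{p + 1}" for g in self.group_labels for p in range(self.plots_per_group)
        ]

    def groups(self) -> list[str]:
        return [g for g in self.group_labels for _ in range(self.plots_per_group)]

    def function_ids(self) -> list[str]:
        out = []
        for cat, k in self.categories.items():
            out += [f"{cat}_{i + 1}" for i in range(k)]
        return out

    def category_map(self) -> dict[str, str]:
        return {fid: fid.rsplit("_", 1)[0] for fid in self.function_ids()}

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
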