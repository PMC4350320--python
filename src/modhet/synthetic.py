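"""Synthetic probe-level expression data with planted modules and dispersion.

The generator emulates a breast-tissue microarray compendium: ~11 phenotypic
states (1 normal, 5 cancerous intrinsic subtypes, 5 matching metastatic
states) with unbalanced sample counts, block-correlated gene modules of
heterogeneous sizes, and a planted per-state multivariate dispersion that
increases along the subtype ladder, with each metastatic state matching its
cancerous counterpart.

Module structure uses a latent-factor model: each module has one latent
factor per sample; a module gene is loading * factor + Gaussian noise, and
background genes are pure noise. Heterogeneity is planted by scaling the
within-state factor standard deviation (default) or, alternatively, the
noise. Each state additionally carries a fixed per-gene mean program (its
expression signature) whose strength complements the within-state spread
(sigma^2 + tau^2 constant), so every gene's marginal variance is the same in
every state — as in real compendia, where subtype programs shift means
while heterogeneity is the within-subtype spread. Quantile normalization
therefore leaves the planted dispersion ladder intact. Genes are emitted as one or more probe
rows plus a fraction of unmapped probes, so preprocessing is exercised end
to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BACKGROUND = "background"

#: Per-state sample counts of the emulated compendium (total 286).
DEFAULT_STATES: tuple[tuple[str, str | None, int], ...] = (
    ("normal", None, 17),
    ("cancerous", "Claudin-low", 42),
    ("cancerous", "HER2-enriched", 22),
    ("cancerous", "Basal-like", 31),
    ("cancerous", "Luminal A", 80),
    ("cancerous", "Luminal B", 45),
    ("metastatic", "Claudin-low", 8),
    ("metastatic", "HER2-enriched", 13),
    ("metastatic", "Basal-like", 17),
    ("metastatic", "Luminal A", 6),
    ("metastatic", "Luminal B", 5),
)

#: Planted dispersion ladder: normal lowest, then Luminal A < HER2-enriched <
#: Luminal B < Claudin-low < Basal-like; metastatic equals its counterpart.
DEFAULT_DISPERSION_SCALE: dict[str, float] = {
    "normal": 1.0,
    "Luminal A": 1.25,
    "HER2-enriched": 1.5,
    "Luminal B": 1.75,
    "Claudin-low": 2.0,
    "Basal-like": 2.25,
    "Metastatic Luminal A": 1.25,
    "Metastatic HER2-enriched": 1.5,
    "Metastatic Luminal B": 1.75,
    "Metastatic Claudin-low": 2.0,
    "Metastatic Basal-like": 2.25,
}

#: Planted module sizes of the default design (8 modules, 2472 genes).
DEFAULT_MODULE_SIZES: tuple[int, ...] = (109, 369, 329, 620, 509, 241, 228, 67)


def state_label(stage: str, subtype: str | None) -> str:
    if stage == "normal":
        return "normal"
    if stage == "metastatic":
        return f"Metastatic {subtype}"
    return str(subtype)


@dataclass(frozen=True)
class SyntheticDesign:
    """Generator configuration; defaults mirror the emulated study design."""

    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    n_background_genes: int = 39
    states: tuple[tuple[str, str | None, int], ...] = DEFAULT_STATES
    dispersion_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISPERSION_SCALE)
    )
    factor_loading_range: tuple[float, float] = (0.6, 0.95)
    factor_energy: float = 2.5  # rms factor magnitude per module, all states
    program_module_weight: float = 0.0  # module-coherent share of state programs
    module_dispersion_scale: dict[str, dict[str, float]] | None = None
    noise_sd: float = 1.0
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive bounds
    probe_noise_sd: float = 0.05
    unmapped_probe_fraction: float = 0.05
    heterogeneity_source: str = "factor"  # or "noise"
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, n in self.states)

    def validate(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every planted module needs at least 2 genes")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")
        budget = sum(self.module_sizes) + self.n_background_genes
        if max(self.module_sizes, default=0) > budget:
            raise ValueError("a module size exceeds the requested gene budget")
        labels = {state_label(st, sub) for st, sub, _ in self.states}
        missing = labels - set(self.dispersion_scale)
        if missing:
            raise ValueError(f"dispersion_scale missing for states {sorted(missing)}")
        if any(v <= 0 for v in self.dispersion_scale.values()):
            raise ValueError("dispersion_scale values must be positive")
        lo, hi = self.factor_loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("factor_loading_range must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.heterogeneity_source == "factor" and self.factor_energy < max(
            self.dispersion_scale.values()
        ):
            raise ValueError(
                "factor_energy must be >= the largest dispersion_scale "
                "(state mean magnitude is sqrt(energy^2 - scale^2))"
            )
        pmin, pmax = self.probes_per_gene
        if pmin < 1 or pmax < pmin:
            raise ValueError("probes_per_gene bounds must satisfy 1 <= min <= max")
        if not (0 <= self.unmapped_probe_fraction < 1):
            raise ValueError("unmapped_probe_fraction must be in [0, 1)")
        if not (0 <= self.program_module_weight <= 1):
            raise ValueError("program_module_weight must be in [0, 1]")
        if self.heterogeneity_source not in ("factor", "noise"):
            raise ValueError("heterogeneity_source must be 'factor' or 'noise'")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for parameter-recovery tests."""

    module_of_gene: pd.Series  # gene -> module label or 'background'
    state_of_sample: pd.Series  # sample -> state label
    dispersion_scale: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "module_of_gene": self.module_of_gene.to_dict(),
            "state_of_sample": self.state_of_sample.to_dict(),
            "dispersion_scale": self.dispersion_scale,
        }


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Generate (probe matrix, probe map, annotation, truth) from a design.

    Fully reproducible from ``design.seed``: the same design yields
    bit-identical outputs.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    sample_rows = []
    for stage, subtype, n in design.states:
        for _ in range(n):
            sample_rows.append((stage, subtype))
    sample_ids = pd.Index(
        [f"s{i + 1:04d}" for i in range(len(sample_rows))], name="sample_id"
    )
    annotation = pd.DataFrame(sample_rows, index=sample_ids, columns=["stage", "subtype"])
    labels = annotation.apply(lambda r: state_label(r["stage"], r["subtype"]), axis=1)
    scale = labels.map(design.dispersion_scale).to_numpy(dtype=float)
    n_samples = len(sample_ids)

    gene_labels: list[str] = []
    module_of_gene: list[str] = []
    blocks: list[np.ndarray] = []
    lo, hi = design.factor_loading_range
    factor_sd = scale if design.heterogeneity_source == "factor" else np.ones(n_samples)
    noise_sd = (
        design.noise_sd * scale
        if design.heterogeneity_source == "noise"
        else np.full(n_samples, design.noise_sd)
    )
    # Each state carries a fixed per-gene mean program whose strength tau
    # complements the within-state factor spread (sigma^2 + tau^2 = energy^2),
    # so every gene has the same marginal variance in every state and quantile
    # normalization leaves the planted dispersion structure intact.
    energy2 = design.factor_energy**2
    program_sd = np.sqrt(np.maximum(energy2 - factor_sd**2, 0.0))
    state_codes, state_idx = np.unique(labels.to_numpy(), return_inverse=True)
    rho = design.program_module_weight
    overrides = design.module_dispersion_scale or {}
    for m, size in enumerate(design.module_sizes):
        name = f"M{m + 1}"
        if name in overrides and design.heterogeneity_source == "factor":
            sd_m = labels.map(overrides[name]).to_numpy(dtype=float)
            if np.isnan(sd_m).any() or (sd_m <= 0).any():
                raise ValueError(f"module_dispersion_scale[{name!r}] must cover all states")
            psd_m = np.sqrt(np.maximum(energy2 - sd_m**2, 0.0))
        else:
            sd_m, psd_m = factor_sd, program_sd
        factor = rng.normal(0.0, sd_m, size=n_samples)
        loadings = rng.uniform(lo, hi, size=size)
        # state program: a module-coherent part (states shift the whole
        # module) plus per-gene jitter (each gene's signature deviates)
        shared = rng.normal(0.0, 1.0, size=len(state_codes))
        own = rng.normal(0.0, 1.0, size=(size, len(state_codes)))
        program = rho * shared[None, :] + np.sqrt(1.0 - rho**2) * own
        noise = rng.normal(0.0, noise_sd, size=(size, n_samples))
        signal = loadings[:, None] * (
            factor[None, :] + program[:, state_idx] * psd_m[None, :]
        )
        blocks.append(signal + noise)
        gene_labels += [f"{name}_g{j + 1:04d}" for j in range(size)]
        module_of_gene += [name] * size
    if design.n_background_genes:
        noise = rng.normal(0.0, noise_sd, size=(design.n_background_genes, n_samples))
        blocks.append(noise)
        gene_labels += [f"BG_g{j + 1:04d}" for j in range(design.n_background_genes)]
        module_of_gene += [BACKGROUND] * design.n_background_genes
    gene_index = pd.Index(gene_labels, name="gene_id")
    gene_matrix = np.concatenate(blocks, axis=0)

    # expand genes into probe rows
    pmin, pmax = design.probes_per_gene
    n_probes_per_gene = rng.integers(pmin, pmax + 1, size=len(gene_index))
    probe_gene_idx = np.repeat(np.arange(len(gene_index)), n_probes_per_gene)
    probe_values = gene_matrix[probe_gene_idx]
    if design.probe_noise_sd > 0:
        probe_values = probe_values + rng.normal(
            0.0, design.probe_noise_sd, size=probe_values.shape
        )
    mapped_genes = [gene_index[i] for i in probe_gene_idx]

    n_mapped = len(mapped_genes)
    frac = design.unmapped_probe_fraction
    n_unmapped = int(round(frac * n_mapped / (1.0 - frac))) if frac > 0 else 0
    if n_unmapped:
        junk = rng.normal(0.0, design.noise_sd, size=(n_unmapped, n_samples))
        probe_values = np.concatenate([probe_values, junk], axis=0)
        mapped_genes += [None] * n_unmapped
    probe_ids = pd.Index(
        [f"p{i + 1:06d}" for i in range(len(mapped_genes))], name="probe_id"
    )
    probe_matrix = pd.DataFrame(probe_values, index=probe_ids, columns=sample_ids)
    probe_map = pd.Series(mapped_genes, index=probe_ids, dtype="object", name="gene_symbol")

    truth = SyntheticTruth(
        module_of_gene=pd.Series(module_of_gene, index=gene_index, name="module"),
        state_of_sample=labels.rename("state"),
        dispersion_scale=dict(design.dispersion_scale),
    )
    return probe_matrix, probe_map, annotation, truth


def planted_group_distances(truth: SyntheticTruth, data: pd.DataFrame) -> dict[str, float]:
    """Empirical mean distance-to-centroid per state, computed directly.

    A deliberately independent oracle for the dispersion pipeline: plain
    numpy arithmetic in gene space, no embedding, no shared code.
    """
    out: dict[str, float] = {}
    states = truth.state_of_sample.reindex(data.columns)
    for label in states.unique():
        cols = data.loc[:, (states == label).to_numpy()]
        x = cols.to_numpy(dtype=float)
        center = x.mean(axis=1, keepdims=True)
        dists = np.sqrt(((x - center) ** 2).sum(axis=0))
        out[str(label)] = float(dists.mean())
    return out


def blocks_design(
    seed: int = 0,
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES,
    n_samples: int = 286,
) -> SyntheticDesign:
    """Pure planted-block design for module-recovery studies.

    All states share the same dispersion scale equal to ``factor_energy``,
    so there are no state programs and genes correlate only through their
    module's latent factor — near-zero cross-block correlation. Single
    probes per gene, no unmapped probes.
    """
    energy = 2.5
    states = (("normal", None, n_samples),)
    return SyntheticDesign(
        module_sizes=tuple(module_sizes),
        n_background_genes=0,
        states=states,
        dispersion_scale={"normal": energy},
        factor_energy=energy,
        probes_per_gene=(1, 1),
        probe_noise_sd=0.0,
        unmapped_probe_fraction=0.0,
        seed=seed,
    )


def small_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """A scaled-down design for fast tests: 3 modules, 2 subtypes, 62 samples."""
    base = SyntheticDesign(
        module_sizes=(40, 30, 20),
        n_background_genes=10,
        states=(
            ("normal", None, 12),
            ("cancerous", "Luminal A", 15),
            ("cancerous", "Basal-like", 15),
            ("metastatic", "Luminal A", 10),
            ("metastatic", "Basal-like", 10),
        ),
        dispersion_scale={
            "normal": 1.0,
            "Luminal A": 1.3,
            "Basal-like": 2.0,
            "Metastatic Luminal A": 1.3,
            "Metastatic Basal-like": 2.0,
        },
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
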