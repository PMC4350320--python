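"""Orchestration: comparison plan, global and per-module dispersion analysis.

The phenotypic states form a design of one normal tissue state, a set of
cancerous subtypes, and metastatic counterparts of (a subset of) those
subtypes. The structured comparison plan covers normal-vs-cancer,
cancer-vs-its-metastatic, all cross-cancer and all cross-metastatic pairs —
with 1 normal + 5 cancerous + 5 metastatic states that is 5 + 5 + 10 + 10 =
30 comparisons. FDR correction is applied in two families: the global plan
on its own, and all per-module p-values pooled (|plan| x n_modules tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from . import dispersion as disp
from .module_detection import UNASSIGNED
from .preprocess import robust_standardize
from .synthetic import state_label

logger = logging.getLogger(__name__)

CATEGORIES = (
    "normal_vs_cancer",
    "cancer_vs_metastatic",
    "cross_cancer",
    "cross_metastatic",
)

GLOBAL_LABEL = "global"


@dataclass(frozen=True)
class PhenotypicState:
    """A (stage, subtype) sample group; subtype is None for normal tissue."""

    stage: str
    subtype: str | None = None

    def __post_init__(self):
        if self.stage not in ("normal", "cancerous", "metastatic"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "normal" and self.subtype is not None:
            raise ValueError("normal state carries no subtype")
        if self.stage != "normal" and not self.subtype:
            raise ValueError(f"{self.stage} state needs a subtype label")

    @property
    def label(self) -> str:
        return state_label(self.stage, self.subtype)


def states_from_annotation(annotation: pd.DataFrame) -> list[PhenotypicState]:
    """Distinct phenotypic states, in order of first appearance."""
    seen = []
    for _, row in annotation.iterrows():
        subtype = row["subtype"] if pd.notna(row["subtype"]) else None
        st = PhenotypicState(row["stage"], subtype)
        if st not in seen:
            seen.append(st)
    return seen


def sample_states(annotation: pd.DataFrame) -> pd.Series:
    """Per-sample state label derived from stage and subtype."""
    return annotation.apply(
        lambda r: state_label(
            r["stage"], r["subtype"] if pd.notna(r["subtype"]) else None
        ),
        axis=1,
    ).rename("state")


def build_comparison_plan(states: list[PhenotypicState]) -> pd.DataFrame:
    """Structured pairwise comparison plan over the phenotypic states.

    Emits normal vs each cancerous subtype, each cancerous subtype vs its
    metastatic counterpart, all cancerous pairs, and all metastatic pairs.
    With c cancerous and m metastatic subtypes the total is
    c + m + C(c,2) + C(m,2).
    """
    normal = [s for s in states if s.stage == "normal"]
    cancer = [s for s in states if s.stage == "cancerous"]
    metastatic = [s for s in states if s.stage == "metastatic"]
    if len(normal) != 1:
        raise ValueError(f"expected exactly one normal state, found {len(normal)}")
    cancer_subtypes = {s.subtype for s in cancer}
    orphans = [s.subtype for s in metastatic if s.subtype not in cancer_subtypes]
    if orphans:
        raise ValueError(f"metastatic states without cancerous counterpart: {orphans}")
    rows = []
    for s in cancer:
        rows.append((normal[0].label, s.label, "normal_vs_cancer"))
    for s in metastatic:
        counterpart = state_label("cancerous", s.subtype)
        rows.append((counterpart, s.label, "cancer_vs_metastatic"))
    for a, b in combinations(cancer, 2):
        rows.append((a.label, b.label, "cross_cancer"))
    for a, b in combinations(metastatic, 2):
        rows.append((a.label, b.label, "cross_metastatic"))
    plan = pd.DataFrame(rows, columns=["state_a", "state_b", "category"])
    key = plan[["state_a", "state_b"]].apply(frozenset, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate unordered state pair in plan")
    return plan


def annotation_report(annotation: pd.DataFrame) -> dict:
    """Per-state sample counts and their total (the sample-accounting check)."""
    states = sample_states(annotation)
    counts = states.value_counts(sort=False)
    return {
        "per_state": {str(k): int(v) for k, v in counts.items()},
        "total": int(counts.sum()),
    }


@dataclass
class DispersionAnalysis:
    """Result of one dispersion analysis (global or one module)."""

    label: str
    beta_diversity: pd.Series  # per-state mean distance to centre
    z: pd.Series  # per-sample distance to its state centre
    comparisons: pd.DataFrame  # state_a, state_b, category, F, p (q added later)


def _analyse(
    matrix: pd.DataFrame,
    states: pd.Series,
    plan: pd.DataFrame,
    label: str,
    n_permutations: int,
    center_type: str,
    master_seed: int,
    bias_adjust: bool = True,
) -> DispersionAnalysis:
    std = robust_standardize(matrix)
    d = disp.euclidean_distances(std)
    emb = disp.pcoa_embed(d)
    z = disp.distances_to_center(
        emb, states, center_type=center_type, bias_adjust=bias_adjust
    )
    bd = disp.beta_diversity(z, states)
    rows = []
    for _, cmp_row in plan.iterrows():
        a, b = cmp_row["state_a"], cmp_row["state_b"]
        mask = states.isin([a, b])
        counts = states[mask].value_counts()
        if counts.min() < 2 or len(counts) < 2:
            logger.warning("skipping %s vs %s in %s: group with < 2 members", a, b, label)
            continue
        seed = disp.comparison_seed(master_seed, label, a, b)
        res = disp.permdisp_test(
            z[mask.to_numpy()], states[mask.to_numpy()], n_permutations, seed
        )
        rows.append(
            {
                "analysis": label,
                "state_a": a,
                "state_b": b,
                "category": cmp_row["category"],
                "beta_div_a": res.beta_div_a,
                "beta_div_b": res.beta_div_b,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    return DispersionAnalysis(
        label=label, beta_diversity=bd, z=z, comparisons=pd.DataFrame(rows)
    )


def run_global(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    plan: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    center_type: str = "spatial_median",
    seed: int = 0,
    bias_adjust: bool = True,
) -> DispersionAnalysis:
    """Global transcriptome heterogeneity over all genes jointly.

    Robust-standardizes all genes together, computes pairwise Euclidean
    sample distances, runs the dispersion analysis over the comparison plan,
    and FDR-adjusts the plan's p-values as one family.
    """
    states = sample_states(annotation).reindex(matrix.columns)
    if states.isna().any():
        raise ValueError("annotation missing for some matrix columns")
    if plan is None:
        plan = build_comparison_plan(states_from_annotation(annotation))
    result = _analyse(
        matrix, states, plan, GLOBAL_LABEL, n_permutations, center_type, seed,
        bias_adjust=bias_adjust,
    )
    result.comparisons["fdr_adjusted_p"] = disp.fdr_adjust(
        result.comparisons["p_value"].to_numpy()
    )
    return result


def run_local(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    modules: pd.Series,
    plan: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    center_type: str = "spatial_median",
    seed: int = 0,
    bias_adjust: bool = True,
) -> dict[str, DispersionAnalysis]:
    """Per-module heterogeneity with a pooled FDR family.

    Each module's genes are robust-standardized separately before the
    dispersion analysis; all modules' p-values are pooled into a single
    FDR family of size |plan| x n_modules.
    """
    states = sample_states(annotation).reindex(matrix.columns)
    if plan is None:
        plan = build_comparison_plan(states_from_annotation(annotation))
    results: dict[str, DispersionAnalysis] = {}
    for label in modules.unique():
        if label == UNASSIGNED:
            continue
        genes = modules.index[modules == label]
        missing = genes.difference(matrix.index)
        if len(missing):
            raise ValueError(f"module {label!r} genes absent from matrix: {list(missing)[:5]}")
        if len(genes) < 2:
            logger.warning("skipping module %s with < 2 genes", label)
            continue
        results[label] = _analyse(
            matrix.loc[genes], states, plan, label, n_permutations, center_type,
            seed, bias_adjust=bias_adjust,
        )
    if results:
        pooled = pd.concat([r.comparisons for r in results.values()], ignore_index=True)
        pooled["fdr_adjusted_p"] = disp.fdr_adjust(pooled["p_value"].to_numpy())
        offset = 0
        for r in results.values():
            k = len(r.comparisons)
            r.comparisons["fdr_adjusted_p"] = pooled["fdr_adjusted_p"].iloc[
                offset : offset + k
            ].to_numpy()
            offset += k
    return results


def pooled_comparison_table(results: dict[str, DispersionAnalysis]) -> pd.DataFrame:
    """All per-module comparisons in one tidy table (module, pair, F, p, q)."""
    if not results:
        return pd.DataFrame()
    return pd.concat([r.comparisons for r in results.values()], ignore_index=True)


def significance_matrix(
    results: dict[str, DispersionAnalysis],
    alpha: float = 0.01,
    exclude_modules: tuple[str, ...] = (),
    include_metastatic: bool = False,
    sort_rows: bool = True,
) -> pd.DataFrame:
    """Module x comparison boolean matrix of FDR-significant dispersion tests.

    By default only the non-metastatic comparisons (normal-vs-cancer and
    cross-cancer) are displayed. Rows are ordered by the number of subtypes
    in which the module has significantly *higher* beta-diversity than
    normal tissue.
    """
    table = pooled_comparison_table(results)
    if table.empty:
        return pd.DataFrame()
    if "fdr_adjusted_p" not in table:
        raise ValueError("FDR-adjusted p-values required; run run_local first")
    table = table[~table["analysis"].isin(exclude_modules)]
    if not include_metastatic:
        table = table[table["category"].isin(["normal_vs_cancer", "cross_cancer"])]
    table = table.copy()
    table["comparison"] = table["state_a"] + " vs " + table["state_b"]
    table["significant"] = table["fdr_adjusted_p"] < alpha
    matrix = table.pivot(index="analysis", columns="comparison", values="significant")
    if sort_rows:
        nvc = table[table["category"] == "normal_vs_cancer"]
        higher = nvc["significant"] & (nvc["beta_div_b"] > nvc["beta_div_a"])
        score = higher.groupby(nvc["analysis"]).sum()
        matrix = matrix.loc[
            score.reindex(matrix.index).fillna(0).sort_values(ascending=False).index
        ]
    return matrix


def z_table(analyses: dict[str, DispersionAnalysis] | list[DispersionAnalysis], states: pd.Series) -> pd.DataFrame:
    """Tidy per-sample distance-to-centre table (the box-plot data)."""
    if isinstance(analyses, dict):
        analyses = list(analyses.values())
    frames = []
    for a in analyses:
        frames.append(
            pd.DataFrame(
                {
                    "analysis": a.label,
                    "sample_id": a.z.index,
                    "state": states.reindex(a.z.index).to_numpy(),
                    "distance_to_center": a.z.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
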