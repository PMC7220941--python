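"""Cumulative-score quantification of reference stimulation signatures.

The question this module answers: which stimulated-vs-control reference
comparison best explains a target tissue contrast? Genes are ranked by
their target-contrast scores; walking down that ranking, the running sum
of each reference comparison's scores for the same genes is compared with
the target's own running sum (the 100% line). The ratio of the two curves
— reported as a percentage, both its maximum over ranks ("up to X%") and
its value at the final rank — quantifies how fully the reference pattern
reproduces the target signature. The reverse analysis swaps roles (target
scores accumulated over reference-defined rankings), and top-N overlap
counts and gene-set filters (e.g. secreted-protein annotations) provide
complementary views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import Compendium
from .pairwise import (
    SelectionCriteria,
    call_changes,
    collapse_to_genes,
    compute_pairwise_slr,
    score_genes,
    select_differential,
)
from .types import ExpressionMatrix, GeneSet, PipelineError

__all__ = [
    "ReferenceComparison",
    "CumulativeScoreCurve",
    "score_contrast",
    "score_reference_comparisons",
    "cumulative_curves",
    "percent_of_target",
    "reverse_analysis",
    "top_overlap",
    "filter_by_gene_set",
]


@dataclass(frozen=True)
class ReferenceComparison:
    """One stimulated-vs-control contrast inside the compendium."""

    name: str
    stimulated: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.stimulated) < 2 or len(self.control) < 2:
            raise PipelineError(f"{self.name!r}: need >= 2 arrays per arm")
        if set(self.stimulated) & set(self.control):
            raise PipelineError(f"{self.name!r}: overlapping arms")

    @classmethod
    def from_compendium(cls, comp: Compendium, condition: str) -> "ReferenceComparison":
        """Build the contrast of a stimulated condition against its linked control."""
        control_cond = comp.control_condition_of(condition)
        if control_cond is None:
            raise PipelineError(f"condition {condition!r} has no control link")
        return cls(
            condition,
            tuple(comp.arrays_of(condition)),
            tuple(comp.arrays_of(control_cond)),
        )


@dataclass
class CumulativeScoreCurve:
    """Running reference score along a target-defined gene ranking.

    ``table`` columns: rank, gene, target_score, ref_score, target_cumsum,
    ref_cumsum, ratio, missing (gene absent from the reference universe,
    contributing 0).
    """

    target_name: str
    reference_name: str
    table: pd.DataFrame
    missing_genes: list[str] = field(default_factory=list)

    @property
    def final_ratio(self) -> float:
        return float(self.table["ratio"].iloc[-1])

    @property
    def max_ratio(self) -> float:
        return float(self.table["ratio"].max())


def score_contrast(
    expr: ExpressionMatrix,
    experimental_group: str,
    baseline_group: str,
    criteria: SelectionCriteria = SelectionCriteria(),
    mapping: pd.Series | None = None,
) -> pd.DataFrame:
    """Select, score and collapse one contrast to a per-gene score table.

    Convenience wrapper chaining the pairwise stage: selection first, then
    the mean-SLR x net-frequency score for every probe-set, collapsed to
    one representative probe-set per gene and ranked by score.
    """
    selection = select_differential(expr, experimental_group, baseline_group, criteria)
    floored = expr.floored(criteria.signal_floor)
    pc = compute_pairwise_slr(floored, experimental_group, baseline_group)
    calls = call_changes(pc, criteria)
    scores = score_genes(pc, calls, selection)
    if mapping is None and expr.gene_map is not None:
        mapping = expr.gene_map
    return collapse_to_genes(scores, mapping)


def score_reference_comparisons(
    comp: Compendium,
    comparisons: list[ReferenceComparison],
    criteria: SelectionCriteria = SelectionCriteria(),
    mapping: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene score table for every reference comparison.

    Reuses the pairwise machinery on each stimulated-vs-control contrast
    of the (normalised) compendium, with the same criteria as the target
    contrast so scores are commensurable.
    """
    sample_set = set(comp.expr.samples)
    out: dict[str, pd.DataFrame] = {}
    for rc in comparisons:
        absent = [a for a in (*rc.stimulated, *rc.control) if a not in sample_set]
        if absent:
            raise PipelineError(f"{rc.name!r}: arrays not in compendium: {absent[:5]}")
        sub = comp.expr.subset(list(rc.stimulated) + list(rc.control))
        groups = pd.Series(
            ["stim"] * len(rc.stimulated) + ["ctrl"] * len(rc.control),
            index=list(rc.stimulated) + list(rc.control),
        )
        sub = ExpressionMatrix(sub.values, groups, comp.expr.gene_map)
        out[rc.name] = score_contrast(sub, "stim", "ctrl", criteria, mapping)
    return out


def _ranked_top(table: pd.DataFrame, top_n: int) -> pd.DataFrame:
    if top_n <= 0:
        raise PipelineError("top_n must be positive")
    if top_n > len(table):
        raise PipelineError(f"top_n={top_n} exceeds table length {len(table)}")
    ranked = table.sort_values("rank") if "rank" in table.columns else table
    return ranked.iloc[:top_n]


def cumulative_curves(
    target: pd.DataFrame,
    references: dict[str, pd.DataFrame],
    top_n: int = 100,
    target_name: str = "target",
    clip_negative: bool = False,
) -> dict[str, CumulativeScoreCurve]:
    """Cumulative reference scores along the target's top-``top_n`` ranking.

    For each reference, genes in the target ranking but absent from the
    reference table contribute 0 and are flagged. With ``clip_negative``,
    negative reference scores are floored at 0 before accumulation;
    by default they enter signed and can depress the curve.
    """
    top = _ranked_top(target, top_n)
    genes = top.index
    t_scores = top["score"].to_numpy(dtype=float)
    t_cum = np.cumsum(t_scores)
    curves: dict[str, CumulativeScoreCurve] = {}
    for name, ref in references.items():
        aligned = ref["score"].reindex(genes)
        missing = [g for g in genes[aligned.isna()]]
        r_scores = aligned.fillna(0.0).to_numpy(dtype=float)
        if clip_negative:
            r_scores = np.clip(r_scores, 0.0, None)
        r_cum = np.cumsum(r_scores)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(t_cum != 0, r_cum / t_cum, np.nan)
        table = pd.DataFrame(
            {
                "rank": np.arange(1, len(genes) + 1),
                "gene": genes,
                "target_score": t_scores,
                "ref_score": r_scores,
                "target_cumsum": t_cum,
                "ref_cumsum": r_cum,
                "ratio": ratio,
                "missing": aligned.isna().to_numpy(),
            }
        ).set_index("rank")
        curves[name] = CumulativeScoreCurve(target_name, name, table, missing)
    return curves


def percent_of_target(curve: CumulativeScoreCurve) -> tuple[float, float]:
    """(max ratio over ranks, final-rank ratio), both as percentages.

    The maximum corresponds to the "reaches up to X% of the target score"
    summary; the final-rank value is reported alongside because a curve
    can peak early and fall back.
    """
    return 100.0 * curve.max_ratio, 100.0 * curve.final_ratio


def summarize_curves(curves: dict[str, CumulativeScoreCurve]) -> pd.DataFrame:
    """One row per reference: percent_max, percent_final, sorted by percent_max."""
    rows = []
    for name, curve in curves.items():
        pct_max, pct_final = percent_of_target(curve)
        rows.append({"reference": name, "percent_max": pct_max, "percent_final": pct_final})
    df = pd.DataFrame(rows).set_index("reference")
    return df.sort_values(["percent_max", "percent_final"], ascending=False)


def reverse_analysis(
    references: dict[str, pd.DataFrame],
    target: pd.DataFrame,
    top_n: int = 100,
    target_name: str = "target",
    clip_negative: bool = False,
) -> dict[str, CumulativeScoreCurve]:
    """Apply target scores to each reference's own top-``top_n`` genes.

    Roles are swapped relative to :func:`cumulative_curves`: the ranking
    and the 100% line come from the reference, and the accumulated scores
    from the target, asking how much of each reference pattern the target
    contrast reproduces.
    """
    out: dict[str, CumulativeScoreCurve] = {}
    for name, ref in references.items():
        curve = cumulative_curves(
            ref, {target_name: target}, top_n, target_name=name, clip_negative=clip_negative
        )[target_name]
        curve.target_name = name
        curve.reference_name = target_name
        out[name] = curve
    return out


def top_overlap(
    table_a: pd.DataFrame, table_b: pd.DataFrame, top_n: int = 100
) -> tuple[int, list[str]]:
    """|top_n(A) ∩ top_n(B)| and the sorted shared gene list."""
    top_a = set(_ranked_top(table_a, top_n).index)
    top_b = set(_ranked_top(table_b, top_n).index)
    shared = sorted(top_a & top_b)
    return len(shared), shared


def filter_by_gene_set(
    table: pd.DataFrame, gene_sets: GeneSet | list[GeneSet]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows whose gene lies in the union of the gene sets.

    Works on any frame whose index (or ``gene`` column) carries symbols,
    e.g. a collapsed score table or a probe-set selection joined with
    symbols. Returns the filtered frame plus probe-set / distinct-gene
    counts.
    """
    sets = [gene_sets] if isinstance(gene_sets, GeneSet) else list(gene_sets)
    if not sets:
        raise PipelineError("no gene sets given")
    union: set[str] = set()
    for gs in sets:
        union |= gs.members
    symbols = (
        table["gene"].astype(str) if "gene" in table.columns else table.index.astype(str)
    )
    mask = symbols.str.upper().isin(union)
    kept = table.loc[np.asarray(mask)]
    kept_symbols = symbols[np.asarray(mask)]
    counts = {
        "probe_sets": int(mask.sum()),
        "genes": int(pd.Index(kept_symbols.str.upper()).nunique()),
    }
    return kept, counts
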