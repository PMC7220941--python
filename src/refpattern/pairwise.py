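"""All-pairs differential expression selection and gene scoring.

Given two sample groups, every experimental sample is compared with every
baseline sample. Each pair yields, per probe-set, a signal log ratio
(SLR = log2 experimental - log2 baseline) and a change call (Increase /
Decrease / NoChange by a symmetric SLR threshold). A probe-set is selected
as differentially expressed when

* (major criterion) at least ``f_major`` of all pairs agree on a
  direction, or
* (minor criterion) at least ``f_minor`` of pairs agree AND the
  experimental group is more homogeneous than the baseline group,

and, in either case, a one-sample t-test of the pairwise SLRs against 0
survives Bonferroni correction over all probe-sets tested. Selected
probe-sets get a signed score — mean SLR times change-call frequency —
which combines effect size with the consistency of the change across pairs, and
per-gene tables keep the probe-set of largest absolute score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigurationError, ExpressionMatrix, PipelineError

__all__ = [
    "SelectionCriteria",
    "PairwiseComparisons",
    "compute_pairwise_slr",
    "call_changes",
    "select_differential",
    "score_genes",
    "collapse_to_genes",
]

CALL_INCREASE = 1
CALL_NOCHANGE = 0
CALL_DECREASE = -1


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the pairwise selection procedure.

    f_major
        Call-frequency threshold that selects on its own (default 0.50).
    f_minor
        Lower frequency threshold that additionally requires the
        experimental group to be more homogeneous (default 0.30).
    slr_call_threshold
        |SLR| in log2 units above which a pair is called changed
        (default 0.5, i.e. ~1.4-fold).
    alpha
        Significance level applied to the Bonferroni-adjusted one-sample
        SLR t-test (default 0.05).
    homogeneity_rule
        Dispersion measure for the minor criterion: 'cv_log2' (coefficient
        of variation of log2 signals, default) or 'sd_log2'.
    signal_floor
        Signals are clipped from below at this value before taking logs.
    """

    f_major: float = 0.50
    f_minor: float = 0.30
    slr_call_threshold: float = 0.5
    alpha: float = 0.05
    homogeneity_rule: str = "cv_log2"
    signal_floor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.f_minor <= self.f_major <= 1):
            raise ConfigurationError("need 0 < f_minor <= f_major <= 1")
        if self.slr_call_threshold < 0:
            raise ConfigurationError("slr_call_threshold must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.homogeneity_rule not in ("cv_log2", "sd_log2"):
            raise ConfigurationError(f"unknown homogeneity_rule {self.homogeneity_rule!r}")
        if self.signal_floor <= 0:
            raise ConfigurationError("signal_floor must be positive")


@dataclass
class PairwiseComparisons:
    """SLRs of every (experimental, baseline) ordered sample pair.

    ``slr`` is probe-sets x pairs; ``pairs`` lists (experimental sample,
    baseline sample) in column order, so n_pairs = n_exp * n_base.
    """

    slr: pd.DataFrame
    pairs: list[tuple[str, str]]
    experimental_group: str
    baseline_group: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _group_samples(expr: ExpressionMatrix, experimental: str, baseline: str):
    exp_samples = expr.samples_in_group(experimental)
    base_samples = expr.samples_in_group(baseline)
    if not exp_samples or not base_samples:
        raise PipelineError("both groups must be non-empty")
    overlap = set(exp_samples) & set(base_samples)
    if overlap:
        raise PipelineError(f"samples in both groups: {sorted(overlap)[:5]}")
    return exp_samples, base_samples


def compute_pairwise_slr(
    expr: ExpressionMatrix, experimental_group: str, baseline_group: str
) -> PairwiseComparisons:
    """SLR(g, i, j) = log2 signal(g, i) - log2 signal(g, j) for all pairs.

    Signals must already be positive (apply :meth:`ExpressionMatrix.floored`
    first if a floor is wanted — flooring is an explicit configuration step,
    not something this function does silently).
    """
    exp_samples, base_samples = _group_samples(expr, experimental_group, baseline_group)
    log2 = expr.log2()
    cols: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str]] = []
    for i in exp_samples:
        li = log2[i].to_numpy()
        for j in base_samples:
            pairs.append((i, j))
            cols[f"{i}|{j}"] = li - log2[j].to_numpy()
    slr = pd.DataFrame(cols, index=expr.probe_sets)
    return PairwiseComparisons(slr, pairs, experimental_group, baseline_group)


def call_changes(
    pc: PairwiseComparisons, criteria: SelectionCriteria = SelectionCriteria()
) -> pd.DataFrame:
    """Per-pair change calls: +1 Increase, -1 Decrease, 0 NoChange."""
    thr = criteria.slr_call_threshold
    arr = pc.slr.to_numpy()
    calls = np.where(arr > thr, CALL_INCREASE, np.where(arr < -thr, CALL_DECREASE, CALL_NOCHANGE))
    return pd.DataFrame(calls.astype(np.int8), index=pc.slr.index, columns=pc.slr.columns)


def _dispersion(log2_block: pd.DataFrame, rule: str) -> np.ndarray:
    sd = log2_block.std(axis=1, ddof=1).to_numpy()
    if rule == "sd_log2":
        return sd
    mean = log2_block.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    return cv


def _slr_t_test(slr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t of the pairwise SLRs against 0.

    Degenerate rows (zero SLR variance) get p = 0 when the common SLR is
    non-zero and p = 1 when it is exactly 0.
    """
    n = slr.shape[1]
    mean = slr.mean(axis=1)
    sd = slr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0
    p[degenerate & (mean != 0)] = 0.0
    t[degenerate & (mean != 0)] = np.inf * np.sign(mean[degenerate & (mean != 0)])
    p[degenerate & (mean == 0)] = 1.0
    t[degenerate & (mean == 0)] = 0.0
    return t, p


def select_differential(
    expr: ExpressionMatrix,
    experimental_group: str,
    baseline_group: str,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> pd.DataFrame:
    """Run the full pairwise selection and return the per-probe-set table.

    Columns: n_increase, n_decrease, n_pairs, freq_increase, freq_decrease,
    mean_slr, t_statistic, p_raw, p_bonferroni, selected, direction
    ('up'/'down'/'none'), criterion_used ('major'/'minor'/'none').
    """
    exp_samples, base_samples = _group_samples(expr, experimental_group, baseline_group)
    if len(exp_samples) < 2 or len(base_samples) < 2:
        raise PipelineError("need >= 2 samples per group for the SLR t-test")
    floored = expr.floored(criteria.signal_floor)
    pc = compute_pairwise_slr(floored, experimental_group, baseline_group)
    calls = call_changes(pc, criteria)

    n_pairs = pc.n_pairs
    call_arr = calls.to_numpy()
    n_inc = (call_arr == CALL_INCREASE).sum(axis=1)
    n_dec = (call_arr == CALL_DECREASE).sum(axis=1)
    freq_inc = n_inc / n_pairs
    freq_dec = n_dec / n_pairs

    slr_arr = pc.slr.to_numpy()
    mean_slr = slr_arr.mean(axis=1)
    t_stat, p_raw = _slr_t_test(slr_arr)
    n_tested = len(expr.probe_sets)
    p_bonf = np.minimum(1.0, p_raw * n_tested)
    significant = p_bonf <= criteria.alpha

    log2 = floored.log2()
    disp_exp = _dispersion(log2[exp_samples], criteria.homogeneity_rule)
    disp_base = _dispersion(log2[base_samples], criteria.homogeneity_rule)
    more_homogeneous = disp_exp < disp_base

    up_major = freq_inc >= criteria.f_major
    up_minor = (freq_inc >= criteria.f_minor) & more_homogeneous
    down_major = freq_dec >= criteria.f_major
    down_minor = (freq_dec >= criteria.f_minor) & more_homogeneous
    up_ok = (up_major | up_minor) & significant
    down_ok = (down_major | down_minor) & significant

    direction = np.full(n_tested, "none", dtype=object)
    criterion = np.full(n_tested, "none", dtype=object)
    # direction with the larger call frequency wins; exact ties stay unselected
    up_wins = up_ok & (~down_ok | (freq_inc > freq_dec))
    down_wins = down_ok & (~up_ok | (freq_dec > freq_inc))
    direction[up_wins] = "up"
    direction[down_wins] = "down"
    criterion[up_wins] = np.where(up_major[up_wins], "major", "minor")
    criterion[down_wins] = np.where(down_major[down_wins], "major", "minor")
    selected = direction != "none"

    return pd.DataFrame(
        {
            "n_increase": n_inc,
            "n_decrease": n_dec,
            "n_pairs": n_pairs,
            "freq_increase": freq_inc,
            "freq_decrease": freq_dec,
            "mean_slr": mean_slr,
            "t_statistic": t_stat,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "selected": selected,
            "direction": direction,
            "criterion_used": criterion,
        },
        index=expr.probe_sets,
    )


def score_genes(
    pc: PairwiseComparisons, calls: pd.DataFrame, selection: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Signed per-probe-set score: mean SLR x change-call frequency.

        score = mean_SLR * (n_increase + n_decrease) / n_pairs

    The mean SLR carries the sign and magnitude of the change; the
    frequency of changed calls weights it by how consistently the change
    appears across pairs. The score is dimensionless (|score| <= max
    |SLR|), positive for consistently increased probe-sets, negative for
    decreased ones, and negates exactly when the groups are swapped.
    Returns a frame with ``score`` plus the selection columns when a
    selection table for the same contrast is supplied.
    """
    if pc.n_pairs == 0:
        raise PipelineError("no pairs to score")
    call_arr = calls.to_numpy()
    n_changed = (call_arr != CALL_NOCHANGE).sum(axis=1)
    score = pc.slr.to_numpy().mean(axis=1) * n_changed / pc.n_pairs
    out = pd.DataFrame({"score": score}, index=pc.slr.index)
    if selection is not None:
        if not out.index.equals(selection.index):
            raise PipelineError("selection table does not match the scored probe-sets")
        out = out.join(selection[["selected", "direction"]])
    return out


def collapse_to_genes(
    scores: pd.DataFrame, mapping: pd.Series | None = None
) -> pd.DataFrame:
    """Keep one representative probe-set per gene and rank by score.

    The representative is the probe-set with maximal |score|; ties are
    broken by lexicographic probe-set ID so runs are reproducible. Genes
    are ranked in descending score order (up-contrast convention), ties
    again broken by probe-set ID. Probe-sets without a mapping pass
    through under their own ID with ``mapped = False``.
    """
    table = scores.copy()
    table.index = table.index.astype(str).rename(None)
    table["probe_set"] = table.index
    if mapping is not None:
        mapped = table["probe_set"].map(mapping)
        table["gene"] = mapped.fillna(table["probe_set"])
        table["mapped"] = mapped.notna()
    else:
        table["gene"] = table["probe_set"]
        table["mapped"] = True
    table["_abs"] = table["score"].abs()
    # max |score| wins; lexicographically smallest probe-set ID on ties
    table = table.sort_values(["_abs", "probe_set"], ascending=[False, True])
    table = table.drop_duplicates("gene", keep="first").drop(columns="_abs")
    table = table.sort_values(["score", "probe_set"], ascending=[False, True])
    table = table.set_index("gene")
    table["rank"] = np.arange(1, len(table) + 1)
    return table
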