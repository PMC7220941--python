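"""Ground-truthed synthetic expression data.

Generates two kinds of inputs for the pipeline:

* a *reference compendium* — replicated arrays of purified cell types, some
  of them under a defined stimulus, each stimulated arm linked to its
  control arm; and
* a *mixed-tissue cohort* — bulk samples that are per-sample simplex
  mixtures of the cell-type profiles, with stimuli acting multiplicatively
  on the contributing cell type's component only.

The generative model is deliberately simple: per-gene log2 signal =
global baseline + cell-type marker offset + stimulus effect + Gaussian
noise on the log2 scale (multiplicative on linear signals). Every draw
flows from one integer seed, and the returned :class:`SyntheticTruth`
records the noise-free expected log2 signal of every gene in every sample,
so downstream stages can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ConfigurationError, ExpressionMatrix, PipelineError

__all__ = [
    "SignatureSpec",
    "StimulusSpec",
    "MixtureDesign",
    "SyntheticTruth",
    "generate_reference_compendium",
    "generate_tissue_cohort",
    "example_signature",
    "example_stimuli",
    "two_group_design",
    "null_design",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BASELINE",
]

# Replicate-level log2 noise typical of expression arrays for well-expressed
# transcripts; the pairwise-frequency selection rule is calibrated for
# replicate-scale variability (see docs/methods.md).
DEFAULT_NOISE_SD = 0.15
DEFAULT_BASELINE = 7.0

_CELL_TYPE_POOL = (
    "macrophage",
    "fibroblast",
    "t_cell",
    "b_cell",
    "granulocyte",
    "endothelial",
    "nk_cell",
    "monocyte",
)


@dataclass(frozen=True)
class SignatureSpec:
    """Cell-type marker structure of the synthetic universe.

    ``marker_blocks`` maps each cell type to ``{gene_id: log2 offset}``;
    blocks must be disjoint across cell types. ``background_genes`` sit at
    the global baseline in every cell type.
    """

    cell_type_names: tuple[str, ...]
    marker_blocks: Mapping[str, Mapping[str, float]]
    global_baseline: float = DEFAULT_BASELINE
    noise_sd: float = DEFAULT_NOISE_SD
    background_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.cell_type_names:
            raise ConfigurationError("need at least one cell type")
        if set(self.marker_blocks) - set(self.cell_type_names):
            raise ConfigurationError("marker block for unknown cell type")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not np.isfinite(self.global_baseline):
            raise ConfigurationError("global_baseline must be finite")
        seen: set[str] = set(self.background_genes)
        for ct, block in self.marker_blocks.items():
            for gene, offset in block.items():
                if gene in seen:
                    raise ConfigurationError(
                        f"gene {gene!r} appears in more than one block"
                    )
                seen.add(gene)
                if not np.isfinite(offset):
                    raise ConfigurationError(f"non-finite offset for {gene!r}")

    @property
    def genes(self) -> list[str]:
        out = list(self.background_genes)
        for ct in self.cell_type_names:
            out.extend(self.marker_blocks.get(ct, {}))
        return out

    def profile_log2(self, cell_type: str) -> pd.Series:
        """Noise-free log2 profile of one cell type over all genes."""
        if cell_type not in self.cell_type_names:
            raise ConfigurationError(f"unknown cell type {cell_type!r}")
        prof = pd.Series(self.global_baseline, index=pd.Index(self.genes), dtype=float)
        for gene, offset in self.marker_blocks.get(cell_type, {}).items():
            prof[gene] += offset
        return prof


@dataclass(frozen=True)
class StimulusSpec:
    """A stimulation condition acting on one cell type.

    ``response`` maps gene IDs to signed log2 effect sizes applied when the
    stimulus is active (scaled by per-sample intensity in tissue mixtures).
    """

    name: str
    base_cell_type: str
    response: Mapping[str, float]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per arm")
        for gene, eff in self.response.items():
            if not np.isfinite(eff):
                raise ConfigurationError(f"non-finite effect for {gene!r}")


@dataclass(frozen=True)
class MixtureDesign:
    """Per-sample composition of a bulk-tissue cohort.

    ``fractions`` is samples x cell types (simplex rows); ``stimulus_intensity``
    is samples x stimulus names with entries in [0, 1]; ``groups`` labels each
    sample with its cohort arm.
    """

    fractions: pd.DataFrame
    stimulus_intensity: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        frac = self.fractions.to_numpy(dtype=float)
        if np.any(frac < 0) or not np.allclose(frac.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("fractions must be >= 0 and sum to 1 per sample")
        inten = self.stimulus_intensity.to_numpy(dtype=float)
        if inten.size and (np.any(inten < 0) or np.any(inten > 1)):
            raise ConfigurationError("stimulus intensities must lie in [0, 1]")
        if list(self.stimulus_intensity.index) != list(self.fractions.index):
            raise ConfigurationError("fraction and intensity tables must share samples")
        missing = [s for s in self.fractions.index if s not in self.groups.index]
        if missing:
            raise ConfigurationError(f"samples without group label: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to verify a synthetic cohort downstream."""

    signature: SignatureSpec
    stimuli: tuple[StimulusSpec, ...]
    design: MixtureDesign
    seed: int
    expected_log2: pd.DataFrame  # genes x samples, noise-free

    def expected_group_diff(self, experimental: str, baseline: str) -> pd.Series:
        """Noise-free expected log2 difference of group means (exp - base)."""
        groups = self.design.groups
        exp_cols = [s for s in self.expected_log2.columns if groups[s] == experimental]
        base_cols = [s for s in self.expected_log2.columns if groups[s] == baseline]
        if not exp_cols or not base_cols:
            raise PipelineError("unknown or empty group")
        return (
            self.expected_log2[exp_cols].mean(axis=1)
            - self.expected_log2[base_cols].mean(axis=1)
        )

    def differential_genes(
        self, experimental: str, baseline: str, min_abs_log2: float = 1.0
    ) -> pd.DataFrame:
        """Ground-truth DE genes: expected |log2 diff| >= ``min_abs_log2``.

        Returns a frame indexed by gene with ``expected_log2_diff`` and
        ``direction`` ('up'/'down').
        """
        diff = self.expected_group_diff(experimental, baseline)
        hit = diff[diff.abs() >= min_abs_log2]
        return pd.DataFrame(
            {
                "expected_log2_diff": hit,
                "direction": np.where(hit > 0, "up", "down"),
            }
        )


def _require_seed(seed) -> np.random.Generator:
    if seed is None or not isinstance(seed, (int, np.integer)):
        raise ConfigurationError("an integer seed is required; runs must be reproducible")
    return np.random.default_rng(int(seed))


def _check_stimuli(spec: SignatureSpec, stimuli: Sequence[StimulusSpec]) -> None:
    names = set()
    for stim in stimuli:
        if stim.base_cell_type not in spec.cell_type_names:
            raise ConfigurationError(
                f"stimulus {stim.name!r} targets unknown cell type "
                f"{stim.base_cell_type!r}"
            )
        if stim.name in names:
            raise ConfigurationError(f"duplicate stimulus name {stim.name!r}")
        names.add(stim.name)
        unknown = set(stim.response) - set(spec.genes)
        if unknown:
            raise ConfigurationError(
                f"stimulus {stim.name!r} responds on unknown genes: "
                f"{sorted(unknown)[:5]}"
            )


def generate_reference_compendium(
    spec: SignatureSpec,
    stimuli: Sequence[StimulusSpec],
    seed: int,
    n_control_replicates: int = 3,
):
    """Simulate replicated reference arrays for every condition.

    Each cell type gets one control arm of ``n_control_replicates`` arrays;
    each stimulus gets an arm of its own ``n_replicates`` arrays linked to
    the control arm of its base cell type (control arms are stored once
    even when several stimuli share them).

    Returns ``(ExpressionMatrix, metadata)`` where metadata has columns
    ``array_id, dataset_id, condition, cell_class, control_of``
    (``control_of`` names the control condition for stimulated arms, and is
    empty for control arms).
    """
    rng = _require_seed(seed)
    if n_control_replicates < 2:
        raise ConfigurationError("need >= 2 replicates per arm")
    _check_stimuli(spec, stimuli)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    genes = pd.Index(spec.genes)

    def add_arm(condition, cell_type, n_rep, expected_log2, control_of):
        for rep in range(1, n_rep + 1):
            array_id = f"{condition}_r{rep}"
            noise = rng.normal(0.0, spec.noise_sd, size=len(genes))
            columns[array_id] = np.exp2(expected_log2.to_numpy() + noise)
            meta_rows.append(
                {
                    "array_id": array_id,
                    "dataset_id": "synthetic",
                    "condition": condition,
                    "cell_class": cell_type,
                    "control_of": control_of,
                }
            )

    for ct in spec.cell_type_names:
        add_arm(f"{ct}_ctrl", ct, n_control_replicates, spec.profile_log2(ct), "")
    for stim in stimuli:
        expected = spec.profile_log2(stim.base_cell_type)
        for gene, eff in stim.response.items():
            expected[gene] += eff
        add_arm(
            stim.name,
            stim.base_cell_type,
            stim.n_replicates,
            expected,
            f"{stim.base_cell_type}_ctrl",
        )

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("array_id", drop=False)
    groups = meta["condition"]
    groups.index = meta.index
    expr = ExpressionMatrix(values, groups)
    return expr, meta


def generate_tissue_cohort(
    spec: SignatureSpec,
    stimuli: Sequence[StimulusSpec],
    design: MixtureDesign,
    seed: int,
):
    """Simulate a bulk-tissue cohort from a mixture design.

    Expected linear signal of gene g in sample s is

        sum_c fraction_{s,c} * 2**(baseline + offset_c(g) + sum_a w_{s,a} e_a(g))

    where the inner sum runs over stimuli a acting on cell type c, with
    per-sample intensity w in [0, 1] and signed log2 effect e. Gaussian
    log2 noise (``spec.noise_sd``) is then applied to the mixed signal.

    Returns ``(ExpressionMatrix, SyntheticTruth)``.
    """
    rng = _require_seed(seed)
    _check_stimuli(spec, stimuli)
    unknown_ct = set(design.fractions.columns) - set(spec.cell_type_names)
    if unknown_ct:
        raise ConfigurationError(f"design references unknown cell types: {sorted(unknown_ct)}")
    stim_by_name = {s.name: s for s in stimuli}
    unknown_stim = set(design.stimulus_intensity.columns) - set(stim_by_name)
    if unknown_stim:
        raise ConfigurationError(f"design references unknown stimuli: {sorted(unknown_stim)}")

    genes = pd.Index(spec.genes)
    base_linear = {
        ct: np.exp2(spec.profile_log2(ct).to_numpy()) for ct in design.fractions.columns
    }
    # per cell type, signed log2 effect vector of each stimulus acting on it
    effects_on: dict[str, list[tuple[str, np.ndarray]]] = {ct: [] for ct in base_linear}
    for name in design.stimulus_intensity.columns:
        stim = stim_by_name[name]
        if stim.base_cell_type in effects_on:
            vec = np.zeros(len(genes))
            for gene, eff in stim.response.items():
                vec[genes.get_loc(gene)] = eff
            effects_on[stim.base_cell_type].append((name, vec))

    expected_log2 = pd.DataFrame(index=genes, columns=design.sample_ids, dtype=float)
    for sample in design.sample_ids:
        mixed = np.zeros(len(genes))
        for ct, base in base_linear.items():
            frac = design.fractions.at[sample, ct]
            if frac == 0:
                continue
            shift = np.zeros(len(genes))
            for name, vec in effects_on[ct]:
                shift += design.stimulus_intensity.at[sample, name] * vec
            mixed += frac * base * np.exp2(shift)
        expected_log2[sample] = np.log2(mixed)

    noise = rng.normal(0.0, spec.noise_sd, size=expected_log2.shape)
    values = np.exp2(expected_log2 + noise)
    expr = ExpressionMatrix(values, design.groups.loc[design.sample_ids].copy())
    truth = SyntheticTruth(spec, tuple(stimuli), design, int(seed), expected_log2)
    return expr, truth


# ---------------------------------------------------------------------------
# Canonical study-condition builders. These encode the default fixtures:
# a small reference panel of purified cell types (a few replicates per arm)
# and a two-arm tissue cohort of 10 vs 10 mixed samples.
# ---------------------------------------------------------------------------


def example_signature(
    n_cell_types: int = 3,
    markers_per_type: int = 40,
    n_background: int = 80,
    offset_range: tuple[float, float] = (2.0, 5.0),
    global_baseline: float = DEFAULT_BASELINE,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SignatureSpec:
    """Deterministic signature: disjoint marker blocks with graded offsets."""
    if n_cell_types > len(_CELL_TYPE_POOL):
        raise ConfigurationError(f"at most {len(_CELL_TYPE_POOL)} cell types supported")
    cell_types = _CELL_TYPE_POOL[:n_cell_types]
    offsets = np.linspace(offset_range[0], offset_range[1], markers_per_type)
    blocks = {
        ct: {
            f"{ct.upper()}_{i:03d}": float(offsets[i])
            for i in range(markers_per_type)
        }
        for ct in cell_types
    }
    background = tuple(f"BG_{i:04d}" for i in range(n_background))
    return SignatureSpec(cell_types, blocks, global_baseline, noise_sd, background)


def example_stimuli(
    spec: SignatureSpec,
    genes_per_stimulus: int = 30,
    effect_range: tuple[float, float] = (1.0, 4.0),
    n_replicates: int = 3,
    negative_every: int = 4,
) -> list[StimulusSpec]:
    """One stimulus per cell type, responding on that cell type's markers.

    Effect magnitudes are graded over ``effect_range``; every
    ``negative_every``-th response gene is down-regulated. Response gene
    sets are disjoint across stimuli (each lives inside its own cell
    type's marker block), so stimuli act as mutual decoys.
    """
    magnitudes = np.linspace(effect_range[0], effect_range[1], genes_per_stimulus)
    out = []
    for ct in spec.cell_type_names:
        block_genes = list(spec.marker_blocks.get(ct, {}))
        if len(block_genes) < genes_per_stimulus:
            raise ConfigurationError(
                f"cell type {ct!r} has too few markers for {genes_per_stimulus} "
                "response genes"
            )
        response = {}
        for i in range(genes_per_stimulus):
            sign = -1.0 if negative_every and (i + 1) % negative_every == 0 else 1.0
            response[block_genes[i]] = sign * float(magnitudes[i])
        out.append(StimulusSpec(f"{ct}_activation", ct, response, n_replicates))
    return out


def _balanced_fractions(cell_types: Sequence[str], dominant: str | None) -> dict:
    if dominant is None:
        return {ct: 1.0 / len(cell_types) for ct in cell_types}
    rest = [ct for ct in cell_types if ct != dominant]
    out = {ct: 0.5 / len(rest) for ct in rest} if rest else {}
    out[dominant] = 1.0 if not rest else 0.5
    return out


def two_group_design(
    spec: SignatureSpec,
    stimulus: StimulusSpec,
    n_per_group: int = 10,
    intensity: float = 1.0,
    group_names: tuple[str, str] = ("disease", "control"),
) -> MixtureDesign:
    """10 vs 10 style cohort: one arm carries ``stimulus`` at ``intensity``.

    Both arms share the same cell-type composition (the stimulated cell
    type holds half the tissue); only stimulus activity differs, so the
    ground-truth DE set is exactly the stimulus response (diluted by
    mixing).
    """
    fracs = _balanced_fractions(spec.cell_type_names, stimulus.base_cell_type)
    samples = [f"{group_names[0]}_{i:02d}" for i in range(1, n_per_group + 1)] + [
        f"{group_names[1]}_{i:02d}" for i in range(1, n_per_group + 1)
    ]
    fractions = pd.DataFrame([fracs] * len(samples), index=samples)
    inten = pd.DataFrame(0.0, index=samples, columns=[stimulus.name])
    inten.loc[[s for s in samples if s.startswith(group_names[0])], stimulus.name] = intensity
    groups = pd.Series(
        [group_names[0]] * n_per_group + [group_names[1]] * n_per_group, index=samples
    )
    return MixtureDesign(fractions, inten, groups)


def null_design(
    spec: SignatureSpec,
    n_per_group: int = 10,
    group_names: tuple[str, str] = ("a", "b"),
) -> MixtureDesign:
    """Two arms with identical composition and no active stimuli."""
    fracs = _balanced_fractions(spec.cell_type_names, None)
    samples = [f"{group_names[0]}_{i:02d}" for i in range(1, n_per_group + 1)] + [
        f"{group_names[1]}_{i:02d}" for i in range(1, n_per_group + 1)
    ]
    fractions = pd.DataFrame([fracs] * len(samples), index=samples)
    inten = pd.DataFrame(index=pd.Index(samples), columns=pd.Index([], dtype=object))
    groups = pd.Series(
        [group_names[0]] * n_per_group + [group_names[1]] * n_per_group, index=samples
    )
    return MixtureDesign(fractions, inten, groups)
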