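import numpy as np
import pandas as pd
import pytest

import refpattern as rp


@pytest.fixture()
def toy_expr():
    """5 genes x (3 disease + 3 control); gene G1 shifted x4 in disease."""
    rng = np.random.default_rng(42)
    base = rng.uniform(50, 200, size=(5, 1))
    values = np.tile(base, (1, 6))
    values[0, :3] *= 4.0  # G1 up in disease, noise-free
    samples = [f"d{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
    df = pd.DataFrame(values, index=[f"G{i+1}" for i in range(5)], columns=samples)
    groups = pd.Series(["disease"] * 3 + ["control"] * 3, index=samples)
    return rp.ExpressionMatrix(df, groups)


@pytest.fixture()
def random_expr():
    """10 genes x (4+4) random positive matrix for oracle comparisons."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        np.exp2(rng.normal(8, 1.5, size=(10, 8))),
        index=[f"P{i:02d}" for i in range(10)],
        columns=[f"e{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
    )
    groups = pd.Series(["E"] * 4 + ["B"] * 4, index=values.columns)
    return rp.ExpressionMatrix(values, groups)


@pytest.fixture(scope="session")
def default_study():
    """Canonical synthetic study: signature, stimuli, 10v10 design, cohort."""
    sig = rp.example_signature()
    stimuli = rp.example_stimuli(sig)
    design = rp.two_group_design(sig, stimuli[0])
    cohort, truth = rp.generate_tissue_cohort(sig, stimuli, design, seed=11)
    return {
        "signature": sig,
        "stimuli": stimuli,
        "design": design,
        "cohort": cohort,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_compendium():
    sig = rp.example_signature()
    stimuli = rp.example_stimuli(sig)
    expr, meta = rp.generate_reference_compendium(sig, stimuli, seed=5)
    return rp.Compendium(expr, meta)
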