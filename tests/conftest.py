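import numpy as np
import pandas as pd
import pytest

from glyconet import ExpressionMatrix, SampleDesign


@pytest.fixture
def toy_registry_dir(tmp_path):
    """Minimal valid registry: 2 genes, 2 reactions, 1 epitope."""
    d = tmp_path / "registry"
    d.mkdir()
    (d / "glyco_genes.tsv").write_text("E1\tenzyme\nE2\tenzyme\n")
    (d / "glyco_reactions.tsv").write_text(
        "r1\tE1\tGal\tGalNAc\tp1\nr2\tE2\tFuc\tGal\tp2\n"
    )
    (d / "glyco_epitopes.tsv").write_text("X1\ttoy epitope\tr1;r2\n")
    return d


@pytest.fixture
def tmm_fixture_matrix():
    """Deterministic 60x4 count matrix with composition bias in two samples.

    The expected TMM factors for this exact matrix were computed once with
    edgeR::calcNormFactors (method="TMM") and are frozen in the test that
    uses this fixture.
    """
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(10, 10 / (10 + 100), size=(60, 4))
    counts[:, 2] = counts[:, 2] * 3
    counts[:10, 3] = counts[:10, 3] * 8
    df = pd.DataFrame(
        counts.astype(float), index=[f"g{i}" for i in range(60)], columns=list("ABCD")
    )
    return ExpressionMatrix(df)


@pytest.fixture
def small_log_matrix():
    """4 genes x 6 samples on log2 scale with one clear case/control split."""
    rng = np.random.default_rng(1)
    base = rng.normal(5.0, 0.3, size=(4, 6))
    base[0, :3] += 3.0  # strong case-shifted gene
    df = pd.DataFrame(
        base,
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    design = SampleDesign(
        {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}, "control"
    )
    return ExpressionMatrix(df, scale="log2"), design
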