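import numpy as np
import pytest

from metamir.dataio import ExpressionStudy, StudyCollection


def make_study(
    rng: np.random.Generator,
    study_id: str = "s1",
    n_genes: int = 20,
    n_cases: int = 4,
    n_controls: int = 4,
    gene_ids=None,
) -> ExpressionStudy:
    """Random null study on the log2 scale."""
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)]
    n = n_cases + n_controls
    return ExpressionStudy(
        study_id=study_id,
        matrix=rng.normal(7.0, 1.0, size=(len(genes), n)),
        gene_ids=list(genes),
        sample_ids=[f"{study_id}_x{i}" for i in range(n)],
        group=["case"] * n_cases + ["control"] * n_controls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_study():
    """3 genes x (3 cases + 3 controls), fixed values."""
    return ExpressionStudy(
        study_id="toy",
        matrix=np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                [5.0, 5.5, 6.0, 5.0, 5.5, 6.0],
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            ]
        ),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=[f"x{i}" for i in range(6)],
        group=["case"] * 3 + ["control"] * 3,
    )


@pytest.fixture
def null_collection(rng):
    genes = [f"g{i}" for i in range(30)]
    return StudyCollection(
        [make_study(rng, f"s{k}", gene_ids=genes) for k in range(1, 5)]
    )
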