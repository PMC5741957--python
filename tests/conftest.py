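import numpy as np
import pandas as pd
import pytest

from droughtgenes import GeneModel, PipelineConfig
from droughtgenes.expression import ExpressionMatrix


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_annotation() -> list[GeneModel]:
    """Three well-separated genes on one chromosome, mixed strands."""
    return [
        GeneModel.from_exons("gA", "chr1", [(100, 200)], "+"),
        GeneModel.from_exons("gB", "chr1", [(500, 600), (700, 800)], "-"),
        GeneModel.from_exons("gC", "chr1", [(1200, 1500)], "+"),
    ]


def make_matrix(
    rows, n_drought=None, n_control=None, genes=None, tissues=("root",)
) -> ExpressionMatrix:
    """Expression fixture: rows is genes x samples; drought columns first."""
    arr = np.asarray(rows, dtype=float)
    total = arr.shape[1]
    if n_drought is None:
        n_drought = total // 2
    if n_control is None:
        n_control = total - n_drought
    cols, meta_rows = [], []
    for treatment, n in (("drought", n_drought), ("control", n_control)):
        per_tissue = max(1, n // len(tissues))
        i = 0
        for tissue in tissues:
            for _ in range(per_tissue):
                if i >= n:
                    break
                sid = f"{treatment}_{tissue}_{i + 1}"
                cols.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "treatment": treatment, "tissue": tissue}
                )
                i += 1
        while i < n:
            sid = f"{treatment}_{tissues[-1]}_{i + 1}"
            cols.append(sid)
            meta_rows.append(
                {"sample_id": sid, "treatment": treatment, "tissue": tissues[-1]}
            )
            i += 1
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cols), meta)
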