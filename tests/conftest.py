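import numpy as np
import pandas as pd
import pytest

from ddgeval.data import PredictorConvention, VariantDataset


def make_dataset(rows, panel=None, harmonized=False):
    """Build a VariantDataset from (variant_id, gene, label, {pred: val}) tuples."""
    predictor_names = sorted({name for *_, ddg in rows for name in ddg})
    if panel is None:
        panel = [PredictorConvention(name) for name in predictor_names]
    frame = pd.DataFrame(
        {
            "variant_id": [r[0] for r in rows],
            "gene": [r[1] for r in rows],
            "label": [r[2] for r in rows],
        }
    )
    for conv in panel:
        frame[conv.name] = [r[3].get(conv.name, np.nan) for r in rows]
    return VariantDataset(frame=frame, panel=list(panel), harmonized=harmonized)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def variant_tsv(tmp_path):
    """Write a small variant table; returns (path, column_map)."""

    def _write(lines, name="variants.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    return _write
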