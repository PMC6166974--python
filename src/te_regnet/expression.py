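"""Gene-by-sample expression container on the TPM scale.

The container carries TPM values (genes x samples) together with a tissue
label per sample.  All downstream statistics (relative coexpression,
rank-product differential expression, TF filtering) consume this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "sqrt_transform"]

TPM_SUM = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample tissue labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values, index = gene ids, columns = sample
        ids.  Usually TPM (columns sum to 1e6) or its square-root transform.
    tissue_of_sample : pandas.Series
        Tissue label per sample id; must cover every column of ``values``.
    """

    values: pd.DataFrame
    tissue_of_sample: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.tissue_of_sample = pd.Series(self.tissue_of_sample)
        missing = [s for s in self.values.columns if s not in self.tissue_of_sample.index]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        self.tissue_of_sample = self.tissue_of_sample.loc[list(self.values.columns)]
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue labels, in first-appearance order."""
        return list(dict.fromkeys(self.tissue_of_sample))

    def samples_of_tissue(self, tissue: str) -> list[str]:
        hits = [s for s, t in self.tissue_of_sample.items() if t == tissue]
        if not hits:
            raise KeyError(f"unknown tissue {tissue!r}")
        return hits

    def tissue_profile(self, tissue: str) -> pd.Series:
        """Per-gene mean over the tissue's samples."""
        return self.values[self.samples_of_tissue(tissue)].mean(axis=1)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.tissue_of_sample)


def sqrt_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise square root of TPM; variance-stabilising transform
    applied before computing between-tissue correlations."""
    arr = expr.values.to_numpy()
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"cannot sqrt-transform negative value at gene "
            f"{expr.values.index[g]!r}, sample {expr.values.columns[s]!r}"
        )
    return ExpressionMatrix(np.sqrt(expr.values), expr.tissue_of_sample)
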