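"""Variable-gene selection, recomputed at every pipeline iteration.

Genes are grouped into expression-level bins and a gene is called variable
when its dispersion (variance / mean) stands out among genes of comparable
mean expression. Binning is by equal gene count (quantile bins) on the mean,
the precedent for this dispersion-z-score procedure; ties are broken by gene
order. Dispersion z-scores use the population (n) denominator within each
bin, and a bin with a single gene (or zero spread) contributes z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError
from .matrix_io import ExpressionMatrix

__all__ = ["VariableGeneParams", "select_variable_genes"]


@dataclass(frozen=True)
class VariableGeneParams:
    """Knobs of the dispersion-based variable-gene selector.

    zscore_cut
        Within-bin dispersion z-score above which a gene is variable
        (default 1.5).
    gene_low
        Minimum mean expression; lower-expressed genes are excluded
        (default 0.5, in the units of the input matrix).
    n_expression_bins
        Number of mean-expression bins (20; shrinks automatically when
        fewer eligible genes remain in a late iteration).
    log1p
        Compute means/dispersions on log1p-transformed values.
    """

    zscore_cut: float = 1.5
    gene_low: float = 0.5
    n_expression_bins: int = 20
    log1p: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.zscore_cut):
            raise ValueError("zscore_cut must be finite")
        if self.gene_low < 0:
            raise ValueError("gene_low must be >= 0")
        if self.n_expression_bins < 1:
            raise ValueError("n_expression_bins must be >= 1")


def select_variable_genes(
    E: ExpressionMatrix, params: VariableGeneParams | None = None
) -> np.ndarray:
    """Return (ascending) indices of variable genes of ``E``.

    A gene is selected when its mean expression is >= ``gene_low`` and its
    within-bin z-normalized dispersion exceeds ``zscore_cut``. An empty
    result signals the iterative engine to terminate.
    """
    params = params or VariableGeneParams()
    if E.n_cells == 0:
        raise DegenerateInputError("expression matrix has zero cells")
    V = np.log1p(E.values) if params.log1p else E.values
    mean = V.mean(axis=1)
    # dispersion is undefined at mean 0; such genes are dropped regardless
    # of gene_low
    eligible = np.flatnonzero((mean >= params.gene_low) & (mean > 0))
    if eligible.size == 0:
        return np.array([], dtype=int)
    var = V[eligible].var(axis=1)
    disp = var / mean[eligible]

    n_bins = min(params.n_expression_bins, eligible.size)
    order = np.argsort(mean[eligible], kind="stable")
    selected: list[int] = []
    for bin_members in np.array_split(order, n_bins):
        d = disp[bin_members]
        sd = d.std()  # population denominator
        # bins whose dispersions are equal up to float noise carry no signal
        if bin_members.size < 2 or sd <= 1e-12 * max(abs(d.mean()), 1.0):
            continue
        z = (d - d.mean()) / sd
        selected.extend(eligible[bin_members[z > params.zscore_cut]])
    return np.sort(np.array(selected, dtype=int))
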